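# Methods

## The model of irregular irregularity

A heart rhythm is *irregular* when consecutive RR intervals change, and
*irregularly irregular* when those changes are themselves random. The MESC
of order n is the n-fold iterated first difference of the RR series
(order 0 = the RR intervals, order 1 = successive differences); it is a
measure of short-term change, near zero for metronomic rhythms and large
for disordered ones. Two window statistics operationalize the definition:

- **Variability** — the width of the windowed MESC distribution. Implemented
  as the sample standard deviation (ddof = 1); an interquartile-range
  estimator is available behind `variability_estimator="iqr"` for
  robustness studies. Units: seconds. Scale-equivariant
  (`variability(c·x) = |c|·variability(x)`).
- **Normality** — the windowed MESC values are standardized by their own
  sample mean and SD and compared to the standard normal by the
  Kolmogorov–Smirnov distance D; the index is 1 − D ∈ [0, 1]. It is
  invariant under affine rescaling of the MESC and under permutation of
  the window. The rationale: ventricular response in AF is a summation of
  many stochastic influences (chaotic atrial input, disordered AV-node
  conduction), so its MESC is approximately normal, whereas regular
  irregularities (bigeminy, trigeminy, AV block, premature complexes) are
  superpositions of a few regular rhythms whose pooled MESC is strongly
  multi-modal. No small-sample correction (e.g. Lilliefors) is applied:
  the index is a bounded feature, not a hypothesis test with a stated α.
- **Mean** — the mean RR interval of the window (mean of the order-0
  MESC), addressing AF's tachycardic tendency.

A window with zero MESC variance is a perfectly regular rhythm — the
extreme opposite of irregular irregularity — and is assigned variability 0
and normality 0 by convention. The zero-variance test uses the data range
(`ptp == 0`) rather than the computed SD, so floating-point rounding of a
constant window cannot leak a spurious positive SD.

## Windowing

Estimation windows are runs of consecutive RR intervals addressed by
0-based half-open beat ranges. Defaults: window length 150 beats, MESC
order 1, stride 30 beats (5× overlap, balancing temporal resolution
against cost; windows down to 70 beats remain usable). Windows are
labeled over their time span against the rhythm segments: wholly inside
AF → "AF", wholly inside non-AF rhythms → "non-AF", spanning a rhythm
boundary (or outside all annotations) → "ambiguous" and excluded from all
downstream computation, since such windows mix distributions from two
rhythms. Boundary-touching windows (window edge exactly at a segment
edge, within 1 ns) are not considered spanning.

## Kolmogorov–Smirnov statistics

`ks_statistic_exact` evaluates the one-sample statistic
D = supₓ |Fₙ(x) − F(x)| at the sorted sample points from both sides
(O(n log n) for the sort). `ks_statistic_fast` is a single-pass binned
estimator: each point is assigned to one of m equal-probability bins of
the reference distribution by one CDF evaluation (no sorting), and the
empirical CDF is compared to the reference at the m − 1 interior bin
edges. At those edges the empirical CDF is exact, and within a bin both
CDFs are monotone and change by at most the bin probability 1/m, so
D_fast ≤ D_exact ≤ D_fast + 1/m. Default grid m = 32 (error ≤ 0.031,
small against the observed class separation); the property suite verifies
the bound on normal, bimodal and uniform samples, n = 70–300.

## Regularogram and AF burden

The RGG is one point per non-ambiguous window, x = variability,
y = normality (z = mean RR in the 3-D variant). AF burden is estimated as
the fraction of non-ambiguous windows whose (variability, normality)
falls inside a closed user-specified rectangle. The denominator is the
window count, matching how the estimate is compared against per-window
annotations; a time-weighted variant (each window weighted by its time
span) is available behind a flag. Rectangle boundaries are inclusive so a
rectangle snapped to data extremes contains them. Rendering pins the SVG
hash salt and strips timestamp metadata, so identical data and options
give byte-identical files.

## Classifier and evaluation protocols

The detector is an axis-aligned binary decision tree over (variability,
normality, mean RR) — non-linear enough to demarcate the curved zone
boundary, and fully explainable: each split is one axis-parallel line in
the RGG space. Growth is best-first under Gini impurity with a cap of 30
internal splits (a k-split binary tree has k + 1 leaves, so the cap is
enforced through `max_leaf_nodes = k + 1`), minimum leaf size 1, no
pruning. Fitting is delegated to scikit-learn's `DecisionTreeClassifier`
with a fixed `random_state`, making training deterministic on identical
input; the fitted structure is exported to the package's own JSON node
arrays, and prediction is a plain threshold-traversal of that structure,
independent of scikit-learn at inference time.

Metrics are computed in exact integer arithmetic from the confusion
counts: Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), ACC = (TP+TN)/total, F1 = 2TP/(2TP+FP+FN). A metric
whose denominator is zero is reported as absent rather than 0 or NaN —
for an all-negative cohort (pure sinus-rhythm recordings) only
specificity and accuracy are defined.

Three protocols:

- **Record-level cross-validation** selects the (MESC order, window
  length) pair. Whole records are assigned to folds, so no record
  contributes windows to both sides of a fold (window-level splitting
  would leak patient identity). Because the hyperparameters being varied
  *are* the indexing parameters, the routine takes raw (RR, segments)
  records and recomputes indices per grid cell. Runner-up cells are
  compared to the best by a one-tailed unpaired t-test over fold
  accuracies (significant at p < 0.05); two cells with identical fold
  vectors give t = 0, one-tailed p = 0.5.
- **Patient-to-self** answers whether an AF region exists per patient:
  within each record, the chronologically first 70% of windows train the
  tree and the rest are held out, sweeping the split cap. Records whose
  training part lacks a class are skipped and reported. The chronological
  (rather than random) split avoids interleaving nearly identical
  overlapping windows across the train/test boundary.
- **Cross-cohort** trains one tree on a full named cohort and tests on
  cohorts with disjoint record ids (enforced); the model's re-evaluation
  on its own training windows is reported but flagged optimistic.

## Synthetic data

The generator targets the distributional structure the indices assume,
not electrophysiology:

- **AF**: RRᵢ₊₁ = RRᵢ − r·(RRᵢ − μ) + N(0, σ), reversion r = 0.05 per
  beat, default μ = 0.55 s, σ = 0.08 s, clipped to [0.25, 2.5] s. The
  order-1 MESC is then ≈ N(0, σ) — wide and normal — while reversion
  keeps RR physiologic (a pure random walk drifts out of range). At the
  defaults ~4.5% of beats touch the clip bounds, the realized MESC SD is
  within 2% of σ and the median window normality is ≈ 0.95.
- **NSR**: μ + A·sin(2πi/P) + N(0, σ_j); defaults A = 0.02 s, P = 5
  beats (respiratory sinus arrhythmia), σ_j = 0.01 s, μ = 0.85 s.
- **Bigeminy/trigeminy**: period-2/period-3 short–long patterns
  (defaults 0.5/1.0 s) plus jitter; the order-1 MESC alternates ±0.5 s,
  giving variability ≈ 0.25–0.5 s with normality ≈ 0.66 — wide but
  decidedly non-normal.
- **AV block**: sinus rhythm with beats dropped at a given probability, a
  dropped beat merging its two intervals; **PAC**: premature interval
  (coupling fraction × μ) followed by a compensatory pause conserving the
  two-beat cycle.

Cohorts draw per-patient parameters (AF μ ∈ [0.45, 0.80] s vs sinus
μ ∈ [0.70, 1.00] s — overlapping on purpose, because mean rate must not
be a clean AF separator; AF σ ∈ [0.05, 0.12] s; sinus A, P, σ_j ranges
around the defaults) and interleave 2–4 AF episodes with sinus runs,
optionally seeding minority bigeminy/trigeminy/AV-block/PAC runs into the
non-AF time. Those ranges imply an irregular-irregularity zone of
variability ≥ 0.045 s (sinus stays below ≈ 0.04 s) and normality ≥ 0.85,
exported as `synth.AF_ZONE` and used as the "marked rectangle" in the
burden experiment.

What the generator does *not* emulate: annotation noise and beat-detection
artifacts, gradual AF onset/offset (transitions are abrupt), atrial
flutter with variable conduction (which genuinely mimics AF in RR data),
circadian non-stationarity, and ectopy *within* AF episodes. Passing the
synthetic experiments therefore demonstrates internal correctness of the
indices and protocols under the assumed model — not clinical performance
on Holter recordings, for which external annotated databases remain
necessary.

## Experiment sizes and numerical choices

The packaged experiments use 20-record cohorts of ~6,000 beats
(~75–90 min of rhythm each), giving ~170 non-ambiguous windows per record
— enough for every protocol while keeping the whole study in seconds. The
patient-to-self experiment uses pure sinus/AF paroxysmal records: with
records this short, a single minority-rhythm run can fall entirely inside
the 30% holdout, which would measure extrapolation to a rhythm the tree
never saw rather than the existence of the patient's AF region; the
mixed-rhythm cohorts are used everywhere else. All randomness flows from
explicit seeds through `numpy.random.default_rng`; ties in tree training
are fixed by the seeded splitter, and the hyperparameter selection breaks
exact mean-accuracy ties toward the smaller order and window.

## Known limitations

- Normality compares against a normal with *estimated* location/scale but
  uses uncorrected KS distances; as a feature this is harmless, but the
  values are not calibrated p-values.
- The burden rectangle is supplied by the user (or taken from
  `synth.AF_ZONE` for synthetic cohorts); the interactive marking of a
  plotted RGG is out of scope.
- `patient_to_self` and `cross_database` consume precomputed index tables
  and therefore fix the indexing hyperparameters; only `cross_validate`
  re-derives indices from RR data.
- RR series are consumed as annotated: no ectopic-beat filtering or
  interval cleaning is applied before indexing.
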