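# regularogram

Quantify, visualize and detect the *irregular irregularity* of atrial
fibrillation (AF) from RR-interval series.

AF is clinically described as an irregularly irregular rhythm: not only do
the inter-beat (RR) intervals vary, the beat-to-beat *changes* themselves
are random. This package turns that description into three per-window
indices, a whole-recording visualization, and an explainable classifier:

- **MESC** (modified entropy scale) of order *n*: the *n*-fold iterated
  first difference of the RR series; order 0 is the RR series itself,
  order 1 is the successive difference ΔRRᵢ = RRᵢ₊₁ − RRᵢ.
- **Variability**: the distribution width (sample SD) of the MESC within a
  fixed-length estimation window (default 150 beats) — high for *any*
  irregular rhythm.
- **Normality**: 1 − D, where D is the Kolmogorov–Smirnov distance between
  the window's standardized MESC values and the standard normal — high only
  when the rate changes are *random*. A bigeminy's MESC is wide but
  bimodal (a superposition of a few regular rhythms), so its normality is
  low; AF's MESC is wide *and* near-normal.
- **Mean**: the window's mean RR interval, capturing AF's tachycardic
  tendency.
- **Regularogram (RGG)**: a scatter of per-window (variability, normality)
  points for a whole recording. AF windows cluster in the
  high-variability/high-normality "irregular irregularity zone"; marking
  that zone with a rectangle and counting the windows inside estimates the
  **AF burden**.
- **Detector**: an axis-aligned decision tree over the three indices,
  capped at 30 splits for explainability, with clinical metrics
  (Se/Sp/PPV/NPV/ACC/F1) and record-level validation protocols.

A seeded synthetic generator produces AF (mean-reverting Gaussian random
walk on RR), sinus rhythm, bigeminy/trigeminy, AV-block and premature-beat
records with ground-truth rhythm segments, so the whole pipeline is
testable without downloading Holter databases. Beat and rhythm annotations
in the MIT/PhysioNet binary format, or plain CSV, are read directly.

## Worked example

```python
import numpy as np
import regularogram as rg

# a paroxysmal record: sinus rhythm, an AF episode, sinus rhythm again
rec = rg.gen_record([(rg.NSR_PROFILE, 1200), (rg.AF_PROFILE, 600),
                     (rg.NSR_PROFILE, 1200)], seed=11)

idx = rg.compute_indices(rec.rr, rec.segments, rg.IndexConfig())
af  = [r for r in idx if r.label == "AF"]
nsr = [r for r in idx if r.label == "non-AF"]
print(f"{len(idx)} unambiguous windows "
      f"({len(af)} AF, {len(nsr)} non-AF)")
print(f"AF : variability {np.median([r.variability for r in af]):.3f} s, "
      f"normality {np.median([r.normality for r in af]):.3f}")
print(f"NSR: variability {np.median([r.variability for r in nsr]):.3f} s, "
      f"normality {np.median([r.normality for r in nsr]):.3f}")

rect = rg.ZoneRect(0.045, 0.40, 0.85, 1.0)      # irregular irregularity zone
print(f"burden estimate {100 * rg.estimate_burden(idx, rect):.1f}% "
      f"(truth {100 * rec.af_window_fraction():.1f}%)")
```

prints

```
88 unambiguous windows (16 AF, 72 non-AF)
AF : variability 0.077 s, normality 0.941
NSR: variability 0.022 s, normality 0.947
burden estimate 18.2% (truth 18.2%)
```

The AF windows are ~3.5× wider in MESC distribution than sinus windows at
equally high normality, so they sit alone in the zone rectangle and the
window-fraction inside it reproduces the annotated burden. (Both rhythms
score high on normality here because this synthetic sinus rhythm has
Gaussian jitter; what puts a window in the zone is the *conjunction* of
high variability and high normality, and patterned irregularities such as
bigeminy fail on the normality axis instead.)

The same pipeline is available from the shell:

```sh
regularogram simulate --profile af_paroxysmal --beats 20000 --seed 7 --out rec.csv
regularogram indices --beats rec.csv --segments rec.csv.segments.csv --out idx.csv
regularogram rgg --input idx.csv --out rgg.svg --rect 0.045,0.4,0.85,1.0
regularogram burden --input idx.csv --rect 0.045,0.4,0.85,1.0
regularogram train --indices idx.csv --out model.json
regularogram eval --model model.json --indices idx.csv --report report.json
```

Every command writes a `*.manifest.json` with the resolved configuration,
seed and SHA-256 digests of its inputs and outputs; identical seed and
configuration reproduce identical artifacts byte for byte.

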