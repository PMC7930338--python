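"""Seeded synthetic RR-interval generator with ground-truth rhythm segments.

The generator targets the distributional structure the irregularity
indices assume, not electrophysiological realism:

* **AF** — ventricular response modeled as a clipped, mean-reverting
  Gaussian random walk on RR: the order-1 MESC (successive difference) is
  then approximately Normal(0, mesc_sd), i.e. wide *and* normal — the
  irregular irregularity signature — while mean reversion keeps RR
  physiologic.  AF runs fast (default mean RR 0.55 s vs 0.85 s in sinus
  rhythm), exercising the mean index.
* **NSR** — a respiratory sinus-arrhythmia sinusoid plus small Gaussian
  jitter: narrow MESC.
* **bigeminy / trigeminy** — strict period-2/period-3 alternation of short
  and long intervals plus jitter: a superposition of a few regular rhythms
  whose MESC is wide but bimodal, hence decidedly non-normal.
* **av_block** — sinus rhythm with random beat drops (a dropped beat merges
  its two intervals); **pac** — sinus rhythm with premature beats followed
  by a compensatory pause.

All intervals are clipped to [0.25, 2.5] s.  Everything is deterministic
per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RhythmSegment, RRSeries

__all__ = ["RhythmProfile", "SyntheticRecord", "gen_segment", "gen_record",
           "gen_cohort", "AF_PROFILE", "NSR_PROFILE", "BIGEMINY_PROFILE"]

RR_MIN, RR_MAX = 0.25, 2.5

#: The irregular-irregularity zone implied by the cohort generator's
#: parameter ranges: AF walk SDs of 0.05-0.12 s put AF variability above
#: 0.045 s (sinus rhythm stays below ~0.04 s), and the near-normal AF MESC
#: keeps normality above 0.85 (patterned rhythms fall well below).
AF_ZONE = (0.045, 0.40, 0.85, 1.0)  # (v_min, v_max, n_min, n_max)
AF_REVERSION = 0.05  # mean-reversion coefficient per beat of the AF walk

KINDS = ("AF", "NSR", "bigeminy", "trigeminy", "av_block", "pac")


@dataclass(frozen=True)
class RhythmProfile:
    """Parameters of one rhythm kind; ``params`` keys are kind-specific."""

    kind: str
    mean_rr: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown rhythm kind {self.kind!r}")
        if not 0.3 <= self.mean_rr <= 2.0:
            raise ValueError("mean_rr must lie in [0.3, 2.0] s")
        for key in ("mesc_sd", "jitter_sd", "resp_amplitude"):
            if self.params.get(key, 0.0) < 0:
                raise ValueError(f"{key} must be non-negative")
        for key in ("drop_probability", "pac_rate", "coupling_fraction"):
            if not 0.0 <= self.params.get(key, 0.0) <= 1.0:
                raise ValueError(f"{key} must lie in [0, 1]")


AF_PROFILE = RhythmProfile("AF", mean_rr=0.55, params={"mesc_sd": 0.08})
NSR_PROFILE = RhythmProfile("NSR", mean_rr=0.85,
                            params={"resp_amplitude": 0.02,
                                    "resp_period_beats": 5.0,
                                    "jitter_sd": 0.01})
BIGEMINY_PROFILE = RhythmProfile("bigeminy", mean_rr=0.75,
                                 params={"short_rr": 0.5, "long_rr": 1.0,
                                         "jitter_sd": 0.01})


@dataclass(frozen=True)
class SyntheticRecord:
    rr: RRSeries
    segments: list[RhythmSegment]
    profile_sequence: tuple
    seed: int

    def af_window_fraction(self, window_length: int = 150, stride: int = 30) -> float:
        """Ground-truth AF fraction among non-ambiguous estimation windows."""
        from .mesc import AMBIGUOUS, label_windows, make_windows
        labeled = [w for w in label_windows(
            make_windows(self.rr, window_length, stride), self.segments)
            if w.label != AMBIGUOUS]
        if not labeled:
            return float("nan")
        return sum(w.label == "AF" for w in labeled) / len(labeled)


def _nsr_like(profile: RhythmProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    amp = profile.params.get("resp_amplitude", 0.02)
    period = profile.params.get("resp_period_beats", 5.0)
    jitter = profile.params.get("jitter_sd", 0.01)
    i = np.arange(n)
    rr = profile.mean_rr + amp * np.sin(2 * np.pi * i / period)
    if jitter > 0:
        rr = rr + rng.normal(0.0, jitter, size=n)
    return rr


def gen_segment(profile: RhythmProfile, n_beats: int, seed) -> np.ndarray:
    """Generate one homogeneous run of RR intervals (seconds)."""
    if n_beats < 2:
        raise ValueError("n_beats must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    kind = profile.kind

    if kind == "AF":
        sd = profile.params.get("mesc_sd", 0.08)
        steps = rng.normal(0.0, sd, size=n_beats)
        rr = np.empty(n_beats)
        x = profile.mean_rr
        for i in range(n_beats):
            x = x - AF_REVERSION * (x - profile.mean_rr) + steps[i]
            x = min(max(x, RR_MIN), RR_MAX)
            rr[i] = x
    elif kind == "NSR":
        rr = _nsr_like(profile, n_beats, rng)
    elif kind in ("bigeminy", "trigeminy"):
        short = profile.params.get("short_rr", 0.5)
        long = profile.params.get("long_rr", 1.0)
        jitter = profile.params.get("jitter_sd", 0.01)
        period = 2 if kind == "bigeminy" else 3
        # one short (post-ectopic) interval per cycle, the rest long
        pattern = np.array([short] + [long] * (period - 1))
        rr = np.tile(pattern, n_beats // period + 1)[:n_beats].astype(float)
        if jitter > 0:
            rr = rr + rng.normal(0.0, jitter, size=n_beats)
    elif kind == "av_block":
        p = profile.params.get("drop_probability", 0.1)
        base = _nsr_like(profile, 2 * n_beats, rng)
        keep = rng.random(2 * n_beats) >= p
        keep[0] = True
        # a dropped beat merges its interval into the following one
        rr_list: list[float] = []
        carry = 0.0
        for iv, k in zip(base, keep):
            if k:
                rr_list.append(carry + iv)
                carry = 0.0
            else:
                carry += iv
            if len(rr_list) == n_beats:
                break
        rr = np.array(rr_list[:n_beats])
        if rr.size < n_beats:  # pragma: no cover - p would have to be ~1
            rr = np.concatenate([rr, np.full(n_beats - rr.size, profile.mean_rr)])
    elif kind == "pac":
        rate = profile.params.get("pac_rate", 0.1)
        coupling = profile.params.get("coupling_fraction", 0.6)
        rr = _nsr_like(profile, n_beats, rng)
        ectopic = np.nonzero(rng.random(n_beats) < rate)[0]
        for j in ectopic:
            if j + 1 >= n_beats:
                continue
            cycle = rr[j] + rr[j + 1]
            rr[j] = coupling * profile.mean_rr  # premature coupling interval
            rr[j + 1] = cycle - rr[j]           # compensatory pause
    else:  # pragma: no cover - guarded by RhythmProfile
        raise ValueError(f"unknown rhythm kind {kind!r}")

    return np.clip(rr, RR_MIN, RR_MAX)


def gen_record(profile_sequence, seed: int, record_id: str | None = None) -> SyntheticRecord:
    """Concatenate (profile, n_beats) runs into one record with true segments.

    Segment boundaries are placed at the temporal seams of the cumulative
    beat times, and AF/non-AF ground truth follows the profile kinds.
    """
    if not profile_sequence:
        raise ValueError("profile_sequence must contain at least one entry")
    rng = np.random.default_rng(seed)
    chunks = [gen_segment(profile, n, rng) for profile, n in profile_sequence]
    rr_all = np.concatenate(chunks)
    timestamps = np.cumsum(rr_all)
    rid = record_id if record_id is not None else f"synt-{seed}"
    rr = RRSeries(intervals=rr_all, timestamps=timestamps, record_id=rid)

    segments = []
    start_time = 0.0
    beat = 0
    for (profile, n), chunk in zip(profile_sequence, chunks):
        beat += n
        end_time = float(timestamps[beat - 1])
        label = "AF" if profile.kind == "AF" else profile.kind
        segments.append(RhythmSegment(start_time, end_time, label))
        start_time = end_time
    return SyntheticRecord(rr=rr, segments=segments,
                           profile_sequence=tuple(profile_sequence), seed=seed)


def gen_cohort(n_patients: int, af_burden_range=(0.05, 0.95), seed: int = 0,
               beats_per_record: int = 6000, other_rhythms: bool = True,
               id_prefix: str = "synt") -> list[SyntheticRecord]:
    """Generate a cohort of paroxysmal-AF records with inter-patient variability.

    Per patient, the AF beat fraction is drawn uniformly from
    ``af_burden_range`` and split over several AF episodes interleaved with
    sinus rhythm; with ``other_rhythms`` a minority of the non-AF time is
    bigeminy/trigeminy/AV-block/PAC runs.  Per-patient mean RR, AF walk SD
    and sinus parameters are themselves randomized, so records differ in
    more than their seed.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be at least 2")
    lo, hi = af_burden_range
    master = np.random.default_rng(seed)
    records = []
    for p in range(n_patients):
        rng = np.random.default_rng(master.integers(2**31))
        burden = rng.uniform(lo, hi)
        # mean-RR ranges overlap: AF is faster on average but not separable
        # from sinus rhythm by rate alone
        af_profile = RhythmProfile("AF",
                                   mean_rr=rng.uniform(0.45, 0.80),
                                   params={"mesc_sd": rng.uniform(0.05, 0.12)})
        nsr_profile = RhythmProfile("NSR",
                                    mean_rr=rng.uniform(0.70, 1.00),
                                    params={"resp_amplitude": rng.uniform(0.01, 0.03),
                                            "resp_period_beats": rng.uniform(4.0, 7.0),
                                            "jitter_sd": rng.uniform(0.005, 0.015)})
        n_episodes = int(rng.integers(2, 5))  # paroxysmal: several AF episodes
        af_beats = int(round(burden * beats_per_record))
        non_af_beats = beats_per_record - af_beats
        af_runs = _split_run(af_beats, n_episodes, rng)
        non_runs = _split_run(non_af_beats, n_episodes + 1, rng)

        sequence: list[tuple[RhythmProfile, int]] = []
        for k in range(n_episodes + 1):
            if non_runs[k] >= 2:
                sequence.extend(_non_af_runs(nsr_profile, non_runs[k], rng,
                                             other_rhythms))
            if k < n_episodes and af_runs[k] >= 2:
                sequence.append((af_profile, af_runs[k]))
        records.append(gen_record(sequence, seed=int(rng.integers(2**31)),
                                  record_id=f"{id_prefix}-{seed}-{p:03d}"))
    return records


def _split_run(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Split ``total`` beats into ``parts`` runs of random (>= 2 where possible) size."""
    if total < 2 * parts:
        return [total] + [0] * (parts - 1)
    w = rng.dirichlet(np.full(parts, 2.0))
    sizes = np.maximum((w * total).astype(int), 2)
    sizes[-1] = max(total - int(sizes[:-1].sum()), 2)
    return sizes.tolist()


def _non_af_runs(nsr_profile: RhythmProfile, n_beats: int,
                 rng: np.random.Generator, other_rhythms: bool):
    """Mostly sinus rhythm, occasionally prefixed by a regularly-irregular run."""
    if not other_rhythms or n_beats < 400 or rng.random() > 0.4:
        return [(nsr_profile, n_beats)]
    kind = rng.choice(["bigeminy", "trigeminy", "av_block", "pac"])
    if kind in ("bigeminy", "trigeminy"):
        other = RhythmProfile(kind, mean_rr=0.75,
                              params={"short_rr": rng.uniform(0.45, 0.55),
                                      "long_rr": rng.uniform(0.9, 1.1),
                                      "jitter_sd": 0.01})
    elif kind == "av_block":
        other = RhythmProfile("av_block", mean_rr=nsr_profile.mean_rr,
                              params={**nsr_profile.params,
                                      "drop_probability": rng.uniform(0.05, 0.15)})
    else:
        other = RhythmProfile("pac", mean_rr=nsr_profile.mean_rr,
                              params={**nsr_profile.params,
                                      "pac_rate": rng.uniform(0.05, 0.15),
                                      "coupling_fraction": rng.uniform(0.5, 0.7)})
    n_other = min(int(rng.integers(200, 400)), n_beats - 200)
    return [(other, n_other), (nsr_profile, n_beats - n_other)]
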