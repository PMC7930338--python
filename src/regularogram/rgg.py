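"""The regularogram (RGG) and rectangle-based AF-burden estimation.

The RGG is a scatter of per-window (variability, normality) points for a
whole recording; each point is one estimation window.  AF windows cluster
in a characteristic high-variability, high-normality region — the
"irregular irregularity zone" — so a whole Holter recording can be read at
a glance, and the fraction of windows inside a marked rectangle estimates
the AF burden.  A 3-D variant adds the mean RR interval as a third axis to
expose AF's tachycardic tendency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indices import WindowIndexRecord

__all__ = ["RGGData", "ZoneRect", "build_rgg", "render_rgg",
           "estimate_burden", "burden_error"]


@dataclass(frozen=True)
class RGGData:
    """Point cloud of an RGG: columns are (variability, normality[, mean_rr])."""

    points: np.ndarray
    labels: list[str]
    record_id: str
    dims: int

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class ZoneRect:
    """A closed rectangle in the (variability, normality) plane."""

    v_min: float
    v_max: float
    n_min: float
    n_max: float

    def __post_init__(self) -> None:
        if not (self.v_min < self.v_max and self.n_min < self.n_max):
            raise ValueError("rectangle bounds must satisfy v_min < v_max and n_min < n_max")

    def contains(self, v: np.ndarray, n: np.ndarray) -> np.ndarray:
        return ((v >= self.v_min) & (v <= self.v_max)
                & (n >= self.n_min) & (n <= self.n_max))


def build_rgg(records: list[WindowIndexRecord], dims: int = 2) -> RGGData:
    """One RGG point per non-ambiguous window index record."""
    if not records:
        raise ValueError("cannot build an RGG from zero windows")
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    cols = [[r.variability for r in records], [r.normality for r in records]]
    if dims == 3:
        cols.append([r.mean_rr for r in records])
    points = np.column_stack(cols)
    return RGGData(points=points, labels=[r.label for r in records],
                   record_id=records[0].record_id, dims=dims)


_LABEL_COLORS = {"AF": "#d62728", "non-AF": "#1f77b4"}


def render_rgg(rgg: RGGData, path, title: str | None = None,
               rect: ZoneRect | None = None, dpi: int = 120) -> None:
    """Write the RGG scatter to an image file (PNG or SVG by extension).

    Output is deterministic: repeated calls with identical data and options
    produce byte-identical files (SVG hash salt and metadata date pinned).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with plt.rc_context({"svg.hashsalt": "regularogram"}):
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(111, projection="3d" if rgg.dims == 3 else None)
        labels = np.asarray(rgg.labels)
        groups = sorted(set(rgg.labels))
        for lab in groups:
            mask = labels == lab
            ax.scatter(*rgg.points[mask].T, s=6,
                       c=_LABEL_COLORS.get(lab, "#7f7f7f"),
                       label=lab if lab else None)
        ax.set_xlabel("variability (s)")
        ax.set_ylabel("normality")
        if rgg.dims == 3:
            ax.set_zlabel("mean RR (s)")
        if rect is not None and rgg.dims == 2:
            from matplotlib.patches import Rectangle
            ax.add_patch(Rectangle((rect.v_min, rect.n_min),
                                   rect.v_max - rect.v_min,
                                   rect.n_max - rect.n_min,
                                   fill=False, edgecolor="black", linewidth=1.2))
        if any(groups) and len(groups) > 1:
            ax.legend(loc="lower right")
        ax.set_title(title if title is not None else rgg.record_id)
        fig.tight_layout()
        fig.savefig(path, dpi=dpi, metadata=_stable_metadata(str(path)))
        plt.close(fig)


def _stable_metadata(path: str) -> dict | None:
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": None}
    return None


def estimate_burden(records: list[WindowIndexRecord], rect: ZoneRect,
                    time_weighted: bool = False) -> float:
    """Fraction of windows whose (variability, normality) falls in the rectangle.

    By default each window counts once; ``time_weighted=True`` weights each
    window by its time span instead.
    """
    if not records:
        raise ValueError("cannot estimate burden from zero windows")
    v = np.array([r.variability for r in records])
    n = np.array([r.normality for r in records])
    inside = rect.contains(v, n)
    if time_weighted:
        w = np.array([r.window.t_end - r.window.t_start for r in records])
        return float(np.sum(w[inside]) / np.sum(w))
    return float(np.mean(inside))


def burden_error(estimates, truths) -> float:
    """Mean absolute error between estimated and true burdens, in percent."""
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.shape != truths.shape or estimates.size == 0:
        raise ValueError("estimates and truths must be equal-length and non-empty")
    return float(np.mean(np.abs(estimates - truths)) * 100.0)
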