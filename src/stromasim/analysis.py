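"""Derived metrics over recorded trajectories and snapshots.

Covers the model's emergent readouts: population dynamics, radial
distributions around the tumor centroid (necrotic core, brush-border
branching, molecular gradients), detection of the linear-to-exponential
turning point in tumor growth, and the three-way fate classification
(extinct / arrested / developed).

Radial quantities are anchored at the centroid of the *living* tumor
cells, so a drifting tumor is handled; distances are Euclidean in sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_export import Snapshot

__all__ = [
    "RadialProfile",
    "tumor_centroid",
    "radial_profile",
    "necrotic_core_stats",
    "branching_profile",
    "detect_turning_point",
    "classify_fate",
    "plot_dynamics",
    "plot_radial_profile",
]

_LIVING_STATES = ("normal", "hypoxic")


@dataclass
class RadialProfile:
    """Binned counts (or amounts) versus distance from the tumor centroid."""

    kind: str
    edges: np.ndarray   # bin edges in sites, len = len(counts) + 1
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "r_lo": self.edges[:-1], "r_hi": self.edges[1:], "count": self.counts,
        })


def tumor_centroid(snapshot: Snapshot) -> np.ndarray:
    """Centroid of living tumor cells; falls back to all tumor cells, then
    to the world center when no tumor cell exists."""
    pos = np.array([c[3:6] for c in snapshot.cells
                    if c[1] == "tumor" and c[2] in _LIVING_STATES], dtype=float)
    if len(pos) == 0:
        pos = np.array([c[3:6] for c in snapshot.cells if c[1] == "tumor"], dtype=float)
    if len(pos) == 0:
        return np.asarray(snapshot.dims, dtype=float) / 2.0
    return pos.mean(axis=0)


def _positions(snapshot: Snapshot, kind: str) -> np.ndarray:
    if kind == "tumor":
        sel = [c[3:6] for c in snapshot.cells if c[1] == "tumor"]
    elif kind == "living_tumor":
        sel = [c[3:6] for c in snapshot.cells if c[1] == "tumor" and c[2] in _LIVING_STATES]
    elif kind == "necrotic":
        sel = [c[3:6] for c in snapshot.cells if c[1] == "tumor" and c[2] == "necrotic"]
    elif kind in ("endothelial", "fibroblast"):
        sel = [c[3:6] for c in snapshot.cells if c[1] == kind]
    elif kind == "caf":
        sel = [c[3:6] for c in snapshot.cells if c[1] == "fibroblast" and c[2] == "caf"]
    else:
        raise ValueError(f"unknown entity kind {kind!r}")
    return np.array(sel, dtype=float).reshape(-1, 3)


def _edges(rmax: float, bin_width: float) -> np.ndarray:
    n = max(1, int(math.ceil((rmax + 1e-9) / bin_width)))
    return np.arange(n + 1, dtype=float) * bin_width


def radial_profile(snapshot: Snapshot, kind: str, bin_width: float = 2.0) -> RadialProfile:
    """Histogram of an entity kind (or a molecular species) by distance
    from the living-tumor centroid."""
    center = tumor_centroid(snapshot)
    if kind in snapshot.fields:
        arr = np.asarray(snapshot.fields[kind], dtype=float)
        grids = np.indices(arr.shape, dtype=float)
        d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
        edges = _edges(float(d.max()), bin_width)
        counts, _ = np.histogram(d.ravel(), bins=edges, weights=arr.ravel())
        return RadialProfile(kind, edges, counts)
    pos = _positions(snapshot, kind)
    if len(pos) == 0:
        return RadialProfile(kind, np.array([0.0, bin_width]), np.zeros(1))
    d = np.linalg.norm(pos - center, axis=1)
    edges = _edges(float(d.max()), bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return RadialProfile(kind, edges, counts)


def necrotic_core_stats(snapshot: Snapshot) -> tuple[float, float]:
    """(fraction of tumor cells that are necrotic, necrotic core radius).

    The core radius is the 95th percentile of necrotic-cell distances
    from the living-tumor centroid; (0, 0) when nothing is necrotic.
    """
    living = _positions(snapshot, "living_tumor")
    necrotic = _positions(snapshot, "necrotic")
    total = len(living) + len(necrotic)
    if total == 0:
        raise ValueError("snapshot contains no tumor cells")
    if len(necrotic) == 0:
        return 0.0, 0.0
    center = tumor_centroid(snapshot)
    d = np.linalg.norm(necrotic - center, axis=1)
    return len(necrotic) / total, float(np.percentile(d, 95))


def branching_profile(events: pd.DataFrame, snapshot: Snapshot,
                      bin_width: float = 2.0) -> RadialProfile:
    """Histogram of vessel-branch events by distance from the tumor centroid."""
    center = tumor_centroid(snapshot)
    branches = events[events["event"] == "branch"]
    if len(branches) == 0:
        return RadialProfile("branch", np.array([0.0, bin_width]), np.zeros(1))
    pos = branches[["x", "y", "z"]].to_numpy(dtype=float)
    d = np.linalg.norm(pos - center, axis=1)
    edges = _edges(float(d.max()), bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return RadialProfile("branch", edges, counts)


# ---------------------------------------------------------------------------
# growth-curve change point
# ---------------------------------------------------------------------------

def _linefit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Least-squares line; returns (intercept, slope, residuals)."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    denom = n * sxx - sx * sx
    if denom == 0.0:
        a, b = y.mean(), 0.0
    else:
        b = (n * sxy - sx * sy) / denom
        a = (sy - b * sx) / n
    return a, b, y - (a + b * x)


def detect_turning_point(
    series: np.ndarray,
    min_segment: int = 10,
    lr_threshold: float = 30.0,
) -> Optional[int]:
    """Change point of a linear-then-exponential two-piece growth fit.

    Exhaustively searches the tick ``t*`` minimizing the total squared
    *relative* error of a fit that is linear in counts on ``[0, t*]``
    and linear in log-counts (i.e. exponential) on ``(t*, end]``;
    counts of zero are handled via log(count + 1).  Residuals are
    scaled by sqrt(count + 1) (a variance-stabilizing weight for
    count data) so the small-count region around the takeoff is
    weighted fairly — under plain least squares the late, large-count
    portion of the curve dominates and the change point drifts far
    from the transition.  Returns None unless the two-piece fit
    beats a single
    straight line by the likelihood-ratio threshold *and* the
    exponential segment grows faster, in relative terms, than the
    linear one — so a series that merely halts or declines has no
    turning point.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 50:
        raise ValueError(f"series too short for change-point search ({n} < 50 points)")
    x = np.arange(n, dtype=float)
    ylog = np.log1p(y)
    scale = np.sqrt(y + 1.0)

    best = None  # (total sse, t, b2, a1, b1)
    for t in range(min_segment - 1, n - min_segment):
        x1, y1 = x[: t + 1], y[: t + 1]
        x2, l2 = x[t + 1:], ylog[t + 1:]
        a1, b1, r1 = _linefit(x1, y1)
        a2, b2, _ = _linefit(x2, l2)
        pred2 = np.expm1(a2 + b2 * x2)
        rel1 = r1 / scale[: t + 1]
        rel2 = (y[t + 1:] - pred2) / scale[t + 1:]
        sse = float(rel1 @ rel1) + float(rel2 @ rel2)
        if best is None or sse < best[0]:
            best = (sse, t, b2, a1, b1)
    sse2p, t_star, b2, _, b1 = best

    _, _, r0 = _linefit(x, y)
    rel0 = r0 / scale
    sse0 = float(rel0 @ rel0)
    if sse2p <= 0.0:
        sse2p = np.finfo(float).tiny
    if sse0 <= 0.0:
        return None  # a single line is already a perfect fit
    lr = n * (math.log(sse0) - math.log(sse2p))
    if lr < lr_threshold:
        return None
    # the exponential piece must grow, and clearly faster in relative
    # terms than the linear piece does at the junction: for a series
    # that is linear throughout, the local relative rate of the "exp"
    # piece equals slope/value at the junction, so demand a margin
    junction = max(float(y[t_star]), 1.0)
    if b2 <= 0.0 or b2 <= 1.5 * b1 / junction:
        return None
    return t_star


def classify_fate(series: np.ndarray, horizon: int,
                  developed_factor: float = 10.0) -> str:
    """Three-way tumor fate from the living-cell series.

    extinct: no living tumor cell at the horizon; developed: a turning
    point exists and the final count is at least ``developed_factor``
    times the typical (median) pre-transition level; arrested:
    everything else.  The median anchors the comparison to the
    avascular plateau rather than to wherever along the upswing the
    squared-error-optimal change point happens to sit.
    """
    y = np.asarray(series, dtype=float)
    if len(y) == 0:
        raise ValueError("empty series")
    if y[-1] == 0:
        return "extinct"
    try:
        tp = detect_turning_point(y)
    except ValueError:
        tp = None
    if tp is not None:
        reference = max(float(np.median(y[: tp + 1])), 1.0)
        if y[-1] >= developed_factor * reference:
            return "developed"
    return "arrested"


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_dynamics(timeseries: pd.DataFrame, path) -> None:
    """Population dynamics curves (tumor, hypoxic, necrotic, endothelial, CAFs)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col, label in [
        ("living_tumor", "living tumor cells"),
        ("hypoxic_tumor", "hypoxic tumor cells"),
        ("necrotic", "necrotic cells"),
        ("endothelial", "endothelial cells"),
        ("activated_endothelial", "activated endothelial"),
        ("cafs", "CAFs"),
    ]:
        ax.plot(timeseries["tick"], timeseries[col], label=label)
    ax.set_xlabel("tick")
    ax.set_ylabel("cells")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_radial_profile(profiles: list[RadialProfile], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.plot(p.centers, p.counts, label=p.kind, drawstyle="steps-mid")
    ax.set_xlabel("distance from tumor centroid (sites)")
    ax.set_ylabel("count / amount per bin")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
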