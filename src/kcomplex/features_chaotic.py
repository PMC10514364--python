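"""Fractal features (f20-f22): correlation, box, and generalized dimension.

EEG is treated as the output of a nonlinear dynamical system; short windows
are summarized by three slope-based dimension estimates:

* f20 — correlation dimension: slope of ln C(r) vs ln r, where C(r) is the
  Grassberger-Procaccia correlation integral (fraction of distinct pairs of
  delay-embedded points closer than r, Chebyshev metric).
* f21 — box dimension of the normalized signal graph: slope of lg N(r) vs
  lg(1/r), N(r) = occupied boxes of size r on a dyadic grid over the unit
  square.
* f22 — generalized (Renyi) dimension D_q: slope of lg sum_i p_i^q / (q-1)
  vs lg r, with p_i the occupancy fraction of box i.  q defaults to 2;
  q = 0 reduces exactly to the box dimension.

Because the theoretical r -> 0 limit is meaningless on a 100-sample window,
each estimate fits a straight line over an automatically chosen scaling
region: the window of at least ``min_fit_points`` consecutive grid points
whose least-squares fit maximizes r^2 (ties broken toward wider windows).
For the graph-based dimensions (f21, f22) the occupancy is computed on a
densely interpolated polyline of the graph — so the curve, not just the
sample points, is counted — and the q = 0 scaling window is reused for all
q, which makes the Renyi ordering D_0 >= D_2 >= D_4 structural.

Degenerate inputs (all points identical, flat fits) return slope 0 with a
flag rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

CHAOTIC_FEATURE_NAMES = ["f20_cd", "f21_bd", "f22_gd"]

# dyadic grid depths for graph box counting: box sizes 2^-1 .. 2^-MAX_DEPTH
_MIN_DEPTH = 1
_MAX_DEPTH = 6
# polyline interpolation density; fine enough that consecutive interpolated
# points never skip a box at the finest grid for bounded-variation windows
_INTERP_POINTS = 8192


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters; ``tau=None`` selects the delay per window
    as the first zero crossing of the autocorrelation, capped at N/8."""

    m: int = 3
    tau: int | None = None

    def resolve_tau(self, values: np.ndarray) -> int:
        if self.tau is not None:
            if self.tau < 1:
                raise ValueError("tau must be >= 1")
            return self.tau
        return autocorr_zero_crossing(values, cap=max(1, len(values) // 8))

    def validate(self, n: int, tau: int) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if (self.m - 1) * tau >= n:
            raise ValueError(
                f"embedding (m={self.m}, tau={tau}) needs more than {n} samples"
            )


@dataclass
class ScalingFit:
    """Diagnostics of one log-log slope fit."""

    r_grid: np.ndarray
    y_values: np.ndarray
    slope: float
    fit_range: tuple[int, int]  # [start, stop) indices into r_grid
    r2_fit: float
    degenerate: bool = False
    note: str = ""


@dataclass(frozen=True)
class ChaoticFeatureVector:
    f20_cd: float
    f21_bd: float
    f22_gd: float
    fits: dict = field(default_factory=dict, compare=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.f20_cd, self.f21_bd, self.f22_gd])


def autocorr_zero_crossing(values: np.ndarray, cap: int) -> int:
    """First lag at which the sample autocorrelation crosses zero (capped)."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 1
    for lag in range(1, min(cap, x.size - 1) + 1):
        if float(np.dot(x[:-lag], x[lag:])) / denom <= 0:
            return lag
    return max(1, cap)


def delay_embed(values: np.ndarray, spec: EmbeddingSpec) -> np.ndarray:
    """Embed a scalar series into R^m: point i = (x_i, x_{i+tau}, ...)."""
    x = np.asarray(values, dtype=float)
    tau = spec.resolve_tau(x)
    spec.validate(x.size, tau)
    n_points = x.size - (spec.m - 1) * tau
    idx = np.arange(n_points)[:, None] + tau * np.arange(spec.m)[None, :]
    return x[idx]


# ---------------------------------------------------------------------------
# scaling-region fit
# ---------------------------------------------------------------------------

def best_scaling_fit(
    log_r: np.ndarray, log_y: np.ndarray, min_fit_points: int = 5
) -> tuple[float, tuple[int, int], float]:
    """Least-squares slope over the best window of >= min_fit_points.

    Returns (slope, (start, stop), r2).  The window maximizing fit r^2 wins;
    among equal r^2 the wider window wins.  A perfectly flat y within a
    window yields slope 0 with r^2 = 1 (a flat line is an exact fit).
    """
    x = np.asarray(log_r, float)
    y = np.asarray(log_y, float)
    n = x.size
    if n < 2:
        return 0.0, (0, n), 0.0
    min_fit_points = min(min_fit_points, n)
    best = (-np.inf, 0, (0, n), 0.0)  # (r2, width, range, slope)
    for i in range(0, n - min_fit_points + 1):
        for j in range(i + min_fit_points, n + 1):
            xs, ys = x[i:j], y[i:j]
            sx = xs - xs.mean()
            sy = ys - ys.mean()
            sxx = float(np.dot(sx, sx))
            syy = float(np.dot(sy, sy))
            if sxx == 0:
                continue
            slope = float(np.dot(sx, sy)) / sxx
            r2 = 1.0 if syy == 0 else float(np.dot(sx, sy)) ** 2 / (sxx * syy)
            key = (r2, j - i)
            if key > (best[0], best[1]):
                best = (r2, j - i, (i, j), slope)
    r2, _, rng, slope = best
    if not np.isfinite(r2):
        return 0.0, (0, n), 0.0
    return slope, rng, r2


# ---------------------------------------------------------------------------
# correlation dimension (Grassberger-Procaccia)
# ---------------------------------------------------------------------------

def correlation_integral(points: np.ndarray, r_grid: np.ndarray) -> np.ndarray:
    """C(r): fraction of distinct point pairs with Chebyshev distance < r."""
    d = pdist(np.atleast_2d(points), metric="chebyshev")
    d.sort()
    return np.searchsorted(d, r_grid, side="left") / d.size


def default_r_grid(points: np.ndarray, n_r: int = 16) -> np.ndarray:
    """16 log-spaced radii between the 5th and 50th percentile of pairwise
    distances."""
    d = pdist(np.atleast_2d(points), metric="chebyshev")
    lo, hi = np.percentile(d[d > 0], [5, 50]) if np.any(d > 0) else (0.0, 0.0)
    if not (lo > 0 and hi > lo):
        return np.array([])
    return np.geomspace(lo, hi, n_r)


def grassberger_procaccia(
    points: np.ndarray, r_grid: np.ndarray | None = None, min_fit_points: int = 5
) -> tuple[float, ScalingFit]:
    """Correlation dimension of a point cloud from the G-P correlation sum."""
    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[0] < 20:
        raise ValueError("need at least 20 embedded points")
    if r_grid is None:
        r_grid = default_r_grid(points)
    r_grid = np.asarray(r_grid, float)
    if r_grid.size == 0:
        fit = ScalingFit(r_grid, np.array([]), 0.0, (0, 0), 0.0, True, "all points identical")
        return 0.0, fit
    C = correlation_integral(points, r_grid)
    ok = C > 0
    if ok.sum() < 2:
        fit = ScalingFit(r_grid, C, 0.0, (0, 0), 0.0, True, "correlation sum empty")
        return 0.0, fit
    slope, rng, r2 = best_scaling_fit(np.log(r_grid[ok]), np.log(C[ok]), min_fit_points)
    return slope, ScalingFit(r_grid[ok], np.log(C[ok]), slope, rng, r2)


def correlation_dimension(
    values: np.ndarray,
    spec: EmbeddingSpec = EmbeddingSpec(),
    r_grid: np.ndarray | None = None,
) -> tuple[float, ScalingFit]:
    """f20: correlation dimension of the delay-embedded window."""
    return grassberger_procaccia(delay_embed(values, spec), r_grid)


# ---------------------------------------------------------------------------
# graph box occupancy (shared by box and generalized dimension)
# ---------------------------------------------------------------------------

def _normalized_graph(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Map the signal graph (n, x_n) into the unit square; returns a dense
    polyline (t, y) and a flag for constant input."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 16:
        raise ValueError("need at least 16 samples for graph box counting")
    t = np.linspace(0.0, 1.0, n)
    lo, hi = float(x.min()), float(x.max())
    constant = hi == lo
    y = np.full(n, 0.5) if constant else (x - lo) / (hi - lo)
    td = np.linspace(0.0, 1.0, _INTERP_POINTS)
    yd = np.interp(td, t, y)
    return td, yd, constant


def graph_box_counts(values: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Occupancy counts of the interpolated graph on dyadic grids.

    Returns (box_sizes, per-size arrays of interpolated-point counts per
    occupied box).
    """
    td, yd, _ = _normalized_graph(values)
    sizes = 0.5 ** np.arange(_MIN_DEPTH, _MAX_DEPTH + 1)
    counts: list[np.ndarray] = []
    for size in sizes:
        k = int(round(1.0 / size))
        ix = np.minimum((td * k).astype(int), k - 1)
        iy = np.minimum((yd * k).astype(int), k - 1)
        occ = np.bincount(ix * k + iy, minlength=k * k)
        counts.append(occ[occ > 0])
    return sizes, counts


def _renyi_log_sums(counts: list[np.ndarray], q: float) -> np.ndarray:
    out = np.empty(len(counts))
    for i, c in enumerate(counts):
        p = c / c.sum()
        out[i] = np.log10(np.sum(p**q))
    return out


def box_dimension(
    values: np.ndarray, min_fit_points: int = 4
) -> tuple[float, ScalingFit]:
    """f21: box-counting dimension of the normalized signal graph."""
    sizes, counts = graph_box_counts(values)
    n_boxes = np.array([c.size for c in counts], dtype=float)
    _, _, constant = _normalized_graph(values)
    if np.all(n_boxes <= 1):
        fit = ScalingFit(sizes, np.log10(n_boxes), 0.0, (0, 0), 0.0, True, "single box")
        return 0.0, fit
    slope, rng, r2 = best_scaling_fit(
        np.log10(1.0 / sizes), np.log10(n_boxes), min_fit_points
    )
    note = "constant signal" if constant else ""
    return slope, ScalingFit(sizes, np.log10(n_boxes), slope, rng, r2, constant, note)


def generalized_dimension(
    values: np.ndarray, q: float = 2.0, min_fit_points: int = 4
) -> tuple[float, ScalingFit]:
    """f22: Renyi dimension D_q of the graph occupancy measure.

    D_q is the slope of lg sum_i p_i^q / (q-1) against lg r.  The scaling
    window is the one selected for q = 0 (plain box counts), shared across
    q so that D_q is monotone non-increasing in q by construction.
    """
    if q == 1:
        raise ValueError(
            "q = 1 is the information-dimension limit; not supported here"
        )
    sizes, counts = graph_box_counts(values)
    log_r = np.log10(sizes)
    # window picked on the q = 0 curve
    y0 = _renyi_log_sums(counts, 0.0)
    if np.ptp(y0) == 0:
        fit = ScalingFit(sizes, y0, 0.0, (0, 0), 0.0, True, "single box")
        return 0.0, fit
    _, (i, j), _ = best_scaling_fit(log_r, y0, min_fit_points)
    yq = _renyi_log_sums(counts, q)
    xs, ys = log_r[i:j], yq[i:j]
    sx = xs - xs.mean()
    sy = ys - ys.mean()
    sxx = float(np.dot(sx, sx))
    slope_raw = float(np.dot(sx, sy)) / sxx if sxx > 0 else 0.0
    syy = float(np.dot(sy, sy))
    r2 = 1.0 if syy == 0 else float(np.dot(sx, sy)) ** 2 / (sxx * syy)
    dim = slope_raw / (q - 1.0)
    return dim, ScalingFit(sizes, yq, dim, (i, j), r2)


def chaotic_features(
    values: np.ndarray,
    spec: EmbeddingSpec = EmbeddingSpec(),
    q: float = 2.0,
) -> ChaoticFeatureVector:
    """Evaluate f20-f22 on one window."""
    f20, fit_cd = correlation_dimension(values, spec)
    f21, fit_bd = box_dimension(values)
    f22, fit_gd = generalized_dimension(values, q=q)
    return ChaoticFeatureVector(
        f20, f21, f22, fits={"cd": fit_cd, "bd": fit_bd, "gd": fit_gd}
    )


def chaotic_feature_matrix(
    windows: np.ndarray, spec: EmbeddingSpec = EmbeddingSpec(), q: float = 2.0
) -> np.ndarray:
    """f20-f22 for every row of a (n_windows, N) array."""
    return np.stack([chaotic_features(w, spec, q).as_array() for w in windows])
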