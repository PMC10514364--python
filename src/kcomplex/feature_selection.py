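"""Feature selection: ReliefF, CFS, search-based selection, and INTERACT.

Five selectors over a (segments x features) matrix with binary labels
(k-complex = 1):

* :func:`relieff` — instance-based feature weighting from k nearest hits
  and misses; features whose min-max-normalized weight exceeds a threshold
  (default 0.7) are kept.
* :func:`cfs` — correlation-based selection: best-first search maximizing
  the merit  k * mean|corr(f, y)| / sqrt(k + k (k-1) mean|corr(f, f')|),
  Pearson correlations on standardized features; fully automatic, no
  threshold.
* :func:`sfs` — search-based selection minimizing either the consistency
  measure (inconsistency rate on discretized features) or a seeded
  internal-cross-validation classifier error.  Exhaustive over all 2^F - 1
  subsets up to ``max_exhaustive`` features, best-first beyond.
* :func:`interact` — backward elimination ordered by symmetrical
  uncertainty: scan from the lowest-SU feature and drop any whose
  consistency contribution is below a threshold.

Continuous features are discretized with equal-frequency binning (default
10 bins) before any consistency or entropy computation.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("kcomplex")


@dataclass
class FeatureMatrix:
    """Segments x features design matrix with binary labels."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be 2-D with one row per label")
        if self.X.shape[1] != len(self.names):
            raise ValueError("names must match the number of columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def require_both_classes(self) -> None:
        if len(np.unique(self.y)) < 2:
            raise ValueError("labels contain a single class")

    def subset(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.names.index(n) for n in names]
        return FeatureMatrix(self.X[:, idx], self.y, list(names))


@dataclass
class SelectionResult:
    selected: list[str]
    scores: dict
    method: str
    params: dict = field(default_factory=dict)

    def indices(self, names: list[str]) -> list[int]:
        return [names.index(n) for n in self.selected]


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize_equal_frequency(X: np.ndarray, bins: int = 10) -> np.ndarray:
    """Equal-frequency (quantile) binning per column; returns integer codes.

    Duplicate quantile edges collapse, so low-cardinality columns keep their
    natural grouping.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty_like(X, dtype=np.int64)
    qs = np.linspace(0, 1, bins + 1)[1:-1]
    for j in range(X.shape[1]):
        edges = np.unique(np.quantile(X[:, j], qs))
        out[:, j] = np.searchsorted(edges, X[:, j], side="left")
    return out


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

def relieff_weights(
    X: np.ndarray,
    y: np.ndarray,
    num_samples: int | str = "all",
    k_neighbors: int = 10,
    seed: int | None = None,
) -> np.ndarray:
    """Raw ReliefF weights: hits pull a feature's weight down, misses up.

    diff(f, A, B) = |A_f - B_f| / range_f (0 for zero-range features);
    neighbors by Manhattan distance on the range-normalized features.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n, F = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("ReliefF needs both classes present")
    rng_f = X.max(axis=0) - X.min(axis=0)
    scale = np.where(rng_f > 0, rng_f, 1.0)
    Xn = (X - X.min(axis=0)) / scale
    Xn[:, rng_f == 0] = 0.0

    if num_samples == "all" or num_samples is None or int(num_samples) >= n:
        sample_idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sample_idx = rng.choice(n, size=int(num_samples), replace=False)
        sample_idx.sort()

    W = np.zeros(F)
    num = len(sample_idx)
    for i in sample_idx:
        d = np.abs(Xn - Xn[i]).sum(axis=1)
        d[i] = np.inf
        for same, sign in ((True, -1.0), (False, +1.0)):
            mask = (y == y[i]) if same else (y != y[i])
            cand = np.where(mask)[0]
            order = cand[np.argsort(d[cand], kind="stable")]
            nb = order[: min(k_neighbors, order.size)]
            if nb.size:
                W += sign * np.abs(Xn[nb] - Xn[i]).sum(axis=0) / (num * nb.size)
    return W


def relieff(
    fm: FeatureMatrix,
    num_samples: int | str = "all",
    k_neighbors: int = 10,
    threshold: float = 0.7,
    seed: int | None = None,
) -> SelectionResult:
    """Select features whose min-max-normalized ReliefF weight > threshold."""
    fm.require_both_classes()
    W = relieff_weights(fm.X, fm.y, num_samples, k_neighbors, seed)
    span = W.max() - W.min()
    Wn = (W - W.min()) / span if span > 0 else np.zeros_like(W)
    selected = [n for n, w in zip(fm.names, Wn) if w > threshold]
    return SelectionResult(
        selected=selected,
        scores={"weights_raw": dict(zip(fm.names, W.tolist())),
                "weights_normalized": dict(zip(fm.names, Wn.tolist()))},
        method="relieff",
        params={"num_samples": num_samples, "k_neighbors": k_neighbors,
                "threshold": threshold, "seed": seed},
    )


# ---------------------------------------------------------------------------
# CFS
# ---------------------------------------------------------------------------

def cfs_merit(rcf: np.ndarray, rff: np.ndarray, subset: tuple[int, ...]) -> float:
    """Merit of a subset from precomputed |corr| vectors/matrices."""
    k = len(subset)
    if k == 0:
        return 0.0
    idx = list(subset)
    mean_cf = float(np.mean(rcf[idx]))
    if k == 1:
        mean_ff = 0.0
    else:
        sub = rff[np.ix_(idx, idx)]
        mean_ff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def _abs_correlations(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    X = fm.X
    sd = X.std(axis=0)
    zero_var = sd == 0
    if np.any(zero_var):
        log.warning("CFS: zero-variance features %s treated as uncorrelated",
                    [fm.names[j] for j in np.where(zero_var)[0]])
    Z = (X - X.mean(axis=0)) / np.where(zero_var, 1.0, sd)
    Z[:, zero_var] = 0.0
    yz = (fm.y - fm.y.mean())
    ysd = yz.std()
    yz = yz / ysd if ysd > 0 else yz
    n = fm.n
    rcf = np.abs(Z.T @ yz) / n
    rff = np.abs(Z.T @ Z) / n
    np.fill_diagonal(rff, 1.0)
    return rcf, rff


def cfs(fm: FeatureMatrix, max_stale: int = 5) -> SelectionResult:
    """Best-first search for the subset maximizing the CFS merit."""
    fm.require_both_classes()
    rcf, rff = _abs_correlations(fm)
    F = fm.n_features
    start: tuple[int, ...] = ()
    best_subset, best_merit = start, 0.0
    # heap of (-merit, subset); visited set on frozen subsets
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, start)]
    visited = {start}
    stale = 0
    while heap and stale < max_stale:
        _, node = heapq.heappop(heap)
        improved = False
        for j in range(F):
            if j in node:
                continue
            child = tuple(sorted(node + (j,)))
            if child in visited:
                continue
            visited.add(child)
            m = cfs_merit(rcf, rff, child)
            if m > best_merit + 1e-12:
                best_subset, best_merit = child, m
                improved = True
            heapq.heappush(heap, (-m, child))
        stale = 0 if improved else stale + 1
    selected = [fm.names[j] for j in best_subset]
    return SelectionResult(
        selected=selected,
        scores={"merit": best_merit,
                "corr_with_label": dict(zip(fm.names, rcf.tolist()))},
        method="cfs",
        params={"max_stale": max_stale},
    )


# ---------------------------------------------------------------------------
# consistency measure
# ---------------------------------------------------------------------------

def inconsistency_rate(
    Xd: np.ndarray, y: np.ndarray, subset: list[int] | None = None
) -> float:
    """Inconsistency rate of a discretized feature subset.

    Instances sharing an identical discretized pattern but differing in
    label are inconsistent; each pattern contributes its occurrence count
    minus its largest single-class count, and the rate is the sum over
    patterns divided by n.
    """
    Xd = np.atleast_2d(Xd)
    cols = Xd if subset is None else Xd[:, list(subset)]
    if cols.shape[1] == 0:
        raise ValueError("subset must be non-empty")
    _, inv = np.unique(cols, axis=0, return_inverse=True)
    n_groups = int(inv.max()) + 1
    tot = np.bincount(inv, minlength=n_groups).astype(float)
    largest = np.zeros(n_groups)
    for cls in np.unique(y):
        cnt = np.bincount(inv[y == cls], minlength=n_groups).astype(float)
        largest = np.maximum(largest, cnt)
    return float(np.sum(tot - largest) / len(y))


# ---------------------------------------------------------------------------
# search-based selection (SFS)
# ---------------------------------------------------------------------------

def _classifier_error(
    X: np.ndarray, y: np.ndarray, subset: tuple[int, ...],
    model: str, seed: int, folds: int = 5,
) -> float:
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    from .detection_eval import make_model

    est = make_model(model, seed=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = cross_val_score(est, X[:, list(subset)], y, cv=cv, scoring="accuracy")
    return 1.0 - float(np.mean(acc))


def sfs(
    fm: FeatureMatrix,
    measure: str = "consistency",
    max_exhaustive: int = 15,
    seed: int | None = 0,
    bins: int = 10,
    model: str = "dt",
    max_stale: int = 5,
) -> SelectionResult:
    """Search-based selection: minimize the measure over candidate subsets.

    Exhaustive over all non-empty subsets when F <= ``max_exhaustive``
    (ties resolved toward smaller, lexicographically earlier subsets);
    best-first search with the same measure otherwise.
    """
    fm.require_both_classes()
    if measure not in ("consistency", "classifier_error"):
        raise ValueError(f"unknown measure {measure!r}")
    F = fm.n_features
    if measure == "consistency":
        Xd = discretize_equal_frequency(fm.X, bins)
        evaluate = lambda s: inconsistency_rate(Xd, fm.y, list(s))
    else:
        evaluate = lambda s: _classifier_error(fm.X, fm.y, s, model, seed or 0)

    n_evaluated = 0
    if F <= max_exhaustive:
        best_subset, best_val = None, np.inf
        for size in range(1, F + 1):
            for combo in itertools.combinations(range(F), size):
                v = evaluate(combo)
                n_evaluated += 1
                if v < best_val - 1e-12:
                    best_subset, best_val = combo, v
        search = "exhaustive"
    else:
        log.warning(
            "SFS: %d features exceeds exhaustive cap %d; falling back to "
            "best-first search with the %s measure", F, max_exhaustive, measure,
        )
        best_subset, best_val = None, np.inf
        heap: list[tuple[float, tuple[int, ...]]] = []
        visited: set[tuple[int, ...]] = set()
        for j in range(F):
            s = (j,)
            v = evaluate(s)
            n_evaluated += 1
            visited.add(s)
            heapq.heappush(heap, (v, s))
            if v < best_val - 1e-12:
                best_subset, best_val = s, v
        stale = 0
        while heap and stale < max_stale:
            _, node = heapq.heappop(heap)
            improved = False
            for j in range(F):
                if j in node:
                    continue
                child = tuple(sorted(node + (j,)))
                if child in visited:
                    continue
                visited.add(child)
                v = evaluate(child)
                n_evaluated += 1
                heapq.heappush(heap, (v, child))
                if v < best_val - 1e-12:
                    best_subset, best_val = child, v
                    improved = True
            stale = 0 if improved else stale + 1
        search = "best_first"

    selected = [fm.names[j] for j in (best_subset or ())]
    return SelectionResult(
        selected=selected,
        scores={"measure_value": float(best_val), "n_subsets_evaluated": n_evaluated},
        method=f"sfs-{measure}",
        params={"measure": measure, "max_exhaustive": max_exhaustive,
                "search": search, "bins": bins, "seed": seed, "model": model},
    )


# ---------------------------------------------------------------------------
# symmetrical uncertainty + INTERACT
# ---------------------------------------------------------------------------

def _entropy(codes: np.ndarray) -> float:
    _, cnt = np.unique(codes, return_counts=True)
    p = cnt / cnt.sum()
    return float(-np.sum(p * np.log2(p)))


def symmetrical_uncertainty(f_discrete: np.ndarray, y: np.ndarray) -> float:
    """SU(f, y) = 2 [H(f) + H(y) - H(f, y)] / [H(f) + H(y)], in [0, 1].

    Defined as 0 when either variable is constant.
    """
    f_discrete = np.asarray(f_discrete)
    y = np.asarray(y)
    hf, hy = _entropy(f_discrete), _entropy(y)
    if hf == 0 or hy == 0:
        return 0.0
    joint = np.unique(np.column_stack([f_discrete, y]), axis=0, return_counts=True)[1]
    p = joint / joint.sum()
    hfy = float(-np.sum(p * np.log2(p)))
    su = 2.0 * (hf + hy - hfy) / (hf + hy)
    return float(min(max(su, 0.0), 1.0))


def interact(
    fm: FeatureMatrix, c_threshold: float = 1e-4, bins: int = 10
) -> SelectionResult:
    """INTERACT: SU-ranked backward elimination by consistency contribution.

    Features are ranked by SU with the label (descending); scanning from the
    tail, a feature is removed when deleting it raises the inconsistency
    rate of the surviving set by no more than ``c_threshold``.
    """
    fm.require_both_classes()
    Xd = discretize_equal_frequency(fm.X, bins)
    su = np.array([symmetrical_uncertainty(Xd[:, j], fm.y) for j in range(fm.n_features)])
    ranked = sorted(range(fm.n_features), key=lambda j: (-su[j], j))
    current = set(ranked)
    c_contrib: dict[str, float] = {}
    for j in reversed(ranked):
        rest = sorted(current - {j})
        if rest:
            c = inconsistency_rate(Xd, fm.y, rest) - inconsistency_rate(Xd, fm.y, sorted(current))
        else:
            # removing the last feature leaves nothing to condition on:
            # contribution is the gap to the majority-class baseline
            base = 1.0 - float(np.max(np.bincount(fm.y)) / fm.n)
            c = base - inconsistency_rate(Xd, fm.y, sorted(current))
        c_contrib[fm.names[j]] = float(c)
        if c <= c_threshold:
            current.remove(j)
    selected = [fm.names[j] for j in ranked if j in current]
    return SelectionResult(
        selected=selected,
        scores={"su": dict(zip(fm.names, su.tolist())), "c_contribution": c_contrib},
        method="interact",
        params={"c_threshold": c_threshold, "bins": bins},
    )


SELECTORS = {
    "relieff": relieff,
    "cfs": cfs,
    "sfs-consistency": lambda fm, **kw: sfs(fm, measure="consistency", **kw),
    "sfs-error": lambda fm, **kw: sfs(fm, measure="classifier_error", **kw),
    "interact": interact,
}


def select_features(fm: FeatureMatrix, method: str, **kwargs) -> SelectionResult:
    """Dispatch to one of the five selectors by name."""
    try:
        fn = SELECTORS[method]
    except KeyError:
        raise ValueError(f"unknown selection method {method!r}; "
                         f"choose from {sorted(SELECTORS)}") from None
    return fn(fm, **kwargs)
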