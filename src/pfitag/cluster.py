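"""Nonparametric cluster-based permutation tests and FDR correction.

Both the temporal and electrode-time variants follow the max-statistic
scheme: suprathreshold points (pointwise paired t, p < 0.05 uncorrected)
are concatenated into contiguous clusters whose summed t-scores are
compared against a null built by randomly permuting the condition averages
within each participant (equivalently, sign-flipping the paired
differences) and retaining the maximum summed cluster statistic per
permutation.  Positive and negative clusters are formed separately from
the signed t-map and both compete against the same two-sided null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "running_paired_t",
    "ClusterResult",
    "temporal_cluster_perm",
    "spatiotemporal_cluster_perm",
    "knn_adjacency",
    "fdr_correct",
]


def running_paired_t(
    cond_a: np.ndarray, cond_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Paired two-tailed t-statistic and p-value at each point.

    Inputs are participants x ... arrays with matched participants.  A zero
    mean difference with zero variance gives t = 0, p = 1; a nonzero mean
    with zero variance is treated as unboundedly significant (t = +-inf,
    p = 0), the documented degenerate-variance convention.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have matching shapes")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    t = np.where((sd == 0) & (mean > 0), np.inf, t)
    t = np.where((sd == 0) & (mean < 0), -np.inf, t)
    p = np.where(
        np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(np.nan_to_num(t)), df=n - 1)
    )
    p = np.where((sd == 0) & (mean == 0), 1.0, p)
    return t, p


@dataclass
class ClusterResult:
    """One contiguous suprathreshold cluster with its permutation p-value."""

    members: np.ndarray  # time indices, or (electrode, time) index pairs
    stat: float  # summed t-scores
    p: float
    polarity: int  # +1 or -1


def _runs(mask: np.ndarray) -> list[np.ndarray]:
    """Contiguous True runs of a 1-D boolean mask, as index arrays."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, splits)


def _temporal_clusters(t: np.ndarray, t_crit: float) -> list[tuple[np.ndarray, float, int]]:
    out = []
    for pol in (1, -1):
        for run in _runs(pol * t > t_crit):
            out.append((run, float(t[run].sum()), pol))
    return out


def _sign_matrix(
    n: int, n_perm, rng: np.random.Generator | None
) -> tuple[np.ndarray, bool]:
    """Sign-flip matrix (n_perm x n).  ``n_perm='all'`` enumerates every
    assignment exhaustively."""
    if isinstance(n_perm, str) and n_perm == "all":
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        return signs, True
    if rng is None:
        rng = np.random.default_rng()
    return rng.choice((1.0, -1.0), size=(int(n_perm), n)), False


def _perm_tmaps(d2: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized paired-t maps under sign flips.

    ``d2`` is the flattened (n_subj, n_points) difference array.  Because
    squared signs are 1, the per-point second moment is permutation
    invariant; only the mean flips.
    """
    n = d2.shape[0]
    means = signs @ d2 / n
    sumsq = (d2**2).sum(axis=0)
    var = (sumsq - n * means**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def temporal_cluster_perm(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int | str = 2000,
    p_thresh: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> list[ClusterResult]:
    """Temporal cluster-based permutation test on participants x time data.

    Returns every observed cluster with its add-one permutation p-value
    ((r + 1) / (n_perm + 1)); under exhaustive enumeration
    (``n_perm='all'``) the p-value is the plain fraction of the complete
    null (identity permutation included) at or above the observed statistic.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    d = a - b
    n = d.shape[0]
    t_obs, _ = running_paired_t(a, b)
    t_crit = stats.t.isf(p_thresh / 2.0, df=n - 1)
    observed = _temporal_clusters(t_obs, t_crit)
    if not observed:
        return []

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    tmaps = _perm_tmaps(d, signs)
    null = np.zeros(signs.shape[0])
    for i in range(signs.shape[0]):
        best = 0.0
        for _, s, _ in _temporal_clusters(tmaps[i], t_crit):
            best = max(best, abs(s))
        null[i] = best

    results = []
    for members, s, pol in observed:
        tol = 1e-9 * max(1.0, abs(s))
        r = int((null >= abs(s) - tol).sum())
        if exhaustive:
            p = r / null.size
        else:
            p = (r + 1) / (null.size + 1)
        results.append(ClusterResult(members=members, stat=s, p=p, polarity=pol))
    results.sort(key=lambda c: c.p)
    return results


# ---------------------------------------------------------------------------
# spatiotemporal variant
# ---------------------------------------------------------------------------

def knn_adjacency(coords: np.ndarray, k: int = 4) -> np.ndarray:
    """Symmetrized k-nearest-neighbor adjacency over 2-D sensor coordinates,
    for synthetic montages."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        adj[i, np.argsort(d2[i])[:k]] = True
    adj |= adj.T
    np.fill_diagonal(adj, False)
    return adj


def _spatiotemporal_clusters(
    t: np.ndarray,
    t_crit: float,
    adjacency: np.ndarray,
    min_neighbors: int,
) -> list[tuple[np.ndarray, float, int]]:
    """Grow clusters over electrode neighbors and adjacent time points.

    A point qualifies only when at least ``min_neighbors`` spatially
    adjacent electrodes are also suprathreshold at the same time point
    (the minimum-spatial-cluster-size criterion).
    """
    n_elec, n_time = t.shape
    out = []
    for pol in (1, -1):
        mask = pol * t > t_crit
        if not mask.any():
            continue
        neighbor_counts = adjacency.astype(int) @ mask.astype(int)
        kept = mask & (neighbor_counts >= min_neighbors)
        if not kept.any():
            continue
        visited = np.zeros_like(kept)
        pts = np.argwhere(kept)
        for e0, t0 in pts:
            if visited[e0, t0]:
                continue
            stack = [(e0, t0)]
            visited[e0, t0] = True
            members = []
            while stack:
                e, tt = stack.pop()
                members.append((e, tt))
                for ee in np.flatnonzero(adjacency[e]):
                    if kept[ee, tt] and not visited[ee, tt]:
                        visited[ee, tt] = True
                        stack.append((ee, tt))
                for dt in (-1, 1):
                    tn = tt + dt
                    if 0 <= tn < n_time and kept[e, tn] and not visited[e, tn]:
                        visited[e, tn] = True
                        stack.append((e, tn))
            members = np.asarray(members)
            s = float(t[members[:, 0], members[:, 1]].sum())
            out.append((members, s, pol))
    return out


def spatiotemporal_cluster_perm(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int | str = 1000,
    p_thresh: float = 0.05,
    min_neighbors: int = 3,
    seed: int | np.random.Generator | None = None,
) -> list[ClusterResult]:
    """Electrode-time cluster permutation test.

    ``cond_a``/``cond_b`` are participants x electrodes x time; ``adjacency``
    is a symmetric boolean electrode-neighborhood matrix covering all
    electrodes.  Otherwise identical to :func:`temporal_cluster_perm`.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have matching shapes")
    n, n_elec, n_time = a.shape
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (n_elec, n_elec):
        raise ValueError("adjacency does not match the electrode count")
    if not (adjacency == adjacency.T).all():
        raise ValueError("adjacency must be symmetric")

    d = a - b
    t_obs, _ = running_paired_t(a, b)
    t_crit = stats.t.isf(p_thresh / 2.0, df=n - 1)
    observed = _spatiotemporal_clusters(t_obs, t_crit, adjacency, min_neighbors)
    if not observed:
        return []

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    tmaps = _perm_tmaps(d.reshape(n, -1), signs)
    null = np.zeros(signs.shape[0])
    for i in range(signs.shape[0]):
        tm = tmaps[i].reshape(n_elec, n_time)
        best = 0.0
        for _, s, _ in _spatiotemporal_clusters(tm, t_crit, adjacency, min_neighbors):
            best = max(best, abs(s))
        null[i] = best

    results = []
    for members, s, pol in observed:
        tol = 1e-9 * max(1.0, abs(s))
        r = int((null >= abs(s) - tol).sum())
        p = r / null.size if exhaustive else (r + 1) / (null.size + 1)
        results.append(ClusterResult(members=members, stat=s, p=p, polarity=pol))
    results.sort(key=lambda c: c.p)
    return results


def fdr_correct(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, float | None]:
    """Benjamini-Hochberg step-up.

    Returns the significance mask and the adaptive p threshold (the largest
    p-value declared significant; None when nothing survives).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    reject = reject.reshape(p.shape)
    threshold = float(p[reject].max()) if reject.any() else None
    return reject, threshold
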