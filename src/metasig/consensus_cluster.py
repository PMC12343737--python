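"""Molecular subtyping by resampled hierarchical consensus clustering.

Each repetition subsamples a fixed fraction of samples, clusters them with
Ward linkage on a 1 - Pearson-correlation dissimilarity (Lance-Williams
Ward.D2 update, as scipy implements it), and cuts the tree at every k up to
k_max. consensus[i, j] is the fraction of co-subsampled repetitions in which
i and j land in the same cluster. Stability is summarized by the empirical
CDF of consensus entries, its area, and the relative delta-area per k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DegenerateInputError, ParameterError

_CDF_GRID = np.linspace(0.0, 1.0, 101)


def filter_low_variance(H_rel: np.ndarray, sd_min: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Drop feature columns whose sample standard deviation (ddof=1) is < sd_min.

    Returns (reduced matrix, boolean keep-mask). At least two columns must
    survive for downstream clustering to be meaningful.
    """
    X = np.asarray(H_rel, dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd >= sd_min  # strict < is dropped, sd == sd_min survives
    if keep.sum() < 2:
        raise DegenerateInputError(
            f"only {int(keep.sum())} feature(s) with sd >= {sd_min}; need at least 2"
        )
    return X[:, keep], keep


def _pair_dissimilarity(X: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson correlation distance between sample rows.

    Zero-variance rows make the correlation undefined; such pairs fall back
    to distance 1 (the documented convention).
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1)
    ok = norm > 0
    denom = np.where(ok, norm, 1.0)
    U = Xc / denom[:, None]
    corr = U @ U.T
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    bad = ~ok
    if bad.any():
        dist[bad, :] = 1.0
        dist[:, bad] = 1.0
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


@dataclass
class ConsensusResult:
    k_values: list[int]
    consensus: dict[int, np.ndarray]  # per-k samples x samples matrix
    cdf: dict[int, np.ndarray]  # CDF evaluated on _CDF_GRID
    area: dict[int, float]
    delta_area: dict[int, float]
    never_cosampled: np.ndarray  # boolean mask of pairs never drawn together
    chosen_k: Optional[int] = None
    labels: Optional[np.ndarray] = None  # 1..k for chosen_k
    cluster_consensus: dict[int, float] = field(default_factory=dict)
    unstable_clusters: list[int] = field(default_factory=list)


def consensus_cluster(
    X: np.ndarray,
    k_max: int = 8,
    reps: int = 1000,
    p_item: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Run the resampled-clustering consensus over k = 2..k_max."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if X.ndim != 2 or X.shape[1] < 2:
        raise ParameterError("X must be samples x features with >= 2 features")
    if n < k_max + 1:
        raise ParameterError(f"need at least k_max+1 = {k_max + 1} samples, got {n}")
    if not (0.0 < p_item <= 1.0):
        raise ParameterError(f"p_item must lie in (0, 1], got {p_item}")
    if reps < 2:
        raise ParameterError("reps must be >= 2")

    rng = np.random.default_rng(seed)
    m = int(np.floor(p_item * n))
    ks = list(range(2, k_max + 1))
    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sample = np.zeros((n, n))

    for _ in range(reps):
        idx = rng.choice(n, size=m, replace=False)
        idx.sort()
        if m < max(ks):
            warnings.warn("subsample smaller than k; repetition skipped", stacklevel=2)
            continue
        d = _pair_dissimilarity(X[idx])
        Z = linkage(d, method="ward")
        co_sample[np.ix_(idx, idx)] += 1
        for k in ks:
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same

    never = co_sample == 0
    np.fill_diagonal(never, False)
    denom = np.where(co_sample > 0, co_sample, 1.0)

    consensus: dict[int, np.ndarray] = {}
    cdf: dict[int, np.ndarray] = {}
    area: dict[int, float] = {}
    delta: dict[int, float] = {}
    iu = np.triu_indices(n, k=1)
    for k in ks:
        M = co_cluster[k] / denom
        M[never] = 0.0  # pairs never co-drawn: consensus undefined, reported as 0
        M = np.clip((M + M.T) / 2, 0.0, 1.0)
        np.fill_diagonal(M, 1.0)
        consensus[k] = M
        vals = M[iu]
        c = np.searchsorted(np.sort(vals), _CDF_GRID, side="right") / vals.size
        cdf[k] = c
        area[k] = float(np.trapezoid(c, _CDF_GRID))
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    return ConsensusResult(
        k_values=ks,
        consensus=consensus,
        cdf=cdf,
        area=area,
        delta_area=delta,
        never_cosampled=never,
    )


def select_k(result: ConsensusResult, elbow: float = 0.1) -> int:
    """Smallest k after which the relative delta-area stays below ``elbow``.

    Advisory only; CLI callers may override. Falls back to the largest k when
    the delta-area never settles.
    """
    ks = result.k_values
    for i, k in enumerate(ks[:-1]):
        if result.delta_area[ks[i + 1]] < elbow:
            return k
    return ks[-1]


def finalize_subtypes(
    result: ConsensusResult,
    k: Optional[int] = None,
    min_cluster_consensus: float = 0.9,
    elbow: float = 0.1,
) -> ConsensusResult:
    """Cut the chosen-k consensus matrix into labels and grade cluster stability.

    Labels come from Ward linkage over 1 - consensus. Clusters whose mean
    within-cluster consensus falls below ``min_cluster_consensus`` are flagged
    unstable; labels are still emitted.
    """
    if k is None:
        k = select_k(result, elbow=elbow)
    if k not in result.consensus:
        raise ParameterError(f"k={k} outside computed range {result.k_values}")
    M = result.consensus[k]
    d = squareform(np.clip(1.0 - M, 0.0, None), checks=False)
    labels = fcluster(linkage(d, method="ward"), t=k, criterion="maxclust")
    result.chosen_k = k
    result.labels = labels
    result.cluster_consensus = {}
    result.unstable_clusters = []
    for c in sorted(set(labels.tolist())):
        members = np.flatnonzero(labels == c)
        if members.size < 2:
            cc = 1.0  # singleton: trivially coherent
        else:
            sub = M[np.ix_(members, members)]
            iu = np.triu_indices(members.size, k=1)
            cc = float(sub[iu].mean())
        result.cluster_consensus[c] = cc
        if cc < min_cluster_consensus:
            result.unstable_clusters.append(c)
    return result
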