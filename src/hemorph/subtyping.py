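"""Consensus-voting subtype discovery from normalized feature distributions.

Each tissue (patient) is a point in R^D, the concatenation of its
equal-weight feature distributions (default: nuclear area and cellularity,
B bins each). For a candidate subtype count K, the cohort is repeatedly
subsampled and clustered; the consensus matrix records how often two
samples co-cluster when co-selected. Stable structure shows up as a
near-binary consensus matrix; K is selected by minimizing the proportion
of ambiguous consensus entries (a PAC-style score), and the ordered matrix
is kept for the qualitative heatmap inspection practitioners use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = [
    "ConsensusResult",
    "consensus_cluster",
    "select_k",
    "ambiguity_score",
    "ordered_consensus",
]


@dataclass
class ConsensusResult:
    """Consensus matrix and final labels for one candidate subtype count."""

    K: int
    consensus: np.ndarray  # (N, N) in [0, 1], symmetric
    labels: np.ndarray  # N integers in {1..K}
    resamples: int
    seed: int

    def __post_init__(self) -> None:
        c = np.asarray(self.consensus, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("consensus must be square")
        if not np.allclose(c, c.T):
            raise ValueError("consensus must be symmetric")
        if c.min() < 0 or c.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")
        self.consensus = c
        self.labels = np.asarray(self.labels, dtype=int)


def consensus_cluster(
    features: np.ndarray,
    K: int,
    resamples: int = 100,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of N samples at a fixed subtype count K.

    Each resample draws ceil(fraction*N) samples without replacement and
    k-means-clusters them with K clusters (seeded, deterministic).
    consensus(i, j) = co-cluster count / co-selection count, 0 for pairs
    never co-selected. Final labels come from average-linkage hierarchical
    clustering of 1 - consensus cut at K.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be an N x D matrix")
    N = X.shape[0]
    if K < 2 or N < K:
        raise ValueError(f"need N >= K >= 2, got N={N}, K={K}")
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    m = int(np.ceil(subsample_fraction * N))
    co_cluster = np.zeros((N, N))
    co_select = np.zeros((N, N))
    for _ in range(resamples):
        idx = np.sort(rng.choice(N, size=m, replace=False))
        km_seed = int(rng.integers(0, 2**31 - 1))
        labels = KMeans(n_clusters=K, n_init=10, random_state=km_seed).fit_predict(
            X[idx]
        )
        sel = np.zeros(N, dtype=bool)
        sel[idx] = True
        co_select += np.outer(sel, sel)
        same = labels[:, None] == labels[None, :]
        co_cluster[np.ix_(idx, idx)] += same
    with np.errstate(divide="ignore", invalid="ignore"):
        consensus = np.where(co_select > 0, co_cluster / np.maximum(co_select, 1), 0.0)
    consensus = (consensus + consensus.T) / 2  # exact symmetry

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=K, criterion="maxclust")
    return ConsensusResult(
        K=K, consensus=consensus, labels=labels, resamples=resamples, seed=seed
    )


def ambiguity_score(
    result: ConsensusResult, lower: float = 0.1, upper: float = 0.9
) -> float:
    """Proportion of off-diagonal consensus entries in the ambiguous band
    (lower, upper) — the PAC score. Lower is better."""
    c = result.consensus
    n = c.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = c[off]
    return float(((vals > lower) & (vals < upper)).mean())


def select_k(results: list[ConsensusResult]) -> int:
    """Candidate K with the lowest ambiguity score.

    Ties go to the largest tied K: merging two well-separated subtypes is
    just as unambiguous as keeping them apart (the merge is reproduced in
    every resample), so among equally stable candidates the finest
    partition is the informative one.
    """
    if not results:
        raise ValueError("need at least one candidate result")
    ordered = sorted(results, key=lambda r: r.K, reverse=True)
    scores = [ambiguity_score(r) for r in ordered]
    return ordered[int(np.argmin(scores))].K


def ordered_consensus(result: ConsensusResult) -> tuple[np.ndarray, np.ndarray]:
    """Consensus matrix reordered by final label (then by mean consensus
    within label) for heatmap inspection. Returns (matrix, order)."""
    order = np.lexsort((-result.consensus.mean(axis=1), result.labels))
    return result.consensus[np.ix_(order, order)], order
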