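"""Equal-weight distribution normalization of per-nucleus features.

Feature values measured in different tissues are not directly comparable
(staining, sectioning and scanner variation), so the cohort is normalized
in four steps: (i) each tissue's feature is an empirical density
distribution; (ii) values from all tissues are pooled into a global
distribution; (iii) the global distribution is re-binned into B
equal-population bins (each bin holds the same number of cells); and
(iv) each tissue's values are remapped onto these global bins, giving a
length-B probability vector per tissue and feature. Patients with several
tissue sections get the elementwise average of their tissue vectors.

The construction is rank-based: any strictly monotone transform applied
jointly to the pooled and tissue values leaves the output unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GlobalBinning",
    "FeatureDistribution",
    "build_global_bins",
    "remap_tissue",
    "average_patient",
    "distributions_to_frame",
]

log = logging.getLogger(__name__)


@dataclass
class GlobalBinning:
    """Equal-population bin edges for one feature over the pooled cohort."""

    feature: str
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if len(self.bin_edges) < 2:
            raise ValueError("need at least two bin edges")
        if not (np.diff(self.bin_edges) > 0).all():
            raise ValueError("bin edges must be strictly ascending")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def to_dict(self) -> dict:
        return {"feature": self.feature, "bin_edges": self.bin_edges.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "GlobalBinning":
        return cls(feature=d["feature"], bin_edges=np.asarray(d["bin_edges"]))


@dataclass
class FeatureDistribution:
    """A tissue's (or patient's) probability vector over the global bins."""

    id: str
    feature: str
    weights: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if len(self.weights) != len(self.bin_edges) - 1:
            raise ValueError("weights/edges length mismatch")


def build_global_bins(
    pooled_values: np.ndarray, B: int, feature: str = "feature"
) -> GlobalBinning:
    """Bin edges at the 0, 1/B, ..., 1 empirical quantiles of the pool.

    Quantiles use the inverse empirical CDF (type 1), which guarantees the
    pigeonhole property: on a pool of N distinct values the per-bin counts
    under half-open bins differ by at most 1. Duplicate edges caused by
    heavily tied data are collapsed, reducing the effective bin count
    (logged).
    """
    v = np.sort(np.asarray(pooled_values, dtype=float).ravel())
    if B < 1:
        raise ValueError("B must be >= 1")
    n_distinct = len(np.unique(v))
    if n_distinct < B:
        raise ValueError(
            f"feature {feature!r}: only {n_distinct} distinct values for {B} bins"
        )
    n = len(v)
    # interior edge b sits at the first value of bin b's slice
    idx = (np.arange(1, B) * n) // B
    edges = np.concatenate([[v[0]], v[idx], [v[-1]]])
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        log.warning(
            "feature %r: %d duplicate bin edges collapsed (effective B = %d)",
            feature,
            len(edges) - len(uniq),
            len(uniq) - 1,
        )
        edges = uniq
    return GlobalBinning(feature=feature, bin_edges=edges)


def remap_tissue(
    values: np.ndarray, binning: GlobalBinning, id: str = ""
) -> FeatureDistribution:
    """Fraction of a tissue's values in each global bin.

    Bins are half-open [e_b, e_{b+1}) with the last bin closed; values
    outside the edge range clamp to the first/last bin so new data scored
    against frozen bins still yields a probability vector.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty value list")
    edges = binning.bin_edges
    idx = np.searchsorted(edges, v, side="right") - 1
    idx = np.clip(idx, 0, binning.n_bins - 1)
    counts = np.bincount(idx, minlength=binning.n_bins).astype(float)
    return FeatureDistribution(
        id=id,
        feature=binning.feature,
        weights=counts / counts.sum(),
        bin_edges=edges,
    )


def average_patient(
    distributions: list[FeatureDistribution], id: str | None = None
) -> FeatureDistribution:
    """Elementwise mean of one patient's tissue distributions."""
    if not distributions:
        raise ValueError("need at least one distribution")
    first = distributions[0]
    for d in distributions[1:]:
        if d.feature != first.feature or not np.array_equal(
            d.bin_edges, first.bin_edges
        ):
            raise ValueError("mismatched feature or binning across distributions")
    weights = np.mean([d.weights for d in distributions], axis=0)
    weights = weights / weights.sum()  # guard fp drift; inputs each sum to 1
    return FeatureDistribution(
        id=id if id is not None else first.id,
        feature=first.feature,
        weights=weights,
        bin_edges=first.bin_edges,
    )


def distributions_to_frame(distributions: list[FeatureDistribution]) -> pd.DataFrame:
    """Wide table `id,feature,w1..wB` of probability vectors."""
    if not distributions:
        return pd.DataFrame(columns=["id", "feature"])
    B = max(len(d.weights) for d in distributions)
    rows = []
    for d in distributions:
        row = {"id": d.id, "feature": d.feature}
        row.update({f"w{i + 1}": w for i, w in enumerate(d.weights)})
        rows.append(row)
    cols = ["id", "feature"] + [f"w{i + 1}" for i in range(B)]
    return pd.DataFrame(rows, columns=cols)
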