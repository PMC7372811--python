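"""Alpha diversity, Bray-Curtis beta diversity, PCoA and hierarchical clustering."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io import AbundanceTable


@dataclass
class DistanceMatrix:
    """Symmetric sample × sample dissimilarity matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a dissimilarity matrix.

    ``eigenvalues`` holds the full spectrum (negatives included, descending);
    ``coordinates`` and ``proportion_explained`` cover positive axes only.
    """

    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def shannon(table: AbundanceTable, base: float = 2.0) -> pd.Series:
    """Shannon diversity H = −Σ pᵢ log_base pᵢ per sample (default bits)."""
    values = table.data.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    zero = np.asarray(table.sample_ids)[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-sum sample(s): {zero}")
    p = values / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1) / np.log(base)
    return pd.Series(h, index=table.data.index, name="shannon")


def observed_otus(table: AbundanceTable) -> pd.Series:
    """Richness: number of species with value > 0 per sample."""
    return (table.data > 0).sum(axis=1).rename("observed_otus")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)."""
    if table.n_samples < 2:
        raise ValueError("Bray-Curtis requires at least 2 samples")
    values = table.data.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    zero = np.asarray(table.sample_ids)[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    condensed = pdist(values, metric="braycurtis")
    return DistanceMatrix(table.sample_ids, squareform(condensed))


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal Coordinates Analysis (classical / metric MDS).

    Eigendecomposition of the double-centered Gower matrix −½ J D² J.
    Coordinates are eigenvectors scaled by √λ for positive eigenvalues;
    proportion explained is λᵢ over the sum of positive eigenvalues.
    Negative eigenvalues (non-Euclidean dissimilarities) are reported in the
    spectrum but excluded from coordinates and the variance denominator.
    """
    if dm.n < 3:
        raise ValueError("PCoA requires at least 3 samples")
    d2 = dm.values ** 2
    n = dm.n
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh((gower + gower.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * abs(eigvals[0])) if n else 0.0
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    axes = [f"PC{i + 1}" for i in range(positive.sum())]
    prop = eigvals[positive] / eigvals[positive].sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.sample_ids, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def hca_complete(dm: DistanceMatrix) -> np.ndarray:
    """Complete-linkage agglomerative clustering; returns a scipy linkage matrix.

    Cluster-to-cluster distance is the maximum pairwise member distance, so
    merge heights are non-decreasing.
    """
    if dm.n < 2:
        raise ValueError("hierarchical clustering requires at least 2 samples")
    return hierarchy.linkage(dm.condensed(), method="complete")
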