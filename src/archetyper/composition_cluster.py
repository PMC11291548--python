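"""Amino-acid composition vectors, Ward clustering, silhouette-guided k.

Insert regions and LCRs are summarized as 20-dimensional percentage
composition vectors ('X' excluded from the denominator) and clustered
with Ward's minimum-variance method on Euclidean distances (the
"ward.D2" formulation: squared-distance Lance–Williams update, heights
reported on the Euclidean scale).  The number of clusters is chosen by
maximizing the mean silhouette over k = 2..k_max, ties toward smaller
k; a maximum below 0.25 is flagged as weak structure.

The silhouette is computed here (rows in singleton clusters score 0,
and the two-singleton edge case is defined rather than rejected);
scikit-learn serves as the cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform, pdist

from .io_formats import AMINO_ACIDS

WEAK_STRUCTURE_CUTOFF = 0.25


def composition_vector(sequence: str) -> np.ndarray:
    """Percent composition over the 20 standard residues ('X' excluded)."""
    counts = np.zeros(20)
    n = 0
    for a in sequence:
        if a == "X":
            continue
        i = AMINO_ACIDS.find(a)
        if i < 0:
            raise ValueError(f"invalid residue {a!r}")
        counts[i] += 1
        n += 1
    if n == 0:
        raise ValueError("region is empty after removing 'X'")
    return 100.0 * counts / n


def composition_matrix(regions: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Regions x 20 percentage table; rows sum to 100 within 1e-9."""
    labels = [r[0] for r in regions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate region labels")
    data = np.vstack([composition_vector(seq) for _, seq in regions])
    df = pd.DataFrame(data, index=labels, columns=list(AMINO_ACIDS))
    _validate_matrix(df)
    return df


def _validate_matrix(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        raise ValueError("duplicate row labels")
    vals = df.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative composition entries")
    if not np.allclose(vals.sum(axis=1), 100.0, atol=1e-9):
        raise ValueError("composition rows must sum to 100")


def ward_linkage(matrix: pd.DataFrame) -> np.ndarray:
    """Ward linkage record on Euclidean row distances (scipy format)."""
    _validate_matrix(matrix)
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows")
    return linkage(matrix.to_numpy(dtype=float), method="ward")


def silhouette_mean(matrix: pd.DataFrame, labels: Sequence[int]) -> float:
    """Mean silhouette s(i) = (b_i - a_i)/max(a_i, b_i) over rows.

    a_i is the mean distance to the other members of i's cluster, b_i
    the smallest mean distance to another cluster.  Rows in singleton
    clusters score 0.  A single cluster overall is a hard error.
    """
    labels = np.asarray(labels)
    X = matrix.to_numpy(dtype=float)
    if len(labels) != len(X):
        raise ValueError("labels length mismatch")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    D = squareform(pdist(X))
    svals = np.zeros(len(X))
    for i in range(len(X)):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            svals[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        svals[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(svals.mean())


@dataclass
class ClusterResult:
    """Ward dendrogram plus per-k silhouettes and the chosen cut."""

    linkage: np.ndarray
    labels_per_k: dict[int, np.ndarray]
    silhouette_per_k: dict[int, float]
    chosen_k: int
    chosen_labels: np.ndarray
    weak_structure: bool
    row_labels: list[str]

    def members(self, cluster: int) -> list[str]:
        return [r for r, l in zip(self.row_labels, self.chosen_labels)
                if l == cluster]


def choose_k(matrix: pd.DataFrame, k_max: int | None = None) -> ClusterResult:
    """Cut the Ward dendrogram at k = 2..k_max, keep the best silhouette.

    Ties go to the smaller k.  ``weak_structure`` is set when the best
    mean silhouette is below 0.25.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("need at least 3 rows to choose k")
    if k_max is None:
        k_max = min(8, n - 1)
    if not (2 <= k_max <= n - 1):
        raise ValueError(f"k_max must be in [2, {n - 1}]")
    Z = ward_linkage(matrix)
    labels_per_k: dict[int, np.ndarray] = {}
    sil_per_k: dict[int, float] = {}
    for k in range(2, k_max + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        labels_per_k[k] = labels
        if np.unique(labels).size < 2:
            sil_per_k[k] = float("-inf")  # degenerate cut (ties in heights)
        else:
            sil_per_k[k] = silhouette_mean(matrix, labels)
    chosen = max(sil_per_k, key=lambda k: (sil_per_k[k], -k))
    best = sil_per_k[chosen]
    return ClusterResult(linkage=Z, labels_per_k=labels_per_k,
                         silhouette_per_k=sil_per_k, chosen_k=chosen,
                         chosen_labels=labels_per_k[chosen],
                         weak_structure=best < WEAK_STRUCTURE_CUTOFF,
                         row_labels=list(matrix.index))
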