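"""Pedigree verification from genotypes.

Computes pairwise identity-by-state (IBS) distances, clusters samples by
complete-linkage agglomeration, projects the distance matrix with classical
multidimensional scaling, and flags outlier samples by the standard score
of their nearest-neighbour distance.  On clean full-sib data the expected
picture is one tight cluster per family, with families sharing a parent
merging at a lower height than unrelated families.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DataError, InvalidConfigError, UndefinedPairError
from .simulate.families import GenotypeMatrix

__all__ = [
    "ibs_distance",
    "complete_linkage_cluster",
    "classical_mds",
    "detect_outliers",
]


def ibs_distance(
    matrix: GenotypeMatrix | np.ndarray,
    sample_ids: list[str] | None = None,
    min_overlap: int = 50,
    block: int = 128,
) -> pd.DataFrame:
    """Pairwise IBS distance: 1 - (mean shared alleles)/2.

    Shared alleles between two genotypes coded as B-allele dosage d1, d2 is
    2 - |d1 - d2|; the mean runs over pairwise-complete markers.  A pair
    with fewer than ``min_overlap`` overlapping calls raises
    :class:`UndefinedPairError`.
    """
    if isinstance(matrix, GenotypeMatrix):
        codes = matrix.codes
        ids = list(matrix.sample_ids)
    else:
        codes = np.asarray(matrix, dtype=np.int8)
        ids = sample_ids or [f"s{i}" for i in range(codes.shape[0])]
    n = codes.shape[0]
    if n < 2:
        raise InvalidConfigError("need at least 2 samples")
    X = codes.astype(np.float64)
    M = (codes >= 0).astype(np.float64)
    X[codes < 0] = 0.0

    D = np.zeros((n, n))
    N = np.zeros((n, n))
    for i0 in range(0, n, block):
        xi = X[i0 : i0 + block]
        mi = M[i0 : i0 + block]
        # |d_i - d_j| summed over overlapping markers, in blocks
        diff = np.abs(xi[:, None, :] - X[None, :, :]) * mi[:, None, :] * M[None, :, :]
        D[i0 : i0 + block] = diff.sum(axis=2)
        N[i0 : i0 + block] = mi @ M.T
    if np.any((N < min_overlap) & ~np.eye(n, dtype=bool)):
        i, j = np.argwhere((N < min_overlap) & ~np.eye(n, dtype=bool))[0]
        raise UndefinedPairError(
            f"samples {ids[i]} and {ids[j]} share only {int(N[i, j])} called markers"
        )
    with np.errstate(invalid="ignore"):
        dist = 1.0 - (2.0 - D / N) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(dist, index=ids, columns=ids)


def complete_linkage_cluster(ibs: pd.DataFrame, n_clusters: int) -> pd.Series:
    """Complete-linkage agglomerative clustering cut at ``n_clusters``."""
    n = len(ibs)
    if n_clusters > n:
        raise InvalidConfigError("n_clusters exceeds sample count")
    Z = linkage(squareform(ibs.to_numpy(), checks=False), method="complete")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=ibs.index, name="cluster")


def classical_mds(ibs: pd.DataFrame, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) scaling of a distance matrix.

    Double-centres the squared distances and projects on the top
    eigenvectors; coordinates are returned in decreasing eigenvalue order.
    """
    n = len(ibs)
    if dims >= n:
        raise InvalidConfigError("dims must be smaller than the number of samples")
    D2 = ibs.to_numpy() ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    coords = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    return pd.DataFrame(coords, index=ibs.index, columns=[f"dim{i + 1}" for i in range(dims)])


def detect_outliers(ibs: pd.DataFrame, z_cut: float = 4.0) -> pd.DataFrame:
    """Z-score of each sample's nearest-neighbour distance.

    A sample whose closest relative is unusually far from it (Z > z_cut,
    measured against the cohort's nearest-neighbour distances) is flagged
    as a likely pedigree error or contaminated sample.
    """
    n = len(ibs)
    if n < 3:
        raise DataError("outlier detection needs at least 3 samples")
    D = ibs.to_numpy().copy()
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    mu, sd = float(nn.mean()), float(nn.std(ddof=1))
    z = (nn - mu) / sd if sd > 0 else np.zeros(n)
    return pd.DataFrame(
        {"nn_distance": nn, "z": z, "flagged": z > z_cut}, index=ibs.index
    )
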