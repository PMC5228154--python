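"""Duplicate collapsing and marker ordering within a linkage group.

Stacked and duplicated markers (identical segregation patterns up to
missing entries) carry no within-group ordering information but inflate
map length when genotyping errors push them apart, so they are collapsed
to a representative (the member with the most informative meioses) before
ordering and reinserted at the representative's position afterwards.

Ordering uses spectral seriation: the Fiedler vector (second-smallest
eigenvector of the graph Laplacian) of a Gaussian similarity kernel over
the pairwise two-point distance matrix orders the markers.  For a noisy
Robinson (serially banded) matrix this exploits *all* pairwise distances
simultaneously, which makes it far more robust than optimisers that
minimise the sum of adjacent distances — at realistic marker densities
that objective is noise-dominated and its optimum is not the true order.
Tiny groups (<= 8 markers) are ordered by exhaustive minimisation, where
the objective is exact.  A second round contracts markers that landed at
identical positions (stacks) and re-runs the seriation on the reduced
set.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ..errors import DataError, InvalidConfigError

__all__ = ["DuplicateClusters", "collapse_duplicates", "order_markers", "reinsert_duplicates",
           "path_length"]

_EXHAUSTIVE_MAX = 8


@dataclass
class DuplicateClusters:
    """Partition of LG markers into duplicate clusters.

    ``representatives`` lists one marker per cluster; ``members`` maps each
    representative to all markers of its cluster (representative included).
    """

    representatives: list[str]
    members: dict[str, list[str]]

    @property
    def n_markers(self) -> int:
        return sum(len(v) for v in self.members.values())


def collapse_duplicates(
    codes: np.ndarray,
    marker_ids: list[str],
    informativeness: np.ndarray,
    missing_tol: float = 0.05,
    block: int = 256,
) -> DuplicateClusters:
    """Cluster markers with identical genotype patterns.

    ``codes`` is offspring x markers (-1 missing).  Two markers are
    duplicates when their patterns never conflict at jointly called
    entries; only markers with a missing fraction at most ``missing_tol``
    participate (others stay singletons).  Clusters are the transitive
    closure of pairwise compatibility; the representative is the member
    with the highest informativeness, ties broken by marker id.
    """
    codes = np.asarray(codes)
    n_off, k = codes.shape
    if k != len(marker_ids):
        raise InvalidConfigError("codes/marker_ids mismatch")
    missing_frac = (codes < 0).mean(axis=0)
    eligible = missing_frac <= missing_tol

    rows_i: list[int] = []
    rows_j: list[int] = []
    elig_idx = np.flatnonzero(eligible)
    M = (codes.T >= 0).astype(np.float64)
    Xz = np.where(codes.T >= 0, codes.T.astype(np.float64), 0.0)
    Xe, Me = Xz[elig_idx], M[elig_idx]
    for a0 in range(0, len(elig_idx), block):
        xa, ma = Xe[a0 : a0 + block], Me[a0 : a0 + block]
        # conflicts: positions both called with different codes
        diff = np.abs(xa[:, None, :] - Xe[None, :, :]) * ma[:, None, :] * Me[None, :, :]
        compat = diff.sum(axis=2) == 0
        ii, jj = np.nonzero(compat)
        rows_i.extend(elig_idx[ii + a0].tolist())
        rows_j.extend(elig_idx[jj].tolist())
    graph = csr_matrix((np.ones(len(rows_i)), (rows_i, rows_j)), shape=(k, k))
    n_comp, labels = connected_components(graph, directed=False)
    members: dict[str, list[str]] = {}
    reps: list[str] = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        ids = [marker_ids[i] for i in idx]
        info = informativeness[idx]
        rep = sorted(zip(-info, ids))[0][1]
        reps.append(rep)
        members[rep] = sorted(ids)
    reps.sort()
    return DuplicateClusters(reps, members)


def path_length(path, D: np.ndarray) -> float:
    p = np.asarray(path)
    return float(D[p[:-1], p[1:]].sum()) if len(p) > 1 else 0.0


def _exhaustive_order(D: np.ndarray) -> list[int]:
    n = D.shape[0]
    best, best_len = list(range(n)), np.inf
    for perm in permutations(range(n)):
        if perm[0] > perm[-1]:  # orientation-free: skip mirror images
            continue
        plen = path_length(list(perm), D)
        if plen < best_len - 1e-15:
            best_len, best = plen, list(perm)
    return best


def _fiedler_order(D: np.ndarray, scale_percentile: float = 10.0) -> list[int]:
    n = D.shape[0]
    off = D[~np.eye(n, dtype=bool)]
    pos = off[off > 0]
    ell = np.percentile(pos, scale_percentile) if pos.size else 1.0
    ell = max(ell, 1e-9)
    W = np.exp(-((D / ell) ** 2))
    np.fill_diagonal(W, 0.0)
    L = np.diag(W.sum(axis=1)) - W
    _, vec = np.linalg.eigh(L)
    fiedler = vec[:, 1]
    return np.argsort(fiedler, kind="stable").tolist()


def _contract_stacks(order: list[int], D: np.ndarray, tol: float = 1e-9):
    """Group adjacent markers at zero distance into stacks."""
    groups: list[list[int]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        if D[prev, cur] <= tol:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    return groups


def order_markers(
    D: np.ndarray,
    n_starts: int = 10,
    n_rounds: int = 2,
    seed: int = 0,
) -> list[int]:
    """Order markers from their pairwise distance matrix.

    ``D`` holds two-point distances (cM) with a large penalty where
    undefined.  Groups of up to 8 markers are solved exactly; larger
    groups by spectral seriation, with a second round that contracts
    co-located stacks and re-runs the seriation on the reduced problem.
    Deterministic (``n_starts``/``seed`` kept for interface stability).
    The result is canonical up to orientation (first index < last).
    """
    n = D.shape[0]
    if n == 0:
        raise DataError("empty marker set")
    if n == 1:
        return [0]
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise DataError("distance matrix must be finite (use a penalty value)")
    if n <= _EXHAUSTIVE_MAX:
        best = _exhaustive_order(D)
    else:
        order = _fiedler_order(D)
        for _ in range(max(0, n_rounds - 1)):
            groups = _contract_stacks(order, D)
            if len(groups) == len(order) or len(groups) < 3:
                break
            reps = [g[0] for g in groups]
            Dr = D[np.ix_(reps, reps)]
            sub = (
                _exhaustive_order(Dr)
                if len(reps) <= _EXHAUSTIVE_MAX
                else _fiedler_order(Dr)
            )
            order = [m for gi in sub for m in groups[gi]]
        best = order
    if best[0] > best[-1]:
        best = best[::-1]
    return best


def reinsert_duplicates(
    ordered_reps: list[str], clusters: DuplicateClusters
) -> tuple[list[str], dict[str, str]]:
    """Expand an ordered representative list to the full marker order.

    Every clustered marker is placed immediately after its representative
    (so it inherits the representative's genetic position).  Returns the
    full order and the marker -> representative mapping.
    """
    rep_set = set(clusters.representatives)
    if set(ordered_reps) != rep_set:
        raise DataError("ordered representatives do not match clusters")
    order: list[str] = []
    rep_of: dict[str, str] = {}
    for rep in ordered_reps:
        for mid in [rep] + [m for m in clusters.members[rep] if m != rep]:
            order.append(mid)
            rep_of[mid] = rep
    return order, rep_of
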