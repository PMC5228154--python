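"""Linkage-group formation from pairwise LOD scores.

Groups are connected components of the marker graph with edges at
LOD >= ``lod_limit``; components below ``min_size`` stay unassigned.
Singletons are then re-attached to established groups when their best
group LOD passes ``lod_limit`` (a lower bar) and beats the second-best
group by at least ``lod_diff``.
"""
from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["separate_chromosomes", "join_singles"]


def separate_chromosomes(
    lod: np.ndarray,
    marker_ids: list[str],
    lod_limit: float = 35.0,
    min_size: int = 10,
) -> tuple[dict[int, list[str]], list[str]]:
    """Partition markers into linkage groups.

    Returns (groups, unassigned): groups maps lg id (1-based, largest
    first) to member marker ids; markers in components smaller than
    ``min_size`` are left unassigned.
    """
    adj = lod >= lod_limit
    np.fill_diagonal(adj, False)
    graph = csr_matrix(adj)
    _, labels = connected_components(graph, directed=False)
    comps: dict[int, list[str]] = {}
    for mid, lab in zip(marker_ids, labels):
        comps.setdefault(int(lab), []).append(mid)
    sized = sorted(
        (v for v in comps.values() if len(v) >= min_size),
        key=lambda v: (-len(v), v[0]),
    )
    groups = {i + 1: sorted(v) for i, v in enumerate(sized)}
    assigned = {m for v in groups.values() for m in v}
    unassigned = [m for m in marker_ids if m not in assigned]
    return groups, unassigned


def join_singles(
    unassigned: list[str],
    groups: dict[int, list[str]],
    lod: np.ndarray,
    marker_ids: list[str],
    lod_limit: float = 10.0,
    lod_diff: float = 3.0,
) -> dict[int, list[str]]:
    """Attach singular markers to their best linkage group.

    A marker's LOD against a group is the maximum pairwise LOD to any
    member; it joins the best group iff that LOD >= ``lod_limit`` and the
    margin over the second-best group is >= ``lod_diff``.
    """
    index = {m: i for i, m in enumerate(marker_ids)}
    out = {lg: list(members) for lg, members in groups.items()}
    member_idx = {lg: np.array([index[m] for m in members]) for lg, members in groups.items()}
    for m in unassigned:
        mi = index[m]
        scores = {lg: float(lod[mi, idx].max()) for lg, idx in member_idx.items() if len(idx)}
        if not scores:
            continue
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        best_lg, best = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else -np.inf
        if best >= lod_limit and best - second >= lod_diff:
            out[best_lg].append(m)
    return {lg: sorted(v) for lg, v in out.items()}
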