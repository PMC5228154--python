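"""Anchoring assembly scaffolds to a genetic map and error-checking them.

Each scaffold with mapped markers is assigned to the linkage group that a
majority of its markers map to, oriented by the rank correlation between
physical (bp) and genetic (cM) marker positions, and screened for order
discordances: runs of markers whose genetic positions move against the
scaffold's dominant orientation suggest inverted segments, runs displaced
far from the local physical-genetic trend (or mapping to another group)
suggest translocated segments.  Accepted calls can be materialised in a
chromosome-level AGP, with inverted cores split out and flipped.

Stacked markers (shared genetic position) are uninformative for order
within a scaffold, so all monotonicity analysis runs on unique genetic
positions only.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InvalidConfigError
from .simulate.genome import GenomeModel

__all__ = [
    "ScaffoldAnchor",
    "MisassemblyCall",
    "anchor_scaffolds",
    "detect_misassembly",
    "coverage_stats",
    "emit_agp",
    "parse_agp",
]


@dataclass
class ScaffoldAnchor:
    scaffold_id: str
    lg: int
    orientation: str  # '+', '-', or 'unknown'
    support: int  # mapped markers voting for the group
    n_markers: int  # all mapped markers on the scaffold
    span_bp: tuple[int, int]
    placement_cM: tuple[float, float]
    minority_lgs: dict = field(default_factory=dict)


@dataclass
class MisassemblyCall:
    scaffold_id: str
    kind: str  # inverted_segment | reversed_whole | translocated_segment | relocated_scaffold
    bp_interval: tuple[int, int]
    target: str
    evidence: int  # markers supporting the call


def _merge_map_coords(gmap: pd.DataFrame, coords: pd.DataFrame) -> pd.DataFrame:
    need = {"marker_id", "scaffold_id", "bp"}
    if not need <= set(coords.columns):
        raise InvalidConfigError(f"marker coordinates need columns {sorted(need)}")
    return gmap.merge(coords, on="marker_id", how="inner")


def anchor_scaffolds(
    gmap: pd.DataFrame,
    coords: pd.DataFrame,
    min_support: int = 2,
    min_orient_markers: int = 3,
    rho_threshold: float = 0.5,
) -> list[ScaffoldAnchor]:
    """Place scaffolds on linkage groups by majority marker vote.

    Orientation is the sign of the Spearman correlation between bp and cM
    over unique genetic positions; scaffolds with fewer than
    ``min_orient_markers`` unique positions (or |rho| below the
    threshold) stay 'unknown'.  Scaffolds with fewer than ``min_support``
    markers for any group are skipped.
    """
    merged = _merge_map_coords(gmap, coords)
    anchors = []
    for sid, sub in merged.groupby("scaffold_id"):
        votes = sub["lg"].value_counts()
        lg = int(votes.idxmax())
        support = int(votes.max())
        if support < min_support:
            continue
        on_lg = sub[sub["lg"] == lg].sort_values("bp")
        uniq = on_lg.drop_duplicates(subset="cM_avg", keep="first")
        orientation = "unknown"
        if len(uniq) >= min_orient_markers:
            rho = stats.spearmanr(uniq["bp"], uniq["cM_avg"]).statistic
            if np.isfinite(rho) and abs(rho) >= rho_threshold:
                orientation = "+" if rho > 0 else "-"
        anchors.append(
            ScaffoldAnchor(
                scaffold_id=sid,
                lg=lg,
                orientation=orientation,
                support=support,
                n_markers=len(sub),
                span_bp=(int(on_lg["bp"].min()), int(on_lg["bp"].max())),
                placement_cM=(float(on_lg["cM_avg"].min()), float(on_lg["cM_avg"].max())),
                minority_lgs={int(k): int(v) for k, v in votes.items() if int(k) != lg},
            )
        )
    return anchors


def _sign_runs(signs: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal nonzero sign: (start_step, end_step, sign)."""
    runs = []
    i = 0
    n = len(signs)
    while i < n:
        s = signs[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and signs[j + 1] == s:
            j += 1
        runs.append((i, j, int(s)))
        i = j + 1
    return runs


def detect_misassembly(
    anchor: ScaffoldAnchor,
    gmap: pd.DataFrame,
    coords: pd.DataFrame,
    min_segment_markers: int = 3,
    jump_cM: float = 10.0,
    prior_orientation: str | None = None,
    prior_lg: int | None = None,
) -> list[MisassemblyCall]:
    """Flag candidate misassemblies on one anchored scaffold.

    Unique-position markers are sorted by bp; runs of at least
    ``min_segment_markers`` markers whose cM steps oppose the dominant
    orientation become ``inverted_segment`` calls, runs of markers voting
    for a different group become ``translocated_segment`` calls, as do
    runs displaced more than ``jump_cM`` from the scaffold's robust
    physical-genetic trend.  With a prior orientation (resp. group) from
    an earlier assembly, a clean but opposite scaffold yields
    ``reversed_whole`` (resp. ``relocated_scaffold``).
    """
    merged = _merge_map_coords(gmap, coords)
    sub = merged[merged["scaffold_id"] == anchor.scaffold_id]
    if sub.empty:
        raise DataError(f"scaffold {anchor.scaffold_id} has no mapped markers")
    calls: list[MisassemblyCall] = []

    # markers voting for a minority group
    off_lg = sub[sub["lg"] != anchor.lg]
    for lg_other, grp in off_lg.groupby("lg"):
        if len(grp) >= min_segment_markers:
            calls.append(
                MisassemblyCall(
                    anchor.scaffold_id,
                    "translocated_segment",
                    (int(grp["bp"].min()), int(grp["bp"].max())),
                    f"LG{int(lg_other)}",
                    len(grp),
                )
            )

    on_lg = sub[sub["lg"] == anchor.lg].sort_values("bp")
    uniq = on_lg.drop_duplicates(subset="cM_avg", keep="first").reset_index(drop=True)
    if len(uniq) < min_segment_markers:
        return calls
    bp = uniq["bp"].to_numpy(float)
    cm = uniq["cM_avg"].to_numpy(float)
    dom = 1 if anchor.orientation != "-" else -1

    # within-group displaced segments: residuals from a robust trend
    if len(uniq) >= 4:
        slope, intercept, *_ = stats.theilslopes(cm, bp)
        resid = cm - (intercept + slope * bp)
        outlier = np.abs(resid) > jump_cM
        for i0, i1, s in _sign_runs(np.where(outlier, 1, 0)):
            n_mark = i1 - i0 + 1
            if n_mark >= min_segment_markers:
                calls.append(
                    MisassemblyCall(
                        anchor.scaffold_id,
                        "translocated_segment",
                        (int(bp[i0]), int(bp[i1])),
                        f"LG{anchor.lg}@{cm[i0]:.1f}cM",
                        n_mark,
                    )
                )
        keep = ~outlier
        bp, cm = bp[keep], cm[keep]
    if len(bp) >= min_segment_markers:
        steps = np.sign(np.diff(cm)) * dom
        for i0, i1, s in _sign_runs(steps.astype(int)):
            if s >= 0:
                continue
            n_mark = i1 - i0 + 2  # a run of k steps spans k+1 markers
            if n_mark >= min_segment_markers:
                calls.append(
                    MisassemblyCall(
                        anchor.scaffold_id,
                        "inverted_segment",
                        (int(bp[i0]), int(bp[i1 + 1])),
                        f"LG{anchor.lg}",
                        n_mark,
                    )
                )

    if prior_orientation in ("+", "-") and anchor.orientation in ("+", "-"):
        if prior_orientation != anchor.orientation and not any(
            c.kind == "inverted_segment" for c in calls
        ):
            calls.append(
                MisassemblyCall(
                    anchor.scaffold_id,
                    "reversed_whole",
                    (int(sub["bp"].min()), int(sub["bp"].max())),
                    f"LG{anchor.lg}",
                    int(anchor.support),
                )
            )
    if prior_lg is not None and prior_lg != anchor.lg:
        calls.append(
            MisassemblyCall(
                anchor.scaffold_id,
                "relocated_scaffold",
                (int(sub["bp"].min()), int(sub["bp"].max())),
                f"LG{anchor.lg}",
                int(anchor.support),
            )
        )
    return calls


def coverage_stats(
    anchors: list[ScaffoldAnchor],
    assembly: GenomeModel | dict[str, int],
    prior_anchored: set | None = None,
) -> dict:
    """Anchored base-pair coverage of the assembly.

    Returns anchored bp, totals, the anchored percentage, and — when a
    prior anchoring list is supplied — how many scaffolds are newly
    placed.
    """
    sizes = assembly.scaffolds if isinstance(assembly, GenomeModel) else dict(assembly)
    anchored_ids = {a.scaffold_id for a in anchors}
    anchored_bp = sum(sizes.get(s, 0) for s in anchored_ids)
    total = sum(sizes.values())
    out = {
        "n_anchored": len(anchored_ids),
        "n_scaffolds": len(sizes),
        "anchored_bp": int(anchored_bp),
        "total_bp": int(total),
        "anchored_pct": 100.0 * anchored_bp / total if total else 0.0,
    }
    if prior_anchored is not None:
        newly = anchored_ids - set(prior_anchored)
        out["newly_anchored"] = len(newly)
        out["newly_anchored_bp"] = int(sum(sizes.get(s, 0) for s in newly))
    return out


def emit_agp(
    anchors: list[ScaffoldAnchor],
    sizes: dict[str, int],
    calls: list[MisassemblyCall] | None = None,
    gap_size: int = 100,
) -> list[tuple]:
    """Chromosome-level AGP 2.1 rows from anchored scaffolds.

    Scaffolds are laid out per linkage group in order of placement cM with
    fixed-size map gaps between components.  A scaffold with an accepted
    ``inverted_segment`` call is split into flank / flipped core / flank
    components.  Returns rows as tuples matching AGP columns.
    """
    calls = calls or []
    accepted = {}
    for c in calls:
        if c.kind == "inverted_segment":
            accepted.setdefault(c.scaffold_id, []).append(c.bp_interval)
    rows: list[tuple] = []
    by_lg: dict[int, list[ScaffoldAnchor]] = {}
    for a in anchors:
        by_lg.setdefault(a.lg, []).append(a)
    for lg in sorted(by_lg):
        placed = sorted(by_lg[lg], key=lambda a: (a.placement_cM[0], a.scaffold_id))
        starts = [a.placement_cM[0] for a in placed]
        if len(set(starts)) != len(starts):
            raise DataError(f"overlapping placements on LG{lg}")
        obj = f"LG{lg}"
        pos = 1
        part = 1
        for ai, a in enumerate(placed):
            size = sizes[a.scaffold_id]
            ori = a.orientation if a.orientation in ("+", "-") else "?"
            pieces: list[tuple[int, int, str]] = []
            if a.scaffold_id in accepted:
                s, e = sorted(accepted[a.scaffold_id])[0]
                flip = "-" if ori != "-" else "+"
                if s > 1:
                    pieces.append((1, s - 1, ori))
                pieces.append((s, e, flip))
                if e < size:
                    pieces.append((e + 1, size, ori))
            else:
                pieces.append((1, size, ori))
            for cs, ce, co in pieces:
                span = ce - cs + 1
                rows.append(
                    (obj, pos, pos + span - 1, part, "W", a.scaffold_id, cs, ce, co)
                )
                pos += span
                part += 1
            if ai != len(placed) - 1:
                rows.append(
                    (obj, pos, pos + gap_size - 1, part, "N", gap_size, "scaffold", "yes", "map")
                )
                pos += gap_size
                part += 1
    return rows


def parse_agp(lines) -> list[tuple]:
    """Parse AGP rows (text lines or an open handle) back to tuples."""
    rows = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if f[4] == "W":
            rows.append((f[0], int(f[1]), int(f[2]), int(f[3]), "W", f[5], int(f[6]), int(f[7]), f[8]))
        else:
            rows.append((f[0], int(f[1]), int(f[2]), int(f[3]), f[4], int(f[5]), f[6], f[7], f[8]))
    return rows
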