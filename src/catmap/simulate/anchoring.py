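"""Synthetic map-vs-assembly fixtures with planted misassemblies.

Lays scaffolds consecutively along one linkage group, gives every marker
a physical coordinate and a genetic position proportional to it (plus
jitter standing in for map noise), then plants structural errors with
known ground truth: inverted segments (a contiguous marker run with its
genetic positions mirrored) and translocated segments (a run displaced in
genetic space).  Used for plant-and-recover validation of the
misassembly detector.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InvalidConfigError

__all__ = ["PlantedEvent", "AnchoredMapSim", "simulate_anchored_scaffolds"]


@dataclass
class PlantedEvent:
    scaffold_id: str
    kind: str  # inverted_segment | translocated_segment
    bp_interval: tuple[int, int]
    n_markers: int


@dataclass
class AnchoredMapSim:
    gmap: pd.DataFrame  # marker_id, lg, cM_avg
    coords: pd.DataFrame  # marker_id, scaffold_id, bp
    sizes: dict[str, int]
    events: list[PlantedEvent] = field(default_factory=list)

    @property
    def clean_scaffolds(self) -> list[str]:
        hit = {e.scaffold_id for e in self.events}
        return [s for s in self.sizes if s not in hit]


def simulate_anchored_scaffolds(
    n_scaffolds: int = 12,
    markers_per_scaffold: int = 12,
    scaffold_bp: int = 1_200_000,
    cm_per_mb: float = 1.0,
    n_inversions: int = 2,
    n_translocations: int = 1,
    inversion_markers: int = 4,
    translocation_markers: int = 3,
    translocation_cm: float = 20.0,
    cm_jitter: float = 0.02,
    seed: int = 0,
) -> AnchoredMapSim:
    """One linkage group of collinear scaffolds with planted errors."""
    if n_inversions + n_translocations >= n_scaffolds:
        raise InvalidConfigError("more planted events than scaffolds")
    rng = np.random.default_rng(seed)
    rows_map, rows_coord = [], []
    sizes = {}
    per_scaffold: dict[str, list[int]] = {}
    spacing = scaffold_bp // markers_per_scaffold
    for s in range(n_scaffolds):
        sid = f"scf{s + 1:03d}"
        sizes[sid] = scaffold_bp
        idxs = []
        for m in range(markers_per_scaffold):
            bp = m * spacing + spacing // 2
            global_bp = s * scaffold_bp + bp
            cm = global_bp * cm_per_mb * 1e-6 + float(rng.normal(0, cm_jitter))
            mid = f"{sid}_m{m + 1:02d}"
            rows_map.append({"marker_id": mid, "lg": 1, "cM_avg": cm})
            rows_coord.append({"marker_id": mid, "scaffold_id": sid, "bp": bp})
            idxs.append(len(rows_map) - 1)
        per_scaffold[sid] = idxs

    events: list[PlantedEvent] = []
    victims = rng.choice(n_scaffolds, size=n_inversions + n_translocations, replace=False)
    for v in victims[:n_inversions]:
        sid = f"scf{v + 1:03d}"
        idxs = per_scaffold[sid]
        start = int(rng.integers(0, markers_per_scaffold - inversion_markers))
        run = idxs[start : start + inversion_markers]
        cms = [rows_map[i]["cM_avg"] for i in run]
        for i, cm in zip(run, cms[::-1]):
            rows_map[i]["cM_avg"] = cm
        events.append(
            PlantedEvent(
                sid,
                "inverted_segment",
                (rows_coord[run[0]]["bp"], rows_coord[run[-1]]["bp"]),
                inversion_markers,
            )
        )
    for v in victims[n_inversions:]:
        sid = f"scf{v + 1:03d}"
        idxs = per_scaffold[sid]
        start = int(rng.integers(0, markers_per_scaffold - translocation_markers))
        run = idxs[start : start + translocation_markers]
        shift = translocation_cm if rng.random() < 0.5 else -translocation_cm
        for i in run:
            rows_map[i]["cM_avg"] += shift
        events.append(
            PlantedEvent(
                sid,
                "translocated_segment",
                (rows_coord[run[0]]["bp"], rows_coord[run[-1]]["bp"]),
                translocation_markers,
            )
        )
    return AnchoredMapSim(pd.DataFrame(rows_map), pd.DataFrame(rows_coord), sizes, events)
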