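"""Scaffold anchoring, misassembly calls, coverage, AGP emission."""
import numpy as np
import pandas as pd
import pytest

from catmap.errors import DataError
from catmap.integration import (
    MisassemblyCall,
    anchor_scaffolds,
    coverage_stats,
    detect_misassembly,
    emit_agp,
    parse_agp,
)


def _frames(scaffolds):
    """Build (gmap, coords) from {scaffold: [(bp, cM, lg), ...]}."""
    rows_map, rows_coord = [], []
    for sid, markers in scaffolds.items():
        for i, (bp, cm, lg) in enumerate(markers):
            mid = f"{sid}_m{i}"
            rows_map.append({"marker_id": mid, "lg": lg, "cM_avg": cm})
            rows_coord.append({"marker_id": mid, "scaffold_id": sid, "bp": bp})
    return pd.DataFrame(rows_map), pd.DataFrame(rows_coord)


class TestAnchoring:
    def test_orientations(self):
        gmap, coords = _frames({
            "fwd": [(i * 1000, i * 0.5, 1) for i in range(10)],
            "rev": [(i * 1000, (9 - i) * 0.5 + 20, 1) for i in range(10)],
        })
        anchors = {a.scaffold_id: a for a in anchor_scaffolds(gmap, coords)}
        assert anchors["fwd"].orientation == "+"
        assert anchors["rev"].orientation == "-"

    def test_majority_vote_with_minority_lg(self):
        gmap, coords = _frames({
            "split": [(i * 1000, i * 0.5, 1 if i < 6 else 2) for i in range(10)],
        })
        a = anchor_scaffolds(gmap, coords)[0]
        assert a.lg == 1
        assert a.support == 6
        assert a.minority_lgs == {2: 4}

    def test_single_marker_scaffold_skipped_below_min_support(self):
        gmap, coords = _frames({"one": [(100, 1.0, 1)]})
        assert anchor_scaffolds(gmap, coords, min_support=2) == []
        a = anchor_scaffolds(gmap, coords, min_support=1)[0]
        assert a.orientation == "unknown"


class TestMisassembly:
    def _clean(self, n=20, lg=1):
        return {"scf": [(i * 100_000, i * 0.4, lg) for i in range(n)]}

    def test_clean_scaffold_no_calls(self):
        gmap, coords = _frames(self._clean())
        a = anchor_scaffolds(gmap, coords)[0]
        assert detect_misassembly(a, gmap, coords) == []

    def test_planted_inversion_recovered_within_one_marker_gap(self):
        """A 1.2 Mb planted inversion on a 12 Mb scaffold is called with
        boundaries within one marker spacing of the plant."""
        spacing = 100_000
        n = 120
        start_bp, end_bp = 9_958_308, 11_156_616
        markers = []
        for i in range(n):
            bp = i * spacing + 50_000
            cm = bp * 1e-6  # 1 cM per Mb
            markers.append([bp, cm, 1])
        inside = [i for i, (bp, _, _) in enumerate(markers) if start_bp <= bp <= end_bp]
        lo_cm = markers[inside[0]][1]
        hi_cm = markers[inside[-1]][1]
        for i in inside:
            markers[i][1] = lo_cm + hi_cm - markers[i][1]  # flip the segment
        gmap, coords = _frames({"scf00172": [tuple(m) for m in markers]})
        a = anchor_scaffolds(gmap, coords)[0]
        calls = [c for c in detect_misassembly(a, gmap, coords) if c.kind == "inverted_segment"]
        assert len(calls) == 1
        lo, hi = calls[0].bp_interval
        assert abs(lo - markers[inside[0]][0]) <= spacing
        assert abs(hi - markers[inside[-1]][0]) <= spacing

    def test_translocated_segment_to_other_lg(self):
        scaff = self._clean()
        for i in (8, 9, 10):
            scaff["scf"][i] = (scaff["scf"][i][0], 55.0 + i, 2)
        gmap, coords = _frames(scaff)
        a = anchor_scaffolds(gmap, coords)[0]
        calls = detect_misassembly(a, gmap, coords)
        kinds = {c.kind for c in calls}
        assert "translocated_segment" in kinds

    def test_monotone_run_matches_bruteforce_oracle(self, rng):
        """Inverted-run calls equal an independent run-scan on random data."""
        for trial in range(20):
            n = 15
            cm = np.sort(rng.uniform(0, 30, size=n))
            flip_len = rng.integers(3, 6)
            start = rng.integers(0, n - flip_len)
            seg = slice(start, start + flip_len)
            cm_f = cm.copy()
            cm_f[seg] = cm_f[seg][::-1]
            markers = [(i * 10_000 + 5000, float(cm_f[i]), 1) for i in range(n)]
            gmap, coords = _frames({"s": markers})
            a = anchor_scaffolds(gmap, coords)[0]
            calls = [c for c in detect_misassembly(a, gmap, coords, jump_cM=100)
                     if c.kind == "inverted_segment"]
            # oracle: maximal runs of >= 2 consecutive decreasing steps over
            # unique positions
            uniq = [markers[0]]
            for m in markers[1:]:
                if m[1] != uniq[-1][1]:
                    uniq.append(m)
            steps = np.sign(np.diff([m[1] for m in uniq]))
            runs = []
            i = 0
            while i < len(steps):
                if steps[i] < 0:
                    j = i
                    while j + 1 < len(steps) and steps[j + 1] < 0:
                        j += 1
                    if j - i + 2 >= 3:
                        runs.append((uniq[i][0], uniq[j + 1][0]))
                    i = j + 1
                else:
                    i += 1
            assert [(c.bp_interval) for c in calls] == runs

    def test_prior_orientation_flags_whole_reversal(self):
        markers = [(i * 1000, (19 - i) * 0.5, 1) for i in range(20)]
        gmap, coords = _frames({"s": markers})
        a = anchor_scaffolds(gmap, coords)[0]
        calls = detect_misassembly(a, gmap, coords, prior_orientation="+")
        assert any(c.kind == "reversed_whole" for c in calls)

    def test_unanchored_scaffold_raises(self):
        gmap, coords = _frames(self._clean())
        a = anchor_scaffolds(gmap, coords)[0]
        a.scaffold_id = "ghost"
        with pytest.raises(DataError):
            detect_misassembly(a, gmap, coords)


class TestCoverage:
    def test_published_scale_fixture(self):
        from catmap.integration import ScaffoldAnchor

        anchors = [ScaffoldAnchor("big", 1, "+", 5, 5, (1, 2), (0, 1))]
        sizes = {"big": 766_000_000, "rest": 17_000_000}
        out = coverage_stats(anchors, sizes)
        assert round(out["anchored_pct"], 1) == 97.8

    def test_nothing_anchored(self):
        assert coverage_stats([], {"a": 100})["anchored_pct"] == 0.0

    def test_random_subset_matches_recount(self, rng):
        from catmap.integration import ScaffoldAnchor

        sizes = {f"s{i}": int(rng.integers(1000, 100_000)) for i in range(30)}
        chosen = [s for s in sizes if rng.random() < 0.5]
        anchors = [ScaffoldAnchor(s, 1, "+", 2, 2, (1, 2), (0, 1)) for s in chosen]
        out = coverage_stats(anchors, sizes, prior_anchored=set(list(sizes)[:5]))
        assert out["anchored_bp"] == sum(sizes[s] for s in chosen)
        assert out["newly_anchored"] == len(set(chosen) - set(list(sizes)[:5]))


class TestAGP:
    def _anchors(self):
        from catmap.integration import ScaffoldAnchor

        return [
            ScaffoldAnchor("s1", 1, "+", 4, 4, (1, 9000), (0.0, 5.0)),
            ScaffoldAnchor("s2", 1, "-", 4, 4, (1, 4000), (6.0, 9.0)),
        ]

    def test_two_scaffolds_three_rows(self):
        rows = emit_agp(self._anchors(), {"s1": 10_000, "s2": 5_000})
        assert len(rows) == 3
        assert rows[1][4] == "N"
        # components tile the object without overlap
        assert rows[0][2] + 1 == rows[1][1]
        assert rows[1][2] + 1 == rows[2][1]

    def test_inversion_call_splits_component(self):
        calls = [MisassemblyCall("s1", "inverted_segment", (3000, 6000), "LG1", 4)]
        rows = emit_agp(self._anchors(), {"s1": 10_000, "s2": 5_000}, calls)
        s1_rows = [r for r in rows if r[4] == "W" and r[5] == "s1"]
        assert len(s1_rows) == 3
        assert [(r[6], r[7]) for r in s1_rows] == [(1, 2999), (3000, 6000), (6001, 10_000)]
        assert s1_rows[1][8] == "-"  # the core flips against the flanks
        total = sum(r[7] - r[6] + 1 for r in s1_rows)
        assert total == 10_000

    def test_roundtrip_identity(self, tmp_path):
        from catmap.io import read_agp_file, write_agp_file

        rows = emit_agp(self._anchors(), {"s1": 10_000, "s2": 5_000})
        path = tmp_path / "out.agp"
        write_agp_file(rows, path)
        assert read_agp_file(path) == rows

    def test_overlapping_placements_rejected(self):
        anchors = self._anchors()
        anchors[1].placement_cM = (0.0, 2.0)
        with pytest.raises(DataError):
            emit_agp(anchors, {"s1": 10_000, "s2": 5_000})
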