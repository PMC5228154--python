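"""Linkage-group formation, duplicate collapsing, and marker ordering."""
import numpy as np
import pytest
from scipy.stats import kendalltau

from catmap.errors import DataError
from catmap.linkage import (
    TransmissionTables,
    collapse_duplicates,
    filter_markers,
    join_singles,
    kosambi,
    order_markers,
    reinsert_duplicates,
    separate_chromosomes,
    two_point_matrix,
)
from catmap.simulate import PedigreeSpec, TrueMapConfig, simulate_families


class TestSeparateChromosomes:
    def test_two_simulated_chromosomes_recovered(self):
        cfg = TrueMapConfig.regular(2, 60.0, 40)
        peds, mat, truth = simulate_families(cfg, PedigreeSpec((120, 120, 120, 120)), seed=50)
        tables = TransmissionTables(mat, peds)
        tp = two_point_matrix(tables)
        groups, unassigned = separate_chromosomes(tp["lod"], mat.marker_ids)
        assert len(groups) == 2
        chrom_of = dict(zip(mat.marker_ids, truth.chrom_of_marker))
        for members in groups.values():
            assert len({chrom_of[m] for m in members}) == 1

    def test_threshold_above_all_edges_gives_nothing(self):
        lod = np.full((20, 20), 30.0)
        groups, unassigned = separate_chromosomes(lod, [f"m{i}" for i in range(20)], 35, 10)
        assert groups == {}
        assert len(unassigned) == 20

    def test_min_size_excludes_small_components(self):
        lod = np.zeros((19, 19))
        lod[:9, :9] = 40.0  # 9-marker component: below the size floor
        lod[9:, 9:] = 40.0  # 10-marker component
        ids = [f"m{i}" for i in range(19)]
        groups, unassigned = separate_chromosomes(lod, ids, 35, 10)
        assert len(groups) == 1
        assert len(groups[1]) == 10
        assert set(unassigned) == {f"m{i}" for i in range(9)}


class TestJoinSingles:
    def _setup(self):
        ids = [f"m{i}" for i in range(5)]
        groups = {1: ["m0", "m1"], 2: ["m2", "m3"]}
        lod = np.zeros((5, 5))
        return ids, groups, lod

    def test_joined_when_both_cuts_pass(self):
        ids, groups, lod = self._setup()
        lod[4, 0] = 12.0
        lod[4, 2] = 8.0
        out = join_singles(["m4"], groups, lod, ids)
        assert "m4" in out[1]

    def test_not_joined_when_margin_too_small(self):
        ids, groups, lod = self._setup()
        lod[4, 0] = 12.0
        lod[4, 2] = 10.0
        out = join_singles(["m4"], groups, lod, ids)
        assert "m4" not in out[1] and "m4" not in out[2]

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            n = 12
            ids = [f"m{i}" for i in range(n)]
            groups = {1: ids[:4], 2: ids[4:8]}
            lod = rng.uniform(0, 15, size=(n, n))
            lod = (lod + lod.T) / 2
            singles = ids[8:]
            out = join_singles(singles, groups, lod, ids, lod_limit=10, lod_diff=3)
            for m in singles:
                mi = ids.index(m)
                best = {
                    lg: max(lod[mi, ids.index(x)] for x in members)
                    for lg, members in groups.items()
                }
                ranked = sorted(best.items(), key=lambda kv: -kv[1])
                should_join = ranked[0][1] >= 10 and ranked[0][1] - ranked[1][1] >= 3
                joined_to = [lg for lg, mem in out.items() if m in mem]
                if should_join:
                    assert joined_to == [ranked[0][0]]
                else:
                    assert joined_to == []


class TestCollapseDuplicates:
    def test_identical_markers_cluster_with_complete_representative(self):
        base = np.array([0, 1, 2, 1, 0, 1, 2, 0, 1, 1], dtype=np.int8)
        codes = np.stack([base, base], axis=1)
        clusters = collapse_duplicates(codes, ["a", "b"], np.array([5.0, 9.0]))
        assert clusters.representatives == ["b"]
        assert clusters.members["b"] == ["a", "b"]

    def test_single_conflict_separates(self):
        base = np.array([0, 1, 2, 1, 0, 1, 2, 0, 1, 1], dtype=np.int8)
        other = base.copy()
        other[3] = 2
        codes = np.stack([base, other], axis=1)
        clusters = collapse_duplicates(codes, ["a", "b"], np.array([5.0, 9.0]))
        assert len(clusters.representatives) == 2

    def test_missing_entries_tolerated_within_rate(self):
        base = np.array([0, 1, 2, 1, 0] * 8, dtype=np.int8)
        masked = base.copy()
        masked[0] = -1  # 2.5% missing, no conflicts
        codes = np.stack([base, masked], axis=1)
        clusters = collapse_duplicates(codes, ["a", "b"], np.array([9.0, 5.0]))
        assert clusters.representatives == ["a"]

    def test_matches_bruteforce_closure_oracle(self, rng):
        n_off, k = 30, 12
        codes = rng.choice([-1, 0, 1, 2], size=(n_off, k), p=[0.02, 0.3, 0.38, 0.3]).astype(np.int8)
        codes[:, 5] = codes[:, 3]  # plant one duplicate pair
        ids = [f"m{i}" for i in range(k)]
        info = rng.uniform(0, 1, size=k)
        clusters = collapse_duplicates(codes, ids, info, missing_tol=0.05)

        # oracle: pairwise compatibility + transitive closure
        missing_ok = (codes < 0).mean(axis=0) <= 0.05
        parent = list(range(k))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i in range(k):
            for j in range(i + 1, k):
                if not (missing_ok[i] and missing_ok[j]):
                    continue
                both = (codes[:, i] >= 0) & (codes[:, j] >= 0)
                if not np.any(codes[both, i] != codes[both, j]):
                    parent[find(i)] = find(j)
        oracle = {}
        for i in range(k):
            oracle.setdefault(find(i), set()).add(ids[i])
        got = {frozenset(v) for v in clusters.members.values()}
        assert got == {frozenset(v) for v in oracle.values()}


class TestOrderMarkers:
    def test_three_marker_exhaustive_example(self):
        r = np.array([[0, 0.05, 0.10], [0.05, 0, 0.05], [0.10, 0.05, 0]])
        D = kosambi(r)
        order = order_markers(D)
        assert order in ([0, 1, 2], [2, 1, 0])

    def test_two_markers(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        assert order_markers(D) in ([0, 1], [1, 0])

    def test_empty_raises(self):
        with pytest.raises(DataError):
            order_markers(np.zeros((0, 0)))

    def test_simulated_fifty_marker_group(self):
        """Seriation + placement refinement recover the true order."""
        from catmap.linkage import compute_map_distances

        cfg = TrueMapConfig.regular(1, 60.0, 50, genotyping_error_rate=0.01, missing_rate=0.02)
        peds, mat, truth = simulate_families(cfg, PedigreeSpec((120, 119, 120, 119)), seed=51)
        fv = filter_markers(mat, peds)
        keep = [m for m in mat.marker_ids if fv.loc[m, "retained"]]
        tables = TransmissionTables(mat, peds)
        idx = mat.marker_positions(keep)
        tp = two_point_matrix(tables, idx)
        r = np.clip(np.nan_to_num(tp["r"], nan=0.5), 0, 0.4999)
        D = np.where(tp["N"] > 0, kosambi(r), 300.0)
        order = order_markers(D)
        df = compute_map_distances(tables, [keep[i] for i in order])
        pos = dict(zip(mat.marker_ids, truth.base_cM))
        tau = kendalltau(np.arange(len(df)), [pos[m] for m in df["marker_id"]]).statistic
        assert abs(tau) >= 0.95


class TestReinsert:
    def test_expansion_arithmetic(self):
        from catmap.linkage import DuplicateClusters

        reps = [f"r{i}" for i in range(10)]
        members = {r: sorted([r] + [f"{r}_d{j}" for j in range(3)]) for r in reps}
        clusters = DuplicateClusters(reps, members)
        order, rep_of = reinsert_duplicates(reps, clusters)
        assert len(order) == 40
        assert len(set(rep_of.values())) == 10

    def test_no_duplicates_is_identity(self):
        from catmap.linkage import DuplicateClusters

        reps = ["a", "b", "c"]
        clusters = DuplicateClusters(reps, {r: [r] for r in reps})
        order, rep_of = reinsert_duplicates(["b", "a", "c"], clusters)
        assert order == ["b", "a", "c"]

    def test_orphan_cluster_raises(self):
        from catmap.linkage import DuplicateClusters

        clusters = DuplicateClusters(["a", "b"], {"a": ["a"], "b": ["b"]})
        with pytest.raises(DataError):
            reinsert_duplicates(["a"], clusters)
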