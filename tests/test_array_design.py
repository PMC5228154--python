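"""Array-design cascade: flanks, filters, classification, spacing, probes."""
import numpy as np
import pytest

from catmap.array_design import (
    ArrayManifest,
    apply_pconvert_threshold,
    build_manifest,
    classify_snp,
    design_array,
    extract_flank,
    filter_candidate,
    filter_candidates,
    filter_unique_flanks,
    flag_less_unique,
    gc_fraction,
    greedy_spacing_select,
    has_low_complexity_run,
    revcomp,
    select_qc_probes,
)
from catmap.errors import FlankTruncationError, InvalidConfigError, ShortfallError
from catmap.simulate import CandidateSNP, default_populations, simulate_pconvert
from catmap.simulate.genome import GenomeModel


def _genome_from_seq(seq, sid="s1"):
    return GenomeModel({sid: len(seq)}, {}, {}, {sid: seq})


def _snp(snp_id, pos=500, scaffold="s1", ref="A", alts=("C",), flank=None,
         freqs=None, genic=False, source="genome"):
    if freqs is None:  # plain channel-specific, not private to one strain
        freqs = {"Thompson": 0.4, "Hatchery": 0.3, "Blue": 0.0}
    return CandidateSNP(
        snp_id, scaffold, pos, ref, list(alts), flank, freqs, genic, source,
    )


class TestFlanks:
    def test_exact_fit_returns_whole_scaffold(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=71))
        g = _genome_from_seq(seq)
        assert extract_flank(g, "s1", 36) == seq

    def test_edge_positions_rejected(self, rng):
        g = _genome_from_seq("".join(rng.choice(list("ACGT"), size=200)))
        with pytest.raises(FlankTruncationError):
            extract_flank(g, "s1", 10)
        with pytest.raises(FlankTruncationError):
            extract_flank(g, "s1", 180)

    def test_flank_matches_independent_slice(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=500))
        g = _genome_from_seq(seq)
        for pos in (36, 100, 465):
            assert extract_flank(g, "s1", pos) == seq[pos - 36 : pos + 35]


class TestUniqueness:
    def test_planted_duplicate_fails(self, rng):
        flank = "".join(rng.choice(list("ACGT"), size=71))
        filler = "".join(rng.choice(list("ACGT"), size=300))
        seq = filler + flank + filler[::-1] + flank + filler
        g = _genome_from_seq(seq)
        pos = 300 + 36
        snp = _snp("dup", pos=pos, flank=flank)
        assert filter_unique_flanks([snp], g)["dup"] is False

    def test_reverse_complement_duplicate_fails(self, rng):
        flank = "".join(rng.choice(list("ACGT"), size=71))
        filler = "".join(rng.choice(list("ACGT"), size=300))
        seq = filler + flank + filler + revcomp(flank)
        g = _genome_from_seq(seq)
        snp = _snp("rc", pos=300 + 36, flank=flank)
        assert filter_unique_flanks([snp], g)["rc"] is False

    def test_unique_flank_passes_vs_scan_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        g = _genome_from_seq(seq)
        pos = 25_000
        flank = seq[pos - 36 : pos + 35]
        # independent oracle: overlapping regex scan on both strands
        import re

        n = len(re.findall(f"(?={re.escape(flank)})", seq))
        n += len(re.findall(f"(?={re.escape(revcomp(flank))})", seq))
        snp = _snp("u", pos=pos, flank=flank)
        assert filter_unique_flanks([snp], g)["u"] is (n == 1)


class TestFilters:
    def test_triallelic_flagged(self):
        v = filter_candidate(_snp("t", alts=("C", "G"), flank="ACGT" * 17 + "ACG"))
        assert "not_biallelic" in v.reason_codes

    def test_gc_bounds(self):
        high_gc = "G" * 25 + "C" * 20 + "ATATGCGCGT" * 2 + "GCGCABG"[:6]
        flank = ("GC" * 35 + "A")[:71]
        v = filter_candidate(_snp("g", flank=flank))
        assert gc_fraction(flank) > 0.70
        assert "gc_out_of_range" in v.reason_codes

    def test_adjacent_snp_within_35bp(self):
        snps = [_snp("a", pos=500), _snp("b", pos=520)]
        verdicts = filter_candidates(snps, genome=None)
        assert "adjacent_snp_35bp" in verdicts["a"].reason_codes
        assert "adjacent_snp_35bp" in verdicts["b"].reason_codes

    def test_distant_neighbor_ok(self):
        snps = [_snp("a", pos=500), _snp("b", pos=600)]
        verdicts = filter_candidates(snps, genome=None)
        assert "adjacent_snp_35bp" not in verdicts["a"].reason_codes

    def test_low_complexity_runs(self):
        assert has_low_complexity_run("ACGT" * 5 + "AAAAAAAA" + "ACGT" * 5)
        assert has_low_complexity_run("CGTA" * 3 + "ATATATAT" + "GGCC" * 3)
        assert not has_low_complexity_run("ACGTTGCAACGGTTACAGTC")

    def test_soft_codes_do_not_fail(self):
        v = filter_candidate(_snp("s", ref="A", alts=("T",), freqs={"Thompson": 0.05}))
        assert v.passed
        assert v.soft_codes == {"at_cg_pair", "low_maf"}
        assert v.tier == 2

    def test_missing_frequencies_error(self):
        with pytest.raises(InvalidConfigError):
            filter_candidate(_snp("m", freqs={}))


class TestClassification:
    def test_examples(self):
        pops = default_populations()
        channel_only = {p.name: 0.3 if p.species == "channel" else 0.0 for p in pops}
        assert classify_snp(channel_only, pops) == "channel_specific"
        fixed = {p.name: 0.0 if p.species == "channel" else 1.0 for p in pops}
        assert classify_snp(fixed, pops) == "interspecific_fixed"
        blue_only = {p.name: 0.0 if p.species == "channel" else 0.4 for p in pops}
        assert classify_snp(blue_only, pops) == "blue_specific"
        shared = {p.name: 0.5 for p in pops}
        assert classify_snp(shared, pops) == "shared_heterozygous"

    def test_strain_refinement(self):
        pops = default_populations()
        private = {p.name: 0.0 for p in pops}
        private["Marion"] = 0.3
        assert classify_snp(private, pops, strain_level=True) == "strain_specific:Marion"
        private = {p.name: 0.0 for p in pops}
        private["Wild"] = 0.2
        assert classify_snp(private, pops, strain_level=True) == "wild_specific"

    def test_random_tables_match_rule_oracle(self, rng):
        pops = default_populations()

        def oracle(freqs):
            ch = [freqs[p.name] for p in pops if p.species == "channel"]
            bl = [freqs[p.name] for p in pops if p.species == "blue"]
            chp = any(0 < f < 1 for f in ch)
            blp = any(0 < f < 1 for f in bl)
            if chp and blp:
                return "shared_heterozygous"
            if chp:
                return "channel_specific"
            if blp:
                return "blue_specific"
            fa = (0 if all(f == 0 for f in ch) else 1 if all(f == 1 for f in ch) else None)
            fb = (0 if all(f == 0 for f in bl) else 1 if all(f == 1 for f in bl) else None)
            if fa is not None and fb is not None and fa != fb:
                return "interspecific_fixed"
            return "monomorphic"

        for _ in range(300):
            freqs = {
                p.name: float(rng.choice([0.0, 1.0, rng.random()])) for p in pops
            }
            assert classify_snp(freqs, pops) == oracle(freqs)


def _greedy_oracle(snps, gap):
    """Independent left-to-right scan (tier-1 only fixtures)."""
    chosen = []
    last = None
    for s in sorted(snps, key=lambda s: (s.pos, -s.pooled_maf, s.snp_id)):
        if last is None or s.pos - last >= gap:
            chosen.append(s.snp_id)
            last = s.pos
    return chosen


class TestGreedySpacing:
    def _verdicts(self, snps):
        # spacing is exercised in isolation: every candidate passes the
        # hard filters (the adjacency filter has its own tests)
        from catmap.array_design import FilterVerdict

        return {s.snp_id: FilterVerdict(s.snp_id) for s in snps}

    def test_documented_example(self):
        snps = [
            _snp("a", pos=100, genic=True),
            _snp("b", pos=250, genic=True),
            _snp("c", pos=450, genic=True),
        ]
        sel = greedy_spacing_select(snps, self._verdicts(snps), genic_gap=200)
        assert set(sel) == {"a", "c"}

    def test_single_snp_selected(self):
        snps = [_snp("only", pos=300, genic=True)]
        assert greedy_spacing_select(snps, self._verdicts(snps)) == ["only"]

    def test_crowded_run_keeps_one_per_run(self):
        snps = [_snp(f"s{i}", pos=1000 + 10 * i, genic=False) for i in range(10)]
        snps += [_snp(f"t{i}", pos=5000 + 10 * i, genic=False) for i in range(10)]
        sel = greedy_spacing_select(snps, self._verdicts(snps), intergenic_gap=350)
        assert len(sel) == 2

    def test_matches_scan_oracle(self, rng):
        positions = np.sort(rng.choice(np.arange(100, 20_000), size=40, replace=False))
        snps = [_snp(f"s{i}", pos=int(p), genic=True) for i, p in enumerate(positions)]
        sel = greedy_spacing_select(snps, self._verdicts(snps), genic_gap=200)
        assert sel == _greedy_oracle(snps, 200)

    def test_shuffle_invariance(self, rng):
        positions = rng.choice(np.arange(100, 30_000), size=30, replace=False)
        snps = [_snp(f"s{i}", pos=int(p), genic=False) for i, p in enumerate(positions)]
        verdicts = self._verdicts(snps)
        base = greedy_spacing_select(snps, verdicts)
        for _ in range(5):
            shuffled = list(snps)
            rng.shuffle(shuffled)
            assert set(greedy_spacing_select(shuffled, verdicts)) == set(base)

    def test_unmapped_sources_exempt_from_spacing(self):
        snps = [
            _snp("a", pos=100, genic=False),
            _snp("u1", pos=110, source="unmapped_scaffold"),
            _snp("u2", pos=120, source="BES"),
        ]
        sel = greedy_spacing_select(snps, self._verdicts(snps))
        assert {"u1", "u2"} <= set(sel)


class TestPconvertThreshold:
    def _scores(self):
        import pandas as pd

        return pd.DataFrame(
            {"forward": [0.9, 0.5, 0.5], "reverse": [0.7, 0.6, 0.6]},
            index=pd.Index(["hi", "cover", "drop"], name="snp_id"),
        )

    def test_max_rule(self):
        out = apply_pconvert_threshold(["hi"], self._scores(), tau=0.65)
        assert out.loc["hi", "n_probes"] == 1
        assert out.loc["hi", "direction"] == "forward"

    def test_cover_anyway_gets_both_probes(self):
        out = apply_pconvert_threshold(
            ["cover"], self._scores(), tau=0.65, cover_anyway={"cover"}
        )
        assert out.loc["cover", "n_probes"] == 2

    def test_failing_snp_dropped(self):
        out = apply_pconvert_threshold(["drop"], self._scores(), tau=0.65)
        assert "drop" not in out.index


class TestQCProbes:
    def test_split_and_class_on_synthetic_genome(self):
        from catmap.simulate import simulate_genome

        g = simulate_genome(3, 150_000, genic_fraction=0.0, repeat_fraction=0.0, seed=30)
        probes = select_qc_probes(g, [], n=200)
        assert (probes["class31"] == "AT").sum() == 100
        assert (probes["class31"] == "GC").sum() == 100
        for _, row in probes.iterrows():
            base31 = row["seq"][30]
            assert base31 in ("AT" if row["class31"] == "AT" else "GC")

    def test_probes_avoid_snp_flanks(self, small_genome, small_pool):
        probes = select_qc_probes(small_genome, small_pool, n=40)
        snp_pos = {(s.scaffold_id, p) for s in small_pool for p in range(s.pos - 35, s.pos + 36)}
        for _, row in probes.iterrows():
            covered = {(row["scaffold_id"], p) for p in range(row["start"], row["start"] + 71)}
            assert not (covered & snp_pos)

    def test_shortfall_raises(self):
        g = _genome_from_seq("ACGT" * 30)
        with pytest.raises(ShortfallError):
            select_qc_probes(g, [], n=2000)


class TestManifest:
    def test_empty_manifest_is_all_zero(self):
        import pandas as pd

        m = ArrayManifest(pd.DataFrame(columns=[
            "snp_id", "scaffold_id", "pos", "ref", "alt", "genic", "source",
            "category", "strain_private", "n_probes", "direction", "score"]))
        c = m.counts()
        assert c["total_snps"] == 0 and c["total_probes"] == 0

    def test_counts_match_recount_oracle(self, small_genome, small_pool):
        scores = simulate_pconvert(small_pool, seed=31)
        manifest = design_array(small_genome, small_pool, scores)
        c = manifest.counts()
        df = manifest.snps
        assert c["total_snps"] == len(df)
        assert c["genic"] == int(df["genic"].sum())
        assert c["total_probes"] == int(df["n_probes"].sum())
        assert (
            c["channel_specific"] + c["blue_specific"] + c["interspecific_fixed"]
            + c["shared_heterozygous"]
            == (df["category"] != "monomorphic").sum()
        )

    def test_spacing_respected_in_full_design(self, small_genome, small_pool):
        scores = simulate_pconvert(small_pool, seed=32)
        manifest = design_array(small_genome, small_pool, scores)
        genic = manifest.snps[manifest.snps["genic"]]
        for sid, sub in genic.groupby("scaffold_id"):
            gaps = np.diff(np.sort(sub["pos"].to_numpy()))
            assert (gaps >= 200).all()
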