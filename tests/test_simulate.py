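"""Generator-level checks: genomes, variant pools, probe scores, families."""
import numpy as np
import pytest
from scipy import stats

from catmap.errors import InvalidConfigError
from catmap.linkage.mapfun import kosambi_inverse
from catmap.simulate import (
    CandidateSNP,
    PedigreeSpec,
    PopulationSpec,
    TrueMapConfig,
    simulate_dqc,
    simulate_families,
    simulate_genome,
    simulate_pconvert,
    simulate_variant_pool,
)


class TestGenome:
    def test_degenerate_fractions_give_no_intervals(self):
        g = simulate_genome(1, 10_000, genic_fraction=0.0, repeat_fraction=0.0, seed=7)
        assert len(g.scaffolds) == 1
        assert all(not v for v in g.genic_intervals.values())
        assert all(not v for v in g.repeat_intervals.values())

    def test_requested_fractions_recovered_at_1mb(self):
        g = simulate_genome(50, 1_000_000, genic_fraction=0.3, repeat_fraction=0.1, seed=1)
        assert 0.28 <= g.genic_bp / g.total_bp <= 0.32
        assert 0.08 <= g.repeat_bp / g.total_bp <= 0.12

    def test_deterministic_for_fixed_seed(self):
        a = simulate_genome(10, 100_000, seed=3)
        b = simulate_genome(10, 100_000, seed=3)
        assert a.scaffolds == b.scaffolds
        assert a.sequences == b.sequences
        assert a.genic_intervals == b.genic_intervals

    def test_zero_length_scaffold_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_genome(100, 50, seed=0)

    def test_interval_invariants_validated(self):
        from catmap.simulate.genome import GenomeModel

        with pytest.raises(InvalidConfigError):
            GenomeModel({"s1": 100}, genic_intervals={"s1": [(10, 200)]})
        with pytest.raises(InvalidConfigError):
            GenomeModel({"s1": 100}, genic_intervals={"s1": [(10, 50), (40, 80)]})


class TestVariantPool:
    def test_poisson_density(self, small_genome):
        g = simulate_genome(20, 1_000_000, seed=2)
        snps = simulate_variant_pool(
            g, density_per_kb=1.0, seed=3, fraction_adjacent=0.0, fraction_triallelic=0.0
        )
        assert abs(len(snps) - 1000) < 3 * np.sqrt(1000)

    def test_monomorphic_population_stays_fixed(self, small_genome):
        pops = [
            PopulationSpec("ch", "channel", "species_pool"),
            PopulationSpec("bl", "blue", "species_pool"),
        ]
        snps = simulate_variant_pool(
            small_genome, pops, density_per_kb=0.5, seed=4,
            category_weights={"channel_specific": 1.0},
        )
        assert snps
        assert all(s.per_population_freqs["bl"] == 0.0 for s in snps)

    def test_triallelic_fraction_within_binomial_bounds(self):
        g = simulate_genome(10, 2_000_000, seed=5, with_sequence=False)
        snps = simulate_variant_pool(g, density_per_kb=1.0, seed=6, fraction_triallelic=0.1)
        n = len(snps)
        k = sum(not s.is_biallelic for s in snps)
        lo, hi = stats.binom.interval(0.99, n, 0.1)
        assert lo <= k <= hi

    def test_pooled_maf_floor_respected(self, small_pool):
        assert all(s.pooled_maf >= 0.049 for s in small_pool)

    def test_empty_population_list_rejected(self, small_genome):
        with pytest.raises(InvalidConfigError):
            simulate_variant_pool(small_genome, populations=[], density_per_kb=1.0)


def _dummy_snps(n):
    return [
        CandidateSNP(f"s{i}", "scf", 100, "A", ["C"], None, {"p": 0.3}) for i in range(n)
    ]


class TestPconvert:
    def test_retained_set_calibration(self):
        """Max of the two probe scores: mean 0.71, 97% above 0.65."""
        scores = simulate_pconvert(_dummy_snps(20_000), seed=8)
        best = scores.max(axis=1)
        assert abs(best.mean() - 0.71) < 0.02
        assert abs((best > 0.65).mean() - 0.97) < 0.02

    def test_degenerate_mass_at_one_passes_any_threshold(self):
        scores = simulate_pconvert(_dummy_snps(500), beta_a=5e5, beta_b=1e-2, seed=9)
        assert (scores > 0.99).all().all()

    def test_deterministic(self):
        snps = _dummy_snps(50)
        a = simulate_pconvert(snps, seed=10)
        b = simulate_pconvert(snps, seed=10)
        assert a.equals(b)


def _mendelian_ok(parent_a, parent_b, off):
    """Offspring dosage must be a possible sum of one allele from each parent."""
    options = {
        (a, b): {x + y for x in ({0} if a == 0 else {1} if a == 2 else {0, 1})
                 for y in ({0} if b == 0 else {1} if b == 2 else {0, 1})}
        for a in (0, 1, 2) for b in (0, 1, 2)
    }
    return all(
        off[i, j] in options[(parent_a[j], parent_b[j])]
        for i in range(off.shape[0]) for j in range(off.shape[1])
    )


class TestFamilies:
    def test_clean_offspring_are_mendelian_consistent(self):
        cfg = TrueMapConfig.regular(2, 50.0, 20)
        peds, mat, _ = simulate_families(cfg, PedigreeSpec((30, 30)), seed=20)
        for fam in peds:
            sire, dam = mat.row(fam.sire_id), mat.row(fam.dam_id)
            off = mat.codes[mat.offspring_rows(fam)]
            assert _mendelian_ok(sire, dam, off)

    def test_zero_distance_markers_never_recombine(self):
        cfg = TrueMapConfig(marker_positions=[np.array([10.0, 10.0])])
        _, _, truth = simulate_families(cfg, PedigreeSpec((50,), shared_sire=()), seed=21)
        for xo_lists in truth.crossovers.values():
            for per_chrom in xo_lists:
                assert all(len(x) == 0 for x in per_chrom)

    def test_kosambi_fifty_cm_recombinant_fraction(self):
        """Across >=5000 meioses, the realised recombinant fraction of a
        50 cM interval matches the inverse Kosambi value 0.3808."""
        cfg = TrueMapConfig(
            marker_positions=[np.array([0.0, 50.0])], female_scale=1.0
        )
        peds, _, truth = simulate_families(cfg, PedigreeSpec((1300, 1300)), seed=22)
        rec = tot = 0
        for xo_lists in truth.crossovers.values():
            for per_chrom in xo_lists:
                rec += len(per_chrom[0]) % 2
                tot += 1
        assert tot >= 5000
        p = kosambi_inverse(50.0)
        assert abs(p - 0.3808) < 5e-4
        lo, hi = stats.binom.interval(0.99, tot, p)
        assert lo <= rec <= hi

    def test_female_meioses_recombine_more_with_scale(self):
        cfg = TrueMapConfig(
            marker_positions=[np.array([0.0, 30.0])], female_scale=1.4
        )
        peds, _, truth = simulate_families(cfg, PedigreeSpec((1250, 1250)), seed=23)
        counts = {"dam": [0, 0], "sire": [0, 0]}
        for (fam, role), xo_lists in truth.crossovers.items():
            for per_chrom in xo_lists:
                counts[role][0] += len(per_chrom[0]) % 2
                counts[role][1] += 1
        p_f = counts["dam"][0] / counts["dam"][1]
        p_m = counts["sire"][0] / counts["sire"][1]
        # one-sided two-proportion comparison at n = 5000
        se = np.sqrt(p_f * (1 - p_f) / counts["dam"][1] + p_m * (1 - p_m) / counts["sire"][1])
        assert (p_f - p_m) / se > 2.33

    def test_missing_rate_applied(self):
        cfg = TrueMapConfig.regular(1, 50.0, 40, missing_rate=0.1)
        peds, mat, _ = simulate_families(cfg, PedigreeSpec((100, 100)), seed=24)
        off_rows = np.concatenate([mat.offspring_rows(f) for f in peds])
        frac = (mat.codes[off_rows] < 0).mean()
        assert 0.08 < frac < 0.12

    def test_shared_sire_identity(self):
        cfg = TrueMapConfig.regular(1, 50.0, 10)
        peds, _, _ = simulate_families(cfg, PedigreeSpec((10, 10, 10), (0, 2)), seed=25)
        assert peds[0].sire_id == peds[2].sire_id != peds[1].sire_id

    def test_marker_count_zero_rejected(self):
        with pytest.raises(InvalidConfigError):
            TrueMapConfig(marker_positions=[np.array([])])

    def test_dqc_scores_bounded_and_mostly_high(self):
        ids = [f"s{i}" for i in range(400)]
        d = simulate_dqc(ids, seed=26)
        assert ((d >= 0) & (d <= 1)).all()
        assert (d > 0.85).mean() > 0.95
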