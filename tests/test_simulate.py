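"""Pedigree, coverage, window-call and qPCR simulator behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from norinherit.genome import Chromosome, GenomeModel, MutationModel
from norinherit.simulate import (
    SimConfig,
    cross,
    draw_segregating_counts,
    founder,
    gamete,
    meiosis,
    simulate_coverage,
    simulate_cross,
    simulate_ma_replicates,
    simulate_population_calls,
    simulate_qpcr,
    simulate_window_calls,
    stage_rngs,
)

NO_JUMP = MutationModel(0.0, 0.0)


def make_f1(genome, c1=500, c2=2500):
    nors = {locus: c1 for locus in genome.nor_chromosomes()}
    p1 = founder("P1", genome, 0, nors)
    p2 = founder("P2", genome, 1, {locus: c2 for locus in genome.nor_chromosomes()})
    return cross(p1, p2, "F1", genome, NO_JUMP, np.random.default_rng(0), role="F1")


class TestMeiosis:
    def test_zero_map_no_mutation_returns_a_parental_haplotype(self):
        genome = GenomeModel(
            chromosomes=[Chromosome("Chr2", 500_000, 0.0), Chromosome("Chr3", 500_000, 0.0)],
            nor_positions={"NOR2": ("Chr2", 0)},
            baseline_region=("Chr3", 0, 500_000),
        )
        f1 = make_f1(genome)
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = meiosis(f1, "Chr2", genome, NO_JUMP, rng)
            h1, h2 = f1.haplotypes["Chr2"]
            assert np.array_equal(g.alleles, h1.alleles) or np.array_equal(
                g.alleles, h2.alleles
            )

    def test_copy_number_conserved_without_mutation(self, mini_genome, rng):
        f1 = make_f1(mini_genome)
        for _ in range(50):
            g = meiosis(f1, "Chr2", mini_genome, NO_JUMP, rng)
            assert g.nor_copies in (500, 2500)
            # copies always travel with the top-window allele
            assert g.nor_copies == (500 if g.alleles[0] == 0 else 2500)

    def test_transmitted_mean_matches_analytic_expectation(self, mini_genome, rng):
        f1 = make_f1(mini_genome)
        draws = np.array(
            [meiosis(f1, "Chr2", mini_genome, NO_JUMP, rng).nor_copies for _ in range(10_000)]
        )
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 1500.0) < 3 * se

    def test_negative_genetic_length_rejected(self):
        with pytest.raises(ValueError):
            Chromosome("Chr1", 1000, -1.0)

    def test_alleles_form_contiguous_blocks(self, mini_genome, rng):
        f1 = make_f1(mini_genome)
        g = gamete(f1, mini_genome, NO_JUMP, rng)
        for hap in g.values():
            switches = int((np.diff(hap.alleles.astype(int)) != 0).sum())
            assert switches <= 20  # crossovers are few on a 50 cM chromosome


class TestSimulateCross:
    def test_f2_single_window_segregation_is_1_2_1(self, mini_genome):
        cfg = SimConfig(design="F2", n_individuals=10_000, mu=0.0, seed=11)
        pop = simulate_cross(cfg, mini_genome)
        codes = np.array([ind.diplotype("Chr2")[0] for ind in pop])
        observed = np.bincount(codes, minlength=3)
        chi2 = stats.chisquare(observed, f_exp=np.array([0.25, 0.5, 0.25]) * len(pop))
        assert chi2.pvalue > 0.01

    def test_ma_without_mutation_keeps_founder_copy_number(self, mini_genome):
        cfg = SimConfig(design="MA", n_individuals=5, n_generations=10, mu=0.0, seed=2)
        pop = simulate_cross(cfg, mini_genome)
        assert len(pop) == 5 * 11
        totals = {ind.total_nor_copies(mini_genome) for ind in pop}
        assert totals == {1000}  # 2 haplotypes x 500 copies at the single NOR

    def test_ril_residual_heterozygosity_decays_as_half_per_generation(self, mini_genome):
        g_self = 6
        cfg = SimConfig(design="RIL", n_individuals=400, n_generations=g_self, mu=0.0, seed=5)
        pop = simulate_cross(cfg, mini_genome)
        het = np.mean([np.mean(ind.diplotype("Chr3") == 1) for ind in pop])
        expect = 0.5**g_self
        se = np.sqrt(expect * (1 - expect) / len(pop))
        assert abs(het - expect) < 4 * se

    def test_total_copy_number_conserved_in_any_pedigree_without_jumps(self, mini_genome):
        cfg = SimConfig(design="RIL", n_individuals=30, n_generations=9, mu=0.0, seed=3)
        for ind in simulate_cross(cfg, mini_genome):
            c1, c2 = ind.nor_copy_pair("Chr2")
            assert {c1, c2}.issubset({500, 2500})

    def test_rejects_empty_population(self):
        with pytest.raises(ValueError):
            SimConfig(design="F2", n_individuals=0)

    def test_fixed_seed_is_bit_reproducible(self, mini_genome):
        cfg = SimConfig(design="F2", n_individuals=25, seed=9)
        rngs1 = stage_rngs(9, ("a", "b"))
        rngs2 = stage_rngs(9, ("a", "b"))
        pop1 = simulate_cross(cfg, mini_genome, rng=rngs1["a"])
        pop2 = simulate_cross(cfg, mini_genome, rng=rngs2["a"])
        for i1, i2 in zip(pop1, pop2):
            assert i1.total_nor_copies(mini_genome) == i2.total_nor_copies(mini_genome)
            assert np.array_equal(i1.diplotype("Chr2"), i2.diplotype("Chr2"))
        calls1 = simulate_population_calls(pop1, mini_genome, cfg, rngs1["b"])
        calls2 = simulate_population_calls(pop2, mini_genome, cfg, rngs2["b"])
        pd.testing.assert_frame_equal(calls1, calls2)


class TestCoverage:
    def test_noise_free_expectations(self, mini_genome, rng):
        f1 = make_f1(mini_genome)  # diploid total 3000
        cov = simulate_coverage(f1, mini_genome, 1.0, 0.0, rng)
        assert cov.mean18S == 1500.0
        assert cov.meanBaseline == 1.0

    def test_same_seed_gives_identical_summary(self, mini_genome):
        f1 = make_f1(mini_genome)
        c1 = simulate_coverage(f1, mini_genome, 20.0, 0.2, np.random.default_rng(7))
        c2 = simulate_coverage(f1, mini_genome, 20.0, 0.2, np.random.default_rng(7))
        assert c1 == c2

    def test_ratio_unbiased_under_negative_binomial_noise(self, mini_genome, rng):
        f1 = make_f1(mini_genome)
        ratios = []
        for _ in range(200):
            cov = simulate_coverage(f1, mini_genome, 20.0, 0.2, rng)
            ratios.append(cov.mean18S / cov.meanBaseline)
        assert abs(np.mean(ratios) - 1500.0) / 1500.0 < 0.01

    def test_negative_dispersion_rejected(self, mini_genome, rng):
        f1 = make_f1(mini_genome)
        with pytest.raises(ValueError):
            simulate_coverage(f1, mini_genome, 20.0, -0.1, rng)


class TestWindowCalls:
    def _aa_individual(self, genome):
        nors = {locus: 500 for locus in genome.nor_chromosomes()}
        return founder("AA", genome, 0, nors)

    def test_no_error_true_aa_gives_only_maternal_calls(self, mini_genome, rng):
        seg = draw_segregating_counts(mini_genome, 300.0, 0.0, rng)
        calls = simulate_window_calls(self._aa_individual(mini_genome), mini_genome, seg, 1.0, 0.0, rng)
        assert (calls["n_maternal"] == calls["n_called"]).all()
        assert (calls["n_het"] == 0).all()
        assert (calls["n_paternal"] == 0).all()

    def test_zero_call_rate_gives_empty_windows(self, mini_genome, rng):
        seg = draw_segregating_counts(mini_genome, 300.0, 0.0, rng)
        calls = simulate_window_calls(self._aa_individual(mini_genome), mini_genome, seg, 0.0, 0.0, rng)
        assert (calls["n_called"] == 0).all()

    def test_error_rate_sets_wrong_class_fraction(self, mini_genome, rng):
        ind = self._aa_individual(mini_genome)
        fracs = []
        for _ in range(100):
            seg = draw_segregating_counts(mini_genome, 100.0, 0.0, rng)
            calls = simulate_window_calls(ind, mini_genome, seg, 1.0, 0.02, rng)
            fracs.append((calls["n_maternal"].sum() / calls["n_called"].sum()))
        assert abs(np.mean(fracs) - 0.98) < 0.003

    def test_counts_are_internally_consistent(self, mini_genome, rng):
        seg = draw_segregating_counts(mini_genome, 300.0, 0.2, rng)
        cfg = SimConfig(design="F2", n_individuals=10, seed=4)
        pop = simulate_cross(cfg, mini_genome, rng=rng)
        calls = simulate_population_calls(pop, mini_genome, cfg, rng)
        assert (
            calls["n_maternal"] + calls["n_paternal"] + calls["n_het"]
            <= calls["n_called"]
        ).all()
        assert (calls["n_called"] <= calls["n_segregating"]).all()

    def test_low_diversity_windows_fall_below_discard_threshold(self, mini_genome, rng):
        seg = draw_segregating_counts(mini_genome, 300.0, 0.5, rng)
        assert (seg["n_segregating"] < 100).any()


class TestQpcr:
    def test_noise_free_table_recovers_copy_number_exactly(self, rng):
        cfg = SimConfig(replicate_sd=0.0, plate_offset_sd=0.0, target_offset_sd=0.0)
        table = simulate_qpcr({"s1": 1500.0, "s2": 500.0}, cfg, rng)
        means = table.groupby(["sample_id", "target"])["ct_value"].mean().unstack()
        est = 2 ** (means["ACT2"] - means["18S"])
        assert est["s1"] == pytest.approx(1500.0)
        assert est["s2"] == pytest.approx(500.0)

    def test_shared_plate_offset_cancels_in_delta_ct(self, rng):
        cfg = SimConfig(replicate_sd=0.0, target_offset_sd=0.0)
        table = simulate_qpcr(
            {"s1": 1200.0}, cfg, rng, plate_offsets={"plate1": 1.0}
        )
        means = table.groupby(["sample_id", "target"])["ct_value"].mean().unstack()
        est = 2 ** (means["ACT2"] - means["18S"])
        assert est["s1"] == pytest.approx(1200.0)

    def test_target_specific_offset_biases_estimate_by_two_to_the_offset(self, rng):
        cfg = SimConfig(replicate_sd=0.0, plate_offset_sd=0.0)
        table = simulate_qpcr(
            {"s1": 1000.0},
            cfg,
            rng,
            plate_offsets={"plate1": 0.0},
            target_offsets={("plate1", "18S"): 0.5, ("plate1", "ACT2"): 0.0},
        )
        means = table.groupby(["sample_id", "target"])["ct_value"].mean().unstack()
        est = 2 ** (means["ACT2"] - means["18S"])
        assert est["s1"] == pytest.approx(1000.0 * 2**-0.5)

    def test_control_present_on_every_plate(self, rng):
        cfg = SimConfig(plate_capacity=3)
        copies = {f"s{i}": 1000.0 for i in range(10)}
        table = simulate_qpcr(copies, cfg, rng)
        for _, grp in table.groupby("plate_id"):
            assert cfg.control_sample_id in set(grp["sample_id"])


class TestMaReplicates:
    def test_no_mutation_keeps_all_values_at_founder(self, mini_genome):
        cfg = SimConfig(design="MA", mu=0.0, seed=6)
        rec = simulate_ma_replicates(
            cfg, n_lines=3, n_replicates=2, measured_generations=(5, 6), genome=mini_genome
        )
        assert set(rec["value"]) == {500.0}
        assert set(rec["generation"]) == {5, 6}

    def test_replicates_nested_within_lines(self, mini_genome):
        cfg = SimConfig(design="MA", mu=0.1, seed=6)
        rec = simulate_ma_replicates(
            cfg, n_lines=4, n_replicates=3, measured_generations=(5, 6), genome=mini_genome
        )
        assert (rec.groupby("replicate")["line"].nunique() == 1).all()
        assert (rec.groupby(["line", "generation"]).size() == 3).all()
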