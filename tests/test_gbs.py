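"""Window genotype calling, VCF ingestion and genetic-map estimation."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from norinherit import gbs
from norinherit.gbs import (
    GeneticMap,
    GenotyperThresholds,
    WindowCallSummary,
    build_genetic_map,
    call_window,
    call_windows,
    genotype_population,
    haldane_cm,
    read_matrix,
    window_call_rates,
    write_matrix,
)
from norinherit.genome import Chromosome, GenomeModel
from norinherit.simulate import SimConfig, simulate_cross, simulate_population_calls


def oracle_call(n_seg: int, n_called: int, n_mat: int, n_pat: int, n_het: int) -> str:
    """Literal restatement of the window rules in exact rational arithmetic."""
    if n_seg < 100 or n_called < 40:
        return "NA"
    if Fraction(n_mat, n_called) > Fraction(9, 10):
        return "A"
    if Fraction(n_pat, n_called) > Fraction(9, 10):
        return "B"
    if Fraction(n_het, n_called) > Fraction(1, 4) or Fraction(
        abs(n_mat - n_pat), n_called
    ) < Fraction(3, 10):
        return "H"
    return "NA"


def ws(n_seg, n_called, n_mat, n_pat, n_het):
    return WindowCallSummary("s", "Chr1", 0, n_seg, n_called, n_mat, n_pat, n_het)


class TestCallWindow:
    @pytest.mark.parametrize(
        "summary,expected",
        [
            (ws(150, 50, 49, 1, 0), "A"),  # 49/50 = 0.98 > 0.90
            (ws(99, 99, 99, 0, 0), "NA"),  # low diversity: 99 < 100 segregating
            (ws(200, 100, 40, 35, 25), "H"),  # |40-35|/100 < 0.30
            (ws(200, 39, 39, 0, 0), "NA"),  # 39 < 40 called
            (ws(150, 50, 1, 49, 0), "B"),
            (ws(200, 100, 50, 24, 26), "H"),  # 26% het > 25%
            (ws(200, 100, 60, 25, 15), "NA"),  # no rule fires
        ],
    )
    def test_rule_table(self, summary, expected):
        assert call_window(summary) == expected

    def test_exact_boundaries_are_strict(self):
        # exactly 90% maternal is NOT A; exactly 25% het is NOT H on its own
        assert call_window(ws(200, 40, 36, 4, 0)) != "A"
        assert call_window(ws(200, 100, 55, 20, 25)) == "NA"
        # exactly 30% parental difference is NOT H
        assert call_window(ws(200, 100, 65, 35, 0)) == "NA"

    def test_matches_exhaustive_oracle_near_thresholds(self):
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(4000):
            n_seg = int(rng.integers(90, 111))
            n_called = int(rng.integers(30, min(n_seg, 60) + 1))
            n_mat = int(rng.integers(0, n_called + 1))
            n_pat = int(rng.integers(0, n_called - n_mat + 1))
            n_het = n_called - n_mat - n_pat if rng.random() < 0.5 else int(
                rng.integers(0, n_called - n_mat - n_pat + 1)
            )
            rows.append((n_seg, n_called, n_mat, n_pat, n_het))
        df = pd.DataFrame(
            rows, columns=["n_segregating", "n_called", "n_maternal", "n_paternal", "n_het"]
        )
        vec = call_windows(df)
        for i, r in enumerate(rows):
            assert vec.iloc[i] == oracle_call(*r), r

    @given(
        n_called=st.integers(40, 120),
        n_mat=st.integers(0, 120),
        extra=st.integers(0, 120),
    )
    @settings(max_examples=200, deadline=None)
    def test_increasing_maternal_count_never_flips_a_to_b(self, n_called, n_mat, extra):
        n_mat = min(n_mat, n_called)
        n_pat = n_called - n_mat
        first = call_window(ws(200, n_called, n_mat, n_pat, 0))
        more = min(n_mat + extra, n_called)
        second = call_window(ws(200, n_called, more, n_called - more, 0))
        if first == "A":
            assert second == "A"
        if second == "B":
            assert first == "B"

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            call_window(ws(100, 50, 40, 20, 10))  # 70 classified > 50 called


class TestGenotypePopulation:
    def test_all_maternal_sample_is_all_a(self):
        df = pd.DataFrame(
            {
                "sample_id": "s1",
                "chrom": "Chr1",
                "window_index": range(5),
                "n_segregating": 200,
                "n_called": 100,
                "n_maternal": 100,
                "n_paternal": 0,
                "n_het": 0,
            }
        )
        m = genotype_population(df)
        assert (m.loc["s1"] == "A").all()

    def test_empty_input_gives_empty_matrix(self):
        assert genotype_population(pd.DataFrame()).empty

    def test_inconsistent_grids_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s2"],
                "chrom": "Chr1",
                "window_index": [0, 1],
                "n_segregating": 200,
                "n_called": 100,
                "n_maternal": 100,
                "n_paternal": 0,
                "n_het": 0,
            }
        )
        with pytest.raises(ValueError):
            genotype_population(df)

    def test_f2_calls_match_truth_at_low_error(self, mini_genome, rng):
        cfg = SimConfig(
            design="F2",
            n_individuals=60,
            mu=0.0,
            seed=8,
            call_rate=0.8,
            error_rate=0.01,
            low_diversity_fraction=0.0,
        )
        pop = simulate_cross(cfg, mini_genome, rng=rng)
        calls = simulate_population_calls(pop, mini_genome, cfg, rng)
        matrix = genotype_population(calls)
        code = {"A": 0, "H": 1, "B": 2}
        n_match = n_called = 0
        for ind in pop:
            truth = ind.diplotype("Chr2")
            for w in range(mini_genome.n_windows("Chr2")):
                call = matrix.loc[ind.id, ("Chr2", w)]
                if call != "NA":
                    n_called += 1
                    n_match += int(code[call] == truth[w])
        assert n_called > 0
        assert n_match / n_called >= 0.99

    def test_window_call_rates(self):
        m = pd.DataFrame(
            [["A", "NA"], ["B", "NA"]],
            index=["s1", "s2"],
            columns=pd.MultiIndex.from_tuples([("Chr1", 0), ("Chr1", 1)]),
        )
        rates = window_call_rates(m)
        assert rates[("Chr1", 0)] == 1.0 and rates[("Chr1", 1)] == 0.0

    def test_matrix_round_trips_through_tsv(self, tmp_path):
        m = pd.DataFrame(
            [["A", "H"], ["B", "NA"]],
            index=pd.Index(["s1", "s2"], name="sample_id"),
            columns=pd.MultiIndex.from_tuples(
                [("Chr1", 0), ("Chr1", 1)], names=["chrom", "window_index"]
            ),
        )
        write_matrix(m, tmp_path / "m.tsv")
        back = read_matrix(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(m, back)


class TestVcfIngestion:
    def _write_vcf(self, path, samples, records):
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=Chr1,length=1000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        lines = [
            f"Chr1\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
            for pos, ref, alt, gts in records
        ]
        path.write_text(header + "\n".join(lines) + "\n")

    def test_toy_three_site_window(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_vcf(
            vcf,
            ["s1"],
            [
                (100, "A", "T", ["0/0"]),
                (200, "G", "C", ["0/0"]),
                (300, "T", "A", ["0/1"]),
            ],
        )
        pmap = pd.DataFrame(
            {
                "chrom": ["Chr1"] * 3,
                "pos": [100, 200, 300],
                "maternal_allele": ["A", "G", "T"],
                "paternal_allele": ["T", "C", "A"],
            }
        )
        out = gbs.ingest_vcf(vcf, pmap)
        row = out.iloc[0]
        assert row["n_segregating"] == 3
        assert row["n_called"] == 3
        assert row["n_maternal"] == 2
        assert row["n_het"] == 1

    def test_missing_genotypes_not_counted_as_called(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_vcf(vcf, ["s1"], [(100, "A", "T", ["./."]), (200, "G", "C", ["./."])])
        pmap = pd.DataFrame(
            {
                "chrom": ["Chr1"] * 2,
                "pos": [100, 200],
                "maternal_allele": ["A", "G"],
                "paternal_allele": ["T", "C"],
            }
        )
        out = gbs.ingest_vcf(vcf, pmap)
        assert (out["n_called"] == 0).all()
        assert (out["n_segregating"] == 2).all()

    def test_sites_outside_parental_map_are_excluded(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_vcf(
            vcf, ["s1"], [(100, "A", "T", ["0/0"]), (200, "G", "C", ["0/0"])]
        )
        pmap = pd.DataFrame(
            {
                "chrom": ["Chr1"],
                "pos": [100],
                "maternal_allele": ["A"],
                "paternal_allele": ["T"],
            }
        )
        out = gbs.ingest_vcf(vcf, pmap)
        assert (out["n_segregating"] == 1).all()
        assert (out["n_called"] == 1).all()

    def test_site_with_unmapped_allele_skipped_with_warning(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        self._write_vcf(
            vcf, ["s1"], [(100, "A", "T", ["0/0"]), (200, "G", "C", ["0/0"])]
        )
        pmap = pd.DataFrame(
            {
                "chrom": ["Chr1"] * 2,
                "pos": [100, 200],
                "maternal_allele": ["A", "G"],
                "paternal_allele": ["T", "T"],  # T not an allele at pos 200
            }
        )
        with pytest.warns(UserWarning, match="skipped"):
            out = gbs.ingest_vcf(vcf, pmap)
        assert (out["n_segregating"] == 1).all()


class TestGeneticMap:
    def _perfect_matrix(self, genome, design, n, seed, spacing_cm):
        cfg = SimConfig(
            design=design,
            n_individuals=n,
            mu=0.0,
            seed=seed,
            call_rate=1.0,
            error_rate=0.0,
            low_diversity_fraction=0.0,
            n_generations=9,
        )
        rng = np.random.default_rng(seed)
        pop = simulate_cross(cfg, genome, rng=rng)
        calls = simulate_population_calls(pop, genome, cfg, rng)
        return genotype_population(calls)

    def test_identical_columns_give_zero_distance(self):
        m = pd.DataFrame(
            [["A", "A"], ["B", "B"], ["H", "H"], ["A", "A"]] * 3,
            index=[f"s{i}" for i in range(12)],
            columns=pd.MultiIndex.from_tuples(
                [("Chr1", 0), ("Chr1", 1)], names=["chrom", "window_index"]
            ),
        )
        gmap = build_genetic_map(m, "F2")
        assert gmap.loci["cM"].iloc[-1] == pytest.approx(0.0, abs=1e-3)

    def test_haldane_closed_form(self):
        assert haldane_cm(0.1) == pytest.approx(-50 * np.log(0.8), abs=1e-9)
        assert haldane_cm(0.1) == pytest.approx(11.157, abs=1e-3)

    def test_f2_map_recovers_5cm_spacing(self):
        genome = GenomeModel(
            chromosomes=[Chromosome("Chr2", 1_000_000, 50.0), Chromosome("Chr3", 1_000_000, 50.0)],
            nor_positions={"NOR2": ("Chr2", 0)},
            baseline_region=("Chr3", 0, 1_000_000),
        )
        matrix = self._perfect_matrix(genome, "F2", 500, 13, 5.0)
        gmap = build_genetic_map(matrix, "F2", genome)
        for chrom in ("Chr2", "Chr3"):
            d = np.diff(gmap.chrom_loci(chrom)["cM"].to_numpy())
            assert np.all(np.abs(d - 5.0) < 2.0)

    def test_ril_map_recovers_spacing_through_selfing_inflation(self):
        genome = GenomeModel(
            chromosomes=[Chromosome("Chr2", 1_000_000, 50.0), Chromosome("Chr3", 1_000_000, 50.0)],
            nor_positions={"NOR2": ("Chr2", 0)},
            baseline_region=("Chr3", 0, 1_000_000),
        )
        matrix = self._perfect_matrix(genome, "RIL", 500, 14, 5.0)
        gmap = build_genetic_map(matrix, "RIL", genome)
        for chrom in ("Chr2", "Chr3"):
            d = np.diff(gmap.chrom_loci(chrom)["cM"].to_numpy())
            assert np.all(np.abs(d - 5.0) < 2.5)

    def test_map_invariant_under_sample_reordering(self):
        genome = GenomeModel(
            chromosomes=[Chromosome("Chr2", 1_000_000, 50.0), Chromosome("Chr3", 1_000_000, 50.0)],
            nor_positions={"NOR2": ("Chr2", 0)},
            baseline_region=("Chr3", 0, 1_000_000),
        )
        matrix = self._perfect_matrix(genome, "F2", 80, 15, 5.0)
        g1 = build_genetic_map(matrix, "F2", genome)
        g2 = build_genetic_map(matrix.sample(frac=1.0, random_state=1), "F2", genome)
        pd.testing.assert_frame_equal(g1.loci, g2.loci)

    def test_monotone_cm_enforced(self):
        bad = pd.DataFrame(
            {"chrom": ["Chr1", "Chr1"], "window_index": [0, 1], "bp": [0, 100], "cM": [5.0, 1.0]}
        )
        with pytest.raises(ValueError):
            GeneticMap(bad)
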