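"""Reproducible study drivers at the scale used for validation.

Each function runs one complete computational experiment — simulation,
estimation, genotyping, scanning or model fitting — and returns the measured
quantities.  They are consumed by the validation test-suite and by
``scripts/acceptance.py``; all randomness is controlled by an explicit seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from norinherit import copy_number as cn
from norinherit import gbs, qtl
from norinherit.genome import GenomeModel
from norinherit.simulate import (
    SimConfig,
    founder,
    simulate_coverage,
    simulate_cross,
    simulate_population_calls,
    simulate_population_coverage,
    stage_rngs,
)
from norinherit.stability import cv_by_generation, fit_lmm, lrt, nor_matched_cv

__all__ = [
    "fish_signal_ratios",
    "genotyper_oracle_study",
    "qtl_recovery_study",
    "permutation_calibration_study",
    "estimator_bias_study",
    "lmm_oracle_study",
    "lrt_type1_study",
    "cv_instability_study",
]


# -- worked cytology examples ----------------------------------------------


def fish_signal_ratios() -> dict[str, float]:
    """Signal-area ratios of NOR2 vs NOR4 in the two parental accessions.

    High-copy northern parent: NOR2 299.64 vs NOR4 125.27 pixel areas;
    low-copy southern parent: NOR4 106.5 vs NOR2 71.17.
    """
    return {
        "high_copy_parent_nor2_vs_nor4": cn.signal_ratio(299.64, 125.27),
        "low_copy_parent_nor4_vs_nor2": cn.signal_ratio(106.5, 71.17),
    }


# -- genotyper rule-table equivalence --------------------------------------


def _oracle_call_int(n_seg: int, n_called: int, n_mat: int, n_pat: int, n_het: int) -> str:
    """Integer-arithmetic restatement of the window rules (independent route)."""
    if n_seg < 100 or n_called < 40:
        return "NA"
    if 10 * n_mat > 9 * n_called:
        return "A"
    if 10 * n_pat > 9 * n_called:
        return "B"
    if 4 * n_het > n_called or 10 * abs(n_mat - n_pat) < 3 * n_called:
        return "H"
    return "NA"


def genotyper_oracle_study(
    n_seg_values: tuple[int, ...] = (90, 99, 100, 101, 110),
    called_range: tuple[int, int] = (30, 60),
) -> dict[str, float]:
    """Exhaustive comparison of the vectorised caller with a brute-force oracle.

    Enumerates every (n_maternal, n_paternal, n_het) partition of each
    n_called in the given range, crossed with segregating-site counts that
    straddle the discard boundary (~2e5 vectors).
    """
    rows = []
    for nc in range(called_range[0], called_range[1] + 1):
        for n_mat in range(nc + 1):
            for n_pat in range(nc - n_mat + 1):
                rows.append((nc, n_mat, n_pat, nc - n_mat - n_pat))
    part = np.array(rows, dtype=np.int64)
    frames = []
    for n_seg in n_seg_values:
        if n_seg < called_range[1]:
            keep = part[part[:, 0] <= n_seg]
        else:
            keep = part
        frames.append(
            pd.DataFrame(
                {
                    "n_segregating": n_seg,
                    "n_called": keep[:, 0],
                    "n_maternal": keep[:, 1],
                    "n_paternal": keep[:, 2],
                    "n_het": keep[:, 3],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    vec = gbs.call_windows(table).to_numpy()
    oracle = np.array(
        [
            _oracle_call_int(s, c, m, p, h)
            for s, c, m, p, h in table.itertuples(index=False)
        ]
    )
    n_total = len(table)
    n_agree = int((vec == oracle).sum())
    return {
        "n_vectors": float(n_total),
        "n_agree": float(n_agree),
        "agreement_fraction": n_agree / n_total,
    }


# -- QTL parameter recovery -------------------------------------------------


def _one_f2_scan(seed: int, n_individuals: int = 93, n_perm: int = 1000):
    genome = GenomeModel.arabidopsis()
    cfg = SimConfig(
        design="F2",
        n_individuals=n_individuals,
        mu=0.0,
        seed=seed,
        parental_copy_numbers={"NOR2": (500, 2500), "NOR4": (500, 500)},
        depth_mean=20.0,
        depth_dispersion=0.1,
    )
    rngs = stage_rngs(seed, ("pedigree", "coverage", "calls"))
    pop = simulate_cross(cfg, genome, rng=rngs["pedigree"])
    coverage = simulate_population_coverage(
        pop, genome, cfg.depth_mean, cfg.depth_dispersion, rngs["coverage"]
    )
    calls = simulate_population_calls(pop, genome, cfg, rngs["calls"])
    matrix = gbs.genotype_population(calls)
    gmap = gbs.build_genetic_map(matrix, "F2", genome)
    grid = qtl.genotype_probabilities(matrix, gmap, 2.0, "F2")
    pheno = cn.estimate_ngs_table(coverage).set_index("sample_id")["value"]
    scan = qtl.scan_sim(grid, pheno)
    thr = qtl.permutation_threshold(grid, pheno, 0.05, n_perm, seed)
    return scan, thr


def qtl_recovery_study(n_runs: int = 100, seed: int = 0, n_perm: int = 1000) -> dict[str, float]:
    """Mapping an F2 whose only heritable variation sits at the NOR2 window.

    For each seeded run, checks (a) whether the genome-wide LOD peak lies on
    chromosome 2 within 10 cM of the NOR at the chromosome top, and (b)
    whether no other chromosome exceeds the 5% permutation threshold.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    on_target = off_target_clean = 0
    for s in seeds:
        scan, thr = _one_f2_scan(int(s), n_perm=n_perm)
        peaks = qtl.find_peaks(scan, thr)
        top = max(peaks, key=lambda p: p.lod)
        if top.chrom == "Chr2" and top.cM <= 10.0:
            on_target += 1
        if all(not p.significant for p in peaks if p.chrom != "Chr2"):
            off_target_clean += 1
    return {
        "n_runs": float(n_runs),
        "peak_on_chr2_within_10cM": float(on_target),
        "no_off_target_significant": float(off_target_clean),
        "peak_fraction": on_target / n_runs,
        "clean_fraction": off_target_clean / n_runs,
    }


# -- permutation threshold calibration --------------------------------------


def permutation_calibration_study(
    n_scans: int = 500, n_perm: int = 200, n_individuals: int = 100, seed: int = 0
) -> dict[str, float]:
    """False-positive rate of the genome-wide 5% threshold under the null.

    One genotype grid is simulated once (compact genome); each replicate
    draws an independent phenotype with no genetic component and tests
    whether the genome-wide maximum LOD exceeds its own 200-permutation
    threshold.
    """
    genome = GenomeModel.compact()
    cfg = SimConfig(
        design="F2",
        n_individuals=n_individuals,
        mu=0.0,
        seed=seed,
        low_diversity_fraction=0.0,
    )
    rng = np.random.default_rng(seed)
    pop = simulate_cross(cfg, genome, rng=rng)
    calls = simulate_population_calls(pop, genome, cfg, rng)
    matrix = gbs.genotype_population(calls)
    gmap = gbs.build_genetic_map(matrix, "F2", genome)
    grid = qtl.genotype_probabilities(matrix, gmap, 2.0, "F2")

    exceed = 0
    for i in range(n_scans):
        y = pd.Series(rng.normal(size=len(grid.samples)), index=grid.samples)
        scan = qtl.scan_sim(grid, y)
        thr = qtl.permutation_threshold(grid, y, 0.05, n_perm, seed=int(rng.integers(2**31)))
        exceed += int(scan.max_lod() > thr.value)
    return {
        "n_scans": float(n_scans),
        "n_exceed": float(exceed),
        "exceedance_rate": exceed / n_scans,
    }


# -- copy-number estimator accuracy -----------------------------------------


def estimator_bias_study(n_replicates: int = 200, seed: int = 0) -> dict[str, float]:
    """NGS ratio estimator against known truth, noiseless and with NB noise."""
    genome = GenomeModel.arabidopsis()
    high = founder("high", genome, 1, {"NOR2": 2000, "NOR4": 500})
    rng = np.random.default_rng(seed)
    exact = cn.estimate_ngs(simulate_coverage(high, genome, 20.0, 0.0, rng)).value
    truth = high.total_nor_copies(genome) / 2.0
    ratios = [
        cn.estimate_ngs(simulate_coverage(high, genome, 20.0, 0.1, rng)).value
        for _ in range(n_replicates)
    ]
    rel_bias = (np.mean(ratios) - truth) / truth
    return {
        "noiseless_estimate": exact,
        "true_copies_per_haploid": truth,
        "noiseless_abs_error": abs(exact - truth),
        "relative_bias_percent": 100.0 * float(rel_bias),
        "n_replicates": float(n_replicates),
    }


# -- mixed-model machinery ---------------------------------------------------


def _ma_like_records(rng, n_lines=10, n_reps=5, s_line=50.0, s_rep=20.0, s_e=5.0, gen_eff=0.0):
    rows = []
    for li in range(n_lines):
        le = rng.normal(0, s_line)
        for ri in range(n_reps):
            re = rng.normal(0, s_rep)
            for gi, g in enumerate((32, 33)):
                rows.append(
                    {
                        "line": f"L{li}",
                        "replicate": f"L{li}r{ri}",
                        "generation": g,
                        "value": 1000 + le + re + gen_eff * gi + rng.normal(0, s_e),
                    }
                )
    return pd.DataFrame(rows)


def lmm_oracle_study(seed: int = 0) -> dict[str, float]:
    """Profiled fitter versus a dense GLS evaluation over a lambda grid."""
    rng = np.random.default_rng(seed)
    df = _ma_like_records(rng)
    fit = fit_lmm(df, ("line", "generation"))

    from norinherit.stability import _design

    x, _ = _design(df, ("line", "generation"))
    y = df["value"].to_numpy()
    groups = pd.Categorical(df["line"] + ":" + df["replicate"]).codes
    n = len(y)
    z = np.zeros((n, groups.max() + 1))
    z[np.arange(n), groups] = 1.0

    def dense_ll(lam: float) -> float:
        v = np.eye(n) + lam * z @ z.T
        vi = np.linalg.inv(v)
        beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
        resid = y - x @ beta
        s2 = resid @ vi @ resid / n
        _, logdet = np.linalg.slogdet(v)
        return float(-0.5 * n * (np.log(2 * np.pi * s2) + 1.0) - 0.5 * logdet)

    grid = np.logspace(-6, 6, 121)
    best_grid = max(dense_ll(l) for l in grid)
    at_optimum = dense_ll(fit.lam)
    return {
        "fit_loglik": fit.loglik,
        "dense_loglik_at_optimum": at_optimum,
        "abs_loglik_diff": abs(fit.loglik - at_optimum),
        "grid_max_minus_fit": best_grid - fit.loglik,
    }


def lrt_type1_study(n_sim: int = 1000, seed: int = 0) -> dict[str, float]:
    """Type-I error of the generation LRT when generation has no effect."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sim):
        df = _ma_like_records(rng, gen_eff=0.0)
        full = fit_lmm(df, ("line", "generation"))
        reduced = fit_lmm(df, ("line",))
        rejections += int(lrt(full, reduced).p_value < 0.05)
    return {
        "n_simulations": float(n_sim),
        "n_rejections": float(rejections),
        "type1_rate": rejections / n_sim,
    }


# -- copy-number instability over generations --------------------------------


def cv_instability_study(
    n_runs: int = 100,
    n_lineages: int = 30,
    n_generations: int = 33,
    mu: float = 0.02,
    seed: int = 0,
) -> dict[str, float]:
    """CV of copy number versus generations since divergence in MA lineages.

    Independent single-seed-descent lineages share both NOR genotypes, so
    the coefficient of variation among them isolates mutational divergence.
    Returns the Spearman correlation between generation and the across-run
    mean CV, plus the stable-inheritance control (mu = 0, CV identically 0).
    """
    genome = GenomeModel.arabidopsis()
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    curves = []
    for s in seeds:
        cfg = SimConfig(
            design="MA", n_individuals=n_lineages, n_generations=n_generations,
            mu=mu, seed=int(s),
        )
        pop = simulate_cross(cfg, genome)
        cv = nor_matched_cv(pop, genome)
        curves.append(cv.set_index("generation")["cv"])
    mean_cv = pd.concat(curves, axis=1).mean(axis=1).sort_index()
    rho = stats.spearmanr(mean_cv.index.to_numpy(), mean_cv.to_numpy())

    cfg0 = SimConfig(design="MA", n_individuals=10, n_generations=10, mu=0.0, seed=seed)
    pop0 = simulate_cross(cfg0, genome)
    cv0 = nor_matched_cv(pop0, genome)
    return {
        "n_runs": float(n_runs),
        "spearman_rho": float(rho.statistic),
        "spearman_p": float(rho.pvalue),
        "mean_cv_final_generation": float(mean_cv.iloc[-1]),
        "max_cv_without_mutation": float(cv0["cv"].max()),
    }
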