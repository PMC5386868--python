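"""End-to-end orchestration: simulate -> estimate -> genotype -> scan -> stability.

A run is driven by one TOML config with a master seed; per-stage random
streams are derived from it so each stage is independently reproducible and
a rerun with the same config produces byte-identical tables.  Every stage
materialises its outputs as TSV/JSON in the run directory and the manifest
records the config hash, seed and produced files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from norinherit import copy_number as cn
from norinherit import gbs, qtl, stability
from norinherit.genome import GenomeModel
from norinherit.simulate import (
    SimConfig,
    simulate_cross,
    simulate_ma_replicates,
    simulate_population_calls,
    simulate_population_coverage,
    simulate_qpcr,
    stage_rngs,
    write_population,
    write_table,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("norinherit")

STAGES = ("pedigree", "coverage", "calls", "qpcr", "scan", "stability")


@dataclass
class RunConfig:
    simulation: SimConfig = field(default_factory=SimConfig)
    genome_preset: str = "arabidopsis"  # arabidopsis | compact
    thresholds: gbs.GenotyperThresholds = field(default_factory=gbs.GenotyperThresholds)
    scan_step_cM: float = 2.0
    scan_alpha: float = 0.05
    scan_permutations: int = 1000
    cofactor_scan: bool = True
    stability_lines: int = 10
    stability_replicates: int = 5
    measured_generations: tuple[int, ...] = (32, 33)
    seed: int = 0
    output_dir: str = "norinherit-run"
    stages: tuple[str, ...] = ("simulate", "estimate", "genotype", "scan", "stability")
    inputs: dict[str, str] = field(default_factory=dict)  # stage inputs when not simulating

    def genome(self) -> GenomeModel:
        if self.genome_preset == "arabidopsis":
            return GenomeModel.arabidopsis(self.thresholds.window_size_bp)
        if self.genome_preset == "compact":
            return GenomeModel.compact(self.thresholds.window_size_bp)
        raise ValueError(f"unknown genome preset {self.genome_preset!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim = SimConfig(**{
            k: (
                {kk: tuple(vv) for kk, vv in v.items()}
                if k == "parental_copy_numbers"
                else v
            )
            for k, v in raw.get("simulation", {}).items()
        })
        thr = gbs.GenotyperThresholds(**raw.get("thresholds", {}))
        run = raw.get("run", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation", "thresholds"}
        unknown = set(run) - known
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        if "stages" in run:
            run["stages"] = tuple(run["stages"])
        if "measured_generations" in run:
            run["measured_generations"] = tuple(run["measured_generations"])
        return cls(simulation=sim, thresholds=thr, **run)

    def config_hash(self) -> str:
        def canon(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: canon(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {str(k): canon(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [canon(v) for v in obj]
            return obj

        blob = json.dumps(canon(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ReportBundle:
    output_dir: Path
    files: dict[str, Path]
    summary: dict
    log_file: Path


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages in dependency order.

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are retained.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_file = outdir / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    genome = config.genome()
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    rngs = stage_rngs(config.seed, STAGES)
    files: dict[str, Path] = {k: Path(v) for k, v in config.inputs.items()}
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    stage = "init"
    try:
        population = None
        estimates = None
        matrix = None
        gmap = None

        if "simulate" in config.stages:
            stage = "simulate"
            log.info("simulate: design=%s n=%d", sim.design, sim.n_individuals)
            population = simulate_cross(sim, genome, rng=rngs["pedigree"])
            write_population(population, genome, outdir / "population.tsv")
            files["population"] = outdir / "population.tsv"
            coverage = simulate_population_coverage(
                population, genome, sim.depth_mean, sim.depth_dispersion, rngs["coverage"]
            )
            write_table(coverage, outdir / "coverage.tsv")
            files["coverage"] = outdir / "coverage.tsv"
            calls = simulate_population_calls(population, genome, sim, rngs["calls"])
            write_table(calls, outdir / "window_calls.tsv")
            files["window_calls"] = outdir / "window_calls.tsv"
            copies = {
                ind.id: ind.total_nor_copies(genome) / 2.0 for ind in population
            }
            qpcr = simulate_qpcr(copies, sim, rngs["qpcr"])
            write_table(qpcr, outdir / "qpcr.tsv")
            files["qpcr"] = outdir / "qpcr.tsv"

        if "estimate" in config.stages:
            stage = "estimate"
            coverage = pd.read_csv(files["coverage"], sep="\t")
            estimates = cn.estimate_ngs_table(coverage)
            write_table(estimates, outdir / "estimates_ngs.tsv")
            files["estimates_ngs"] = outdir / "estimates_ngs.tsv"
            qpcr = pd.read_csv(files["qpcr"], sep="\t")
            raw = cn.estimate_qpcr_table(qpcr)
            std = cn.standardize_plates(raw, "control", sim.control_sample_id)
            qpcr_est = cn.sample_estimates(std)
            write_table(qpcr_est, outdir / "estimates_qpcr.tsv")
            files["estimates_qpcr"] = outdir / "estimates_qpcr.tsv"
            log.info("estimate: %d NGS, %d qPCR estimates", len(estimates), len(qpcr_est))

        design = sim.design if sim.design in {"F2", "RIL"} else None
        if "genotype" in config.stages and design:
            stage = "genotype"
            calls = pd.read_csv(files["window_calls"], sep="\t")
            matrix = gbs.genotype_population(calls, config.thresholds)
            gbs.write_matrix(matrix, outdir / "genotypes.tsv")
            files["genotypes"] = outdir / "genotypes.tsv"
            gmap = gbs.build_genetic_map(matrix, design, genome)
            write_table(gmap.loci, outdir / "map.tsv")
            files["map"] = outdir / "map.tsv"
            log.info("genotype: %d samples x %d windows", *matrix.shape)

        if "scan" in config.stages and design:
            stage = "scan"
            if estimates is None:
                estimates = pd.read_csv(files["estimates_ngs"], sep="\t")
            if matrix is None:
                matrix = gbs.read_matrix(files["genotypes"])
                gmap = gbs.GeneticMap(pd.read_csv(files["map"], sep="\t"))
            pheno = estimates.set_index("sample_id")["value"]
            pheno = pheno.loc[pheno.index.isin(matrix.index)]
            grid = qtl.genotype_probabilities(matrix, gmap, config.scan_step_cM, design)
            scan = qtl.scan_sim(grid, pheno)
            write_table(scan.table, outdir / "scan_sim.tsv")
            files["scan_sim"] = outdir / "scan_sim.tsv"
            thr = qtl.permutation_threshold(
                grid, pheno, config.scan_alpha, config.scan_permutations, config.seed
            )
            _write_json(dataclasses.asdict(thr), outdir / "threshold.json")
            files["threshold"] = outdir / "threshold.json"
            peaks = qtl.find_peaks(scan, thr)
            peaks_df = pd.DataFrame([dataclasses.asdict(p) for p in peaks])
            write_table(peaks_df, outdir / "peaks.tsv")
            files["peaks"] = outdir / "peaks.tsv"
            sig = [p for p in peaks if p.significant]
            summary["threshold"] = thr.value
            summary["peaks"] = [dataclasses.asdict(p) for p in peaks]
            if sig:
                top = max(sig, key=lambda p: p.lod)
                summary["top_peak"] = dataclasses.asdict(top)
            if config.cofactor_scan and sig:
                cof = [(p.chrom, p.cM) for p in sig]
                cscan = qtl.scan_cofactor(grid, pheno, cof)
                write_table(cscan.table, outdir / "scan_cofactor.tsv")
                files["scan_cofactor"] = outdir / "scan_cofactor.tsv"
            log.info("scan: threshold=%.3f peaks=%d significant", thr.value, len(sig))

        if "stability" in config.stages:
            stage = "stability"
            records = simulate_ma_replicates(
                sim,
                n_lines=config.stability_lines,
                n_replicates=config.stability_replicates,
                measured_generations=config.measured_generations,
                genome=genome,
                rng=rngs["stability"],
                measurement_sd=0.02,
            )
            write_table(records, outdir / "stability_records.tsv")
            files["stability_records"] = outdir / "stability_records.tsv"
            full = stability.fit_lmm(records, ("line", "generation"))
            no_line = stability.fit_lmm(records, ("generation",))
            no_gen = stability.fit_lmm(records, ("line",))
            lrt_line = stability.lrt(full, no_line)
            lrt_gen = stability.lrt(full, no_gen)
            lrt_json = {
                "line": dataclasses.asdict(lrt_line),
                "generation": dataclasses.asdict(lrt_gen),
                "full_loglik": full.loglik,
                "sigma2_rep": full.sigma2_rep,
                "sigma2_e": full.sigma2_e,
            }
            _write_json(lrt_json, outdir / "lrt.json")
            files["lrt"] = outdir / "lrt.json"
            summary["lrt"] = {
                "line": {"chi_square": lrt_line.chi_square, "df": lrt_line.df, "p": lrt_line.p_value},
                "generation": {
                    "chi_square": lrt_gen.chi_square,
                    "df": lrt_gen.df,
                    "p": lrt_gen.p_value,
                },
            }
            if population is not None:
                cv = stability.nor_matched_cv(population, genome)
                write_table(cv, outdir / "cv.tsv")
                files["cv"] = outdir / "cv.tsv"
                summary["cv_points"] = len(cv)
            log.info(
                "stability: line chi2=%.2f (df %d), generation chi2=%.2f (df %d)",
                lrt_line.chi_square,
                lrt_line.df,
                lrt_gen.chi_square,
                lrt_gen.df,
            )
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": {k: str(v.name) for k, v in files.items()},
    }
    _write_json(manifest, outdir / "manifest.json")
    _write_json(summary, outdir / "summary.json")
    files["manifest"] = outdir / "manifest.json"
    files["summary"] = outdir / "summary.json"
    return ReportBundle(outdir, files, summary, log_file)
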