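"""Synthetic pedigrees with unstable NOR copy-number inheritance.

Simulates the three experimental designs used to study 45S rDNA copy-number
inheritance — F2 crosses, recombinant inbred lines (RILs) advanced by
single-seed descent, and mutation-accumulation (MA) lineages — together with
the three measurement layers the analyses consume:

* sequencing-coverage summaries whose 18S / baseline depth ratio has
  expectation equal to rRNA gene copies per haploid genome,
* per-window SNP-call summaries with configurable call and error rates,
* qPCR Ct tables with plate offsets and technical-replicate noise.

Meiosis places crossovers under a no-interference (Haldane) model on the
genetic map.  The NOR allele and its copy count always travel with the
topmost window of their chromosome — homologous NORs do not recombine with
each other — and with probability ``mu`` per NOR per meiosis the transmitted
copy count jumps, emulating unequal crossing-over within the array.

All randomness flows through :class:`numpy.random.Generator` streams derived
from one master seed, so a fixed seed reproduces every table bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from norinherit.genome import GenomeModel, MutationModel

__all__ = [
    "Haplotype",
    "Individual",
    "SimConfig",
    "meiosis",
    "gamete",
    "cross",
    "self_individual",
    "simulate_cross",
    "simulate_ma_replicates",
    "simulate_coverage",
    "simulate_population_coverage",
    "simulate_window_calls",
    "simulate_population_calls",
    "simulate_qpcr",
    "population_frame",
    "write_population",
    "read_population",
    "write_table",
    "read_table",
    "stage_rngs",
]

DIPLOTYPE_CODES = {0: "A", 1: "H", 2: "B"}


def stage_rngs(seed: int, stages: tuple[str, ...]) -> dict[str, np.random.Generator]:
    """Derive one independent generator per pipeline stage from a master seed."""
    children = np.random.SeedSequence(seed).spawn(len(stages))
    return {name: np.random.default_rng(s) for name, s in zip(stages, children)}


# ---------------------------------------------------------------------------
# pedigree data model
# ---------------------------------------------------------------------------


@dataclass
class Haplotype:
    """One chromosome copy: per-window founder labels plus its NOR count.

    ``alleles[w]`` is 0 for maternal-founder ("A") origin of window ``w`` and
    1 for paternal-founder ("B") origin.  ``nor_copies`` is the 45S repeat
    count of the NOR carried at the top of this chromosome (0 on chromosomes
    without a NOR).
    """

    alleles: np.ndarray
    nor_copies: int = 0
    origin_label: str = ""

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.nor_copies < 0:
            raise ValueError("nor_copies must be non-negative")


@dataclass
class Individual:
    """A diploid pedigree member: two haplotypes per chromosome."""

    id: str
    generation: int
    design_role: str
    haplotypes: dict[str, tuple[Haplotype, Haplotype]]

    def diplotype(self, chrom: str) -> np.ndarray:
        """Per-window genotype code: 0=AA, 1=AB (het), 2=BB."""
        h1, h2 = self.haplotypes[chrom]
        return h1.alleles.astype(np.int8) + h2.alleles.astype(np.int8)

    def nor_copy_pair(self, chrom: str) -> tuple[int, int]:
        h1, h2 = self.haplotypes[chrom]
        return h1.nor_copies, h2.nor_copies

    def total_nor_copies(self, genome: GenomeModel) -> int:
        """Total diploid 45S copy number, summed over both NORs and haplotypes."""
        total = 0
        for chrom in set(genome.nor_chromosomes().values()):
            total += sum(self.nor_copy_pair(chrom))
        return total

    def nor_genotype(self, genome: GenomeModel, locus: str) -> str:
        """Founder genotype at a NOR locus, e.g. 'AA', 'AB' or 'BB'."""
        chrom = genome.nor_chromosomes()[locus]
        h1, h2 = self.haplotypes[chrom]
        labels = sorted("AB"[h.alleles[0]] for h in (h1, h2))
        return "".join(labels)


def founder(
    ind_id: str,
    genome: GenomeModel,
    allele: int,
    nor_copies: dict[str, int],
    generation: int = 0,
    role: str = "parent",
) -> Individual:
    """A fully inbred founder, homozygous for one allele label genome-wide."""
    haps: dict[str, tuple[Haplotype, Haplotype]] = {}
    chrom_of = genome.nor_chromosomes()
    copies_by_chrom = {
        chrom_of[locus]: c for locus, c in nor_copies.items() if locus in chrom_of
    }
    for c in genome.chromosomes:
        n = genome.n_windows(c.name)
        copies = copies_by_chrom.get(c.name, 0)
        haps[c.name] = (
            Haplotype(np.full(n, allele, dtype=np.uint8), copies, ind_id),
            Haplotype(np.full(n, allele, dtype=np.uint8), copies, ind_id),
        )
    return Individual(ind_id, generation, role, haps)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def meiosis(
    parent: Individual,
    chrom: str,
    genome: GenomeModel,
    mutation: MutationModel,
    rng: np.random.Generator,
) -> Haplotype:
    """Produce one gamete haplotype for ``chrom``.

    Crossovers are Poisson on the genetic map (no interference); windows are
    assigned to the parental haplotype active at the window start.  The NOR
    copy count travels with window 0 and may jump per the mutation model.
    """
    c = genome.chromosome(chrom)
    h1, h2 = parent.haplotypes[chrom]
    n_win = len(h1.alleles)

    start_hap = int(rng.integers(2))
    n_x = rng.poisson(c.length_cM / 100.0) if c.length_cM > 0 else 0
    if n_x > 0:
        x_cm = np.sort(rng.uniform(0.0, c.length_cM, size=n_x))
        win_cm = genome.window_starts(chrom) * (c.length_cM / c.length_bp)
        hap_idx = (start_hap + np.searchsorted(x_cm, win_cm, side="right")) % 2
    else:
        hap_idx = np.full(n_win, start_hap, dtype=np.int64)

    alleles = np.where(hap_idx == 0, h1.alleles, h2.alleles).astype(np.uint8)

    donor = (h1, h2)[hap_idx[0]]
    copies = donor.nor_copies
    is_nor_chrom = chrom in set(genome.nor_chromosomes().values())
    if is_nor_chrom:
        copies = mutation.perturb(copies, rng)
    return Haplotype(alleles, copies, parent.id)


def gamete(
    parent: Individual,
    genome: GenomeModel,
    mutation: MutationModel,
    rng: np.random.Generator,
) -> dict[str, Haplotype]:
    return {
        c.name: meiosis(parent, c.name, genome, mutation, rng)
        for c in genome.chromosomes
    }


def cross(
    mother: Individual,
    father: Individual,
    child_id: str,
    genome: GenomeModel,
    mutation: MutationModel,
    rng: np.random.Generator,
    role: str = "offspring",
) -> Individual:
    gm = gamete(mother, genome, mutation, rng)
    gf = gamete(father, genome, mutation, rng)
    haps = {chrom: (gm[chrom], gf[chrom]) for chrom in gm}
    return Individual(child_id, max(mother.generation, father.generation) + 1, role, haps)


def self_individual(
    parent: Individual,
    child_id: str,
    genome: GenomeModel,
    mutation: MutationModel,
    rng: np.random.Generator,
    role: str = "offspring",
) -> Individual:
    child = cross(parent, parent, child_id, genome, mutation, rng, role)
    child.generation = parent.generation + 1
    return child


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Full parameterisation of one simulated study.

    Copy numbers default to the contrast between a low-copy accession
    (~500 units per haploid genome) and a high-copy accession (~2500), with
    the difference carried entirely by NOR2 so chromosome 2 is the sole
    heritable source of variation.  Depth, call-rate and qPCR parameters
    default to low-coverage resequencing scale (mean depth 20x, about half
    of segregating sites called per sample, four technical qPCR replicates
    with ~0.04-cycle noise).
    """

    design: str = "F2"  # F2 | RIL | MA
    n_individuals: int = 93
    n_generations: int = 9  # selfing generations (RIL) or SSD generations (MA)
    parental_copy_numbers: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"NOR2": (500, 2500), "NOR4": (500, 500)}
    )
    mu: float = 0.02
    jump_scale: float = 100.0
    # coverage layer
    depth_mean: float = 20.0
    depth_dispersion: float = 0.1
    # window-call layer
    mean_segregating_per_window: float = 300.0
    low_diversity_fraction: float = 0.05
    call_rate: float = 0.5
    error_rate: float = 0.01
    # qPCR layer
    n_technical_replicates: int = 4
    replicate_sd: float = 0.04
    plate_offset_sd: float = 0.5
    target_offset_sd: float = 0.25
    plate_capacity: int = 11
    control_sample_id: str = "control-1002"
    control_copies: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in {"F2", "RIL", "MA"}:
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for rate in (self.mu, self.call_rate, self.error_rate, self.low_diversity_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def mutation_model(self) -> MutationModel:
        return MutationModel(self.mu, self.jump_scale)

    @classmethod
    def from_toml(cls, path: str | Path) -> "SimConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        section = raw.get("simulation", raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        if "parental_copy_numbers" in section:
            section["parental_copy_numbers"] = {
                k: tuple(v) for k, v in section["parental_copy_numbers"].items()
            }
        return cls(**section)


def _founder_pair(config: SimConfig, genome: GenomeModel) -> tuple[Individual, Individual]:
    p1_copies = {loc: c[0] for loc, c in config.parental_copy_numbers.items()}
    p2_copies = {loc: c[1] for loc, c in config.parental_copy_numbers.items()}
    p1 = founder("P1", genome, 0, p1_copies)
    p2 = founder("P2", genome, 1, p2_copies)
    return p1, p2


def simulate_cross(
    config: SimConfig,
    genome: GenomeModel | None = None,
    mutation: MutationModel | None = None,
    rng: np.random.Generator | None = None,
) -> list[Individual]:
    """Simulate one population under the configured design.

    F2: P1 x P2 -> F1, F1 selfed into ``n_individuals`` F2s.
    RIL: each F2 advanced by single-seed descent to ``n_generations`` total
    selfing generations (the F2 itself counts as the first).
    MA: ``n_individuals`` independent single-seed-descent lineages from one
    founder; every generation of every lineage is returned.
    """
    genome = genome or GenomeModel.arabidopsis()
    mutation = mutation or config.mutation_model()
    rng = rng or np.random.default_rng(config.seed)

    if config.design == "MA":
        p1_copies = {loc: c[0] for loc, c in config.parental_copy_numbers.items()}
        out: list[Individual] = []
        for i in range(config.n_individuals):
            plant = founder(f"MA{i + 1}_g0", genome, 0, p1_copies, role="MA_line")
            out.append(plant)
            for g in range(1, config.n_generations + 1):
                plant = self_individual(
                    plant, f"MA{i + 1}_g{g}", genome, mutation, rng, role="MA_line"
                )
                out.append(plant)
        return out

    p1, p2 = _founder_pair(config, genome)
    f1 = cross(p1, p2, "F1", genome, mutation, rng, role="F1")
    f2s = [
        self_individual(f1, f"F2_{i + 1}", genome, mutation, rng, role="F2")
        for i in range(config.n_individuals)
    ]
    if config.design == "F2":
        return f2s

    rils: list[Individual] = []
    for i, plant in enumerate(f2s):
        for _ in range(config.n_generations - 1):
            plant = self_individual(plant, plant.id, genome, mutation, rng, role="RIL")
        plant.id = f"RIL_{i + 1}"
        rils.append(plant)
    return rils


def simulate_ma_replicates(
    config: SimConfig,
    n_lines: int = 10,
    n_replicates: int = 5,
    measured_generations: tuple[int, ...] = (32, 33),
    genome: GenomeModel | None = None,
    mutation: MutationModel | None = None,
    rng: np.random.Generator | None = None,
    measurement_sd: float = 0.0,
) -> pd.DataFrame:
    """MA stability design: lines x biological replicates x generations.

    Each line descends independently from the founder to the generation
    before the first measured one; sibling replicate plants are then drawn
    (each through its own meiosis, so copy-number jumps can differ) and each
    replicate lineage is advanced through the measured generations.  Returns
    a tidy table (line, generation, replicate, value) of copies per haploid
    genome; ``measurement_sd`` adds relative Gaussian measurement noise.
    """
    genome = genome or GenomeModel.arabidopsis()
    mutation = mutation or config.mutation_model()
    rng = rng or np.random.default_rng(config.seed)
    first = min(measured_generations)
    p1_copies = {loc: c[0] for loc, c in config.parental_copy_numbers.items()}

    rows = []
    for li in range(n_lines):
        plant = founder(f"line{li + 1}_g0", genome, 0, p1_copies, role="MA_line")
        for g in range(1, first):
            plant = self_individual(plant, f"line{li + 1}_g{g}", genome, mutation, rng)
        for ri in range(n_replicates):
            rep = self_individual(plant, f"line{li + 1}_r{ri + 1}", genome, mutation, rng)
            for g in sorted(measured_generations):
                while rep.generation < g:
                    rep = self_individual(rep, rep.id, genome, mutation, rng)
                value = rep.total_nor_copies(genome) / 2.0
                if measurement_sd > 0:
                    value *= 1.0 + rng.normal(0.0, measurement_sd)
                rows.append(
                    {
                        "line": f"line{li + 1}",
                        "generation": g,
                        "replicate": f"line{li + 1}_r{ri + 1}",
                        "value": max(value, 0.0),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# measurement layers
# ---------------------------------------------------------------------------

_18S_LENGTH_BP = 4002 - 2195 + 1  # annotated 18S interval on the 45S repeat unit


def _aggregate_mean_depth(
    mean_per_base: float, n_bases: int, dispersion: float, rng: np.random.Generator
) -> float:
    """Mean depth over a region of iid per-base counts, drawn in aggregate.

    Per-base counts are negative binomial with variance m + dispersion*m^2;
    the regional sum is itself negative binomial, so one draw suffices.
    dispersion == 0 returns the exact expectation (noise-free contract).
    """
    if mean_per_base < 0:
        raise ValueError("depth mean must be non-negative")
    if dispersion < 0:
        raise ValueError("negative dispersion")
    if dispersion == 0.0 or mean_per_base == 0.0:
        return float(mean_per_base)
    size_total = n_bases / dispersion
    mean_total = n_bases * mean_per_base
    p = size_total / (size_total + mean_total)
    return float(rng.negative_binomial(size_total, p)) / n_bases


def simulate_coverage(
    ind: Individual,
    genome: GenomeModel,
    depth_mean: float,
    dispersion: float,
    rng: np.random.Generator,
):
    """Coverage summary whose 18S/baseline ratio estimates copies per haploid.

    Baseline mean depth has expectation ``depth_mean``; the 18S mean has
    expectation ``depth_mean * C_diploid / 2`` because reads from every rDNA
    copy in the diploid genome pile onto the single reference repeat unit.
    """
    from norinherit.copy_number import CoverageSummary

    if depth_mean <= 0:
        raise ValueError("depth mean must be positive")
    c_hap = ind.total_nor_copies(genome) / 2.0
    _, b_start, b_end = genome.baseline_region
    mean_baseline = _aggregate_mean_depth(depth_mean, b_end - b_start, dispersion, rng)
    mean_18s = _aggregate_mean_depth(depth_mean * c_hap, _18S_LENGTH_BP, dispersion, rng)
    return CoverageSummary(ind.id, mean_18s, mean_baseline)


def simulate_population_coverage(
    population: list[Individual],
    genome: GenomeModel,
    depth_mean: float,
    dispersion: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = [
        simulate_coverage(ind, genome, depth_mean, dispersion, rng)._asdict()
        for ind in population
    ]
    return pd.DataFrame(rows)


def draw_segregating_counts(
    genome: GenomeModel,
    mean_per_window: float,
    low_diversity_fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-window segregating-site counts, shared by all samples of a cross.

    A configurable fraction of windows is low-diversity (< 100 segregating
    sites) to exercise the downstream discard rule.
    """
    frames = []
    for c in genome.chromosomes:
        n = genome.n_windows(c.name)
        n_seg = rng.poisson(mean_per_window, size=n)
        low = rng.random(n) < low_diversity_fraction
        n_seg[low] = rng.integers(0, 100, size=int(low.sum()))
        frames.append(
            pd.DataFrame(
                {"chrom": c.name, "window_index": np.arange(n), "n_segregating": n_seg}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_window_calls(
    ind: Individual,
    genome: GenomeModel,
    segregating: pd.DataFrame,
    call_rate: float,
    error_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-window SNP-call summary for one individual.

    Each segregating site is called with probability ``call_rate``; a called
    site reports the class of the individual's true window diplotype
    (maternal / heterozygous / paternal) and is flipped to one of the two
    wrong classes, equiprobably, with probability ``error_rate``.
    """
    if not 0.0 <= call_rate <= 1.0 or not 0.0 <= error_rate <= 1.0:
        raise ValueError("call_rate and error_rate must lie in [0, 1]")
    out = []
    for c in genome.chromosomes:
        seg = segregating.loc[segregating["chrom"] == c.name].sort_values("window_index")
        n_seg = seg["n_segregating"].to_numpy()
        truth = ind.diplotype(c.name)  # 0=AA, 1=H, 2=BB
        n_called = rng.binomial(n_seg, call_rate)
        n_wrong = rng.binomial(n_called, error_rate)
        wrong_first = rng.binomial(n_wrong, 0.5)
        wrong_second = n_wrong - wrong_first
        n_correct = n_called - n_wrong

        n_mat = np.select([truth == 0, truth == 1], [n_correct, wrong_first], wrong_first)
        n_het = np.select([truth == 1, truth == 0], [n_correct, wrong_second], wrong_second)
        n_pat = n_called - n_mat - n_het
        out.append(
            pd.DataFrame(
                {
                    "sample_id": ind.id,
                    "chrom": c.name,
                    "window_index": seg["window_index"].to_numpy(),
                    "n_segregating": n_seg,
                    "n_called": n_called,
                    "n_maternal": n_mat,
                    "n_paternal": n_pat,
                    "n_het": n_het,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def simulate_population_calls(
    population: list[Individual],
    genome: GenomeModel,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    segregating = draw_segregating_counts(
        genome, config.mean_segregating_per_window, config.low_diversity_fraction, rng
    )
    frames = [
        simulate_window_calls(ind, genome, segregating, config.call_rate, config.error_rate, rng)
        for ind in population
    ]
    return pd.concat(frames, ignore_index=True)


BASE_CT = 28.0  # reference-gene threshold cycle; cancels in every delta-Ct


def simulate_qpcr(
    copy_numbers: dict[str, float],
    config: SimConfig,
    rng: np.random.Generator,
    plate_layout: dict[str, list[str]] | None = None,
    plate_offsets: dict[str, float] | None = None,
    target_offsets: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """qPCR Ct table for samples with known copies-per-haploid values.

    True cycles satisfy ``2**(Ct_ACT2 - Ct_18S) == copy_number``.  Observed
    cycles add a per-plate offset (shared by both targets, cancelling in the
    delta), an optional target-specific plate offset (which does not cancel
    and is what control standardization corrects), and Gaussian
    technical-replicate noise.  The common control sample is placed on every
    plate.
    """
    control = config.control_sample_id
    samples = [s for s in copy_numbers if s != control]
    if plate_layout is None:
        cap = config.plate_capacity
        plate_layout = {
            f"plate{p + 1}": samples[p * cap : (p + 1) * cap]
            for p in range(-(-len(samples) // cap) or 1)
        }
    layout = {p: list(ids) + [control] for p, ids in plate_layout.items()}
    if plate_offsets is None:
        plate_offsets = {p: rng.normal(0.0, config.plate_offset_sd) for p in layout}
    if target_offsets is None:
        target_offsets = {
            (p, t): rng.normal(0.0, config.target_offset_sd)
            for p in layout
            for t in ("18S", "ACT2")
        }
    truth = dict(copy_numbers)
    truth.setdefault(control, config.control_copies)

    rows = []
    for plate, ids in layout.items():
        for sid in ids:
            if truth[sid] <= 0:
                raise ValueError(f"sample {sid}: copy number must be positive for qPCR")
            true_ct = {"18S": BASE_CT - np.log2(truth[sid]), "ACT2": BASE_CT}
            for target in ("18S", "ACT2"):
                base = (
                    true_ct[target]
                    + plate_offsets[plate]
                    + target_offsets.get((plate, target), 0.0)
                )
                for rep in range(1, config.n_technical_replicates + 1):
                    ct = base + (rng.normal(0.0, config.replicate_sd) if config.replicate_sd > 0 else 0.0)
                    rows.append(
                        {
                            "sample_id": sid,
                            "plate_id": plate,
                            "target": target,
                            "replicate_index": rep,
                            "ct_value": ct,
                        }
                    )
    df = pd.DataFrame(rows)
    if (df["ct_value"] <= 0).any():
        raise ValueError("simulated Ct values fell below zero; lower copy numbers or offsets")
    return df


# ---------------------------------------------------------------------------
# tables and round-trip I/O
# ---------------------------------------------------------------------------


def population_frame(population: list[Individual], genome: GenomeModel) -> pd.DataFrame:
    """Tidy truth table: one row per individual with NOR copies and diplotypes.

    Per-window true diplotypes are stored as one 'A'/'H'/'B' string column per
    chromosome, ordered by window index.
    """
    chrom_of = genome.nor_chromosomes()
    rows = []
    for ind in population:
        row: dict[str, object] = {
            "id": ind.id,
            "generation": ind.generation,
            "design_role": ind.design_role,
        }
        for locus in sorted(chrom_of):
            c1, c2 = ind.nor_copy_pair(chrom_of[locus])
            row[f"{locus.lower()}_hap1"] = c1
            row[f"{locus.lower()}_hap2"] = c2
        row["total_copies"] = ind.total_nor_copies(genome)
        for c in genome.chromosomes:
            codes = ind.diplotype(c.name)
            row[f"diplotype_{c.name}"] = "".join(DIPLOTYPE_CODES[int(x)] for x in codes)
        rows.append(row)
    return pd.DataFrame(rows)


def write_population(population: list[Individual], genome: GenomeModel, path: str | Path) -> None:
    population_frame(population, genome).to_csv(path, sep="\t", index=False)


def read_population(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
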