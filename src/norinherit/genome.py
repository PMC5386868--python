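"""Genome and copy-number mutation models.

The genome model is deliberately coarse: chromosomes are linear intervals with
a physical length (bp), a genetic length (cM, Haldane map function assumed
throughout) and a fixed window grid.  The two 45S rDNA clusters, NOR2 and
NOR4, are represented as single loci pinned to the topmost window of their
chromosome; intra-array structure is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Chromosome", "GenomeModel", "MutationModel"]


@dataclass(frozen=True)
class Chromosome:
    """A linear chromosome with a uniform physical-to-genetic scaling."""

    name: str
    length_bp: int
    length_cM: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.name}: length_bp must be positive")
        if self.length_cM < 0:
            raise ValueError(f"{self.name}: negative genetic length")


@dataclass
class GenomeModel:
    """Chromosome set, window grid, NOR loci and the depth-baseline region.

    Parameters
    ----------
    chromosomes:
        Ordered chromosomes.
    window_size_bp:
        Width of the genotyping windows; the last window of a chromosome is
        truncated if the length is not a multiple.
    nor_positions:
        Locus name -> (chromosome name, bp offset).  NORs sit at the start
        (top) of their chromosome, so the offset is 0 by construction.
    baseline_region:
        (chromosome, start bp, end bp), half-open, used as the copy-number
        depth baseline.  Must avoid the NOR-bearing chromosomes.
    """

    chromosomes: list[Chromosome]
    window_size_bp: int = 100_000
    nor_positions: dict[str, tuple[str, int]] = field(
        default_factory=lambda: {"NOR2": ("Chr2", 0), "NOR4": ("Chr4", 0)}
    )
    baseline_region: tuple[str, int, int] = ("Chr3", 0, 10_000_000)

    def __post_init__(self) -> None:
        if self.window_size_bp <= 0:
            raise ValueError("window_size_bp must be positive")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for locus, (chrom, offset) in self.nor_positions.items():
            if chrom not in names:
                raise ValueError(f"{locus}: unknown chromosome {chrom!r}")
            if offset != 0:
                raise ValueError(f"{locus}: NOR loci must sit at the chromosome top")
        bchrom = self.baseline_region[0]
        if bchrom not in names:
            raise ValueError(f"baseline region on unknown chromosome {bchrom!r}")
        nor_chroms = {c for c, _ in self.nor_positions.values()}
        if bchrom in nor_chroms:
            raise ValueError("baseline region must exclude NOR-bearing chromosomes")

    # -- lookups ----------------------------------------------------------

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def n_windows(self, chrom: str) -> int:
        c = self.chromosome(chrom)
        return -(-c.length_bp // self.window_size_bp)  # ceil division

    def window_starts(self, chrom: str) -> np.ndarray:
        """0-based, half-open window start coordinates (bp)."""
        return np.arange(self.n_windows(chrom), dtype=np.int64) * self.window_size_bp

    def nor_chromosomes(self) -> dict[str, str]:
        """Locus name -> chromosome name."""
        return {locus: chrom for locus, (chrom, _) in self.nor_positions.items()}

    def cm_per_window(self, chrom: str) -> float:
        c = self.chromosome(chrom)
        return c.length_cM * self.window_size_bp / c.length_bp

    # -- presets ----------------------------------------------------------

    @classmethod
    def arabidopsis(cls, window_size_bp: int = 100_000) -> "GenomeModel":
        """TAIR10-scale *A. thaliana* genome with a consensus-scale genetic map."""
        return cls(
            chromosomes=[
                Chromosome("Chr1", 30_400_000, 120.0),
                Chromosome("Chr2", 19_700_000, 90.0),
                Chromosome("Chr3", 23_500_000, 100.0),
                Chromosome("Chr4", 18_600_000, 105.0),
                Chromosome("Chr5", 26_900_000, 120.0),
            ],
            window_size_bp=window_size_bp,
        )

    @classmethod
    def compact(cls, window_size_bp: int = 100_000) -> "GenomeModel":
        """A down-scaled five-chromosome genome for fast simulation studies.

        Keeps the NOR/baseline topology of the full genome but with ~20
        windows per chromosome so that repeated whole-pipeline runs are cheap.
        """
        return cls(
            chromosomes=[
                Chromosome("Chr1", 2_000_000, 80.0),
                Chromosome("Chr2", 2_000_000, 80.0),
                Chromosome("Chr3", 2_000_000, 80.0),
                Chromosome("Chr4", 2_000_000, 80.0),
                Chromosome("Chr5", 2_000_000, 80.0),
            ],
            window_size_bp=window_size_bp,
            baseline_region=("Chr3", 0, 2_000_000),
        )


@dataclass
class MutationModel:
    """Per-meiosis NOR copy-number jump model.

    Unequal crossing-over between misaligned sister repeats expands or
    contracts a tandem array.  That process is summarised as: with
    probability ``jump_probability`` per NOR per meiosis the transmitted copy
    count is perturbed by a symmetric discretized-Gaussian jump with standard
    deviation ``jump_scale``, truncated so counts stay non-negative.  The
    defaults make 100-250-copy excursions visible within tens of generations;
    the rates themselves are free parameters of the model.
    """

    jump_probability: float = 0.02
    jump_scale: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jump_probability <= 1.0:
            raise ValueError("jump_probability must be in [0, 1]")
        if self.jump_scale < 0:
            raise ValueError("jump_scale must be non-negative")

    def perturb(self, copies: int, rng: np.random.Generator) -> int:
        """Return the transmitted copy count after a possible jump."""
        if copies < 0:
            raise ValueError("copies must be non-negative")
        if self.jump_probability == 0.0 or rng.random() >= self.jump_probability:
            return int(copies)
        jump = int(np.rint(rng.normal(0.0, self.jump_scale)))
        return max(0, int(copies) + jump)
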