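"""Windowed genotyping-by-sequencing and genetic-map construction.

Low-coverage samples are genotyped against the segregating sites of the two
parental accessions, binned in 100-kb windows.  A window is discarded (NA)
when it has fewer than 100 segregating sites (low parental diversity) or
fewer than 40 called sites (poor read support); otherwise it is called "A"
(maternal) or "B" (paternal) when more than 90% of calls support one parent,
and "H" when more than 25% of calls are heterozygous or the maternal and
paternal call counts differ by less than 30% of the calls.

Threshold comparisons are evaluated in exact rational arithmetic so calls on
the rule boundaries never depend on floating-point rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "GenotyperThresholds",
    "WindowCallSummary",
    "GeneticMap",
    "call_window",
    "call_windows",
    "genotype_population",
    "window_call_rates",
    "ingest_vcf",
    "read_parental_map",
    "build_genetic_map",
    "haldane_cm",
    "haldane_r",
    "write_matrix",
    "read_matrix",
]


class WindowCallSummary(NamedTuple):
    """SNP-call counts for one sample in one 100-kb window."""

    sample_id: str
    chrom: str
    window_index: int
    n_segregating: int
    n_called: int
    n_maternal: int
    n_paternal: int
    n_het: int


@dataclass(frozen=True)
class GenotyperThresholds:
    min_segregating: int = 100
    min_called: int = 40
    homozygous_fraction: float = 0.90
    het_fraction: float = 0.25
    parental_diff_fraction: float = 0.30
    window_size_bp: int = 100_000

    def __post_init__(self) -> None:
        for f in (self.homozygous_fraction, self.het_fraction, self.parental_diff_fraction):
            if not 0.0 < f < 1.0:
                raise ValueError("fractions must lie in (0, 1)")
        if self.min_segregating <= 0 or self.min_called <= 0:
            raise ValueError("count thresholds must be positive")


def _frac(x: float) -> Fraction:
    return Fraction(str(x))


def call_window(ws: WindowCallSummary, t: GenotyperThresholds | None = None) -> str:
    """Assign A / B / H / NA to one window summary."""
    t = t or GenotyperThresholds()
    counts = (ws.n_segregating, ws.n_called, ws.n_maternal, ws.n_paternal, ws.n_het)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative counts in window summary {ws}")
    if ws.n_maternal + ws.n_paternal + ws.n_het > ws.n_called or ws.n_called > ws.n_segregating:
        raise ValueError(f"inconsistent counts in window summary {ws}")

    if ws.n_segregating < t.min_segregating or ws.n_called < t.min_called:
        return "NA"
    hom = _frac(t.homozygous_fraction)
    het = _frac(t.het_fraction)
    diff = _frac(t.parental_diff_fraction)
    nc = ws.n_called
    if ws.n_maternal * hom.denominator > hom.numerator * nc:
        return "A"
    if ws.n_paternal * hom.denominator > hom.numerator * nc:
        return "B"
    if (
        ws.n_het * het.denominator > het.numerator * nc
        or abs(ws.n_maternal - ws.n_paternal) * diff.denominator < diff.numerator * nc
    ):
        return "H"
    return "NA"


def call_windows(summaries: pd.DataFrame, t: GenotyperThresholds | None = None) -> pd.Series:
    """Vectorised :func:`call_window` over a summary table (integer arithmetic)."""
    t = t or GenotyperThresholds()
    n_seg = summaries["n_segregating"].to_numpy(dtype=np.int64)
    n_called = summaries["n_called"].to_numpy(dtype=np.int64)
    n_mat = summaries["n_maternal"].to_numpy(dtype=np.int64)
    n_pat = summaries["n_paternal"].to_numpy(dtype=np.int64)
    n_het = summaries["n_het"].to_numpy(dtype=np.int64)
    if (n_mat + n_pat + n_het > n_called).any() or (n_called > n_seg).any():
        raise ValueError("inconsistent counts in window summaries")

    hom, het, diff = (
        _frac(t.homozygous_fraction),
        _frac(t.het_fraction),
        _frac(t.parental_diff_fraction),
    )
    retained = (n_seg >= t.min_segregating) & (n_called >= t.min_called)
    is_a = n_mat * hom.denominator > hom.numerator * n_called
    is_b = n_pat * hom.denominator > hom.numerator * n_called
    is_h = (n_het * het.denominator > het.numerator * n_called) | (
        np.abs(n_mat - n_pat) * diff.denominator < diff.numerator * n_called
    )
    call = np.select(
        [~retained, is_a, is_b, is_h], ["NA", "A", "B", "H"], default="NA"
    )
    return pd.Series(call, index=summaries.index, name="call")


def genotype_population(
    summaries: pd.DataFrame, thresholds: GenotyperThresholds | None = None
) -> pd.DataFrame:
    """Call every (sample, window) and pivot to a samples x windows matrix.

    Columns are a (chrom, window_index) MultiIndex; cells hold A/B/H/NA.
    Every sample must cover the same window grid; no imputation is applied.
    """
    if summaries.empty:
        return pd.DataFrame()
    df = summaries.copy()
    df["call"] = call_windows(df, thresholds)
    matrix = df.pivot_table(
        index="sample_id",
        columns=["chrom", "window_index"],
        values="call",
        aggfunc="first",
    )
    if matrix.isna().any().any():
        raise ValueError("inconsistent window grids across samples")
    matrix = matrix.sort_index(axis=1)
    return matrix


def window_call_rates(matrix: pd.DataFrame) -> pd.Series:
    """Fraction of samples with a non-NA call per window."""
    return (matrix != "NA").mean(axis=0)


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def read_parental_map(path: str | Path) -> pd.DataFrame:
    """Parental allele map TSV: chrom, pos (1-based), maternal_allele, paternal_allele."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "maternal_allele", "paternal_allele"}
    if not required.issubset(df.columns):
        raise ValueError(f"parental map must have columns {sorted(required)}")
    return df


def ingest_vcf(
    vcf_path: str | Path,
    parental_map: pd.DataFrame,
    window_size_bp: int = 100_000,
) -> pd.DataFrame:
    """Aggregate per-sample VCF genotype calls into window call summaries.

    Sites absent from the parental map are ignored; sites whose mapped
    parental alleles are not both present among REF/ALT are skipped with a
    warning count.  Missing genotypes (./.) are not counted as called; a
    genotype carrying an allele outside the parental pair is not counted.
    Windows are 0-based half-open on POS-1.  n_segregating counts the
    map-listed VCF sites per window (shared by all samples).
    """
    from cyvcf2 import VCF

    pmap = {
        (str(r.chrom), int(r.pos)): (str(r.maternal_allele), str(r.paternal_allele))
        for r in parental_map.itertuples()
    }
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    counts: dict[tuple[str, int], np.ndarray] = {}
    seg: dict[tuple[str, int], int] = {}
    n_skipped = 0

    for variant in vcf:
        key = (variant.CHROM, variant.POS)
        pair = pmap.get(key)
        if pair is None:
            continue
        alleles = [variant.REF] + list(variant.ALT)
        if pair[0] not in alleles or pair[1] not in alleles or pair[0] == pair[1]:
            n_skipped += 1
            continue
        win = (variant.CHROM, (variant.POS - 1) // window_size_bp)
        seg[win] = seg.get(win, 0) + 1
        block = counts.setdefault(win, np.zeros((len(samples), 4), dtype=np.int64))
        for si, gt in enumerate(variant.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                continue
            g = {alleles[a0], alleles[a1]}
            if not g.issubset(set(pair)):
                n_skipped += 1
                continue
            block[si, 0] += 1  # called
            if g == {pair[0]}:
                block[si, 1] += 1
            elif g == {pair[1]}:
                block[si, 2] += 1
            else:
                block[si, 3] += 1

    if n_skipped:
        warnings.warn(f"skipped {n_skipped} VCF sites/calls with alleles outside the parental map")
    rows = []
    for (chrom, win), block in sorted(counts.items()):
        for si, sid in enumerate(samples):
            rows.append(
                {
                    "sample_id": sid,
                    "chrom": chrom,
                    "window_index": win,
                    "n_segregating": seg[(chrom, win)],
                    "n_called": block[si, 0],
                    "n_maternal": block[si, 1],
                    "n_paternal": block[si, 2],
                    "n_het": block[si, 3],
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = n_skipped
    return out


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


def haldane_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Haldane map distance (cM) from a recombination fraction."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction from a Haldane map distance (cM)."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, dtype=float) / 50.0))


@dataclass
class GeneticMap:
    """Ordered marker loci with physical (bp) and genetic (cM) positions."""

    loci: pd.DataFrame  # columns: chrom, window_index, bp, cM
    map_function: str = "haldane"
    chrom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, grp in self.loci.groupby("chrom", sort=False):
            if (np.diff(grp["cM"].to_numpy()) < -1e-12).any():
                raise ValueError(f"{chrom}: cM positions must be non-decreasing")
            if (np.diff(grp["window_index"].to_numpy()) <= 0).any():
                raise ValueError(f"{chrom}: loci must follow physical order")
        if not self.chrom_order:
            self.chrom_order = list(self.loci["chrom"].unique())

    def chrom_loci(self, chrom: str) -> pd.DataFrame:
        return self.loci.loc[self.loci["chrom"] == chrom]


_R_GRID = np.concatenate([[1e-8], np.linspace(1e-4, 0.4999, 1200)])
_R_CAP = 0.49


def _f2_pair_tables(r_grid: np.ndarray) -> np.ndarray:
    """Joint genotype tables P(g1, g2 | r) for an F2 locus pair; (len(r), 3, 3)."""
    r = r_grid[:, None, None]
    # gamete joint: P(a1, a2) = 0.5 * [[1-r, r], [r, 1-r]]
    j = 0.5 * np.concatenate(
        [
            np.concatenate([1 - r, r], axis=2),
            np.concatenate([r, 1 - r], axis=2),
        ],
        axis=1,
    )  # (n, 2, 2)
    tables = np.zeros((len(r_grid), 3, 3))
    for a1 in range(2):
        for a2 in range(2):
            for b1 in range(2):
                for b2 in range(2):
                    tables[:, a1 + b1, a2 + b2] += j[:, a1, a2] * j[:, b1, b2]
    return tables


_F2_TABLES = _f2_pair_tables(_R_GRID)
_F2_LOG_TABLES = np.log(np.clip(_F2_TABLES, 1e-300, None)).reshape(len(_R_GRID), 9)


def _estimate_r_f2(codes: np.ndarray) -> np.ndarray:
    """Per-interval ML recombination fractions for F2 3-state codes.

    ``codes``: (n_ind, n_loci) with 0/1/2 and -1 for missing.  Likelihood of
    each adjacent pair is maximised over a dense r grid (two independent
    meioses per individual).
    """
    n_loci = codes.shape[1]
    rs = np.zeros(n_loci - 1)
    for k in range(n_loci - 1):
        g1, g2 = codes[:, k], codes[:, k + 1]
        ok = (g1 >= 0) & (g2 >= 0)
        if ok.sum() < 2:
            rs[k] = 0.0
            continue
        cell = g1[ok] * 3 + g2[ok]
        counts = np.bincount(cell, minlength=9).astype(float)
        ll = _F2_LOG_TABLES @ counts
        rs[k] = _R_GRID[int(np.argmax(ll))]
    return rs


def _estimate_r_ril(codes: np.ndarray) -> np.ndarray:
    """Per-interval r for RIL 2-state codes (0=A, 2=B; -1/H missing).

    The observed discordance fraction between fixed lines relates to the
    per-meiosis r through R = 2r / (1 + 2r); inverting gives r.
    """
    n_loci = codes.shape[1]
    rs = np.zeros(n_loci - 1)
    for k in range(n_loci - 1):
        g1, g2 = codes[:, k], codes[:, k + 1]
        ok = (g1 >= 0) & (g2 >= 0) & (g1 != 1) & (g2 != 1)
        n = int(ok.sum())
        if n < 2:
            rs[k] = 0.0
            continue
        r_obs = float((g1[ok] != g2[ok]).sum()) / n
        if r_obs >= 2 * _R_CAP / (1 + 2 * _R_CAP):
            warnings.warn(f"interval {k}: apparent r >= 0.5; distance capped")
            rs[k] = _R_CAP
        else:
            rs[k] = r_obs / (2.0 * (1.0 - r_obs))
    return rs


CODE_OF = {"A": 0, "H": 1, "B": 2, "NA": -1}


def encode_matrix(matrix: pd.DataFrame) -> np.ndarray:
    """A/H/B/NA matrix to integer codes 0/1/2/-1 (samples x windows)."""
    return matrix.apply(lambda col: col.map(CODE_OF)).to_numpy(dtype=np.int64)


def build_genetic_map(
    matrix: pd.DataFrame,
    design: str = "F2",
    genome=None,
    min_call_fraction: float = 0.5,
    r_cap: float = _R_CAP,
) -> GeneticMap:
    """Estimate a genetic map from adjacent-window recombination fractions.

    Windows called in fewer than ``min_call_fraction`` of samples are
    dropped as uninformative.  F2 maps use the full 3-state pair likelihood;
    RIL maps treat H as missing and map the observed discordance back through
    the selfing relation before applying the Haldane function.  ``genome``
    (optional) supplies window bp coordinates; otherwise window_index *
    100 kb is used.
    """
    if design not in {"F2", "RIL"}:
        raise ValueError(f"unsupported design {design!r}")
    frames = []
    window_bp = 100_000 if genome is None else genome.window_size_bp
    for chrom in matrix.columns.get_level_values(0).unique():
        sub = matrix[chrom]
        informative = (sub != "NA").mean(axis=0) >= min_call_fraction
        sub = sub.loc[:, informative[informative].index]
        if sub.shape[1] < 2:
            warnings.warn(f"{chrom}: fewer than 2 informative windows; skipped")
            continue
        codes = sub.apply(lambda col: col.map(CODE_OF)).to_numpy(dtype=np.int64)
        if design == "F2":
            rs = _estimate_r_f2(codes)
        else:
            rs = _estimate_r_ril(codes)
        capped = rs >= r_cap
        if capped.any():
            warnings.warn(f"{chrom}: {int(capped.sum())} interval(s) capped at r={r_cap}")
            rs = np.minimum(rs, r_cap)
        cm = np.concatenate([[0.0], np.cumsum(haldane_cm(rs))])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "window_index": sub.columns.to_numpy(dtype=np.int64),
                    "bp": sub.columns.to_numpy(dtype=np.int64) * window_bp,
                    "cM": cm,
                }
            )
        )
    if not frames:
        raise ValueError("no chromosome had >= 2 informative windows")
    return GeneticMap(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Genotype matrix TSV: samples as rows, chrom:window columns."""
    flat = matrix.copy()
    flat.columns = [f"{c}:{w}" for c, w in matrix.columns]
    flat.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    # keep_default_na: the genotype symbol "NA" is data, not a missing value
    flat = pd.read_csv(path, sep="\t", index_col="sample_id", keep_default_na=False)
    cols = [(c.split(":")[0], int(c.split(":")[1])) for c in flat.columns]
    flat.columns = pd.MultiIndex.from_tuples(cols, names=["chrom", "window_index"])
    return flat
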