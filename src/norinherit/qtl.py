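"""Single-QTL genome scans with permutation thresholds.

Interval mapping is realised as Haley-Knott regression: at each marker and
2-cM pseudomarker the phenotype is regressed on expected genotype dosages
computed from flanking-marker genotype probabilities under Haldane
recombination, and ``LOD = (n/2) * log10(RSS0 / RSS1)`` compares the fit to
the intercept-only model.  Genome-wide significance comes from the empirical
(1 - alpha) quantile of the maximum LOD over seeded phenotype permutations.
A cofactor-adjusted scan (conditioning on markers outside a 10-cM exclusion
window around the test position) approximates multiple-QTL mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from norinherit.gbs import CODE_OF, GeneticMap, haldane_r

__all__ = [
    "ProbGrid",
    "ScanResult",
    "Threshold",
    "QTLPeak",
    "genotype_probabilities",
    "scan_sim",
    "permutation_threshold",
    "scan_cofactor",
    "find_peaks",
]

LOD_CAP_RATIO = 1e-12  # RSS1 floored at RSS0 * this; a perfect fit is capped


@dataclass
class ProbGrid:
    """Genotype probabilities P(AA), P(AB), P(BB) on a scan grid.

    ``probs`` has shape (n_positions, n_samples, 3); positions carry the
    chromosome, cM coordinate and whether the position is an observed marker.
    """

    positions: pd.DataFrame  # chrom, cM, is_marker, window_index (<0 for pseudomarkers)
    probs: np.ndarray
    samples: list[str]
    design: str

    def dosages(self, idx: int) -> np.ndarray:
        """Regression dosage columns at one position (additive [, dominance])."""
        p = self.probs[idx]
        additive = p[:, 2] - p[:, 0]
        if self.design == "F2":
            return np.column_stack([additive, p[:, 1]])
        return additive[:, None]


@dataclass
class ScanResult:
    table: pd.DataFrame  # chrom, cM, lod
    n_individuals: int
    model: str

    def max_lod(self) -> float:
        return float(self.table["lod"].max())


@dataclass
class Threshold:
    alpha: float
    n_permutations: int
    value: float
    seed: int


@dataclass
class QTLPeak:
    chrom: str
    cM: float
    lod: float
    significant: bool


# ---------------------------------------------------------------------------
# genotype probabilities
# ---------------------------------------------------------------------------


def _f2_row(r: np.ndarray, g: np.ndarray) -> np.ndarray:
    """P(g2 | g1=g) rows of the F2 genotype transition at rec. fraction r."""
    r = np.asarray(r, dtype=float)
    one = 1.0 - r
    rows = np.empty((len(r), 3))
    rows0 = np.column_stack([one**2, 2 * r * one, r**2])
    rows1 = np.column_stack([r * one, one**2 + r**2, r * one])
    rows2 = np.column_stack([r**2, 2 * r * one, one**2])
    rows = np.where((g == 0)[:, None], rows0, np.where((g == 1)[:, None], rows1, rows2))
    return rows


def _f2_col(r: np.ndarray, g: np.ndarray) -> np.ndarray:
    """P(g2=g | g1) columns, i.e. entries M[:, g] of the F2 transition."""
    r = np.asarray(r, dtype=float)
    one = 1.0 - r
    col0 = np.column_stack([one**2, r * one, r**2])
    col1 = np.column_stack([2 * r * one, one**2 + r**2, 2 * r * one])
    col2 = np.column_stack([r**2, r * one, one**2])
    return np.where((g == 0)[:, None], col0, np.where((g == 1)[:, None], col1, col2))


def _ril_row(r: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Two-locus RIL transition rows using R = 2r/(1+2r) between fixed loci."""
    r = np.asarray(r, dtype=float)
    big_r = 2.0 * r / (1.0 + 2.0 * r)
    rows0 = np.column_stack([1.0 - big_r, np.zeros_like(big_r), big_r])
    rows2 = np.column_stack([big_r, np.zeros_like(big_r), 1.0 - big_r])
    return np.where((g == 0)[:, None], rows0, rows2)


_F2_PRIOR = np.array([0.25, 0.5, 0.25])
_RIL_PRIOR = np.array([0.5, 0.0, 0.5])


def genotype_probabilities(
    matrix: pd.DataFrame,
    gmap: GeneticMap,
    step_cM: float = 2.0,
    design: str = "F2",
) -> ProbGrid:
    """Flanking-marker genotype probabilities at markers and pseudomarkers.

    At each grid position the three genotype probabilities are obtained by
    conditioning on the nearest non-missing flanking markers under Haldane
    recombination (RILs use the 2-state chain with H treated as missing).
    Positions without an informative flank fall back to the design prior.
    """
    if design not in {"F2", "RIL"}:
        raise ValueError(f"unsupported design {design!r}")
    samples = list(matrix.index)
    prior = _F2_PRIOR if design == "F2" else _RIL_PRIOR
    row_fn = _f2_row if design == "F2" else _ril_row
    col_fn = _f2_col if design == "F2" else _ril_row  # RIL transition is symmetric

    pos_frames = []
    prob_blocks = []
    for chrom in gmap.chrom_order:
        loci = gmap.chrom_loci(chrom)
        if loci.empty:
            raise ValueError(f"empty chromosome {chrom!r} in map")
        marker_cm = loci["cM"].to_numpy(dtype=float)
        widx = loci["window_index"].to_numpy(dtype=np.int64)
        cols = [(chrom, int(w)) for w in widx]
        missing_cols = [c for c in cols if c not in matrix.columns]
        if missing_cols:
            raise ValueError(f"map loci absent from matrix: {missing_cols[:3]}")
        codes = (
            matrix.loc[:, cols].apply(lambda col: col.map(CODE_OF)).to_numpy(dtype=np.int64)
        )
        if design == "RIL":
            codes = np.where(codes == 1, -1, codes)  # H -> missing in inbred lines

        pseudo = np.arange(0.0, marker_cm[-1], step_cM)
        grid = np.unique(np.concatenate([marker_cm, pseudo]))
        is_marker = np.isin(grid, marker_cm)
        grid_widx = np.full(len(grid), -1, dtype=np.int64)
        grid_widx[is_marker] = widx[np.searchsorted(marker_cm, grid[is_marker])]

        block = np.empty((len(grid), len(samples), 3))
        for si in range(len(samples)):
            obs = np.flatnonzero(codes[si] >= 0)
            if obs.size == 0:
                block[:, si, :] = prior
                continue
            obs_cm = marker_cm[obs]
            obs_codes = codes[si][obs]
            li = np.searchsorted(obs_cm, grid, side="right") - 1
            ri = np.searchsorted(obs_cm, grid, side="left")
            has_l, has_r = li >= 0, ri < obs.size

            # left flank conditions the row; a right flank multiplies in the
            # column term (positions with only a right flank start from the
            # prior, giving prior * column as required by reversibility).
            p = np.tile(prior, (len(grid), 1))
            if has_l.any():
                r1 = haldane_r(grid[has_l] - obs_cm[li[has_l]])
                p[has_l] = row_fn(r1, obs_codes[li[has_l]])
            if has_r.any():
                r2 = haldane_r(obs_cm[ri[has_r]] - grid[has_r])
                p[has_r] = p[has_r] * col_fn(r2, obs_codes[ri[has_r]])
            total = p.sum(axis=1, keepdims=True)
            degenerate = total[:, 0] <= 0
            if degenerate.any():
                p[degenerate] = prior
                total[degenerate] = 1.0
            block[:, si, :] = p / total
        pos_frames.append(
            pd.DataFrame(
                {"chrom": chrom, "cM": grid, "is_marker": is_marker, "window_index": grid_widx}
            )
        )
        prob_blocks.append(block)

    positions = pd.concat(pos_frames, ignore_index=True)
    probs = np.concatenate(prob_blocks, axis=0)
    return ProbGrid(positions, probs, samples, design)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _rss_multi(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of columns of ``y`` on design ``x`` (with QR).

    Collinear design columns are excluded via the R diagonal so the Q basis
    spans exactly the column space (an arbitrary completion direction would
    understate the RSS).
    """
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    fitted_sq = (q[:, keep].T @ y) ** 2
    return (y**2).sum(axis=0) - fitted_sq.sum(axis=0)


def _align_phenotype(grid: ProbGrid, phenotype: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    pheno = phenotype.reindex(grid.samples)
    keep = np.isfinite(pheno.to_numpy(dtype=float))
    if keep.sum() < 3:
        raise ValueError("fewer than 3 individuals with finite phenotype")
    return pheno.to_numpy(dtype=float)[keep], keep


def _lod_scan(grid: ProbGrid, y: np.ndarray, keep: np.ndarray) -> np.ndarray:
    n = len(y)
    ymat = y[:, None]
    rss0 = float(((y - y.mean()) ** 2).sum())
    lods = np.zeros(grid.probs.shape[0])
    if rss0 == 0.0:
        warnings.warn("zero phenotypic variance; scan is identically zero")
        return lods
    ones = np.ones((n, 1))
    for i in range(grid.probs.shape[0]):
        x = np.hstack([ones, grid.dosages(i)[keep]])
        rss1 = float(_rss_multi(x, ymat)[0])
        rss1 = max(rss1, rss0 * LOD_CAP_RATIO)
        lods[i] = 0.5 * n * np.log10(rss0 / rss1)
    return lods


def scan_sim(grid: ProbGrid, phenotype: pd.Series) -> ScanResult:
    """Simple interval mapping scan (Haley-Knott regression).

    F2 scans fit additive + dominance dosages; RIL scans additive only.
    Individuals with missing phenotype are dropped.
    """
    y, keep = _align_phenotype(grid, phenotype)
    lods = _lod_scan(grid, y, keep)
    table = grid.positions[["chrom", "cM"]].copy()
    table["lod"] = lods
    return ScanResult(table, int(keep.sum()), "SIM")


def permutation_threshold(
    grid: ProbGrid,
    phenotype: pd.Series,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> Threshold:
    """Genome-wide LOD threshold from seeded phenotype permutations.

    The threshold is the empirical (1 - alpha) quantile (linear, "type 7")
    of the genome-wide maximum LOD over ``n_perm`` label permutations.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y, keep = _align_phenotype(grid, phenotype)
    n = len(y)
    rng = np.random.default_rng(seed)
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    rss0 = ((y - y.mean()) ** 2).sum()
    if rss0 == 0.0:
        return Threshold(alpha, n_perm, 0.0, seed)
    ones = np.ones((n, 1))
    max_lod = np.zeros(n_perm)
    for i in range(grid.probs.shape[0]):
        x = np.hstack([ones, grid.dosages(i)[keep]])
        rss1 = np.maximum(_rss_multi(x, perms), rss0 * LOD_CAP_RATIO)
        np.maximum(max_lod, 0.5 * n * np.log10(rss0 / rss1), out=max_lod)
    return Threshold(alpha, n_perm, float(np.quantile(max_lod, 1.0 - alpha)), seed)


def _cofactor_design(
    grid: ProbGrid, cofactors: list[tuple[str, float]], keep: np.ndarray
) -> tuple[np.ndarray, list[tuple[str, float]]]:
    """Dosage columns for cofactor positions, dropping collinear ones."""
    cols, kept = [], []
    pos = grid.positions
    for chrom, cm in cofactors:
        on_chrom = (pos["chrom"] == chrom).to_numpy()
        if not on_chrom.any():
            raise ValueError(f"cofactor chromosome {chrom!r} not in grid")
        idx_all = np.flatnonzero(on_chrom)
        idx = idx_all[np.argmin(np.abs(pos["cM"].to_numpy()[idx_all] - cm))]
        cols.append(grid.dosages(int(idx))[keep])
        kept.append((chrom, float(pos["cM"].iloc[idx])))
    if not cols:
        return np.empty((int(keep.sum()), 0)), []
    x = np.hstack(cols)
    # drop collinear columns greedily by QR rank test
    keep_cols, kept_cf = [], []
    per = x.shape[1] // len(kept)
    for j, cf in enumerate(kept):
        cand = keep_cols + list(range(j * per, (j + 1) * per))
        sub = np.hstack([np.ones((x.shape[0], 1)), x[:, cand]])
        if np.linalg.matrix_rank(sub) == sub.shape[1]:
            keep_cols = cand
            kept_cf.append(cf)
        else:
            warnings.warn(f"dropping collinear cofactor at {cf}")
    return x[:, keep_cols], kept_cf


def scan_cofactor(
    grid: ProbGrid,
    phenotype: pd.Series,
    cofactors: list[tuple[str, float]],
    exclusion_window_cM: float = 10.0,
) -> ScanResult:
    """Cofactor-adjusted genome scan (a CIM-style approximation of MQM).

    At each test position, cofactor dosages are included in both the null
    and the full model, except cofactors on the same chromosome within
    ``exclusion_window_cM`` of the test position, which are excluded from
    both.  With no cofactors this reduces exactly to :func:`scan_sim`.
    """
    y, keep = _align_phenotype(grid, phenotype)
    n = len(y)
    ymat = y[:, None]
    cf_x, kept_cf = _cofactor_design(grid, cofactors, keep)
    rss_null_total = float(((y - y.mean()) ** 2).sum())
    if rss_null_total == 0.0:
        warnings.warn("zero phenotypic variance; scan is identically zero")
        table = grid.positions[["chrom", "cM"]].copy()
        table["lod"] = 0.0
        return ScanResult(table, n, "cofactor")

    per = cf_x.shape[1] // len(kept_cf) if kept_cf else 0
    ones = np.ones((n, 1))
    lods = np.zeros(grid.probs.shape[0])
    pos_chrom = grid.positions["chrom"].to_numpy()
    pos_cm = grid.positions["cM"].to_numpy()
    for i in range(grid.probs.shape[0]):
        include = [
            j
            for j, (chrom, cm) in enumerate(kept_cf)
            if chrom != pos_chrom[i] or abs(cm - pos_cm[i]) >= exclusion_window_cM
        ]
        cf_cols = (
            cf_x[:, [j * per + k for j in include for k in range(per)]]
            if include
            else np.empty((n, 0))
        )
        x0 = np.hstack([ones, cf_cols])
        x1 = np.hstack([x0, grid.dosages(i)[keep]])
        rss0 = float(_rss_multi(x0, ymat)[0])
        rss1 = max(float(_rss_multi(x1, ymat)[0]), rss_null_total * LOD_CAP_RATIO)
        lods[i] = 0.5 * n * np.log10(max(rss0, rss_null_total * LOD_CAP_RATIO) / rss1)
    table = grid.positions[["chrom", "cM"]].copy()
    table["lod"] = lods
    return ScanResult(table, n, "cofactor")


def find_peaks(scan: ScanResult, threshold: Threshold | float) -> list[QTLPeak]:
    """Per-chromosome maximum-LOD peaks, flagged against the threshold."""
    cut = threshold.value if isinstance(threshold, Threshold) else float(threshold)
    peaks = []
    for chrom, grp in scan.table.groupby("chrom", sort=False):
        row = grp.loc[grp["lod"].idxmax()]
        peaks.append(
            QTLPeak(str(chrom), float(row["cM"]), float(row["lod"]), bool(row["lod"] > cut))
        )
    return peaks
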