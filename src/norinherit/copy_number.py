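"""45S rRNA gene copy-number estimation.

Two routes to copies-per-haploid-genome:

* **NGS** — the mean read depth along the annotated 18S subunit of the 45S
  repeat unit divided by the mean depth along the first 10 Mb of chromosome 3
  (a region free of centromeres and 5S/45S arrays).  Because all rDNA copies
  map onto a single reference unit, the ratio estimates copies per haploid
  genome directly.
* **qPCR** — relative abundance of the 18S amplicon versus the single-copy
  gene ACT2 (At3g18780): ``copy number = 2**(Ct_ACT2 - Ct_18S)``, with
  plate standardization either through a common control sample present on
  every plate or through a least-squares plate-factor fit on cross-plate
  technical replicates.

Also includes the FISH signal-area ratio arithmetic used to compare NOR
sizes cytologically.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CoverageSummary",
    "CopyNumberEstimate",
    "EstimationError",
    "estimate_ngs",
    "estimate_ngs_table",
    "coverage_from_depth",
    "estimate_qpcr",
    "estimate_qpcr_table",
    "standardize_plates",
    "sample_estimates",
    "signal_ratio",
    "SubunitInterval",
    "SUBUNIT_18S",
]


class EstimationError(ValueError):
    """Raised when a copy-number estimate cannot be formed."""


class CoverageSummary(NamedTuple):
    """Per-sample mean depths over the 18S subunit and the chr3 baseline."""

    sample_id: str
    mean18S: float
    meanBaseline: float


class CopyNumberEstimate(NamedTuple):
    sample_id: str
    value: float
    method: str  # "NGS" | "qPCR"
    standardized: bool = False


class SubunitInterval(NamedTuple):
    """1-based inclusive coordinates of a subunit on the 45S repeat unit."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


SUBUNIT_18S = SubunitInterval(2195, 4002)


# ---------------------------------------------------------------------------
# NGS route
# ---------------------------------------------------------------------------


def estimate_ngs(cov: CoverageSummary) -> CopyNumberEstimate:
    """Copies per haploid genome as mean 18S depth over mean baseline depth."""
    if cov.mean18S < 0 or cov.meanBaseline < 0:
        raise EstimationError(f"sample {cov.sample_id}: negative mean depth")
    if cov.meanBaseline == 0:
        raise EstimationError(
            f"sample {cov.sample_id}: baseline mean depth is zero; cannot form ratio"
        )
    return CopyNumberEstimate(cov.sample_id, cov.mean18S / cov.meanBaseline, "NGS")


def estimate_ngs_table(coverage: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`estimate_ngs` over a coverage table.

    Expects columns ``sample_id, mean18S, meanBaseline``; returns
    ``sample_id, value, method``.
    """
    required = {"sample_id", "mean18S", "meanBaseline"}
    if not required.issubset(coverage.columns):
        raise EstimationError(f"coverage table must have columns {sorted(required)}")
    bad = coverage.loc[coverage["meanBaseline"] <= 0, "sample_id"].tolist()
    if bad:
        raise EstimationError(f"zero/negative baseline depth for samples: {bad}")
    out = pd.DataFrame(
        {
            "sample_id": coverage["sample_id"],
            "value": coverage["mean18S"] / coverage["meanBaseline"],
            "method": "NGS",
        }
    )
    return out


def coverage_from_depth(
    sample_id: str,
    unit_depth: pd.DataFrame,
    genome_depth: pd.DataFrame,
    subunit: SubunitInterval = SUBUNIT_18S,
    baseline_chrom: str = "Chr3",
    baseline_end: int = 10_000_000,
) -> CoverageSummary:
    """Build a :class:`CoverageSummary` from per-base depth tables.

    ``unit_depth``: columns (pos, depth), 1-based positions on the 45S repeat
    unit.  ``genome_depth``: columns (chrom, pos, depth), 1-based.  Bases
    absent from a table count as depth 0: the mean keeps a fixed denominator
    (the full subunit / baseline length).
    """
    in_18s = unit_depth.loc[
        (unit_depth["pos"] >= subunit.start) & (unit_depth["pos"] <= subunit.end)
    ]
    mean18s = in_18s["depth"].sum() / subunit.length
    base = genome_depth.loc[
        (genome_depth["chrom"] == baseline_chrom)
        & (genome_depth["pos"] >= 1)
        & (genome_depth["pos"] <= baseline_end)
    ]
    mean_base = base["depth"].sum() / baseline_end
    return CoverageSummary(sample_id, float(mean18s), float(mean_base))


# ---------------------------------------------------------------------------
# qPCR route
# ---------------------------------------------------------------------------


def estimate_qpcr(ct_18s: float, ct_act2: float, sample_id: str = "") -> CopyNumberEstimate:
    """Relative 18S abundance ``2**(Ct_ACT2 - Ct_18S)``."""
    if not (math.isfinite(ct_18s) and math.isfinite(ct_act2)):
        raise EstimationError(f"sample {sample_id}: non-finite Ct value")
    return CopyNumberEstimate(sample_id, 2.0 ** (ct_act2 - ct_18s), "qPCR")


def estimate_qpcr_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-(sample, plate) qPCR estimates from a Ct record table.

    Technical replicates are averaged per (sample, plate, target); each
    sample-plate pair must carry both the 18S and the ACT2 target.
    Returns columns ``sample_id, plate_id, value``.
    """
    required = {"sample_id", "plate_id", "target", "ct_value"}
    if not required.issubset(ct_table.columns):
        raise EstimationError(f"Ct table must have columns {sorted(required)}")
    means = (
        ct_table.groupby(["sample_id", "plate_id", "target"], sort=False)["ct_value"]
        .mean()
        .unstack("target")
    )
    for target in ("18S", "ACT2"):
        if target not in means.columns:
            raise EstimationError(f"no Ct records for target {target!r}")
    missing = means.index[means[["18S", "ACT2"]].isna().any(axis=1)].tolist()
    if missing:
        raise EstimationError(f"missing replicate group for sample/plate pairs: {missing}")
    out = means.reset_index()
    out["value"] = 2.0 ** (out["ACT2"] - out["18S"])
    return out[["sample_id", "plate_id", "value"]]


def _connected(table: pd.DataFrame) -> bool:
    """True when cross-plate sample sharing links every plate to the rest."""
    plates = list(table["plate_id"].unique())
    parent = {p: p for p in plates}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for _, grp in table.groupby("sample_id"):
        ps = grp["plate_id"].unique()
        for other in ps[1:]:
            parent[find(other)] = find(ps[0])
    return len({find(p) for p in plates}) == 1


def standardize_plates(
    table: pd.DataFrame,
    mode: str = "control",
    control_sample_id: str | None = None,
) -> pd.DataFrame:
    """Remove multiplicative plate effects from raw per-plate estimates.

    ``table`` has columns ``sample_id, plate_id, value``.

    mode="control": every plate's values are divided by that plate's control
    reading relative to the grand mean of the control across plates, so the
    control itself becomes identical on all plates.

    mode="regression": per-plate multiplicative factors fitted by least
    squares on the log scale, using samples measured on more than one plate
    as the cross-plate links; factors are normalised to geometric mean 1.
    Requires the plate-sharing graph to be connected.
    """
    required = {"sample_id", "plate_id", "value"}
    if not required.issubset(table.columns):
        raise EstimationError(f"plate table must have columns {sorted(required)}")
    out = table.copy()

    if mode == "control":
        if control_sample_id is None:
            raise EstimationError("control mode requires control_sample_id")
        controls = (
            out.loc[out["sample_id"] == control_sample_id]
            .groupby("plate_id")["value"]
            .mean()
        )
        missing = sorted(set(out["plate_id"].unique()) - set(controls.index))
        if missing:
            raise EstimationError(f"control sample absent from plates: {missing}")
        factors = controls / controls.mean()
    elif mode == "regression":
        n_links = int((out.groupby("sample_id")["plate_id"].nunique() > 1).sum())
        if n_links < 1 or not _connected(out):
            raise EstimationError(
                "regression standardization needs cross-plate replicates linking every plate"
            )
        if (out["value"] <= 0).any():
            raise EstimationError("regression standardization requires positive values")
        samples = pd.Categorical(out["sample_id"])
        plates = pd.Categorical(out["plate_id"])
        n = len(out)
        x = np.zeros((n, len(samples.categories) + len(plates.categories)))
        x[np.arange(n), samples.codes] = 1.0
        x[np.arange(n), len(samples.categories) + plates.codes] = 1.0
        coef, *_ = np.linalg.lstsq(x, np.log(out["value"].to_numpy()), rcond=None)
        log_f = coef[len(samples.categories):]
        log_f = log_f - log_f.mean()  # geometric-mean-1 normalisation
        factors = pd.Series(np.exp(log_f), index=plates.categories)
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")

    out["value"] = out["value"] / out["plate_id"].map(factors).to_numpy()
    out.attrs["standardized"] = True
    out.attrs["mode"] = mode
    return out


def sample_estimates(table: pd.DataFrame, method: str = "qPCR") -> pd.DataFrame:
    """Collapse a (sample, plate, value) table to one estimate per sample."""
    agg = table.groupby("sample_id", sort=False)["value"].mean().reset_index()
    agg["method"] = method
    agg["standardized"] = bool(table.attrs.get("standardized", False))
    return agg


# ---------------------------------------------------------------------------
# FISH arithmetic
# ---------------------------------------------------------------------------


def signal_ratio(area_a: float, area_b: float) -> float:
    """Ratio of two fluorescence signal areas, truncated to two decimals.

    Truncation (round toward zero) matches the convention of the reported
    cytology ratios.
    """
    if area_b <= 0:
        raise ValueError("area_b must be positive")
    if area_a < 0:
        raise ValueError("area_a must be non-negative")
    ratio = area_a / area_b
    return math.floor(ratio * 100.0 + 1e-9) / 100.0
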