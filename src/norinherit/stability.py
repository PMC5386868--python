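"""Copy-number stability: mixed-model LRTs and CV-by-generation series.

For mutation-accumulation data the model is

    value ~ line + generation  (fixed)  +  (1 | line:replicate)  +  error,

fitted by maximum likelihood (not REML, so that likelihoods remain
comparable when the fixed structure changes between nested models).  The
single variance ratio ``lambda = sigma2_replicate / sigma2_error`` is
profiled out: for fixed lambda the GLS solution and the error variance have
closed forms, leaving a one-dimensional likelihood maximised on a bracketed
log grid refined by golden-section search.

Instability across generations is summarised as the coefficient of
variation (sd / mean, sample sd with n-1 denominator) of copy number among
individuals sharing the same genotypes at both NOR loci, as a function of
generations since divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LMMFit",
    "LRTResult",
    "fit_lmm",
    "profile_loglik",
    "lrt",
    "cv_by_generation",
    "nor_matched_cv",
]


@dataclass
class LMMFit:
    """ML fit of a random-intercept linear mixed model."""

    fixed_terms: tuple[str, ...]
    coef: pd.Series
    sigma2_rep: float
    sigma2_e: float
    loglik: float
    n_obs: int
    n_fixed_params: int
    lam: float  # sigma2_rep / sigma2_e


@dataclass
class LRTResult:
    chi_square: float
    df: int
    p_value: float


def _design(data: pd.DataFrame, fixed_terms: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with intercept."""
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for term in fixed_terms:
        cat = pd.Categorical(data[term])
        if len(cat.categories) < 2:
            raise ValueError(f"fixed term {term!r} needs >= 2 levels")
        dummies = pd.get_dummies(cat, drop_first=True, dtype=float)
        cols.append(dummies.to_numpy())
        names.extend(f"{term}[{lvl}]" for lvl in dummies.columns)
    return np.column_stack(cols), names


def _group_stats(x: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group sufficient statistics for the Woodbury GLS evaluations."""
    order = np.argsort(groups, kind="stable")
    xs, ys, gs = x[order], y[order], groups[order]
    _, starts, sizes = np.unique(gs, return_index=True, return_counts=True)
    sum_x = np.add.reduceat(xs, starts, axis=0)  # (G, p)
    sum_y = np.add.reduceat(ys, starts)  # (G,)
    xtx = xs.T @ xs
    xty = xs.T @ ys
    yty = float(ys @ ys)
    return sum_x, sum_y, sizes.astype(float), xtx, xty, yty


def profile_loglik(lam: float, stats_tuple, n: int) -> tuple[float, np.ndarray, float]:
    """Profiled ML log-likelihood at variance ratio ``lam``.

    With V = I + lam * Z Z' block-diagonal over replicate groups,
    V_g^{-1} = I - c_g J with c_g = lam / (1 + lam * n_g), so all GLS
    quantities reduce to per-group sums.  Returns (loglik, beta, sigma2_e).
    """
    sum_x, sum_y, sizes, xtx, xty, yty = stats_tuple
    c = lam / (1.0 + lam * sizes)  # (G,)
    xvx = xtx - (sum_x * c[:, None]).T @ sum_x
    xvy = xty - sum_x.T @ (c * sum_y)
    yvy = yty - float(c @ sum_y**2)
    beta = np.linalg.solve(xvx, xvy)
    rss_v = yvy - 2.0 * beta @ xvy + beta @ xvx @ beta
    rss_v = max(rss_v, 1e-300)
    sigma2 = rss_v / n
    logdet_v = float(np.log1p(lam * sizes).sum())
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0) - 0.5 * logdet_v
    return ll, beta, sigma2


def fit_lmm(
    data: pd.DataFrame,
    fixed_terms: tuple[str, ...] = ("line", "generation"),
    value_col: str = "value",
    replicate_col: str = "replicate",
    line_col: str = "line",
    tol: float = 1e-8,
) -> LMMFit:
    """ML fit of value ~ fixed_terms + (1 | line:replicate).

    Replicates must be nested within lines; the random intercept applies to
    each line:replicate combination.  The variance ratio is profiled on a
    log-spaced bracket and refined by golden-section search to ``tol``.
    """
    required = {value_col, replicate_col, line_col, *fixed_terms}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    nesting = data.groupby(replicate_col)[line_col].nunique()
    if (nesting > 1).any():
        raise ValueError("replicate ids must be nested within lines")
    if not (data.groupby(replicate_col).size() >= 2).any():
        raise ValueError("need at least one replicate with >= 2 observations")

    y = data[value_col].to_numpy(dtype=float)
    x, names = _design(data, tuple(fixed_terms))
    groups = pd.Categorical(
        data[line_col].astype(str) + ":" + data[replicate_col].astype(str)
    ).codes
    n = len(y)
    st = _group_stats(x, y, groups)

    lams = np.concatenate([[0.0], np.logspace(-8, 8, 81)])
    lls = np.array([profile_loglik(l, st, n)[0] for l in lams])
    best = int(np.argmax(lls))

    if best == 0:
        lam_hat = 0.0
    else:
        lo = lams[max(best - 1, 1)]
        hi = lams[min(best + 1, len(lams) - 1)]
        if lo == hi:
            lam_hat = lams[best]
        else:
            # golden-section on log(lambda)
            a, b = np.log(lo), np.log(hi)
            gr = (np.sqrt(5.0) - 1.0) / 2.0
            c1, c2 = b - gr * (b - a), a + gr * (b - a)
            f1 = profile_loglik(np.exp(c1), st, n)[0]
            f2 = profile_loglik(np.exp(c2), st, n)[0]
            while b - a > tol:
                if f1 < f2:
                    a, c1, f1 = c1, c2, f2
                    c2 = a + gr * (b - a)
                    f2 = profile_loglik(np.exp(c2), st, n)[0]
                else:
                    b, c2, f2 = c2, c1, f1
                    c1 = b - gr * (b - a)
                    f1 = profile_loglik(np.exp(c1), st, n)[0]
            lam_hat = float(np.exp(0.5 * (a + b)))
        if profile_loglik(0.0, st, n)[0] >= profile_loglik(lam_hat, st, n)[0]:
            lam_hat = 0.0

    ll, beta, sigma2 = profile_loglik(lam_hat, st, n)
    return LMMFit(
        fixed_terms=tuple(fixed_terms),
        coef=pd.Series(beta, index=names),
        sigma2_rep=lam_hat * sigma2,
        sigma2_e=sigma2,
        loglik=float(ll),
        n_obs=n,
        n_fixed_params=x.shape[1],
        lam=lam_hat,
    )


def lrt(full: LMMFit, reduced: LMMFit) -> LRTResult:
    """Likelihood-ratio test of nested ML fits (chi-square reference)."""
    if not set(reduced.fixed_terms).issubset(full.fixed_terms):
        raise ValueError("reduced model fixed terms must nest within the full model")
    if reduced.n_obs != full.n_obs:
        raise ValueError("models must be fitted to the same data")
    df = full.n_fixed_params - reduced.n_fixed_params
    if df < 0:
        raise ValueError("full model must have at least as many fixed-effect parameters")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        # identical fixed structures: chi-square mass at zero
        return LRTResult(chi2, 0, 1.0 if chi2 <= 1e-8 else 0.0)
    return LRTResult(chi2, df, float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# CV trajectories
# ---------------------------------------------------------------------------


def cv_by_generation(
    records: pd.DataFrame,
    group_col: str = "group",
    generation_col: str = "generation",
    value_col: str = "value",
    method_col: str | None = "method",
) -> pd.DataFrame:
    """Coefficient of variation per (group, generation).

    CV = sample standard deviation (n-1 denominator) / mean; groups with a
    zero mean are flagged NaN with a warning, points need n >= 2.
    """
    keys = [group_col, generation_col] + ([method_col] if method_col in records else [])
    rows = []
    for key, grp in records.groupby(keys, sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            continue
        mean = vals.mean()
        if mean == 0.0:
            warnings.warn(f"group {key}: zero mean; CV undefined")
            cv = np.nan
        else:
            cv = vals.std(ddof=1) / mean
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update({"cv": cv, "n": len(vals)})
        rows.append(row)
    return pd.DataFrame(rows)


def nor_matched_cv(
    population,
    genome,
    values: dict[str, float] | None = None,
    method: str = "NGS",
) -> pd.DataFrame:
    """CV-by-generation among individuals sharing both NOR genotypes.

    ``values`` maps individual id to a copy-number estimate; when omitted the
    true copies-per-haploid values are used.  The grouping key concatenates
    the founder genotypes at every NOR locus; an individual's generation is
    its generations since the groups diverged from their common ancestor.
    """
    rows = []
    for ind in population:
        genos = "/".join(
            f"{locus}:{ind.nor_genotype(genome, locus)}"
            for locus in sorted(genome.nor_chromosomes())
        )
        value = (
            values[ind.id] if values is not None else ind.total_nor_copies(genome) / 2.0
        )
        rows.append(
            {
                "group": genos,
                "generation": ind.generation,
                "value": value,
                "method": method,
            }
        )
    return cv_by_generation(pd.DataFrame(rows))
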