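"""Per-morph linear regressions of morph frequencies on raw environmental
variables.

Complements the distance-based inference: morph proportions are
arcsine-square-root transformed, environmental predictors are
log-transformed and z-scored, and one OLS fit per morph yields
standardized coefficients, an overall F test, and Benjamini-Hochberg FDR
adjustment across the family of slope tests. Outlier populations flagged
by the Grubbs screen can be excluded explicitly for a sensitivity refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import MORPH_ORDER, DistanceMatrix, SiteTable
from .morphstats import FrequencyTable

LOG_SHIFT = 1e-6  # epsilon shift applied to zero covariate values before log


@dataclass(frozen=True)
class MorphRegressionResult:
    morph: str
    predictors: tuple[str, ...]
    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    p_model: float
    coefficients: pd.Series  # standardized slopes
    p_raw: pd.Series
    p_fdr: pd.Series
    excluded_population: str | None


def transform(
    freqs: FrequencyTable,
    sites: SiteTable,
    predictors: Sequence[str] = ("aridity", "vegetation"),
) -> pd.DataFrame:
    """Design table: arcsine-root morph responses plus log-z-scored predictors.

    Response columns ``asin_<morph>`` hold arcsin(sqrt(p)); predictor
    columns hold ln(x) z-scored across sites. Zero covariate values are
    shifted by a small epsilon before the log (with a warning); negative
    values are an error.
    """
    pops = freqs.populations
    if set(pops) - set(sites.sites):
        raise ValueError("site table does not cover all populations")
    out = pd.DataFrame(index=pops)
    for m in MORPH_ORDER:
        p = freqs.proportions()[m].to_numpy(dtype=float)
        out[f"asin_{m}"] = np.arcsin(np.sqrt(p))
    for var in predictors:
        x = sites.values(var).reindex(pops).to_numpy(dtype=float)
        if (x < 0).any():
            raise ValueError(f"negative values in {var!r}: log transform undefined")
        if (x == 0).any():
            warnings.warn(f"{var!r} contains zeros; applying epsilon shift before log")
            x = x + LOG_SHIFT
        lx = np.log(x)
        sd = lx.std(ddof=1)
        if sd == 0:
            raise ValueError(f"constant predictor {var!r}")
        out[var] = (lx - lx.mean()) / sd
    return out


def fit_morph_regressions(
    freqs: FrequencyTable,
    sites: SiteTable,
    predictors: Sequence[str] = ("aridity", "vegetation"),
    exclude_population: str | None = None,
    fdr_alpha: float = 0.05,
) -> list[MorphRegressionResult]:
    """One OLS fit per morph of transformed frequency on raw predictors.

    Standardized coefficients are slope * sd(x)/sd(y); the FDR family is
    all morphs x predictors slope P values (Benjamini-Hochberg). An
    explicitly named population can be excluded (outlier sensitivity);
    exclusion is never automatic.
    """
    design = transform(freqs, sites, predictors)
    if exclude_population is not None:
        if exclude_population not in design.index:
            raise ValueError(f"unknown population {exclude_population!r}")
        design = design.drop(index=exclude_population)
    n = len(design)
    if n < len(predictors) + 2:
        raise ValueError("need at least k_predictors + 2 populations")
    x = sm.add_constant(design[list(predictors)])
    partial = []
    for m in MORPH_ORDER:
        y = design[f"asin_{m}"]
        fit = sm.OLS(y, x).fit()
        sd_y = y.std(ddof=1)
        std_coef = fit.params[list(predictors)] * design[list(predictors)].std(ddof=1) / sd_y
        partial.append((m, fit, std_coef))
    # family-wide FDR across all slope P values
    raw = np.concatenate([f.pvalues[list(predictors)].to_numpy() for _, f, _ in partial])
    adj = multipletests(raw, alpha=fdr_alpha, method="fdr_bh")[1]
    results = []
    k = len(predictors)
    for i, (m, fit, std_coef) in enumerate(partial):
        p_raw = fit.pvalues[list(predictors)]
        p_fdr = pd.Series(adj[i * k : (i + 1) * k], index=list(predictors))
        results.append(
            MorphRegressionResult(
                morph=m,
                predictors=tuple(predictors),
                r_squared=float(fit.rsquared),
                f_statistic=float(fit.fvalue),
                df_model=int(fit.df_model),
                df_resid=int(fit.df_resid),
                p_model=float(fit.f_pvalue),
                coefficients=std_coef,
                p_raw=p_raw,
                p_fdr=p_fdr,
                excluded_population=exclude_population,
            )
        )
    return results


def regressions_frame(results: Sequence[MorphRegressionResult]) -> pd.DataFrame:
    """Tidy one-row-per-(morph, predictor) view of regression results."""
    rows = []
    for r in results:
        for var in r.predictors:
            rows.append(
                {
                    "morph": r.morph,
                    "predictor": var,
                    "std_coefficient": r.coefficients[var],
                    "p_raw": r.p_raw[var],
                    "p_fdr": r.p_fdr[var],
                    "r_squared": r.r_squared,
                    "f_statistic": r.f_statistic,
                    "df_model": r.df_model,
                    "df_resid": r.df_resid,
                    "p_model": r.p_model,
                    "excluded_population": r.excluded_population,
                }
            )
    return pd.DataFrame(rows)


def collinearity_screen(
    matrices: Mapping[str, DistanceMatrix], threshold: float = 0.6
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Flag predictor pairs whose distance vectors are strongly correlated.

    Computes all pairwise Pearson correlations between the lower-triangle
    vectors of the candidate predictor matrices (include the geographic
    distance matrix to screen it against environmental variables). Pairs
    with |r| >= threshold (closed boundary) are returned for use as
    ``exclusion_pairs`` in model selection, together with the full
    correlation table.
    """
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least two matrices to screen")
    ref = matrices[names[0]].labels
    vecs = {}
    for name in names:
        v = matrices[name].reorder(ref).condensed()
        if v.std() == 0:
            raise ValueError(f"constant variable {name!r}")
        vecs[name] = v
    corr = np.corrcoef(np.array([vecs[n] for n in names]))
    table = pd.DataFrame(corr, index=names, columns=names)
    flagged = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if abs(corr[i, j]) >= threshold
    ]
    return flagged, table
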