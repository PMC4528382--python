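"""Morph-frequency estimation, heterogeneity tests and outlier screening.

Pearson chi-square tests (no continuity correction, matching R's
``chisq.test`` on r x c tables), Bonferroni/Holm post-hoc pairwise
comparisons, per-population temporal-stability tests, and the Grubbs
single-outlier test used to screen extreme morph frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MORPH_ORDER, MorphCountTable


@dataclass(frozen=True)
class FrequencyTable:
    """Per-population morph proportions (canonical morph order) with N."""

    data: pd.DataFrame  # index: population; columns: MORPH_ORDER + N

    @property
    def populations(self) -> list[str]:
        return list(self.data.index)

    def vector(self, population: str) -> np.ndarray:
        return self.data.loc[population, list(MORPH_ORDER)].to_numpy(dtype=float)

    def proportions(self) -> pd.DataFrame:
        return self.data[list(MORPH_ORDER)]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    low_expected_warning: bool


@dataclass(frozen=True)
class GrubbsResult:
    statistic: float
    index: int
    p_value: float
    n: int
    tied_indices: tuple[int, ...]
    alternative: str


def frequencies(counts: MorphCountTable, year: int | None = None) -> FrequencyTable:
    """Morph proportions counts/N per population."""
    m = counts.counts_matrix(year=year)
    n = m.sum(axis=1)
    if (n == 0).any():
        bad = list(n.index[n == 0])
        raise ValueError(f"zero total count for population(s) {bad}")
    props = m.div(n, axis=0)
    props["N"] = n
    return FrequencyTable(props)


def _pearson_chi2(table: np.ndarray) -> ChiSquareResult:
    table = np.asarray(table, dtype=float)
    col_ok = table.sum(axis=0) > 0
    row_ok = table.sum(axis=1) > 0
    if not col_ok.all() or not row_ok.all():
        warnings.warn(
            "all-zero row/column dropped; degrees of freedom adjusted",
            stacklevel=3,
        )
        table = table[np.ix_(row_ok, col_ok)]
    r, c = table.shape
    if r < 2 or c < 2:
        raise ValueError("contingency table needs >=2 informative rows and columns")
    stat, p, df, expected = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        expected=expected,
        low_expected_warning=bool((expected < 5).any()),
    )


def _simulated_p(table: np.ndarray, n_sim: int, seed: int | None) -> float:
    """Monte-Carlo chi-square P under fixed margins (independent multinomials per row)."""
    rng = np.random.default_rng(seed)
    table = np.asarray(table, dtype=float)
    obs = _pearson_chi2(table).statistic
    row_n = table.sum(axis=1).astype(int)
    col_p = table.sum(axis=0) / table.sum()
    exceed = 0
    for _ in range(n_sim):
        sim = np.vstack([rng.multinomial(n, col_p) for n in row_n])
        colsum = sim.sum(axis=0)
        expected = np.outer(sim.sum(axis=1), colsum) / sim.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = np.where(expected > 0, (sim - expected) ** 2 / expected, 0.0)
        if cells.sum() >= obs - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_sim + 1)


def heterogeneity_test(
    counts: MorphCountTable,
    populations: list[str] | None = None,
    simulate_p: bool = False,
    n_simulations: int = 10_000,
    seed: int | None = None,
) -> ChiSquareResult:
    """Pearson chi-square of the populations x morphs contingency table.

    With ``simulate_p`` the P value is replaced by a Monte-Carlo estimate
    (useful when expected counts fall below 5), leaving the statistic and
    df unchanged.
    """
    m = counts.counts_matrix()
    if populations is not None:
        m = m.loc[populations]
    if len(m) < 2:
        raise ValueError("need at least two populations")
    res = _pearson_chi2(m.to_numpy())
    if simulate_p:
        p = _simulated_p(m.to_numpy(), n_simulations, seed)
        res = ChiSquareResult(res.statistic, res.df, p, res.expected, res.low_expected_warning)
    return res


def posthoc_pairwise(
    counts: MorphCountTable,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """All pairwise 2 x morphs chi-square tests with multiplicity adjustment.

    Returns a tidy frame with one row per unordered population pair:
    statistic, df, raw and adjusted P. Adjustment is Bonferroni (default)
    or Holm over the n(n-1)/2 comparisons.
    """
    if adjust not in ("bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    m = counts.counts_matrix()
    pops = list(m.index)
    if len(pops) < 3:
        raise ValueError("post-hoc comparisons need at least three populations")
    rows = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            res = _pearson_chi2(m.iloc[[i, j]].to_numpy())
            rows.append(
                {
                    "pop_a": pops[i],
                    "pop_b": pops[j],
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_raw": res.p_value,
                }
            )
    df = pd.DataFrame(rows)
    k = len(df)
    if adjust == "bonferroni":
        df["p_adjusted"] = np.minimum(1.0, df["p_raw"] * k)
    else:  # holm step-down
        order = np.argsort(df["p_raw"].to_numpy())
        adj = np.empty(k)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (k - rank) * df["p_raw"].iloc[idx])
            adj[idx] = min(1.0, running)
        df["p_adjusted"] = adj
    return df


def temporal_stability(
    counts_year1: MorphCountTable, counts_year2: MorphCountTable
) -> pd.DataFrame:
    """Per-population year x morph chi-square tests across two sampling years.

    Also reports the most common morph in each year so rank consistency
    can be checked alongside the test.
    """
    m1 = counts_year1.counts_matrix()
    m2 = counts_year2.counts_matrix()
    if set(m1.index) != set(m2.index):
        raise ValueError("population labels differ between years")
    rows = []
    for pop in m1.index:
        a = m1.loc[pop].to_numpy()
        b = m2.loc[pop].to_numpy()
        res = _pearson_chi2(np.vstack([a, b]))
        rows.append(
            {
                "population": pop,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "top_morph_year1": MORPH_ORDER[int(np.argmax(a))],
                "top_morph_year2": MORPH_ORDER[int(np.argmax(b))],
            }
        )
    return pd.DataFrame(rows)


def grubbs_test(values, alternative: str = "two-sided") -> GrubbsResult:
    """Grubbs single-outlier test.

    G = max_i |x_i - mean| / s with the sample (n-1) standard deviation.
    The P value inverts the t-distribution critical-value relation
    G_crit(alpha) = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)); with
    ``alternative="two-sided"`` the multiplier is 2n (t quantile at
    alpha/(2n)), with ``"one-sided"`` it is n — the form appropriate when
    only a suspected high (or low) extreme is tested. Ties on the maximal
    deviation are broken by lowest index; all tied indices are reported.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero variance: Grubbs statistic undefined")
    if alternative not in ("two-sided", "one-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    dev = np.abs(x - x.mean())
    g = dev.max() / s
    tied = tuple(np.flatnonzero(np.isclose(dev, dev.max(), rtol=1e-12)))
    # invert G -> t, then t -> tail probability
    denom = (n - 1) ** 2 - n * g**2
    if denom <= 0:  # G at its attainable bound (n-1)/sqrt(n)
        p = 0.0
    else:
        t = np.sqrt(n * (n - 2) * g**2 / denom)
        mult = 2 * n if alternative == "two-sided" else n
        p = min(1.0, mult * stats.t.sf(t, n - 2))
    return GrubbsResult(
        statistic=float(g),
        index=int(tied[0]),
        p_value=float(p),
        n=n,
        tied_indices=tied,
        alternative=alternative,
    )
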