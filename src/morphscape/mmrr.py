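"""Distance-matrix inference: Mantel tests, multiple matrix regression with
randomization (MMRR), and AICc multimodel selection with variable-importance
weights.

MMRR regresses the vectorized lower triangle of a response distance matrix
on those of one or more predictor matrices by OLS. Because the n(n-1)/2
pairwise distances are not independent, slope significance comes from a
permutation test that relabels the populations of the response matrix
(rows and columns together), refits, and compares |t| statistics. Model
selection enumerates predictor subsets, scores each with the small-sample
AICc computed from R-squared, retains models within a delta-AICc window of
the best, renormalizes Akaike weights over that set, and sums them per
variable into relative importance values (RIV).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DistanceMatrix

_EXHAUSTIVE_MAX = 7  # n! enumeration only for tiny matrices


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None


def _pair_index_matrix(n: int) -> np.ndarray:
    m = np.zeros((n, n), dtype=np.intp)
    c = 0
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = c
            c += 1
    return m


def _aligned_condensed(
    response: DistanceMatrix, predictors: Mapping[str, DistanceMatrix]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    labels = response.labels
    cols = {}
    for name, mat in predictors.items():
        if set(mat.labels) != set(labels):
            raise ValueError(f"predictor {name!r}: label set differs from response")
        cols[name] = mat.reorder(labels).condensed()
    return response.condensed(), cols


def _pair_permutations(
    n: int,
    n_permutations: int,
    rng: np.random.Generator | None,
    exhaustive: bool,
) -> tuple[np.ndarray, bool]:
    """Index array mapping condensed positions under label permutations."""
    pim = _pair_index_matrix(n)
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    else:
        assert rng is not None
        perms = np.array([rng.permutation(n) for _ in range(n_permutations)], dtype=np.intp)
    iu, ju = np.triu_indices(n, k=1)
    return pim[perms[:, iu], perms[:, ju]], exhaustive


def mantel_test(
    x: DistanceMatrix,
    y: DistanceMatrix,
    n_permutations: int = 10_000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> MantelResult:
    """Simple Mantel test between two labelled distance matrices.

    r is the Pearson correlation of the lower-triangle vectors; the null
    relabels one matrix's rows and columns jointly. Two-sided
    P = (#{|r_perm| >= |r_obs|} + 1)/(n_permutations + 1), or the exact
    fraction over all n! relabelings when ``exhaustive`` (automatic for
    n <= 7).
    """
    xv, cols = _aligned_condensed(x, {"y": y})
    yv = cols["y"]
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r_obs = float(np.corrcoef(xv, yv)[0, 1])
    n = x.n
    if exhaustive is None:
        exhaustive = n <= _EXHAUSTIVE_MAX and math.factorial(n) <= n_permutations
    rng = None if exhaustive else np.random.default_rng(seed)
    idx, _ = _pair_permutations(n, n_permutations, rng, exhaustive)
    yp = yv[idx]  # (n_perm, n_pairs)
    yp_c = yp - yp.mean(axis=1, keepdims=True)
    xv_c = xv - xv.mean()
    r_perm = (yp_c @ xv_c) / (
        np.sqrt((yp_c**2).sum(axis=1)) * np.sqrt((xv_c**2).sum())
    )
    exceed = int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
    if exhaustive:
        p = exceed / len(idx)
    else:
        p = (exceed + 1) / (len(idx) + 1)
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=len(idx), exhaustive=exhaustive, seed=seed)


class MMRR:
    """Multiple matrix regression with randomization.

    Parameters
    ----------
    response : DistanceMatrix
        Dependent distance matrix (e.g. morph-frequency distance).
    predictors : mapping of name -> DistanceMatrix
        One or more predictor matrices sharing the response's labels.

    All lower-triangle vectors are z-scored before fitting, so slopes are
    standardized; R-squared and t statistics are unaffected by this choice.
    """

    def __init__(self, response: DistanceMatrix, predictors: Mapping[str, DistanceMatrix]):
        if not predictors:
            raise ValueError("need at least one predictor matrix")
        self.response = response
        self.predictor_names = tuple(predictors)
        yv, cols = _aligned_condensed(response, predictors)
        if yv.std() == 0:
            raise ValueError("constant response matrix")
        for name, v in cols.items():
            if v.std() == 0:
                raise ValueError(f"constant predictor matrix {name!r}")
        self._y = (yv - yv.mean()) / yv.std()
        self._xcols = {n: (v - v.mean()) / v.std() for n, v in cols.items()}
        corr = np.corrcoef(np.array(list(self._xcols.values())))
        names = self.predictor_names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(corr[i, j]) > 1 - 1e-10:
                    raise ValueError(
                        f"predictors {names[i]!r} and {names[j]!r} are collinear"
                    )

    def fit(
        self,
        n_permutations: int = 10_000,
        seed: int | None = None,
        exhaustive: bool | None = None,
    ) -> "MMRRResults":
        """OLS fit with permutation P values for each slope.

        The null permutes the response matrix's population labels, refits,
        and records each |t|; P_j is the exceedance fraction (with the +1
        correction for sampled permutations, exact for exhaustive ones).
        ``n_permutations=0`` skips the permutation test (P values NaN).
        """
        y = self._y
        x = np.column_stack([np.ones_like(y)] + [self._xcols[n] for n in self.predictor_names])
        n_pairs, ncol = x.shape
        p = ncol - 1
        dof = n_pairs - ncol
        if dof <= 0:
            raise ValueError("more parameters than pairwise observations")
        xtx_inv = np.linalg.inv(x.T @ x)
        pinv = xtx_inv @ x.T
        beta = pinv @ y
        resid = y - x @ beta
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss
        sigma2 = rss / dof
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.sign(beta) * np.inf)
        # partial correlations from t: r = sign(t) * sqrt(t^2/(t^2+dof))
        with np.errstate(invalid="ignore"):
            r_partial = np.where(
                np.isinf(tvals[1:]),
                np.sign(tvals[1:]),
                np.sign(tvals[1:]) * np.sqrt(tvals[1:] ** 2 / (tvals[1:] ** 2 + dof)),
            )
        pvals = np.full(p, np.nan)
        used = 0
        exh = False
        if n_permutations > 0:
            n = self.response.n
            if exhaustive is None:
                exhaustive = n <= _EXHAUSTIVE_MAX and math.factorial(n) <= n_permutations
            exh = exhaustive
            rng = None if exhaustive else np.random.default_rng(seed)
            idx, _ = _pair_permutations(n, n_permutations, rng, exhaustive)
            yp = y[idx].T  # (n_pairs, n_perm)
            betas = pinv @ yp
            resid_p = yp - x @ betas
            sig2 = (resid_p**2).sum(axis=0) / dof
            se_p = np.sqrt(np.outer(np.diag(xtx_inv), sig2))
            with np.errstate(divide="ignore", invalid="ignore"):
                t_p = np.where(se_p > 0, betas / se_p, np.inf)
            used = yp.shape[1]
            for j in range(p):
                exceed = int((np.abs(t_p[j + 1]) >= abs(tvals[j + 1]) - 1e-12).sum())
                pvals[j] = exceed / used if exhaustive else (exceed + 1) / (used + 1)
        return MMRRResults(
            model=self,
            params=pd.Series(beta[1:], index=self.predictor_names),
            intercept=float(beta[0]),
            bse=pd.Series(se[1:], index=self.predictor_names),
            tvalues=pd.Series(tvals[1:], index=self.predictor_names),
            r_partial=pd.Series(r_partial, index=self.predictor_names),
            pvalues=pd.Series(pvals, index=self.predictor_names),
            rsquared=float(r2),
            n_pairs=int(n_pairs),
            df_resid=int(dof),
            n_permutations=int(used),
            exhaustive=bool(exh),
            seed=seed,
        )


@dataclass(frozen=True)
class MMRRResults:
    """Estimates, permutation inference and diagnostics for one MMRR fit."""

    model: MMRR
    params: pd.Series  # standardized slopes
    intercept: float
    bse: pd.Series
    tvalues: pd.Series
    r_partial: pd.Series
    pvalues: pd.Series  # permutation P per slope
    rsquared: float
    n_pairs: int
    df_resid: int
    n_permutations: int
    exhaustive: bool
    seed: int | None

    @property
    def k(self) -> int:
        """Parameter count used by AICc: predictors + intercept."""
        return len(self.params) + 1

    @property
    def aicc(self) -> float:
        return aicc_from_fit(self.n_pairs, self.k, self.rsquared)

    def summary(self) -> str:
        lines = [
            "Multiple matrix regression (permutation inference)",
            "=" * 58,
            f"n pairs: {self.n_pairs}    R-squared: {self.rsquared:.4f}"
            f"    AICc: {self.aicc:.2f}",
            f"permutations: {self.n_permutations}"
            + (" (exhaustive)" if self.exhaustive else ""),
            "-" * 58,
            f"{'predictor':<16}{'std. slope':>12}{'r_partial':>12}{'perm P':>10}",
        ]
        for name in self.params.index:
            pv = self.pvalues[name]
            lines.append(
                f"{name:<16}{self.params[name]:>12.4f}{self.r_partial[name]:>12.4f}"
                + (f"{pv:>10.4f}" if np.isfinite(pv) else f"{'--':>10}")
            )
        lines.append("=" * 58)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# AICc model selection
# ---------------------------------------------------------------------------


def aicc_from_fit(n_pairs: int, k: int, r_squared: float) -> float:
    """Small-sample AICc from a model's R-squared.

    AICc = n ln(1 - R^2) + 2k + 2k(k+1)/(n - k - 1) with n the number of
    pairwise distances and k the parameter count (predictors + intercept).
    The additive constant n ln(TSS/n) is dropped; it cancels in delta-AICc
    and in Akaike weights.
    """
    if not 0 <= r_squared < 1:
        raise ValueError("R-squared must lie in [0, 1) for a finite AICc")
    if n_pairs <= k + 1:
        raise ValueError("AICc requires n_pairs > k + 1")
    n = float(n_pairs)
    return n * math.log(1.0 - r_squared) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(delta_aicc: Sequence[float]) -> np.ndarray:
    """Normalized Akaike weights exp(-delta/2) / sum."""
    d = np.asarray(delta_aicc, dtype=float)
    if d.size == 0:
        raise ValueError("empty delta-AICc list")
    if abs(d.min()) > 1e-6:
        raise ValueError("delta-AICc list must contain 0 for the best model")
    w = np.exp(-d / 2.0)
    return w / w.sum()


@dataclass(frozen=True)
class ModelSelectionTable:
    """All-subsets MMRR model selection results.

    ``table`` has one row per enumerated model sorted by AICc, with the
    delta-AICc, the weight renormalized over the retained (delta <= window)
    subset (NaN outside it), and a retained flag. ``riv`` sums retained
    weights per variable. ``fits`` maps predictor tuples to MMRRResults
    (permutation P values computed for retained models).
    """

    table: pd.DataFrame
    riv: pd.Series
    fits: dict[tuple[str, ...], MMRRResults] = field(repr=False, default_factory=dict)
    delta_window: float = 5.0

    @property
    def best(self) -> tuple[str, ...]:
        return tuple(self.table.iloc[0]["predictors"])

    @property
    def best_fit(self) -> MMRRResults:
        return self.fits[self.best]

    def summary(self) -> str:
        lines = [
            "AICc model selection over predictor subsets",
            "=" * 70,
            f"{'model':<38}{'k':>3}{'R2':>8}{'dAICc':>8}{'weight':>9}",
        ]
        for _, row in self.table[self.table["retained"]].iterrows():
            name = "+".join(row["predictors"])
            lines.append(
                f"{name:<38}{row['k']:>3d}{row['r_squared']:>8.4f}"
                f"{row['delta_aicc']:>8.2f}{row['weight']:>9.3f}"
            )
        lines.append("-" * 70)
        lines.append("relative importance of variables (RIV):")
        for name, v in self.riv.sort_values(ascending=False).items():
            lines.append(f"  {name:<20}{v:.3f}")
        lines.append("=" * 70)
        return "\n".join(lines)


def enumerate_subsets(
    pool: Sequence[str], exclusion_pairs: Sequence[tuple[str, str]] = ()
) -> list[tuple[str, ...]]:
    """All non-empty predictor subsets not containing an excluded pair."""
    pool = list(pool)
    for a, b in exclusion_pairs:
        for v in (a, b):
            if v not in pool:
                raise ValueError(f"exclusion pair references unknown variable {v!r}")
    subsets = []
    for r in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, r):
            s = set(combo)
            if any({a, b} <= s for a, b in exclusion_pairs):
                continue
            subsets.append(combo)
    return subsets


def model_selection(
    response: DistanceMatrix,
    predictor_pool: Mapping[str, DistanceMatrix],
    exclusion_pairs: Sequence[tuple[str, str]] = (),
    delta_window: float = 5.0,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> ModelSelectionTable:
    """Enumerate, fit and rank all admissible predictor subsets.

    Every non-empty subset of the pool that does not contain a declared
    exclusion pair is fitted by MMRR; models are ranked by AICc (ties
    broken toward the lexicographically smallest predictor set), the
    subset within ``delta_window`` of the best is retained, weights are
    renormalized over it, and RIV(v) sums retained weights of models
    containing v. Permutation P values are computed for retained models
    only; the enumeration itself needs only R-squared.
    """
    subsets = enumerate_subsets(list(predictor_pool), exclusion_pairs)
    rows = []
    models: dict[tuple[str, ...], MMRR] = {}
    for combo in subsets:
        m = MMRR(response, {name: predictor_pool[name] for name in combo})
        fit = m.fit(n_permutations=0)
        models[combo] = m
        rows.append(
            {
                "predictors": combo,
                "k": fit.k,
                "r_squared": fit.rsquared,
                "aicc": fit.aicc,
            }
        )
    df = pd.DataFrame(rows)
    # sort by AICc; ties (within float comparison) fall back to the
    # lexicographically smallest predictor set via a stable pre-sort
    df["_order"] = df["predictors"].map(lambda t: (len(t), t))
    df = (
        df.sort_values("_order")
        .sort_values("aicc", kind="stable")
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    df["retained"] = df["delta_aicc"] <= delta_window + 1e-12
    w = np.exp(-df.loc[df["retained"], "delta_aicc"] / 2.0)
    df["weight"] = np.nan
    df.loc[df["retained"], "weight"] = w / w.sum()
    riv = pd.Series(0.0, index=list(predictor_pool))
    for _, row in df[df["retained"]].iterrows():
        for name in row["predictors"]:
            riv[name] += row["weight"]
    fits: dict[tuple[str, ...], MMRRResults] = {}
    for combo in df.loc[df["retained"], "predictors"]:
        fits[combo] = models[combo].fit(n_permutations=n_permutations, seed=seed)
    return ModelSelectionTable(table=df, riv=riv, fits=fits, delta_window=delta_window)
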