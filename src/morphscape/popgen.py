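"""Population-genetic structure statistics for microsatellite panels.

Implements the Weir & Cockerham (1984) theta estimator of F_ST with a
between-population individual-permutation significance test, per-locus
heterozygosity summaries with a Monte-Carlo Hardy-Weinberg exact test,
Evanno's delta-K post-processing of external clustering log-likelihoods,
and the orchestration helper that splits a panel by inferred clusters for
hierarchical re-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel, LikelihoodSeries


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    population: str
    allele_frequencies: dict[int, float]
    h_obs: float
    h_exp: float
    hwe_p: float
    n_genotyped: int
    monomorphic: bool


@dataclass(frozen=True)
class FstResult:
    pop_a: str
    pop_b: str
    theta: float
    per_locus_theta: dict[str, float]
    p_value: float
    significant_bonferroni: bool
    n_permutations: int


@dataclass(frozen=True)
class DeltaKResult:
    table: pd.DataFrame  # K, mean_l, sd_l, delta_k (NaN at endpoints / sd==0)
    best_k: int


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------


def _locus_components(genos: np.ndarray, pops: np.ndarray) -> tuple[float, float]:
    """Sum of a and of (a+b+c) over alleles for one locus.

    ``genos``: (N, 2) allele codes, 0 = missing; ``pops``: (N,) integer
    population index. Populations with <1 genotyped individual at this
    locus are dropped; a locus informative in <2 populations contributes
    (0, 0).
    """
    called = (genos != MISSING).all(axis=1)
    genos = genos[called]
    pops = pops[called]
    labels = np.unique(pops)
    if labels.size < 2:
        return 0.0, 0.0
    alleles = np.unique(genos)
    r = labels.size
    n_i = np.array([(pops == l).sum() for l in labels], dtype=float)
    n_bar = n_i.mean()
    if n_bar <= 1:
        return 0.0, 0.0
    n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
    if n_c <= 0:
        return 0.0, 0.0
    het = genos[:, 0] != genos[:, 1]
    # per-population allele-copy counts and heterozygote-carrier counts,
    # vectorized over alleles
    copies = (genos[:, :, None] == alleles[None, None, :]).sum(axis=1)  # (N, K)
    p_i = np.empty((r, alleles.size))
    h_i = np.empty((r, alleles.size))
    for k, l in enumerate(labels):
        sel = pops == l
        p_i[k] = copies[sel].sum(axis=0) / (2 * n_i[k])
        h_i[k] = ((copies[sel] == 1) & het[sel, None]).sum(axis=0) / n_i[k]
    w = n_i[:, None]
    p_bar = (w * p_i).sum(axis=0) / (r * n_bar)
    s2 = (w * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (w * h_i).sum(axis=0) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return float(a.sum()), float((a + b + c).sum())


def weir_cockerham_theta(panel: GenotypePanel) -> tuple[float, dict[str, float]]:
    """Multilocus Weir-Cockerham theta and per-locus components.

    The multilocus estimate combines loci by ratio of sums of the variance
    components (not a mean of per-locus ratios). Negative estimates are
    preserved. Returns NaN when no locus is informative.
    """
    pop_order = panel.population_order
    pop_idx = np.array([pop_order.index(p) for p in panel.populations])
    a_total = 0.0
    abc_total = 0.0
    per_locus: dict[str, float] = {}
    for j, locus in enumerate(panel.loci):
        a, abc = _locus_components(panel.genotypes[:, j, :], pop_idx)
        per_locus[locus] = a / abc if abc > 0 else float("nan")
        a_total += a
        abc_total += abc
    theta = a_total / abc_total if abc_total > 0 else float("nan")
    return theta, per_locus


def _pair_theta(genos: np.ndarray, pop_idx: np.ndarray) -> float:
    a_total = 0.0
    abc_total = 0.0
    for j in range(genos.shape[1]):
        a, abc = _locus_components(genos[:, j, :], pop_idx)
        a_total += a
        abc_total += abc
    return a_total / abc_total if abc_total > 0 else float("nan")


def _pair_theta_batch(genos: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Two-population multilocus theta for a batch of label assignments.

    ``genos``: (N, L, 2) allele codes with 0 = missing; ``z``: boolean
    (n_batch, N), True = individual assigned to population A. Vectorized
    over assignments via matrix products so permutation tests stay cheap.
    """
    n_batch = z.shape[0]
    zf = z.astype(float)
    a_tot = np.zeros(n_batch)
    abc_tot = np.zeros(n_batch)
    for j in range(genos.shape[1]):
        g = genos[:, j, :]
        called = (g != MISSING).all(axis=1).astype(float)
        alleles = np.unique(g[g != MISSING])
        if alleles.size == 0:
            continue
        copies = (g[:, :, None] == alleles[None, None, :]).sum(axis=1).astype(float)
        het = (g[:, 0] != g[:, 1]).astype(float)
        carriers = (copies == 1) * het[:, None]  # (N, K)
        n0 = zf @ called
        n1 = called.sum() - n0
        ok = (n0 >= 1) & (n1 >= 1)
        n0s = np.where(ok, n0, 1.0)
        n1s = np.where(ok, n1, 1.0)
        c0 = zf @ copies
        c1 = copies.sum(axis=0) - c0
        h0 = zf @ carriers
        h1 = carriers.sum(axis=0) - h0
        p0 = c0 / (2 * n0s[:, None])
        p1 = c1 / (2 * n1s[:, None])
        f0 = h0 / n0s[:, None]
        f1 = h1 / n1s[:, None]
        r = 2.0
        n_bar = (n0s + n1s) / r
        n_c = (r * n_bar - (n0s**2 + n1s**2) / (r * n_bar)) / (r - 1)
        ok2 = ok & (n_bar > 1) & (n_c > 0)
        nb = np.where(ok2, n_bar, 2.0)[:, None]
        nc = np.where(ok2, n_c, 1.0)[:, None]
        w0 = n0s[:, None]
        w1 = n1s[:, None]
        p_bar = (w0 * p0 + w1 * p1) / (r * nb)
        s2 = (w0 * (p0 - p_bar) ** 2 + w1 * (p1 - p_bar) ** 2) / ((r - 1) * nb)
        h_bar = (w0 * f0 + w1 * f1) / (r * nb)
        a = (nb / nc) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (nb - 1)
        )
        b = (nb / (nb - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * nb - 1) / (4 * nb) * h_bar
        )
        c = h_bar / 2
        contrib_ok = ok2[:, None]
        a_tot += np.where(contrib_ok, a, 0.0).sum(axis=1)
        abc_tot += np.where(contrib_ok, a + b + c, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(abc_tot > 0, a_tot / abc_tot, np.nan)
    return theta


def pairwise_fst(
    panel: GenotypePanel,
    n_permutations: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> list[FstResult]:
    """Pairwise multilocus theta with permutation P values.

    The null distribution shuffles whole individuals (genotypes intact)
    between the two populations of a pair; P = (#{theta_perm >= theta_obs}
    + 1)/(n_permutations + 1). Significance flags apply a Bonferroni
    threshold alpha / n_pairs.
    """
    pops = panel.population_order
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    sizes = {p: sum(q == p for q in panel.populations) for p in pops}
    small = [p for p, n in sizes.items() if n < 2]
    if small:
        raise ValueError(f"populations with <2 individuals: {small}")
    n_pairs = len(pops) * (len(pops) - 1) // 2
    rng = np.random.default_rng(seed)
    results = []
    for pa, pb in combinations(pops, 2):
        mask = np.array([p in (pa, pb) for p in panel.populations])
        genos = panel.genotypes[mask]
        labels = np.array([0 if p == pa else 1 for p in np.array(panel.populations)[mask]])
        theta_obs = _pair_theta(genos, labels)
        sub = panel.subset([pa, pb])
        _, per_locus = weir_cockerham_theta(sub)
        perms = np.array([rng.permutation(labels) for _ in range(n_permutations)])
        theta_perm = _pair_theta_batch(genos, perms == 0)
        exceed = int(np.nansum(theta_perm >= theta_obs - 1e-15))
        p = (exceed + 1) / (n_permutations + 1)
        results.append(
            FstResult(
                pop_a=pa,
                pop_b=pb,
                theta=float(theta_obs),
                per_locus_theta=per_locus,
                p_value=float(p),
                significant_bonferroni=bool(p < alpha / n_pairs),
                n_permutations=n_permutations,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Heterozygosity and Hardy-Weinberg
# ---------------------------------------------------------------------------


def _hwe_monte_carlo(genos: np.ndarray, n_shuffles: int, rng: np.random.Generator) -> float:
    """Two-sided Monte-Carlo HWE exact test on one population-locus cell.

    Statistic is the heterozygote count; the null re-pairs the observed
    alleles at random. Two-sided P doubles the smaller tail (capped at 1),
    with the +1 permutation correction on each tail.
    """
    obs_het = int((genos[:, 0] != genos[:, 1]).sum())
    alleles = genos.ravel().copy()
    n = len(genos)
    le = ge = 0
    for _ in range(n_shuffles):
        rng.shuffle(alleles)
        pairs = alleles.reshape(n, 2)
        het = int((pairs[:, 0] != pairs[:, 1]).sum())
        le += het <= obs_het
        ge += het >= obs_het
    p_le = (le + 1) / (n_shuffles + 1)
    p_ge = (ge + 1) / (n_shuffles + 1)
    return min(1.0, 2 * min(p_le, p_ge))


def locus_summaries(
    panel: GenotypePanel,
    n_shuffles: int = 10_000,
    seed: int | None = None,
) -> list[LocusSummary]:
    """Per population-locus allele frequencies, H_obs, unbiased H_exp and HWE P.

    H_exp uses the small-sample correction (2n/(2n-1)) * (1 - sum p_i^2).
    Monomorphic cells report HWE P = 1 with a flag.
    """
    rng = np.random.default_rng(seed)
    out = []
    for j, locus in enumerate(panel.loci):
        for pop in panel.population_order:
            genos = panel.population_genotypes(pop, j)
            n = len(genos)
            if n < 2:
                raise ValueError(f"{pop}/{locus}: need >=2 genotyped individuals")
            alleles, counts = np.unique(genos.ravel(), return_counts=True)
            freqs = counts / counts.sum()
            h_obs = float((genos[:, 0] != genos[:, 1]).mean())
            h_exp = float(2 * n / (2 * n - 1) * (1 - (freqs**2).sum()))
            mono = alleles.size == 1
            p = 1.0 if mono else _hwe_monte_carlo(genos, n_shuffles, rng)
            out.append(
                LocusSummary(
                    locus=locus,
                    population=pop,
                    allele_frequencies={int(a): float(f) for a, f in zip(alleles, freqs)},
                    h_obs=h_obs,
                    h_exp=h_exp,
                    hwe_p=float(p),
                    n_genotyped=n,
                    monomorphic=bool(mono),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------


def evanno_delta_k(series: LikelihoodSeries) -> DeltaKResult:
    """Second-difference-over-sd statistic on clustering log-likelihoods.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K),
    undefined (NaN) at the endpoints and where the replicate sd is zero.
    The reported best K maximises delta-K over the defined interior.
    """
    ks = series.k_values
    if len(ks) < 3:
        raise ValueError("delta-K needs at least three consecutive K values")
    mean_l = np.array([series.replicates[k].mean() for k in ks])
    sd_l = np.array([series.replicates[k].std(ddof=1) for k in ks])
    delta = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        if sd_l[i] > 0:
            delta[i] = abs(mean_l[i + 1] - 2 * mean_l[i] + mean_l[i - 1]) / sd_l[i]
    table = pd.DataFrame({"K": ks, "mean_l": mean_l, "sd_l": sd_l, "delta_k": delta})
    if np.isnan(delta).all():
        raise ValueError("delta-K undefined everywhere (zero replicate sd)")
    best = ks[int(np.nanargmax(delta))]
    return DeltaKResult(table=table, best_k=best)


# ---------------------------------------------------------------------------
# Hierarchical re-analysis orchestration
# ---------------------------------------------------------------------------


def hierarchical_cluster_plan(
    panel: GenotypePanel, assignments: dict[str, object]
) -> list[GenotypePanel]:
    """Split a panel into sub-panels for per-cluster re-analysis.

    ``assignments`` maps each individual id (or each population label) to a
    cluster label, as produced by an external clustering program. The split
    is disjoint and exhaustive; with a single cluster the original panel is
    returned unchanged. No clustering is performed here.
    """
    if set(assignments) == set(panel.population_order):
        labels = [assignments[p] for p in panel.populations]
    elif set(assignments) >= set(panel.individual_ids):
        labels = [assignments[i] for i in panel.individual_ids]
    else:
        missing = set(panel.individual_ids) - set(assignments)
        raise ValueError(f"assignments do not cover all individuals: {sorted(missing)[:5]}")
    clusters = list(dict.fromkeys(labels))
    if len(clusters) == 1:
        return [panel]
    out = []
    for c in clusters:
        keep = [i for i, l in enumerate(labels) if l == c]
        out.append(
            GenotypePanel(
                tuple(panel.individual_ids[i] for i in keep),
                tuple(panel.populations[i] for i in keep),
                panel.loci,
                panel.genotypes[keep],
            )
        )
    return out
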