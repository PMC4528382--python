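"""Population-structure statistics against independent oracles."""

import numpy as np
import pytest

from morphscape.io import GenotypePanel, LikelihoodSeries
from morphscape.popgen import (
    evanno_delta_k,
    hierarchical_cluster_plan,
    locus_summaries,
    pairwise_fst,
    weir_cockerham_theta,
)


def wc_theta_oracle(genotype_lists):
    """Naive Weir-Cockerham (1984) theta, written directly from the
    variance-component definitions with explicit loops.

    ``genotype_lists``: per locus, a list over populations of lists of
    (allele, allele) tuples (missing genotypes omitted). Returns the
    multilocus ratio-of-sums estimate.
    """
    a_total = abc_total = 0.0
    for locus in genotype_lists:
        pops = [p for p in locus if len(p) >= 1]
        if len(pops) < 2:
            continue
        r = len(pops)
        n = [len(p) for p in pops]
        n_bar = sum(n) / r
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - sum(ni**2 for ni in n) / (r * n_bar)) / (r - 1)
        if n_c <= 0:
            continue
        alleles = sorted({a for p in pops for g in p for a in g})
        for u in alleles:
            p_i = [sum(g.count(u) for g in p) / (2 * ni) for p, ni in zip(pops, n)]
            h_i = [
                sum(1 for g in p if g[0] != g[1] and u in g) / ni
                for p, ni in zip(pops, n)
            ]
            p_bar = sum(ni * pi for ni, pi in zip(n, p_i)) / (r * n_bar)
            s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p_i)) / ((r - 1) * n_bar)
            h_bar = sum(ni * hi for ni, hi in zip(n, h_i)) / (r * n_bar)
            a = (n_bar / n_c) * (
                s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            a_total += a
            abc_total += a + b + c
    return a_total / abc_total if abc_total else float("nan")


def panel_to_lists(panel):
    out = []
    for j in range(len(panel.loci)):
        locus = []
        for pop in panel.population_order:
            g = panel.population_genotypes(pop, j)
            locus.append([tuple(row) for row in g])
        out.append(locus)
    return out


def random_panel(rng, n_pops, n_ind, n_loci, n_alleles, missing_rate=0.0):
    genos = rng.integers(1, n_alleles + 1, size=(n_pops * n_ind, n_loci, 2))
    if missing_rate:
        drop = rng.random((n_pops * n_ind, n_loci)) < missing_rate
        genos[drop] = 0
    ids = tuple(f"p{i}_{k}" for i in range(n_pops) for k in range(n_ind))
    pops = tuple(f"p{i}" for i in range(n_pops) for _ in range(n_ind))
    return GenotypePanel(ids, pops, tuple(f"l{j}" for j in range(n_loci)), genos)


class TestWeirCockerham:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle_on_small_panels(self, seed):
        rng = np.random.default_rng(seed)
        n_pops = int(rng.integers(2, 4))
        panel = random_panel(
            rng,
            n_pops=n_pops,
            n_ind=int(rng.integers(3, 7)),
            n_loci=int(rng.integers(1, 3)),
            n_alleles=int(rng.integers(2, 4)),
            missing_rate=0.1 if seed % 2 else 0.0,
        )
        theta, _ = weir_cockerham_theta(panel)
        oracle = wc_theta_oracle(panel_to_lists(panel))
        assert theta == pytest.approx(oracle, abs=1e-10)

    def test_tiny_panel_matches_oracle(self, tiny_panel):
        theta, _ = weir_cockerham_theta(tiny_panel)
        assert theta == pytest.approx(wc_theta_oracle(panel_to_lists(tiny_panel)), abs=1e-10)

    def test_fixed_differences_give_theta_one(self):
        genos = np.zeros((8, 2, 2), dtype=int)
        genos[:4] = 1
        genos[4:] = 2
        panel = GenotypePanel(
            tuple(f"a_{i}" for i in range(4)) + tuple(f"b_{i}" for i in range(4)),
            ("a",) * 4 + ("b",) * 4,
            ("l1", "l2"),
            genos,
        )
        theta, per_locus = weir_cockerham_theta(panel)
        assert theta == pytest.approx(1.0, abs=1e-12)
        assert all(v == pytest.approx(1.0) for v in per_locus.values())

    def test_copied_populations_near_zero_with_large_p(self):
        rng = np.random.default_rng(3)
        half = rng.integers(1, 5, size=(12, 3, 2))
        genos = np.vstack([half, half])
        panel = GenotypePanel(
            tuple(f"a_{i}" for i in range(12)) + tuple(f"b_{i}" for i in range(12)),
            ("a",) * 12 + ("b",) * 12,
            ("l1", "l2", "l3"),
            genos,
        )
        res = pairwise_fst(panel, n_permutations=499, seed=0)[0]
        assert res.theta <= 0.01  # identical populations: estimator noise only
        assert res.p_value > 0.3

    def test_too_small_population_rejected(self):
        genos = np.ones((3, 1, 2), dtype=int)
        panel = GenotypePanel(("a_1", "a_2", "b_1"), ("a", "a", "b"), ("l1",), genos)
        with pytest.raises(ValueError, match="<2 individuals"):
            pairwise_fst(panel, n_permutations=10)


class TestLocusSummaries:
    def test_heterozygosity_hand_example(self):
        # one population: AA, AB, AB, BB -> H_obs = 0.5, H_exp = (8/7)(1-0.5)
        genos = np.array([[[1, 1]], [[1, 2]], [[1, 2]], [[2, 2]]])
        panel = GenotypePanel(
            ("p_1", "p_2", "p_3", "p_4"), ("p",) * 4, ("l1",), genos
        )
        s = locus_summaries(panel, n_shuffles=200, seed=0)[0]
        assert s.h_obs == pytest.approx(0.5)
        assert s.h_exp == pytest.approx(8 / 7 * 0.5)
        assert s.allele_frequencies == {1: 0.5, 2: 0.5}

    def test_monomorphic_locus_flagged(self):
        genos = np.full((4, 1, 2), 7)
        panel = GenotypePanel(("p_1", "p_2", "p_3", "p_4"), ("p",) * 4, ("l1",), genos)
        s = locus_summaries(panel, n_shuffles=10, seed=0)[0]
        assert s.monomorphic
        assert s.h_obs == 0.0
        assert s.h_exp == 0.0
        assert s.hwe_p == 1.0


class TestEvannoDeltaK:
    @staticmethod
    def series_with_exact_moments(means, sd=1.0):
        """Two replicates per K give the exact mean and sd requested."""
        d = sd / np.sqrt(2)
        return LikelihoodSeries(
            {k + 1: np.array([m - d, m + d]) for k, m in enumerate(means)}
        )

    def test_linear_likelihood_gives_zero(self):
        s = self.series_with_exact_moments([-100, -80, -60, -40])
        res = evanno_delta_k(s)
        inner = res.table["delta_k"].iloc[1:-1]
        np.testing.assert_allclose(inner, 0.0, atol=1e-9)

    def test_worked_example(self):
        s = self.series_with_exact_moments([-100, -50, -49, -48])
        res = evanno_delta_k(s)
        # |L(3) - 2 L(2) + L(1)| / sd = |-49 + 100 - 100| / 1 = 49
        assert res.table.set_index("K").loc[2, "delta_k"] == pytest.approx(49.0)
        assert res.best_k == 2

    def test_sd_scaling_halves_delta(self):
        s1 = self.series_with_exact_moments([-100, -50, -49, -48], sd=1.0)
        s2 = self.series_with_exact_moments([-100, -50, -49, -48], sd=2.0)
        d1 = evanno_delta_k(s1).table["delta_k"].iloc[1]
        d2 = evanno_delta_k(s2).table["delta_k"].iloc[1]
        assert d2 == pytest.approx(d1 / 2)

    def test_constant_shift_invariance(self):
        means = [-100.0, -50, -49, -48]
        d1 = evanno_delta_k(self.series_with_exact_moments(means)).table["delta_k"]
        shifted = [m + 12345.0 for m in means]
        d2 = evanno_delta_k(self.series_with_exact_moments(shifted)).table["delta_k"]
        np.testing.assert_allclose(d1, d2, equal_nan=True)

    def test_zero_sd_flagged_undefined(self):
        s = LikelihoodSeries(
            {
                1: np.array([-100.0, -99.0]),
                2: np.array([-50.0, -50.0]),  # sd 0
                3: np.array([-49.0, -48.0]),
                4: np.array([-48.0, -47.0]),
            }
        )
        res = evanno_delta_k(s)
        assert np.isnan(res.table.set_index("K").loc[2, "delta_k"])


class TestHierarchicalPlan:
    def test_single_cluster_returns_input(self, tiny_panel):
        plan = hierarchical_cluster_plan(tiny_panel, {"popA": 1, "popB": 1})
        assert plan == [tiny_panel]

    def test_population_level_split(self, tiny_panel):
        plan = hierarchical_cluster_plan(tiny_panel, {"popA": "c1", "popB": "c2"})
        assert len(plan) == 2
        assert plan[0].population_order == ["popA"]
        assert plan[1].population_order == ["popB"]

    def test_split_is_disjoint_and_exhaustive(self, tiny_panel):
        assignments = {i: (0 if k % 2 else 1) for k, i in enumerate(tiny_panel.individual_ids)}
        plan = hierarchical_cluster_plan(tiny_panel, assignments)
        ids = [i for sub in plan for i in sub.individual_ids]
        assert sorted(ids) == sorted(tiny_panel.individual_ids)
        assert len(set(ids)) == len(ids)

    def test_incomplete_assignments_rejected(self, tiny_panel):
        with pytest.raises(ValueError, match="cover"):
            hierarchical_cluster_plan(tiny_panel, {"popA_1": 0})
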