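"""Mantel/MMRR permutation inference and AICc multimodel selection."""

import itertools

import numpy as np
import pytest

from morphscape.io import DistanceMatrix
from morphscape.mmrr import (
    MMRR,
    aicc_from_fit,
    akaike_weights,
    enumerate_subsets,
    mantel_test,
    model_selection,
)

LABELS4 = ("A", "B", "C", "D")


def dm(values, labels=LABELS4):
    v = np.asarray(values, dtype=float)
    return DistanceMatrix(tuple(labels), (v + v.T) / 2)


def random_dm(rng, labels=LABELS4):
    n = len(labels)
    v = rng.random((n, n))
    v = v + v.T
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(tuple(labels), v)


def mantel_oracle(x, y):
    """Exact two-sided Mantel P by direct enumeration of all relabelings."""
    n = x.n
    iu = np.triu_indices(n, 1)
    xv = x.values[iu]
    r_obs = np.corrcoef(xv, y.values[iu])[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        yp = y.values[np.ix_(perm, perm)][iu]
        r = np.corrcoef(xv, yp)[0, 1]
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


def mmrr_oracle_pvalues(response, predictors):
    """Exact slope permutation P by enumerating relabelings, refitting OLS
    and comparing |t| statistics (naive lstsq route)."""
    n = response.n
    iu = np.triu_indices(n, 1)
    xcols = [p.values[iu] for p in predictors]
    x = np.column_stack([np.ones(len(iu[0]))] + [(c - c.mean()) / c.std() for c in xcols])

    def tstats(yv):
        yv = (yv - yv.mean()) / yv.std()
        beta, *_ = np.linalg.lstsq(x, yv, rcond=None)
        resid = yv - x @ beta
        dof = len(yv) - x.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(x.T @ x)
        return beta[1:] / np.sqrt(np.diag(cov)[1:])

    t_obs = tstats(response.values[iu])
    counts = np.zeros(len(t_obs))
    total = 0
    for perm in itertools.permutations(range(n)):
        yp = response.values[np.ix_(perm, perm)][iu]
        t = tstats(yp)
        counts += np.abs(t) >= np.abs(t_obs) - 1e-12
        total += 1
    return counts / total


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = random_dm(rng)
        res = mantel_test(x, x, n_permutations=100)
        assert res.r == pytest.approx(1.0)

    def test_negative_affine_gives_minus_one(self):
        rng = np.random.default_rng(1)
        x = random_dm(rng)
        y = DistanceMatrix(x.labels, np.where(np.eye(x.n, dtype=bool), 0.0, 5.0 - x.values))
        res = mantel_test(x, y, n_permutations=100)
        assert res.r == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_exhaustive_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = random_dm(rng), random_dm(rng)
        res = mantel_test(x, y, n_permutations=10_000)
        assert res.exhaustive
        assert res.p_value == pytest.approx(mantel_oracle(x, y), abs=1e-12)

    def test_constant_matrix_rejected(self):
        rng = np.random.default_rng(2)
        x = random_dm(rng)
        const = DistanceMatrix(LABELS4, np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError, match="constant"):
            mantel_test(x, const, n_permutations=10)


class TestMMRR:
    def test_exact_linear_single_predictor(self):
        rng = np.random.default_rng(3)
        x = random_dm(rng)
        y = DistanceMatrix(x.labels, x.values * 2.0)
        fit = MMRR(y, {"x": x}).fit(n_permutations=0)
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.r_partial["x"] == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(1.0)  # standardized slope

    def test_single_predictor_degenerates_to_mantel(self):
        rng = np.random.default_rng(4)
        x, y = random_dm(rng), random_dm(rng)
        m = mantel_test(y, x, n_permutations=10_000)
        fit = MMRR(y, {"x": x}).fit(n_permutations=10_000)
        iu = np.triu_indices(4, 1)
        r = np.corrcoef(y.values[iu], x.values[iu])[0, 1]
        assert abs(fit.r_partial["x"]) == pytest.approx(abs(r), abs=1e-12)
        assert abs(m.r) == pytest.approx(abs(r), abs=1e-12)
        # both exhaustive on 4 populations: identical achievable P grid
        assert fit.exhaustive and m.exhaustive
        assert fit.pvalues["x"] == pytest.approx(m.p_value, abs=1e-12)

    @pytest.mark.parametrize("n_predictors", [1, 2])
    def test_exhaustive_p_matches_enumeration_oracle(self, n_predictors):
        rng = np.random.default_rng(5)
        y = random_dm(rng)
        preds = {f"p{i}": random_dm(rng) for i in range(n_predictors)}
        fit = MMRR(y, preds).fit(n_permutations=10_000)
        assert fit.exhaustive
        oracle = mmrr_oracle_pvalues(y, list(preds.values()))
        for j, name in enumerate(preds):
            assert fit.pvalues[name] == pytest.approx(oracle[j], abs=1e-12)

    def test_five_population_exhaustive_oracle(self):
        labels = tuple("ABCDE")
        rng = np.random.default_rng(6)
        y = random_dm(rng, labels)
        preds = {"p0": random_dm(rng, labels), "p1": random_dm(rng, labels)}
        fit = MMRR(y, preds).fit(n_permutations=200_000)
        assert fit.exhaustive and fit.n_permutations == 120
        oracle = mmrr_oracle_pvalues(y, list(preds.values()))
        for j, name in enumerate(preds):
            assert fit.pvalues[name] == pytest.approx(oracle[j], abs=1e-12)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(7)
        x = random_dm(rng)
        x2 = DistanceMatrix(x.labels, x.values * 3.0)
        with pytest.raises(ValueError, match="collinear"):
            MMRR(random_dm(rng), {"a": x, "b": x2})

    def test_summary_mentions_predictors(self):
        rng = np.random.default_rng(8)
        fit = MMRR(random_dm(rng), {"geo": random_dm(rng)}).fit(n_permutations=100)
        text = fit.summary()
        assert "geo" in text and "R-squared" in text


class TestAicc:
    def test_depends_only_on_k_at_zero_r2(self):
        assert aicc_from_fit(28, 2, 0.0) == pytest.approx(2 * 2 + 12 / 25)
        assert aicc_from_fit(28, 3, 0.0) == pytest.approx(2 * 3 + 24 / 24)

    def test_delta_between_printed_model_pairs(self):
        # two-predictor best model vs the three-predictor runner-up at n=28
        d = aicc_from_fit(28, 4, 0.4651) - aicc_from_fit(28, 3, 0.4546)
        assert d == pytest.approx(2.19, abs=0.01)
        # vs the single-predictor aridity model
        d2 = aicc_from_fit(28, 2, 0.3226) - aicc_from_fit(28, 3, 0.4546)
        assert d2 == pytest.approx(3.55, abs=0.01)

    def test_r2_one_and_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc_from_fit(28, 3, 1.0)
        with pytest.raises(ValueError):
            aicc_from_fit(4, 3, 0.5)


class TestAkaikeWeights:
    def test_printed_delta_column_reproduces_weights(self):
        deltas = [0, 2.19, 2.23, 2.71, 3.55, 3.77, 4.66, 4.82]
        printed = [0.412, 0.137, 0.135, 0.106, 0.070, 0.062, 0.040, 0.037]
        w = akaike_weights(deltas)
        np.testing.assert_allclose(w, printed, atol=1e-3)

    def test_single_model_weight_one(self):
        assert akaike_weights([0.0])[0] == pytest.approx(1.0)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(9)
        d = np.sort(rng.uniform(0, 10, size=12))
        d[0] = 0.0
        assert akaike_weights(d).sum() == pytest.approx(1.0)

    def test_missing_zero_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([1.0, 2.0])


class TestModelSelection:
    def test_exclusion_pair_subset_count(self):
        pool = [f"v{i}" for i in range(6)]
        subsets = enumerate_subsets(pool, [("v0", "v1")])
        assert len(subsets) == 2**6 - 1 - 2**4  # 47

    def test_unknown_exclusion_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            enumerate_subsets(["a", "b"], [("a", "zzz")])

    def test_riv_is_one_for_always_present_variable(self):
        rng = np.random.default_rng(10)
        labels = tuple("ABCDEFGH")
        y = random_dm(rng, labels)
        sel = model_selection(y, {"only": random_dm(rng, labels)}, n_permutations=0)
        assert sel.riv["only"] == pytest.approx(1.0)

    def test_retained_weights_sum_to_one(self):
        rng = np.random.default_rng(11)
        labels = tuple("ABCDEFGH")
        y = random_dm(rng, labels)
        pool = {f"v{i}": random_dm(rng, labels) for i in range(4)}
        sel = model_selection(y, pool, n_permutations=0)
        retained = sel.table[sel.table["retained"]]
        assert retained["weight"].sum() == pytest.approx(1.0)
        assert retained["delta_aicc"].iloc[0] == pytest.approx(0.0)
        assert ((sel.riv >= 0) & (sel.riv <= 1 + 1e-12)).all()

    def test_delta_invariant_to_additive_constant(self):
        # adding back the dropped n ln(TSS/n) constant cannot change deltas
        deltas = [0, 2.19, 3.55]
        shifted = [d + 137.2 for d in deltas]
        w1 = akaike_weights(deltas)
        w2 = np.exp(-np.asarray(shifted) / 2)
        w2 /= w2.sum()
        np.testing.assert_allclose(w1, w2)

    def test_permutation_p_available_for_retained_models(self):
        rng = np.random.default_rng(12)
        labels = tuple("ABCDEF")
        y = random_dm(rng, labels)
        pool = {"a": random_dm(rng, labels), "b": random_dm(rng, labels)}
        sel = model_selection(y, pool, n_permutations=500, seed=1)
        fit = sel.best_fit
        assert np.isfinite(fit.pvalues).all()
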