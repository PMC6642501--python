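"""The interpretation engine: ascent, ensemble statistics, GMM, OFIV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import deepresolve.core as core
from deepresolve.core import (AscentConfig, CATEGORY_ADDITIVE,
                              CATEGORY_NONADD_CONSISTENT,
                              CATEGORY_NONADD_INCONSISTENT, FIVEnsemble)


def weighted_var_oracle(fivs, weights):
    """Brute-force double-loop weighted variance, per channel."""
    T, K = fivs.shape
    out = np.zeros(K)
    wsum = weights.sum()
    for k in range(K):
        mu = sum(weights[t] * fivs[t, k] for t in range(T)) / wsum
        out[k] = sum(weights[t] * (fivs[t, k] - mu) ** 2 for t in range(T)) / wsum
    return out


class TestLearningRate:
    def test_constant_before_decay(self):
        cfg = AscentConfig(lr0=0.1, start_decay=50)
        assert all(core.lr_at(s, cfg) == 0.1 for s in (0, 10, 50))

    def test_first_decay_step_equals_lr0(self):
        cfg = AscentConfig(lr0=0.1, start_decay=50, alpha=0.7, min_lr=0.01)
        assert core.lr_at(51, cfg) == pytest.approx(0.1)

    def test_floor_at_min_lr(self):
        cfg = AscentConfig(lr0=0.1, start_decay=0, alpha=0.5, min_lr=0.01)
        assert core.lr_at(10 ** 9, cfg) == pytest.approx(0.1 * 0.01)

    def test_decay_follows_power_law(self):
        cfg = AscentConfig(lr0=0.2, start_decay=10, alpha=0.5, min_lr=1e-6)
        assert core.lr_at(14, cfg) == pytest.approx(0.2 * 4 ** -0.5)


class TestAscent:
    def test_recovers_closed_form_optimum(self, linear_handle):
        """For a linear score the regularized optimum is w/(2*lambda)."""
        cfg = AscentConfig(lam=0.7, n_steps=300)
        fim = core.ascend(linear_handle, 1, cfg, seed=3)
        expected = linear_handle.weights[1] / (2 * 0.7)
        assert np.allclose(fim.values, expected, atol=1e-3)

    def test_large_lambda_shrinks_optimum(self, linear_handle):
        small = core.ascend(linear_handle, 0, AscentConfig(lam=0.5), seed=1)
        large = core.ascend(linear_handle, 0, AscentConfig(lam=50.0), seed=1)
        assert np.linalg.norm(large.values) < 0.05 * np.linalg.norm(small.values)

    def test_score_improves_on_trained_model(self, small_trained_model_i):
        handle = core.feature_space(small_trained_model_i)
        cfg = AscentConfig()
        rng = np.random.default_rng(4)
        H0 = rng.normal(0, cfg.init_std, size=(handle.K, handle.W))
        fim = core.ascend(handle, 0, cfg, seed=4)
        assert fim.final_score > handle.score(H0, 0)

    def test_class_out_of_range(self, linear_handle):
        with pytest.raises(ValueError, match="out of range"):
            core.ascend(linear_handle, 5, AscentConfig(), seed=0)


class TestFivAndWeights:
    def test_fiv_is_row_mean(self):
        rng = np.random.default_rng(0)
        fim = rng.normal(size=(3, 5))
        oracle = np.array([sum(fim[k]) / 5 for k in range(3)])
        assert np.allclose(core.fim_to_fiv(fim), oracle)

    def test_fiv_identity_at_w1(self):
        fim = np.array([[1.5], [-2.0]])
        assert np.array_equal(core.fim_to_fiv(fim), [1.5, -2.0])

    def test_cancellation(self):
        assert core.fim_to_fiv(np.array([[1.0, -1.0]]))[0] == 0.0

    @pytest.mark.parametrize("scores,expected", [
        ([2.0, 3.0], [1e-6, 1 + 1e-6]),
        ([-5.0, 0.0], [1e-6, 5 + 1e-6]),
        ([1.0, 1.0, 1.0], [1e-6] * 3),
    ])
    def test_trial_weights(self, scores, expected):
        w = core.trial_weights(np.array(scores))
        assert np.allclose(w, expected)
        assert np.all(w > 0)


class TestInconsistencyLevel:
    def test_identical_fivs_zero_variance(self):
        fivs = np.tile([1.0, -2.0, 0.5], (4, 1))
        ens = FIVEnsemble(fivs=fivs, scores=np.zeros(4), weights=np.ones(4))
        assert np.allclose(core.inconsistency_level(ens), 0.0)

    def test_alternating_sign_closed_form(self):
        a = 1.7
        fivs = np.array([[a], [-a], [a], [-a]])
        ens = FIVEnsemble(fivs=fivs, scores=np.zeros(4), weights=np.ones(4))
        assert core.inconsistency_level(ens)[0] == pytest.approx(a ** 2)

    @given(hnp.arrays(np.float64, (5, 4), elements=st.floats(-10, 10)),
           hnp.arrays(np.float64, (5,), elements=st.floats(0.01, 5)))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_oracle(self, fivs, weights):
        ens = FIVEnsemble(fivs=fivs, scores=np.zeros(5), weights=weights)
        assert np.allclose(core.inconsistency_level(ens),
                           weighted_var_oracle(fivs, weights), atol=1e-10)

    def test_shift_invariance_and_quadratic_scaling(self):
        rng = np.random.default_rng(5)
        fivs = rng.normal(size=(6, 3))
        w = rng.uniform(0.1, 1, size=6)
        ens = FIVEnsemble(fivs=fivs, scores=np.zeros(6), weights=w)
        il = core.inconsistency_level(ens)
        shifted = FIVEnsemble(fivs=fivs + 7.0, scores=np.zeros(6), weights=w)
        assert np.allclose(core.inconsistency_level(shifted), il)
        scaled = FIVEnsemble(fivs=3.0 * fivs, scores=np.zeros(6), weights=w)
        assert np.allclose(core.inconsistency_level(scaled), 9.0 * il)

    def test_single_trial_rejected(self):
        ens = FIVEnsemble(fivs=np.ones((1, 3)), scores=np.zeros(1),
                          weights=np.ones(1))
        with pytest.raises(ValueError):
            core.inconsistency_level(ens)


class TestGMM:
    def test_single_tight_gaussian_gives_one_component(self):
        rng = np.random.default_rng(0)
        il = rng.normal(5.0, 0.1, size=40)
        assert core.fit_il_gmm(il, seed=0).n_components == 1

    def test_well_separated_groups_give_three_components(self):
        rng = np.random.default_rng(1)
        il = np.concatenate([rng.normal(0, 0.05, 20),
                             rng.normal(5, 0.05, 10),
                             rng.normal(20, 0.05, 6)])
        res = core.fit_il_gmm(il, seed=0)
        assert res.n_components == 3
        assert res.bic[3] < res.bic[1]

    def test_degenerate_identical_values(self):
        res = core.fit_il_gmm(np.full(10, 2.5), seed=0)
        assert res.n_components == 1
        assert np.all(res.assignments == 0)

    def test_assignments_follow_means(self):
        rng = np.random.default_rng(2)
        il = np.concatenate([rng.normal(0, 0.5, 20), rng.normal(10, 0.5, 10)])
        res = core.fit_il_gmm(il, seed=0)
        # points from the low cluster land in low-mean components, points
        # from the high cluster in high-mean components
        assigned_means = res.means[res.assignments]
        assert np.all(assigned_means[:20] < 5)
        assert np.all(assigned_means[20:] > 5)


class TestCategorizeAndOfiv:
    def _ens(self, fivs, weights=None):
        fivs = np.asarray(fivs, dtype=float)
        T = fivs.shape[0]
        w = np.ones(T) if weights is None else np.asarray(weights, dtype=float)
        return FIVEnsemble(fivs=fivs, scores=np.zeros(T), weights=w)

    def test_one_component_gmm_means_all_additive(self):
        ens = self._ens(np.ones((3, 4)))
        gmm = core.GMMResult(1, np.array([0.0]), np.array([1.0]),
                             np.array([1.0]), np.zeros(4, dtype=int), {1: 0.0})
        assert core.categorize(ens, gmm) == [CATEGORY_ADDITIVE] * 4

    def test_sign_consistency_split(self):
        # channel 0: flips sign -> inconsistent; channel 1: always positive
        fivs = np.array([[2.0, 1.0], [-2.0, 1.5], [2.0, 0.5]])
        ens = self._ens(fivs)
        gmm = core.GMMResult(2, np.array([0.0, 5.0]), np.ones(2), np.ones(2),
                             np.array([1, 1]), {2: 0.0})
        cats = core.categorize(ens, gmm)
        assert cats == [CATEGORY_NONADD_INCONSISTENT, CATEGORY_NONADD_CONSISTENT]

    def test_near_zero_weight_outlier_ignored(self):
        # the sign flip only occurs in a trial with negligible weight
        fivs = np.array([[1.0], [1.2], [-5.0]])
        ens = self._ens(fivs, weights=[1.0, 1.0, 1e-6])
        gmm = core.GMMResult(2, np.array([0.0, 5.0]), np.ones(2), np.ones(2),
                             np.array([1]), {2: 0.0})
        assert core.categorize(ens, gmm) == [CATEGORY_NONADD_CONSISTENT]

    def test_ofiv_identical_fivs(self):
        fivs = np.tile([1.0, -2.0], (3, 1))
        ens = self._ens(fivs)
        res = core.compute_ofiv(ens, [CATEGORY_ADDITIVE] * 2)
        assert np.allclose(res.ofiv, [1.0, -2.0])

    def test_inconsistent_channel_averages_positive_trials_only(self):
        fivs = np.array([[2.0], [-2.0]])
        ens = self._ens(fivs, weights=[1.0, 3.0])
        res = core.compute_ofiv(ens, [CATEGORY_NONADD_INCONSISTENT])
        assert res.ofiv[0] == pytest.approx(2.0)

    def test_inconsistent_channel_all_negative_gives_zero(self):
        fivs = np.array([[-1.0], [-2.0]])
        ens = self._ens(fivs)
        res = core.compute_ofiv(ens, [CATEGORY_NONADD_INCONSISTENT])
        assert res.ofiv[0] == 0.0

    def test_weighted_average_rule(self):
        fivs = np.array([[1.0], [3.0]])
        ens = self._ens(fivs, weights=[3.0, 1.0])
        res = core.compute_ofiv(ens, [CATEGORY_ADDITIVE])
        assert res.ofiv[0] == pytest.approx(1.5)


class TestDegenerateEnsemble:
    def test_t1_pipeline_reduces_to_single_fiv(self, small_trained_model_i):
        """With one trial the OFIV equals that trial's FIV and IL is zero."""
        handle = core.feature_space(small_trained_model_i)
        cfg = AscentConfig(T=1, n_steps=50)
        res = core.analyze_class(handle, 0, cfg, seed=9)
        assert np.allclose(res.il, 0.0)
        assert np.allclose(res.ofiv, res.ensemble.fivs[0])
        assert res.gmm.n_components == 1


class TestCalibrateLambda:
    def test_single_candidate_returned(self, small_trained_model_i,
                                       tiny_dataset_i):
        handle = core.feature_space(small_trained_model_i)
        X = tiny_dataset_i.one_hot_matrix()[:50]
        lam = core.calibrate_lambda(handle, 0, X, [0.8],
                                    AscentConfig(n_steps=50))
        assert lam == 0.8

    def test_selects_from_range(self, small_trained_model_i, tiny_dataset_i):
        handle = core.feature_space(small_trained_model_i)
        X = tiny_dataset_i.one_hot_matrix()[:50]
        candidates = [0.3, 1.0, 2.8]
        lam = core.calibrate_lambda(handle, 0, X, candidates,
                                    AscentConfig(n_steps=100))
        assert lam in candidates

    def test_empty_candidates_rejected(self, small_trained_model_i,
                                       tiny_dataset_i):
        handle = core.feature_space(small_trained_model_i)
        X = tiny_dataset_i.one_hot_matrix()[:10]
        with pytest.raises(ValueError):
            core.calibrate_lambda(handle, 0, X, [])


class TestResultsObject:
    def test_fit_returns_per_class_tables(self, small_trained_model_i):
        cfg = AscentConfig(T=3, n_steps=50)
        res = core.DeepResolve(small_trained_model_i, config=cfg).fit(seed=0)
        df = res.summary()
        assert set(df.columns) >= {"class", "channel", "ofiv", "il", "category"}
        assert len(df) == small_trained_model_i.K
        assert res.ofiv_matrix().shape == (1, small_trained_model_i.K)

    def test_refit_reproducible(self, small_trained_model_i):
        cfg = AscentConfig(T=2, n_steps=30)
        a = core.DeepResolve(small_trained_model_i, config=cfg).fit(seed=3)
        b = core.DeepResolve(small_trained_model_i, config=cfg).fit(seed=3)
        assert np.array_equal(a.per_class[0].ofiv, b.per_class[0].ofiv)
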