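"""Balanced sampling, dirty-model solver, CV decoding and generalisation."""

import numpy as np
import pytest

from conftest import make_trials
from wfopto import decoding, preprocess
from wfopto.core import EpochRegistry
from wfopto.decoding import (
    _prox_linf,
    _soft,
    balance_trials,
    dirty_objective,
    fit_dirty_model,
)
from wfopto.synth import SimConfig, generate_session

LATE = EpochRegistry({"late_delay": (1.2, 1.9)})
CHOICE = EpochRegistry({"choice": (2.0, 2.5)})


def bcd_reference(X, Y, lb, ls, iters=4000):
    """Slow exact block-coordinate minimiser of the dirty objective.

    Row blocks of B (exact l-infinity prox) and of S (soft threshold)
    are cyclically minimised; for this convex objective with
    block-separable nonsmooth terms the iterates reach the optimum.
    """
    p, k = X.shape[1], Y.shape[1]
    B = np.zeros((p, k))
    S = np.zeros((p, k))
    G = X.T @ X
    c = X.T @ Y
    for _ in range(iters):
        for i in range(p):
            a = G[i, i]
            r = c[i] - G[i] @ (B + S) + a * S[i]
            S[i] = _soft((r / a)[None, :], ls / (2 * a))[0]
            r = c[i] - G[i] @ (B + S) + a * B[i]
            B[i] = _prox_linf((r / a)[None, :], lb / (2 * a))[0]
    return B, S


class TestBalanceTrials:
    def test_equal_cells_keep_everything(self):
        t = make_trials(["correct", "error"] * 20,
                        sides=["contra", "contra", "ipsi", "ipsi"] * 10)
        idx = balance_trials(t, seed=0)
        assert len(idx) == 40

    def test_min_cell_rule(self):
        outcomes = (["correct"] * 30 + ["error"] * 5
                    + ["correct"] * 20 + ["error"] * 8)
        sides = ["contra"] * 35 + ["ipsi"] * 28
        t = make_trials(outcomes, sides=sides)
        idx = balance_trials(t, seed=0)
        assert len(idx) == 20
        sub = t.iloc[idx]
        for outcome in ("correct", "error"):
            for side in ("contra", "ipsi"):
                assert ((sub.outcome == outcome)
                        & (sub.stimulus_side == side)).sum() == 5

    def test_same_seed_same_draw(self):
        t = make_trials(["correct", "error"] * 30,
                        sides=["contra", "contra", "ipsi", "ipsi"] * 15)
        a = balance_trials(t, seed=5)
        b = balance_trials(t, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_empty_cell_reports_counts(self):
        t = make_trials(["correct"] * 10)
        with pytest.raises(ValueError, match="counts"):
            balance_trials(t)

    def test_omissions_never_selected(self):
        t = make_trials(["correct", "error", "omission"] * 10,
                        sides=["contra", "ipsi"] * 15)
        idx = balance_trials(t, seed=1)
        assert (t.iloc[idx].outcome != "omission").all()


class TestFeaturize:
    def test_constant_stack_gives_constant_features(self, small_dff):
        const = small_dff.copy_with(data=np.full_like(small_dff.data, 0.7))
        F = decoding.featurize_epoch(const, (1.2, 1.9), np.arange(5))
        np.testing.assert_allclose(F, 0.7, atol=1e-7)

    def test_single_frame_epoch_equals_that_frame(self, small_dff):
        t = small_dff.frame_times
        k = np.argmin(np.abs(t - 1.2))
        F = decoding.featurize_epoch(small_dff, (t[k], t[k] + 0.049),
                                     np.arange(4))
        expect = small_dff.data[:, :, k, :4].reshape(-1, 4).T
        expect = expect[:, small_dff.valid_mask.ravel()]
        np.testing.assert_allclose(F, expect, atol=1e-7)

    def test_matches_brute_force_loop(self, small_dff):
        idx = np.array([3, 7, 11])
        F = decoding.featurize_epoch(small_dff, (0.0, 0.5), idx)
        t = small_dff.frame_times
        win = np.flatnonzero((t >= 0.0) & (t < 0.5))
        for row, j in enumerate(idx):
            flat = []
            for y in range(small_dff.data.shape[0]):
                for x in range(small_dff.data.shape[1]):
                    if small_dff.valid_mask[y, x]:
                        flat.append(
                            small_dff.data[y, x, win, j].astype(np.float64).mean())
            np.testing.assert_allclose(F[row], flat, atol=1e-12)

    def test_empty_epoch_raises(self, small_dff):
        with pytest.raises(ValueError, match="no frames"):
            decoding.featurize_epoch(small_dff, (10.0, 10.01), np.arange(3))


class TestDirtyModel:
    def test_huge_penalties_zero_the_weights(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 8))
        Y = np.sign(rng.standard_normal((30, 2)))
        m = fit_dirty_model(X, Y, 1e7, 1e7)
        assert np.all(m.W == 0)
        # all-zero weights predict one class -> 0.5 on balanced labels
        y_bal = np.array([1.0, -1.0] * 15)
        assert np.mean(m.predict(X)[:, 0] == y_bal) == 0.5

    def test_zero_penalty_separable_training_accuracy_is_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((120, 6))
        W0 = rng.standard_normal((6, 2))
        score = X @ W0
        margin = np.all(np.abs(score) > 0.8, axis=1)  # wide-margin subset
        X, Y = X[margin], np.sign(score[margin])
        assert X.shape[0] > 2 * X.shape[1]
        m = fit_dirty_model(X, Y, 0.0, 0.0, max_iter=5000, tol=1e-12)
        assert np.mean(m.predict(X) == Y) == 1.0
        # and matches the least-squares solution
        ls = np.linalg.lstsq(X, Y, rcond=None)[0]
        np.testing.assert_allclose(m.W, ls, atol=1e-4)

    def test_objective_is_monotonically_nonincreasing(self):
        rng = np.random.default_rng(2)
        for rep in range(5):
            X = rng.standard_normal((25, 12))
            Y = np.sign(rng.standard_normal((25, 2)))
            m = fit_dirty_model(X, Y, 3.0, 2.0)
            d = np.diff(m.objective)
            assert (d <= 1e-12).all()

    @pytest.mark.parametrize("lb,ls", [(5.0, 3.0), (0.5, 8.0), (12.0, 0.1)])
    def test_matches_block_coordinate_reference(self, lb, ls):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 10))
        Y = np.sign(X @ rng.standard_normal((10, 2)))
        m = fit_dirty_model(X, Y, lb, ls, max_iter=20000, tol=1e-14)
        B, S = bcd_reference(X, Y, lb, ls)
        f_ref = dirty_objective(X, Y, B, S, lb, ls)
        assert abs(m.objective[-1] - f_ref) <= 1e-6 * abs(f_ref)

    def test_decomposition_is_exact(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 6))
        Y = np.sign(rng.standard_normal((30, 2)))
        m = fit_dirty_model(X, Y, 2.0, 2.0)
        np.testing.assert_array_equal(m.W, m.B + m.S)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fit_dirty_model(np.ones((4, 2)), np.ones((4, 1)), -1.0, 0.0)


@pytest.fixture(scope="module")
def separable_session():
    """Low-sensor-noise, trial-stable memory: a separable regime."""
    cfg = SimConfig(n_pixels_y=32, n_pixels_x=32, n_trials=200, seed=7,
                    noise_sd=0.005, memory_noise_sd=0.2, decision_noise_sd=1.5,
                    lick_rate_biased=12.0)
    s = generate_session(cfg)
    return s, preprocess.compute_dff(s.stack, s.trials)


class TestCrossvalDecode:
    def test_separable_session_decodes_lick_and_stimulus(self, separable_session):
        s, dff = separable_session
        res = decoding.crossval_decode(
            dff, s.trials, EpochRegistry({"late_delay": (1.2, 1.9),
                                          "choice": (2.0, 2.5)}),
            downsample=2, seed=1)
        assert res.accuracy[("late_delay", "stimulus_side")] >= 0.95
        assert res.accuracy[("choice", "lick_side")] >= 0.95

    def test_shuffled_labels_fall_to_chance(self, separable_session):
        s, dff = separable_session
        rng = np.random.default_rng(0)
        shuffled = s.trials.copy()
        resp = shuffled.outcome != "omission"
        # permute stimulus sides among responded trials, relabel outcomes
        sides = shuffled.loc[resp, "stimulus_side"].to_numpy()
        shuffled.loc[resp, "stimulus_side"] = rng.permutation(sides)
        shuffled.loc[resp, "outcome"] = np.where(
            shuffled.loc[resp, "stimulus_side"]
            == shuffled.loc[resp, "first_lick_side"], "correct", "error")
        res = decoding.crossval_decode(dff, shuffled, LATE,
                                       tasks=("stimulus_side",),
                                       downsample=2, seed=3)
        n = len(res.balanced_index)
        acc = res.accuracy[("late_delay", "stimulus_side")]
        assert abs(acc - 0.5) <= 2.5 * np.sqrt(0.25 / n)

    def test_single_class_fold_is_rejected(self, separable_session):
        s, dff = separable_session
        idx = decoding.balance_trials(s.trials, seed=0)[:10]
        fold = np.zeros(10, dtype=int)  # every trial in fold 0
        with pytest.raises(ValueError, match="single class"):
            decoding.crossval_decode(dff, s.trials, LATE, n_folds=5, seed=0,
                                     balanced_index=idx, fold_assignment=fold)


class TestBootstrap:
    def test_single_draw_percentile_is_zero_or_hundred(self, separable_session):
        s, dff = separable_session
        res = decoding.bootstrap_significance(
            dff, s.trials, LATE, tasks=("stimulus_side",), n_boot=1,
            seed=2, downsample=4)
        p = res.bootstrap_percentile[("late_delay", "stimulus_side")]
        assert p in (0.0, 100.0)

    def test_informative_data_scores_high_percentile(self, separable_session):
        s, dff = separable_session
        res = decoding.bootstrap_significance(
            dff, s.trials, LATE, tasks=("stimulus_side",), n_boot=30,
            seed=2, downsample=4)
        assert res.bootstrap_percentile[("late_delay", "stimulus_side")] > 95


class TestCrossCondition:
    @pytest.mark.parametrize("regime,direction", [
        ("global_excite", 1), ("local_suppress", -1)])
    def test_opto_bias_shifts_predictions_for_both_sides(self, regime, direction):
        cfg = SimConfig(n_pixels_y=32, n_pixels_x=32, n_trials=400, seed=11,
                        opto_regime=regime)
        s = generate_session(cfg)
        dff = preprocess.compute_dff(s.stack, s.trials)
        cc = decoding.cross_condition_test(dff, s.trials, downsample=2, seed=2)
        for side in ("contra", "ipsi"):
            shift = (cc.predicted_contra[("opto_on", side)]
                     - cc.predicted_contra[("opto_off", side)])
            assert direction * shift > 0

    def test_without_opto_trials_raises(self, separable_session):
        s, dff = separable_session
        with pytest.raises(ValueError, match="no optogenetic"):
            decoding.cross_condition_test(dff, s.trials, seed=0)
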