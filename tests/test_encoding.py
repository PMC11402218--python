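"""Design-matrix construction, ridge solver, CV R² and circular-shift ΔR²."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_trials
from wfopto import encoding, preprocess
from wfopto.synth import SimConfig, generate_session


def _tiny_inputs(n_trials=12, nf=20, seed=0, n_licks=10):
    rng = np.random.default_rng(seed)
    trials = make_trials(
        rng.choice(["correct", "error"], size=n_trials).tolist(),
        sides=rng.choice(["contra", "ipsi"], size=n_trials).tolist())
    ft = -0.2 + np.arange(nf) / 20.0
    licks = pd.DataFrame({
        "trial_id": rng.integers(0, n_trials, n_licks),
        "time": rng.uniform(0.0, ft[-1], n_licks),
        "side": rng.choice(["contra", "ipsi"], n_licks),
    })
    cont = {"body": rng.random((nf, n_trials)), "eye": rng.random((nf, n_trials))}
    return trials, licks, cont, ft


class TestDesignMatrix:
    def test_intercept_only_without_events_or_continuous(self):
        trials = make_trials(["omission"] * 4)
        trials["stimulus_side"] = "contra"
        ft = np.arange(10) / 20.0 - 0.6  # all frames before stimulus onset
        dm = encoding.build_design_matrix(
            trials, pd.DataFrame(columns=["trial_id", "time", "side"]), {}, ft)
        assert dm.X.shape[1] == 1
        assert list(dm.groups) == ["intercept"]
        np.testing.assert_array_equal(dm.X[:, 0], 1.0)

    def test_lag_structure_of_a_single_event(self):
        trials = make_trials(["correct"], sides=["contra"])
        ft = -0.1 + np.arange(8) / 20.0  # onset at frame 2
        dm = encoding.build_design_matrix(
            trials, pd.DataFrame(columns=["trial_id", "time", "side"]), {}, ft,
            kernel_len=3)
        cols = dm.groups["stimulus_side"]
        block = dm.X[:, cols]
        expect = np.zeros((8, 3))
        expect[2, 0] = expect[3, 1] = expect[4, 2] = 1.0
        np.testing.assert_array_equal(block, expect)

    def test_matches_brute_force_lag_expansion(self):
        trials, licks, cont, ft = _tiny_inputs(seed=3)
        dm = encoding.build_design_matrix(trials, licks, cont, ft,
                                          rebaseline_continuous=False)
        nf, nt = len(ft), len(trials)
        for p in dm.predictors:
            if p.kind != "event":
                continue
            block = dm.X[:, p.columns]
            expect = np.zeros_like(block)
            for j, trial in enumerate(trials.itertuples()):
                if p.name.startswith("stim"):
                    side = p.name.split("_")[1]
                    onsets = [0.0] if trial.stimulus_side == side else []
                else:
                    side = p.name.split("_")[1]
                    sel = (licks.trial_id == trial.trial_id) & (licks.side == side)
                    onsets = licks.loc[sel, "time"].tolist()
                for t in onsets:
                    k = int(round((t - ft[0]) * 20))
                    for li, lag in enumerate(p.lags):
                        if k + lag < nf:
                            expect[j * nf + k + lag, li] = 1.0
            np.testing.assert_array_equal(block, expect)

    def test_values_bounded_and_groups_partition_columns(self):
        trials, licks, cont, ft = _tiny_inputs(seed=4)
        dm = encoding.build_design_matrix(trials, licks, cont, ft)
        assert dm.X.min() >= 0.0 and dm.X.max() <= 1.0
        all_cols = np.concatenate(list(dm.groups.values()))
        assert sorted(all_cols) == list(range(dm.X.shape[1]))

    def test_event_outside_window_names_trial(self):
        trials, licks, cont, ft = _tiny_inputs()
        bad = pd.concat([licks, pd.DataFrame(
            {"trial_id": [3], "time": [9.0], "side": ["contra"]})])
        with pytest.raises(ValueError, match="trial 3"):
            encoding.build_design_matrix(trials, bad, cont, ft)


class TestRidgeSolve:
    def test_alpha_zero_matches_pseudo_inverse(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 12))
        y = rng.standard_normal(60)
        b = encoding.ridge_solve(X, y, 0.0)
        np.testing.assert_allclose(b, np.linalg.pinv(X) @ y, atol=1e-8)

    def test_exact_interpolation_at_alpha_zero(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 8))
        b0 = rng.standard_normal(8)
        b = encoding.ridge_solve(X, X @ b0, 0.0)
        np.testing.assert_allclose(b, b0, atol=1e-8)

    def test_shrinkage_is_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.standard_normal((40, 6)), np.ones(40)])
        y = rng.standard_normal(40)
        norms = []
        for alpha in [0.0, 1.0, 10.0, 100.0, 1e4, 1e6]:
            b = encoding.ridge_solve(X, y, alpha, intercept_col=6)
            norms.append(np.linalg.norm(b[:6]))
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-3 * max(norms[0], 1e-12)

    def test_rank_deficiency_raises_at_alpha_zero(self):
        X = np.ones((10, 3))
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            encoding.ridge_solve(X, np.ones(10), 0.0)

    def test_unpenalized_intercept_centering_equivalence(self):
        """Centred eigen-path solution equals the explicit D-matrix solve."""
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.standard_normal((30, 5)), np.ones(30)])
        Y = rng.standard_normal((30, 2))
        direct = encoding.ridge_solve(X, Y, 7.5, intercept_col=5)
        path = encoding._RidgePath(X, Y, intercept_col=5)
        np.testing.assert_allclose(path.beta(7.5), direct, atol=1e-9)


class TestSelectAlpha:
    def test_grid_of_one_returns_that_value(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        tr = np.repeat(np.arange(10), 4)
        got = encoding.select_alpha(X, y, tr, grid=np.array([3.5]))
        assert got[0] == 3.5

    def test_noiseless_linear_target_selects_zero(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.standard_normal((60, 5)), np.ones(60)])
        y = X @ rng.standard_normal(6)
        tr = np.repeat(np.arange(12), 5)
        got = encoding.select_alpha(X, y, tr, grid=np.arange(0, 10.5, 0.5),
                                    intercept_col=5)
        assert got[0] == 0.0

    def test_pure_noise_with_many_columns_prefers_regularisation(self):
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(100 + rep)
            X = np.column_stack([rng.standard_normal((45, 30)), np.ones(45)])
            y = rng.standard_normal(45)
            tr = np.repeat(np.arange(15), 3)
            a = encoding.select_alpha(X, y, tr, grid=np.arange(0, 50.5, 2.5),
                                      seed=rep, intercept_col=30)
            hits += int(a[0] > 0)
        assert hits >= 38  # ≥95% of repeats


@pytest.fixture(scope="module")
def fitted_small():
    cfg = SimConfig(n_pixels_y=12, n_pixels_x=12, n_trials=60, seed=21,
                    noise_sd=0.0, memory_noise_sd=0.0)
    s = generate_session(cfg)
    dff = preprocess.compute_dff(s.stack, s.trials)
    dm = encoding.build_design_matrix(s.trials, s.licks, s.continuous,
                                      dff.frame_times)
    Y, idx = encoding.flatten_stack(dff)
    fit = encoding.crossval_r2(dm, Y, seed=0, alpha_grid=np.arange(0, 50.1, 2.0))
    return s, dff, dm, Y, idx, fit


class TestCrossvalR2:
    def test_noiseless_session_r2_near_one(self, fitted_small):
        s, dff, dm, Y, idx, fit = fitted_small
        amp = sum(np.abs(v) for v in s.truth.beta_maps.values()) \
            + np.abs(s.truth.memory_template_contra) \
            + np.abs(s.truth.memory_template_ipsi)
        active = amp.ravel()[idx] > 0.1 * amp.max()
        assert np.median(fit.cv_r2[active]) >= 0.999

    def test_independent_target_r2_near_zero(self):
        trials, licks, cont, ft = _tiny_inputs(n_trials=60, nf=15, seed=8)
        dm = encoding.build_design_matrix(trials, licks, cont, ft, kernel_len=6)
        rng = np.random.default_rng(0)
        y = rng.standard_normal(dm.X.shape[0])
        fit = encoding.crossval_r2(dm, y, seed=1,
                                   alpha_grid=np.arange(0, 50.1, 5.0))
        assert fit.cv_r2[0] <= 0.05

    def test_folds_split_whole_trials(self, fitted_small):
        _, _, dm, _, _, fit = fitted_small
        # structural: every row of a trial shares that trial's fold
        fold_rows = fit.fold_of_trial[dm.trial_index]
        for t in range(dm.n_trials):
            rows = fold_rows[dm.trial_index == t]
            assert len(set(rows.tolist())) == 1


class TestDeltaR2:
    def test_zero_shift_identity(self, fitted_small):
        _, _, dm, Y, _, _ = fitted_small
        same = dm.with_shifted_group("stimulus_side", 0)
        np.testing.assert_array_equal(same.X, dm.X)
        full = dm.with_shifted_group("stimulus_side", dm.n_trials)
        np.testing.assert_array_equal(full.X, dm.X)

    def test_shift_permutes_trial_blocks(self, fitted_small):
        _, _, dm, _, _, _ = fitted_small
        cols = dm.groups["stimulus_side"]
        shifted = dm.with_shifted_group("stimulus_side", 3)
        nf = dm.n_frames
        a = dm.X[:, cols].reshape(dm.n_trials, nf, -1)
        b = shifted.X[:, cols].reshape(dm.n_trials, nf, -1)
        np.testing.assert_array_equal(b[3], a[0])
        np.testing.assert_array_equal(b[0], a[dm.n_trials - 3])

    def test_informative_group_has_delta_near_r2(self):
        """Rotating the only informative group destroys the fit.

        The target is side-antisymmetric (opposite kernels for contra
        and ipsi stimuli), so the rotated predictors retain no usable
        structure: every trial still has a stimulus, but its side no
        longer matches the response.
        """
        trials, licks, cont, ft = _tiny_inputs(n_trials=40, nf=15, seed=5)
        dm = encoding.build_design_matrix(trials, licks, cont, ft, kernel_len=6)
        rng = np.random.default_rng(1)
        contra = next(p for p in dm.predictors if p.name == "stim_contra")
        ipsi = next(p for p in dm.predictors if p.name == "stim_ipsi")
        b = rng.standard_normal(len(contra.columns))
        y = dm.X[:, contra.columns] @ b - dm.X[:, ipsi.columns] @ b
        fit = encoding.delta_r2(dm, y, "stimulus_side", n_shifts=20, seed=2,
                                alpha_grid=np.arange(0, 20.1, 2.0))
        assert fit.cv_r2[0] > 0.98
        assert fit.delta_r2["stimulus_side"][0] > 0.85 * fit.cv_r2[0]
        assert fit.significant["stimulus_side"][0]
        assert np.max(fit.null_r2["stimulus_side"][:, 0]) < 0.5

    def test_group_without_events_warns_and_is_insignificant(self):
        trials, licks, cont, ft = _tiny_inputs(n_trials=20, nf=15, seed=6)
        trials["opto"] = "off"
        dm = encoding.build_design_matrix(trials, licks, cont, ft, kernel_len=6)
        assert "opto" not in dm.groups  # pruned entirely: no opto events
        with pytest.raises(KeyError):
            encoding.delta_r2(dm, np.zeros(dm.X.shape[0]), "opto", n_shifts=5)

    def test_unknown_group_raises(self, fitted_small):
        _, _, dm, Y, _, _ = fitted_small
        with pytest.raises(KeyError, match="unknown predictor group"):
            encoding.delta_r2(dm, Y[:, :1], "wheel", n_shifts=2)


class TestExcludeUnexplained:
    def test_any_significant_group_keeps_target(self):
        sig = {"a": np.array([True, False, False]),
               "b": np.array([False, False, True])}
        got = encoding.exclude_unexplained(sig, ["a", "b"])
        np.testing.assert_array_equal(got, [True, False, True])

    def test_no_groups_raises(self):
        with pytest.raises(ValueError):
            encoding.exclude_unexplained({}, [])
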