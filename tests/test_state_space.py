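"""Two-rate/one-rate simulation, fitting, and AIC model comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tworate as tw
from tworate.state_space import grid_search_starts


def valid_two_rate():
    """Strategy for parameter sets satisfying the ordering constraints."""
    return st.tuples(
        st.floats(0.60, 0.999), st.floats(0.001, 0.3),   # Rs, Ls
        st.floats(0.10, 0.55), st.floats(0.35, 0.999),   # Rf, Lf
    ).map(lambda t: tw.TwoRateParams(Rs=t[0], Ls=t[1], Rf=t[2], Lf=t[3]))


class TestSimulateTwoRate:
    def test_no_learning_gives_zero_output(self, schedule):
        params = tw.TwoRateParams(Rs=1.0, Ls=0.0, Rf=0.5, Lf=0.0)
        traj = tw.simulate_two_rate(params, schedule, require_order=False)
        assert np.all(traj.x_total == 0)

    def test_one_step_update_after_first_rotated_trial(self):
        sched = tw.build_schedule([(1, 0, False), (2, 30, False)])
        params = tw.TwoRateParams(Rs=1.0, Ls=0.055, Rf=0.825, Lf=0.226)
        traj = tw.simulate_two_rate(params, sched)
        # state reported on the trial after the first rotated trial:
        # (Ls + Lf) * 30
        assert traj.x_total[2] == pytest.approx((0.055 + 0.226) * 30)
        assert traj.x_total[1] == 0.0  # pre-update state on the rotated trial

    @given(valid_two_rate())
    def test_constant_perturbation_converges_to_closed_form(self, params):
        sched = tw.build_schedule([(20000, 30.0, False)])
        traj = tw.simulate_two_rate(params, sched)
        G = params.Ls / (1 - params.Rs) + params.Lf / (1 - params.Rf)
        assert traj.x_total[-1] == pytest.approx(30.0 * G / (1 + G), abs=1e-6)

    def test_table_like_steady_state_error(self, nocursor_params):
        sched = tw.build_schedule([(8000, 30.0, False)])
        traj = tw.simulate_two_rate(nocursor_params, sched)
        assert 30.0 - traj.x_total[-1] == pytest.approx(5.39, abs=0.01)

    @given(valid_two_rate())
    def test_additivity_and_clamp_error(self, params):
        sched = tw.build_schedule()
        traj = tw.simulate_two_rate(params, sched)
        assert np.array_equal(traj.x_total, traj.x_slow + traj.x_fast)
        assert np.all(traj.error[sched.is_clamp] == 0)

    @given(valid_two_rate())
    def test_zero_perturbation_invariance(self, params):
        sched = tw.build_schedule([(100, 0.0, False)])
        traj = tw.simulate_two_rate(params, sched)
        assert np.all(traj.x_total == 0)

    def test_rebound_toward_slow_process(self, schedule, pause_params):
        traj = tw.simulate_two_rate(pause_params, schedule)
        last_counter = traj.x_total[239]          # last counter-rotation trial
        mid_clamp = traj.x_total[260]
        assert mid_clamp > last_counter           # spontaneous recovery
        assert np.sign(mid_clamp) == np.sign(traj.x_slow[260])

    def test_invalid_params_rejected_before_simulation(self, schedule):
        with pytest.raises(ValueError, match="slow learning"):
            tw.simulate_two_rate(
                tw.TwoRateParams(Rs=0.9, Ls=0.5, Rf=0.5, Lf=0.2), schedule)
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            tw.simulate_two_rate(
                tw.TwoRateParams(Rs=1.2, Ls=0.1, Rf=0.5, Lf=0.3), schedule)


class TestSimulateOneRate:
    def test_no_learning(self, schedule):
        traj = tw.simulate_one_rate(tw.OneRateParams(R=0.9, L=0.0), schedule)
        assert np.all(traj.x_total == 0)

    def test_full_correction_in_one_step(self):
        sched = tw.build_schedule([(3, 30.0, False)])
        traj = tw.simulate_one_rate(tw.OneRateParams(R=0.0, L=1.0), sched)
        assert traj.x_total[1] == pytest.approx(30.0)

    def test_fixed_point(self):
        sched = tw.build_schedule([(3000, 30.0, False)])
        traj = tw.simulate_one_rate(tw.OneRateParams(R=0.9, L=0.1), sched)
        # x* = P * L / (L + 1 - R)
        assert traj.x_total[-1] == pytest.approx(15.0, abs=1e-6)


class TestGridSearchStarts:
    def test_best_node_is_nearest_to_target(self):
        target = np.array([0.31, 0.62])
        obj = lambda x: float(np.sum((x - target) ** 2))
        starts = grid_search_starts(obj, [(0, 1), (0, 1)], 11, n_best=1)
        assert np.allclose(starts[0], [0.3, 0.6])

    def test_n_best_clipped_to_feasible_count(self):
        obj = lambda x: float(x[0])
        starts = grid_search_starts(obj, [(0, 1)], 3, n_best=10)
        assert len(starts) == 3

    def test_quadratic_ordering_on_three_point_grid(self):
        obj = lambda x: float((x[0] - 0.4) ** 2)
        starts = grid_search_starts(obj, [(0, 1)], 3, n_best=3)
        assert [s[0] for s in starts] == [0.5, 0.0, 1.0]

    def test_no_feasible_node_raises(self):
        with pytest.raises(ValueError, match="finer grid"):
            grid_search_starts(lambda x: 0.0, [(0, 1)], 3,
                               feasible=lambda x: False)


class TestFitStateSpace:
    def test_noiseless_self_recovery(self, schedule):
        truth = tw.TwoRateParams(Rs=0.996, Ls=0.05, Rf=0.8, Lf=0.2)
        data = tw.simulate_two_rate(truth, schedule).x_total
        fit = tw.fit_state_space(data, schedule)
        assert fit.mse < 1e-8
        assert np.abs(fit.params.as_array() - truth.as_array()).max() < 1e-4
        assert fit.k == 4 and fit.n_points == 288

    def test_one_rate_noiseless_recovery(self, schedule):
        truth = tw.OneRateParams(R=0.95, L=0.15)
        data = tw.simulate_one_rate(truth, schedule).x_total
        fit = tw.fit_state_space(data, schedule, model_kind="one_rate")
        assert fit.mse < 1e-8
        assert np.abs(fit.params.as_array() - truth.as_array()).max() < 1e-4
        assert fit.k == 2

    def test_zero_data_all_aligned_reaches_zero_mse(self):
        sched = tw.build_schedule([(50, 0.0, False)])
        fit = tw.fit_state_space(np.zeros(50), sched)
        assert fit.mse == pytest.approx(0.0, abs=1e-12)

    def test_slow_target_fits_slow_process(self, schedule, pause_params):
        slow = tw.simulate_two_rate(pause_params, schedule).x_slow
        fit = tw.fit_state_space(slow, schedule, fit_target="slow")
        resid = fit.trajectory.x_slow - slow
        assert float(np.mean(resid ** 2)) == pytest.approx(fit.mse, rel=1e-6)
        assert fit.mse < 1e-6

    def test_missing_data_ignored(self, schedule, pause_trajectory):
        data = pause_trajectory.x_total.copy()
        data[::7] = np.nan
        fit = tw.fit_state_space(data, schedule)
        assert fit.n_points == np.isfinite(data).sum()
        assert fit.mse < 1e-8

    def test_length_mismatch_and_all_missing_rejected(self, schedule):
        with pytest.raises(ValueError, match="length"):
            tw.fit_state_space(np.zeros(100), schedule)
        with pytest.raises(ValueError, match="finite"):
            tw.fit_state_space(np.full(288, np.nan), schedule)

    def test_one_rate_fit_matches_exhaustive_grid_oracle(self, rng):
        """Independent oracle: vectorized exhaustive grid minimization."""
        sched = tw.build_schedule([(20, 0, False), (60, 30.0, False)])
        truth = tw.OneRateParams(R=0.9, L=0.12)
        data = tw.simulate_one_rate(truth, sched).x_total \
            + rng.normal(0, 2.0, sched.n_trials)
        step = 0.002
        R = np.arange(0.001, 0.999 + step / 2, step)
        L = np.arange(0.001, 0.999 + step / 2, step)
        Rg, Lg = np.meshgrid(R, L, indexing="ij")
        x = np.zeros_like(Rg)
        sse = np.zeros_like(Rg)
        for t in range(sched.n_trials):
            sse += (x - data[t]) ** 2
            e = 0.0 if sched.is_clamp[t] else sched.perturbation[t] - x
            x = Lg * e + Rg * x
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        fit = tw.fit_state_space(data, sched, model_kind="one_rate")
        assert fit.params.R == pytest.approx(R[i], abs=step)
        assert fit.params.L == pytest.approx(L[j], abs=step)


class TestModelComparison:
    @pytest.mark.parametrize("pair, expected", [
        ((13.901, 19.110), 0.074),
        ((19.293, 25.697), 0.041),
        ((15.605, 27.004), 0.003),
        ((19.548, 27.207), 0.022),
    ])
    def test_relative_likelihood_of_worse_model(self, pair, expected):
        rl = tw.relative_likelihoods(pair)
        assert rl[0] == 1.0
        assert round(float(rl[1]), 3) == expected

    def test_equal_aics_both_one(self):
        assert np.allclose(tw.relative_likelihoods([10.0, 10.0]), 1.0)

    def test_aic_rejects_zero_mse(self):
        with pytest.raises(ValueError, match="undefined"):
            tw.aic(0.0, 288, 4)

    def test_compare_fitted_models(self, schedule, pause_trajectory, rng):
        data = pause_trajectory.x_total + rng.normal(0, 2, 288)
        fit2 = tw.fit_state_space(data, schedule)
        fit1 = tw.fit_state_space(data, schedule, model_kind="one_rate")
        cmp = tw.compare_models([fit2, fit1])
        d = cmp.as_dict()
        assert d["two_rate"]["aic"] < d["one_rate"]["aic"]
        assert d["two_rate"]["relative_likelihood"] == 1.0
        assert 0 < d["one_rate"]["relative_likelihood"] <= 1.0

    def test_single_fit_rejected(self, schedule, pause_trajectory):
        fit = tw.fit_state_space(pause_trajectory.x_total + 0.1, schedule)
        with pytest.raises(ValueError):
            tw.compare_models([fit])
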