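"""Tests for metrics, DTW, leave-one-wave-out and sensitivity scans."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrodyn.dynamics import CoupledTraitParams, InitialCondition, simulate
from entrodyn.errors import InvalidInputError, UndefinedMetricError
from entrodyn.estimation import (
    ObservedTrajectories,
    ParamEntry,
    ParameterSpec,
    fit_multistart,
)
from entrodyn.validation import (
    basic_metrics,
    dtw_distance,
    loo_validate,
    sensitivity_scan,
    trait_metrics,
)


def dtw_bruteforce(a, b):
    """Exhaustive minimization over all monotone boundary-matched warping
    paths (independent oracle; exponential, lengths <= 6 only)."""
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == len(a) - 1 and j == len(b) - 1:
            best[0] = acc
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < len(a) and nj < len(b):
                walk(ni, nj, acc)

    walk(0, 0, 0.0)
    return best[0]


class TestBasicMetrics:
    def test_perfect_fit(self):
        rep = basic_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.rmse == 0.0
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.pearson_r == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        rep = basic_metrics([0.0, 1.0], [1.0, 0.0])
        assert rep.rmse == pytest.approx(1.0)
        assert rep.pearson_r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # residuals (0.1,-0.1,0.2,-0.2): SSE=0.10, RMSE=sqrt(0.025);
        # SStot=5 about the mean 2.5 -> R^2=0.98; r and its two-sided
        # t-test p (2 df) hand-checked against the correlation formula
        rep = basic_metrics([1, 2, 3, 4], [1.1, 1.9, 3.2, 3.8])
        assert rep.rmse == pytest.approx(0.1581138830084191, abs=1e-12)
        assert rep.r_squared == pytest.approx(0.98, abs=1e-12)
        assert rep.pearson_r == pytest.approx(0.9908470001860921, abs=1e-12)
        assert rep.pearson_p == pytest.approx(0.009152999813907934, abs=1e-9)

    def test_constant_observed_raises(self):
        with pytest.raises(UndefinedMetricError):
            basic_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_negative_r_squared_allowed(self):
        rep = basic_metrics([0.0, 1.0, 0.0], [5.0, -5.0, 5.0])
        assert rep.r_squared < 0


class TestDTW:
    def test_identical_sequences_zero(self):
        assert dtw_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_repeated_element_absorbed(self):
        assert dtw_distance([1, 2, 3], [1, 2, 2, 3]) == 0.0

    def test_constant_offset_pair(self):
        # 2x2 grid: every admissible path accumulates >= 2 unit costs
        assert dtw_distance([0, 0], [1, 1]) == pytest.approx(2.0)

    def test_symmetry(self):
        a, b = [0.3, 1.0, 0.2, 0.7], [0.1, 0.9, 0.8]
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            dtw_distance([], [1.0])

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=6),
        st.lists(st.floats(-5, 5), min_size=1, max_size=6),
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_exhaustive_path_enumeration(self, a, b):
        assert dtw_distance(a, b) == pytest.approx(dtw_bruteforce(a, b))

    def test_zero_iff_equal_after_deduplication(self):
        assert dtw_distance([1, 1, 2, 3, 3], [1, 2, 2, 3]) == 0.0
        assert dtw_distance([1, 2], [1, 2.1]) > 0


@pytest.fixture(scope="module")
def noiseless_model_obs():
    params = CoupledTraitParams(mu=0.05, alpha=0.3, beta=0.4, gamma=0.15,
                                c1=1.0, c2=0.2, c3=1.0, K=0.5)
    init = InitialCondition(0.0, 0.8, 0.85, 0.05)
    times = np.array([0.0, 3.0, 9.0, 13.0, 19.0, 23.0])
    traj = simulate(params, init, times)
    return params, init, ObservedTrajectories(times, traj.N, traj.P)


def all_fixed_spec(params, init):
    entries = {
        name: ParamEntry(False, getattr(params, name),
                         *{"mu": (0, 1), "alpha": (0, 5), "beta": (-2, 2),
                           "gamma": (0, 1), "c1": (0, 20), "c2": (0, 20),
                           "c3": (0, 20), "K": (1e-3, 10), "G": (1e-3, 10)}[name])
        for name in ("mu", "alpha", "beta", "gamma", "c1", "c2", "c3", "K", "G")
    }
    entries["N0"] = ParamEntry(False, init.N0, 0.0, 1.0)
    entries["P0"] = ParamEntry(False, init.P0, 1e-4, 1.0)
    entries["E0"] = ParamEntry(False, init.E0, 1e-4, 1.0)
    return ParameterSpec(entries)


class TestLOO:
    def test_nothing_free_predicts_exactly(self, noiseless_model_obs):
        params, init, obs = noiseless_model_obs
        spec = all_fixed_spec(params, init)
        report = loo_validate(obs, spec, n_starts=1, seed=0)
        assert len(report.folds) == obs.n_waves
        assert report.loo_rmse_n == pytest.approx(0.0, abs=1e-7)
        assert report.loo_rmse_p == pytest.approx(0.0, abs=1e-7)

    def test_four_wave_input_gives_four_folds(self):
        params = CoupledTraitParams(mu=0.01)
        init = InitialCondition(0.0, 0.5, 0.5, 0.0)
        times = np.array([0.0, 1.0, 2.0, 3.0])
        traj = simulate(params, init, times)
        obs = ObservedTrajectories(times, traj.N, traj.P)
        report = loo_validate(obs, all_fixed_spec(params, init),
                              n_starts=1, seed=0)
        assert len(report.folds) == 4

    def test_first_fold_frees_pinned_initial_conditions(self, noiseless_model_obs):
        params, init, obs = noiseless_model_obs
        entries = all_fixed_spec(params, init).entries
        entries["alpha"] = ParamEntry(True, 0.3, 0.0, 5.0)
        spec = ParameterSpec(entries)
        report = loo_validate(obs, spec, n_starts=2, seed=1)
        # first-wave prediction comes from the freed initial state, fitted
        # only to the later waves; on noiseless data it recovers the truth
        fold0 = report.folds[0]
        assert not fold0.failed
        assert fold0.predicted_n == pytest.approx(fold0.observed_n, abs=1e-3)

    def test_too_few_waves_rejected(self):
        obs = ObservedTrajectories([0.0, 1.0], [0.5, 0.6], [0.5, 0.6])
        with pytest.raises(InvalidInputError):
            loo_validate(obs, ParameterSpec.full(obs))


class TestSensitivity:
    def _fit(self, obs, free_alpha_gamma=True):
        entries = {
            "mu": ParamEntry(False, 0.05, 0, 1),
            "alpha": ParamEntry(True, 0.3, 0, 5),
            "gamma": ParamEntry(True, 0.15, 0, 1),
            "beta": ParamEntry(False, 0.4, -2, 2),
            "c1": ParamEntry(False, 1.0, 0, 20),
            "c2": ParamEntry(False, 0.2, 0, 20),
            "c3": ParamEntry(False, 1.0, 0, 20),
            "K": ParamEntry(False, 0.5, 1e-3, 10),
            "G": ParamEntry(False, 1.0, 1e-3, 10),
            "N0": ParamEntry(False, float(obs.n_observed[0]), 0, 1),
            "P0": ParamEntry(False, float(obs.p_observed[0]), 1e-4, 1),
            "E0": ParamEntry(False, 0.05, 1e-4, 1),
        }
        spec = ParameterSpec(entries)
        return spec, fit_multistart(spec, obs, n_starts=2, seed=9)

    def test_two_rows_per_free_parameter(self, noiseless_model_obs):
        _, _, obs = noiseless_model_obs
        spec, fit = self._fit(obs)
        report = sensitivity_scan(fit, obs, spec)
        assert len(report.rows) == 2 * len(fit.free_names)
        per_param = {n: [r for r in report.rows if r.parameter == n]
                     for n in fit.free_names}
        assert all(len(v) == 2 for v in per_param.values())

    def test_alpha_perturbation_changes_rmse(self, noiseless_model_obs):
        _, _, obs = noiseless_model_obs
        spec, fit = self._fit(obs)
        report = sensitivity_scan(fit, obs, spec)
        alpha_rows = [r for r in report.rows if r.parameter == "alpha"]
        assert all(r.total_rmse > 0 for r in alpha_rows)
        assert any(abs(r.percent_change) > 0 for r in alpha_rows)

    def test_dead_parameter_has_zero_effect(self):
        # c3 multiplies E_stress; with E0 ~ 0 and no forcing the signal
        # it scales is identically zero
        params = CoupledTraitParams(mu=0.05, alpha=0.3, beta=0.4, c1=1.0,
                                    c3=2.0, K=0.5)
        init = InitialCondition(0.0, 0.8, 0.85, 0.0)
        times = np.array([0.0, 2.0, 4.0, 6.0])
        traj = simulate(params, init, times)
        obs = ObservedTrajectories(times, traj.N, traj.P)
        entries = all_fixed_spec(params, init).entries
        entries["c3"] = ParamEntry(True, 2.0, 0.0, 20.0)
        entries["E0"] = ParamEntry(False, 0.0, 0.0, 1.0)
        spec = ParameterSpec(entries)
        fit = fit_multistart(spec, obs, n_starts=1, seed=2)
        report = sensitivity_scan(fit, obs, spec)
        c3_rows = [r for r in report.rows if r.parameter == "c3"]
        assert all(r.percent_change == pytest.approx(0.0, abs=1e-6)
                   for r in c3_rows)

    def test_refit_mode_no_worse_than_perturb_only(self, noiseless_model_obs):
        _, _, obs = noiseless_model_obs
        spec, fit = self._fit(obs)
        only = sensitivity_scan(fit, obs, spec, mode="perturb_only")
        refit = sensitivity_scan(fit, obs, spec, mode="perturb_refit_others")
        for a, b in zip(only.rows, refit.rows):
            assert b.total_rmse <= a.total_rmse + 1e-6

    def test_trait_metrics_includes_dtw(self, noiseless_model_obs):
        params, init, obs = noiseless_model_obs
        spec = all_fixed_spec(params, init)
        fit = fit_multistart(spec, obs, n_starts=1, seed=0)
        reports = trait_metrics(obs, fit)
        assert reports["N"].dtw_distance == pytest.approx(0.0, abs=1e-6)
        assert reports["P"].rmse == pytest.approx(0.0, abs=1e-7)
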