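"""MAE cost, gradient-descent fitting, fitting errors and confidence intervals."""

import numpy as np
import pytest

from lqrg import (
    GroupData,
    LQRGParams,
    TumorSpec,
    fit_model,
    fitting_errors,
    mae_cost,
    parameter_confidence_intervals,
    tcp_time_curve,
)
from lqrg.synthetic_cohort import default_cohort_spec


def _noise_free_groups(params, times=None):
    """Fitting data lying exactly on the LQRG model curves."""
    times = np.arange(1.0, 61.0, 3.0) if times is None else np.asarray(times)
    groups = []
    for spec in default_cohort_spec().groups:
        sched = spec.schedule()
        tumor = TumorSpec(spec.gtv_mean_cm3)
        lpfs = np.asarray(tcp_time_curve("lqrg", params, sched, tumor, times))
        groups.append(GroupData(spec.name, sched, tumor, tuple(times), tuple(lpfs)))
    return groups


class TestMAECost:
    def test_zero_on_exact_data(self, lqrg_params):
        groups = _noise_free_groups(lqrg_params)
        assert mae_cost("lqrg", lqrg_params, groups) == pytest.approx(0.0, abs=1e-15)

    def test_constant_offset_equals_offset(self, lqrg_params):
        eps = 0.037
        groups = _noise_free_groups(lqrg_params)
        shifted = [
            GroupData(g.name, g.schedule, g.tumor, g.times_months,
                      tuple(np.asarray(g.lpfs) + eps))
            for g in groups
        ]
        assert mae_cost("lqrg", lqrg_params, shifted) == pytest.approx(eps, abs=1e-12)

    def test_generating_parameters_beat_random_perturbations(self, lqrg_params, rng):
        groups = _noise_free_groups(lqrg_params)
        c0 = mae_cost("lqrg", lqrg_params, groups)
        for _ in range(50):
            factors = np.exp(rng.normal(0.0, 0.2, 3))
            perturbed = lqrg_params.replace(
                alpha=lqrg_params.alpha * factors[0],
                beta=lqrg_params.beta * factors[1],
                delta=min(1.0, lqrg_params.delta * factors[2]),
            )
            assert c0 <= mae_cost("lqrg", perturbed, groups)

    def test_order_invariance(self, lqrg_params):
        groups = _noise_free_groups(lqrg_params)
        assert mae_cost("lqrg", lqrg_params, groups) == pytest.approx(
            mae_cost("lqrg", lqrg_params, list(reversed(groups))), abs=1e-15
        )

    def test_empty_data_rejected(self, lqrg_params, group_schedules, group_tumors):
        empty = GroupData("A", group_schedules["A"], group_tumors["A"], (), ())
        with pytest.raises(ValueError):
            mae_cost("lqrg", lqrg_params, [empty])


class TestFitModel:
    def test_alpha_recovery_from_doubled_init(self, lqrg_params):
        groups = _noise_free_groups(lqrg_params)
        init = lqrg_params.replace(alpha=2 * lqrg_params.alpha)
        fit = fit_model("lqrg", groups, init=init, free=("alpha",), seed=0,
                        n_starts=3, max_iter=2000)
        assert fit.converged
        assert fit.params.alpha == pytest.approx(lqrg_params.alpha, rel=0.01)

    def test_determinism_bit_identical(self, lqrg_params):
        groups = _noise_free_groups(lqrg_params)
        init = lqrg_params.replace(alpha=1.7 * lqrg_params.alpha, beta=0.5 * lqrg_params.beta)
        kw = dict(init=init, free=("alpha", "beta"), seed=42, n_starts=4, max_iter=400)
        f1 = fit_model("lqrg", groups, **kw)
        f2 = fit_model("lqrg", groups, **kw)
        assert f1.params == f2.params
        assert f1.cost == f2.cost
        assert f1.start_costs == f2.start_costs

    def test_init_outside_bounds_rejected(self, lqrg_params):
        groups = _noise_free_groups(lqrg_params)
        with pytest.raises(ValueError):
            fit_model("lqrg", groups, free=("alpha",),
                      bounds={"alpha": (1.0, 2.0)})

    def test_unknown_free_parameter_rejected(self, lqrg_params):
        groups = _noise_free_groups(lqrg_params)
        with pytest.raises(ValueError):
            fit_model("lq", groups, free=("sigma2",))

    def test_result_bookkeeping(self, lqrg_params):
        groups = _noise_free_groups(lqrg_params)
        fit = fit_model("lqrg", groups, free=("alpha",), seed=0, n_starts=2,
                        max_iter=200)
        assert fit.k == 1
        assert fit.n_samples == sum(g.n_samples for g in groups)
        assert fit.to_dict()["model"] == "lqrg"


class TestFittingErrors:
    def test_identical_series(self):
        assert fitting_errors([0.5, 0.4], [0.5, 0.4]) == (0.0, 0.0)

    def test_ten_percent_relative(self):
        obs = np.array([0.8, 0.5, 0.2])
        abs_err, rel_err = fitting_errors(1.1 * obs, obs)
        assert rel_err == pytest.approx(10.0, rel=1e-12)
        assert abs_err == pytest.approx(100 * np.mean(0.1 * obs), rel=1e-12)

    def test_hand_worked_three_points(self):
        pred = [0.9, 0.6, 0.25]
        obs = [1.0, 0.5, 0.25]
        abs_err, rel_err = fitting_errors(pred, obs)
        assert abs_err == pytest.approx(100 * (0.1 + 0.1 + 0.0) / 3)
        assert rel_err == pytest.approx(100 * (0.1 / 1.0 + 0.1 / 0.5 + 0.0) / 3)

    def test_zero_observation_makes_relative_undefined(self):
        abs_err, rel_err = fitting_errors([0.1, 0.2], [0.0, 0.2])
        assert abs_err == pytest.approx(5.0)
        assert np.isnan(rel_err)


class TestConfidenceIntervals:
    def test_bootstrap_deterministic_and_contains_point_estimate(self, lqrg_params, rng):
        times = np.arange(2.0, 62.0, 4.0)
        groups = []
        for g in _noise_free_groups(lqrg_params, times):
            noisy = np.clip(np.asarray(g.lpfs) + rng.normal(0, 0.02, len(g.lpfs)), 0, 1)
            groups.append(GroupData(g.name, g.schedule, g.tumor, g.times_months,
                                    tuple(noisy)))
        fit = fit_model("lqrg", groups, free=("alpha",), seed=0, n_starts=2,
                        max_iter=500)
        kw = dict(method="bootstrap", seed=7, n_boot=30,
                  refit_kwargs=dict(max_iter=150))
        ci1 = parameter_confidence_intervals(fit, groups, **kw)
        ci2 = parameter_confidence_intervals(fit, groups, **kw)
        assert ci1 == ci2
        lo, hi = ci1["alpha"]
        assert lo <= fit.params.alpha <= hi

    def test_hessian_width_shrinks_toward_zero_on_noise_free_data(self, lqrg_params):
        groups = _noise_free_groups(lqrg_params)
        init = lqrg_params.replace(alpha=1.05 * lqrg_params.alpha)
        fit = fit_model("lqrg", groups, init=init, free=("alpha",), seed=0,
                        n_starts=1, max_iter=3000)
        ci = parameter_confidence_intervals(fit, groups, method="hessian")
        lo, hi = ci["alpha"]
        # near-perfect fit: surrogate-likelihood curvature explodes, CI collapses
        assert (hi - lo) / fit.params.alpha < 0.05

    def test_unconverged_fit_rejected(self, lqrg_params):
        groups = _noise_free_groups(lqrg_params)
        fit = fit_model("lqrg", groups, free=("alpha",), seed=0, n_starts=1, max_iter=200)
        fit.converged = False
        with pytest.raises(ValueError):
            parameter_confidence_intervals(fit, groups)
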