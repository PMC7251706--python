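"""Surviving fraction, BED and beta_eff identities."""

import math

import numpy as np
import pytest

from lqrg import (
    LQParams,
    LQRGParams,
    bed_lqrg,
    beta_eff,
    build_uniform_schedule,
    lea_catcheside_G,
    log_sf_lq,
    log_sf_lqrg,
    surviving_fraction_lq,
    surviving_fraction_lqrg,
)
from lqrg._units import HOURS_PER_DAY

LN2 = math.log(2.0)


def _hand_exponent(p, schedule, t_hours):
    """Term-by-term oracle for the LQRG log surviving fraction."""
    D = schedule.total_dose_gy
    g_r = lea_catcheside_G(schedule, p.tau_r_h)
    g_s = lea_catcheside_G(schedule, p.tau_s_h)
    T_d = schedule.overall_time_h / HOURS_PER_DAY
    tk_d = p.t_k_h / HOURS_PER_DAY
    return (
        -p.alpha * D
        - p.beta * g_r * D**2
        + 0.5 * p.sigma2 * g_s * D**2
        + LN2 * max(0.0, T_d - tk_d) / p.tau_p_days
        + (LN2 * (t_hours / HOURS_PER_DAY) / p.tau_p_days) ** p.delta
    )


class TestSurvivingFractionLQRG:
    def test_no_dose_no_time_gives_unity(self, lqrg_params):
        # a vanishing dose is represented by a tiny fraction; T <= T_k
        s = build_uniform_schedule(1, 1e-12)
        assert surviving_fraction_lqrg(lqrg_params, s, 0.0) == pytest.approx(1.0, abs=1e-10)

    def test_matches_term_by_term_oracle_on_group_schedule(
        self, lqrg_params, group_schedules
    ):
        t = 12 * 730.5  # 12 months in hours
        for s in group_schedules.values():
            assert log_sf_lqrg(lqrg_params, s, t) == pytest.approx(
                _hand_exponent(lqrg_params, s, t), abs=1e-12
            )

    def test_reduces_to_simple_lq_form_for_acute_fraction(self):
        # sigma^2 -> 0, delta = 1: exponent is -aD - bD^2 + regrowth + linear decay
        p = LQRGParams().replace(sigma2=1e-300, delta=1.0)
        s = build_uniform_schedule(1, 8.0)
        t = 1000.0
        expected = (
            -p.alpha * 8.0
            - p.beta * 64.0
            + LN2 * (t / 24.0) / p.tau_p_days
        )
        assert log_sf_lqrg(p, s, t) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_time(self, lqrg_params, group_schedules):
        s = group_schedules["B"]
        t = np.array([0.0, 100.0, 1000.0, 10000.0])
        sf = surviving_fraction_lqrg(lqrg_params, s, t)
        assert np.all(np.diff(sf) > 0)

    def test_negative_time_rejected(self, lqrg_params, group_schedules):
        with pytest.raises(ValueError):
            surviving_fraction_lqrg(lqrg_params, group_schedules["A"], -1.0)


class TestSurvivingFractionLQ:
    def test_quadratic_term_uses_complete_repair_g(self, lq_params):
        # 30 uniform fractions: the quadratic term equals beta*G*D^2 with G = 1/30
        s = build_uniform_schedule(30, 2.1, weekday_only=True)
        D = s.total_dose_gy
        expected_quad = lq_params.beta * (1.0 / 30.0) * D**2
        base = log_sf_lq(lq_params, s, 0.0)
        no_beta = log_sf_lq(lq_params.replace(beta=1e-300), s, 0.0)
        assert (no_beta - base) == pytest.approx(expected_quad, rel=1e-9)
        assert round(1.0 / 30.0, 3) == 0.033

    def test_time_doubling_adds_linear_regrowth(self, lq_params):
        s = build_uniform_schedule(10, 2.0)
        t = 2000.0
        delta = log_sf_lq(lq_params, s, 2 * t) - log_sf_lq(lq_params, s, t)
        assert delta == pytest.approx(LN2 * (t / 24.0) / lq_params.tau_p_days, rel=1e-12)

    def test_lqrg_degenerates_to_lq_with_matched_parameters(self):
        # sigma^2 -> 0, delta = 1, tau_R -> 0+ turns LQRG into classical LQ
        lq = LQParams()
        lqrg = LQRGParams().replace(
            sigma2=1e-300,
            delta=1.0,
            tau_r_h=1e-3,
            alpha=lq.alpha,
            beta=lq.beta,
            tau_p_days=lq.tau_p_days,
            t_k_h=lq.t_k_h,
        )
        s = build_uniform_schedule(25, 2.5, weekday_only=True)
        for t in (0.0, 500.0, 5000.0):
            assert log_sf_lqrg(lqrg, s, t) == pytest.approx(
                log_sf_lq(lq, s, t), abs=1e-12
            )


class TestBED:
    def test_single_acute_dose_classical_bed(self):
        p = LQRGParams().replace(sigma2=1e-300)
        s = build_uniform_schedule(1, 10.0)  # T = 0 <= T_k
        assert bed_lqrg(p, s) == pytest.approx(10.0 + p.beta * 100.0 / p.alpha, rel=1e-12)

    def test_regrowth_clamped_before_lag_time(self, lqrg_params):
        short = build_uniform_schedule(5, 2.0)  # T = 96 h < T_k = 533.5 h
        p_long_lag = lqrg_params.replace(t_k_h=5000.0)
        assert bed_lqrg(lqrg_params, short) == pytest.approx(
            bed_lqrg(p_long_lag, short), rel=1e-12
        )

    def test_bed_ordering_across_groups(self, lqrg_params, group_schedules):
        beds = {k: bed_lqrg(lqrg_params, s) for k, s in group_schedules.items()}
        assert beds["A"] < beds["B"] < beds["C"]

    def test_consistency_with_log_sf_at_t_zero(self, lqrg_params, group_schedules):
        for s in group_schedules.values():
            assert -log_sf_lqrg(lqrg_params, s, 0.0) == pytest.approx(
                lqrg_params.alpha * bed_lqrg(lqrg_params, s), abs=1e-10
            )


class TestBetaEff:
    def test_single_acute_fraction_reduces_to_beta(self):
        p = LQRGParams().replace(sigma2=1e-300)
        s = build_uniform_schedule(1, 2.0)
        res = beta_eff(p, s)
        assert res.beta_eff == pytest.approx(p.beta, rel=1e-12)
        assert res.alpha_over_beta_eff == pytest.approx(p.alpha / p.beta, rel=1e-12)

    def test_full_recovery_limit_algebra(self, lqrg_params):
        # tau -> inf makes both G factors 1: beta_eff = n*beta - (n/2)*sigma^2
        p = lqrg_params.replace(tau_r_h=1e9, tau_s_h=1e9)
        n = 4
        s = build_uniform_schedule(n, 2.0)
        expected = n * p.beta - 0.5 * n * p.sigma2
        assert beta_eff(p, s).beta_eff == pytest.approx(expected, rel=1e-6)

    def test_recast_identity_on_random_uniform_schedules(self, lqrg_params, rng):
        # -beta_eff*D*d must equal the combined quadratic exponent terms
        for _ in range(20):
            n = int(rng.integers(2, 40))
            d = float(rng.uniform(1.0, 4.0))
            s = build_uniform_schedule(n, d, float(rng.uniform(6.0, 48.0)))
            D = s.total_dose_gy
            g_r = lea_catcheside_G(s, lqrg_params.tau_r_h)
            g_s = lea_catcheside_G(s, lqrg_params.tau_s_h)
            quad = -lqrg_params.beta * g_r * D**2 + 0.5 * lqrg_params.sigma2 * g_s * D**2
            assert -beta_eff(lqrg_params, s).beta_eff * D * d == pytest.approx(
                quad, abs=1e-10
            )

    def test_negative_beta_eff_flagged_not_raised(self):
        # resensitization dominating repair makes beta_eff <= 0
        p = LQRGParams().replace(beta=1e-6, sigma2=1.0)
        s = build_uniform_schedule(10, 2.0)
        res = beta_eff(p, s)
        assert res.beta_eff < 0
        assert res.alpha_over_beta_eff is None
        assert not res.defined


class TestParams:
    def test_defaults_round_trip_through_json_dict(self):
        for cls in (LQRGParams, LQParams):
            p = cls()
            assert cls.from_dict(p.to_dict()) == p

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            LQRGParams(alpha=-0.1)
        with pytest.raises(ValueError):
            LQRGParams(delta=1.5)
        with pytest.raises(ValueError):
            LQParams(tau_p_days=0.0)
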