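"""MO2 extraction, exponential metabolic model, COT and blocking
correction."""

import math

import numpy as np
import pytest

from dragtag.errors import DomainError, InsufficientDataError
from dragtag.respirometry import (
    BlockingContext,
    MetabolicModel,
    MO2Sample,
    O2Trace,
    correct_speed,
    cot,
    cot_min,
    fit_metabolic_model,
    mo2_from_trace,
    uopt,
)


def linear_trace(slope, mass=0.65, volume=127.0, speed=0.5, n=31, noise=0.0, seed=0):
    t = np.linspace(0.0, 0.5, n)
    y = 8.0 + slope * t
    if noise:
        y = y + np.random.default_rng(seed).normal(0.0, noise, n)
    return O2Trace(t, y, volume, mass, speed)


class TestMO2FromTrace:
    def test_exact_linear_trace_arithmetic(self):
        # slope -0.5 mg/L/h in a 127 L chamber with a 0.65 kg fish:
        # MO2 = 0.5 * (127 - 0.65) / 0.65
        s = mo2_from_trace(linear_trace(-0.5))
        assert s.mo2 == pytest.approx(0.5 * 126.35 / 0.65, rel=1e-9)
        assert s.mo2 == pytest.approx(97.2, abs=0.1)
        assert s.r2 == pytest.approx(1.0)
        assert s.accepted

    def test_null_slope_rejected_under_noise(self):
        rejected = 0
        n_sim = 500
        for seed in range(n_sim):
            tr = linear_trace(0.0, noise=0.05, seed=seed)
            s = mo2_from_trace(tr, min_r2=0.85)
            rejected += not s.accepted
        assert rejected / n_sim >= 0.90

    def test_positive_slope_rejected(self):
        assert not mo2_from_trace(linear_trace(+0.5)).accepted

    def test_acceptance_filter_consistency(self):
        # an accepted sample always satisfies the filter it was tested at
        for seed in range(50):
            s = mo2_from_trace(linear_trace(-0.4, noise=0.05, seed=seed), min_r2=0.85)
            if s.accepted:
                assert s.r2 >= 0.85 and s.p_value < 0.05

    def test_too_few_samples(self):
        t = np.linspace(0, 0.5, 4)
        tr = O2Trace(t, 8.0 - 0.5 * t, 127.0, 0.65, 0.5)
        with pytest.raises(InsufficientDataError):
            mo2_from_trace(tr)

    def test_blocking_context_corrects_reported_speed(self):
        ctx = BlockingContext(fish_area=150.5, tunnel_area=602.0)
        s = mo2_from_trace(linear_trace(-0.5, speed=0.6), ctx=ctx)
        assert s.speed == pytest.approx(0.6 * (1 + ctx.epsilon_s))


class TestBlockingCorrection:
    def test_quarter_area_ratio_closed_form(self):
        # A_O/A_T = 0.25 with tau=0.8, lam=0.5: eps = 0.4 * 0.25^1.5 = 0.05
        ctx = BlockingContext(fish_area=25.0, tunnel_area=100.0)
        assert ctx.epsilon_s == pytest.approx(0.05)
        assert correct_speed(1.0, ctx) == pytest.approx(1.05)

    def test_zero_fish_area_no_correction(self):
        ctx = BlockingContext(fish_area=0.0, tunnel_area=100.0)
        assert correct_speed(0.7, ctx) == 0.7

    def test_epsilon_monotone_in_fish_area(self):
        eps = [
            BlockingContext(fish_area=a, tunnel_area=100.0).epsilon_s
            for a in (10.0, 20.0, 40.0, 80.0)
        ]
        assert all(a < b for a, b in zip(eps, eps[1:]))

    def test_order_preserving(self):
        ctx = BlockingContext(fish_area=150.5, tunnel_area=17671.0)
        assert correct_speed(0.3, ctx) < correct_speed(0.31, ctx)

    def test_fish_larger_than_tunnel_rejected(self):
        with pytest.raises(DomainError):
            BlockingContext(fish_area=120.0, tunnel_area=100.0)


class TestMetabolicModel:
    def test_exact_recovery(self, exact_mo2_samples):
        m = fit_metabolic_model(exact_mo2_samples)
        assert m.smr == pytest.approx(40.58, rel=1e-6)
        assert m.c == pytest.approx(1.4706, rel=1e-6)
        assert m.fit_r2 == pytest.approx(1.0)

    def test_single_top_speed_point_incorporated(self, control_model):
        # a heavily burdened fish managing only one extra speed still fits
        speeds = [0.3, 0.4, 0.5, 0.6]
        samples = [
            MO2Sample(u, control_model.smr * math.exp(control_model.c * u), 1.0, 1e-9)
            for u in speeds
        ]
        m = fit_metabolic_model(samples)
        assert m.smr == pytest.approx(control_model.smr, rel=1e-6)

    def test_rejected_samples_excluded(self, exact_mo2_samples):
        bad = MO2Sample(0.55, 1e4, 0.2, 0.9, accepted=False)
        m = fit_metabolic_model(list(exact_mo2_samples) + [bad])
        assert m.smr == pytest.approx(40.58, rel=1e-6)

    def test_insufficient_speeds(self):
        samples = [MO2Sample(0.3, 60.0, 1.0, 1e-9), MO2Sample(0.5, 80.0, 1.0, 1e-9)]
        with pytest.raises(InsufficientDataError):
            fit_metabolic_model(samples)


class TestDerivedEndpoints:
    def test_uopt_is_reciprocal_c(self, control_model):
        assert uopt(control_model) == pytest.approx(1 / 1.4706)
        assert uopt(control_model) == pytest.approx(0.68, abs=0.001)

    def test_uopt_halves_when_c_doubles(self, control_model):
        doubled = MetabolicModel(control_model.smr, 2 * control_model.c, 1.0)
        assert uopt(doubled) == pytest.approx(uopt(control_model) / 2)

    def test_uopt_matches_grid_minimiser(self, control_model):
        grid = np.arange(0.01, 2.0, 1e-4)
        cots = [cot(control_model, u) for u in grid]
        u_star = grid[int(np.argmin(cots))]
        assert abs(u_star - uopt(control_model)) <= 1e-4

    def test_cotmin_closed_form(self, control_model):
        # SMR * c * e / 3.6 for the control curve
        assert cot_min(control_model) == pytest.approx(
            40.58 * 1.4706 * math.e / 3.6, rel=1e-12
        )
        assert cot_min(control_model) == pytest.approx(45.06, abs=0.01)

    def test_cotmin_equals_cot_at_uopt(self, control_model):
        assert cot_min(control_model) == pytest.approx(
            cot(control_model, uopt(control_model)), rel=1e-12
        )

    def test_cotmin_linear_in_smr(self, control_model):
        doubled = MetabolicModel(2 * control_model.smr, control_model.c, 1.0)
        assert cot_min(doubled) == pytest.approx(2 * cot_min(control_model))

    def test_cot_unique_minimum_and_divergence_at_zero(self, control_model):
        u0 = uopt(control_model)
        for u in (0.1, 0.3, u0 / 2, 2 * u0, 1.5):
            if abs(u - u0) > 1e-9:
                assert cot(control_model, u) > cot_min(control_model)
        assert cot(control_model, 1e-6) > 1e5

    def test_cot_convex_on_grid(self, control_model):
        u = np.linspace(0.05, 3.0, 400)
        y = np.array([cot(control_model, v) for v in u])
        second = np.diff(y, 2)
        assert (second > -1e-9).all()

    def test_degenerate_c_rejected(self):
        flat = MetabolicModel(smr=40.0, c=-0.5, fit_r2=1.0)
        with pytest.raises(DomainError):
            uopt(flat)
        with pytest.raises(DomainError):
            cot_min(flat)


class TestCohortRecovery:
    def test_cohort_parameter_recovery_under_noise(self):
        """Simulated eels with 10% multiplicative MO2 noise over seven
        speed steps: the cohort-pooled SMR comes back within 10% and
        U_opt within 5% of the generating values."""
        rng = np.random.default_rng(42)
        speeds = np.round(np.arange(0.3, 0.95, 0.1), 10)
        n = 200
        rec_smr, rec_uopt, true_smr, true_uopt = [], [], [], []
        for _ in range(n):
            smr = max(rng.normal(40.58, 18.24), 5.0)
            u0 = max(rng.normal(0.68, 0.085), 0.3)
            c = 1.0 / u0
            mo2 = smr * np.exp(c * speeds) * (1 + 0.10 * rng.standard_normal(7))
            samples = [
                MO2Sample(float(u), float(m), 1.0, 1e-9)
                for u, m in zip(speeds, mo2)
                if m > 0
            ]
            model = fit_metabolic_model(samples)
            rec_smr.append(model.smr)
            rec_uopt.append(uopt(model))
            true_smr.append(smr)
            true_uopt.append(u0)
        assert abs(np.mean(rec_smr) - np.mean(true_smr)) / np.mean(true_smr) < 0.10
        assert abs(np.mean(rec_uopt) - np.mean(true_uopt)) / np.mean(true_uopt) < 0.05
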