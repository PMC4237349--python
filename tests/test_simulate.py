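"""Synthetic-cohort generators: determinism, round-trips and
end-to-end parameter recovery."""

import numpy as np
import pytest

from dragtag.errors import ConfigError
from dragtag.impairment import UCRIT_COEFFS, fit_impairment, percent_effects
from dragtag.kinematics import (
    LandmarkTrack,
    amplitude,
    strouhal,
    tailbeat_frequency,
)
from dragtag.respirometry import fit_metabolic_model, mo2_from_trace, uopt
from dragtag.simulate import (
    CohortConfig,
    condition_label,
    generate_cohort,
    generate_kinematics,
    generate_o2_traces,
    generate_ucrit_log,
    treated_ucrit,
    true_effects,
)
from dragtag.ucrit import ucrit_from_steps

import pandas as pd


ZERO_NOISE = dict(
    mo2_cv=0.0,
    o2_trace_noise=0.0,
    kinematic_noise=0.0,
    effect_sd=0.0,
    ucrit_noise_sd=0.0,
)


class TestGenerateCohort:
    def test_deterministic_under_seed(self):
        a = generate_cohort(CohortConfig(seed=4))
        b = generate_cohort(CohortConfig(seed=4))
        assert a == b

    def test_zero_sd_collapses_to_means(self):
        cfg = CohortConfig(
            body_mass_sd=0, body_length_sd=0, fish_area_sd=0,
            smr_sd=0, uopt_sd=0, ucrit_baseline_sd=0, seed=1,
        )
        eels = generate_cohort(cfg)
        assert all(e.smr == cfg.smr_mean for e in eels)
        assert all(e.uopt == cfg.uopt_mean for e in eels)

    def test_cohort_mean_smr_near_population_value(self):
        # sample mean over many seeds stays within 2 population SEs
        means = [
            np.mean([e.smr for e in generate_cohort(CohortConfig(seed=s))])
            for s in range(100)
        ]
        se = 6.45  # published SE at n = 8
        assert abs(np.mean(means) - 40.58) < 2 * se / np.sqrt(100)

    def test_all_parameters_positive(self):
        for e in generate_cohort(CohortConfig(seed=2)):
            assert min(e.body_mass, e.smr, e.uopt, e.ucrit_baseline) > 0
            assert e.c > 0

    def test_impossible_truncation_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(smr_mean=-1.0)


class TestO2Traces:
    def test_noise_free_round_trip(self):
        cfg = CohortConfig(seed=3, **ZERO_NOISE)
        eel = generate_cohort(cfg)[0]
        traces = generate_o2_traces(eel, [0.3, 0.5, 0.7], config=cfg)
        for tr in traces:
            s = mo2_from_trace(tr)
            assert s.accepted
            expected = eel.smr * np.exp(eel.c * tr.tunnel_speed)
            assert s.mo2 == pytest.approx(expected, rel=1e-9)

    def test_large_drag_raises_cotmin(self):
        cfg = CohortConfig(seed=3, **ZERO_NOISE)
        eel = generate_cohort(cfg)[0]
        speeds = [0.3, 0.4, 0.5]
        ctl = [mo2_from_trace(t) for t in generate_o2_traces(eel, speeds, config=cfg)]
        big = [
            mo2_from_trace(t)
            for t in generate_o2_traces(eel, speeds, drag=0.2, config=cfg)
        ]
        from dragtag.respirometry import cot_min

        m_ctl = fit_metabolic_model(ctl)
        m_big = fit_metabolic_model(big)
        assert cot_min(m_big) > cot_min(m_ctl)

    def test_trace_quality_matches_protocol(self):
        # default noise level puts the regression r^2 near the
        # experimental 0.857 +/- 2.5
        cfg = CohortConfig(seed=6)
        eel = generate_cohort(cfg)[0]
        rng = np.random.default_rng(8)
        r2s = []
        for _ in range(30):
            for tr in generate_o2_traces(eel, [0.4, 0.6, 0.8], config=cfg, rng=rng):
                r2s.append(mo2_from_trace(tr, min_r2=0.85).r2)
        assert np.mean(r2s) == pytest.approx(0.857, abs=0.05)


class TestUcritLogs:
    def test_noise_free_round_trip(self):
        cfg = CohortConfig(seed=5, **ZERO_NOISE)
        eel = generate_cohort(cfg)[0]
        log = generate_ucrit_log(eel, 0.0, "A", cfg)
        res = ucrit_from_steps(log.step_speed_m_s, log.completed_min)
        assert res.u_crit == pytest.approx(eel.ucrit_baseline, abs=1e-9)

    def test_drag_reduces_ucrit_stochastically(self):
        cfg = CohortConfig(seed=5)
        eels = generate_cohort(cfg)
        rng = np.random.default_rng(10)
        diffs = []
        for eel in eels:
            u0 = treated_ucrit(eel, cfg, 0.0, "A", rng)
            u2 = treated_ucrit(eel, cfg, 0.2, "A", rng)
            diffs.append(u0 - u2)
        assert np.mean(diffs) > 0

    def test_end_to_end_impairment_recovery(self):
        """Cohort at the three dummy drags, effects re-measured from
        generated step logs, refit within 3 SE of generating values."""
        cfg = CohortConfig(seed=17)
        eels = generate_cohort(cfg)
        rng = np.random.default_rng(18)

        def measured(drag):
            rows = []
            for eel in eels:
                log = generate_ucrit_log(eel, drag, "A", cfg, rng=rng)
                res = ucrit_from_steps(log.step_speed_m_s, log.completed_min)
                rows.append((eel.eel_id, res.u_crit))
            return pd.DataFrame(
                {"eel_id": [r[0] for r in rows], "ucrit": [r[1] for r in rows],
                 "cot_min": 55.0}
            )

        ctrl = measured(0.0)
        effects = []
        for d in (0.05, 0.1, 0.2):
            effects.extend(percent_effects(ctrl, measured(d), d))
        fit = fit_impairment(effects, "ucrit")
        assert abs(fit.lin_coeff - UCRIT_COEFFS[0]) < 3 * fit.lin_se
        assert abs(fit.quad_coeff - UCRIT_COEFFS[1]) < 3 * fit.quad_se


class TestKinematicsGenerator:
    def test_noise_free_frequency_recovery(self):
        cfg = CohortConfig(seed=7, **ZERO_NOISE)
        eel = generate_cohort(cfg)[0]
        df = generate_kinematics(eel, [0.65], config=cfg, duration=20.0)
        tail = df[df.site == "tail"]
        tr = LandmarkTrack(
            tail.time_s.to_numpy(), tail.lateral_m.to_numpy(), 30.0, 0.65, "tail"
        )
        f_true = 1.26 + 2.15 * 0.65
        assert tailbeat_frequency(tr, (0.0, 20.0)) == pytest.approx(f_true, abs=0.02)

    def test_control_strouhal_in_printed_band(self):
        cfg = CohortConfig(seed=7)
        eel = generate_cohort(cfg)[0]
        df = generate_kinematics(
            eel, [0.65], config=cfg, rng=np.random.default_rng(9), duration=20.0
        )
        tail = df[df.site == "tail"]
        tr = LandmarkTrack(
            tail.time_s.to_numpy(), tail.lateral_m.to_numpy(), 30.0, 0.65, "tail"
        )
        st = strouhal(
            amplitude(tr, (0.0, 20.0)) / 100,
            tailbeat_frequency(tr, (0.0, 20.0)),
            0.65,
        )
        assert 0.32 - 0.12 <= st <= 0.32 + 0.12

    def test_site_b_strouhal_exceeds_control(self):
        cfg = CohortConfig(seed=7)
        eel = generate_cohort(cfg)[0]
        rng = np.random.default_rng(11)

        def st_for(drag, site):
            df = generate_kinematics(
                eel, [0.65], drag, site, cfg, rng, duration=20.0
            )
            tail = df[df.site == "tail"]
            tr = LandmarkTrack(
                tail.time_s.to_numpy(), tail.lateral_m.to_numpy(), 30.0, 0.65
            )
            return strouhal(
                amplitude(tr, (0.0, 20.0)) / 100,
                tailbeat_frequency(tr, (0.0, 20.0)),
                0.65,
            )

        assert st_for(0.1, "B") > st_for(0.0, "A")

    def test_condition_mapping(self):
        assert condition_label(0.0, "A") == "control1"
        assert condition_label(0.1, "B") == "intermediate_B"
        assert condition_label(0.2, "A") == "large_A"
        assert condition_label(0.06, "A") == "small_A"


class TestEffectModel:
    def test_effects_zero_at_zero_drag(self):
        cfg = CohortConfig()
        assert true_effects(cfg, 0.0, "A") == (0.0, 0.0)
        assert true_effects(cfg, 0.0, "B") == (0.0, 0.0)

    def test_site_b_adds_increments(self):
        cfg = CohortConfig()
        ea_u, ea_c = true_effects(cfg, 0.1, "A")
        eb_u, eb_c = true_effects(cfg, 0.1, "B")
        assert eb_u - ea_u == pytest.approx(15.0)
        assert eb_c - ea_c == pytest.approx(63.0)
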