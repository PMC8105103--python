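"""Linear-quadratic kill, impulse/window fractions and course simulation."""

import numpy as np
import pytest

from lungrt import (
    CompartmentParams,
    Fraction,
    FractionationPlan,
    InputError,
    RadiosensitivityParams,
    TumorState,
    apply_fraction_impulse,
    integrate_fraction_window,
    lq_survival,
    simulate_course,
    simulate_mcm,
)


class TestLQSurvival:
    def test_zero_dose_full_survival(self):
        assert lq_survival(0.0, 0.194, 0.063) == 1.0

    def test_conventional_two_gray(self):
        expected = np.exp(-(0.194 * 2 + 0.063 * 4))
        assert lq_survival(2.0, 0.194, 0.063) == pytest.approx(expected, rel=1e-12)

    def test_sbrt_scale_dose(self):
        # 12.5 Gy = 50 Gy in 5 fractions
        expected = np.exp(-(0.3705 * 12.5 + 0.02335 * 156.25))
        assert lq_survival(12.5, 0.3705, 0.02335) == pytest.approx(expected, rel=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(InputError):
            lq_survival(-1.0, 0.1, 0.01)


class TestImpulse:
    def test_zero_dose_identity(self, rs_params):
        s = TumorState(V=[100.0, 50.0], V_Q=20.0, V_ND=5.0)
        hit = apply_fraction_impulse(s, 0.0, rs_params)
        np.testing.assert_allclose(hit.to_vector(), s.to_vector())

    def test_nondividing_compartment_untouched(self, rs_params):
        s = TumorState(V=[0.0, 0.0], V_Q=0.0, V_ND=42.0)
        hit = apply_fraction_impulse(s, 20.0, rs_params)
        np.testing.assert_allclose(hit.to_vector(), s.to_vector())

    def test_componentwise_survival_products(self, rs_params):
        s = TumorState(V=[100.0, 100.0], V_Q=100.0, V_ND=10.0)
        hit = apply_fraction_impulse(s, 2.0, rs_params)
        s1 = np.exp(-(0.194 * 2 + 0.063 * 4))
        s2 = np.exp(-(0.3705 * 2 + 0.02335 * 4))
        sq = np.exp(-(0.3 * 2 + 0.15 * 4))
        np.testing.assert_allclose(hit.V, [100 * s1, 100 * s2], rtol=1e-12)
        assert hit.V_Q == pytest.approx(100 * sq, rel=1e-12)
        assert hit.V_ND == 10.0

    def test_dimension_mismatch(self, rs_params):
        with pytest.raises(InputError):
            apply_fraction_impulse(TumorState(V=[1.0]), 2.0, rs_params)


class TestWindow:
    def test_matched_window_reproduces_lq(self, growth_off, rs_params):
        # at duration 2, the constant-rate exponent alpha*D + 2 beta D^2/t_R
        # collapses to the LQ exponent alpha*D + beta*D^2
        s = TumorState(V=[100.0, 100.0], V_Q=100.0, V_ND=10.0)
        out = integrate_fraction_window(s, 2.0, 2.0, growth_off, rs_params)
        ref = apply_fraction_impulse(s, 2.0, rs_params)
        np.testing.assert_allclose(out.to_vector(), ref.to_vector(), rtol=1e-8)

    @pytest.mark.parametrize("duration", [0.5, 1.0, 2.0, 4.0])
    def test_constant_rate_exponent(self, growth_off, rs_params, duration):
        dose = 2.0
        s = TumorState(V=[100.0, 100.0], V_Q=100.0, V_ND=10.0)
        out = integrate_fraction_window(s, dose, duration, growth_off, rs_params)
        expo1 = 0.194 * dose + 2 * 0.063 * dose**2 / duration
        assert out.V[0] == pytest.approx(100 * np.exp(-expo1), rel=1e-8)
        assert out.V_ND == pytest.approx(10.0, rel=1e-12)

    def test_linear_term_is_rate_independent(self, rs_params):
        p = CompartmentParams(
            a=[0.0, 0.0], K=[1.0, 1.0], p_Qm=[0.0, 0.0], p_mQ=[0.0, 0.0],
            p_mND=[0.0, 0.0], p_QND=0.0, eta=0.0,
        )
        rs = RadiosensitivityParams(
            alpha=[0.194, 0.3705], beta=[0.0, 0.0], alpha_Q=0.3, beta_Q=0.0
        )
        s = TumorState(V=[50.0, 50.0], V_Q=50.0)
        for duration in (0.5, 2.0, 8.0):
            out = integrate_fraction_window(s, 4.0, duration, p, rs)
            assert out.V[0] == pytest.approx(50 * np.exp(-0.194 * 4), rel=1e-8)

    def test_zero_duration_rejected(self, growth_off, rs_params):
        with pytest.raises(InputError):
            integrate_fraction_window(
                TumorState(V=[1.0, 1.0]), 2.0, 0.0, growth_off, rs_params
            )


def one_shot_plan(dose, at=0.0):
    return FractionationPlan([Fraction(start_time=at, dose=dose)])


class TestCourse:
    def test_empty_plan_matches_pure_growth(self, mcm_params, rs_params, seed_state):
        plan = FractionationPlan([])
        traj, result = simulate_course(
            mcm_params, rs_params, plan, seed_state, followup_days=20.0
        )
        ref = simulate_mcm(mcm_params, seed_state, traj.times)
        np.testing.assert_allclose(traj.states, ref.states, rtol=1e-9)
        grow = ref.states[-1, 0] / ref.states[0, 0]
        assert result.ratio["T1"] == pytest.approx(grow, rel=1e-9)

    def test_single_fraction_growth_off_gives_lq_ratios(self, growth_off, rs_params):
        init = TumorState(V=[100.0, 100.0], V_Q=100.0, V_ND=10.0)
        _, result = simulate_course(
            growth_off, rs_params, one_shot_plan(10.0), init
        )
        assert result.ratio["T1"] == pytest.approx(
            float(lq_survival(10.0, 0.194, 0.063)), rel=1e-9
        )
        assert result.ratio["T2"] == pytest.approx(
            float(lq_survival(10.0, 0.3705, 0.02335)), rel=1e-9
        )
        assert result.ratio["Q"] == pytest.approx(
            float(lq_survival(10.0, 0.3, 0.15)), rel=1e-9
        )
        assert result.ratio["ND"] == 1.0

    @pytest.mark.parametrize("n", [1, 4, 5, 8, 30])
    def test_fractionation_sparing_closed_form(self, growth_off, rs_params, n):
        # splitting dose D into n impulses gives exp(-alpha D - beta D^2 / n)
        D = 60.0
        plan = FractionationPlan(
            [Fraction(start_time=float(i), dose=D / n) for i in range(n)]
        )
        init = TumorState(V=[100.0, 100.0], V_Q=100.0)
        _, result = simulate_course(growth_off, rs_params, plan, init)
        assert result.ratio["T1"] == pytest.approx(
            np.exp(-(0.194 * D + 0.063 * D**2 / n)), rel=1e-9
        )
        assert result.ratio["T2"] == pytest.approx(
            np.exp(-(0.3705 * D + 0.02335 * D**2 / n)), rel=1e-9
        )

    def test_ratio_nonincreasing_in_dose(self, growth_off, rs_params):
        init = TumorState(V=[100.0, 100.0], V_Q=10.0)
        last = np.inf
        for dose_per_fraction in (0.5, 1.0, 2.0, 4.0, 8.0):
            plan = FractionationPlan(
                [Fraction(float(i), dose_per_fraction) for i in range(5)]
            )
            _, result = simulate_course(growth_off, rs_params, plan, init)
            assert result.ratio["T1"] < last
            last = result.ratio["T1"]

    def test_nd_volume_never_reduced(self, mcm_params, rs_params, seed_state):
        plan = FractionationPlan([Fraction(float(i), 8.0) for i in range(5)])
        traj, _ = simulate_course(
            mcm_params, rs_params, plan, seed_state, run_in_days=10.0
        )
        # across every impulse jump (duplicated sample time) ND is unchanged
        for e in traj.event_log:
            i = int(np.argmin(np.abs(traj.times - e.time)))
            assert traj.times[i + 1] - traj.times[i] < 1e-6  # the jump pair
            assert traj.states[i + 1, 3] == pytest.approx(
                traj.states[i, 3], rel=1e-12
            )
            # while the active compartments do drop
            assert traj.states[i + 1, 0] < traj.states[i, 0]

    def test_course_composition(self, mcm_params, rs_params, seed_state):
        plan = FractionationPlan([Fraction(0.0, 5.0), Fraction(1.0, 5.0)])
        _, full = simulate_course(mcm_params, rs_params, plan, seed_state)
        # same course as two single-fraction legs
        traj1, _ = simulate_course(
            mcm_params, rs_params, one_shot_plan(5.0), seed_state, followup_days=1.0
        )
        mid = traj1.final_state
        _, second = simulate_course(mcm_params, rs_params, one_shot_plan(5.0), mid)
        np.testing.assert_allclose(
            [second.post[k] for k in ("T1", "T2", "Q", "ND")],
            [full.post[k] for k in ("T1", "T2", "Q", "ND")],
            rtol=1e-9,
        )

    def test_window_course_runs(self, mcm_params, rs_params, seed_state):
        plan = FractionationPlan(
            [Fraction(float(i), 2.0, duration=0.01) for i in range(3)]
        )
        _, result = simulate_course(
            mcm_params, rs_params, plan, seed_state, mode="window", run_in_days=5.0
        )
        assert 0 < result.ratio["T1"] < 1

    def test_window_mode_needs_durations(self, mcm_params, rs_params, seed_state):
        with pytest.raises(InputError):
            simulate_course(
                mcm_params, rs_params, one_shot_plan(2.0), seed_state, mode="window"
            )

    def test_eval_day_left_limit(self, mcm_params, rs_params, seed_state):
        # a fraction fires exactly at the evaluation instant: the ratio uses
        # the state just before it
        plan = FractionationPlan([Fraction(0.0, 2.0), Fraction(1.0, 2.0)])
        _, at_eval = simulate_course(
            mcm_params, rs_params, plan, seed_state, run_in_days=5.0, eval_day=1.0
        )
        _, pre_only = simulate_course(
            mcm_params, rs_params, one_shot_plan(2.0), seed_state,
            run_in_days=5.0, followup_days=1.0,
        )
        assert at_eval.post["T1"] == pytest.approx(pre_only.post["T1"], rel=1e-9)

    def test_invalid_inputs(self, mcm_params, rs_params, seed_state):
        with pytest.raises(InputError):
            simulate_course(
                mcm_params, rs_params, one_shot_plan(2.0), seed_state, mode="laser"
            )
        with pytest.raises(InputError):
            simulate_course(
                mcm_params, rs_params, one_shot_plan(2.0), seed_state, eval_day=-1.0
            )
        with pytest.raises(InputError):
            simulate_course(
                mcm_params, rs_params, one_shot_plan(2.0, at=-3.0), seed_state
            )


class TestPlanContainer:
    def test_overlap_and_ordering_rejected(self):
        with pytest.raises(InputError):
            FractionationPlan([Fraction(1.0, 2.0), Fraction(0.5, 2.0)])
        with pytest.raises(InputError):
            FractionationPlan([Fraction(0.0, 2.0, duration=1.0), Fraction(0.5, 2.0)])

    def test_summary_properties(self):
        plan = FractionationPlan([Fraction(0.0, 2.0), Fraction(1.0, 3.0)])
        assert plan.n_fractions == 2
        assert plan.total_dose == 5.0
        assert plan.course_length == 1.0

    def test_dict_round_trip(self):
        plan = FractionationPlan([Fraction(0.0, 2.0), Fraction(1.0, 3.0)], label="x")
        back = FractionationPlan.from_dict(plan.to_dict())
        assert back.to_dict() == plan.to_dict()

    def test_result_json(self, growth_off, rs_params, tmp_path):
        init = TumorState(V=[100.0, 100.0], V_Q=10.0, V_ND=5.0)
        _, result = simulate_course(growth_off, rs_params, one_shot_plan(10.0), init)
        path = tmp_path / "result.json"
        result.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["treatment_ratio"]["ND"] == 1.0
        assert data["total_dose_gy"] == 10.0
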