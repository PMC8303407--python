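"""Closed-form during- and post-dialysis solutions."""

import numpy as np
import pytest

from ureakin import (
    OdeCoefficients,
    PatientParameters,
    TimeDomainError,
    TreatmentParameters,
    compartment_volumes,
    concentration_during,
    concentration_post,
    during_constants,
    ode_coefficients,
    post_constants,
    resolve_treatment,
    simulate_timeline,
)


class TestDuringConstants:
    def test_sum_to_initial_concentration(self, standard_patient, standard_treatment):
        c = during_constants(standard_patient, standard_treatment)
        assert c.c1 + c.c2 + c.particular == pytest.approx(0.80, rel=1e-9)

    def test_zero_state_stays_zero(self, standard_treatment):
        patient = PatientParameters(
            v_ex0=14400.0, v_in0=21600.0, eps=None, c_s=0.0, s_prod=0.0, ah=500.0
        )
        c = during_constants(patient, standard_treatment)
        assert c.c1 == 0.0 and c.c2 == 0.0

    def test_root_relabelling_is_a_symmetry(self, standard_patient, standard_treatment):
        """Swapping (lambda1, lambda2) swaps (C1, C2) and leaves Cex alone."""
        co = ode_coefficients(standard_patient, standard_treatment)
        swapped = OdeCoefficients(
            alpha=co.alpha, beta=co.beta, gamma=co.gamma,
            lambda1=co.lambda2, lambda2=co.lambda1,
        )
        c = during_constants(standard_patient, standard_treatment, co)
        cs = during_constants(standard_patient, standard_treatment, swapped)
        assert cs.c1 == pytest.approx(c.c2, rel=1e-12)
        assert cs.c2 == pytest.approx(c.c1, rel=1e-12)
        t = np.linspace(0.0, 240.0, 9)
        ex1, in1 = concentration_during(
            t, standard_patient, standard_treatment, co, c
        )
        ex2, in2 = concentration_during(
            t, standard_patient, standard_treatment, swapped, cs
        )
        np.testing.assert_allclose(ex2, ex1, rtol=1e-12)
        np.testing.assert_allclose(in2, in1, rtol=1e-12)


class TestConcentrationDuring:
    def test_initial_condition(self, standard_patient, standard_treatment):
        c_ex, c_in = concentration_during(0.0, standard_patient, standard_treatment)
        assert c_ex == pytest.approx(80.0, abs=1e-9)
        assert c_in == pytest.approx(80.0, abs=1e-9)

    def test_extracellular_drains_faster(self, standard_patient, standard_treatment):
        for t in (30.0, 120.0, 240.0):
            c_ex, c_in = concentration_during(t, standard_patient, standard_treatment)
            assert c_ex < c_in < 80.0

    def test_domain_errors(self, standard_patient, standard_treatment):
        with pytest.raises(TimeDomainError):
            concentration_during(-1.0, standard_patient, standard_treatment)
        with pytest.raises(TimeDomainError):
            concentration_during(241.0, standard_patient, standard_treatment)

    def test_mass_balance_holds_along_solution(
        self, standard_patient, standard_treatment
    ):
        """The closed form must satisfy the variable-volume mass balances

        Vex(t) Cex' = -K Cex - Ah(Cex - Cin) + wpl Cin + (wf - wpl) Cex
        Vin(t) Cin' =  Ah(Cex - Cin) + S

        (mg/mL units), checked by central differencing the closed form.
        This pins down the second-order-ODE coefficients end to end.
        """
        p, tr = standard_patient, standard_treatment
        k, ah = tr.k_clear, p.ah
        wpl, net = tr.omega_pl, tr.omega_f - tr.omega_pl
        h = 1e-3
        for t in (30.0, 90.0, 150.0, 210.0):
            exm, inm = concentration_during(t - h, p, tr)
            exp_, inp_ = concentration_during(t + h, p, tr)
            ex, in_ = concentration_during(t, p, tr)
            ex, in_ = ex / 100.0, in_ / 100.0
            dex = (exp_ - exm) / (2 * h) / 100.0
            din = (inp_ - inm) / (2 * h) / 100.0
            v_ex, v_in = compartment_volumes(t, p, tr)
            rhs_ex = -k * ex - ah * (ex - in_) + wpl * in_ + net * ex
            rhs_in = ah * (ex - in_) + p.s_prod
            assert v_ex * dex == pytest.approx(rhs_ex, rel=1e-5)
            assert v_in * din == pytest.approx(rhs_in, rel=1e-5)


class TestPostPhase:
    def test_lambda3_value(self, standard_patient, standard_treatment):
        post = post_constants(standard_patient, standard_treatment)
        assert post.v_ex_T == pytest.approx(12480.0)
        assert post.v_in_T == pytest.approx(18720.0)
        expected = 500.0 * (12480.0 + 18720.0) / (12480.0 * 18720.0)
        assert post.lambda3 == pytest.approx(expected, rel=1e-12)

    def test_continuity_at_end_of_dialysis(self, standard_patient, standard_treatment):
        end = concentration_during(240.0, standard_patient, standard_treatment)
        post = post_constants(standard_patient, standard_treatment)
        again = concentration_post(240.0, post, standard_patient)
        assert again[0] == pytest.approx(end[0], rel=1e-9)
        assert again[1] == pytest.approx(end[1], rel=1e-9)

    def test_equilibrated_end_state_is_stationary(self, standard_treatment):
        patient = PatientParameters(
            v_ex0=14400.0, v_in0=21600.0, eps=None, c_s=80.0, s_prod=0.0, ah=500.0
        )
        post = post_constants(patient, standard_treatment, end_state=(30.0, 30.0))
        assert post.c3 == pytest.approx(0.0, abs=1e-15)
        for t in (240.0, 300.0, 1000.0):
            c_ex, c_in = concentration_post(t, post, patient)
            assert c_ex == pytest.approx(30.0, rel=1e-12)
            assert c_in == pytest.approx(30.0, rel=1e-12)

    def test_long_time_equilibrium_without_production(self, standard_treatment):
        """With S = 0 both compartments relax to the mass-weighted mean of
        the end-of-dialysis state (conservation algebra)."""
        patient = PatientParameters(
            v_ex0=14400.0, v_in0=21600.0, eps=None, c_s=80.0, s_prod=0.0, ah=500.0
        )
        post = post_constants(patient, standard_treatment)
        v_tot = post.v_ex_T + post.v_in_T
        expected = (
            post.v_ex_T * post.c_ex_T + post.v_in_T * post.c_in_T
        ) / v_tot * 100.0
        c_ex, c_in = concentration_post(2000.0, post, patient)
        assert c_ex == pytest.approx(expected, rel=1e-9)
        assert c_in == pytest.approx(expected, rel=1e-9)
        assert c_ex == pytest.approx(post.c4 * 100.0, rel=1e-9)

    def test_late_drift_is_production_over_total_volume(
        self, standard_patient, standard_treatment
    ):
        post = post_constants(standard_patient, standard_treatment)
        t1, t2 = 1500.0, 1600.0
        slope = (
            concentration_post(t2, post, standard_patient)[0]
            - concentration_post(t1, post, standard_patient)[0]
        ) / (t2 - t1)
        expected = 100.0 * standard_patient.s_prod / (post.v_ex_T + post.v_in_T)
        assert slope == pytest.approx(expected, rel=1e-9)

    def test_mass_conservation_without_production(self, standard_treatment):
        patient = PatientParameters(
            v_ex0=14400.0, v_in0=21600.0, eps=None, c_s=80.0, s_prod=0.0, ah=500.0
        )
        post = post_constants(patient, standard_treatment)
        t = np.linspace(240.0, 640.0, 41)
        c_ex, c_in = concentration_post(t, post, patient)
        mass = post.v_ex_T * c_ex + post.v_in_T * c_in
        np.testing.assert_allclose(mass, mass[0], rtol=1e-8)

    def test_pre_end_time_rejected(self, standard_patient, standard_treatment):
        post = post_constants(standard_patient, standard_treatment)
        with pytest.raises(TimeDomainError):
            concentration_post(239.0, post, standard_patient)


class TestSimulateTimeline:
    def test_single_point_grid(self, standard_patient, standard_treatment):
        s = simulate_timeline(standard_patient, standard_treatment, [0.0])
        assert s.times.tolist() == [0.0]
        assert s.c_ex[0] == pytest.approx(80.0, abs=1e-9)
        assert s.c_in[0] == pytest.approx(80.0, abs=1e-9)

    def test_no_jump_across_phase_switch(self, standard_patient, standard_treatment):
        grid = [239.0, 240.0, 240.0 + 1e-9, 241.0]
        s = simulate_timeline(standard_patient, standard_treatment, grid)
        assert s.phase.tolist() == ["during", "during", "post", "post"]
        assert s.c_ex[2] == pytest.approx(s.c_ex[1], rel=1e-9)
        assert s.c_in[2] == pytest.approx(s.c_in[1], rel=1e-9)

    def test_fig_shape_fall_then_rebound(self, standard_patient, standard_treatment):
        grid = np.arange(0.0, 401.0)
        s = simulate_timeline(standard_patient, standard_treatment, grid)
        during = s.times <= 240.0
        assert np.all(np.diff(s.c_ex[during]) < 0)  # monotone washout
        post = s.times >= 240.0
        assert np.all(np.diff(s.c_ex[post]) > 0)  # rebound + production
        assert np.all(s.c_in[during][1:] >= s.c_ex[during][1:])
        assert np.all(s.c_ex >= 0.0)
        # exactly one phase switch
        assert np.sum(s.phase[:-1] != s.phase[1:]) == 1

    def test_volumes_follow_linear_kinetics_then_freeze(
        self, standard_patient, standard_treatment
    ):
        grid = np.array([0.0, 120.0, 240.0, 300.0, 400.0])
        s = simulate_timeline(standard_patient, standard_treatment, grid)
        np.testing.assert_allclose(s.v_ex[:3], [14400.0, 13440.0, 12480.0])
        np.testing.assert_allclose(s.v_in[:3], [21600.0, 20160.0, 18720.0])
        np.testing.assert_allclose(s.v_ex[3:], 12480.0)
        np.testing.assert_allclose(s.v_in[3:], 18720.0)


class TestSinglePoolLimit:
    def test_compartments_merge_as_transfer_grows(self, standard_treatment):
        """As Ah -> infinity the two compartments behave as one pool: the
        concentration gap shrinks monotonically with Ah."""
        t = np.linspace(1.0, 240.0, 64)
        gaps = []
        for ah in (500.0, 5e3, 5e4, 5e5):
            patient = PatientParameters(
                v_ex0=14400.0, v_in0=21600.0, eps=None, c_s=80.0, s_prod=4.0, ah=ah
            )
            c_ex, c_in = concentration_during(t, patient, standard_treatment)
            gaps.append(np.max(np.abs(c_in - c_ex)))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 0.05

    def test_limit_matches_variable_volume_single_pool(self):
        """At huge Ah and S = 0 the model collapses to the well-mixed
        variable-volume pool C(t) = Cs (1 - wf t / V0)^((K - wf)/wf)."""
        patient = PatientParameters(
            v_ex0=14400.0, v_in0=21600.0, eps=None, c_s=80.0, s_prod=0.0, ah=1e6
        )
        treat = resolve_treatment(
            patient, TreatmentParameters(k_clear=200.0, t_end=240.0, omega_f=20.0)
        )
        t = np.linspace(0.0, 240.0, 25)
        c_ex, c_in = concentration_during(t, patient, treat)
        v0 = patient.v_ex0 + patient.v_in0
        single = 80.0 * (1.0 - treat.omega_f * t / v0) ** (
            (treat.k_clear - treat.omega_f) / treat.omega_f
        )
        np.testing.assert_allclose(c_ex, single, atol=1.0)
        np.testing.assert_allclose(c_in, single, atol=1.0)
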