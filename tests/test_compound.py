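"""Compound parameters, albumin binding, micro/macro conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gadosim as g
from gadosim.compound import calibrate_q

from conftest import ode_profile, random_subject


class TestFractionUnbound:
    @pytest.mark.parametrize(
        "kd, alb, expected",
        [
            (85.0, 45.0 / 66_500.0 * 1e6, 0.11),  # plasma albumin 45 g/L
            (85.0, 0.0, 1.0),  # no binder present
            (85.0, 85.0, 0.5),  # half-saturation at [Alb] = Kd
        ],
    )
    def test_reference_values(self, kd, alb, expected):
        assert g.fraction_unbound(kd, alb) == pytest.approx(expected, abs=0.005)

    def test_rounds_to_printed_value(self):
        fu = g.fraction_unbound(85.0, g.albumin_um(45.0))
        assert round(fu, 2) == 0.11

    def test_invalid_kd(self):
        with pytest.raises(g.InvalidParameterError):
            g.fraction_unbound(0.0, 100.0)
        with pytest.raises(g.InvalidParameterError):
            g.fraction_unbound(-1.0, 100.0)

    @given(st.floats(min_value=1.0, max_value=1000.0))
    @settings(deadline=None)
    def test_strictly_decreasing_in_albumin(self, alb):
        fu1 = g.fraction_unbound(85.0, alb)
        fu2 = g.fraction_unbound(85.0, alb * 1.1)
        assert 0 < fu2 < fu1 <= 1

    def test_theoretical_filtration_clearance(self):
        # fu*GFR for a young male: ~0.86 L/h at fu = 0.11
        assert g.theoretical_filtration_clearance(0.11) == pytest.approx(0.858)
        with pytest.raises(g.InvalidParameterError):
            g.theoretical_filtration_clearance(0.0)


class TestMicroToMacro:
    def test_against_ode_oracle_random_subjects(self):
        rng = np.random.default_rng(7)
        times = np.linspace(0.0, 72.0, 145)
        for _ in range(50):
            s = random_subject(rng)
            alpha, beta, ca, cb = g.micro_to_macro(s.v1, s.v2, s.q_inter, s.cl_renal)
            analytic = 100.0 * (ca * np.exp(-alpha * times) + cb * np.exp(-beta * times))
            numeric = ode_profile(s, 100.0, times)
            assert np.max(np.abs(analytic - numeric) / numeric[0]) < 1e-6

    def test_coefficients_sum_to_inverse_v1(self):
        _, _, ca, cb = g.micro_to_macro(4.03, 6.92, 3.72, 0.559)
        assert ca + cb == pytest.approx(1.0 / 4.03, rel=1e-12)

    def test_one_compartment_collapse(self):
        # q -> 0 decouples the peripheral compartment: the profile becomes
        # mono-exponential with rate cl/v1 (the slow root's amplitude -> 0)
        alpha, beta, ca, cb = g.micro_to_macro(4.0, 6.0, 1e-9, 0.5)
        assert alpha == pytest.approx(0.5 / 4.0, rel=1e-6)
        assert cb == pytest.approx(0.0, abs=1e-9)
        assert ca == pytest.approx(1.0 / 4.0, rel=1e-6)

    @given(
        st.floats(min_value=1.0, max_value=10.0),
        st.floats(min_value=1.0, max_value=20.0),
        st.floats(min_value=0.5, max_value=8.0),
        st.floats(min_value=0.05, max_value=2.0),
    )
    @settings(deadline=None)
    def test_vieta_identities(self, v1, v2, q, cl):
        alpha, beta, _, _ = g.micro_to_macro(v1, v2, q, cl)
        assert alpha > beta > 0
        assert alpha * beta * v1 * v2 == pytest.approx(cl * q, rel=1e-10)
        assert alpha + beta == pytest.approx(cl / v1 + q / v1 + q / v2, rel=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(g.InvalidParameterError):
            g.micro_to_macro(0.0, 6.0, 3.0, 0.5)


class TestSolveSubjectPK:
    def test_reference_macro_inversion(self):
        # CL and Vss of the labelled agent with both observed half-lives
        pk = g.solve_subject_pk(cl=0.486, vss=0.148 * 74, t_half_dist=0.48,
                                t_half_elim=16.3)
        assert pk.v1 == pytest.approx(4.729, abs=0.01)
        assert pk.v2 == pytest.approx(6.223, abs=0.01)
        assert pk.v1 + pk.v2 == pytest.approx(0.148 * 74, rel=1e-12)

    def test_round_trip_recovers_half_lives(self):
        for the in (16.0, 16.3, 18.5, 30.0):
            pk = g.solve_subject_pk(cl=0.5, vss=11.0, t_half_dist=0.48,
                                    t_half_elim=the)
            assert pk.t_half_dist == pytest.approx(0.48, rel=1e-8)
            assert pk.t_half_elim == pytest.approx(the, rel=1e-8)

    def test_infeasible_half_life_raises(self):
        # terminal phase too fast for the given CL and Vss: no positive v1
        with pytest.raises(g.InfeasibleCalibrationError):
            g.solve_subject_pk(cl=0.486, vss=10.95, t_half_dist=0.48,
                               t_half_elim=2.0)

    def test_inflated_elimination_half_life_keeps_positive_volumes(self):
        # 10x inflated elimination half-life: v1 collapses but stays positive
        pk = g.solve_subject_pk(cl=0.486, vss=10.95, t_half_dist=0.48,
                                t_half_elim=163.0)
        assert 0 < pk.v1 < 0.5
        assert pk.v2 > 0 and pk.q_inter > 0

    def test_ordering_validation(self):
        with pytest.raises(g.InvalidParameterError):
            g.solve_subject_pk(cl=0.5, vss=11.0, t_half_dist=20.0, t_half_elim=1.0)


class TestCompoundParams:
    def test_defaults_are_valid_and_fu_matches(self, compound):
        assert compound.fu() == pytest.approx(0.1116, abs=0.001)
        assert compound.fu(albumin_g_l=0.0) == 1.0

    def test_fu_override(self):
        c = g.CompoundParams(fu_override=0.15)
        assert c.fu() == 0.15

    def test_invariants_enforced(self):
        with pytest.raises(g.InvalidParameterError):
            g.CompoundParams(t_half_dist=20.0, t_half_elim=16.3)
        with pytest.raises(g.InvalidParameterError):
            g.CompoundParams(v1_per_kg=0.2)  # exceeds vss_per_kg
        with pytest.raises(g.InvalidParameterError):
            g.CompoundParams(kd_albumin=-1.0)

    def test_calibrated_q_pins_distribution_half_life(self, compound, ref_subject):
        alpha = math.log(2) / compound.t_half_dist
        q = calibrate_q(ref_subject.v1, ref_subject.v2, compound.cl_ref, alpha)
        assert q == pytest.approx(ref_subject.q_inter, rel=1e-12)
        assert ref_subject.t_half_dist == pytest.approx(0.48, rel=1e-12)
        # emergent elimination half-life close to the observed 16.3 h
        assert ref_subject.t_half_elim == pytest.approx(16.3, rel=0.05)
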