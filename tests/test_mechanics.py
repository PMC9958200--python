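import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import hillmuscle as hm
from hillmuscle import MuscleParams


@pytest.fixture(scope="module")
def p():
    return MuscleParams()


class TestForceLength:
    def test_optimum_and_overlap_limits(self, p):
        assert hm.force_length(1.0, p) == 1.0
        assert hm.force_length(2.0, p) == 0.0

    def test_descending_limb_value_from_breakpoints(self, p):
        # hand evaluation of the linear descending limb at 1.23 L0
        expected = (p.fl_zero_high - 1.23) / (p.fl_zero_high - p.fl_plateau_high)
        assert hm.force_length(1.23, p) == pytest.approx(expected, rel=1e-12)
        assert 0.0 < hm.force_length(1.23, p) < 1.0

    def test_unimodal_piecewise_profile(self, p):
        ls = np.linspace(0.1, 2.2, 400)
        fl = hm.force_length(ls, p)
        assert fl.min() >= 0.0 and fl.max() == 1.0
        peak_region = (ls >= p.fl_plateau_low) & (ls <= p.fl_plateau_high)
        assert np.all(fl[peak_region] == 1.0)
        # single rise then single fall
        d = np.diff(fl)
        first_fall = np.argmax(d < 0)
        assert np.all(d[first_fall:] <= 1e-12)

    def test_nonpositive_length_rejected(self, p):
        with pytest.raises(ValueError):
            hm.force_length(0.0, p)


class TestForceVelocity:
    def test_isometric_and_unloaded_limits(self, p):
        assert hm.force_velocity(0.0, p) == pytest.approx(1.0)
        assert hm.force_velocity(p.vmax, p) == pytest.approx(0.0, abs=1e-12)

    def test_eccentric_force_at_vmax_lengthening_equals_ceiling(self, p):
        # the eccentric branch reaches c exactly at a lengthening speed vmax
        assert hm.force_velocity(-p.vmax, p) == pytest.approx(p.ecc_c)
        # and 1.0 at zero velocity because c - k = 1
        assert hm.force_velocity(-1e-12, p) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_decreasing_in_velocity(self, p):
        v = np.linspace(-p.vmax, p.vmax, 500)
        f = hm.force_velocity(v, p)
        assert np.all(np.diff(f) < 0)

    @given(st.floats(min_value=0.0, max_value=1.79))
    @settings(max_examples=60, deadline=None)
    def test_inverse_round_trips(self, p_rel):
        p = MuscleParams()
        v = hm.inverse_force_velocity(p_rel, p)
        assert hm.force_velocity(v, p) == pytest.approx(p_rel, abs=1e-10)

    def test_inverse_matches_bisection_oracle(self, p):
        for p_rel in (0.25, 0.5, 0.9, 1.0, 1.3, 1.7):
            v_closed = hm.inverse_force_velocity(p_rel, p)
            v_bisect = brentq(
                lambda v: hm.force_velocity(v, p) - p_rel,
                -p.vmax, p.vmax, xtol=1e-13,
            )
            assert v_closed == pytest.approx(v_bisect, abs=1e-9)

    def test_inverse_limits_and_clamp(self, p):
        assert hm.inverse_force_velocity(1.0, p) == pytest.approx(0.0, abs=1e-12)
        assert hm.inverse_force_velocity(0.0, p) == pytest.approx(p.vmax)
        # demands at/above the eccentric ceiling clamp to -vmax
        assert hm.inverse_force_velocity(5.0, p) == pytest.approx(-p.vmax)
        with pytest.raises(ValueError):
            hm.inverse_force_velocity(-0.1, p)


class TestPassiveElements:
    def test_pee_slack_and_normalisation_points(self, p):
        assert hm.pee_force(0.98, p) == 0.0
        assert hm.pee_force(0.98 + 0.57, p) == pytest.approx(1.0, rel=1e-12)

    def test_pee_value_at_study_length(self, p):
        # direct arithmetic: (e^{4*(1.23-0.98)/0.57} - 1)/(e^4 - 1)
        expected = (np.exp(4 * 0.25 / 0.57) - 1) / (np.exp(4.0) - 1)
        assert hm.pee_force(1.23, p) == pytest.approx(expected, rel=1e-12)

    def test_see_normalisation_and_inverse(self, p):
        assert hm.see_force(0.0, p) == 0.0
        assert hm.see_force(15.0, p) == pytest.approx(1.0, rel=1e-12)
        # closed-form inverse at quarter load
        d = hm.see_deformation(0.25, p)
        assert d == pytest.approx(15.0 * 0.25 ** (1 / p.see_exponent), rel=1e-12)
        assert hm.see_force(d, p) == pytest.approx(0.25, abs=1e-10)

    @given(st.floats(min_value=0.981, max_value=1.8),
           st.floats(min_value=0.981, max_value=1.8))
    @settings(max_examples=50, deadline=None)
    def test_pee_monotone(self, l1, l2):
        p = MuscleParams()
        lo, hi = sorted((l1, l2))
        assert hm.pee_force(lo, p) <= hm.pee_force(hi, p)

    @given(st.floats(min_value=0.0, max_value=30.0),
           st.floats(min_value=0.0, max_value=30.0))
    @settings(max_examples=50, deadline=None)
    def test_see_monotone(self, d1, d2):
        p = MuscleParams()
        lo, hi = sorted((d1, d2))
        assert hm.see_force(lo, p) <= hm.see_force(hi, p)

    def test_negative_inputs_rejected(self, p):
        with pytest.raises(ValueError):
            hm.see_force(-1.0, p)
        with pytest.raises(ValueError):
            hm.see_deformation(-0.5, p)


class TestActivationSigmoidAndPca:
    def test_half_activation_and_limits(self, p):
        assert hm.activation_from_activator(p.a50, p.a50, p.nH) == pytest.approx(0.5)
        assert hm.activation_from_activator(0.0, p.a50, p.nH) == 0.0
        expected = 1.0 / (1.0 + 0.1025 ** 3)
        assert hm.activation_from_activator(1.0, 0.1025, 3) == pytest.approx(
            expected, rel=1e-12)

    def test_pca_conversions(self):
        assert hm.a50_to_pca50(1.0) == pytest.approx(5.0)
        assert hm.a50_to_pca50(0.1025) == pytest.approx(5.99, abs=0.005)
        # a 0.05 pCa-unit desensitisation multiplies a50 by 10^0.05
        a50 = hm.pca50_to_a50(hm.a50_to_pca50(0.1025) - 0.05)
        assert a50 == pytest.approx(0.1025 * 10 ** 0.05, rel=1e-12)
        with pytest.raises(ValueError):
            hm.a50_to_pca50(0.0)

    def test_activator_and_pca_round_trip(self):
        for a in (1e-3, 0.1025, 0.9):
            assert hm.pca_to_activator(hm.activator_to_pca(a)) == pytest.approx(
                a, rel=1e-12)

    @given(st.floats(min_value=4.0, max_value=8.0))
    @settings(max_examples=60, deadline=None)
    def test_activator_sigmoid_equals_hill_force_pca_form(self, pca):
        # the two parameterisations of the activation curve are identical
        p = MuscleParams()
        via_activator = hm.activation_from_activator(
            hm.pca_to_activator(pca), p.a50, p.nH)
        via_pca = hm.activation_from_pca(pca, p.pCa50, p.nH)
        assert via_activator == pytest.approx(via_pca, abs=1e-12)
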