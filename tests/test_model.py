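"""Unit and property tests for the circuit response functions and RHS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetswitch.model import (
    dox_repression,
    dox_repression_mm_approx,
    fit_mm_approx,
    nopfl_jacobian,
    nopfl_rhs,
    observe,
    pfl_jacobian,
    pfl_rhs,
    transcription_rate,
)
from tetswitch.params import ParameterSet

positive = st.floats(min_value=1e-3, max_value=1e3)


class TestDoxRepression:
    def test_zero_dox_gives_full_activity(self):
        assert dox_repression(0.0, 2.5, 1.7) == 1.0

    def test_half_saturation_at_k_dox(self):
        assert dox_repression(3.7, 3.7, 0.9) == pytest.approx(0.5, abs=1e-12)

    def test_fitted_hill_at_100nM(self):
        # closed form 1/(1 + 100**0.0603) evaluated independently
        assert dox_repression(100.0, 1.00, 6.03e-2) == pytest.approx(
            0.4310197619117582, rel=1e-12
        )

    def test_negative_dox_rejected(self):
        with pytest.raises(ValueError):
            dox_repression(-1.0, 1.0, 1.0)

    @given(k_dox=positive, h=st.floats(min_value=0.02, max_value=6.0),
           a=st.floats(min_value=0.0, max_value=1e4),
           b=st.floats(min_value=1e-6, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing(self, k_dox, h, a, b):
        # nonincreasing everywhere; strictly decreasing once the doses are
        # separated enough for the Hill terms to differ in float arithmetic
        lo, hi = min(a, a + b), a + b
        assert dox_repression(hi, k_dox, h) <= dox_repression(lo, k_dox, h)
        assert dox_repression(10.0 * k_dox, k_dox, h) < dox_repression(k_dox, k_dox, h)


class TestMMApproximation:
    def test_full_activity_at_zero(self):
        assert dox_repression_mm_approx(0.0, 2.0, 0.1) == 1.0

    def test_asymptote_equals_leak(self):
        assert dox_repression_mm_approx(1e12, 2.0, 0.1) == pytest.approx(0.1, rel=1e-9)

    def test_leak_domain(self):
        with pytest.raises(ValueError):
            dox_repression_mm_approx(1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            dox_repression_mm_approx(1.0, 2.0, -0.1)

    def test_approximates_fitted_hill_over_working_range(self, p):
        # least-squares surrogate reproduces the shallow Hill response with a
        # small residual and a substantial activity floor (no complete shut-off)
        k_mm, leak, max_dev = fit_mm_approx(p, dox_min=0.1, dox_max=100.0)
        assert max_dev < 0.04
        assert 0.0 < leak < 1.0
        assert leak > 0.2  # tTA activity cannot be fully shut down


class TestTranscriptionRate:
    def test_basal_leakiness_only(self, p):
        assert transcription_rate(0.0, p) == pytest.approx(p.v1 * p.alpha0, rel=1e-12)

    def test_half_max_at_theta(self, p):
        assert transcription_rate(p.theta, p) == pytest.approx(
            p.v1 * (p.alpha0 + 0.5), rel=1e-12
        )

    def test_at_nopfl_steady_state_tta(self, p):
        # closed-form value at the constitutive tTA level, frozen from a
        # direct high-precision evaluation of v1*(alpha0 + hill(13.69))
        assert transcription_rate(13.69, p) == pytest.approx(
            0.07273235864301564, rel=1e-12
        )

    @given(a=st.floats(min_value=0.0, max_value=1e4),
           b=st.floats(min_value=1e-6, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, p, a, b):
        lo_v, hi_v = transcription_rate(a, p), transcription_rate(a + b, p)
        assert hi_v >= lo_v
        assert p.v1 * p.alpha0 <= lo_v <= hi_v <= p.v1 * (p.alpha0 + 1.0)


class TestRhs:
    def test_origin_is_equilibrium_without_leak(self, p):
        p0 = p.replace(alpha0=0.0)
        assert np.allclose(pfl_rhs(np.zeros(4), 5.0, p0), 0.0)
        assert np.allclose(nopfl_rhs(np.zeros(3), 5.0, p0.replace(rho_tTA=1e-12)), 0.0)

    def test_negative_state_rejected(self, p):
        with pytest.raises(ValueError):
            pfl_rhs([-1.0, 1.0, 1.0, 1.0], 0.0, p)
        with pytest.raises(ValueError):
            nopfl_rhs([1.0, -1.0, 1.0], 0.0, p)

    def test_pfl_jacobian_matches_finite_differences(self, p):
        x = np.array([2.0, 6.0, 10.0, 14.0])
        jac = pfl_jacobian(x, 1.0, p)
        eps = 1e-6
        fd = np.empty((4, 4))
        for j in range(4):
            dx = np.zeros(4)
            dx[j] = eps
            fd[:, j] = (pfl_rhs(x + dx, 1.0, p) - pfl_rhs(x - dx, 1.0, p)) / (2 * eps)
        assert np.allclose(jac, fd, rtol=1e-6, atol=1e-9)

    def test_nopfl_eigenvalues_are_degradation_rates(self, p):
        eig = np.sort(np.linalg.eigvals(nopfl_jacobian(p)).real)
        expected = np.sort([-p.d1, -(p.Kf + p.d3), -p.d3])
        assert np.allclose(eig, expected, rtol=1e-12)
        # the slowest mode is the reporter degradation rate d3
        assert np.max(eig) == pytest.approx(-3.24e-3, rel=1e-12)

    def test_nopfl_linear_steady_state(self, p):
        x1_star = transcription_rate(p.rho_tTA, p) / p.d1
        assert np.allclose(
            nopfl_rhs([x1_star, 0.0, 0.0], 0.0, p)[0], 0.0, atol=1e-15
        )


class TestObserve:
    def test_zero_reporter_gives_zero(self):
        assert observe([1.0, 2.0, 3.0, 0.0], 5.0) == 0.0

    def test_identity_and_linearity(self):
        state = np.array([1.0, 2.0, 3.0, 4.0])
        assert observe(state, 1.0) == 4.0
        assert observe(state, 2.0) == 2.0 * observe(state, 1.0)

    def test_array_of_states(self):
        states = np.arange(8.0).reshape(2, 4)
        assert np.allclose(observe(states, 3.0), [9.0, 21.0])
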