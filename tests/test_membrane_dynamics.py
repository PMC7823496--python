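"""Order parameter and correlation times: closed forms, flags, invariances."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saslepr import (
    FieldGrid,
    SpectralFeatures,
    correlation_times,
    extract_anisotropic_features,
    extract_fast_motion_features,
    ground_truth_tau,
    order_parameter,
    simulate_anisotropic,
    simulate_fast_motion,
)
from saslepr.pipeline import anisotropic_params_for_order, fast_motion_params_for_tau


def aniso_features(a_par, a_perp):
    return SpectralFeatures(A_par_prime=a_par, A_perp_prime=a_perp, analyzable=True)


def triplet_features(dh0_mT, h_plus, h_zero, h_minus):
    return SpectralFeatures(
        deltaH0=dh0_mT, h_plus=h_plus, h_zero=h_zero, h_minus=h_minus, analyzable=True
    )


class TestOrderParameter:
    def test_isotropic_limit_gives_zero(self):
        op = order_parameter(aniso_features(1.5, 1.5))
        assert op.S == 0.0
        assert op.a0 == pytest.approx(1.5)
        assert not op.out_of_range

    def test_worked_example(self):
        op = order_parameter(aniso_features(3.0, 1.5))
        assert op.a0 == pytest.approx(2.0, abs=1e-12)
        assert op.S == pytest.approx(0.405525, abs=1e-9)

    def test_rigid_overshoot_is_flagged_not_clamped(self):
        op = order_parameter(aniso_features(3.0, 0.0))
        assert op.S == pytest.approx(1.6221, abs=1e-4)
        assert op.out_of_range

    def test_missing_splittings_raise(self):
        with pytest.raises(ValueError):
            order_parameter(SpectralFeatures(deltaH0=0.2, analyzable=True))

    @settings(derandomize=True, max_examples=50)
    @given(
        a_perp=st.floats(0.5, 3.0),
        gap=st.floats(0.01, 3.0),
        k=st.floats(0.1, 10.0),
    )
    def test_scale_invariance(self, a_perp, gap, k):
        """S is invariant under common scaling of the splittings; a0 scales."""
        op1 = order_parameter(aniso_features(a_perp + gap, a_perp))
        op2 = order_parameter(aniso_features(k * (a_perp + gap), k * a_perp))
        assert op2.S == pytest.approx(op1.S, rel=1e-9)
        assert op2.a0 == pytest.approx(k * op1.a0, rel=1e-9)


class TestCorrelationTimes:
    def test_symmetric_triplet_gives_zero_taus(self):
        ct = correlation_times(triplet_features(0.15, 2.0, 2.0, 2.0))
        assert ct.tau2B == pytest.approx(0.0, abs=1e-25)
        assert ct.tau2C == pytest.approx(0.0, abs=1e-25)

    def test_worked_examples_in_gauss(self):
        # deltaH0 = 1.5 G stored as 0.15 mT; h0/h- = 4, h0/h+ = 1
        ct = correlation_times(triplet_features(0.15, 4.0, 4.0, 1.0))
        assert ct.tau2B == pytest.approx(9.765e-10, rel=1e-9)
        assert ct.tau2C == pytest.approx(9.765e-10, rel=1e-9)
        # deltaH0 = 2 G; h0/h+ = h0/h- = 4
        ct = correlation_times(triplet_features(0.20, 1.0, 4.0, 1.0))
        assert ct.tau2B == pytest.approx(0.0, abs=1e-25)
        assert ct.tau2C == pytest.approx(2.604e-9, rel=1e-9)

    def test_explicit_mT_unit_convention(self):
        ct_gauss = correlation_times(triplet_features(0.15, 4.0, 4.0, 1.0), units="gauss")
        ct_mT = correlation_times(triplet_features(0.15, 4.0, 4.0, 1.0), units="mT")
        assert ct_gauss.tau2B == pytest.approx(10.0 * ct_mT.tau2B, rel=1e-12)

    def test_nonpositive_amplitude_raises(self):
        with pytest.raises(ValueError, match="positive"):
            correlation_times(triplet_features(0.15, 0.0, 2.0, 1.0))

    @settings(derandomize=True, max_examples=50)
    @given(
        h=st.tuples(st.floats(0.5, 5.0), st.floats(0.5, 5.0), st.floats(0.5, 5.0)),
        k=st.floats(0.1, 10.0),
        dh=st.floats(0.05, 0.5),
    )
    def test_amplitude_scaling_and_linewidth_linearity(self, h, k, dh):
        ct1 = correlation_times(triplet_features(dh, *h))
        ct2 = correlation_times(triplet_features(dh, *(k * v for v in h)))
        assert ct2.tau2B == pytest.approx(ct1.tau2B, rel=1e-9, abs=1e-22)
        ct3 = correlation_times(triplet_features(2 * dh, *h))
        assert ct3.tau2C == pytest.approx(2 * ct1.tau2C, rel=1e-9, abs=1e-22)


class TestEndToEndRecovery:
    def test_tau_round_trip_five_percent(self, grid4096):
        """simulate → extract → τ formulas recovers the analytic ground truth."""
        p = fast_motion_params_for_tau(2.604e-10, 3.906e-10, width_A=0.15)
        gt = ground_truth_tau(p)
        f = extract_fast_motion_features(simulate_fast_motion(p, grid4096))
        ct = correlation_times(f)
        assert ct.tau2B == pytest.approx(gt.tau2B, rel=0.05)
        assert ct.tau2C == pytest.approx(gt.tau2C, rel=0.05)

    def test_order_parameter_round_trip(self, grid4096):
        p = anisotropic_params_for_order(0.405525, a0=2.0)
        f = extract_anisotropic_features(simulate_anisotropic(p, grid4096))
        op = order_parameter(f)
        assert op.S == pytest.approx(0.405525, abs=0.01)

    def test_order_parameter_monotone_in_measurement_temperature(self, grid2048):
        """A series with shrinking splitting gap yields strictly decreasing S."""
        recovered = []
        for temp in range(0, 45, 5):
            s_target = 0.65 - 0.01 * temp
            p = anisotropic_params_for_order(s_target)
            f = extract_anisotropic_features(simulate_anisotropic(p, grid2048))
            recovered.append(order_parameter(f).S)
        assert all(a > b for a, b in zip(recovered, recovered[1:]))
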