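"""Feature extraction: round trips, invariances, baseline, noise rules."""

import dataclasses

import numpy as np
import pytest

from saslepr import (
    AnisotropicParams,
    ExtractionOptions,
    FastMotionParams,
    FieldGrid,
    Spectrum,
    correct_baseline,
    extract_anisotropic_features,
    extract_fast_motion_features,
    simulate_anisotropic,
    simulate_fast_motion,
)


class TestFastMotionExtraction:
    def test_central_linewidth_recovered_to_half_grid_step(self, grid4096):
        p = FastMotionParams(width_A=0.15, width_B=0.0, width_C=0.0)
        f = extract_fast_motion_features(simulate_fast_motion(p, grid4096))
        assert f.analyzable
        assert abs(f.deltaH0 - 0.15) <= 0.5 * grid4096.step

    def test_pure_noise_is_not_analyzable(self, grid4096, rng):
        s = Spectrum(field=grid4096.values(), intensity=rng.normal(0.0, 1.0, grid4096.n_points))
        assert extract_fast_motion_features(s).analyzable is False

    def test_two_lines_only_is_not_analyzable(self, grid4096):
        from saslepr.synthetic_spectra import _deriv_lorentzian

        x = grid4096.values()
        y = _deriv_lorentzian(x - 333.5, 0.2) + _deriv_lorentzian(x - 336.5, 0.2)
        f = extract_fast_motion_features(Spectrum(field=x, intensity=y))
        assert f.analyzable is False

    def test_amplitude_scale_equivariance(self, asymmetric_fast_spectrum):
        f1 = extract_fast_motion_features(asymmetric_fast_spectrum)
        scaled = Spectrum(
            field=asymmetric_fast_spectrum.field,
            intensity=3.5 * asymmetric_fast_spectrum.intensity,
        )
        f2 = extract_fast_motion_features(scaled)
        assert f2.h_zero == pytest.approx(3.5 * f1.h_zero, rel=1e-9)
        assert f2.h_plus == pytest.approx(3.5 * f1.h_plus, rel=1e-9)
        assert f2.deltaH0 == pytest.approx(f1.deltaH0, rel=1e-9)
        assert f2.h_zero / f2.h_plus == pytest.approx(f1.h_zero / f1.h_plus, rel=1e-9)

    def test_field_translation_invariance(self, asymmetric_fast_spectrum):
        f1 = extract_fast_motion_features(asymmetric_fast_spectrum)
        shifted = Spectrum(
            field=asymmetric_fast_spectrum.field + 2.0,
            intensity=asymmetric_fast_spectrum.intensity,
        )
        f2 = extract_fast_motion_features(shifted)
        assert f2.deltaH0 == pytest.approx(f1.deltaH0, rel=1e-9)
        assert f2.h_minus == pytest.approx(f1.h_minus, rel=1e-9)

    def test_grid_refinement_convergence(self, asymmetric_fast_params):
        coarse_grid = FieldGrid.default(2048)
        f_coarse = extract_fast_motion_features(
            simulate_fast_motion(asymmetric_fast_params, coarse_grid)
        )
        f_fine = extract_fast_motion_features(
            simulate_fast_motion(asymmetric_fast_params, FieldGrid.default(4096))
        )
        assert abs(f_fine.deltaH0 - f_coarse.deltaH0) < 0.5 * coarse_grid.step

    def test_noise_robustness_at_snr_50(self, grid4096):
        """Recovered features stay within 2% of noiseless values at SNR 50."""
        p0 = FastMotionParams(width_A=0.2, width_B=-0.015, width_C=0.02)
        clean = extract_fast_motion_features(simulate_fast_motion(p0, grid4096))
        for seed in range(20):
            p = dataclasses.replace(p0, noise_sd=clean.h_zero / 50.0, seed=seed)
            f = extract_fast_motion_features(simulate_fast_motion(p, grid4096))
            assert f.analyzable
            devs = (
                abs(f.deltaH0 / clean.deltaH0 - 1),
                abs(f.h_plus / clean.h_plus - 1),
                abs(f.h_zero / clean.h_zero - 1),
                abs(f.h_minus / clean.h_minus - 1),
            )
            assert max(devs) < 0.02, f"seed {seed}: {devs}"


class TestAnisotropicExtraction:
    def test_splitting_recovery_to_half_grid_step(self, grid4096):
        p = AnisotropicParams(A_par=3.0, A_perp=1.5)
        f = extract_anisotropic_features(simulate_anisotropic(p, grid4096))
        assert f.analyzable
        assert abs(f.A_par_prime - 3.0) <= 0.5 * grid4096.step
        assert abs(f.A_perp_prime - 1.5) <= 0.5 * grid4096.step

    def test_mirror_about_center_preserves_splittings(self, grid4096):
        s = simulate_anisotropic(AnisotropicParams(A_par=3.0, A_perp=1.5), grid4096)
        f1 = extract_anisotropic_features(s)
        center = 0.5 * (s.field[0] + s.field[-1])
        mirrored = Spectrum(
            field=(2.0 * center - s.field)[::-1], intensity=s.intensity[::-1]
        )
        f2 = extract_anisotropic_features(mirrored)
        assert f2.analyzable
        assert f2.A_par_prime == pytest.approx(f1.A_par_prime, abs=1e-9)
        assert f2.A_perp_prime == pytest.approx(f1.A_perp_prime, abs=1e-9)

    def test_noise_robustness_of_splittings_at_snr_50(self, grid4096):
        p0 = AnisotropicParams(A_par=3.0, A_perp=1.5)
        clean = extract_anisotropic_features(simulate_anisotropic(p0, grid4096))
        for seed in range(20):
            p = dataclasses.replace(p0, noise_sd=p0.mixing_weight / 50.0, seed=seed)
            f = extract_anisotropic_features(simulate_anisotropic(p, grid4096))
            assert f.analyzable
            assert abs(f.A_par_prime / clean.A_par_prime - 1) < 0.02
            assert abs(f.A_perp_prime / clean.A_perp_prime - 1) < 0.02

    def test_heavy_noise_drowns_inner_extrema(self, grid2048):
        """Raising noise past the 3×noise rule flips spectra to non-analyzable."""
        p0 = AnisotropicParams(A_par=3.0, A_perp=1.5)
        inner_amp = 1.0 - p0.mixing_weight
        low = extract_anisotropic_features(
            simulate_anisotropic(dataclasses.replace(p0, noise_sd=inner_amp / 60, seed=1), grid2048)
        )
        high = extract_anisotropic_features(
            simulate_anisotropic(dataclasses.replace(p0, noise_sd=2.0 * inner_amp, seed=1), grid2048)
        )
        assert low.analyzable is True
        assert high.analyzable is False


class TestBaselineCorrection:
    def test_removes_linear_baseline_pointwise(self, grid4096):
        # Gaussian lines: edge windows are truly line-free, so the corrected
        # spectrum must reproduce the slope-0 simulation pointwise
        p0 = FastMotionParams(width_A=0.2, lineshape="gaussian")
        flat = simulate_fast_motion(p0, grid4096)
        sloped = simulate_fast_motion(dataclasses.replace(p0, baseline_slope=0.3), grid4096)
        corrected = correct_baseline(sloped)
        scale = np.max(np.abs(flat.intensity))
        assert np.allclose(corrected.intensity, flat.intensity, atol=1e-6 * scale)

    def test_idempotent_on_flat_spectrum(self, asymmetric_fast_spectrum):
        once = correct_baseline(asymmetric_fast_spectrum)
        twice = correct_baseline(once)
        scale = np.max(np.abs(once.intensity))
        assert np.allclose(once.intensity, twice.intensity, atol=1e-9 * scale)

    def test_all_zero_signal_stays_zero(self, grid2048):
        s = Spectrum(field=grid2048.values(), intensity=np.zeros(grid2048.n_points))
        assert np.allclose(correct_baseline(s).intensity, 0.0)

    def test_line_overlapping_edge_window_raises(self, grid2048):
        from saslepr.synthetic_spectra import _deriv_lorentzian

        x = grid2048.values()
        y = _deriv_lorentzian(x - (x[0] + 0.2), 0.3)  # line inside the left window
        with pytest.raises(ValueError, match="overlap"):
            correct_baseline(Spectrum(field=x, intensity=y))

    def test_nonuniform_grid_rejected_by_extractor(self):
        field = np.concatenate([np.linspace(329, 335, 500), np.linspace(335.1, 341, 600)])
        s = Spectrum(field=field, intensity=np.zeros(field.size))
        with pytest.raises(ValueError, match="uniform"):
            extract_fast_motion_features(s, ExtractionOptions(baseline_correct=False))
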