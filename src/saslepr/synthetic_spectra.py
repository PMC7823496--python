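"""Forward simulation of nitroxide spin-label first-derivative EPR spectra.

Two phenomenological generators with analytically known ground truth stand
in for raw spectrometer output:

* :func:`simulate_fast_motion` — the motionally narrowed three-line
  (¹⁴N, mI = +1, 0, −1) spectrum typical of 16-SASL in a fluid membrane.
  Each line is the analytic first derivative of a Lorentzian or Gaussian
  absorption profile of equal integrated intensity, with an mI-dependent
  peak-to-peak linewidth ΔH(mI) = A + B·mI + C·mI².  For Lorentzian lines
  the derivative amplitude scales as 1/ΔH², which makes the fast-motion
  correlation-time formulas exactly invertible
  (:func:`ground_truth_tau`).
* :func:`simulate_anisotropic` — the axially anisotropic lineshape typical
  of 5-SASL near the polar head groups, built so that the outermost
  derivative extrema are separated by exactly 2·A∥ and the inner extrema
  pair by 2·A⊥, which is the geometry the order-parameter formula
  consumes.

Field modulation is not modelled explicitly; modulation broadening is
treated as folded into the effective peak-to-peak widths.  Noise is
additive i.i.d. Gaussian and the baseline is linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np

__all__ = [
    "FieldGrid",
    "FastMotionParams",
    "AnisotropicParams",
    "Spectrum",
    "simulate_fast_motion",
    "simulate_anisotropic",
    "ground_truth_tau",
    "KIVELSON_PREFACTOR_S_PER_G",
]

#: Prefactor of the fast-motion correlation-time formulas, seconds per gauss.
KIVELSON_PREFACTOR_S_PER_G = 6.51e-10

MT_TO_GAUSS = 10.0


@dataclass(frozen=True)
class FieldGrid:
    """Uniform magnetic-field axis in millitesla."""

    start: float
    stop: float
    n_points: int = 2048

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"start must be < stop, got [{self.start}, {self.stop}]")
        if self.n_points < 64:
            raise ValueError(f"n_points must be >= 64, got {self.n_points}")

    @property
    def step(self) -> float:
        return (self.stop - self.start) / (self.n_points - 1)

    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)

    @classmethod
    def default(cls, n_points: int = 2048) -> "FieldGrid":
        # 12 mT sweep centred at 335 mT: a conventional X-band window.
        return cls(329.0, 341.0, n_points)


@dataclass(frozen=True)
class FastMotionParams:
    """Ground truth for a motionally narrowed nitroxide triplet.

    The low-field line is mI = +1 (it carries the amplitude h₊), the
    high-field line mI = −1.  Peak-to-peak width of line mI is
    ``width_A + width_B*mI + width_C*mI**2`` (mT).
    """

    center_field: float = 335.0
    hyperfine_splitting_aN: float = 1.5
    width_A: float = 0.2
    width_B: float = 0.0
    width_C: float = 0.0
    lineshape: Literal["lorentzian", "gaussian"] = "lorentzian"
    noise_sd: float = 0.0
    baseline_slope: float = 0.0
    seed: int = 0

    def linewidth(self, m_i: int) -> float:
        return self.width_A + self.width_B * m_i + self.width_C * m_i * m_i

    def __post_init__(self) -> None:
        widths = [self.linewidth(m) for m in (+1, 0, -1)]
        if min(widths) <= 0:
            raise ValueError(f"all three linewidths must be positive, got {widths}")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")
        if not self.hyperfine_splitting_aN > 3.0 * max(widths):
            raise ValueError(
                "resolved-line regime requires aN > 3×max linewidth; "
                f"aN={self.hyperfine_splitting_aN}, widths={widths}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class AnisotropicParams:
    """Ground truth for an axially anisotropic (polar-head-region) spectrum."""

    center_field: float = 335.0
    A_par: float = 3.0
    A_perp: float = 1.5
    component_width: float = 0.25
    mixing_weight: float = 0.65
    noise_sd: float = 0.0
    baseline_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.A_par > self.A_perp > 0):
            raise ValueError(
                f"require A_par > A_perp > 0, got A_par={self.A_par}, A_perp={self.A_perp}"
            )
        if self.component_width <= 0:
            raise ValueError("component_width must be positive")
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing_weight must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Spectrum:
    """A sampled first-derivative EPR signal over a magnetic-field axis.

    ``metadata`` carries acquisition context (spin_label, genotype,
    measurement_temperature_C, growth_temperature_C, replicate_id, ...).
    """

    field: np.ndarray
    intensity: np.ndarray
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.ndim != 1 or self.field.shape != self.intensity.shape:
            raise ValueError("field and intensity must be 1-D arrays of equal length")
        if not np.all(np.diff(self.field) > 0):
            raise ValueError("field axis must be strictly increasing")

    def __len__(self) -> int:
        return self.field.size


def _deriv_lorentzian(x: np.ndarray, pp_width: float) -> np.ndarray:
    """First derivative of a unit-area Lorentzian absorption line.

    ``pp_width`` is the peak-to-peak width of the derivative; the
    half-width at half maximum is Γ = (√3/2)·pp_width.
    """
    gamma = 0.5 * np.sqrt(3.0) * pp_width
    return -(2.0 / np.pi) * gamma * x / (gamma * gamma + x * x) ** 2


def _deriv_gaussian(x: np.ndarray, pp_width: float) -> np.ndarray:
    """First derivative of a unit-area Gaussian absorption line (pp_width = 2σ)."""
    sigma = 0.5 * pp_width
    return -x / (sigma**3 * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * (x / sigma) ** 2)


_DERIV_SHAPES = {"lorentzian": _deriv_lorentzian, "gaussian": _deriv_gaussian}


def _finish(field: np.ndarray, signal: np.ndarray, noise_sd: float,
            baseline_slope: float, seed: int, metadata: dict | None) -> Spectrum:
    center = 0.5 * (field[0] + field[-1])
    signal = signal + baseline_slope * (field - center)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=field.size)
    return Spectrum(field=field.copy(), intensity=signal, metadata=dict(metadata or {}))


def simulate_fast_motion(
    params: FastMotionParams,
    grid: FieldGrid | None = None,
    metadata: dict | None = None,
) -> Spectrum:
    """Simulate a motionally narrowed three-line nitroxide spectrum.

    The three lines sit at ``center_field − mI·aN`` (mI = +1 low field),
    each the analytic derivative of an equal-area absorption profile with
    its mI-dependent peak-to-peak width.  Identical parameters and seed
    produce identical output.

    Raises
    ------
    ValueError
        If the grid does not contain all three lines ± 3 linewidths.
    """
    grid = grid or FieldGrid.default()
    widths = {m: params.linewidth(m) for m in (+1, 0, -1)}
    max_w = max(widths.values())
    lo_line = params.center_field - params.hyperfine_splitting_aN
    hi_line = params.center_field + params.hyperfine_splitting_aN
    if grid.start > lo_line - 3 * max_w or grid.stop < hi_line + 3 * max_w:
        raise ValueError(
            f"field grid [{grid.start}, {grid.stop}] mT does not cover all three "
            f"lines ± 3 linewidths ([{lo_line - 3 * max_w:.2f}, {hi_line + 3 * max_w:.2f}])"
        )
    shape = _DERIV_SHAPES[params.lineshape]
    B = grid.values()
    signal = np.zeros_like(B)
    for m_i in (+1, 0, -1):
        center = params.center_field - m_i * params.hyperfine_splitting_aN
        signal += shape(B - center, widths[m_i])
    return _finish(B, signal, params.noise_sd, params.baseline_slope, params.seed, metadata)


def ground_truth_tau(params: FastMotionParams):
    """Closed-form rotational correlation times implied by the forward model.

    For equal-area Lorentzian lines the derivative peak-to-peak amplitude
    scales as 1/ΔH(mI)², so √(h₀/h±) = ΔH(±1)/ΔH(0) and the fast-motion
    formulas collapse to linewidth differences (in gauss):

        τ₂B = 6.51e-10 · (ΔH(−1) − ΔH(+1)) = 6.51e-10 · (−2·B)
        τ₂C = 6.51e-10 · (ΔH(−1) + ΔH(+1) − 2·ΔH(0)) = 6.51e-10 · (2·C)

    Only defined for the Lorentzian lineshape; the amplitude identity used
    above is exact there.
    """
    from .membrane_dynamics import CorrelationTimes

    if params.lineshape != "lorentzian":
        raise ValueError("ground_truth_tau is defined only for the Lorentzian lineshape")
    b_gauss = params.width_B * MT_TO_GAUSS
    c_gauss = params.width_C * MT_TO_GAUSS
    return CorrelationTimes(
        tau2B=KIVELSON_PREFACTOR_S_PER_G * (-2.0 * b_gauss),
        tau2C=KIVELSON_PREFACTOR_S_PER_G * (2.0 * c_gauss),
    )


def _gaussian_bump(x: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (x / sigma) ** 2)


def _anisotropic_clean(
    params: AnisotropicParams, B: np.ndarray, a_par: float, a_perp: float
) -> np.ndarray:
    """Noise- and baseline-free anisotropic lineshape on field axis ``B``.

    Antisymmetric about the centre: a positive/negative absorption-shaped
    pair at centre ∓ a_par (the axial doublet turning points) and a
    negative/positive inner pair at centre ∓ a_perp.  The derivative
    extrema therefore sit at the component placements (up to small
    overlap shifts, compensated by the caller), and the running integral
    of the signal returns to zero at the window edges because the pairs
    carry equal and opposite area.
    """
    c, s = params.center_field, params.component_width
    w = params.mixing_weight
    outer = _gaussian_bump(B - (c - a_par), s) - _gaussian_bump(B - (c + a_par), s)
    inner = -_gaussian_bump(B - (c - a_perp), s) + _gaussian_bump(B - (c + a_perp), s)
    return w * outer + (1.0 - w) * inner


def simulate_anisotropic(
    params: AnisotropicParams,
    grid: FieldGrid | None = None,
    metadata: dict | None = None,
) -> Spectrum:
    """Simulate an axially anisotropic first-derivative spectrum.

    The outermost extrema (global low-field maximum, global high-field
    minimum) are separated by 2·A∥ and the inner extrema pair by 2·A⊥.
    Before returning, the realized geometry is verified by self-extraction
    to within half a grid step.

    Raises
    ------
    ValueError
        If the geometry is unresolvable (component_width too large to
        yield four distinct extrema) or the grid does not contain the
        outer features ± 3 component widths.
    """
    from .spectral_features import ExtractionOptions, extract_anisotropic_features

    grid = grid or FieldGrid.default()
    s = params.component_width
    if params.A_par - params.A_perp <= 2.0 * s or 2.0 * params.A_perp <= 2.0 * s:
        raise ValueError(
            "unresolvable geometry: component_width too large relative to the "
            f"splitting gaps (A_par−A_perp={params.A_par - params.A_perp:.3f}, "
            f"2·A_perp={2 * params.A_perp:.3f}, width={s:.3f} mT)"
        )
    lo = params.center_field - params.A_par
    hi = params.center_field + params.A_par
    if grid.start > lo - 3 * s or grid.stop < hi + 3 * s:
        raise ValueError("field grid does not cover the outer features ± 3 component widths")

    B = grid.values()
    opts = ExtractionOptions(baseline_correct=False, smooth=False)
    half_step = 0.5 * grid.step

    # Component overlap nudges the realized extrema off the component
    # placements; a fixed-point calibration of the placements makes the
    # realized splittings equal the requested ones.
    a_par_eff, a_perp_eff = params.A_par, params.A_perp
    clean = None
    for _ in range(30):
        clean = _anisotropic_clean(params, B, a_par_eff, a_perp_eff)
        check = extract_anisotropic_features(Spectrum(field=B, intensity=clean), opts)
        if not check.analyzable:
            raise ValueError(
                "unresolvable geometry: realized spectrum lacks four distinct extrema"
            )
        err_par = check.A_par_prime - params.A_par
        err_perp = check.A_perp_prime - params.A_perp
        if abs(err_par) <= 0.4 * half_step and abs(err_perp) <= 0.4 * half_step:
            break
        a_par_eff -= err_par
        a_perp_eff -= err_perp
        if not (a_par_eff > a_perp_eff > 0):
            raise ValueError("unresolvable geometry: placement calibration diverged")
    else:
        raise ValueError(
            "self-extraction mismatch: realized splittings did not converge to the "
            "requested ones within half a grid step"
        )
    return _finish(B, clean, params.noise_sd, params.baseline_slope, params.seed, metadata)
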