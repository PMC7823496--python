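"""Order parameter and rotational correlation times from spectral features.

The dynamic orientational order parameter is computed from the outer and
inner hyperfine half-splittings of an anisotropic (5-SASL-type) spectrum:

    a₀ = (A'∥ + 2·A'⊥) / 3
    S  = 0.5407 · (A'∥ − A'⊥) / a₀

S ranges from 1 (maximally ordered membrane) down to 0 (maximally
disordered); measured splittings near the rigid limit can push S outside
[0, 1], which is flagged rather than clamped so downstream statistics can
exclude such points explicitly.

The fast-motion rotational correlation times come from the three-line
(16-SASL-type) anatomy:

    τ₂B = 6.51·10⁻¹⁰ · ΔH₀ · (√(h₀/h₋) − √(h₀/h₊))           [s]
    τ₂C = 6.51·10⁻¹⁰ · ΔH₀ · (√(h₀/h₋) + √(h₀/h₊) − 2)       [s]

with ΔH₀ in gauss.  τ₂B reflects rotation about the long molecular axis
of the labelled chain, τ₂C motion perpendicular to it; lower values mean
greater motional freedom, i.e. higher local fluidity.  Features store
fields in mT; the mT→gauss conversion applied inside the τ formulas is
explicit and configurable via ``units``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .spectral_features import SpectralFeatures
from .synthetic_spectra import KIVELSON_PREFACTOR_S_PER_G, MT_TO_GAUSS

__all__ = [
    "OrderParameters",
    "CorrelationTimes",
    "order_parameter",
    "correlation_times",
    "S_PREFACTOR",
]

#: Prefactor of the order-parameter formula (dimensionless).
S_PREFACTOR = 0.5407


@dataclass(frozen=True)
class OrderParameters:
    """Order parameter S (dimensionless) and isotropic coupling a₀ (mT)."""

    S: float
    a0: float
    out_of_range: bool = False


@dataclass(frozen=True)
class CorrelationTimes:
    """Rotational correlation times in seconds."""

    tau2B: float
    tau2C: float


def order_parameter(features: SpectralFeatures) -> OrderParameters:
    """Compute S and a₀ from the anisotropic splittings of ``features``.

    Raises ``ValueError`` if the splittings are missing or a₀ is zero;
    S outside [0, 1] sets ``out_of_range`` instead of raising.
    """
    a_par, a_perp = features.A_par_prime, features.A_perp_prime
    if a_par is None or a_perp is None:
        raise ValueError("order_parameter requires A_par_prime and A_perp_prime")
    if a_par <= 0 or a_perp < 0:
        raise ValueError(f"splittings must be positive, got A'par={a_par}, A'perp={a_perp}")
    a0 = (a_par + 2.0 * a_perp) / 3.0
    if a0 == 0.0:
        raise ValueError("a0 is zero; order parameter undefined")
    s = S_PREFACTOR * (a_par - a_perp) / a0
    return OrderParameters(S=s, a0=a0, out_of_range=not (0.0 <= s <= 1.0))


def correlation_times(
    features: SpectralFeatures, units: str = "gauss"
) -> CorrelationTimes:
    """Compute τ₂B and τ₂C from the fast-motion anatomy of ``features``.

    ``units`` selects the field unit ΔH₀ takes inside the formulas:
    ``"gauss"`` (default: the stored mT value is multiplied by 10) or
    ``"mT"`` (used as-is).  Raises ``ValueError`` for missing features or
    non-positive amplitudes.
    """
    needed = (features.deltaH0, features.h_plus, features.h_zero, features.h_minus)
    if any(v is None for v in needed):
        raise ValueError("correlation_times requires deltaH0, h_plus, h_zero, h_minus")
    dh0, h_p, h_0, h_m = needed
    if min(h_p, h_0, h_m) <= 0:
        raise ValueError(f"amplitudes must be positive, got h+={h_p}, h0={h_0}, h-={h_m}")
    if dh0 <= 0:
        raise ValueError(f"deltaH0 must be positive, got {dh0}")
    if units == "gauss":
        dh0 = dh0 * MT_TO_GAUSS
    elif units != "mT":
        raise ValueError(f"units must be 'gauss' or 'mT', got {units!r}")
    r_minus = (h_0 / h_m) ** 0.5
    r_plus = (h_0 / h_p) ** 0.5
    pref = KIVELSON_PREFACTOR_S_PER_G * dh0
    return CorrelationTimes(
        tau2B=pref * (r_minus - r_plus),
        tau2C=pref * (r_minus + r_plus - 2.0),
    )
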