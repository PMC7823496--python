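"""Chlorophyll and carotenoid quantification from 80 %-acetone extracts.

Concentrations in µg/mL of extract from absorbances at 663.2, 664.8 and
470 nm (the standard coefficient set for 80 % aqueous acetone):

    Ca    = 12.25·A663.2 − 2.79·A664.8
    Cb    = 21.50·A664.8 − 5.10·A663.2
    Ca+b  =  7.15·A663.2 + 18.71·A664.8
    Cx+c  = (1000·A470 − 1.82·Ca − 85.02·Cb) / 198

The coefficient identity (12.25 − 5.10 = 7.15, 21.50 − 2.79 = 18.71)
makes Ca + Cb = Ca+b exact.  Negative results are flagged (a blank or
turbidity indicator), never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

__all__ = ["PigmentAbsorbances", "PigmentConcentrations", "pigment_concentrations",
           "DEFAULT_DILUTION_FACTOR"]

#: Extract volume over sample volume: 2.09 mL acetone + 0.01 mL sample.
DEFAULT_DILUTION_FACTOR = 210.0


@dataclass(frozen=True)
class PigmentAbsorbances:
    """One absorbance triple with its extract dilution factor."""

    A663_2: float
    A664_8: float
    A470: float
    dilution_factor: float = DEFAULT_DILUTION_FACTOR

    def __post_init__(self) -> None:
        if min(self.A663_2, self.A664_8, self.A470) < 0:
            raise ValueError("absorbances must be >= 0")
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be > 0")


@dataclass(frozen=True)
class PigmentConcentrations:
    """Pigment concentrations in µg/mL of extract.

    ``per_sample`` (µg/mL of original sample, = extract value ×
    dilution factor) is populated when requested.
    """

    Ca: float
    Cb: float
    Ca_plus_b: float
    Cx_plus_c: float
    negative_flag: bool = False
    per_sample: Optional[dict] = None


def pigment_concentrations(
    absorbances: PigmentAbsorbances, per_sample: bool = False
) -> PigmentConcentrations:
    """Apply the 80 %-acetone equations to one absorbance triple."""
    a1, a2, a3 = absorbances.A663_2, absorbances.A664_8, absorbances.A470
    ca = 12.25 * a1 - 2.79 * a2
    cb = 21.50 * a2 - 5.10 * a1
    cab = 7.15 * a1 + 18.71 * a2
    cxc = (1000.0 * a3 - 1.82 * ca - 85.02 * cb) / 198.0
    values = {"Ca": ca, "Cb": cb, "Ca_plus_b": cab, "Cx_plus_c": cxc}
    sample = None
    if per_sample:
        d = absorbances.dilution_factor
        sample = {k: v * d for k, v in values.items()}
    return PigmentConcentrations(
        Ca=ca,
        Cb=cb,
        Ca_plus_b=cab,
        Cx_plus_c=cxc,
        negative_flag=min(values.values()) < 0,
        per_sample=sample,
    )
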