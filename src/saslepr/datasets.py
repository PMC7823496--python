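"""Bundled reference data.

The fatty-acid mole-percent composition of chloroplast membranes from the
barley cultivar Delisa and its brassinosteroid-deficient 522DK mutant,
grown at 20 °C and acclimated at 5 °C or 27 °C (published GC-FAME
measurements; ``<LOD`` marks below-detection cells).  Used as the worked
input for the unsaturation-ratio computations and their validation.
"""

from __future__ import annotations

from .lipid_composition import FattyAcidProfile, profiles_from_csv_text

__all__ = [
    "BARLEY_CHLOROPLAST_FA_CSV",
    "BARLEY_PUBLISHED_RATIOS",
    "load_barley_chloroplast_profiles",
]

BARLEY_CHLOROPLAST_FA_CSV = """\
fatty_acid,delisa_20C,522DK_20C,delisa_5C,522DK_5C,delisa_27C,522DK_27C
10:0,<LOD,0.79,0.47,0.50,<LOD,0.35
12:0,4.00,3.93,4.49,4.37,4.12,4.60
14:0,0.28,0.25,0.23,0.19,0.29,0.21
16:0,16.54,18.76,16.16,17.41,17.20,16.11
16:1,6.29,4.95,4.25,4.23,6.45,3.36
18:0,3.53,3.24,3.37,3.47,2.96,2.59
18:1 d9cis,1.05,1.84,0.93,1.15,1.36,1.54
18:2 d6cis,4.24,4.32,3.05,3.01,6.85,7.64
18:3 n3,63.87,61.85,66.45,65.33,60.43,63.28
20:1,0.19,0.06,0.34,0.34,0.34,0.31
"""

#: Ratio rows as published alongside the composition (authors computed
#: them from unrounded data, so recomputation from the table matches to
#: within rounding).
BARLEY_PUBLISHED_RATIOS = {
    "18:3/18:2": {
        "delisa_20C": 15.09,
        "522DK_20C": 14.38,
        "delisa_5C": 22.29,
        "522DK_5C": 21.70,
        "delisa_27C": 8.84,
        "522DK_27C": 8.29,
    },
    "U/S": {
        "delisa_20C": 3.11,
        "522DK_20C": 2.72,
        "delisa_5C": 3.01,
        "522DK_5C": 2.86,
        "delisa_27C": 3.08,
        "522DK_27C": 3.20,
    },
}


def load_barley_chloroplast_profiles() -> dict[str, FattyAcidProfile]:
    """Parse the bundled composition into one profile per genotype × temperature."""
    return profiles_from_csv_text(BARLEY_CHLOROPLAST_FA_CSV, layout="wide")
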