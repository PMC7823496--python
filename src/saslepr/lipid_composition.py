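"""Fatty-acid composition summaries from GC-FAME mole-percent tables.

Profiles map fatty-acid identifiers (``carbon:double_bonds`` with an
optional positional tag, e.g. ``18:1 d9cis``) to mole percent.  Cells
reported below the detection limit (``<LOD``) parse to 0 with a flag and
never abort a ratio.  Two membrane-fluidity proxies are computed:

* U/S — total unsaturated over total saturated mole percent;
* 18:3/18:2 — trienoic over dienoic C18 mole percent.

Saturation is classified purely by the double-bond count parsed from the
identifier; positional tags are ignored.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FattyAcidProfile",
    "unsaturation_ratio",
    "trienoic_dienoic_ratio",
    "parse_fatty_acid_id",
    "read_profiles_long",
    "read_profiles_wide",
]

_FA_ID = re.compile(r"^\s*(\d+)\s*:\s*(\d+)")
LOD_TOKEN = "<LOD"


def parse_fatty_acid_id(identifier: str) -> tuple[int, int]:
    """Return (carbon_count, double_bond_count); raises on unparseable ids."""
    m = _FA_ID.match(identifier)
    if m is None:
        raise ValueError(f"not a fatty-acid identifier: {identifier!r}")
    return int(m.group(1)), int(m.group(2))


@dataclass
class FattyAcidProfile:
    """Mole-percent composition of one sample with below-detection flags."""

    entries: dict[str, float]
    lod_flags: set[str] = field(default_factory=set)
    sample_id: str = ""

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            parse_fatty_acid_id(key)
            if value < 0:
                raise ValueError(f"negative mole percent for {key}: {value}")
        total = sum(self.entries.values())
        if self.entries and not 95.0 <= total <= 105.0:
            warnings.warn(
                f"mole percents of {self.sample_id or 'profile'} sum to {total:.2f}, "
                "outside the [95, 105] audit range",
                stacklevel=2,
            )

    def percent(self, carbon: int, double_bonds: int) -> float:
        """Summed mole percent over entries with the given chain chemistry."""
        return sum(
            v
            for k, v in self.entries.items()
            if parse_fatty_acid_id(k) == (carbon, double_bonds)
        )


def unsaturation_ratio(profile: FattyAcidProfile) -> float:
    """Total unsaturated over total saturated mole percent (U/S)."""
    unsat = sum(v for k, v in profile.entries.items() if parse_fatty_acid_id(k)[1] >= 1)
    sat = sum(v for k, v in profile.entries.items() if parse_fatty_acid_id(k)[1] == 0)
    if sat == 0:
        raise ValueError("no saturated fatty acid with positive value; U/S undefined")
    return unsat / sat


def trienoic_dienoic_ratio(profile: FattyAcidProfile) -> float:
    """18:3 over 18:2 mole percent; 18:3 below detection yields 0."""
    dienoic = profile.percent(18, 2)
    if dienoic <= 0:
        raise ValueError("18:2 absent or zero; 18:3/18:2 undefined")
    return profile.percent(18, 3) / dienoic


def _cell_to_value(cell) -> tuple[float, bool]:
    if isinstance(cell, str) and cell.strip().upper() == LOD_TOKEN.upper():
        return 0.0, True
    value = float(cell)
    return value, False


def _build(sample_id: str, raw: dict[str, object]) -> FattyAcidProfile:
    entries: dict[str, float] = {}
    flags: set[str] = set()
    for fa, cell in raw.items():
        value, is_lod = _cell_to_value(cell)
        entries[fa] = value
        if is_lod:
            flags.add(fa)
    return FattyAcidProfile(entries=entries, lod_flags=flags, sample_id=sample_id)


def read_profiles_long(source) -> dict[str, FattyAcidProfile]:
    """Read a long-format CSV (sample, fatty_acid, mol_percent)."""
    df = pd.read_csv(source, dtype={"mol_percent": str})
    required = {"sample", "fatty_acid", "mol_percent"}
    if not required.issubset(df.columns):
        raise ValueError(f"long format requires columns {sorted(required)}")
    out: dict[str, FattyAcidProfile] = {}
    for sample, group in df.groupby("sample", sort=False):
        raw = dict(zip(group["fatty_acid"], group["mol_percent"]))
        out[str(sample)] = _build(str(sample), raw)
    return out


def read_profiles_wide(source) -> dict[str, FattyAcidProfile]:
    """Read a wide CSV: first column fatty-acid ids, one column per sample.

    Rows whose first cell is not a ``carbon:double_bonds`` identifier
    (e.g. derived-ratio rows) are ignored.
    """
    df = pd.read_csv(source, dtype=str)
    id_col = df.columns[0]
    keep = df[id_col].map(lambda s: _FA_ID.match(str(s)) is not None)
    df = df[keep]
    out: dict[str, FattyAcidProfile] = {}
    for sample in df.columns[1:]:
        raw = dict(zip(df[id_col], df[sample]))
        out[str(sample)] = _build(str(sample), raw)
    return out


def profiles_from_csv_text(text: str, layout: str = "wide") -> dict[str, FattyAcidProfile]:
    """Parse an in-memory CSV string in either supported layout."""
    reader = read_profiles_wide if layout == "wide" else read_profiles_long
    return reader(io.StringIO(text))
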