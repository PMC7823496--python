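"""Readers and writers for the plain-text spectrum dialect and result tables.

A spectrum file is two-column ASCII (field in mT, first-derivative
intensity in arbitrary units), whitespace- or comma-separated, preceded
by ``#``-prefixed ``key: value`` metadata lines.  Values are written with
17 significant digits so write→read round-trips are exact.  A JSON
sidecar (same path + ``.json``) can carry the metadata instead.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral_features import SpectralFeatures
from .synthetic_spectra import Spectrum

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "features_to_dataframe",
    "write_features_csv",
    "read_features_csv",
]

FEATURE_COLUMNS = [
    "A_par_prime_mT",
    "A_perp_prime_mT",
    "deltaH0_mT",
    "h_plus",
    "h_zero",
    "h_minus",
    "analyzable",
]


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def write_spectrum(spectrum: Spectrum, path, json_sidecar: bool = False) -> Path:
    path = Path(path)
    lines = []
    if json_sidecar:
        Path(str(path) + ".json").write_text(json.dumps(spectrum.metadata, indent=2))
    else:
        for key, value in spectrum.metadata.items():
            lines.append(f"# {key}: {value}")
    lines.append("# field_mT intensity")
    for b, i in zip(spectrum.field, spectrum.intensity):
        lines.append(f"{b:.17g} {i:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    metadata: dict = {}
    field, intensity = [], []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                metadata[key.strip()] = _coerce(value.strip())
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed data line {raw!r}")
        field.append(float(parts[0]))
        intensity.append(float(parts[1]))
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        metadata.update(json.loads(sidecar.read_text()))
    metadata.pop("field_mT intensity", None)
    if not field:
        raise ValueError(f"{path}: no data points")
    return Spectrum(field=np.asarray(field), intensity=np.asarray(intensity), metadata=metadata)


def features_to_dataframe(features: list[tuple[str, SpectralFeatures]]) -> pd.DataFrame:
    """One row per spectrum, columns in the documented order."""
    rows = []
    for spectrum_id, f in features:
        rows.append(
            {
                "spectrum_id": spectrum_id,
                "A_par_prime_mT": f.A_par_prime,
                "A_perp_prime_mT": f.A_perp_prime,
                "deltaH0_mT": f.deltaH0,
                "h_plus": f.h_plus,
                "h_zero": f.h_zero,
                "h_minus": f.h_minus,
                "analyzable": f.analyzable,
            }
        )
    return pd.DataFrame(rows, columns=["spectrum_id"] + FEATURE_COLUMNS)


def write_features_csv(features: list[tuple[str, SpectralFeatures]], path) -> Path:
    path = Path(path)
    features_to_dataframe(features).to_csv(path, index=False, float_format="%.17g")
    return path


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
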