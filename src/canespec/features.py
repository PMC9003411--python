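"""Vegetation indices and the modeling feature table.

Ten classical broadband indices computed from 5-band canopy
reflectance (B 475, G 560, R 668, RE 717, NIR 840 nm).  All formulas
take strictly positive reflectance, which every upstream producer in
this package guarantees, so ratio denominators never vanish.

Note: MSRI as defined here, (NIR/R - 1)/(NIR/R + 1), is algebraically
identical to NDVI for positive reflectance; it is kept as a separate
registry entry because both names circulate in the crop-sensing
literature and redundancy is exactly what the downstream selection
stage is designed to detect.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import BANDS, SpectralSample

_A = np.asarray  # formulas are vectorized; scalars pass through as 0-d


def _ndvi(B, G, R, RE, NIR):
    return (NIR - R) / (NIR + R)


def _msri(B, G, R, RE, NIR):
    sr = NIR / R
    return (sr - 1.0) / (sr + 1.0)


def _osavi(B, G, R, RE, NIR):
    return 1.16 * (NIR - R) / (NIR + R + 0.16)


def _rvi(B, G, R, RE, NIR):
    return NIR / R


def _savi(B, G, R, RE, NIR):
    return 1.5 * (NIR - R) / (NIR + R + 0.5)


def _sipi(B, G, R, RE, NIR):
    return (NIR - B) / (NIR + B)


def _srpi(B, G, R, RE, NIR):
    return B / R


def _npci(B, G, R, RE, NIR):
    return (R - B) / (R + B)


def _rvi2(B, G, R, RE, NIR):
    return NIR / G


def _ngbdi(B, G, R, RE, NIR):
    return (G - B) / (G + B)


#: name -> (function, human-readable formula, bands used)
VI_REGISTRY: dict[str, tuple] = {
    "NDVI": (_ndvi, "(NIR - R)/(NIR + R)", ("R", "NIR")),
    "MSRI": (_msri, "(NIR/R - 1)/(NIR/R + 1)", ("R", "NIR")),
    "OSAVI": (_osavi, "1.16 (NIR - R)/(NIR + R + 0.16)", ("R", "NIR")),
    "RVI": (_rvi, "NIR/R", ("R", "NIR")),
    "SAVI": (_savi, "1.5 (NIR - R)/(NIR + R + 0.5)", ("R", "NIR")),
    "SIPI": (_sipi, "(NIR - B)/(NIR + B)", ("B", "NIR")),
    "SRPI": (_srpi, "B/R", ("B", "R")),
    "NPCI": (_npci, "(R - B)/(R + B)", ("B", "R")),
    "RVI2": (_rvi2, "NIR/G", ("G", "NIR")),
    "NGBDI": (_ngbdi, "(G - B)/(G + B)", ("B", "G")),
}

VI_NAMES = tuple(VI_REGISTRY)


def registry_json() -> str:
    """Dump the index registry (name, formula, bands) for documentation."""
    return json.dumps(
        {name: {"formula": f, "bands": list(b)} for name, (_, f, b) in VI_REGISTRY.items()},
        indent=2,
    )


def compute_vi(name: str, reflectance: dict[str, float] | pd.DataFrame):
    """Evaluate one index from 5-band reflectance.

    `reflectance` is a mapping band -> value (scalars or arrays) or a
    DataFrame with columns refl_B..refl_NIR.
    """
    if name not in VI_REGISTRY:
        raise KeyError(f"unknown VI {name!r}; registry: {', '.join(VI_REGISTRY)}")
    fn = VI_REGISTRY[name][0]
    if isinstance(reflectance, pd.DataFrame):
        vals = [_A(reflectance[f"refl_{b}"].to_numpy(float)) for b in BANDS]
    else:
        vals = [_A(reflectance[b], dtype=float) for b in BANDS]
    for b, v in zip(BANDS, vals):
        if np.any(v <= 0):
            raise ValueError(f"reflectance in band {b} must be strictly positive")
    out = fn(*vals)
    return float(out) if np.ndim(out) == 0 else out


def build_feature_table(
    samples: list[SpectralSample] | pd.DataFrame,
    vi_names: Sequence[str] = VI_NAMES,
) -> pd.DataFrame:
    """Assemble the modeling table: identifiers, treatments, band
    reflectance columns, and one column per requested index.

    Row order follows the input.  Unknown index names raise with the
    registry listed.  Absent CNC stays NaN — explicit, never dropped.
    """
    unknown = [n for n in vi_names if n not in VI_REGISTRY]
    if unknown:
        raise KeyError(
            f"unknown VI name(s) {unknown}; registry: {', '.join(VI_REGISTRY)}"
        )
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
    else:
        from .synthetic import samples_to_frame

        df = samples_to_frame(samples)
    for name in vi_names:
        df[name] = compute_vi(name, df)
    return df


BAND_FEATURES = tuple(f"refl_{b}" for b in BANDS)


def feature_columns(table: pd.DataFrame, include_vis: bool = True) -> list[str]:
    cols = [c for c in BAND_FEATURES if c in table.columns]
    if include_vis:
        cols += [c for c in VI_NAMES if c in table.columns]
    return cols


def resolve_feature_set(table: pd.DataFrame, names: Iterable[str]) -> list[str]:
    """Map user-facing feature names to table columns.

    Accepts band names ('R', 'blue', 'refl_NIR'), VI names, and the
    shorthand 'FR' for all five band reflectances.
    """
    alias = {b.lower(): f"refl_{b}" for b in BANDS}
    alias.update(
        {"blue": "refl_B", "green": "refl_G", "red": "refl_R",
         "rededge": "refl_RE", "red_edge": "refl_RE", "nir": "refl_NIR"}
    )
    out: list[str] = []
    for n in names:
        key = n.strip()
        if key.upper() == "FR":
            out.extend(BAND_FEATURES)
            continue
        if key in table.columns:
            out.append(key)
        elif key.lower() in alias:
            out.append(alias[key.lower()])
        elif key.upper() in VI_NAMES:
            out.append(key.upper())
        else:
            raise KeyError(f"cannot resolve feature {n!r}")
    missing = [c for c in out if c not in table.columns]
    if missing:
        raise KeyError(f"feature columns not in table: {missing}")
    return out
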