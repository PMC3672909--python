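"""Biomarker preprocessing: LOD substitution, creatinine adjustment,
daily output, log transform, and geometric summaries.

All cadmium concentrations are in ug/L, creatinine in g/L, 24-hr urine
volume in L/day; logs are natural throughout.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "LOD_DEFAULT",
    "substitute_lod",
    "creatinine_adjust",
    "daily_output",
    "gm_gsd",
    "process_samples",
]

LOD_DEFAULT = 0.1   # ug/L, assay limit of detection


def substitute_lod(value, lod: float = LOD_DEFAULT):
    """Replace non-detects by LOD/sqrt(2).

    Values strictly below ``lod`` are replaced by ``lod / sqrt(2)``
    (0.0707... ug/L at the default 0.1 ug/L limit, conventionally printed
    0.07); values at or above the limit are detects and pass through
    unchanged.  Accepts scalars or arrays.  Idempotent: the substitution
    value is itself below the limit and maps back to itself.
    """
    if lod <= 0:
        raise ValueError("lod must be positive")
    sub = lod / math.sqrt(2.0)
    arr = np.asarray(value, dtype=float)
    out = np.where(arr < lod, sub, arr)
    return float(out) if np.isscalar(value) else out


def creatinine_adjust(cadmium, creatinine):
    """Creatinine-adjusted concentration, ug/g = (ug/L) / (g/L)."""
    cr = np.asarray(creatinine, dtype=float)
    if np.any(cr <= 0):
        raise ValueError("creatinine must be positive")
    out = np.asarray(cadmium, dtype=float) / cr
    return float(out) if np.isscalar(cadmium) and np.isscalar(creatinine) else out


def daily_output(cadmium, volume):
    """24-hr cadmium output, ug/day = (ug/L) x (L/day)."""
    vol = np.asarray(volume, dtype=float)
    if np.any(vol <= 0):
        raise ValueError("volume must be positive")
    out = np.asarray(cadmium, dtype=float) * vol
    return float(out) if np.isscalar(cadmium) and np.isscalar(volume) else out


def gm_gsd(values: Iterable[float]) -> tuple[float, float]:
    """Geometric mean and geometric SD of positive values.

    GM = exp(mean(ln x)); GSD = exp(sd(ln x)) with the sample (n-1)
    standard deviation.  With a single value the GSD is undefined (NaN).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("gm_gsd requires at least one value")
    if np.any(arr <= 0):
        raise ValueError("gm_gsd requires strictly positive values")
    logs = np.log(arr)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if arr.size > 1 else float("nan")
    return gm, gsd


def process_samples(samples: pd.DataFrame, lod: float = LOD_DEFAULT) -> pd.DataFrame:
    """Derive the analysis columns from raw urine-sample records.

    Adds ``cadmium_sub`` (LOD-substituted concentration; a record is a
    non-detect when flagged ``below_lod`` or when its value lies below the
    limit), ``cd_per_creatinine`` (ug/g), ``cd_output`` (ug/day),
    ``log_cd`` and ``log_cd_adj`` (natural logs of the substituted and
    creatinine-adjusted concentrations).
    """
    required = {"cadmium_ugL", "creatinine_gL", "volume_L"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples missing columns: {sorted(missing)}")
    out = samples.copy()
    cd = out["cadmium_ugL"].to_numpy(dtype=float)
    flagged = (
        out["below_lod"].to_numpy(dtype=bool)
        if "below_lod" in out.columns
        else np.zeros(len(out), dtype=bool)
    )
    sub = np.where(flagged | (cd < lod), lod / math.sqrt(2.0), cd)
    out["cadmium_sub"] = sub
    out["cd_per_creatinine"] = creatinine_adjust(sub, out["creatinine_gL"].to_numpy())
    out["cd_output"] = daily_output(sub, out["volume_L"].to_numpy())
    out["log_cd"] = np.log(sub)
    out["log_cd_adj"] = np.log(out["cd_per_creatinine"].to_numpy())
    return out
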