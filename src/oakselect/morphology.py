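"""Stem volume and relative growth rate from repeated height/diameter measures.

Stem volume is approximated as a conoid, V = H * pi * Drc^2 / 12 (cm^3),
from height H (cm, root collar to apical meristem) and root-collar diameter
Drc (cm). Relative growth rate is the log-volume change per day,
RGR = (ln V_final - ln V_initial) / (T_final - T_initial).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["conoid_volume", "relative_growth_rate", "rescale_traits"]


def conoid_volume(H, Drc):
    """Conoid stem volume in cm^3 from height and root-collar diameter (cm)."""
    H = np.asarray(H, dtype=float)
    Drc = np.asarray(Drc, dtype=float)
    if np.any(H < 0) or np.any(Drc < 0):
        raise ValueError("height and diameter must be non-negative")
    v = H * math.pi * Drc**2 / 12.0
    return float(v) if v.ndim == 0 else v


def relative_growth_rate(Vinit, Vfinal, Tinit, Tfinal):
    """Per-day relative growth rate (ln Vfinal - ln Vinit)/(Tfinal - Tinit)."""
    Vinit = np.asarray(Vinit, dtype=float)
    Vfinal = np.asarray(Vfinal, dtype=float)
    Tinit = np.asarray(Tinit, dtype=float)
    Tfinal = np.asarray(Tfinal, dtype=float)
    if np.any(Vinit <= 0) or np.any(Vfinal <= 0):
        raise ValueError("volumes must be positive")
    if np.any(Tfinal <= Tinit):
        raise ValueError("measurement interval must be positive")
    r = (np.log(Vfinal) - np.log(Vinit)) / (Tfinal - Tinit)
    return float(r) if r.ndim == 0 else r


def rescale_traits(
    table: pd.DataFrame, traits: Sequence[str], factor: float
) -> pd.DataFrame:
    """Multiply the listed trait columns by a constant factor.

    Used to bring very small trait values (e.g. RGR in per-day units) onto a
    numerically comfortable scale before variance-component estimation;
    heritability is invariant to the rescaling since both V_g and V_e scale
    by factor^2. The applied factors are recorded in ``table.attrs``.
    """
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise KeyError(f"unknown trait column(s): {missing}")
    out = table.copy()
    for t in traits:
        out[t] = out[t] * factor
    scales = dict(out.attrs.get("trait_scale_factors", {}))
    for t in traits:
        scales[t] = scales.get(t, 1.0) * factor
    out.attrs["trait_scale_factors"] = scales
    return out
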