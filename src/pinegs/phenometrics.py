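"""Growth-trait derivation from tabulated stem measurements.

Terrestrial laser scanning yields, per tree, the stem circumference at
1.2 m, total height, and the horizontal deviations of the stem centerline
from an imaginary straight baseline (root collar to 6 m) at heights
0.5, 1.5, ..., 5.5 m.  This module turns those tabulated values into the
four analysis traits:

* DBH (m): circumference at 1.2 m divided by pi,
* height (m): as measured,
* volume (m^3): the index DBH^2 x height,
* straightness: -ln(SD of the six centerline deviations) — the closer the
  stem tracks the baseline, the smaller the SD and the larger the score.

Point-cloud acquisition and segmentation are upstream of this module; the
contract starts at the measurement table.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: measurement-noise floor (m) used to cap the straightness score when the
#: six deviations are numerically identical; sub-millimeter by construction.
SD_FLOOR = 1e-6

N_CENTERLINE = 6


def dbh_from_circumference(circumference: float) -> float:
    """Diameter at breast height from the stem circumference at 1.2 m."""
    c = np.asarray(circumference, dtype=float)
    if np.any(c <= 0) or not np.all(np.isfinite(c)):
        raise ValueError("circumference must be positive and finite")
    out = c / math.pi
    return float(out) if out.ndim == 0 else out


def stem_volume(dbh: float, height: float) -> float:
    """Volume index DBH^2 x height (m^3)."""
    d = np.asarray(dbh, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(d <= 0) or np.any(h <= 0) or not (np.all(np.isfinite(d)) and np.all(np.isfinite(h))):
        raise ValueError("dbh and height must be positive and finite")
    out = d**2 * h
    return float(out) if out.ndim == 0 else out


def straightness_score(distances, ddof: int = 1) -> float:
    """-ln of the standard deviation of the six centerline deviations.

    Parameters
    ----------
    distances
        Exactly six non-negative deviations (m) of the stem centerline from
        the baseline at heights 0.5-5.5 m.
    ddof
        SD denominator convention; 1 (sample SD) by default.

    A perfectly straight stem has SD 0; the score is then capped at
    ``-ln(SD_FLOOR)`` so downstream models stay finite.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape != (N_CENTERLINE,):
        raise ValueError(f"expected exactly {N_CENTERLINE} centerline distances, got shape {d.shape}")
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("centerline distances must be finite and non-negative")
    sd = float(np.std(d, ddof=ddof))
    return -math.log(max(sd, SD_FLOOR))


def derive_traits(measurements: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Phenotype columns from a measurement table.

    Expects columns ``id, circumference, height, d0p5 ... d5p5`` and returns
    ``id, dbh, height, straightness, volume``.
    """
    dist_cols = ["d0p5", "d1p5", "d2p5", "d3p5", "d4p5", "d5p5"]
    for col in ["id", "circumference", "height", *dist_cols]:
        if col not in measurements.columns:
            raise ValueError(f"measurement table missing column {col!r}")
    dbh = dbh_from_circumference(measurements["circumference"].to_numpy())
    height = measurements["height"].to_numpy(dtype=float)
    straight = np.array([
        straightness_score(row, ddof=ddof)
        for row in measurements[dist_cols].to_numpy(dtype=float)
    ])
    return pd.DataFrame(
        {
            "id": measurements["id"].to_numpy(),
            "dbh": dbh,
            "height": height,
            "straightness": straight,
            "volume": stem_volume(dbh, height),
        }
    )
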