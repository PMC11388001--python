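"""Narrowband-to-broadband albedo conversion.

Broadband surface albedo is estimated from visible-band reflectances with
the Landsat-7 weighting

    albedo = 0.443 * blue + 0.317 * green + 0.240 * red

(weights sum to 1.000, so the result is a convex combination of the band
values).  A helper aggregates per-pixel broadband albedo over a surface-class
mask, e.g. roof pixels, to characterise the control-case roof albedo.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["BAND_WEIGHTS", "broadband_albedo", "class_mean_albedo"]

BAND_WEIGHTS = {"blue": 0.443, "green": 0.317, "red": 0.240}


def broadband_albedo(blue, green, red):
    """Broadband albedo from blue/green/red reflectances, each in [0, 1]."""
    b = np.asarray(blue, dtype=float)
    g = np.asarray(green, dtype=float)
    r = np.asarray(red, dtype=float)
    for name, arr in (("blue", b), ("green", g), ("red", r)):
        if np.any((arr < 0.0) | (arr > 1.0)):
            raise ValueError(f"{name} reflectance outside [0, 1]")
    out = BAND_WEIGHTS["blue"] * b + BAND_WEIGHTS["green"] * g + BAND_WEIGHTS["red"] * r
    return out if out.ndim else float(out)


def class_mean_albedo(pixels: pd.DataFrame, mask_col: str = "mask") -> pd.DataFrame:
    """Mean broadband albedo per surface class.

    ``pixels`` must carry columns blue, green, red and a class/mask column
    (e.g. "roof"/"road").  Returns a DataFrame (class, mean_albedo).
    """
    required = {"blue", "green", "red", mask_col}
    if not required.issubset(pixels.columns):
        raise ValueError(f"pixel table must have columns {sorted(required)}")
    alb = broadband_albedo(pixels["blue"], pixels["green"], pixels["red"])
    out = (pd.DataFrame({"class": pixels[mask_col], "albedo": alb})
           .groupby("class", as_index=False)["albedo"].mean()
           .rename(columns={"albedo": "mean_albedo"}))
    return out
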