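"""Xenograft tumor growth quantification from caliper measurements.

Tumor volume from the two caliper diameters uses the modified-ellipsoid
formula ``V = pi/6 * a * b^2`` with ``a`` the longest and ``b`` the
perpendicular shorter diameter.  Growth curves are expressed as percent of a
reference-day volume per animal, averaged within treatment group; the
inhibition ratio between two groups is the ratio of their percent-growth
values.  Group statistics (one-way ANOVA, Tukey post-hoc) are delegated to
scipy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "tumor_volume",
    "load_measurements",
    "relative_growth",
    "inhibition_ratio",
    "group_comparison",
    "ENDPOINT_DIAMETER_MM",
]

#: Humane endpoint: animals are sacrificed when any diameter reaches 15 mm.
ENDPOINT_DIAMETER_MM = 15.0

GROUPS = ("control", "FUS", "RT", "FUS+RT")


def tumor_volume(a_mm, b_mm):
    """Modified-ellipsoid tumor volume ``pi/6 * a * b^2`` in mm^3.

    ``a`` must be the longest diameter; if the axes arrive swapped they are
    auto-swapped with a warning.  Accepts scalars or arrays.
    """
    a = np.asarray(a_mm, dtype=float)
    b = np.asarray(b_mm, dtype=float)
    if np.any(b <= 0) or np.any(a <= 0):
        raise ValueError("diameters must be positive")
    swapped = a < b
    if np.any(swapped):
        warnings.warn("a < b for some measurements; swapping axes", stacklevel=2)
        a, b = np.where(swapped, b, a), np.where(swapped, a, b)
    v = np.pi / 6.0 * a * b ** 2
    return float(v) if v.ndim == 0 else v


def load_measurements(path_or_df) -> pd.DataFrame:
    """Load caliper CSV (columns animal, group, day, a_mm, b_mm).

    Adds ``volume_mm3`` and the humane-endpoint flag (any diameter >= 15 mm).
    """
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) \
        else pd.read_csv(path_or_df)
    required = {"animal", "group", "day", "a_mm", "b_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    df["volume_mm3"] = tumor_volume(df["a_mm"].to_numpy(), df["b_mm"].to_numpy())
    df["endpoint"] = np.maximum(df["a_mm"], df["b_mm"]) >= ENDPOINT_DIAMETER_MM
    return df


def relative_growth(df: pd.DataFrame, reference_day: int = 0) -> pd.DataFrame:
    """Percent-of-baseline growth per animal and the group mean curve.

    Each animal's volumes are scaled to 100% at ``reference_day`` (measurement
    on that day is required); the group curve is the mean over animals at each
    measured day.  Returns a tidy DataFrame with columns
    ``group, day, percent_mean, percent_sem, n``.
    """
    df = df if "volume_mm3" in df.columns else load_measurements(df)
    out = []
    for animal, sub in df.groupby("animal"):
        base = sub.loc[sub["day"] == reference_day, "volume_mm3"]
        if base.empty:
            raise ValueError(f"animal {animal!r} has no day-{reference_day} baseline")
        pct = 100.0 * sub["volume_mm3"] / float(base.iloc[0])
        out.append(pd.DataFrame({"animal": animal, "group": sub["group"],
                                 "day": sub["day"], "percent": pct}))
    tidy = pd.concat(out, ignore_index=True)
    agg = (tidy.groupby(["group", "day"])["percent"]
           .agg(percent_mean="mean", percent_sem="sem", n="count")
           .reset_index())
    return agg


def inhibition_ratio(group_a_percent: float, group_b_percent: float) -> float:
    """Fold difference in percent growth between two groups (a over b)."""
    if group_a_percent <= 0 or group_b_percent <= 0:
        raise ValueError("percent growth values must be positive")
    return group_a_percent / group_b_percent


def group_comparison(df: pd.DataFrame, day: int, reference_day: int = 0) -> dict:
    """One-way ANOVA plus Tukey HSD across groups at a given day.

    Operates on percent-of-baseline values; statistics are standard library
    routines, reported as-is.
    """
    df = df if "volume_mm3" in df.columns else load_measurements(df)
    pcts = []
    labels = []
    for group, sub in df.groupby("group", sort=False):
        vals = []
        for animal, a_sub in sub.groupby("animal"):
            base = a_sub.loc[a_sub["day"] == reference_day, "volume_mm3"]
            at = a_sub.loc[a_sub["day"] == day, "volume_mm3"]
            if not base.empty and not at.empty:
                vals.append(100.0 * float(at.iloc[0]) / float(base.iloc[0]))
        if vals:
            pcts.append(np.asarray(vals))
            labels.append(group)
    if len(pcts) < 2:
        raise ValueError("need at least two groups with data at the requested day")
    f, p = stats.f_oneway(*pcts)
    tukey = stats.tukey_hsd(*pcts)
    return {"groups": labels, "anova_F": float(f), "anova_p": float(p),
            "tukey_pvalues": tukey.pvalue.tolist()}
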