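"""Egg morphometrics and clutch-level summaries.

Volume is estimated from external length/breadth calliper measurements with the
great-tit-specific formula v = 0.4673·L·B² + 0.042 (mm³); sphericity is the
breadth/length ratio. The module also implements the classical last-egg
deviation statistic D — the single-number summary of within-clutch investment
used in the comparative literature — and the first/late clutch classification
(first clutches start within 30 days of the year's earliest clutch).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Species-specific volume coefficients (great tit); override for other species.
VOLUME_COEF = 0.4673
VOLUME_CONST = 0.042

__all__ = [
    "compute_volume",
    "compute_sphericity",
    "invert_volume",
    "last_egg_deviation",
    "classify_clutch_lateness",
    "add_derived_columns",
    "clutch_summaries",
]


def compute_volume(length_mm, breadth_mm, *, coef: float = VOLUME_COEF,
                   const: float = VOLUME_CONST):
    """Egg volume (mm³) from length and breadth (mm).

    Uses v = coef·L·B² + const with species-specific constants.
    Accepts scalars or arrays; raises ``ValueError`` on non-positive input.
    """
    length_mm = np.asarray(length_mm, dtype=float)
    breadth_mm = np.asarray(breadth_mm, dtype=float)
    if np.any(length_mm <= 0) or np.any(breadth_mm <= 0):
        raise ValueError("length and breadth must be strictly positive (mm)")
    out = coef * length_mm * breadth_mm**2 + const
    return out if out.ndim else float(out)


def invert_volume(volume_mm3, sphericity, *, coef: float = VOLUME_COEF,
                  const: float = VOLUME_CONST):
    """Back-solve (length, breadth) from volume and sphericity s = B/L.

    With B = s·L, v = coef·s²·L³ + const, so L = ((v − const)/(coef·s²))^(1/3).
    Raises ``ValueError`` if the volume is not above the formula's constant term.
    """
    volume_mm3 = np.asarray(volume_mm3, dtype=float)
    sphericity = np.asarray(sphericity, dtype=float)
    if np.any(volume_mm3 <= const):
        raise ValueError("volume must exceed the formula constant; invalid config?")
    if np.any(sphericity <= 0) or np.any(sphericity > 1):
        raise ValueError("sphericity must lie in (0, 1]")
    length = np.cbrt((volume_mm3 - const) / (coef * sphericity**2))
    breadth = sphericity * length
    return length, breadth


def compute_sphericity(length_mm, breadth_mm):
    """Sphericity = breadth/length, in (0, 1] when length ≥ breadth."""
    length_mm = np.asarray(length_mm, dtype=float)
    breadth_mm = np.asarray(breadth_mm, dtype=float)
    if np.any(length_mm <= 0):
        raise ValueError("length must be strictly positive")
    out = breadth_mm / length_mm
    return out if out.ndim else float(out)


def last_egg_deviation(volumes, *, exclude_last: bool = False) -> float:
    """Last-egg deviation D, in percent of the clutch mean volume.

    ``volumes`` must be ordered by laying position. D = 100·(v_last − v̄)/v̄
    where v̄ by default averages all eggs including the last; set
    ``exclude_last=True`` for the convention that averages the earlier eggs only.
    """
    v = np.asarray(volumes, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("D requires at least two eggs ordered by position")
    ref = v[:-1].mean() if exclude_last else v.mean()
    if ref <= 0:
        raise ValueError("mean clutch volume must be positive")
    return float(100.0 * (v[-1] - ref) / ref)


def classify_clutch_lateness(first_egg_dates: pd.Series, years: pd.Series,
                             *, window_days: int = 30) -> pd.Series:
    """Classify clutches as 'first' or 'late' within each year.

    Per year, day 0 is the earliest first-egg date; clutches starting within
    ``window_days`` days (inclusive) are 'first', the rest 'late'.
    """
    dates = pd.to_datetime(first_egg_dates)
    if dates.isna().any():
        raise ValueError("missing first-egg dates")
    out = pd.Series(index=dates.index, dtype=object)
    for _, grp in dates.groupby(np.asarray(years)):
        delta = (grp - grp.min()).dt.days
        out.loc[grp.index] = np.where(delta <= window_days, "first", "late")
    return out


def add_derived_columns(eggs: pd.DataFrame) -> pd.DataFrame:
    """Append volume_mm3 and sphericity columns to an egg table (copy)."""
    out = eggs.copy()
    out["volume_mm3"] = compute_volume(out["length_mm"].values, out["breadth_mm"].values)
    out["sphericity"] = compute_sphericity(out["length_mm"].values, out["breadth_mm"].values)
    return out


def clutch_summaries(eggs: pd.DataFrame, *, exclude_last: bool = False,
                     lateness_window_days: int = 30) -> pd.DataFrame:
    """Per-clutch summary: size, first-egg date, lateness, mean volume and D.

    Expects derived columns (``add_derived_columns``) to be present or computable.
    """
    df = eggs if "volume_mm3" in eggs.columns else add_derived_columns(eggs)
    rows = []
    for cid, grp in df.groupby("clutch_id", sort=True):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            raise ValueError(f"clutch {cid}: positions must be exactly 1..n")
        rows.append({
            "clutch_id": cid,
            "year": int(grp["year"].iloc[0]),
            "clutch_size": len(grp),
            "first_egg_date": pd.to_datetime(grp["lay_date"].iloc[0]),
            "mean_volume_mm3": float(grp["volume_mm3"].mean()),
            "d_statistic": last_egg_deviation(grp["volume_mm3"].to_numpy(),
                                              exclude_last=exclude_last),
        })
    out = pd.DataFrame(rows)
    out["lateness"] = classify_clutch_lateness(out["first_egg_date"], out["year"],
                                               window_days=lateness_window_days)
    return out
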