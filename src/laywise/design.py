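"""Model-frame construction: scaling, temperature windows, collinearity screen.

The response (egg volume) and the dataset-level covariates (clutch size, 3-day
pre-laying minimum temperature) are standard-scored over the entire dataset;
laying position is standard-scored within each clutch so clutches of different
sizes share one functional scale. All scalings use the sample (n−1) standard
deviation and are recorded so every scaled column can be inverted exactly.
Laying date is computed but excluded from the default design: under a seasonal
temperature trend it is nearly collinear with the temperature window, which the
Pearson collinearity screen reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import add_derived_columns

__all__ = ["zscore_dataset", "zscore_within_clutch", "mean_tmin_window",
           "collinearity_screen", "build_model_frame", "ModelFrame"]


def zscore_dataset(values):
    """Standard-score over the whole dataset; returns (scaled, (mean, sd)).

    Uses the sample (n−1) standard deviation. Raises on a constant column.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("cannot z-score a constant column")
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    return (x - mean) / sd, (mean, sd)


def zscore_within_clutch(positions, clutch_ids):
    """Standard-score laying positions within each clutch (sample sd).

    Every clutch must have ≥ 2 eggs. Returns an array aligned with the input.
    """
    pos = np.asarray(positions, dtype=float)
    cid = np.asarray(clutch_ids)
    out = np.empty_like(pos)
    for c in pd.unique(cid):
        mask = cid == c
        p = pos[mask]
        if p.size < 2:
            raise ValueError(f"clutch {c!r} has a single egg; cannot scale position")
        out[mask] = (p - p.mean()) / p.std(ddof=1)
    return out


def mean_tmin_window(temps: pd.DataFrame, lay_date, *, window: int = 3,
                     interpolate: bool = False) -> float:
    """Mean daily minimum temperature over the ``window`` days before laying.

    The laying day itself is excluded (the window covers egg formation).
    Missing days raise unless ``interpolate`` allows single-day linear fill.
    """
    d = pd.to_datetime(lay_date)
    series = pd.Series(temps["tmin_c"].to_numpy(),
                       index=pd.to_datetime(temps["date"]))
    days = [d - pd.Timedelta(days=k) for k in range(window, 0, -1)]
    vals = []
    for day in days:
        if day in series.index:
            vals.append(float(series.loc[day]))
        elif interpolate:
            prev, nxt = day - pd.Timedelta(days=1), day + pd.Timedelta(days=1)
            if prev in series.index and nxt in series.index:
                vals.append(0.5 * (float(series.loc[prev]) + float(series.loc[nxt])))
            else:
                raise ValueError(f"temperature missing on {day.date()} and not "
                                 "bracketed for interpolation")
        else:
            raise ValueError(f"temperature missing on {day.date()}")
    return float(np.mean(vals))


def collinearity_screen(covariates: pd.DataFrame, *, threshold: float = 0.7):
    """Pairwise Pearson r matrix plus flagged high-|r| pairs.

    Returns ``(r_matrix, flags)`` where flags is a list of
    ``(col_a, col_b, r)`` with |r| above the threshold. Constant columns are
    rejected (their correlation is undefined).
    """
    if len(covariates) < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    for c in covariates.columns:
        if covariates[c].nunique() < 2:
            raise ValueError(f"column {c!r} is constant; correlation undefined")
    r = covariates.corr(method="pearson")
    flags = []
    cols = list(covariates.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if abs(r.loc[a, b]) > threshold:
                flags.append((a, b, float(r.loc[a, b])))
    return r, flags


def _tmin_windows(temps: pd.DataFrame, lay_dates, *, window: int = 3,
                  interpolate: bool = False) -> np.ndarray:
    """Vectorized 3-day formation-window means for many eggs at once."""
    tser = pd.Series(temps["tmin_c"].to_numpy(),
                     index=pd.to_datetime(temps["date"]))
    tser = tser[~tser.index.duplicated()]
    if interpolate:
        full = tser.reindex(pd.date_range(tser.index.min(), tser.index.max()))
        filled = full.interpolate(method="linear", limit=1, limit_area="inside")
        tser = filled
    lay = pd.to_datetime(pd.Series(lay_dates).reset_index(drop=True))
    cols = []
    for k in range(window, 0, -1):
        vals = tser.reindex(lay - pd.Timedelta(days=k)).to_numpy()
        if np.isnan(vals).any():
            bad = lay[np.isnan(vals)].dt.date.unique()[:5]
            raise ValueError("temperature missing within the formation window "
                             f"for laying dates near {list(bad)}")
        cols.append(vals)
    return np.mean(cols, axis=0)


@dataclass
class ModelFrame:
    """Per-egg model frame with dataset/within-clutch scalings recorded."""

    data: pd.DataFrame
    scaling_record: dict = field(default_factory=dict)

    def unscale(self, column: str, values):
        """Invert a dataset-level scaling using the stored (mean, sd)."""
        mean, sd = self.scaling_record[column]
        return np.asarray(values, dtype=float) * sd + mean

    @property
    def mean_volume(self) -> float:
        return self.scaling_record["volume_scaled"][0]

    @property
    def sd_volume(self) -> float:
        return self.scaling_record["volume_scaled"][1]


def build_model_frame(eggs: pd.DataFrame, temps: pd.DataFrame, *,
                      response: str = "volume_mm3",
                      interpolate_temps: bool = False) -> ModelFrame:
    """Assemble the scaled model frame from egg and temperature tables.

    Adds derived geometry columns when absent, computes the 3-day formation
    window temperature per egg, and produces the scaled columns the default
    model design expects (volume_scaled, position_z, clutch_size_scaled,
    tmin3_scaled), sorted by clutch then position so AR(1) structures can be
    applied blockwise.
    """
    df = add_derived_columns(eggs) if response not in eggs.columns else eggs.copy()
    df = df.sort_values(["clutch_id", "position"]).reset_index(drop=True)

    sizes = df.groupby("clutch_id")["position"].transform("max")
    df["clutch_size"] = sizes

    tmin3 = _tmin_windows(temps, df["lay_date"], interpolate=interpolate_temps)
    df["tmin3_c"] = tmin3
    # laying date as day offset from the year's first egg (screened, not modelled)
    dates = pd.to_datetime(df["lay_date"])
    year_start = dates.groupby(df["year"]).transform("min")
    df["lay_doy"] = (dates - year_start).dt.days.astype(float)

    record = {}
    df["volume_scaled"], record["volume_scaled"] = zscore_dataset(df[response])
    df["clutch_size_scaled"], record["clutch_size_scaled"] = zscore_dataset(df["clutch_size"])
    df["tmin3_scaled"], record["tmin3_scaled"] = zscore_dataset(df["tmin3_c"])
    df["position_z"] = zscore_within_clutch(df["position"], df["clutch_id"])

    return ModelFrame(data=df, scaling_record=record)
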