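"""Generative model for clutch-structured egg morphometrics.

Emulates a 5-year great-tit study: each year a set of clutches starts on a
random date inside the laying window, eggs are laid one per calendar day, and
egg volume is

    v = μ·(1 + b_year + b_clutch + f_order(z) + β_T·T̃ + γ·z·T̃ + ε),

with year and clutch random effects, a quadratic laying-order effect on the
within-clutch standard score z, an optional effect of the scaled 3-day
pre-laying minimum temperature T̃ (and its interaction with z), and a
within-clutch AR(1) residual ε restarting independently at each clutch
(stationary initialization, so the marginal variance is constant across
positions). Length and breadth are back-solved from volume under a sphericity
profile that increases along the laying sequence, so the geometry formulas are
exercised end to end. All latent effects are returned in a truth record for
recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .geometry import invert_volume

__all__ = ["SyntheticConfig", "quadratic_through", "default_order_effect",
           "generate_dataset"]

#: Clutch-size distribution over 4..10 eggs, mean ≈ 7.7 (the study population's
#: reported mean clutch size); configurable, not hard-coded downstream.
DEFAULT_CLUTCH_SIZE_PROBS = (0.005, 0.012, 0.060, 0.340, 0.400, 0.163, 0.020)

#: Order-effect anchor points (z, relative effect): first eggs ~2.5% below the
#: mean, a peak of ~+2% just past mid-sequence, last eggs back at the mean.
DEFAULT_ORDER_POINTS = ((-1.4, -0.025), (0.25, 0.02), (1.4, 0.0))


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the generative model.

    Effects are expressed as fractions of the grand mean volume; temperatures
    in °C; dates as day-of-year offsets.
    """

    n_years: int = 5
    clutches_per_year: int = 29
    clutch_size_probs: tuple = DEFAULT_CLUTCH_SIZE_PROBS
    grand_mean_volume: float = 1506.24
    between_clutch_cv: float = 0.0769
    between_year_sd: float = 0.015
    order_effect_points: tuple = DEFAULT_ORDER_POINTS
    temp_effect_slope: float = 0.0
    order_temp_interaction_amp: float = 0.0
    ar1_rho: float = 0.19
    residual_sd: float = 0.02
    season_start_doy: int = 80
    laying_window_days: int = 45
    temp_intercept: float = 6.0
    temp_trend_per_day: float = 0.12
    temp_noise_sd: float = 1.8
    first_year: int = 2000
    sphericity_base: float = 0.76
    sphericity_slope: float = 0.005
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.clutch_size_probs, dtype=float)
        if p.size != 7 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("clutch_size_probs must be 7 non-negative values over "
                             "sizes 4..10 summing to 1 within 1e-12")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")
        if self.between_clutch_cv < 0 or self.residual_sd < 0:
            raise ValueError("between_clutch_cv and residual_sd must be >= 0")
        z = [pt[0] for pt in self.order_effect_points]
        if len(z) != 3 or not (z[0] < z[1] < z[2]):
            raise ValueError("order_effect_points need three strictly increasing z values")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


def quadratic_through(points) -> np.ndarray:
    """Coefficients (a, b, c) of the unique quadratic a + b·z + c·z² through
    three points with distinct z values."""
    pts = np.asarray(points, dtype=float)
    z, y = pts[:, 0], pts[:, 1]
    if len(np.unique(z)) != 3:
        raise ValueError("degenerate interpolation: duplicated z among the points")
    V = np.column_stack([np.ones(3), z, z * z])
    return np.linalg.solve(V, y)


def default_order_effect(z, points=DEFAULT_ORDER_POINTS):
    """Relative laying-order effect (fraction of mean volume) at scaled position z."""
    a, b, c = quadratic_through(points)
    z = np.asarray(z, dtype=float)
    out = a + b * z + c * z * z
    return out if out.ndim else float(out)


def _position_scores(n: int) -> np.ndarray:
    """Within-clutch standard scores of positions 1..n (sample sd)."""
    pos = np.arange(1, n + 1, dtype=float)
    return (pos - pos.mean()) / pos.std(ddof=1)


def _temperature_table(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    # cover formation windows (3 days before first possible laying) through the
    # last possible laying day of a 10-egg clutch, with margin
    lo = cfg.season_start_doy - 5
    hi = cfg.season_start_doy + cfg.laying_window_days + 14
    for j in range(cfg.n_years):
        year = cfg.first_year + j
        base = date(year, 1, 1)
        doys = np.arange(lo, hi + 1)
        temps = (cfg.temp_intercept
                 + cfg.temp_trend_per_day * (doys - cfg.season_start_doy)
                 + rng.normal(0.0, cfg.temp_noise_sd, size=doys.size))
        for doy, t in zip(doys, temps):
            rows.append({"date": (base + timedelta(days=int(doy))).isoformat(),
                         "tmin_c": float(t)})
    return pd.DataFrame(rows)


def generate_dataset(config: SyntheticConfig):
    """Simulate (egg table, temperature table, truth record).

    Returns the egg CSV schema (clutch_id, year, lay_date, position, length_mm,
    breadth_mm), a daily minimum-temperature table (date, tmin_c), and a truth
    record holding every latent effect (year/clutch intercepts, order-effect
    coefficients, AR(1) residuals, per-egg true volumes).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    abc = quadratic_through(cfg.order_effect_points)
    temps = _temperature_table(cfg, rng)
    tmin_by_date = dict(zip(temps["date"], temps["tmin_c"]))

    sizes = np.arange(4, 11)
    b_year = rng.normal(0.0, cfg.between_year_sd, size=cfg.n_years)

    egg_rows = []
    truth_eggs = {k: [] for k in ("clutch_id", "b_clutch", "eps", "f_order",
                                  "z", "true_volume")}
    b_clutch_map = {}
    for j in range(cfg.n_years):
        year = cfg.first_year + j
        base = date(year, 1, 1)
        for c in range(cfg.clutches_per_year):
            cid = f"{year}-C{c + 1:03d}"
            start = cfg.season_start_doy + int(rng.integers(0, cfg.laying_window_days))
            n = int(rng.choice(sizes, p=np.asarray(cfg.clutch_size_probs)))
            b_clutch = rng.normal(0.0, cfg.between_clutch_cv)
            b_clutch_map[cid] = float(b_clutch)
            z = _position_scores(n)
            # AR(1) residuals, stationary start, restarting at each clutch
            eps = np.empty(n)
            eps[0] = rng.normal(0.0, cfg.residual_sd)
            innov_sd = cfg.residual_sd * np.sqrt(1.0 - cfg.ar1_rho**2)
            for t in range(1, n):
                eps[t] = cfg.ar1_rho * eps[t - 1] + rng.normal(0.0, innov_sd)
            for t in range(n):
                d = (base + timedelta(days=start + t)).isoformat()
                egg_rows.append({"clutch_id": cid, "year": year, "lay_date": d,
                                 "position": t + 1, "_z": z[t], "_eps": eps[t],
                                 "_b_year": b_year[j], "_b_clutch": b_clutch})

    eggs = pd.DataFrame(egg_rows)

    # 3-day formation-window temperature, dataset-scaled (only enters when the
    # temperature effect or interaction is switched on)
    tmin3 = np.empty(len(eggs))
    for i, d in enumerate(pd.to_datetime(eggs["lay_date"])):
        window = [(d - pd.Timedelta(days=k)).date().isoformat() for k in (3, 2, 1)]
        tmin3[i] = np.mean([tmin_by_date[w] for w in window])
    if tmin3.std(ddof=1) > 0:
        tmin3_scaled = (tmin3 - tmin3.mean()) / tmin3.std(ddof=1)
    else:
        tmin3_scaled = np.zeros_like(tmin3)

    z = eggs["_z"].to_numpy()
    f_order = abc[0] + abc[1] * z + abc[2] * z * z
    rel = (eggs["_b_year"].to_numpy() + eggs["_b_clutch"].to_numpy() + f_order
           + cfg.temp_effect_slope * tmin3_scaled
           + cfg.order_temp_interaction_amp * z * tmin3_scaled
           + eggs["_eps"].to_numpy())
    volume = cfg.grand_mean_volume * (1.0 + rel)
    sph = np.clip(cfg.sphericity_base + cfg.sphericity_slope * z, 0.5, 1.0)
    length, breadth = invert_volume(volume, sph)

    truth_eggs["clutch_id"] = eggs["clutch_id"].tolist()
    truth_eggs["b_clutch"] = eggs["_b_clutch"].tolist()
    truth_eggs["eps"] = eggs["_eps"].tolist()
    truth_eggs["f_order"] = f_order.tolist()
    truth_eggs["z"] = z.tolist()
    truth_eggs["true_volume"] = volume.tolist()

    out = eggs[["clutch_id", "year", "lay_date", "position"]].copy()
    out["length_mm"] = length
    out["breadth_mm"] = breadth

    truth = {
        "config": {f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)},
        "order_effect_coef": abc.tolist(),
        "b_year": {cfg.first_year + j: float(b_year[j]) for j in range(cfg.n_years)},
        "b_clutch": b_clutch_map,
        "eggs": truth_eggs,
        "tmin3_scaled": tmin3_scaled.tolist(),
    }
    return out, temps, truth
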