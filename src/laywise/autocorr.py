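"""Within-clutch residual-dependence analysis.

Two jobs: (1) the two-pass AR(1) procedure — fit without an autocorrelation
structure, estimate the pooled lag-1 correlation of the residuals from all
within-clutch consecutive pairs, refit with that ρ fixed; and (2) the
per-clutch ACF/PACF profile of residuals, aggregated per lag (mean ± sd over
clutches) against the ±2/√n̄ white-noise band, where n̄ is the mean clutch
size. Lags are egg-position offsets, which equal days under one-egg-per-day
laying. PACF uses the Durbin–Levinson recursion on the sample autocorrelations
(the least-squares autoregression under the empirical second moments, as in
R's pacf); at lag 1 it coincides with the ACF exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelFrame
from .gamm import AdditiveMixedModel, ModelDesign, fit_gamm

__all__ = ["lag1_residual_rho", "two_pass_ar_fit", "clutch_acf", "clutch_pacf",
           "whitenoise_band", "aggregate_lag_stats", "LagCorrelation",
           "residual_lag_table"]


def lag1_residual_rho(residuals, clutch_ids):
    """Pooled lag-1 Pearson correlation of within-clutch consecutive residuals.

    Builds all (r_{t−1}, r_t) pairs within clutches (rows must be ordered by
    position within clutch), pools them, and returns
    ``(rho, t, df, p_value)`` with t = ρ·√df/√(1−ρ²), df = #pairs − 2.
    """
    r = np.asarray(residuals, dtype=float)
    cid = np.asarray(clutch_ids)
    same = cid[1:] == cid[:-1]
    lead, lag = r[:-1][same], r[1:][same]
    if lead.size < 3:
        raise ValueError("need at least 3 within-clutch pairs")
    rho = float(stats.pearsonr(lead, lag).statistic)
    df = lead.size - 2
    if abs(rho) >= 1.0 - 1e-12:
        raise FloatingPointError("degenerate lag-1 correlation (|rho| = 1)")
    t = rho * np.sqrt(df) / np.sqrt(1.0 - rho * rho)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return rho, float(t), int(df), p


def two_pass_ar_fit(design: ModelDesign, frame: ModelFrame,
                    group_col: str = "clutch_id") -> dict:
    """Two-pass AR(1) estimation: fit without AR, estimate ρ from the pooled
    lag-1 residual correlation, refit with that ρ fixed.

    Returns a dict with both fitted models, the estimated ρ and its test.
    """
    pass1 = fit_gamm(design.with_rho(None), frame, group_col=group_col)
    rho, t, df, p = lag1_residual_rho(pass1.residuals_,
                                      frame.data[group_col].to_numpy())
    pass2 = fit_gamm(design.with_rho(rho), frame, group_col=group_col)
    return {"pass1": pass1, "pass2": pass2, "rho": rho, "t": t, "df": df,
            "p_value": p}


def clutch_acf(series, max_lag: int | None = None, *, center: str = "series"):
    """Sample autocorrelation of one short series for lags 0..max_lag.

    Standard estimator: c_ℓ = (1/n)Σ(x_t − x̄)(x_{t+ℓ} − x̄), r_ℓ = c_ℓ/c_0,
    so r_0 ≡ 1. ``center='global'`` skips per-series centering (for residuals
    already centered over the dataset); default centers by the series mean.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = n - 2
    if n < max_lag + 2:
        raise ValueError("series too short for requested lag")
    xc = x - (x.mean() if center == "series" else 0.0)
    c0 = float(xc @ xc) / n
    if c0 <= 0:
        raise ValueError("constant series: autocorrelation undefined")
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for l in range(1, max_lag + 1):
        out[l] = float(xc[:-l] @ xc[l:]) / n / c0
    return out


def clutch_pacf(series, max_lag: int | None = None, *, center: str = "series"):
    """Partial autocorrelation for lags 1..max_lag via Durbin–Levinson.

    Equals the last coefficient of the order-ℓ autoregression solved from the
    empirical autocovariances (Yule–Walker normal equations); identical to the
    ACF at lag 1.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag is None:
        max_lag = n - 2
    r = clutch_acf(x, max_lag, center=center)
    phi = np.zeros((max_lag + 1, max_lag + 1))
    out = np.empty(max_lag)
    out[:] = np.nan
    phi[1, 1] = r[1]
    out[0] = r[1]
    denom_prev = 1.0 - r[1] ** 2
    for l in range(2, max_lag + 1):
        if denom_prev <= 1e-12:
            break  # singular autoregression; remaining lags omitted (NaN)
        num = r[l] - float(phi[l - 1, 1:l] @ r[l - 1:0:-1])
        phi[l, l] = num / denom_prev
        phi[l, 1:l] = phi[l - 1, 1:l] - phi[l, l] * phi[l - 1, l - 1:0:-1]
        out[l - 1] = phi[l, l]
        denom_prev *= 1.0 - phi[l, l] ** 2
    return out


def whitenoise_band(mean_clutch_size: float) -> float:
    """Half-width 2/√n̄ of the white-noise non-significance band."""
    if mean_clutch_size <= 0:
        raise ValueError("mean clutch size must be positive")
    return 2.0 / np.sqrt(mean_clutch_size)


@dataclass
class LagCorrelation:
    """Aggregate of per-clutch lag coefficients at one lag."""

    lag: int
    kind: str                      # 'acf' | 'pacf'
    residual_type: str             # 'raw' | 'standardized'
    per_clutch: list = field(default_factory=list)
    mean: float = np.nan
    sd: float = np.nan
    band_halfwidth: float = np.nan
    mean_within_band: bool = True
    interval_overlaps_zero: bool = True


def aggregate_lag_stats(per_clutch: dict, band: float, *, lag: int,
                        kind: str = "acf",
                        residual_type: str = "raw") -> LagCorrelation:
    """Mean ± sd over clutches of one lag's coefficients, with the white-noise
    band and the two significance flags (mean inside band; mean±sd overlaps 0)."""
    items = [(cid, c) for cid, c in per_clutch.items() if np.isfinite(c)]
    if len(items) < 2:
        raise ValueError(f"fewer than 2 clutches contribute at lag {lag}")
    vals = np.array([c for _, c in items])
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return LagCorrelation(
        lag=lag, kind=kind, residual_type=residual_type, per_clutch=items,
        mean=mean, sd=sd, band_halfwidth=band,
        mean_within_band=bool(abs(mean) <= band),
        interval_overlaps_zero=bool(mean - sd <= 0.0 <= mean + sd),
    )


def residual_lag_table(residuals, clutch_ids, *, max_lag: int | None = None,
                       residual_type: str = "raw",
                       center: str = "series") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-clutch ACF/PACF of residuals plus the per-lag aggregate summary.

    A clutch contributes at lag ℓ only if its size is ≥ ℓ + 2; the maximum lag
    defaults to (largest clutch size − 2). Returns ``(tidy, summary)`` — the
    tabular twin of the study's lag-profile figure.
    """
    r = np.asarray(residuals, dtype=float)
    cid = np.asarray(clutch_ids)
    sizes = pd.Series(cid).value_counts()
    if max_lag is None:
        max_lag = int(sizes.max()) - 2
    band = whitenoise_band(float(sizes.mean()))

    coefs = {("acf", l): {} for l in range(1, max_lag + 1)}
    coefs.update({("pacf", l): {} for l in range(1, max_lag + 1)})
    for c in pd.unique(cid):
        x = r[cid == c]
        top = min(x.size - 2, max_lag)
        if top < 1:
            continue
        try:
            a = clutch_acf(x, top, center=center)
            pcf = clutch_pacf(x, top, center=center)
        except ValueError:
            continue
        for l in range(1, top + 1):
            coefs[("acf", l)][c] = float(a[l])
            if np.isfinite(pcf[l - 1]):
                coefs[("pacf", l)][c] = float(pcf[l - 1])

    tidy_rows, summary_rows = [], []
    for (kind, l), d in sorted(coefs.items()):
        if len(d) < 2:
            continue
        agg = aggregate_lag_stats(d, band, lag=l, kind=kind,
                                  residual_type=residual_type)
        for c, v in agg.per_clutch:
            tidy_rows.append({"lag": l, "kind": kind,
                              "residual_type": residual_type,
                              "clutch_id": c, "coefficient": v})
        summary_rows.append({"lag": l, "kind": kind,
                             "residual_type": residual_type,
                             "n_clutches": len(d), "mean": agg.mean,
                             "sd": agg.sd, "band_halfwidth": band,
                             "mean_within_band": agg.mean_within_band,
                             "interval_overlaps_zero": agg.interval_overlaps_zero})
    return pd.DataFrame(tidy_rows), pd.DataFrame(summary_rows)
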