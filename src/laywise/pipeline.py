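"""Configuration-driven orchestration of the full analysis.

One call (or one CLI invocation) runs: simulate or load the egg/temperature
tables → geometry → model frame → two-pass AR(1) fit → diagnostics (smooth
tests, deviance partition, concurvity, basis check) → residual lag analysis
(raw and AR-standardized residuals) → per-clutch D statistics, and writes the
tabular artifacts behind the study's result tables. All randomness flows from
one top-level seed; identical config + seed produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autocorr, gamm, geometry
from .design import build_model_frame, collinearity_screen
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("laywise")

__all__ = ["RunConfig", "validate_inputs", "run_full_analysis", "load_config"]


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one input mode is active."""

    mode: str = "simulate"                      # 'simulate' | 'files'
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    eggs_path: str | None = None
    temps_path: str | None = None
    column_map: dict = field(default_factory=dict)   # user columns -> schema
    include_order_temp_interaction: bool = False
    factor_smooth: bool = False
    partition_method: str = "drop_one"
    d_exclude_last: bool = False
    interpolate_temps: bool = False
    make_plots: bool = False
    seed: int = 0
    out_dir: str = "laywise_run"

    def __post_init__(self):
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files" and not (self.eggs_path and self.temps_path):
            raise ValueError("files mode needs eggs_path and temps_path")


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON) file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    syn = raw.pop("synthetic", {})
    cfg = RunConfig(**raw)
    if syn:
        cfg.synthetic = SyntheticConfig(**{**dataclasses.asdict(cfg.synthetic), **syn})
    return cfg


class ValidationError(ValueError):
    """Raised when input tables violate the data contract."""

    def __init__(self, issues):
        self.issues = issues
        super().__init__("input validation failed:\n" + "\n".join(issues))


def validate_inputs(eggs: pd.DataFrame, temps: pd.DataFrame, *,
                    interpolate_temps: bool = False,
                    strict_dates: bool = True):
    """Enforce the egg/temperature data contract; returns (eggs, temps, warnings).

    Hard failures (raised as :class:`ValidationError`): missing columns,
    non-positive or inverted dimensions, duplicated/gapped positions within a
    clutch, missing formation-window temperature days (unless interpolation is
    enabled). Laying-gap violations are warnings unless ``strict_dates``.
    """
    issues, warnings = [], []
    need = {"clutch_id", "year", "lay_date", "position", "length_mm", "breadth_mm"}
    missing = need - set(eggs.columns)
    if missing:
        raise ValidationError([f"egg table missing columns: {sorted(missing)}"])
    if not {"date", "tmin_c"} <= set(temps.columns):
        raise ValidationError(["temperature table must have columns date, tmin_c"])

    bad = eggs[(eggs["length_mm"] <= 0) | (eggs["breadth_mm"] <= 0)]
    for i in bad.index:
        issues.append(f"row {i}: non-positive egg dimensions")
    bad = eggs[eggs["length_mm"] < eggs["breadth_mm"]]
    for i in bad.index:
        issues.append(f"row {i}: breadth exceeds length")

    for cid, grp in eggs.groupby("clutch_id"):
        pos = np.sort(grp["position"].to_numpy())
        if not np.array_equal(pos, np.arange(1, len(pos) + 1)):
            issues.append(f"clutch {cid}: positions are not exactly 1..{len(pos)}")
            continue
        g = grp.sort_values("position")
        gaps = pd.to_datetime(g["lay_date"]).diff().dt.days.iloc[1:]
        if not (gaps == 1).all():
            msg = f"clutch {cid}: consecutive eggs not laid one day apart"
            (issues if strict_dates else warnings).append(msg)

    tdates = set(pd.to_datetime(temps["date"]))
    if not interpolate_temps:
        for i, d in zip(eggs.index, pd.to_datetime(eggs["lay_date"])):
            for k in (3, 2, 1):
                if d - pd.Timedelta(days=k) not in tdates:
                    issues.append(f"row {i}: temperature missing "
                                  f"{(d - pd.Timedelta(days=k)).date()}")
    if issues:
        raise ValidationError(issues)
    return eggs, temps, warnings


def _load_files(cfg: RunConfig):
    eggs = pd.read_csv(cfg.eggs_path)
    temps = pd.read_csv(cfg.temps_path)
    if cfg.column_map:
        eggs = eggs.rename(columns=cfg.column_map)
        temps = temps.rename(columns=cfg.column_map)
    return eggs, temps


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole pipeline and write CSV/JSON artifacts to out_dir.

    Returns a results dict with the fitted models and all output tables.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if cfg.mode == "simulate":
            syn = cfg.synthetic.replace(seed=cfg.seed)
            eggs, temps, truth = generate_dataset(syn)
            with open(out / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=1)
        else:
            eggs, temps = _load_files(cfg)
            truth = None
        log.info("stage=input rows=%d clutches=%d", len(eggs),
                 eggs["clutch_id"].nunique())

        stage = "validate"
        eggs, temps, warns = validate_inputs(eggs, temps,
                                             interpolate_temps=cfg.interpolate_temps)
        for w in warns:
            log.warning(w)

        stage = "design_prep"
        frame = build_model_frame(eggs, temps,
                                  interpolate_temps=cfg.interpolate_temps)
        screen, screen_flags = collinearity_screen(
            frame.data[["position_z", "clutch_size_scaled", "tmin3_scaled",
                        "lay_doy"]])

        stage = "two_pass_ar_fit"
        design = gamm.default_design(
            include_order_temp_interaction=cfg.include_order_temp_interaction,
            factor_smooth=cfg.factor_smooth)
        two = autocorr.two_pass_ar_fit(design, frame)
        fit = two["pass2"]
        log.info("stage=fit rho=%.4f dev_explained=%.4f", two["rho"],
                 fit.deviance_explained_)

        stage = "diagnostics"
        terms = pd.DataFrame([gamm.test_smooth(fit, t.name) for t in design.terms])
        position_terms = [t.name for t in design.terms
                          if "position_z" in t.covariates]
        partition = gamm.deviance_partition(design, frame, two["rho"],
                                            method=cfg.partition_method,
                                            groups={"position_terms": position_terms})
        conc = gamm.concurvity(fit)
        kcheck = gamm.basis_check(fit, frame)

        stage = "autocorr"
        cids = frame.data["clutch_id"].to_numpy()
        raw_tidy, raw_summary = autocorr.residual_lag_table(
            fit.residuals_, cids, residual_type="raw")
        std_tidy, std_summary = autocorr.residual_lag_table(
            fit.std_residuals_, cids, residual_type="standardized")
        lags = pd.concat([raw_tidy, std_tidy], ignore_index=True)
        lag_summary = pd.concat([raw_summary, std_summary], ignore_index=True)

        stage = "clutch_summaries"
        clutches = geometry.clutch_summaries(frame.data,
                                             exclude_last=cfg.d_exclude_last)
        curve = gamm.predict_order_effect(fit, frame)

        stage = "write"
        terms.to_csv(out / "terms.csv", index=False)
        partition.to_csv(out / "partition.csv", index=False)
        conc.to_csv(out / "concurvity.csv", index=False)
        kcheck.to_csv(out / "basis_check.csv", index=False)
        lags.to_csv(out / "lags.csv", index=False)
        lag_summary.to_csv(out / "lag_summary.csv", index=False)
        clutches.to_csv(out / "clutches.csv", index=False)
        curve.to_csv(out / "order_effect_curve.csv", index=False)
        screen.to_csv(out / "collinearity.csv")
        run_meta = {
            "seed": cfg.seed,
            "mode": cfg.mode,
            "rho_pass1": two["rho"],
            "rho_t": two["t"], "rho_df": two["df"], "rho_p": two["p_value"],
            "deviance_explained_pct": 100.0 * fit.deviance_explained_,
            "deviance_null": fit.deviance_null_,
            "deviance_residual": fit.deviance_,
            "edf": fit.edf_,
            "smoothing_params": fit.smoothing_params_,
            "mean_volume_mm3": frame.mean_volume,
            "collinearity_flags": [list(f) for f in screen_flags],
            "n_eggs": int(len(frame.data)),
            "n_clutches": int(frame.data["clutch_id"].nunique()),
            "config": _config_dict(cfg),
        }
        with open(out / "run.json", "w") as fh:
            json.dump(run_meta, fh, indent=1, default=float)

        if cfg.make_plots:
            stage = "plots"
            try:
                _plots(out, curve, lag_summary)
            except Exception as exc:          # plots are optional, never fatal
                log.warning("plotting skipped: %s", exc)

        return {"frame": frame, "two_pass": two, "terms": terms,
                "partition": partition, "concurvity": conc,
                "basis_check": kcheck, "lags": lags,
                "lag_summary": lag_summary, "clutches": clutches,
                "curve": curve, "run": run_meta, "truth": truth}
    except Exception:
        log.error("pipeline failed at stage=%s (partial artifacts in %s)",
                  stage, out)
        raise


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _plots(out: Path, curve: pd.DataFrame, lag_summary: pd.DataFrame):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["position_z"], curve["deviation_pct"], "k-")
    ax.fill_between(curve["position_z"],
                    curve["deviation_pct"] - 2 * curve["se_pct"],
                    curve["deviation_pct"] + 2 * curve["se_pct"], alpha=0.3)
    ax.axhline(0.0, color="r", lw=0.8)
    ax.set_xlabel("laying position (within-clutch z)")
    ax.set_ylabel("deviation from mean egg volume (%)")
    fig.tight_layout()
    fig.savefig(out / "order_effect.png", dpi=120)
    plt.close(fig)

    std = lag_summary[lag_summary["residual_type"] == "standardized"]
    fig, axes = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    for ax, kind in zip(axes, ("acf", "pacf")):
        sub = std[std["kind"] == kind]
        ax.errorbar(sub["lag"], sub["mean"], yerr=sub["sd"], fmt="^", color="tab:blue")
        if len(sub):
            b = float(sub["band_halfwidth"].iloc[0])
            ax.axhline(b, color="tab:blue", ls="--", lw=0.8)
            ax.axhline(-b, color="tab:blue", ls="--", lw=0.8)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_ylabel(kind.upper())
    axes[1].set_xlabel("lag (days within clutch)")
    fig.tight_layout()
    fig.savefig(out / "lag_profile.png", dpi=120)
    plt.close(fig)
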