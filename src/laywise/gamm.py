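"""Hierarchical penalized-smooth Gaussian model with AR(1) residuals.

The estimator fits

    y = β₀ + Σ_j f_j(x_j) + Σ_g b_g + ε,

where the f_j are penalized regression splines (cubic for one covariate,
isotropic thin-plate radial for two), the b_g are ridge-penalized random
intercepts (equivalent to i.i.d. Gaussian effects), and ε is optionally a
within-group AR(1) process handled by exact whitening: within each clutch
e₁ = r₁ and e_t = (r_t − ρ·r_{t−1})/√(1−ρ²), which has constant variance and
makes penalized least squares on the whitened data the exact GLS fit.

Smoothing parameters are chosen by minimizing the restricted-likelihood
criterion of the Gaussian model (a fast-REML-type criterion), with the scale
profiled out and a deterministic all-zeros initialization of the
log-smoothing-parameters so fits are reproducible without seeds. Diagnostics
follow standard GAM practice: Wald-like flatness tests per smooth built from
the coefficient subvector and its Bayesian covariance at a rank tied to the
term's effective degrees of freedom, deviance partitioning by dropping or
adding single terms under a fixed ρ, observed/worst-case concurvity, and a
nearest-neighbour k-index for basis-dimension adequacy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .bases import (CubicSplineBasis, RandomInterceptBasis, RandomSlopeBasis,
                    ThinPlateBasis)
from .design import ModelFrame

__all__ = ["SmoothTermSpec", "ModelDesign", "AdditiveMixedModel", "default_design",
           "fit_gamm", "test_smooth", "deviance_partition", "concurvity",
           "basis_check", "predict_order_effect"]


@dataclass(frozen=True)
class SmoothTermSpec:
    """One model term: a smooth, a random intercept, or a random slope.

    ``covariates`` holds 1 name (cubic regression spline) or 2 (isotropic
    thin-plate interaction); random terms name their grouping factor instead.
    """

    name: str
    covariates: tuple = ()
    k: int = 5
    is_random_intercept: bool = False
    is_factor_smooth: bool = False
    factor: str | None = None

    @property
    def basis(self) -> str:
        if self.is_random_intercept:
            return "random_intercept"
        if self.is_factor_smooth:
            return "factor_smooth"
        return "cubic_regression_spline" if len(self.covariates) == 1 else "thin_plate"

    def make_basis(self):
        if self.is_random_intercept:
            return RandomInterceptBasis(self.factor)
        if self.is_factor_smooth:
            return RandomSlopeBasis(self.factor, self.covariates[0])
        if len(self.covariates) == 1:
            return CubicSplineBasis(self.covariates[0], k=self.k)
        if len(self.covariates) == 2:
            return ThinPlateBasis(self.covariates, k=self.k)
        raise ValueError("a smooth takes 1 or 2 covariates")


@dataclass(frozen=True)
class ModelDesign:
    """Declarative model specification: response, terms, AR(1) structure."""

    response: str = "volume_scaled"
    terms: tuple = ()
    ar1_rho: float | None = None
    fit_criterion: str = "reml"

    def with_rho(self, rho):
        return replace(self, ar1_rho=rho)

    def drop(self, names) -> "ModelDesign":
        names = {names} if isinstance(names, str) else set(names)
        unknown = names - {t.name for t in self.terms}
        if unknown:
            raise KeyError(f"no term named {sorted(unknown)}")
        return replace(self, terms=tuple(t for t in self.terms
                                         if t.name not in names))

    def only(self, name: str) -> "ModelDesign":
        kept = tuple(t for t in self.terms if t.name == name)
        if not kept:
            raise KeyError(f"no term named {name!r}")
        return replace(self, terms=kept)


def default_design(*, include_order_temp_interaction: bool = False,
                   factor_smooth: bool = False,
                   ar1_rho: float | None = None) -> ModelDesign:
    """The study's default design: smooths of laying position (within-clutch
    scale), clutch size and formation-window temperature; isotropic bivariate
    interactions of position×clutch-size and temperature×clutch-size; random
    intercepts for year and clutch. The order×temperature surface and the
    per-clutch factor smooth are optional."""
    terms = [
        SmoothTermSpec("s(position_z)", ("position_z",), k=5),
        SmoothTermSpec("s(clutch_size)", ("clutch_size_scaled",), k=5),
        SmoothTermSpec("s(tmin3)", ("tmin3_scaled",), k=8),
        SmoothTermSpec("ti(position_z,clutch_size)",
                       ("position_z", "clutch_size_scaled"), k=25),
        SmoothTermSpec("ti(tmin3,clutch_size)",
                       ("tmin3_scaled", "clutch_size_scaled"), k=25),
        SmoothTermSpec("re(year)", factor="year", is_random_intercept=True),
        SmoothTermSpec("re(clutch_id)", factor="clutch_id", is_random_intercept=True),
    ]
    if include_order_temp_interaction:
        terms.insert(5, SmoothTermSpec("ti(position_z,tmin3)",
                                       ("position_z", "tmin3_scaled"), k=25))
    if factor_smooth:
        terms.append(SmoothTermSpec("fs(position_z|clutch)", ("position_z",),
                                    factor="clutch_id", is_factor_smooth=True))
    return ModelDesign(terms=tuple(terms), ar1_rho=ar1_rho)


def _whiten(A: np.ndarray, first: np.ndarray, rho: float) -> np.ndarray:
    """Apply the within-group AR(1) whitening transform row-wise.

    ``first`` marks the first row of each group; rows must be ordered by group
    then position. e₁ = r₁; e_t = (r_t − ρ r_{t−1})/√(1−ρ²).
    """
    if rho == 0.0:
        return A
    out = np.array(A, dtype=float, copy=True)
    later = ~first
    idx = np.where(later)[0]
    out[idx] = (A[idx] - rho * A[idx - 1]) / np.sqrt(1.0 - rho * rho)
    return out


class AdditiveMixedModel(RegressorMixin, BaseEstimator):
    """Penalized-smooth Gaussian additive mixed model.

    Parameters
    ----------
    design : ModelDesign
        Terms, response column and (optional) fixed AR(1) ρ.
    group_col : str
        Grouping column for the AR(1) blocks (independent across groups).
    tol : float
        Convergence tolerance on the restricted-likelihood criterion.

    Fitted attributes (trailing underscore) include ``coef_``, ``edf_``,
    ``smoothing_params_``, ``deviance_explained_``, ``residuals_``,
    ``std_residuals_``, ``scale_``, ``reml_criterion_``.
    """

    def __init__(self, design: ModelDesign | None = None, group_col: str = "clutch_id",
                 tol: float = 1e-8, max_evals: int = 4000,
                 fixed_smoothing: dict | None = None):
        self.design = design
        self.group_col = group_col
        self.tol = tol
        self.max_evals = max_evals
        self.fixed_smoothing = fixed_smoothing

    # ------------------------------------------------------------------ fit

    def fit(self, X: pd.DataFrame, y=None):
        design = self.design if self.design is not None else default_design()
        df = X.data if isinstance(X, ModelFrame) else X
        if y is None:
            y = df[design.response].to_numpy(dtype=float)
        else:
            y = np.asarray(y, dtype=float)
        n = len(df)
        rho = float(design.ar1_rho) if design.ar1_rho else 0.0
        if not -1.0 < rho < 1.0:
            raise ValueError("ar1_rho must lie in (-1, 1)")

        groups = df[self.group_col].to_numpy()
        first = np.ones(n, dtype=bool)
        first[1:] = groups[1:] != groups[:-1]
        if rho != 0.0:
            pos = df["position"].to_numpy() if "position" in df else None
            if pos is not None:
                ok = np.all(first | (np.r_[0, np.diff(pos)] == 1))
                if not ok:
                    raise ValueError("rows must be ordered by group then position "
                                     "for an AR(1) structure")

        # assemble blocks: column 0 is the unpenalized intercept
        cols = [np.ones((n, 1))]
        self.bases_ = []
        self.slices_ = {}
        self.penalties_ = []
        p = 1
        for spec in design.terms:
            basis = spec.make_basis()
            Xj, Sj = basis.build(df)
            if Xj.shape[1] == 0:
                raise ValueError(f"term {spec.name!r}: empty basis")
            self.bases_.append((spec, basis))
            self.slices_[spec.name] = slice(p, p + Xj.shape[1])
            w = np.linalg.eigvalsh(0.5 * (Sj + Sj.T))
            wpos = w[w > max(w.max(), 1.0) * 1e-9]
            self.penalties_.append({"S": Sj, "rank": int(wpos.size),
                                    "logdet": float(np.sum(np.log(wpos)))})
            cols.append(Xj)
            p += Xj.shape[1]
        Xmat = np.hstack(cols)
        if p >= n:
            raise ValueError(f"design has {p} coefficients for {n} rows")
        self.n_ = n
        self.p_ = p
        self.first_ = first
        self.rho_ = rho
        self.X_ = Xmat
        self.y_ = y

        Xw = _whiten(Xmat, first, rho)
        yw = _whiten(y[:, None], first, rho)[:, 0]
        XtX = Xw.T @ Xw
        Xty = Xw.T @ yw
        yty = float(yw @ yw)
        m = len(self.penalties_)
        mp = p - sum(b["rank"] for b in self.penalties_)

        fixed = dict(self.fixed_smoothing or {})
        unknown = set(fixed) - {t.name for t in design.terms}
        if unknown:
            raise ValueError(f"fixed_smoothing for unknown terms: {sorted(unknown)}")
        free_idx = [j for j, t in enumerate(design.terms) if t.name not in fixed]
        base_loglam = np.array([np.log(fixed.get(t.name, 1.0))
                                for t in design.terms])

        def assemble(loglam):
            H = XtX.copy()
            for j, pen in enumerate(self.penalties_):
                sl = self.slices_[design.terms[j].name]
                H[sl, sl] += np.exp(loglam[j]) * pen["S"]
            return H

        def expand(free):
            loglam = base_loglam.copy()
            loglam[free_idx] = np.clip(free, -18.0, 18.0)
            return loglam

        def criterion(loglam):
            H = assemble(loglam)
            try:
                L = np.linalg.cholesky(H)
            except np.linalg.LinAlgError:
                return 1e12
            beta = np.linalg.solve(H, Xty)
            rss_pen = max(yty - float(beta @ Xty), 1e-12)
            sig2 = rss_pen / (n - mp)
            logdetH = 2.0 * float(np.sum(np.log(np.diag(L))))
            logdetS = sum(pen["rank"] * loglam[j] + pen["logdet"]
                          for j, pen in enumerate(self.penalties_))
            return ((n - mp) * (1.0 + np.log(2.0 * np.pi * sig2))
                    + logdetH - logdetS)

        obj = lambda free: criterion(expand(free))
        if free_idx:
            x0 = np.zeros(len(free_idx))
            res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": self.tol,
                                             "maxfev": self.max_evals})
            # polish from the simplex optimum; cheap and improves reliability
            res2 = optimize.minimize(obj, res.x, method="Nelder-Mead",
                                     options={"xatol": 1e-8, "fatol": self.tol,
                                              "maxfev": self.max_evals // 2})
            loglam = expand(res2.x if res2.fun <= res.fun else res.x)
        else:
            loglam = base_loglam

        H = assemble(loglam)
        self.coef_ = np.linalg.solve(H, Xty)
        Hinv = np.linalg.inv(H)
        F = Hinv @ XtX
        rss_pen = max(yty - float(self.coef_ @ Xty), 1e-12)
        self.scale_ = rss_pen / (n - mp)
        self.coef_cov_ = self.scale_ * Hinv
        self.smoothing_params_ = {t.name: float(np.exp(loglam[j]))
                                  for j, t in enumerate(design.terms)}
        self.edf_ = {t.name: float(np.trace(F[self.slices_[t.name],
                                              self.slices_[t.name]]))
                     for t in design.terms}
        self.edf_total_ = float(np.trace(F))
        self.reml_criterion_ = float(criterion(loglam))

        self.fitted_ = Xmat @ self.coef_
        self.residuals_ = y - self.fitted_
        self.std_residuals_ = _whiten(self.residuals_[:, None], first, rho)[:, 0]

        # deviance accounting on the whitened scale (null = intercept only)
        resid_w = yw - Xw @ self.coef_
        self.deviance_ = float(resid_w @ resid_w)
        ones_w = _whiten(np.ones((n, 1)), first, rho)
        mu0 = float((ones_w[:, 0] @ yw) / (ones_w[:, 0] @ ones_w[:, 0]))
        null_resid = yw - ones_w[:, 0] * mu0
        self.deviance_null_ = float(null_resid @ null_resid)
        self.deviance_explained_ = 1.0 - self.deviance_ / self.deviance_null_
        self.design_ = design
        self.n_features_in_ = df.shape[1]
        return self

    # -------------------------------------------------------------- predict

    def _term_matrix(self, name: str, df: pd.DataFrame) -> np.ndarray:
        for spec, basis in self.bases_:
            if spec.name == name:
                return basis.matrix(df)
        raise KeyError(f"no term named {name!r}")

    def predict(self, X, *, include_random: bool = True) -> np.ndarray:
        df = X.data if isinstance(X, ModelFrame) else X
        out = np.full(len(df), self.coef_[0])
        for spec, basis in self.bases_:
            if not include_random and (spec.is_random_intercept or spec.is_factor_smooth):
                continue
            out += basis.matrix(df) @ self.coef_[self.slices_[spec.name]]
        return out

    def partial_effect(self, name: str, df: pd.DataFrame, *, se: bool = False):
        """Centered contribution of one term at new covariate values."""
        M = self._term_matrix(name, df)
        sl = self.slices_[name]
        eff = M @ self.coef_[sl]
        if not se:
            return eff
        V = self.coef_cov_[sl, sl]
        return eff, np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", M, V, M), 0.0))

    @property
    def term_names_(self):
        return [spec.name for spec, _ in self.bases_]


# ------------------------------------------------------------------ wrappers


def fit_gamm(design: ModelDesign, frame: ModelFrame, **kw) -> AdditiveMixedModel:
    """Fit the design on a model frame; returns the fitted estimator."""
    return AdditiveMixedModel(design=design, **kw).fit(frame)


def test_smooth(fit: AdditiveMixedModel, term: str) -> dict:
    """Wald-like test that a term's function is flat (zero).

    The statistic is built from the term's coefficient subvector and its
    Bayesian covariance, pseudo-inverted at a rank tied to the term's effective
    degrees of freedom; referenced against an F distribution with the model's
    residual degrees of freedom.
    """
    sl = fit.slices_[term]
    beta = fit.coef_[sl]
    V = 0.5 * (fit.coef_cov_[sl, sl] + fit.coef_cov_[sl, sl].T)
    edf = fit.edf_[term]
    dim = beta.size
    if edf < 1e-3:
        return {"term": term, "statistic": 0.0, "rank": 0, "edf": edf,
                "p_value": 1.0, "flag": "zero-edf term"}
    frac = edf - np.floor(edf)
    rank = int(np.floor(edf) + (1 if frac > 0.05 else 0))
    rank = max(1, min(rank, dim))
    # statistic on the term's fitted values: f̂' (X_j V X_j')⁻ f̂ truncated at
    # rank ≈ edf, via the thin SVD of X_j·V^{1/2}
    Xj = fit.X_[:, sl]
    fhat = Xj @ beta
    w, U = np.linalg.eigh(V)
    B = U * np.sqrt(np.clip(w, 0.0, None))
    Usv, sv, _ = np.linalg.svd(Xj @ B, full_matrices=False)
    sv2 = sv[:rank] ** 2
    sv2 = np.maximum(sv2, sv2[0] * 1e-12)
    t = Usv[:, :rank].T @ fhat
    stat = float(t @ (t / sv2))
    df2 = max(fit.n_ - fit.edf_total_, 1.0)
    p = float(stats.f.sf(stat / rank, rank, df2))
    return {"term": term, "statistic": stat / rank, "rank": rank, "edf": edf,
            "p_value": p, "flag": ""}


def deviance_partition(design: ModelDesign, frame: ModelFrame, rho: float | None,
                       method: str = "drop_one",
                       groups: dict | None = None) -> pd.DataFrame:
    """Per-term share of null deviance under a fixed AR(1) ρ.

    drop_one: share(term) = 100·(dev_expl(full) − dev_expl(full − term));
    add_one: share(term) = 100·dev_expl(intercept + term alone).
    ``method='both'`` reports both columns. Every sub-model re-optimizes its
    smoothing parameters under the same fixed ρ.

    ``groups`` maps a label to a list of term names; each group gets an extra
    drop-one row removing all its terms at once. Useful because a covariate's
    main effect and the interaction smooths containing it can stand in for one
    another, masking single-term drops.
    """
    if method not in ("drop_one", "add_one", "both"):
        raise ValueError("method must be drop_one, add_one or both")
    design = design.with_rho(rho)
    full = fit_gamm(design, frame)
    rows = []
    for t in design.terms:
        row = {"term": t.name, "rho": rho or 0.0,
               "full_dev_explained_pct": 100.0 * full.deviance_explained_}
        if method in ("drop_one", "both"):
            reduced = fit_gamm(design.drop(t.name), frame)
            row["drop_one_share_pct"] = 100.0 * (full.deviance_explained_
                                                 - reduced.deviance_explained_)
        if method in ("add_one", "both"):
            alone = fit_gamm(design.only(t.name), frame)
            row["add_one_share_pct"] = 100.0 * alone.deviance_explained_
        rows.append(row)
    for label, names in (groups or {}).items():
        reduced = fit_gamm(design.drop(names), frame)
        rows.append({"term": f"group:{label}", "rho": rho or 0.0,
                     "full_dev_explained_pct": 100.0 * full.deviance_explained_,
                     "drop_one_share_pct": 100.0 * (full.deviance_explained_
                                                    - reduced.deviance_explained_)})
    return pd.DataFrame(rows)


def concurvity(fit: AdditiveMixedModel) -> pd.DataFrame:
    """Observed and worst-case concurvity of each term against all others.

    Observed: share of the term's fitted contribution lying in the column span
    of every other term (plus intercept). Worst-case: largest squared singular
    value between the orthonormalized spans. Both clipped to [0, 1].
    """
    if len(fit.bases_) < 2:
        raise ValueError("concurvity needs at least two terms")
    rows = []
    for spec, basis in fit.bases_:
        sl = fit.slices_[spec.name]
        Xj = fit.X_[:, sl]
        f = Xj @ fit.coef_[sl]
        others = np.column_stack(
            [fit.X_[:, :1]] + [fit.X_[:, fit.slices_[s.name]]
                               for s, _ in fit.bases_ if s.name != spec.name])
        denom = float(f @ f)
        if denom <= 1e-12:
            rows.append({"term": spec.name, "observed": 0.0, "worst_case": 0.0,
                         "flag": "zero-contribution term"})
            continue
        theta, *_ = np.linalg.lstsq(others, f, rcond=None)
        resid = f - others @ theta
        obs = float(np.clip(1.0 - (resid @ resid) / denom, 0.0, 1.0))
        Qj, _ = np.linalg.qr(Xj)
        Qo, _ = np.linalg.qr(others)
        smax = np.linalg.svd(Qj.T @ Qo, compute_uv=False).max()
        rows.append({"term": spec.name, "observed": obs,
                     "worst_case": float(np.clip(smax**2, 0.0, 1.0)), "flag": ""})
    return pd.DataFrame(rows)


def basis_check(fit: AdditiveMixedModel, frame=None) -> pd.DataFrame:
    """Per-term basis-dimension adequacy: edf/k usage and a residual k-index.

    The k-index is the mean squared nearest-neighbour difference of the
    residuals, ordered by the term's (first) covariate, over twice the residual
    variance — ≈ 1 for white noise, substantially below 1 when the residuals
    still contain structure along that covariate. Terms whose edf comes within
    0.1 of their basis dimension are flagged for a larger k.
    """
    df = frame.data if isinstance(frame, ModelFrame) else (
        frame if frame is not None else None)
    r = fit.residuals_
    var = float(np.var(r))
    rows = []
    for spec, basis in fit.bases_:
        dim = fit.slices_[spec.name].stop - fit.slices_[spec.name].start
        edf = fit.edf_[spec.name]
        row = {"term": spec.name, "k_effective": dim, "edf": edf,
               "usage": edf / dim,
               "flag": "raise k" if dim - edf < 0.1 else ""}
        if spec.covariates and df is not None and var > 0:
            x = np.asarray(df[spec.covariates[0]], dtype=float)
            order = np.argsort(x, kind="stable")
            d = np.diff(r[order])
            row["k_index"] = float(np.mean(d * d) / (2.0 * var))
        else:
            row["k_index"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def predict_order_effect(fit: AdditiveMixedModel, frame: ModelFrame,
                         z_grid=None, *, term: str = "s(position_z)") -> pd.DataFrame:
    """Predicted laying-order effect curve on a z grid.

    Other covariates are held at their scaled means (0) and random effects at
    0, so the prediction is intercept + the position smooth. Returned on both
    axes of the study's investment figure: absolute volume (mm³), deviation
    from the dataset mean volume (mm³ and %). Grid points outside the observed
    z range are flagged as extrapolation.
    """
    zobs = fit.X_ is not None and np.asarray(frame.data["position_z"], dtype=float)
    if z_grid is None:
        z_grid = np.linspace(zobs.min(), zobs.max(), 101)
    z_grid = np.asarray(z_grid, dtype=float)
    grid_df = pd.DataFrame({"position_z": z_grid})
    eff, se = fit.partial_effect(term, grid_df, se=True)
    scaled = fit.coef_[0] + eff
    mean_v, sd_v = frame.mean_volume, frame.sd_volume
    out = pd.DataFrame({
        "position_z": z_grid,
        "volume_mm3": mean_v + sd_v * scaled,
        "deviation_mm3": sd_v * scaled,
        "deviation_pct": 100.0 * sd_v * scaled / mean_v,
        "se_pct": 100.0 * sd_v * se / mean_v,
        "extrapolated": (z_grid < zobs.min() - 1e-9) | (z_grid > zobs.max() + 1e-9),
    })
    return out
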