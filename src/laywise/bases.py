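"""Penalized smooth bases: cubic regression splines, isotropic thin-plate
radial smooths for bivariate interactions, and ridge-penalized random effects.

Each builder produces a design-matrix block, its quadratic penalty, and a
reproducible evaluator for new data. Univariate smooths are cubic B-splines
with the integrated-squared-second-derivative penalty (computed exactly by
2-point Gauss–Legendre quadrature per knot interval, since the integrand is
piecewise quadratic). Bivariate interactions use the thin-plate radial basis
η(r) = r²·log r on a deterministic knot subset; their {1, x, y} polynomial
null space is removed (it duplicates the univariate terms' null spaces and the
intercept), so interaction terms are fully penalized and shrink to zero — the
usual convention for interaction smooths added on top of main effects.

All smooths are sum-to-zero centered over the observed covariate values, with
the constraint absorbed by a null-space reparameterization, so the global
intercept is the only unconstrained constant in the model.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


def _nullspace_of_row(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z (p × p−m) of the null space of constraint rows c."""
    c = np.atleast_2d(np.asarray(c, dtype=float))
    _, _, vt = np.linalg.svd(c, full_matrices=True)
    return vt[c.shape[0]:].T


def _gauss2_weights(a: float, b: float):
    """2-point Gauss–Legendre nodes/weights on [a, b]."""
    h = 0.5 * (b - a)
    m = 0.5 * (a + b)
    x = np.array([m - h / np.sqrt(3.0), m + h / np.sqrt(3.0)])
    w = np.array([h, h])
    return x, w


class CubicSplineBasis:
    """Cubic regression spline on one covariate, k basis functions.

    Knots: boundary at the data range, interior at quantiles. Penalty:
    ∫ f''(x)² dx. After sum-to-zero centering the block has k−1 columns and a
    penalty of rank k−2 (the centered linear function is unpenalized).
    """

    def __init__(self, covariate: str, k: int = 5):
        self.covariate = covariate
        self.k = k

    def build(self, df):
        x = np.asarray(df[self.covariate], dtype=float)
        uniq = np.unique(x)
        k = int(min(self.k, uniq.size))
        if k < 4:
            raise ValueError(f"{self.covariate}: need k >= 4 (and that many unique "
                             f"values) for a cubic spline; got {k}")
        lo, hi = float(uniq[0]), float(uniq[-1])
        if k == 4:
            interior = np.array([])
        else:
            qs = np.linspace(0, 1, k - 2)[1:-1]
            interior = np.quantile(uniq, qs)
        self.knots_ = np.concatenate([[lo] * 4, interior, [hi] * 4])
        self.k_ = k

        raw = self._raw(x)
        S = self._penalty()
        # sum-to-zero over data, absorbed by reparameterization
        self.Z_ = _nullspace_of_row(raw.mean(axis=0))
        self.S_ = self.Z_.T @ S @ self.Z_
        return raw @ self.Z_, self.S_

    def _raw(self, x):
        x = np.clip(x, self.knots_[0], self.knots_[-1])
        return BSpline.design_matrix(x, self.knots_, 3).toarray()

    def _penalty(self):
        t, k = self.knots_, self.k_
        S = np.zeros((k, k))
        breaks = np.unique(t)
        for a, b in zip(breaks[:-1], breaks[1:]):
            xq, wq = _gauss2_weights(a, b)
            D = np.empty((2, k))
            for i in range(k):
                c = np.zeros(k)
                c[i] = 1.0
                D[:, i] = BSpline(t, c, 3).derivative(2)(xq)
            S += D.T @ (wq[:, None] * D)
        return 0.5 * (S + S.T)

    def matrix(self, df):
        return self._raw(np.asarray(df[self.covariate], dtype=float)) @ self.Z_


class ThinPlateBasis:
    """Isotropic bivariate thin-plate radial smooth for interaction surfaces.

    Basis η(‖x − κ_j‖) with η(r) = r² log r at up to k knots chosen as an
    evenly-spaced subset of the sorted unique covariate pairs (deterministic).
    The polynomial null space is projected out, the penalty is the (clipped)
    conditionally-positive-definite radial energy, and the block is sum-to-zero
    centered; every remaining direction is penalized.
    """

    def __init__(self, covariates, k: int = 25):
        self.covariates = tuple(covariates)
        self.k = k

    @staticmethod
    def _eta(r):
        out = np.zeros_like(r)
        nz = r > 0
        out[nz] = r[nz] ** 2 * np.log(r[nz])
        return out

    def build(self, df):
        X = np.column_stack([np.asarray(df[c], dtype=float) for c in self.covariates])
        uniq = np.unique(X, axis=0)
        if uniq.shape[0] < 6:
            raise ValueError("too few unique covariate pairs for a bivariate smooth")
        k = int(min(self.k, uniq.shape[0]))
        idx = np.round(np.linspace(0, uniq.shape[0] - 1, k)).astype(int)
        self.knots_ = uniq[np.unique(idx)]
        kk = self.knots_.shape[0]

        Ek = self._eta(np.linalg.norm(self.knots_[:, None, :] - self.knots_[None, :, :], axis=2))
        T = np.column_stack([np.ones(kk), self.knots_])
        Zd = _nullspace_of_row(T.T)                      # kk × (kk−3)
        P = Zd.T @ Ek @ Zd
        P = 0.5 * (P + P.T)
        w, V = np.linalg.eigh(P)
        w = np.clip(w, 0.0, None)                        # numerical safety
        P = (V * w) @ V.T
        self.Zd_ = Zd

        raw = self._radial(X) @ Zd
        self.Zc_ = _nullspace_of_row(raw.mean(axis=0))
        self.S_ = self.Zc_.T @ P @ self.Zc_
        return raw @ self.Zc_, self.S_

    def _radial(self, X):
        return self._eta(np.linalg.norm(X[:, None, :] - self.knots_[None, :, :], axis=2))

    def matrix(self, df):
        X = np.column_stack([np.asarray(df[c], dtype=float) for c in self.covariates])
        return self._radial(X) @ self.Zd_ @ self.Zc_


class RandomInterceptBasis:
    """I.i.d. Gaussian random intercepts as a ridge-penalized indicator block."""

    def __init__(self, factor: str):
        self.factor = factor

    def build(self, df):
        levels = np.asarray(sorted(set(df[self.factor])))
        self.levels_ = levels
        self.S_ = np.eye(levels.size)
        return self.matrix(df), self.S_

    def matrix(self, df):
        f = np.asarray(df[self.factor])
        out = np.zeros((f.size, self.levels_.size))
        pos = {lv: j for j, lv in enumerate(self.levels_)}
        for i, lv in enumerate(f):
            j = pos.get(lv)
            if j is not None:
                out[i, j] = 1.0
        return out


class RandomSlopeBasis:
    """Per-level random slopes in one covariate (first-order factor smooth)."""

    def __init__(self, factor: str, covariate: str):
        self.factor = factor
        self.covariate = covariate

    def build(self, df):
        self._ri = RandomInterceptBasis(self.factor)
        Z, _ = self._ri.build(df)
        self.S_ = np.eye(Z.shape[1])
        return self.matrix(df), self.S_

    def matrix(self, df):
        Z = self._ri.matrix(df)
        return Z * np.asarray(df[self.covariate], dtype=float)[:, None]
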