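"""Regression models for the kinematic parameter fits.

Three small scikit-learn-style estimators cover every fit in the analysis:
an ordinary least-squares line, a vertex-form parabola
``y = a*(x - b)**2 + c``, and a four-parameter logistic
``y = a + h / (1 + exp(-k*(x + b)))``.  All expose ``fit`` / ``predict``,
``get_params`` / ``set_params`` and trailing-underscore fitted attributes,
so they compose with sklearn model selection; the fitted estimator itself
is the "fit result" object the rest of the package passes around.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "SlopeInterceptRegression",
    "QuadraticVertexRegression",
    "LogisticCurveRegression",
]


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError("expected a 1-d predictor (or a single-column 2-d array)")
    if not np.all(np.isfinite(x)):
        raise ValueError("predictor contains non-finite values")
    return x


def _check_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    x = _as_1d(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("X and y lengths differ")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    return x, y


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan


class SlopeInterceptRegression(RegressorMixin, BaseEstimator):
    """Ordinary least squares of y on a single predictor.

    Fitted attributes: ``slope_``, ``intercept_``, ``slope_se_``,
    ``intercept_se_``, ``pearson_r_``, ``r_squared_``, ``n_``.
    """

    def fit(self, X, y):
        x, y = _check_xy(X, y)
        if len(x) < 2:
            raise ValueError("need at least 2 points")
        sxx = float(np.sum((x - x.mean()) ** 2))
        if sxx == 0:
            raise ValueError("zero variance in the predictor")
        sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
        self.slope_ = sxy / sxx
        self.intercept_ = float(y.mean() - self.slope_ * x.mean())
        resid = y - (self.slope_ * x + self.intercept_)
        dof = max(len(x) - 2, 1)
        sigma2 = float(np.sum(resid**2)) / dof
        self.slope_se_ = float(np.sqrt(sigma2 / sxx))
        self.intercept_se_ = float(np.sqrt(sigma2 * (1.0 / len(x) + x.mean() ** 2 / sxx)))
        syy = float(np.sum((y - y.mean()) ** 2))
        self.pearson_r_ = sxy / np.sqrt(sxx * syy) if syy > 0 else np.nan
        self.r_squared_ = _r_squared(y, self.slope_ * x + self.intercept_)
        self.n_ = len(x)
        return self

    def predict(self, X):
        return self.slope_ * _as_1d(X) + self.intercept_


class QuadraticVertexRegression(RegressorMixin, BaseEstimator):
    """Least-squares parabola in vertex form, y = a*(x - b)**2 + c.

    The fit is the unconstrained quadratic least-squares solution
    reparameterized to vertex form; standard errors of (a, b, c) follow by
    the delta method from the polynomial coefficient covariance.  Fitted
    attributes: ``a_``, ``b_``, ``c_``, ``a_se_``, ``b_se_``, ``c_se_``,
    ``r_squared_``, ``n_``, and ``sensitivity_mhz_`` (a in mHz/deg^2 when y
    is a rate in Hz and x an angle in degrees).
    """

    def fit(self, X, y):
        x, y = _check_xy(X, y)
        if len(np.unique(x)) < 3:
            raise ValueError("need at least 3 distinct predictor values")
        A = np.column_stack([x**2, x, np.ones_like(x)])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        p2, p1, p0 = coef
        if p2 == 0:
            raise ValueError("degenerate fit: zero quadratic coefficient")
        resid = y - A @ coef
        dof = max(len(x) - 3, 1)
        sigma2 = float(np.sum(resid**2)) / dof
        cov = sigma2 * np.linalg.inv(A.T @ A)
        self.a_ = float(p2)
        self.b_ = float(-p1 / (2.0 * p2))
        self.c_ = float(p0 - p1**2 / (4.0 * p2))
        # delta method: gradients of (a, b, c) w.r.t. (p2, p1, p0)
        g_a = np.array([1.0, 0.0, 0.0])
        g_b = np.array([p1 / (2.0 * p2**2), -1.0 / (2.0 * p2), 0.0])
        g_c = np.array([p1**2 / (4.0 * p2**2), -p1 / (2.0 * p2), 1.0])
        self.a_se_ = float(np.sqrt(g_a @ cov @ g_a))
        self.b_se_ = float(np.sqrt(g_b @ cov @ g_b))
        self.c_se_ = float(np.sqrt(g_c @ cov @ g_c))
        self.r_squared_ = _r_squared(y, A @ coef)
        self.n_ = len(x)
        return self

    @property
    def sensitivity_mhz_(self) -> float:
        return self.a_ * 1e3

    def predict(self, X):
        x = _as_1d(X)
        return self.a_ * (x - self.b_) ** 2 + self.c_


def _logistic(x, a, b, k, h):
    return a + h / (1.0 + np.exp(-k * (x + b)))


class LogisticCurveRegression(RegressorMixin, BaseEstimator):
    """Least-squares logistic y = a + h/(1 + exp(-k*(x + b))), h, k >= 0.

    Sigmoid least squares is multimodal, so the fit runs from several
    data-driven starts and keeps the best solution.  Fitted attributes:
    ``a_``, ``b_``, ``k_``, ``h_``, their standard errors, the (k, h)
    variances ``V_k_`` / ``V_h_``, ``fin_body_ratio_`` (= k*h/4, the
    maximal slope of the curve), ``r_squared_``, ``n_``.
    """

    def __init__(self, k_max: float = 10.0, h_max: float = 90.0, n_starts: int = 5,
                 tol: float = 1e-10):
        self.k_max = k_max
        self.h_max = h_max
        self.n_starts = n_starts
        self.tol = tol

    def _starts(self, x, y):
        h0 = float(np.clip(np.percentile(y, 95) - np.percentile(y, 5), 1e-3, self.h_max))
        a0 = float(np.percentile(y, 5))
        b0 = float(-np.median(x))
        x_scale = max(float(np.std(x)), 1e-6)
        ks = [1.0 / x_scale, 2.0 / x_scale, 0.5 / x_scale, 4.0 / x_scale, 0.25 / x_scale]
        starts = []
        for i in range(self.n_starts):
            k0 = float(np.clip(ks[i % len(ks)], 1e-4, self.k_max))
            starts.append([a0, b0, k0, h0])
        return starts

    def fit(self, X, y):
        x, y = _check_xy(X, y)
        if len(x) < 4:
            raise ValueError("need at least 4 points for a 4-parameter logistic")
        lo = [-np.inf, -np.inf, 0.0, 0.0]
        hi = [np.inf, np.inf, self.k_max, self.h_max]
        best, best_cov, best_sse = None, None, np.inf
        errors = []
        for p0 in self._starts(x, y):
            try:
                popt, pcov = curve_fit(
                    _logistic, x, y, p0=p0, bounds=(lo, hi),
                    ftol=self.tol, xtol=self.tol, gtol=self.tol, maxfev=20000,
                )
            except (RuntimeError, ValueError) as exc:
                errors.append(str(exc))
                continue
            sse = float(np.sum((y - _logistic(x, *popt)) ** 2))
            if sse < best_sse:
                best, best_cov, best_sse = popt, pcov, sse
        if best is None:
            raise RuntimeError(
                "logistic fit failed to converge from all starts: " + "; ".join(errors[:3])
            )
        self.a_, self.b_, self.k_, self.h_ = (float(v) for v in best)
        se = np.sqrt(np.clip(np.diag(best_cov), 0.0, np.inf))
        self.a_se_, self.b_se_, self.k_se_, self.h_se_ = (float(v) for v in se)
        self.V_k_ = float(best_cov[2, 2])
        self.V_h_ = float(best_cov[3, 3])
        self.r_squared_ = _r_squared(y, _logistic(x, *best))
        self.n_ = len(x)
        return self

    @property
    def fin_body_ratio_(self) -> float:
        """Maximal slope of the fitted sigmoid, exactly k*h/4."""
        return self.k_ * self.h_ / 4.0

    def predict(self, X):
        return _logistic(_as_1d(X), self.a_, self.b_, self.k_, self.h_)
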