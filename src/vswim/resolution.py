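"""Resampling-based resolution and power analysis.

How many bouts (or IBIs) are needed to resolve a given change in a
kinematic parameter?  Two complementary answers:

* :func:`ci_width_vs_n` — bootstrap N points, fit, convert the standard
  error into a 95% normal confidence-interval width, and report the mean
  (±SD) width over repeated resamples per N;
* :func:`effect_size_curve` — impose a fractional change on one
  coefficient (keeping the other coefficients and the y-residuals at the
  observed x values), bootstrap both the original and altered datasets,
  and summarize the separation of the two fitted-parameter distributions
  with Cohen's d, where the normalizing sigma is the SD of *all* the
  fitted values from both distributions pooled.

For the fin-body ratio (k*h/4) the standard error comes from the variance
propagation of a product, :func:`finbody_slope_variance`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import LogisticCurveRegression, QuadraticVertexRegression, SlopeInterceptRegression

__all__ = [
    "ResampleConfig",
    "EffectSizeConfig",
    "ci_width_vs_n",
    "finbody_slope_variance",
    "impose_effect",
    "effect_size_curve",
    "cohens_d",
    "fit_parameter",
    "PARAMETERS",
]

log = logging.getLogger(__name__)

PARAMETERS = ("sensitivity", "steering", "finbody", "righting")


@dataclass(frozen=True)
class ResampleConfig:
    n_resamples: int = 20
    confidence: float = 0.95
    sample_sizes: tuple[int, ...] = (500, 1000, 2000, 4000)

    def __post_init__(self) -> None:
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")


@dataclass(frozen=True)
class EffectSizeConfig:
    fractions: tuple[float, ...] = (-0.2, -0.1, 0.1, 0.2)
    inner_reps: int = 200
    outer_reps: int = 20
    fixed_angvel_lead: float = 40.0  # ms; fixed steering-related-rotation time

    def __post_init__(self) -> None:
        if self.inner_reps < 2:
            raise ValueError("inner_reps must be >= 2")
        if self.outer_reps < 1:
            raise ValueError("outer_reps must be >= 1")


def fit_parameter(parameter: str, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit one relationship on raw (x, y) points; return (estimate, SE).

    ``sensitivity`` is the quadratic coefficient of the bout-timing
    parabola (Hz/deg^2); ``steering`` / ``righting`` are OLS slopes;
    ``finbody`` is k*h/4 with its SE from :func:`finbody_slope_variance`.
    """
    if parameter == "sensitivity":
        fit = QuadraticVertexRegression().fit(x, y)
        return fit.a_, fit.a_se_
    if parameter in ("steering", "righting"):
        fit = SlopeInterceptRegression().fit(x, y)
        return fit.slope_, fit.slope_se_
    if parameter == "finbody":
        fit = LogisticCurveRegression().fit(x, y)
        se = float(np.sqrt(finbody_slope_variance(fit.k_, fit.h_, fit.V_k_, fit.V_h_)))
        return fit.fin_body_ratio_, se
    raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAMETERS}")


def ci_width_vs_n(x, y, parameter: str, cfg: ResampleConfig = ResampleConfig(),
                  seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Confidence-interval width of a kinematic parameter versus sample size.

    For each N, N points are drawn with replacement from the dataset and
    fitted; CI width = 2 * z_(1-alpha/2) * SE under the normal
    approximation.  The draw-and-fit is repeated ``n_resamples`` times;
    rows report mean and SD of the widths (plus the count of redrawn
    resamples after fit failures).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = stats.norm.ppf(0.5 + cfg.confidence / 2.0)
    rows = []
    for n in cfg.sample_sizes:
        widths = []
        redraws = 0
        while len(widths) < cfg.n_resamples:
            idx = rng.integers(0, len(x), size=n)
            try:
                _, se = fit_parameter(parameter, x[idx], y[idx])
            except (ValueError, RuntimeError):
                redraws += 1
                if redraws > 10 * cfg.n_resamples:
                    raise RuntimeError(f"too many failed resamples for {parameter} at N={n}")
                continue
            widths.append(2.0 * z * se)
        widths = np.asarray(widths)
        if redraws:
            log.info("%s at N=%d: %d resamples redrawn", parameter, n, redraws)
        rows.append({
            "parameter": parameter, "N": n,
            "mean_ci_width": float(widths.mean()),
            "sd_ci_width": float(widths.std(ddof=1)),
            "n_redrawn": redraws,
        })
    return pd.DataFrame(rows)


def finbody_slope_variance(E_k: float, E_h: float, V_k: float, V_h: float) -> float:
    """Variance of the maximal sigmoid slope k*h/4 from the (k, h) moments.

    V = (E_k^2 * V_h + E_h^2 * V_k + V_k * V_h) * (1/4)^2 — the exact
    variance of a product of independent variables, scaled by the 1/4.
    """
    if V_k < 0 or V_h < 0:
        raise ValueError("variances must be non-negative")
    return (E_k**2 * V_h + E_h**2 * V_k + V_k * V_h) * 0.0625


def _fit_relationship(parameter: str, x: np.ndarray, y: np.ndarray):
    if parameter == "sensitivity":
        fit = QuadraticVertexRegression().fit(x, y)

        def orig(xx):
            return fit.predict(xx)

        def altered(xx, f):
            return fit.a_ * (1.0 + f) * (np.asarray(xx) - fit.b_) ** 2 + fit.c_

        return orig, altered
    if parameter in ("steering", "righting"):
        fit = SlopeInterceptRegression().fit(x, y)

        def orig(xx):
            return fit.predict(xx)

        def altered(xx, f):
            return fit.slope_ * (1.0 + f) * np.asarray(xx) + fit.intercept_

        return orig, altered
    if parameter == "finbody":
        fit = LogisticCurveRegression().fit(x, y)

        def orig(xx):
            return fit.predict(xx)

        def altered(xx, f):
            # scaling k scales the maximal slope k*h/4 by exactly (1 + f)
            return fit.a_ + fit.h_ / (1.0 + np.exp(-fit.k_ * (1.0 + f) * (np.asarray(xx) + fit.b_)))

        return orig, altered
    raise ValueError(f"unknown parameter {parameter!r}")


def impose_effect(x, y, parameter: str, fraction: float) -> np.ndarray:
    """Return altered y with the target coefficient scaled by (1 + fraction).

    The model is fitted on (x, y); the altered dataset is
    ``y_new = f_altered(x) + (y - f_orig(x))`` — x values and y residuals
    are preserved exactly, only the coefficient of interest moves.
    """
    if fraction == -1.0:
        raise ValueError("fraction = -1 collapses the coefficient to zero (degenerate)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    orig, altered = _fit_relationship(parameter, x, y)
    return altered(x, fraction) + (y - orig(x))


def cohens_d(ori_values, sim_values) -> float:
    """Effect size (mu_sim - mu_ori) / sigma.

    sigma is the standard deviation of *all* the fitted values from both
    groups pooled together (not the within-group pooled SD), so d
    saturates at |d| = 2 for fully separated distributions.
    """
    ori = np.asarray(ori_values, dtype=float)
    sim = np.asarray(sim_values, dtype=float)
    sigma = float(np.concatenate([ori, sim]).std(ddof=0))
    if sigma == 0:
        raise ValueError("zero pooled SD; Cohen's d undefined")
    return float((sim.mean() - ori.mean()) / sigma)


def effect_size_curve(x, y, parameter: str, sample_sizes,
                      cfg: EffectSizeConfig = EffectSizeConfig(),
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Mean Cohen's d over (fraction, N) grids for one kinematic parameter.

    Per cell: draw N points with replacement independently from the
    original and the altered dataset, fit each, repeat ``inner_reps``
    times; d compares the two distributions of fitted values.  The whole
    procedure repeats ``outer_reps`` times and the mean d is reported.
    Non-convergent fits are redrawn and counted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rows = []
    for fraction in cfg.fractions:
        y_alt = impose_effect(x, y, parameter, fraction)
        for n in sample_sizes:
            ds = []
            redraws = 0
            for _ in range(cfg.outer_reps):
                ori_vals, sim_vals = [], []
                for vals, yy in ((ori_vals, y), (sim_vals, y_alt)):
                    while len(vals) < cfg.inner_reps:
                        idx = rng.integers(0, len(x), size=n)
                        try:
                            est, _ = fit_parameter(parameter, x[idx], yy[idx])
                        except (ValueError, RuntimeError):
                            redraws += 1
                            if redraws > 10 * cfg.inner_reps:
                                raise RuntimeError(
                                    f"too many failed fits for {parameter} at N={n}"
                                )
                            continue
                        vals.append(est)
                ds.append(cohens_d(ori_vals, sim_vals))
            if redraws:
                log.info("%s fraction=%g N=%d: %d fits redrawn", parameter, fraction, n, redraws)
            rows.append({
                "parameter": parameter, "fraction": fraction, "N": int(n),
                "mean_d": float(np.mean(ds)), "sd_d": float(np.std(ds, ddof=1)) if len(ds) > 1 else 0.0,
                "n_redrawn": redraws,
            })
    return pd.DataFrame(rows)
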