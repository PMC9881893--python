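"""Per-bout features and the four kinematic parameter fits.

The four parameters quantify distinct aspects of vertical locomotion:

* **sensitivity** — quadratic coefficient of the bout-frequency-versus-
  IBI-pitch parabola (reported in mHz/deg^2): how strongly postural
  eccentricity accelerates movement initiation;
* **steering gain** — OLS slope of pitch-at-peak-speed on bout trajectory;
* **fin-body ratio** — maximal slope (k*h/4) of the logistic relating the
  steering-related rotation to the attack angle: division of labor between
  trunk and fins;
* **righting gain / set point** — negated slope and x-intercept of the
  righting-rotation-versus-initial-pitch line.

Fits are always performed on raw per-bout / per-IBI points; binned
averages exist for display only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extraction import AlignedBout, IBIRecord
from .models import LogisticCurveRegression, QuadraticVertexRegression, SlopeInterceptRegression

__all__ = [
    "BoutFeatures",
    "bout_features",
    "features_table",
    "fit_bout_timing",
    "fit_steering",
    "fit_righting",
    "fit_fin_body",
    "angular_velocity_summary",
    "AngularVelocitySummary",
    "binned_average",
    "analyze_repeats",
    "KinematicsReport",
    "compare_profiles",
]

FEATURE_TIMES_MS = {"initial": -250.0, "peak": 0.0, "post": 100.0, "end": 200.0}


@dataclass
class BoutFeatures:
    initial_pitch: float  # deg, at -250 ms
    pitch_at_peak: float  # deg, at t=0
    post_bout_pitch: float  # deg, at +100 ms
    end_pitch: float  # deg, at +200 ms
    trajectory: float  # deg, elevation of the displacement vector at t=0
    peak_speed: float  # mm/s
    displacement: float  # mm, net over the super-threshold span containing t=0
    steering_rotation: float  # deg, initial -> t=0
    steering_related_rotation: float  # deg, initial -> time of peak angular velocity
    righting_rotation: float  # deg, t=0 -> +100 ms
    attack_angle: float  # deg, trajectory - pitch_at_peak (exact)
    trajectory_deviation: float  # deg, trajectory - initial_pitch (exact)
    t_peak: float = 0.0
    epoch_id: int = 0
    repeat_id: str = ""


def _nearest(times_ms: np.ndarray, target: float) -> int:
    return int(np.argmin(np.abs(times_ms - target)))


def bout_features(bout: AlignedBout, srr_time_ms: float = 40.0,
                  speed_threshold: float = 5.0) -> BoutFeatures:
    """Compute the kinematic features of one aligned bout.

    ``srr_time_ms`` is the time of peak angular velocity *before* the
    speed peak (default the fixed 40 ms convention); the steering-related
    rotation is the pitch change from -250 ms to that time.  The trajectory
    is the elevation angle of the displacement between the frames adjacent
    to t = 0, heading-invariant via ``atan2(dz, |dx|)``.
    """
    t = bout.times_ms
    i0 = _nearest(t, 0.0)
    idx = {k: _nearest(t, v) for k, v in FEATURE_TIMES_MS.items()}
    pitch = bout.pitch
    initial = float(pitch[idx["initial"]])
    at_peak = float(pitch[idx["peak"]])
    post = float(pitch[idx["post"]])
    end = float(pitch[idx["end"]])
    # the ramp is steepest at the angular-velocity peak, so interpolate
    # rather than snapping to the nearest grid point
    srr = float(np.interp(-abs(srr_time_ms), t, pitch) - initial)

    dx = bout.x[min(i0 + 1, len(t) - 1)] - bout.x[max(i0 - 1, 0)]
    dz = bout.z[min(i0 + 1, len(t) - 1)] - bout.z[max(i0 - 1, 0)]
    if dx == 0 and dz == 0:
        trajectory = 0.0
    else:
        trajectory = float(np.degrees(np.arctan2(dz, abs(dx))))

    above = bout.speed > speed_threshold
    lo = i0
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(t) - 1 and above[hi + 1]:
        hi += 1
    displacement = float(np.hypot(bout.x[hi] - bout.x[lo], bout.z[hi] - bout.z[lo]))

    return BoutFeatures(
        initial_pitch=initial,
        pitch_at_peak=at_peak,
        post_bout_pitch=post,
        end_pitch=end,
        trajectory=trajectory,
        peak_speed=float(bout.peak_speed),
        displacement=displacement,
        steering_rotation=at_peak - initial,
        steering_related_rotation=srr,
        righting_rotation=post - at_peak,
        attack_angle=trajectory - at_peak,
        trajectory_deviation=trajectory - initial,
        t_peak=bout.t_peak,
        epoch_id=bout.epoch_id,
        repeat_id=bout.repeat_id,
    )


def features_table(bouts: list[AlignedBout], srr_time_ms: float = 40.0,
                   speed_threshold: float = 5.0) -> pd.DataFrame:
    """One row of :class:`BoutFeatures` per bout."""
    rows = [bout_features(b, srr_time_ms, speed_threshold).__dict__ for b in bouts]
    cols = [f for f in BoutFeatures.__dataclass_fields__]
    return pd.DataFrame(rows, columns=cols)


def _xy_from(data, x_col, y_col):
    if isinstance(data, pd.DataFrame):
        return data[x_col].to_numpy(), data[y_col].to_numpy()
    raise TypeError("expected a DataFrame")


def fit_bout_timing(ibis) -> QuadraticVertexRegression:
    """Parabola fit of bout frequency on IBI pitch, on raw (unbinned) points.

    The quadratic coefficient is the sensitivity (``sensitivity_mhz_`` in
    mHz/deg^2), the y-intersect ``c_`` the baseline bout rate.  A negative
    baseline is flagged with a warning.
    """
    if isinstance(ibis, list):
        x = np.array([r.mean_pitch for r in ibis])
        y = np.array([r.bout_frequency for r in ibis])
    else:
        x, y = _xy_from(ibis, "mean_pitch", "bout_frequency")
    fit = QuadraticVertexRegression().fit(x, y)
    if fit.c_ < 0:
        warnings.warn(f"bout-timing fit has negative baseline rate c={fit.c_:.3g}")
    return fit


def fit_steering(features: pd.DataFrame) -> SlopeInterceptRegression:
    """OLS of pitch-at-peak (y) on trajectory (x); the slope is the steering gain."""
    x, y = _xy_from(features, "trajectory", "pitch_at_peak")
    fit = SlopeInterceptRegression().fit(x, y)
    fit.steering_gain_ = fit.slope_
    return fit


def fit_righting(features: pd.DataFrame) -> SlopeInterceptRegression:
    """OLS of righting rotation (y) on initial pitch (x).

    The behavior is corrective, so the slope is negative;
    ``righting_gain_`` = -slope and ``set_point_`` = -intercept/slope (the
    x-intercept).  A non-negative slope (non-corrective) is reported with a
    warning.
    """
    x, y = _xy_from(features, "initial_pitch", "righting_rotation")
    fit = SlopeInterceptRegression().fit(x, y)
    if fit.slope_ >= 0:
        warnings.warn("righting slope is non-negative (non-corrective behavior)")
    fit.righting_gain_ = -fit.slope_
    fit.set_point_ = -fit.intercept_ / fit.slope_ if fit.slope_ != 0 else np.nan
    return fit


def fit_fin_body(features: pd.DataFrame, min_speed: float = 7.0,
                 model: LogisticCurveRegression | None = None) -> LogisticCurveRegression:
    """Logistic fit of attack angle on steering-related rotation.

    Bouts slower than ``min_speed`` are dropped; among the kept bouts,
    those whose steering rotation exceeds its 50th percentile while having
    a negative attack angle are excluded (large rotations that produced no
    lift are decelerating artifacts).  ``fin_body_ratio_`` is k*h/4.  The
    fitted estimator carries ``n_used_`` and ``n_excluded_``.
    """
    kept = features[features["peak_speed"] >= min_speed]
    if len(kept) < 10:
        raise ValueError(f"only {len(kept)} bouts at >= {min_speed} mm/s; need >= 10")
    p50 = float(kept["steering_rotation"].quantile(0.5))
    excl = (kept["steering_rotation"] > p50) & (kept["attack_angle"] < 0)
    used = kept[~excl]
    fit = model if model is not None else LogisticCurveRegression()
    fit.fit(used["steering_related_rotation"].to_numpy(), used["attack_angle"].to_numpy())
    fit.n_used_ = int(len(used))
    fit.n_excluded_ = int(excl.sum())
    return fit


@dataclass
class AngularVelocitySummary:
    """Median adjusted angular-velocity traces per experimental repeat."""

    times_ms: np.ndarray
    median_traces: dict[str, np.ndarray]  # repeat_id -> deg/s
    peak_times: dict[str, float]  # repeat_id -> ms before t=0
    mean_peak_time: float  # ms
    sd_peak_time: float  # ms


def _smooth(a: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return a
    pad = window // 2
    padded = np.pad(a, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def angular_velocity_summary(bouts: list[AlignedBout], smoothing: int = 11) -> AngularVelocitySummary:
    """Adjusted angular velocity, median per repeat, and its pre-peak peak time.

    Per bout, pitch is smoothed by an ``smoothing``-frame centered moving
    average and differentiated; the sign is flipped for bouts whose mean
    pre-peak (-250..0 ms) angular velocity is negative, so every bout
    starts nose-up.  The per-repeat median trace's maximum before t = 0
    defines that repeat's peak time (reported as ms *before* the peak).
    """
    if not bouts:
        raise ValueError("no bouts")
    if smoothing > len(bouts[0].times_ms):
        raise ValueError("smoothing window longer than the bout window")
    times = bouts[0].times_ms
    by_repeat: dict[str, list[np.ndarray]] = {}
    dt_s = (times[1] - times[0]) / 1000.0
    pre = (times >= -250.0) & (times <= 0.0)
    for b in bouts:
        sm = _smooth(b.pitch, smoothing)
        av = np.gradient(sm, dt_s)  # deg/s
        if av[pre].mean() < 0:
            av = -av
        by_repeat.setdefault(b.repeat_id, []).append(av)
    median_traces = {rid: np.median(np.vstack(trs), axis=0) for rid, trs in by_repeat.items()}
    peak_times = {}
    before = times < 0
    for rid, trace in median_traces.items():
        i = int(np.argmax(trace[before]))
        peak_times[rid] = float(-times[before][i])
    vals = np.array(list(peak_times.values()))
    return AngularVelocitySummary(
        times_ms=times,
        median_traces=median_traces,
        peak_times=peak_times,
        mean_peak_time=float(vals.mean()),
        sd_peak_time=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
    )


def binned_average(x, y, bin_width: float) -> pd.DataFrame:
    """Per-bin mean pairs for display; bins aligned to multiples of bin_width.

    Empty bins are omitted.  Never used for fitting.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    idx = np.floor(x / bin_width).astype(int)
    df = pd.DataFrame({"bin": idx, "x": x, "y": y}).groupby("bin").mean()
    df["bin_center"] = (df.index + 0.5) * bin_width
    return df.rename(columns={"x": "x_mean", "y": "y_mean"}).reset_index(drop=True)


_PARAMETERS = ("sensitivity", "baseline_rate", "steering_gain", "righting_gain",
               "set_point", "fin_body_ratio", "sigmoid_height")


def _fit_all(features: pd.DataFrame, ibis: pd.DataFrame, min_finbody: int = 10) -> dict[str, float]:
    out: dict[str, float] = {}
    timing = fit_bout_timing(ibis)
    out["sensitivity"] = timing.sensitivity_mhz_
    out["baseline_rate"] = timing.c_
    out["steering_gain"] = fit_steering(features).slope_
    righting = fit_righting(features)
    out["righting_gain"] = righting.righting_gain_
    out["set_point"] = righting.set_point_
    finbody = fit_fin_body(features)
    out["fin_body_ratio"] = finbody.fin_body_ratio_
    out["sigmoid_height"] = finbody.h_
    return out


@dataclass
class KinematicsReport:
    """Per-repeat and pooled kinematic parameters for one condition."""

    condition: str
    per_repeat: pd.DataFrame  # rows: repeat_id x parameter columns
    summary: pd.DataFrame  # parameter, mean, sd, n_repeats
    pooled: dict[str, float]

    def parameter_means(self) -> dict[str, float]:
        return dict(zip(self.summary["parameter"], self.summary["mean"]))


def analyze_repeats(features: pd.DataFrame, ibis: pd.DataFrame,
                    condition: str = "") -> KinematicsReport:
    """Fit every kinematic parameter per experimental repeat and pooled.

    The report gives mean (SD) across repeats per parameter (the standard
    reporting convention) alongside the pooled fit.  Repeats with too few
    bouts for a fit are skipped with a warning.
    """
    rows = []
    for rid in sorted(features["repeat_id"].unique()):
        f = features[features["repeat_id"] == rid]
        i = ibis[ibis["repeat_id"] == rid]
        try:
            row = _fit_all(f, i)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"repeat {rid!r} skipped: {exc}")
            continue
        row["repeat_id"] = rid
        rows.append(row)
    per_repeat = pd.DataFrame(rows)
    summary_rows = []
    for p in _PARAMETERS:
        vals = per_repeat[p].to_numpy() if p in per_repeat else np.array([])
        summary_rows.append({
            "parameter": p,
            "mean": float(np.mean(vals)) if len(vals) else np.nan,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n_repeats": len(vals),
        })
    pooled = _fit_all(features, ibis)
    return KinematicsReport(
        condition=condition,
        per_repeat=per_repeat,
        summary=pd.DataFrame(summary_rows),
        pooled=pooled,
    )


def compare_profiles(reference, other) -> pd.DataFrame:
    """Signed percent differences, 100 * (other/reference - 1), per parameter.

    Accepts anything mapping parameter names to values (plain dicts,
    :func:`vswim.profiles.reference_parameters` output, or
    ``KinematicsReport.parameter_means()``); only shared parameters are
    compared.  A zero reference value yields NaN and is flagged.
    """
    if isinstance(reference, KinematicsReport):
        reference = reference.parameter_means()
    if isinstance(other, KinematicsReport):
        other = other.parameter_means()
    shared = [k for k in reference if k in other]
    rows = []
    for k in shared:
        ref, oth = float(reference[k]), float(other[k])
        if ref == 0:
            warnings.warn(f"reference value for {k!r} is zero; percent change undefined")
            pct = np.nan
        else:
            pct = 100.0 * (oth / ref - 1.0)
        rows.append({"parameter": k, "reference": ref, "other": oth, "percent_change": pct})
    return pd.DataFrame(rows)
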