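"""Reference kinematic parameter sets for the synthetic swimmer.

A :class:`KinematicProfile` bundles everything the generator needs to emit
realistic vertical-swimming behavior of larval zebrafish: the bout-timing
parabola (rate of movement initiation as a function of posture), the
steering and righting lines, the fin-body sigmoid, and the marginal
distributions of peak speed, posture and trajectory.  Presets are provided
for three developmental stages (4, 7 and 14 days post-fertilization); the
7 dpf peak-speed and pitch-at-peak moments are the pooled 7-9 dpf values.

Angles are degrees (nose-up positive), speeds mm/s, rates Hz.  The
bout-timing sensitivity ``sensitivity_a`` is stored in Hz/deg^2 and
conventionally *reported* in mHz/deg^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

__all__ = ["KinematicProfile", "make_profile", "reference_parameters", "AGE_LABELS"]


@dataclass(frozen=True)
class KinematicProfile:
    # acquisition
    frame_rate: float = 166.0  # Hz

    # bout timing: rate(pitch) = a*(pitch - b)^2 + c
    sensitivity_a: float = 1.06e-3  # Hz/deg^2 (reported as mHz/deg^2)
    timing_vertex_b: float = 8.06  # deg
    baseline_rate_c: float = 0.51  # Hz

    # steering: slope of pitch-at-peak on trajectory
    steering_gain: float = 0.67

    # fin-body sigmoid: attack = a + h / (1 + exp(-k*(x + b)))
    sigmoid_a: float = -5.14  # deg
    sigmoid_b: float = 0.0  # deg
    sigmoid_k: float = 0.8833  # 1/deg
    sigmoid_h: float = 10.28  # deg

    # righting: rotation = -gain * (initial_pitch - set_point)
    righting_gain: float = 0.18
    set_point: float = 19.47  # deg

    # marginal distributions
    peak_speed_mean: float = 12.90  # mm/s, moments of the observed (>5) distribution
    peak_speed_sd: float = 4.91
    pitch_at_peak_mean: float = 8.48  # deg
    pitch_at_peak_sd: float = 15.23
    ibi_pitch_mean: float = 8.06  # deg
    ibi_pitch_sd: float = 12.66
    trajectory_mean: float = 8.92  # deg
    trajectory_sd: float = 20.19

    # bout shape
    bout_displacement_mean: float = 1.36  # mm, above-threshold displacement
    angvel_peak_lead: float = 40.0  # ms before the speed peak

    # noise terms
    ibi_lognoise_sigma: float = 0.6  # lognormal (mean-1) multiplier on IBI duration
    initial_pitch_jitter: float = 1.0  # deg, IBI pitch -> initial pitch
    steering_resid_sd: float = 6.0  # deg, targeted-mode steering residual
    attack_resid_sd: float = 3.5  # deg
    righting_resid_sd: float = 2.0  # deg

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not self.baseline_rate_c > 0:
            raise ValueError("baseline_rate_c must be positive")
        if self.sigmoid_h < 0:
            raise ValueError("sigmoid_h must be non-negative")
        if not self.peak_speed_mean > 5.0:
            raise ValueError("peak_speed_mean must exceed the 5 mm/s detection threshold")
        for name in (
            "peak_speed_sd", "pitch_at_peak_sd", "ibi_pitch_sd", "trajectory_sd",
            "ibi_lognoise_sigma", "initial_pitch_jitter", "steering_resid_sd",
            "attack_resid_sd", "righting_resid_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for f in fields(self):
            if not math.isfinite(getattr(self, f.name)):
                raise ValueError(f"{f.name} is not finite")

    @property
    def fin_body_ratio(self) -> float:
        """Maximal slope of the fin-body sigmoid, k*h/4."""
        return self.sigmoid_k * self.sigmoid_h / 4.0

    def sigmoid(self, x):
        """Evaluate the fin-body logistic a + h/(1 + exp(-k*(x + b)))."""
        import numpy as np

        x = np.asarray(x, dtype=float)
        return self.sigmoid_a + self.sigmoid_h / (1.0 + np.exp(-self.sigmoid_k * (x + self.sigmoid_b)))

    def bout_rate(self, pitch):
        """Bout-timing parabola a*(pitch - b)^2 + c, in Hz."""
        import numpy as np

        p = np.asarray(pitch, dtype=float)
        return self.sensitivity_a * (p - self.timing_vertex_b) ** 2 + self.baseline_rate_c


def _ratio_to_k(ratio: float, h: float) -> float:
    return 4.0 * ratio / h


# IQR-scaled spreads (IQR / 1.349) are used where only median (IQR) spreads
# are available for a stage, assuming approximate normality.
_PRESETS: dict[str, dict[str, float]] = {
    "4dpf": dict(
        sensitivity_a=0.61e-3, timing_vertex_b=8.75, baseline_rate_c=0.51,
        steering_gain=0.64,
        sigmoid_h=16.47, sigmoid_k=_ratio_to_k(3.41, 16.47), sigmoid_a=-16.47 / 2, sigmoid_b=0.0,
        righting_gain=0.15, set_point=13.00,
        peak_speed_mean=10.42, peak_speed_sd=3.85,
        pitch_at_peak_mean=9.74, pitch_at_peak_sd=29.16 / 1.349,
        ibi_pitch_mean=8.75, ibi_pitch_sd=17.48,
        trajectory_mean=12.29, trajectory_sd=27.52,
        bout_displacement_mean=1.12, angvel_peak_lead=50.0,
    ),
    "7dpf": dict(
        sensitivity_a=1.06e-3, timing_vertex_b=8.06, baseline_rate_c=0.51,
        steering_gain=0.67,
        sigmoid_h=10.28, sigmoid_k=_ratio_to_k(2.27, 10.28), sigmoid_a=-10.28 / 2, sigmoid_b=0.0,
        righting_gain=0.18, set_point=19.47,
        peak_speed_mean=12.90, peak_speed_sd=4.91,
        pitch_at_peak_mean=8.48, pitch_at_peak_sd=15.23,
        ibi_pitch_mean=8.06, ibi_pitch_sd=12.66,
        trajectory_mean=8.92, trajectory_sd=20.19,
        bout_displacement_mean=1.36, angvel_peak_lead=40.0,
    ),
    "14dpf": dict(
        sensitivity_a=1.31e-3, timing_vertex_b=6.08, baseline_rate_c=0.47,
        steering_gain=0.51,
        sigmoid_h=25.15, sigmoid_k=_ratio_to_k(3.55, 25.15), sigmoid_a=-25.15 / 2, sigmoid_b=0.0,
        righting_gain=0.18, set_point=13.60,
        peak_speed_mean=11.41, peak_speed_sd=4.20,
        pitch_at_peak_mean=4.36, pitch_at_peak_sd=19.73 / 1.349,
        ibi_pitch_mean=6.08, ibi_pitch_sd=11.23,
        trajectory_mean=7.85, trajectory_sd=22.89,
        bout_displacement_mean=1.35, angvel_peak_lead=50.0,
    ),
}

AGE_LABELS = tuple(_PRESETS)

_FIELD_NAMES = {f.name for f in fields(KinematicProfile)}


def make_profile(age_label: str | None = None, **overrides) -> KinematicProfile:
    """Build a :class:`KinematicProfile` from an age preset and/or overrides.

    Parameters
    ----------
    age_label
        One of ``"4dpf"``, ``"7dpf"``, ``"14dpf"``, or ``None`` to build a
        profile purely from keyword overrides (class defaults fill the rest,
        which amounts to the 7 dpf reference set).
    **overrides
        Any :class:`KinematicProfile` field; replaces the preset value.
    """
    unknown = set(overrides) - _FIELD_NAMES
    if unknown:
        raise TypeError(f"unknown profile fields: {sorted(unknown)}")
    if age_label is None:
        return KinematicProfile(**overrides)
    if age_label not in _PRESETS:
        raise ValueError(f"unknown age label {age_label!r}; expected one of {AGE_LABELS}")
    base = KinematicProfile(**_PRESETS[age_label])
    return replace(base, **overrides) if overrides else base


def reference_parameters(profile: KinematicProfile) -> dict[str, float]:
    """Named kinematic parameters of a profile, in reporting units.

    Sensitivity is converted to mHz/deg^2; the fin-body ratio is k*h/4.
    The mapping is suitable for cross-condition percent comparisons.
    """
    return {
        "sensitivity": profile.sensitivity_a * 1e3,
        "baseline_rate": profile.baseline_rate_c,
        "steering_gain": profile.steering_gain,
        "righting_gain": profile.righting_gain,
        "set_point": profile.set_point,
        "fin_body_ratio": profile.fin_body_ratio,
        "sigmoid_height": profile.sigmoid_h,
        "ibi_pitch_mean": profile.ibi_pitch_mean,
        "ibi_pitch_sd": profile.ibi_pitch_sd,
        "peak_speed_mean": profile.peak_speed_mean,
        "pitch_at_peak_mean": profile.pitch_at_peak_mean,
        "trajectory_mean": profile.trajectory_mean,
        "bout_displacement_mean": profile.bout_displacement_mean,
    }
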