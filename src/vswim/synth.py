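"""Ground-truth generator for vertical swimming behavior.

Two generation modes are provided:

* **Session mode** (:func:`simulate_session`) builds a continuous pose trace
  at the acquisition frame rate from a causal latent chain
  (IBI pitch -> IBI duration, initial pitch -> steering rotation ->
  pitch at peak, attack angle, righting rotation), so the full
  tracking/extraction/analysis pipeline can be tested end to end with the
  generating latents attached to every bout.
* **Targeted mode** (:func:`generate_relationship_samples`) draws (x, y)
  pairs directly from a single kinematic relationship so that its fit is
  exactly recoverable in expectation.  The four fitted relationships cannot
  in general hold simultaneously and exactly, which is why coefficient
  recovery is tested per relationship.

Conventions: z is positive up; pitch is the trunk angle above the horizon,
nose-up positive and invariant to left/right heading; the trajectory is the
elevation angle of the displacement vector, ``atan2(dz, |dx|)`` in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .profiles import KinematicProfile

__all__ = [
    "GroundTruthBout",
    "PoseTrace",
    "sample_bout_latents",
    "generate_relationship_samples",
    "relationship_params",
    "simulate_session",
    "trace_to_records",
    "steering_related_rotation_moments",
    "solve_truncnorm_parent",
]

SPEED_THRESHOLD = 5.0  # mm/s, detection threshold shared with extraction

RELATIONSHIPS = ("timing", "steering", "finbody", "righting")

# speed-bump width limits (s): keep the super-threshold span well inside the
# -500/+300 ms alignment window and shorter than the smallest IBI
_BUMP_WIDTH_MIN = 0.12
_BUMP_WIDTH_MAX = 0.30
_IBI_MIN = 0.4  # s, floor on sampled IBI durations (keeps adjacent bouts separable)
_RIGHTING_DURATION = 0.1  # s, righting ramp completes 100 ms after the peak


@dataclass
class GroundTruthBout:
    """Latent variables behind one simulated swim bout."""

    onset_time: float  # s, time of peak speed
    initial_pitch: float  # deg
    steering_related_rotation: float  # deg, initial -> time of peak angular velocity
    attack_angle: float  # deg
    pitch_at_peak: float  # deg
    trajectory: float  # deg, = pitch_at_peak + attack_angle exactly
    righting_rotation: float  # deg
    peak_speed: float  # mm/s
    preceding_ibi_duration: float  # s
    preceding_ibi_pitch: float  # deg


@dataclass
class PoseTrace:
    """Continuous pose on a uniform frame grid, with ground truth attached.

    ``epoch_id`` is an integer per contiguous visible span; frames where the
    animal is out of view carry ``epoch_id == -1`` and NaN pose.  ``heading``
    is the horizontal direction of travel (+1 right / -1 left), constant
    within an epoch.
    """

    times: np.ndarray  # s
    x: np.ndarray  # mm
    z: np.ndarray  # mm
    pitch: np.ndarray  # deg
    epoch_id: np.ndarray  # int, -1 = not visible
    heading: np.ndarray  # +1 / -1
    frame_rate: float  # Hz
    body_length: float = 4.0  # mm
    ground_truth: list[GroundTruthBout] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("x", "z", "pitch", "epoch_id", "heading"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if n > 1:
            dt = np.diff(self.times)
            if not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-6)):
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def n_frames(self) -> int:
        return len(self.times)


@lru_cache(maxsize=64)
def solve_truncnorm_parent(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a normal whose truncation below ``lower`` has
    the given observed mean and SD.

    Recorded peak speeds are conditioned on exceeding the detection
    threshold, so the profile's peak-speed moments describe the truncated
    distribution; sampling must invert that conditioning.
    """
    if sd <= 0:
        return float(mean), 0.0

    def moments(params):
        mu, log_sigma = params
        sigma = math.exp(log_sigma)
        a = (lower - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(moments, [mean, math.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - hybr converges for sane inputs
        raise RuntimeError(f"truncated-normal moment matching failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def _sample_truncated_speed(profile: KinematicProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    mu, sigma = solve_truncnorm_parent(
        profile.peak_speed_mean, profile.peak_speed_sd, SPEED_THRESHOLD
    )
    if sigma == 0:
        return np.full(n, mu)
    a = (SPEED_THRESHOLD - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def steering_related_rotation_moments(profile: KinematicProfile) -> tuple[float, float]:
    """Mean and SD of the steering-related rotation implied by a profile.

    The pre-peak ramp is symmetric about the angular-velocity peak, so the
    rotation from bout start to the peak-angular-velocity time is half the
    total steering rotation.  Its distribution is derived from the profile's
    IBI-pitch and pitch-at-peak marginals so that
    pitch_at_peak = initial_pitch + 2 * steering_related_rotation reproduces
    the stated pitch-at-peak mean and SD.
    """
    mu = (profile.pitch_at_peak_mean - profile.ibi_pitch_mean) / 2.0
    var = (
        profile.pitch_at_peak_sd**2
        - profile.ibi_pitch_sd**2
        - profile.initial_pitch_jitter**2
    ) / 4.0
    return mu, math.sqrt(max(var, 0.25))


def _lognormal_mean_one(sigma: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Lognormal multiplier with mean exactly 1."""
    if sigma == 0:
        return np.ones(n)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def _sample_latent_arrays(profile: KinematicProfile, n: int, rng: np.random.Generator) -> dict:
    ibi_pitch = rng.normal(profile.ibi_pitch_mean, profile.ibi_pitch_sd, size=n)
    rate = np.asarray(profile.bout_rate(ibi_pitch), dtype=float)
    eps = _lognormal_mean_one(profile.ibi_lognoise_sigma, n, rng)
    ibi_duration = eps / rate

    initial_pitch = ibi_pitch + rng.normal(0.0, profile.initial_pitch_jitter, size=n)
    mu_sr, sd_sr = steering_related_rotation_moments(profile)
    srr = rng.normal(mu_sr, sd_sr, size=n)
    pitch_at_peak = initial_pitch + 2.0 * srr
    attack = np.asarray(profile.sigmoid(srr), dtype=float)
    attack = attack + rng.normal(0.0, profile.attack_resid_sd, size=n)
    trajectory = pitch_at_peak + attack
    # re-derive the attack angle so trajectory - pitch_at_peak - attack
    # is exactly zero in floating point
    attack = trajectory - pitch_at_peak
    righting = -profile.righting_gain * (initial_pitch - profile.set_point)
    righting = righting + rng.normal(0.0, profile.righting_resid_sd, size=n)
    peak_speed = _sample_truncated_speed(profile, n, rng)
    return {
        "ibi_pitch": ibi_pitch,
        "ibi_duration": ibi_duration,
        "initial_pitch": initial_pitch,
        "srr": srr,
        "pitch_at_peak": pitch_at_peak,
        "attack": attack,
        "trajectory": trajectory,
        "righting": righting,
        "peak_speed": peak_speed,
    }


def sample_bout_latents(
    profile: KinematicProfile, n: int, seed: int | np.random.Generator = 0
) -> list[GroundTruthBout]:
    """Draw ``n`` ground-truth bout latents from the causal chain.

    The same (profile, seed) pair always yields an identical list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lat = _sample_latent_arrays(profile, n, rng)
    onset = np.cumsum(lat["ibi_duration"])
    return [
        GroundTruthBout(
            onset_time=float(onset[i]),
            initial_pitch=float(lat["initial_pitch"][i]),
            steering_related_rotation=float(lat["srr"][i]),
            attack_angle=float(lat["attack"][i]),
            pitch_at_peak=float(lat["pitch_at_peak"][i]),
            trajectory=float(lat["trajectory"][i]),
            righting_rotation=float(lat["righting"][i]),
            peak_speed=float(lat["peak_speed"][i]),
            preceding_ibi_duration=float(lat["ibi_duration"][i]),
            preceding_ibi_pitch=float(lat["ibi_pitch"][i]),
        )
        for i in range(n)
    ]


def relationship_params(profile: KinematicProfile, relationship: str) -> dict[str, float]:
    """Targeted-mode parameter set for one relationship, from a profile."""
    if relationship == "timing":
        return {
            "a": profile.sensitivity_a,
            "b": profile.timing_vertex_b,
            "c": profile.baseline_rate_c,
            "x_mean": profile.ibi_pitch_mean,
            "x_sd": profile.ibi_pitch_sd,
            "lognoise_sigma": profile.ibi_lognoise_sigma,
        }
    if relationship == "steering":
        gain = profile.steering_gain
        return {
            "gain": gain,
            "intercept": profile.pitch_at_peak_mean - gain * profile.trajectory_mean,
            "x_mean": profile.trajectory_mean,
            "x_sd": profile.trajectory_sd,
            "resid_sd": profile.steering_resid_sd,
        }
    if relationship == "finbody":
        mu_sr, sd_sr = steering_related_rotation_moments(profile)
        return {
            "sigmoid_a": profile.sigmoid_a,
            "sigmoid_b": profile.sigmoid_b,
            "sigmoid_k": profile.sigmoid_k,
            "sigmoid_h": profile.sigmoid_h,
            "x_mean": mu_sr,
            "x_sd": sd_sr,
            "resid_sd": profile.attack_resid_sd,
        }
    if relationship == "righting":
        slope = -profile.righting_gain
        return {
            "slope": slope,
            "intercept": -slope * profile.set_point,
            "x_mean": profile.ibi_pitch_mean,
            "x_sd": profile.ibi_pitch_sd,
            "resid_sd": profile.righting_resid_sd,
        }
    raise ValueError(f"unknown relationship {relationship!r}; expected one of {RELATIONSHIPS}")


_MIN_N = {"timing": 3, "steering": 2, "finbody": 4, "righting": 2}


def generate_relationship_samples(
    relationship: str,
    params: dict[str, float],
    n: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired (x, y) samples from a single kinematic relationship.

    ``E[y | x]`` follows the relationship's model exactly, so downstream
    fits recover the generating coefficients in expectation.  Use
    :func:`relationship_params` to derive defaults from a profile.
    """
    if relationship not in RELATIONSHIPS:
        raise ValueError(f"unknown relationship {relationship!r}; expected one of {RELATIONSHIPS}")
    if n < _MIN_N[relationship]:
        raise ValueError(f"n={n} below the number of {relationship} coefficients")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.normal(params["x_mean"], params["x_sd"], size=n)
    if relationship == "timing":
        rate = params["a"] * (x - params["b"]) ** 2 + params["c"]
        y = rate * _lognormal_mean_one(params.get("lognoise_sigma", 0.0), n, rng)
    elif relationship == "steering":
        y = params["gain"] * x + params["intercept"]
        y = y + rng.normal(0.0, params.get("resid_sd", 0.0), size=n)
    elif relationship == "finbody":
        y = params["sigmoid_a"] + params["sigmoid_h"] / (
            1.0 + np.exp(-params["sigmoid_k"] * (x + params["sigmoid_b"]))
        )
        y = y + rng.normal(0.0, params.get("resid_sd", 0.0), size=n)
    else:  # righting
        y = params["slope"] * x + params["intercept"]
        y = y + rng.normal(0.0, params.get("resid_sd", 0.0), size=n)
    return x, y


# ---------------------------------------------------------------------------
# session mode


def _bump_width(peak_speed: float, displacement: float) -> float:
    """Width (s) of the raised-cosine speed bump s(t) = pk*cos^2(pi*t/W).

    Chosen so that the displacement accumulated while the speed exceeds the
    detection threshold approximates ``displacement``; clipped to keep the
    bout well inside its alignment window.
    """
    u = SPEED_THRESHOLD / peak_speed
    phi = math.acos(math.sqrt(u))
    denom = peak_speed * (phi + math.sqrt(u - u * u))
    w = math.pi * displacement / denom if denom > 0 else _BUMP_WIDTH_MAX
    return float(np.clip(w, _BUMP_WIDTH_MIN, _BUMP_WIDTH_MAX))


def _hann_step(s: np.ndarray) -> np.ndarray:
    """Smooth 0->1 step whose derivative is a raised-cosine bump at s=0.5."""
    s = np.clip(s, 0.0, 1.0)
    return s - np.sin(2.0 * np.pi * s) / (2.0 * np.pi)


def simulate_session(
    profile: KinematicProfile,
    duration: float,
    seed: int | np.random.Generator = 0,
    epoch_break_rate: float = 0.05,
) -> PoseTrace:
    """Simulate a recording session as a continuous pose trace.

    The trace concatenates epochs of swimming separated by out-of-view gaps
    (``epoch_break_rate`` is the per-bout probability of ending the epoch).
    Within an epoch, inter-bout intervals carry a slow linear pitch drift
    toward the next bout's initial pitch; each bout superimposes a
    raised-cosine speed bump (peak on the frame grid), a pre-peak steering
    ramp whose angular velocity peaks ``angvel_peak_lead`` ms before the
    speed peak, and a post-peak righting ramp completing 100 ms after the
    peak.  Displacement during a bout points along the bout's trajectory
    angle.  Ground-truth latents are attached for every realized bout.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fr = profile.frame_rate
    dt = 1.0 / fr
    n_frames = int(round(duration * fr))
    lead = profile.angvel_peak_lead / 1000.0  # s

    times = np.arange(n_frames) * dt
    x = np.full(n_frames, np.nan)
    z = np.full(n_frames, np.nan)
    pitch = np.full(n_frames, np.nan)
    epoch_id = np.full(n_frames, -1, dtype=int)
    heading = np.ones(n_frames, dtype=int)
    gt: list[GroundTruthBout] = []

    # latent pool, replenished on demand
    pool = _sample_latent_arrays(profile, max(64, int(duration)), rng)
    pool_i = 0

    def next_latent():
        nonlocal pool, pool_i
        if pool_i >= len(pool["ibi_pitch"]):
            pool = _sample_latent_arrays(profile, 256, rng)
            pool_i = 0
        lat = {k: v[pool_i] for k, v in pool.items()}
        pool_i += 1
        return lat

    cur = 0  # frame cursor
    epoch = 0
    pos_x, pos_z = 0.0, 0.0
    min_epoch_frames = int(round(2.6 * fr))

    while True:
        # decide the bouts of this epoch up front
        ep_heading = 1 if rng.random() < 0.5 else -1
        bouts = [next_latent()]
        while rng.random() >= epoch_break_rate:
            bouts.append(next_latent())
            if len(bouts) >= 200:
                break

        widths = [_bump_width(b["peak_speed"], profile.bout_displacement_mean) for b in bouts]
        half_spans = []
        for b, w in zip(bouts, widths):
            u = SPEED_THRESHOLD / b["peak_speed"]
            half_spans.append((w / math.pi) * math.acos(math.sqrt(u)))

        # peak times relative to epoch start
        lead_in = max(bouts[0]["ibi_duration"], 0.6)
        peaks = [lead_in + half_spans[0]]
        for j in range(1, len(bouts)):
            ibi = max(bouts[j]["ibi_duration"], _IBI_MIN)
            bouts[j]["ibi_duration"] = ibi
            peaks.append(peaks[-1] + half_spans[j - 1] + ibi + half_spans[j])
        ep_len = peaks[-1] + max(half_spans[-1] + 0.05, 0.45)
        ep_len = max(ep_len, min_epoch_frames * dt)

        ep_n = int(round(ep_len * fr))
        if cur + ep_n > n_frames:
            # truncate: keep only bouts whose full surroundings fit
            fit = [j for j, p in enumerate(peaks) if cur * dt + p + 0.45 < duration]
            if not fit:
                break
            bouts = [bouts[j] for j in fit]
            widths = [widths[j] for j in fit]
            half_spans = [half_spans[j] for j in fit]
            peaks = [peaks[j] for j in fit]
            ep_n = n_frames - cur
            if ep_n < min_epoch_frames:
                break

        t_ep = times[cur : cur + ep_n] - times[cur]  # relative time within epoch
        peak_frames = [int(round(p * fr)) for p in peaks]
        peak_t = [k * dt for k in peak_frames]  # snapped to the grid

        speed = np.zeros(ep_n)
        vx = np.zeros(ep_n)
        vz = np.zeros(ep_n)
        ep_pitch = np.zeros(ep_n)
        # slow sub-threshold drift between bouts (fish sink/glide); keeps
        # the animal from parking on one spot for seconds at a time
        drift_speed = rng.uniform(0.3, 0.8)
        drift_angle = rng.uniform(0.0, 2.0 * np.pi)

        # drift backbone through (peak - 0.25 s, initial - cum) nodes
        cum = 0.0
        nodes_t = [0.0]
        nodes_v = [bouts[0]["initial_pitch"]]
        for j, b in enumerate(bouts):
            sr = 2.0 * b["srr"]
            for tn in (peak_t[j] - 0.25, peak_t[j] + 0.25):
                if tn > nodes_t[-1] + dt / 2 and tn < t_ep[-1]:
                    nodes_t.append(tn)
                    nodes_v.append(b["initial_pitch"] - cum)
            cum += sr + b["righting"]
        nodes_t.append(t_ep[-1] + dt)
        nodes_v.append(nodes_v[-1])
        ep_pitch = np.interp(t_ep, nodes_t, nodes_v)

        for j, b in enumerate(bouts):
            w = widths[j]
            tj = t_ep - peak_t[j]
            in_bump = np.abs(tj) <= w / 2
            s = b["peak_speed"] * np.cos(np.pi * tj[in_bump] / w) ** 2
            speed[in_bump] += s
            theta = math.radians(b["trajectory"])
            vx[in_bump] += s * math.cos(theta) * ep_heading
            vz[in_bump] += s * math.sin(theta)
            # steering ramp: angular velocity peaks `lead` before the speed peak
            ep_pitch += 2.0 * b["srr"] * _hann_step((tj + 2.0 * lead) / (2.0 * lead))
            ep_pitch += b["righting"] * _hann_step(tj / _RIGHTING_DURATION)
            gt.append(
                GroundTruthBout(
                    onset_time=float(times[cur] + peak_t[j]),
                    initial_pitch=float(b["initial_pitch"]),
                    steering_related_rotation=float(b["srr"]),
                    attack_angle=float(b["attack"]),
                    pitch_at_peak=float(b["initial_pitch"] + 2.0 * b["srr"]),
                    trajectory=float(b["trajectory"]),
                    righting_rotation=float(b["righting"]),
                    peak_speed=float(b["peak_speed"]),
                    preceding_ibi_duration=float(b["ibi_duration"]),
                    preceding_ibi_pitch=float(b["ibi_pitch"]),
                )
            )

        still = speed == 0.0
        vx[still] += drift_speed * math.cos(drift_angle)
        vz[still] += drift_speed * math.sin(drift_angle)

        sl = slice(cur, cur + ep_n)
        x[sl] = pos_x + np.cumsum(vx) * dt
        z[sl] = pos_z + np.cumsum(vz) * dt
        pitch[sl] = ep_pitch
        epoch_id[sl] = epoch
        heading[sl] = ep_heading
        pos_x = x[cur + ep_n - 1]
        pos_z = z[cur + ep_n - 1]

        epoch += 1
        gap = rng.uniform(0.5, 1.5)
        cur += ep_n + int(round(gap * fr))
        if cur + min_epoch_frames >= n_frames:
            break

    return PoseTrace(
        times=times, x=x, z=z, pitch=pitch, epoch_id=epoch_id, heading=heading,
        frame_rate=fr, ground_truth=gt,
    )


def trace_to_records(trace: PoseTrace, metadata=None):
    """Convert a pose trace into a raw record table (one row per visible frame).

    Head coordinates are placed half a body length from the body centroid
    along the pitch direction, signed by the heading.  Fish length is
    constant per session.  Frames with ``epoch_id < 0`` (animal out of view)
    are dropped.  Returns a DataFrame in the raw-records schema of
    :mod:`vswim.records`.
    """
    from . import records

    vis = trace.epoch_id >= 0
    pitch_rad = np.radians(trace.pitch[vis])
    half = 0.5 * trace.body_length
    head_x = trace.x[vis] + half * np.cos(pitch_rad) * trace.heading[vis]
    head_z = trace.z[vis] + half * np.sin(pitch_rad)
    return records.make_records(
        time=trace.times[vis],
        body_x=trace.x[vis],
        body_z=trace.z[vis],
        head_x=head_x,
        head_z=head_z,
        pitch=trace.pitch[vis],
        epoch_id=trace.epoch_id[vis],
        length=np.full(int(vis.sum()), trace.body_length),
    )
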