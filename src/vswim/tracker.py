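"""Frame-level animal tracking: frames in, pose records out.

The processing chain mirrors real-time acquisition: (1) background
subtraction, (2) noise thresholding, (3) rejection of frames without an
animal or with more than one animal in view, (4) size and intensity
criteria separating two animal parts (body and head), (5) centroid and
orientation extraction.  A record is emitted only for accepted frames;
the epoch id increments whenever a frame fails detection, so an epoch is
a contiguous run of frames with exactly one well-sized animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from . import records
from .render import FrameSequence, RenderConfig

__all__ = [
    "TrackerThresholds",
    "THRESHOLD_PRESETS",
    "DetectionStatus",
    "Detection",
    "estimate_background",
    "detect_frame",
    "track_frames",
    "suggest_thresholds",
]

_NOISE_AREA_FLOOR = 5  # px; smaller components are sensor noise
_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class TrackerThresholds:
    """Intensity bands and blob-size bounds for one organism/optics setup."""

    body_low: int
    body_high: int
    head_low: int
    head_high: int
    initial_cut_low: int
    initial_cut_high: int
    size_low: int
    size_high: int

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.body_low, self.body_high),
            (self.head_low, self.head_high),
            (self.initial_cut_low, self.initial_cut_high),
            (self.size_low, self.size_high),
        ):
            if lo > hi:
                raise ValueError("each low threshold must be <= its high threshold")
        for name in ("body_low", "body_high", "head_low", "head_high",
                     "initial_cut_low", "initial_cut_high"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in [0, 255]")


# standard recording presets per organism
THRESHOLD_PRESETS: dict[str, TrackerThresholds] = {
    "zebrafish": TrackerThresholds(14, 255, 45, 255, 25, 120, 180, 260),  # larvae <= 12 dpf
    "zebrafish_juvenile": TrackerThresholds(14, 255, 45, 255, 25, 120, 250, 450),  # > 12 dpf
    "fly": TrackerThresholds(100, 255, 30, 255, 45, 145, 80, 180),
    "worm": TrackerThresholds(20, 255, 21, 255, 3, 30, 30, 80),
}


class DetectionStatus(str, Enum):
    ok = "ok"
    no_animal = "no_animal"
    multiple_animals = "multiple_animals"
    size_out_of_range = "size_out_of_range"
    parts_not_separable = "parts_not_separable"


@dataclass
class Detection:
    """Per-frame detection result; pose fields are set iff status is ok."""

    status: DetectionStatus
    body_centroid: tuple[float, float] | None = None  # (col, row) px
    head_centroid: tuple[float, float] | None = None
    pitch: float | None = None  # deg, nose-up positive
    length: float | None = None  # px, major-axis extent of the blob
    pixel_count: int = 0


def estimate_background(frames: np.ndarray, mode: str = "median") -> np.ndarray:
    """Per-pixel background estimate over a frame stack.

    ``median`` is robust to a moving animal; ``first_n_mean`` averages the
    first 25 frames (faster, adequate when the animal enters late).
    """
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) == 0:
        raise ValueError("no frames")
    if mode == "median":
        # subsample long stacks: the background is static
        step = max(len(frames) // 101, 1)
        return np.median(frames[::step], axis=0).astype(frames.dtype)
    if mode == "first_n_mean":
        return frames[: min(25, len(frames))].mean(axis=0).astype(frames.dtype)
    raise ValueError(f"unknown background mode {mode!r}")


def detect_frame(frame: np.ndarray, background: np.ndarray,
                 thr: TrackerThresholds) -> Detection:
    """Detect a single animal and its head/body pose in one frame.

    The foreground is the absolute background difference thresholded at
    the initial-cut band, cleaned by an area floor; exactly one component
    with a pixel count inside [size_low, size_high] is accepted.  Head
    pixels are the foreground pixels whose *raw* intensity falls in the
    head band; the body is the remainder of the blob in the body band.
    Pitch is the elevation angle of the head-minus-body centroid vector,
    nose-up positive and heading-invariant.
    """
    frame = np.asarray(frame)
    if frame.shape != np.shape(background):
        raise ValueError("frame and background shapes differ")
    diff = np.abs(frame.astype(np.int16) - np.asarray(background, dtype=np.int16))
    fg = (diff >= thr.initial_cut_low) & (diff <= thr.initial_cut_high)
    labels, n = ndimage.label(fg, structure=_EIGHT_CONN)
    if n == 0:
        return Detection(DetectionStatus.no_animal)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    animal_ids = np.flatnonzero(areas >= thr.size_low) + 1
    if len(animal_ids) == 0:
        return Detection(DetectionStatus.no_animal)
    if len(animal_ids) > 1:
        return Detection(DetectionStatus.multiple_animals)
    blob_id = int(animal_ids[0])
    count = int(areas[blob_id - 1])
    if count > thr.size_high:
        return Detection(DetectionStatus.size_out_of_range, pixel_count=count)
    blob = labels == blob_id
    head = blob & (frame >= thr.head_low) & (frame <= thr.head_high)
    # pixels bordering the head are ambiguous between the two parts
    # (partial-intensity rim); keep them out of the body set
    body = blob & ~ndimage.binary_dilation(head, structure=_EIGHT_CONN)
    body &= (frame >= thr.body_low) & (frame <= thr.body_high)
    if not head.any() or not body.any():
        return Detection(DetectionStatus.parts_not_separable, pixel_count=count)
    # intensity-weighted centroids: edge pixels count by their
    # background-subtracted brightness, giving sub-pixel localization
    weight = diff.astype(float)
    rr, cc = np.nonzero(body)
    wb = weight[rr, cc]
    br, bc = float(np.average(rr, weights=wb)), float(np.average(cc, weights=wb))
    rr, cc = np.nonzero(head)
    wh = weight[rr, cc]
    hr, hc = float(np.average(rr, weights=wh)), float(np.average(cc, weights=wh))
    dz = br - hr  # z increases upward = decreasing row
    dx = hc - bc
    pitch = float(np.degrees(np.arctan2(dz, abs(dx))))
    # blob extent along its principal axis
    pts = np.argwhere(blob).astype(float)
    pts -= pts.mean(axis=0)
    _, vecs = np.linalg.eigh(np.cov(pts.T))
    proj = pts @ vecs[:, -1]
    length = float(proj.max() - proj.min())
    return Detection(
        DetectionStatus.ok,
        body_centroid=(bc, br),
        head_centroid=(hc, hr),
        pitch=pitch,
        length=length,
        pixel_count=count,
    )


def track_frames(frames, thr: TrackerThresholds, mm_per_pixel: float,
                 frame_rate: float, background: np.ndarray | None = None,
                 background_mode: str = "median"):
    """Track a frame stack into a raw record table.

    Coordinates are converted to mm with z increasing upward; the epoch id
    increments across any rejected frame.  Accepts a plain (n, H, W) array
    or a :class:`~vswim.render.FrameSequence`.
    """
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    if isinstance(frames, FrameSequence):
        frames = frames.frames
    frames = np.asarray(frames)
    if background is None:
        background = estimate_background(frames, background_mode)
    H = frames.shape[1]
    rows = []
    epoch = 0
    in_epoch = False
    for i, frame in enumerate(frames):
        det = detect_frame(frame, background, thr)
        if det.status is not DetectionStatus.ok:
            if in_epoch:
                epoch += 1
                in_epoch = False
            continue
        in_epoch = True
        bc, br = det.body_centroid
        hc, hr = det.head_centroid
        rows.append((
            i / frame_rate,
            bc * mm_per_pixel, (H - 1 - br) * mm_per_pixel,
            hc * mm_per_pixel, (H - 1 - hr) * mm_per_pixel,
            det.pitch, epoch, det.length * mm_per_pixel,
        ))
    if not rows:
        warnings.warn("no frames passed detection; returning an empty series")
        return records.make_records(**{c: [] for c in records.RECORD_COLUMNS})
    arr = np.asarray(rows)
    return records.make_records(**{c: arr[:, j] for j, c in enumerate(records.RECORD_COLUMNS)})


def suggest_thresholds(cfg: RenderConfig) -> TrackerThresholds:
    """Detection thresholds matched to a render configuration.

    Intensity cuts sit midway between the scene levels; the size band
    brackets the analytic blob area of the rendered body + head shape.
    """
    area = (
        np.pi * cfg.body_semi_major_px * cfg.body_semi_minor_px
        + np.pi * cfg.head_radius_px**2
    )
    cut_low = int((cfg.body_intensity - cfg.background_level) // 2)
    return TrackerThresholds(
        body_low=int((cfg.background_level + cfg.body_intensity) // 2),
        body_high=255,
        head_low=int((cfg.body_intensity + cfg.head_intensity) // 2),
        head_high=255,
        initial_cut_low=max(cut_low, int(cfg.background_level + 4 * cfg.noise_sd)),
        initial_cut_high=255,
        size_low=int(0.5 * area),
        size_high=int(1.8 * area),
    )
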