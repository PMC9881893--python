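"""Synthetic grayscale frame rendering for tracker testing.

Frames consist of a static noisy background plus, per frame, a body
ellipse and a brighter head disc positioned and oriented from a pose
trace.  Ground-truth pose (in the rendered coordinate frame) is retained
per frame so tracking error can be measured exactly.

Image coordinates: row 0 is the top of the frame; z increases upward, so
``row = (H - 1) - z / mm_per_pixel``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import PoseTrace

__all__ = ["RenderConfig", "FrameSequence", "render_frames", "save_frames", "load_frames"]


@dataclass(frozen=True)
class RenderConfig:
    """Geometry and intensities of the rendered scene.

    The default 400x400 px frame at 0.1 mm/px gives a 40 mm field of view
    at desk scale; the full acquisition format (1200x1216) is supported by
    overriding ``image_size`` and ``mm_per_pixel``.
    """

    image_size: tuple[int, int] = (400, 400)  # (height, width) px
    mm_per_pixel: float = 0.1
    background_level: int = 8  # 8-bit
    noise_sd: float = 2.0  # static background noise, intensity units
    body_length: float = 4.0  # mm
    body_intensity: int = 35
    head_intensity: int = 110
    n_animals: int = 1  # >= 2 only to exercise multi-animal rejection

    def __post_init__(self) -> None:
        if not self.head_intensity > self.body_intensity:
            raise ValueError("head must be brighter than body")
        if not self.body_intensity > self.background_level + 3 * self.noise_sd:
            raise ValueError("body must be brighter than background + 3*noise_sd")
        if self.n_animals < 0:
            raise ValueError("n_animals must be >= 0")

    # body ellipse semi-axes and head disc radius as fractions of body length
    @property
    def body_semi_major_px(self) -> float:
        return 0.40 * self.body_length / self.mm_per_pixel

    @property
    def body_semi_minor_px(self) -> float:
        return 0.12 * self.body_length / self.mm_per_pixel

    @property
    def head_radius_px(self) -> float:
        return 0.13 * self.body_length / self.mm_per_pixel


@dataclass
class FrameSequence:
    frames: np.ndarray  # uint8, (n, H, W)
    ground_truth: pd.DataFrame  # frame, body_x, body_z, pitch, length (mm / deg)
    background: np.ndarray  # uint8, (H, W), the true static background
    config: RenderConfig
    frame_rate: float

    def __len__(self) -> int:
        return len(self.frames)


def _paint_fish(frame: np.ndarray, cfg: RenderConfig, col: float, row: float,
                pitch_deg: float, heading: int, supersample: int = 4):
    """Anti-aliased body ellipse + head disc, painted in place.

    (col, row) is the body-ellipse center in pixel coordinates; the head
    disc center sits half a body length along the pitch direction.
    Returns the coverage-weighted centroids ((col, row) tuples) of the
    painted body and head regions — the pose an ideal detector recovers.
    """
    H, W = frame.shape
    a = cfg.body_semi_major_px
    b = cfg.body_semi_minor_px
    r = cfg.head_radius_px
    half_len = 0.5 * cfg.body_length / cfg.mm_per_pixel
    th = np.radians(pitch_deg)
    ux, uz = np.cos(th) * heading, np.sin(th)  # unit axis, z up
    hc_col = col + half_len * ux
    hc_row = row - half_len * uz

    pad = 2
    c0 = int(np.floor(min(col, hc_col) - max(a, r) - pad))
    c1 = int(np.ceil(max(col, hc_col) + max(a, r) + pad))
    r0 = int(np.floor(min(row, hc_row) - max(a, r) - pad))
    r1 = int(np.ceil(max(row, hc_row) + max(a, r) + pad))
    if c0 < 0 or r0 < 0 or c1 >= W or r1 >= H:
        raise ValueError("animal out of bounds of the rendered frame")

    ss = supersample
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    off = (np.arange(ss) + 0.5) / ss - 0.5
    sub_c = (cols[:, None] + off[None, :]).ravel()  # (nc*ss,)
    sub_r = (rows[:, None] + off[None, :]).ravel()
    CC, RR = np.meshgrid(sub_c, sub_r)  # (nr*ss, nc*ss)

    # body ellipse in the axis-aligned fish frame (z up => -row direction)
    dc = CC - col
    dr = RR - row
    axial = dc * ux + (-dr) * uz
    perp = dc * (-uz) + (-dr) * ux
    in_body = (axial / a) ** 2 + (perp / b) ** 2 <= 1.0
    in_head = (CC - hc_col) ** 2 + (RR - hc_row) ** 2 <= r * r

    def coverage(mask):
        m = mask.reshape(len(rows), ss, len(cols), ss)
        return m.mean(axis=(1, 3))

    cov_head = coverage(in_head)
    cov_body = np.clip(coverage(in_body & ~in_head), 0.0, 1.0 - cov_head)
    patch = frame[r0 : r1 + 1, c0 : c1 + 1].astype(float)
    patch = (
        patch * (1.0 - cov_body - cov_head)
        + cfg.body_intensity * cov_body
        + cfg.head_intensity * cov_head
    )
    frame[r0 : r1 + 1, c0 : c1 + 1] = np.clip(np.round(patch), 0, 255).astype(np.uint8)

    CJ, RJ = np.meshgrid(cols.astype(float), rows.astype(float))

    def centroid(cov):
        w = cov.sum()
        return (float((CJ * cov).sum() / w), float((RJ * cov).sum() / w))

    return centroid(cov_body), centroid(cov_head)


def render_frames(trace: PoseTrace, cfg: RenderConfig = RenderConfig(),
                  seed: int | np.random.Generator = 0) -> FrameSequence:
    """Render a pose trace into grayscale frames.

    The trace is translated so its bounding box is centered in the frame.
    Frames with ``epoch_id < 0`` show pure background (animal out of
    view).  With ``n_animals >= 2`` additional copies of the animal are
    painted at a fixed spatial offset; with 0, only background is drawn.
    The same seed always yields identical pixel arrays.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    H, W = cfg.image_size
    background = np.clip(
        np.round(cfg.background_level + rng.normal(0.0, cfg.noise_sd, size=(H, W))),
        0, 255,
    ).astype(np.uint8)

    vis = trace.epoch_id >= 0
    if vis.any():
        cx = (np.nanmin(trace.x[vis]) + np.nanmax(trace.x[vis])) / 2.0
        cz = (np.nanmin(trace.z[vis]) + np.nanmax(trace.z[vis])) / 2.0
    else:
        cx = cz = 0.0
    # mm coordinates of the rendered scene: centered in the frame
    x_mm = trace.x - cx + (W / 2.0) * cfg.mm_per_pixel
    z_mm = trace.z - cz + (H / 2.0) * cfg.mm_per_pixel

    offsets_px = [(0.0, 0.0)]
    for k in range(1, cfg.n_animals):
        offsets_px.append((k * W / 4.0, -k * H / 4.0 * 0.5))

    n = trace.n_frames
    frames = np.empty((n, H, W), dtype=np.uint8)
    gt_rows = []
    mpp = cfg.mm_per_pixel
    for i in range(n):
        frame = background.copy()
        body_c = head_c = None
        if vis[i] and cfg.n_animals >= 1:
            col = x_mm[i] / mpp
            row = (H - 1) - z_mm[i] / mpp
            for (doc, dor) in offsets_px:
                bc, hc = _paint_fish(frame, cfg, col + doc, row + dor,
                                     trace.pitch[i], int(trace.heading[i]))
                if doc == 0.0 and dor == 0.0:
                    body_c, head_c = bc, hc
        frames[i] = frame
        # ground truth = coverage centroids of the painted regions, in mm
        gt_rows.append({
            "frame": i,
            "body_x": body_c[0] * mpp if body_c else np.nan,
            "body_z": (H - 1 - body_c[1]) * mpp if body_c else np.nan,
            "head_x": head_c[0] * mpp if head_c else np.nan,
            "head_z": (H - 1 - head_c[1]) * mpp if head_c else np.nan,
            "pitch": trace.pitch[i] if vis[i] else np.nan,
            "length": trace.body_length,
        })
    return FrameSequence(
        frames=frames,
        ground_truth=pd.DataFrame(gt_rows),
        background=background,
        config=cfg,
        frame_rate=trace.frame_rate,
    )


def save_frames(seq: FrameSequence, tiff_path, ground_truth_csv=None) -> None:
    """Write frames as a multipage TIFF plus an optional ground-truth CSV."""
    import tifffile

    tifffile.imwrite(tiff_path, seq.frames)
    if ground_truth_csv is not None:
        seq.ground_truth.to_csv(ground_truth_csv, index=False)


def load_frames(path) -> np.ndarray:
    """Read a multipage TIFF (or a directory of numbered TIFF/PNG frames)."""
    import os

    import tifffile

    if os.path.isdir(path):
        from imageio.v3 import imread

        names = sorted(
            f for f in os.listdir(path) if f.lower().endswith((".tif", ".tiff", ".png"))
        )
        return np.stack([imread(os.path.join(path, f)) for f in names])
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr
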