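"""Extraction of vertical head-movement trajectories from facial video.

Pipeline: detect the face once on the first frame (boosted LBP cascade, the
same family of detector as Viola-Jones), derive forehead and nose
sub-regions from the face box, pick strong corners inside them
(Shi-Tomasi "good features to track"), then follow each corner through the
sequence with an iterative Lucas-Kanade translation tracker and keep the
sub-pixel y-coordinate of every point.

Only geometry is used, so color input is converted to grayscale luminance
up front.  Recordings at rates other than 30 fps are tracked at native rate
and resampled to 30 Hz by cubic interpolation so the downstream feature
dimension is rate-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import map_coordinates

from . import errors

__all__ = [
    "FrameSequence",
    "RoiSet",
    "PointTrajectories",
    "detect_face",
    "derive_subrois",
    "extract_points",
    "track",
    "resample_trajectories",
    "trajectories_from_video",
]

#: Working sampling rate (Hz) all trajectories are resampled to.
WORKING_FPS = 30.0

#: Default cap on corners kept per sub-region.
MAX_POINTS_PER_ROI = 50

#: Corner quality floor, relative to the strongest corner in the region.
MIN_CORNER_QUALITY = 0.01

# Lucas-Kanade parameters: half window size, iteration cap, convergence
# tolerance in pixels.
_LK_HALF_WIN = 10
_LK_MAX_ITER = 30
_LK_TOL = 1e-3


@dataclass(frozen=True)
class FrameSequence:
    """A stack of same-sized grayscale frames at a constant rate."""

    frames: np.ndarray  # [n_frames x height x width]
    fps: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need >= 2 frames of identical size")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])


@dataclass(frozen=True)
class RoiSet:
    """Face box plus the forehead and nose sub-boxes, (x, y, w, h) pixels."""

    face_box: tuple[int, int, int, int]
    forehead_box: tuple[int, int, int, int]
    nose_box: tuple[int, int, int, int]


@dataclass
class PointTrajectories:
    """Per-point vertical coordinates over time, with validity flags."""

    y: np.ndarray           # [n_points x n_frames], sub-pixel
    fps: float
    valid_mask: np.ndarray  # bool, same shape as y

    @property
    def n_points(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.y.shape[1])

    def fully_valid_matrix(self) -> np.ndarray:
        """Rows tracked through every frame (partial tracks are dropped)."""
        keep = self.valid_mask.all(axis=1)
        return self.y[keep]


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Luminance conversion; grayscale input passes through."""
    f = np.asarray(frame, dtype=float)
    if f.ndim == 3:
        f = 0.2125 * f[..., 0] + 0.7154 * f[..., 1] + 0.0721 * f[..., 2]
    return f


def detect_face(
    frame: np.ndarray,
    manual_box: tuple[int, int, int, int] | None = None,
) -> tuple[int, int, int, int]:
    """Locate the largest frontal face on a frame.

    A boosted multi-block LBP cascade (scikit-image's bundled frontal-face
    model) stands in for the Viola-Jones Haar cascade; both are
    boosted-cascade sliding-window detectors.  ``manual_box`` bypasses
    detection entirely, which lets synthetic non-face videos run the full
    pipeline.

    Raises
    ------
    errors.NoFaceFound
        If the cascade returns no detection.
    """
    if manual_box is not None:
        return tuple(int(v) for v in manual_box)
    from skimage import data as _skdata
    from skimage.feature import Cascade

    gray = to_grayscale(frame)
    if gray.size == 0:
        raise errors.NoFaceFound("empty frame")
    detector = Cascade(_skdata.lbp_frontal_face_cascade_filename())
    h, w = gray.shape
    min_side = max(24, min(h, w) // 10)
    detections = detector.detect_multi_scale(
        img=gray,
        scale_factor=1.2,
        step_ratio=1,
        min_size=(min_side, min_side),
        max_size=(h, w),
    )
    if not detections:
        raise errors.NoFaceFound("cascade found no face")
    best = max(detections, key=lambda d: d["width"] * d["height"])
    x, y = int(best["c"]), int(best["r"])
    bw = min(int(best["width"]), w - x)
    bh = min(int(best["height"]), h - y)
    return (x, y, bw, bh)


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def derive_subrois(face_box: tuple[int, int, int, int]) -> RoiSet:
    """Carve the forehead and nose regions out of a face box.

    Forehead: middle 50% of the width, top 20% of the height.
    Nose: middle 50% of the width, middle 25% of the height.
    Fractions are applied before rounding (nearest integer, half up), so the
    construction is scale-equivariant.

    Raises
    ------
    errors.DegenerateBox
        If rounding produces a zero-area sub-box.
    """
    x, y, w, h = face_box
    if w <= 0 or h <= 0:
        raise errors.DegenerateBox(f"face box {face_box} has no area")
    forehead = (
        _round_half_up(x + 0.25 * w),
        _round_half_up(y),
        _round_half_up(0.5 * w),
        _round_half_up(0.2 * h),
    )
    nose = (
        _round_half_up(x + 0.25 * w),
        _round_half_up(y + 0.375 * h),
        _round_half_up(0.5 * w),
        _round_half_up(0.25 * h),
    )
    for box in (forehead, nose):
        if box[2] <= 0 or box[3] <= 0:
            raise errors.DegenerateBox(f"sub-box {box} has no area")
    return RoiSet(face_box=tuple(int(v) for v in face_box),
                  forehead_box=forehead, nose_box=nose)


def extract_points(
    frame: np.ndarray,
    rois: RoiSet,
    max_points: int = MAX_POINTS_PER_ROI,
) -> np.ndarray:
    """Pick Shi-Tomasi corners inside the forehead and nose boxes.

    Returns an ``[n x 2]`` array of (x, y) points in frame coordinates,
    strongest corners first within each sub-box, at most ``max_points`` per
    box.  Corners weaker than ``MIN_CORNER_QUALITY`` of the best corner in
    their box are discarded.

    Raises
    ------
    errors.NoTrackablePoints
        If neither sub-box yields a corner.
    """
    from skimage.feature import corner_peaks, corner_shi_tomasi

    gray = to_grayscale(frame)
    points: list[tuple[float, float]] = []
    for box in (rois.forehead_box, rois.nose_box):
        x0, y0, w, h = box
        crop = gray[y0:y0 + h, x0:x0 + w]
        if crop.size == 0:
            continue
        response = corner_shi_tomasi(crop)
        peaks = corner_peaks(
            response, min_distance=3, threshold_rel=MIN_CORNER_QUALITY,
            num_peaks=max_points,
        )
        if peaks.size == 0:
            continue
        strengths = response[peaks[:, 0], peaks[:, 1]]
        order = np.argsort(strengths)[::-1]
        for r, c in peaks[order]:
            points.append((float(c + x0), float(r + y0)))
    if not points:
        raise errors.NoTrackablePoints("no corners in forehead or nose region")
    return np.asarray(points, dtype=float)


def _lk_track_point(
    prev: np.ndarray,
    prev_gy: np.ndarray,
    prev_gx: np.ndarray,
    nxt: np.ndarray,
    pt: np.ndarray,
) -> tuple[np.ndarray, bool]:
    """One inter-frame Lucas-Kanade translation update for one point.

    Minimizes the SSD between a fixed template window around ``pt`` in the
    previous frame and a translated window in the next frame, using the
    template's spatial gradients (Gauss-Newton on the 2-vector offset).
    """
    h, w = prev.shape
    x, y = pt
    half = _LK_HALF_WIN
    if not (half <= x <= w - 1 - half and half <= y <= h - 1 - half):
        return pt, False
    dy, dx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    rows = y + dy
    cols = x + dx
    template = map_coordinates(prev, [rows, cols], order=1)
    gx = map_coordinates(prev_gx, [rows, cols], order=1)
    gy = map_coordinates(prev_gy, [rows, cols], order=1)
    g = np.array([
        [np.sum(gx * gx), np.sum(gx * gy)],
        [np.sum(gx * gy), np.sum(gy * gy)],
    ])
    if np.linalg.cond(g) > 1e8:
        return pt, False

    offset = np.zeros(2)  # (dx, dy)
    for _ in range(_LK_MAX_ITER):
        r2 = rows + offset[1]
        c2 = cols + offset[0]
        if (r2.min() < 0 or r2.max() > h - 1 or
                c2.min() < 0 or c2.max() > w - 1):
            return pt, False
        warped = map_coordinates(nxt, [r2, c2], order=1)
        err = template - warped
        b = np.array([np.sum(gx * err), np.sum(gy * err)])
        step = np.linalg.solve(g, b)
        offset += step
        if np.hypot(*step) < _LK_TOL:
            break
    new = np.array([x + offset[0], y + offset[1]])
    ok = bool(half <= new[0] <= w - 1 - half and half <= new[1] <= h - 1 - half)
    return new, ok


def track(frames: FrameSequence, points: np.ndarray) -> PointTrajectories:
    """Follow first-frame points through the sequence; keep y-coordinates.

    A point's ``valid_mask`` turns (and stays) false from the first frame on
    which tracking fails -- the window leaving the image or the normal
    equations becoming singular.

    Raises
    ------
    errors.AllPointsLost
        If every point fails before the last frame.
    """
    pts = np.asarray(points, dtype=float)
    n_pts, n_frames = pts.shape[0], frames.n_frames
    y = np.full((n_pts, n_frames), np.nan)
    valid = np.zeros((n_pts, n_frames), dtype=bool)
    positions = pts.copy()
    y[:, 0] = positions[:, 1]
    valid[:, 0] = True
    alive = np.ones(n_pts, dtype=bool)

    for t in range(1, n_frames):
        prev = np.asarray(frames.frames[t - 1], dtype=float)
        nxt = np.asarray(frames.frames[t], dtype=float)
        gy, gx = np.gradient(prev)
        for i in range(n_pts):
            if not alive[i]:
                continue
            new, ok = _lk_track_point(prev, gy, gx, nxt, positions[i])
            if ok:
                positions[i] = new
                y[i, t] = new[1]
                valid[i, t] = True
            else:
                alive[i] = False
        if not alive.any() and t < n_frames - 1:
            raise errors.AllPointsLost(f"all points lost at frame {t}")
    if not valid[:, -1].any():
        raise errors.AllPointsLost("no point survived to the last frame")
    return PointTrajectories(y=y, fps=frames.fps, valid_mask=valid)


def resample_trajectories(
    traj: PointTrajectories, target_fps: float = WORKING_FPS
) -> PointTrajectories:
    """Cubic-interpolate fully valid trajectories onto a uniform target grid.

    Used to bring e.g. 60 fps recordings onto the 30 Hz working rate so the
    RPD dimension stays fixed.  Partially tracked points are dropped.
    """
    if np.isclose(traj.fps, target_fps):
        return traj
    y = traj.fully_valid_matrix()
    if y.shape[0] == 0:
        raise errors.AllPointsLost("no fully valid trajectory to resample")
    t_src = np.arange(traj.n_frames) / traj.fps
    t_dst = np.arange(0.0, t_src[-1] + 0.5 / target_fps, 1.0 / target_fps)
    t_dst = t_dst[t_dst <= t_src[-1]]
    out = np.vstack([CubicSpline(t_src, row)(t_dst) for row in y])
    return PointTrajectories(
        y=out, fps=target_fps, valid_mask=np.ones(out.shape, dtype=bool)
    )


def trajectories_from_video(
    frames: FrameSequence,
    manual_box: tuple[int, int, int, int] | None = None,
    max_points: int = MAX_POINTS_PER_ROI,
) -> PointTrajectories:
    """Convenience front end: detect, pick points on frame 0, track, resample."""
    face = detect_face(frames.frames[0], manual_box=manual_box)
    rois = derive_subrois(face)
    pts = extract_points(frames.frames[0], rois, max_points=max_points)
    traj = track(frames, pts)
    return resample_trajectories(traj)
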