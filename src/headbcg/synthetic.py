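"""Synthetic data with known ground truth for every pipeline stage.

Generates (a) multi-point head-movement trajectory matrices carrying a
cardiac fundamental in 0.75-2.5 Hz plus harmonics, low-frequency drift,
optional artifact bouts and white noise; (b) ECG-like beat trains at known
rates; (c) videos of a textured patch translating vertically by the
ballistocardiographic waveform; and (d) whole multi-subject cohorts whose
trajectories and ECG share one beat timeline.

All generators are pure functions of (spec, seed): the same spec yields the
same arrays.  Artifact levels mirror increasingly hostile recording
conditions -- ``none`` (still subject), ``expressions`` (smooth 2-5 s
transient bumps) and ``expressions+motion`` (bumps plus step displacements
and 0.3-0.7 Hz oscillatory bouts).  Bout amplitudes are configuration, not
constants; the defaults are chosen so the three levels degrade the
baselines in the expected order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d, map_coordinates

from . import errors
from .features import EcgRecord
from .tracking import FrameSequence, PointTrajectories

__all__ = [
    "ARTIFACT_LEVELS",
    "BcgSpec",
    "EcgSpec",
    "gen_trajectories",
    "gen_ecg",
    "gen_video",
    "gen_cohort",
]

ARTIFACT_LEVELS = ("none", "expressions", "expressions+motion")


@dataclass(frozen=True)
class BcgSpec:
    """Recipe for one synthetic head-movement recording."""

    hr_bpm: float | np.ndarray = 72.0
    n_points: int = 10
    harmonic_amps: tuple[float, ...] = (1.0, 0.5, 0.25)
    drift_amp_px: float = 1.0
    drift_hz: float = 0.2
    artifact_level: str = "none"
    noise_sd_px: float = 0.05
    duration_sec: float = 60.0
    fps: float = 30.0
    seed: int = 0
    # Artifact bout magnitudes (pixels), tunable per experiment level.
    expression_amp_px: float = 12.0
    motion_step_px: float = 25.0
    motion_osc_px: float = 15.0

    def validate(self) -> None:
        hr = np.atleast_1d(np.asarray(self.hr_bpm, dtype=float))
        if hr.min() < 45.0 or hr.max() > 150.0:
            raise errors.InvalidSpec(f"hr_bpm outside [45, 150]: {hr.min()}-{hr.max()}")
        if self.fps < 15.0:
            raise errors.InvalidSpec("fps must be >= 15")
        if self.duration_sec < 30.0:
            raise errors.InvalidSpec("duration must be >= 30 s")
        if self.drift_hz >= 0.3:
            raise errors.InvalidSpec("drift must stay below 0.3 Hz")
        if self.artifact_level not in ARTIFACT_LEVELS:
            raise errors.InvalidSpec(f"unknown artifact level {self.artifact_level!r}")
        if self.n_points < 1 or len(self.harmonic_amps) < 1:
            raise errors.InvalidSpec("need >= 1 point and >= 1 harmonic amplitude")


@dataclass(frozen=True)
class EcgSpec:
    """Recipe for one synthetic single-lead ECG record."""

    hr_bpm: float | np.ndarray = 72.0
    rr_jitter_sd_sec: float = 0.0
    qrs_width_sec: float = 0.02
    fs_hz: float = 250.0
    duration_sec: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        hr = np.atleast_1d(np.asarray(self.hr_bpm, dtype=float))
        if hr.min() < 45.0 or hr.max() > 150.0:
            raise errors.InvalidSpec("hr_bpm outside [45, 150]")
        if self.qrs_width_sec >= 60.0 / hr.max():
            raise errors.InvalidSpec("QRS wider than the shortest RR interval")
        if self.fs_hz <= 0 or self.duration_sec <= 0:
            raise errors.InvalidSpec("fs_hz and duration must be positive")


def _rate_track(hr_bpm, n: int) -> np.ndarray:
    """Broadcast a scalar or per-frame heart-rate track to length n."""
    hr = np.asarray(hr_bpm, dtype=float)
    if hr.ndim == 0:
        return np.full(n, float(hr))
    if hr.size != n:
        raise errors.InvalidSpec(f"hr track length {hr.size} != {n} frames")
    return hr


def _cardiac_waveform(spec: BcgSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic pulse waveform following the (possibly varying) rate track."""
    n = int(round(spec.duration_sec * spec.fps))
    hr = _rate_track(spec.hr_bpm, n)
    phase = 2.0 * np.pi * np.cumsum(hr / 60.0) / spec.fps
    wave = np.zeros(n)
    phases = rng.uniform(0, 2 * np.pi, size=len(spec.harmonic_amps))
    for h, amp in enumerate(spec.harmonic_amps):
        wave += amp * np.sin((h + 1) * phase + phases[h])
    return wave, hr


def _hann_bout(n_samples: int, shape: np.ndarray) -> np.ndarray:
    """Window an arbitrary bout shape so it starts and ends at zero."""
    w = np.hanning(n_samples)
    out = shape * w
    peak = np.max(np.abs(out))
    return out / peak if peak > 0 else out


def _artifact_bouts(
    spec: BcgSpec, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[tuple[float, float, str]]]:
    """Individual artifact bout signals and their (start, end, kind) intervals.

    Each bout is a full-length array that is zero outside its interval; the
    caller mixes bouts into trajectories with per-point weights, so that --
    unlike the rank-1 cardiac pulse -- artifacts spread across all PCA
    components, as incoherent facial motion does.
    """
    n = int(round(spec.duration_sec * spec.fps))
    bouts: list[np.ndarray] = []
    intervals: list[tuple[float, float, str]] = []
    if spec.artifact_level == "none":
        return bouts, intervals

    fundamental = spec.harmonic_amps[0]

    # Smooth transient bumps standing in for facial expressions.
    n_bouts = max(1, int(round(spec.duration_sec / 15.0)))
    for _ in range(n_bouts):
        dur = rng.uniform(2.0, 5.0)
        t0 = rng.uniform(0.0, spec.duration_sec - dur)
        i0 = int(t0 * spec.fps)
        m = int(dur * spec.fps)
        walk = gaussian_filter1d(np.cumsum(rng.standard_normal(m)), 0.05 * spec.fps)
        sig = np.zeros(n)
        sig[i0:i0 + m] = (_hann_bout(m, walk) * spec.expression_amp_px * fundamental)[: n - i0]
        bouts.append(sig)
        intervals.append((t0, t0 + dur, "expression"))

    if spec.artifact_level == "expressions+motion":
        # Step displacements: abrupt posture shifts smoothed over ~0.5 s.
        n_steps = max(1, int(round(spec.duration_sec / 25.0)))
        for _ in range(n_steps):
            t0 = rng.uniform(1.0, spec.duration_sec - 1.0)
            i0 = int(t0 * spec.fps)
            amp = rng.choice([-1.0, 1.0]) * spec.motion_step_px
            step = np.zeros(n)
            step[i0:] = amp
            bouts.append(gaussian_filter1d(step, 0.1 * spec.fps))
            intervals.append((max(0.0, t0 - 0.5), min(spec.duration_sec, t0 + 0.5), "step"))
        # Oscillatory head-motion bouts below the cardiac band.
        n_osc = max(1, int(round(spec.duration_sec / 25.0)))
        for _ in range(n_osc):
            dur = rng.uniform(3.0, 6.0)
            t0 = rng.uniform(0.0, spec.duration_sec - dur)
            freq = rng.uniform(0.3, 0.7)
            i0 = int(t0 * spec.fps)
            m = int(dur * spec.fps)
            tt = np.arange(m) / spec.fps
            osc = np.sin(2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))
            sig = np.zeros(n)
            sig[i0:i0 + m] = (_hann_bout(m, osc) * spec.motion_osc_px)[: n - i0]
            bouts.append(sig)
            intervals.append((t0, t0 + dur, "oscillation"))
    return bouts, intervals


def gen_trajectories(spec: BcgSpec) -> tuple[PointTrajectories, dict]:
    """Synthesize an ``[n_points x n_frames]`` vertical-trajectory matrix.

    Each trajectory is ``gain_i * cardiac(t) + drift_i(t) + a_i * artifact(t)
    + noise`` around a random resting coordinate.  The truth record carries
    the heart-rate track, the shared cardiac and artifact signals, the
    artifact intervals and the per-point gains.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_sec * spec.fps))
    t = np.arange(n) / spec.fps

    cardiac, hr = _cardiac_waveform(spec, rng)
    bouts, intervals = _artifact_bouts(spec, rng)
    artifact = np.sum(bouts, axis=0) if bouts else np.zeros(n)

    gains = rng.uniform(0.5, 1.5, size=spec.n_points)
    # Per-bout, per-point mixing: incoherent across points so artifacts leak
    # into every PCA component instead of separating into one.
    bout_weights = rng.normal(1.0, 0.7, size=(len(bouts), spec.n_points))
    base = rng.uniform(50.0, 200.0, size=spec.n_points)
    y = np.empty((spec.n_points, n))
    for i in range(spec.n_points):
        drift = spec.drift_amp_px * np.sin(
            2 * np.pi * spec.drift_hz * t + rng.uniform(0, 2 * np.pi)
        )
        noise = rng.normal(0.0, spec.noise_sd_px, size=n)
        art_i = sum(bout_weights[b, i] * bouts[b] for b in range(len(bouts)))
        y[i] = base[i] + gains[i] * cardiac + drift + art_i + noise

    traj = PointTrajectories(
        y=y, fps=spec.fps, valid_mask=np.ones(y.shape, dtype=bool)
    )
    truth = {
        "hr_track_bpm": hr,
        "cardiac": cardiac,
        "artifact": artifact,
        "artifact_intervals": intervals,
        "gains": gains,
        "seed": spec.seed,
    }
    return traj, truth


def _beat_times_from_rate(
    hr_track: np.ndarray, fs: float, jitter_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Integrate an instantaneous-rate track into beat instants."""
    duration = hr_track.size / fs
    beats = []
    t = 0.15  # first beat shortly after record start
    while t < duration:
        beats.append(t)
        idx = min(int(t * fs), hr_track.size - 1)
        rr = 60.0 / hr_track[idx]
        if jitter_sd > 0:
            rr = max(0.4, rr + rng.normal(0.0, jitter_sd))
        t += rr
    return np.asarray(beats)


def gen_ecg(spec: EcgSpec) -> tuple[EcgRecord, np.ndarray]:
    """Synthesize an ECG-like record and its true beat instants.

    Beat times accumulate RR intervals (60/rate plus optional Gaussian
    jitter); the waveform places a Gaussian-derivative QRS template at each
    beat over a small noise floor.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_sec * spec.fs_hz))
    hr = _rate_track(spec.hr_bpm, n)
    beat_times = _beat_times_from_rate(hr, spec.fs_hz, spec.rr_jitter_sd_sec, rng)

    t = np.arange(n) / spec.fs_hz
    sigma = spec.qrs_width_sec / 2.0
    x = rng.normal(0.0, 0.01, size=n)
    for tb in beat_times:
        lo = max(0, int((tb - 5 * sigma) * spec.fs_hz))
        hi = min(n, int((tb + 5 * sigma) * spec.fs_hz) + 1)
        dt = t[lo:hi] - tb
        x[lo:hi] += -(dt / sigma) * np.exp(-(dt**2) / (2 * sigma**2))
    return EcgRecord(samples=x, fs_hz=spec.fs_hz), beat_times


def gen_video(
    spec: BcgSpec,
    patch_size: tuple[int, int] = (80, 100),
    frame_size: tuple[int, int] = (160, 200),
) -> tuple[FrameSequence, dict]:
    """Render a textured patch translating vertically by the BCG waveform.

    The patch plays the role of the face: the truth record's ``roi`` is the
    manual face box to hand to the tracker.  Rendering is bilinear, so
    sub-pixel motion is preserved.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_sec * spec.fps))
    cardiac, hr = _cardiac_waveform(spec, rng)
    bouts, intervals = _artifact_bouts(spec, rng)
    artifact = np.sum(bouts, axis=0) if bouts else np.zeros(n)
    motion = cardiac + artifact

    ph, pw = patch_size
    fh, fw = frame_size
    if ph >= fh or pw >= fw:
        raise errors.InvalidSpec("patch must fit inside the frame")
    margin = int(np.ceil(np.max(np.abs(motion)))) + 2
    texture = gaussian_filter1d(
        gaussian_filter1d(rng.uniform(0, 1, size=(ph + 2 * margin, pw)), 1.0, axis=0),
        1.0, axis=1,
    )
    texture = 0.1 + 0.8 * (texture - texture.min()) / np.ptp(texture)

    y0 = (fh - ph) // 2
    x0 = (fw - pw) // 2
    rows, cols = np.mgrid[0:ph, 0:pw].astype(float)
    frames = np.full((n, fh, fw), 0.5)
    for k in range(n):
        sampled = map_coordinates(
            texture, [rows + margin - motion[k], cols], order=1
        )
        frames[k, y0:y0 + ph, x0:x0 + pw] = sampled

    seq = FrameSequence(frames=frames, fps=spec.fps)
    truth = {
        "motion_px": motion,
        "hr_track_bpm": hr,
        "artifact_intervals": intervals,
        "roi": (x0, y0, pw, ph),
        "seed": spec.seed,
    }
    return seq, truth


def gen_cohort(
    n_subjects: int,
    hr_range: tuple[float, float] = (55.0, 95.0),
    artifact_level: str = "none",
    seed: int = 0,
    duration_sec: float = 180.0,
    fps: float = 30.0,
    ecg_fs_hz: float = 250.0,
    wander_bpm: float = 3.0,
    **spec_overrides,
) -> list[dict]:
    """Generate a multi-subject cohort with shared beat timing per subject.

    Each subject's resting rate is drawn uniformly from ``hr_range`` and
    wanders slowly by ``+/- wander_bpm``; the same rate track drives both
    the trajectory phase and the ECG beat train, so features and labels are
    physically consistent.  Returns one dict per subject with keys
    ``subject_id``, ``trajectories``, ``ecg``, ``truth``.
    """
    if n_subjects < 2:
        raise errors.InvalidSpec("a cohort needs >= 2 subjects")
    if artifact_level not in ARTIFACT_LEVELS:
        raise errors.InvalidSpec(f"unknown artifact level {artifact_level!r}")
    cohort = []
    n_frames = int(round(duration_sec * fps))
    t = np.arange(n_frames) / fps
    for s in range(n_subjects):
        sub_seed = int(np.random.SeedSequence([seed, s]).generate_state(1)[0])
        rng = np.random.default_rng(sub_seed)
        base = rng.uniform(*hr_range)
        period = rng.uniform(40.0, 70.0)
        hr_track = base + wander_bpm * np.sin(
            2 * np.pi * t / period + rng.uniform(0, 2 * np.pi)
        )
        hr_track = np.clip(hr_track, 45.0, 150.0)
        spec = BcgSpec(
            hr_bpm=hr_track,
            artifact_level=artifact_level,
            duration_sec=duration_sec,
            fps=fps,
            seed=sub_seed,
            **spec_overrides,
        )
        traj, truth = gen_trajectories(spec)
        n_ecg = int(round(duration_sec * ecg_fs_hz))
        hr_ecg = np.interp(np.arange(n_ecg) / ecg_fs_hz, t, hr_track)
        ecg, beat_times = gen_ecg(
            EcgSpec(
                hr_bpm=hr_ecg,
                fs_hz=ecg_fs_hz,
                duration_sec=duration_sec,
                rr_jitter_sd_sec=0.003,
                seed=sub_seed + 1,
            )
        )
        truth = dict(truth, beat_times_sec=beat_times, base_bpm=base)
        cohort.append(
            {
                "subject_id": f"s{s:02d}",
                "trajectories": traj,
                "ecg": ecg,
                "truth": truth,
            }
        )
    return cohort
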