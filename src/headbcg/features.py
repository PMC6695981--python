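"""Spectral feature extraction and ECG labeling.

The clustering feature is the *relative power density* (RPD): the one-sided
FFT power values falling in the cardiac band (0.75-2.5 Hz inclusive),
normalized so they sum to one.  For a 30 s window sampled at 30 Hz the bin
spacing is ``df = 30/900 = 0.0333 Hz`` and the band holds 53 bins, so the
feature vector has 53 dimensions.

Ground-truth labels come from a single-lead ECG: the record is bandpassed to
0.75-2.5 Hz, beats are located with the Pan-Tompkins stages (derivative,
squaring, moving-window integration, adaptive thresholding) and the window
label is the mean of the instantaneous rates ``60/RR``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import errors

__all__ = [
    "CARDIAC_BAND_HZ",
    "PowerSpectrum",
    "RPDVector",
    "EcgRecord",
    "HeartRateLabel",
    "LabeledSample",
    "power_spectrum",
    "band_indices",
    "rpd",
    "ecg_heart_rate",
    "build_dataset",
]

logger = logging.getLogger(__name__)

#: Cardiac pass band in Hz; 0.75-2.5 Hz corresponds to 45-150 bpm.
CARDIAC_BAND_HZ: tuple[float, float] = (0.75, 2.5)

#: Accepted label range in beats per minute (the band converted to bpm).
LABEL_RANGE_BPM: tuple[float, float] = (45.0, 150.0)

# Absolute tolerance (Hz) used when testing band membership of FFT bin
# frequencies; guards against k/fs rounding placing the 2.5 Hz bin a few
# ulps outside the inclusive band.
_BAND_EPS_HZ = 1e-9


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided squared-magnitude FFT spectrum of a real signal."""

    freqs_hz: np.ndarray
    power: np.ndarray
    df_hz: float

    def __post_init__(self) -> None:
        if self.freqs_hz.shape != self.power.shape:
            raise errors.LengthMismatch("freqs_hz and power differ in length")


@dataclass(frozen=True)
class RPDVector:
    """Normalized in-band power densities; the clustering feature."""

    values: np.ndarray
    band: tuple[float, float] = CARDIAC_BAND_HZ

    @property
    def dim(self) -> int:
        return int(self.values.size)

    def __post_init__(self) -> None:
        total = float(np.sum(self.values))
        if not np.isclose(total, 1.0, rtol=1e-9, atol=1e-9):
            raise ValueError(f"RPD values must sum to 1, got {total}")


@dataclass(frozen=True)
class EcgRecord:
    """Raw single-lead ECG samples with their sampling rate."""

    samples: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def duration_sec(self) -> float:
        return self.samples.size / self.fs_hz


@dataclass(frozen=True)
class HeartRateLabel:
    """Per-window heart-rate label derived from detected beats."""

    bpm: float
    beat_times_sec: np.ndarray


@dataclass(frozen=True)
class LabeledSample:
    """One (RPD, heart rate) pair from time-aligned 30 s windows."""

    rpd: RPDVector
    label: HeartRateLabel
    subject_id: str
    window_start_sec: float = 0.0


def power_spectrum(samples: np.ndarray, fps: float) -> PowerSpectrum:
    """Compute the one-sided squared-magnitude FFT spectrum.

    No taper and no zero-padding are applied, so the bin spacing is exactly
    ``fps / len(samples)``.

    Parameters
    ----------
    samples
        Real-valued time series, length >= 2.
    fps
        Sampling rate in Hz.

    Returns
    -------
    PowerSpectrum
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise errors.EmptySignal("need at least 2 samples for a spectrum")
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2
    df = fps / x.size
    freqs = np.arange(power.size) * df
    return PowerSpectrum(freqs_hz=freqs, power=power, df_hz=df)


def band_indices(
    freqs_hz: np.ndarray, band: tuple[float, float] = CARDIAC_BAND_HZ
) -> np.ndarray:
    """Indices of FFT bins inside the inclusive band (both endpoints kept)."""
    low, high = band
    f = np.asarray(freqs_hz, dtype=float)
    return np.flatnonzero((f >= low - _BAND_EPS_HZ) & (f <= high + _BAND_EPS_HZ))


def rpd(ps: PowerSpectrum, band: tuple[float, float] = CARDIAC_BAND_HZ) -> RPDVector:
    """Normalize the in-band power values to the RPD feature.

    Each in-band power is divided by the total in-band power, so the values
    are non-negative and sum to one; ordering is by ascending frequency.

    Raises
    ------
    errors.EmptyBand
        If no FFT bin falls inside the band.
    errors.ZeroBandPower
        If the total in-band power is zero.
    """
    idx = band_indices(ps.freqs_hz, band)
    if idx.size == 0:
        raise errors.EmptyBand(f"no FFT bin in band {band} (df={ps.df_hz:g} Hz)")
    in_band = ps.power[idx]
    total = float(np.sum(in_band))
    if total <= 0.0:
        raise errors.ZeroBandPower("total in-band power is zero")
    return RPDVector(values=in_band / total, band=band)


# --------------------------------------------------------------------------
# ECG labeling (Pan-Tompkins stages on the bandpassed record)
# --------------------------------------------------------------------------

def _pan_tompkins_beats(ecg: EcgRecord) -> np.ndarray:
    """Detect beat instants with the Pan-Tompkins stage chain.

    Stages: 0.75-2.5 Hz Butterworth bandpass (zero phase), five-point
    derivative, squaring, 150 ms moving-window integration, then adaptive
    signal/noise thresholding with a 300 ms refractory period.
    """
    from .cardiac import FilterSpec, bandpass  # local import avoids a cycle

    fs = ecg.fs_hz
    filtered = bandpass(ecg.samples, fs, FilterSpec())

    # Five-point derivative (classic Pan-Tompkins kernel), then squaring.
    kernel = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) * (fs / 8.0)
    deriv = np.convolve(filtered, kernel[::-1], mode="same")
    squared = deriv**2

    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    # Candidate local maxima, no closer than the refractory period.
    from scipy.signal import find_peaks

    refractory = max(1, int(round(0.300 * fs)))
    candidates, _ = find_peaks(mwi, distance=refractory)
    # Forward-backward filtering leaves large transients at the window
    # edges; exclude the first and last 0.5 s from detection.
    guard = int(round(0.5 * fs))
    candidates = candidates[(candidates >= guard) & (candidates < mwi.size - guard)]
    if candidates.size == 0:
        return np.empty(0)

    # Adaptive signal/noise peak-level estimates (Pan-Tompkins thresholding),
    # initialized robustly from the candidate-peak distribution.
    peaks0 = mwi[candidates]
    spki = float(np.percentile(peaks0, 75))
    npki = float(np.percentile(peaks0, 25)) * 0.5
    beats: list[int] = []
    for i in candidates:
        peak = float(mwi[i])
        threshold = npki + 0.25 * (spki - npki)
        if peak > threshold:
            beats.append(int(i))
            spki = 0.125 * peak + 0.875 * spki
        else:
            npki = 0.125 * peak + 0.875 * npki
    return np.asarray(beats, dtype=float) / fs


def ecg_heart_rate(ecg: EcgRecord) -> HeartRateLabel:
    """Label a window of ECG with its mean instantaneous heart rate.

    The label is ``mean(60 / RR)`` over the window's beat-to-beat
    intervals.

    Raises
    ------
    errors.TooFewBeats
        If fewer than 3 beats are detected (no usable RR intervals).
    """
    if ecg.duration_sec < 10.0:
        raise errors.SignalTooShort("ECG window shorter than 10 s")
    beat_times = _pan_tompkins_beats(ecg)
    if beat_times.size < 3:
        raise errors.TooFewBeats(
            f"detected {beat_times.size} beats; need at least 3"
        )
    rr = np.diff(beat_times)
    bpm = float(np.mean(60.0 / rr))
    return HeartRateLabel(bpm=bpm, beat_times_sec=beat_times)


# --------------------------------------------------------------------------
# Dataset assembly
# --------------------------------------------------------------------------

def build_dataset(
    traj_windows: Sequence,
    ecg_windows: Sequence[EcgRecord],
    subject_ids: Sequence[str],
    window_starts_sec: Sequence[float] | None = None,
    ecg_starts_sec: Sequence[float] | None = None,
) -> list[LabeledSample]:
    """Pair cardiac-signal features with ECG labels, window by window.

    ``traj_windows`` holds per-window trajectory matrices (anything accepted
    by :func:`headbcg.cardiac.estimate_cardiac`); ``ecg_windows`` the
    time-aligned ECG windows.  Windows whose ECG labeling fails (too few
    beats, out-of-range rate) are dropped and logged rather than raised.

    Raises
    ------
    errors.AlignmentError
        If paired start times disagree by more than 0.5 s.
    """
    from .cardiac import estimate_cardiac

    n = len(traj_windows)
    if len(ecg_windows) != n or len(subject_ids) != n:
        raise errors.LengthMismatch("window lists must have equal length")
    if window_starts_sec is None:
        window_starts_sec = [0.0] * n
    if ecg_starts_sec is None:
        ecg_starts_sec = list(window_starts_sec)

    samples: list[LabeledSample] = []
    for i in range(n):
        if abs(window_starts_sec[i] - ecg_starts_sec[i]) > 0.5:
            raise errors.AlignmentError(
                f"window {i}: trajectory starts at {window_starts_sec[i]} s "
                f"but ECG at {ecg_starts_sec[i]} s"
            )
        try:
            label = ecg_heart_rate(ecg_windows[i])
        except errors.BcgError as exc:
            logger.warning("window %d dropped: ECG labeling failed (%s)", i, exc)
            continue
        if not LABEL_RANGE_BPM[0] <= label.bpm <= LABEL_RANGE_BPM[1]:
            logger.warning(
                "window %d dropped: label %.1f bpm outside %s",
                i, label.bpm, LABEL_RANGE_BPM,
            )
            continue
        try:
            cardiac = estimate_cardiac(traj_windows[i])
            feature = rpd(power_spectrum(cardiac.samples, cardiac.fps))
        except errors.BcgError as exc:
            logger.warning("window %d dropped: feature extraction failed (%s)", i, exc)
            continue
        samples.append(
            LabeledSample(
                rpd=feature,
                label=label,
                subject_id=str(subject_ids[i]),
                window_start_sec=float(window_starts_sec[i]),
            )
        )
    return samples


def dataset_to_frame(samples: Sequence[LabeledSample]):
    """Flatten labeled samples to a pandas DataFrame (CSV persistence layout)."""
    import pandas as pd

    if not samples:
        return pd.DataFrame()
    dim = samples[0].rpd.dim
    cols = {f"rpd_{i}": [s.rpd.values[i] for s in samples] for i in range(dim)}
    cols["bpm"] = [s.label.bpm for s in samples]
    cols["subject_id"] = [s.subject_id for s in samples]
    cols["window_start_sec"] = [s.window_start_sec for s in samples]
    return pd.DataFrame(cols)


def frame_to_dataset(df) -> list[LabeledSample]:
    """Inverse of :func:`dataset_to_frame` (beat times are not persisted)."""
    rpd_cols = sorted(
        (c for c in df.columns if c.startswith("rpd_")),
        key=lambda c: int(c.split("_")[1]),
    )
    out = []
    for _, row in df.iterrows():
        values = np.asarray([row[c] for c in rpd_cols], dtype=float)
        out.append(
            LabeledSample(
                rpd=RPDVector(values=values),
                label=HeartRateLabel(bpm=float(row["bpm"]), beat_times_sec=np.empty(0)),
                subject_id=str(row["subject_id"]),
                window_start_sec=float(row["window_start_sec"]),
            )
        )
    return out
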