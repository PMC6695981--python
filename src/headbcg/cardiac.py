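"""Cardiac-signal estimation from raw head-movement trajectories.

The chain is: zero-phase 2nd-order Butterworth bandpass (0.75-2.5 Hz,
i.e. 45-150 bpm), PCA to five components over the filtered point
trajectories, then selection of the component with the highest
*periodicity* -- the ratio of the maximum in-band spectral density to the
total in-band power.  A heartbeat is tone-like with harmonics, so the most
periodic component is taken as the cardiac signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from . import errors
from .features import CARDIAC_BAND_HZ, band_indices, power_spectrum

__all__ = [
    "FilterSpec",
    "ComponentSet",
    "CardiacSignal",
    "bandpass",
    "pca_components",
    "periodicity",
    "select_cardiac",
    "estimate_cardiac",
]

#: Number of PCA components retained.
N_COMPONENTS = 5


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass design: 2nd order, 0.75-2.5 Hz."""

    order: int = 2
    low_hz: float = CARDIAC_BAND_HZ[0]
    high_hz: float = CARDIAC_BAND_HZ[1]

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")


@dataclass(frozen=True)
class ComponentSet:
    """Exactly five zero-mean PCA component time series."""

    components: np.ndarray  # [5 x n_frames]
    fps: float

    def __post_init__(self) -> None:
        if self.components.shape[0] != N_COMPONENTS:
            raise ValueError(f"expected {N_COMPONENTS} components")


@dataclass(frozen=True)
class CardiacSignal:
    """The selected component together with its periodicity score."""

    samples: np.ndarray
    fps: float
    periodicity: float
    component_index: int


def bandpass(signal: np.ndarray, fps: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Apply the Butterworth bandpass forward and backward (zero phase).

    The output has the same length as the input.  Because the filter runs
    twice, the effective magnitude response is the square of the 2nd-order
    design.

    Raises
    ------
    errors.NyquistViolation
        If ``fps <= 2 * high_hz``.
    errors.SignalTooShort
        If the signal is too short for stable forward-backward filtering.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if fps <= 2.0 * spec.high_hz:
        raise errors.NyquistViolation(
            f"fps={fps} Hz cannot represent {spec.high_hz} Hz"
        )
    b, a = butter(spec.order, [spec.low_hz, spec.high_hz], btype="band", fs=fps)
    padlen = 3 * max(len(a), len(b))  # filtfilt default edge padding
    if x.shape[-1] <= padlen:
        raise errors.SignalTooShort(
            f"need more than {padlen} samples, got {x.shape[-1]}"
        )
    y = filtfilt(b, a, x, axis=-1)
    return y[0] if np.ndim(signal) == 1 else y


def pca_components(y: np.ndarray, fps: float) -> ComponentSet:
    """Project trajectories onto the top-5 principal directions.

    ``y`` is an ``[n_points x n_frames]`` matrix of (already bandpassed)
    trajectories.  Each row is mean-centered; no variance scaling is applied
    since all rows share pixel units.  Components are ordered by explained
    variance, descending, and each is zero mean.

    Raises
    ------
    errors.InsufficientPoints
        If fewer than 5 trajectories are supplied.
    """
    x = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape[0] < N_COMPONENTS:
        raise errors.InsufficientPoints(
            f"need >= {N_COMPONENTS} trajectories, got {x.shape[0] if x.ndim == 2 else 0}"
        )
    centered = x - x.mean(axis=1, keepdims=True)
    # Point-wise covariance is small (n_points x n_points); eigendecompose it
    # and project the trajectories onto the leading eigenvectors.
    cov = centered @ centered.T / max(1, centered.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:N_COMPONENTS]
    comps = evecs[:, order].T @ centered
    return ComponentSet(components=comps, fps=fps)


def periodicity(samples: np.ndarray, fps: float) -> float:
    """Max in-band spectral density over total in-band power.

    Uses the same spectrum estimator as the RPD feature (one-sided squared
    magnitude, no taper), so component selection and the feature agree.  The
    score lies in ``(0, 1]``; a pure on-bin tone scores 1.

    Raises
    ------
    errors.EmptyBand
        If no FFT bin falls in the 0.75-2.5 Hz band.
    errors.ZeroBandPower
        If the in-band power is zero.
    """
    ps = power_spectrum(samples, fps)
    idx = band_indices(ps.freqs_hz)
    if idx.size == 0:
        raise errors.EmptyBand(f"df={ps.df_hz:g} Hz leaves no in-band bin")
    in_band = ps.power[idx]
    total = float(np.sum(in_band))
    if total <= 0.0:
        raise errors.ZeroBandPower("zero in-band power")
    return float(np.max(in_band) / total)


def select_cardiac(components: ComponentSet) -> CardiacSignal:
    """Pick the component with the highest periodicity (ties: lower index)."""
    scores = np.array(
        [periodicity(c, components.fps) for c in components.components]
    )
    best = int(np.argmax(scores))  # argmax returns the first maximum
    return CardiacSignal(
        samples=components.components[best],
        fps=components.fps,
        periodicity=float(scores[best]),
        component_index=best,
    )


def estimate_cardiac(trajectories, fps: float | None = None,
                     spec: FilterSpec = FilterSpec()) -> CardiacSignal:
    """Full chain: bandpass -> PCA -> periodicity selection.

    ``trajectories`` may be a :class:`headbcg.tracking.PointTrajectories`
    (only fully tracked points are used) or an ``[n_points x n_frames]``
    array with ``fps`` given explicitly.
    """
    if fps is None:
        y = trajectories.fully_valid_matrix()
        fps = trajectories.fps
    else:
        y = np.asarray(trajectories, dtype=float)
    if y.shape[0] < N_COMPONENTS:
        raise errors.InsufficientPoints(
            f"need >= {N_COMPONENTS} fully tracked points, got {y.shape[0]}"
        )
    filtered = bandpass(y, fps, spec)
    comps = pca_components(filtered, fps)
    return select_cardiac(comps)
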