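"""Heart-rate estimation from an RPD feature, plus classic baselines.

The clustering estimator ranks model entries by Euclidean distance to the
query RPD, takes the ``k`` nearest and averages their heart-rate labels.
The baselines operate directly on the cardiac time series: peak detection
(mean of 60/PPI over peak-to-peak intervals) and FFT (60 x the dominant
in-band frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from . import errors
from .cardiac import CardiacSignal
from .features import (
    CARDIAC_BAND_HZ,
    LabeledSample,
    RPDVector,
    band_indices,
    power_spectrum,
)
from .model import HRModel

__all__ = [
    "EstimationConfig",
    "HREstimate",
    "estimate_clustering",
    "optimize_k",
    "estimate_peak",
    "estimate_fft",
]

#: Minimum peak separation for the peak baseline: 60/150 bpm = 0.4 s.
MIN_PEAK_DISTANCE_SEC = 0.4


@dataclass(frozen=True)
class EstimationConfig:
    """Number of model candidates averaged into one estimate."""

    k: int = 1
    farthest: bool = False  # rank by descending distance (diagnostic only)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class HREstimate:
    """One per-window heart-rate estimate."""

    bpm: float
    method: str
    candidates: tuple[tuple[float, float], ...] = ()  # (rep_bpm, distance)


def estimate_clustering(
    rpd: RPDVector,
    model: HRModel,
    cfg: EstimationConfig = EstimationConfig(),
) -> HREstimate:
    """Average the heart rates of the ``k`` nearest model entries.

    Distances are Euclidean in RPD space; ties are broken by lower entry
    index (stable sort).  Setting ``cfg.farthest`` ranks by *descending*
    distance instead, reproducing a literal reading of the ranking rule for
    comparison -- the default is nearest-first.

    Raises
    ------
    errors.EmptyModel / errors.DimensionMismatch
    """
    if model.n_entries == 0:
        raise errors.EmptyModel("model has no entries")
    if rpd.dim != model.feature_dim:
        raise errors.DimensionMismatch(
            f"rpd dim {rpd.dim} vs model dim {model.feature_dim}"
        )
    k = min(cfg.k, model.n_entries)
    dists = np.linalg.norm(model.centroids - rpd.values[None, :], axis=1)
    order = np.argsort(-dists if cfg.farthest else dists, kind="stable")[:k]
    cand = tuple((float(model.rep_bpms[i]), float(dists[i])) for i in order)
    return HREstimate(
        bpm=float(np.mean([c[0] for c in cand])),
        method="clustering",
        candidates=cand,
    )


def optimize_k(
    model: HRModel,
    validation: list[LabeledSample],
    k_range: range = range(1, 11),
) -> int:
    """Pick the ``k`` minimizing mean |label - estimate| on validation data.

    Ties go to the smaller ``k``.

    Raises
    ------
    errors.EmptyValidation
    """
    if not validation:
        raise errors.EmptyValidation("no validation samples")
    best_k, best_err = None, np.inf
    for k in k_range:
        errs = [
            abs(s.label.bpm - estimate_clustering(s.rpd, model, EstimationConfig(k=k)).bpm)
            for s in validation
        ]
        mean_err = float(np.mean(errs))
        if mean_err < best_err:
            best_k, best_err = k, mean_err
    return int(best_k)


def estimate_peak(cardiac: CardiacSignal) -> HREstimate:
    """Peak-detection baseline: mean of 60/PPI over detected peaks.

    Peaks are local maxima separated by at least 0.4 s (the 150 bpm
    ceiling).

    Raises
    ------
    errors.TooFewPeaks
        If fewer than 3 peaks are found (no usable intervals).
    """
    x = np.asarray(cardiac.samples, dtype=float)
    if x.size / cardiac.fps < 10.0:
        raise errors.SignalTooShort("window shorter than 10 s")
    distance = max(1, int(round(MIN_PEAK_DISTANCE_SEC * cardiac.fps)))
    peaks, _ = find_peaks(x, distance=distance)
    if peaks.size < 3:
        raise errors.TooFewPeaks(f"found {peaks.size} peaks; need >= 3")
    ppi = np.diff(peaks) / cardiac.fps
    return HREstimate(bpm=float(np.mean(60.0 / ppi)), method="peak")


def estimate_fft(cardiac: CardiacSignal) -> HREstimate:
    """FFT baseline: 60 x the in-band frequency with the highest power.

    Raises
    ------
    errors.ZeroBandPower
        If the in-band spectrum is identically zero.
    """
    x = np.asarray(cardiac.samples, dtype=float)
    if x.size / cardiac.fps < 10.0:
        raise errors.SignalTooShort("window shorter than 10 s")
    ps = power_spectrum(x, cardiac.fps)
    idx = band_indices(ps.freqs_hz, CARDIAC_BAND_HZ)
    if idx.size == 0:
        raise errors.EmptyBand("no in-band FFT bin")
    in_band = ps.power[idx]
    if float(np.sum(in_band)) <= 0.0:
        raise errors.ZeroBandPower("no in-band power")
    dominant = ps.freqs_hz[idx[int(np.argmax(in_band))]]
    return HREstimate(bpm=float(60.0 * dominant), method="fft")
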