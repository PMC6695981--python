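"""Heart-rate model training: kurtosis-gated k-means over RPD features.

Training samples are first split into 10-bpm bins so sparse rates are not
swamped by common ones.  Within each bin, k-means runs for every cluster
count ``n`` from 3 up to the number of distinct (1-bpm-rounded) labels; a
cluster survives only if the Pearson kurtosis of its member labels exceeds
the Gaussian value of 3 -- i.e. the labels are concentrated around one rate.
Each survivor contributes one ``(centroid, representative bpm)`` entry, and
the model is the union over all bins and all ``n``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from . import errors
from .features import LabeledSample

__all__ = [
    "ClusterCandidate",
    "HRModel",
    "euclidean",
    "kmeans",
    "gate_by_kurtosis",
    "train",
    "save_model",
    "load_model",
]

MODEL_SCHEMA_VERSION = 1

#: Pearson kurtosis of a Gaussian; the gate keeps clusters above this.
GAUSSIAN_KURTOSIS = 3.0

#: Minimum cluster size for the kurtosis to be meaningful.
MIN_CLUSTER_SIZE = 4

#: 10-bpm training bins covering the measurable band 45-150 bpm.
BIN_EDGES_BPM = [(lo, min(lo + 10.0, 150.0)) for lo in np.arange(45.0, 150.0, 10.0)]

_SWEEP_START = 3  # smallest cluster count tried per bin


@dataclass(frozen=True)
class ClusterCandidate:
    """One k-means cluster: centroid, member labels and their kurtosis."""

    centroid: np.ndarray
    member_labels: np.ndarray

    @property
    def kurtosis(self) -> float:
        """Pearson kurtosis of the member labels (Gaussian = 3).

        A zero-variance cluster is maximally peaked, so it scores ``inf``
        rather than the undefined 0/0.
        """
        labels = self.member_labels
        if labels.size < 2 or np.var(labels) < 1e-24:
            return float("inf") if labels.size >= 2 else float("nan")
        return float(stats.kurtosis(labels, fisher=False, bias=True))

    @property
    def rep_bpm(self) -> float:
        return float(np.mean(self.member_labels))


@dataclass
class HRModel:
    """Trained estimator: (RPD centroid, heart-rate label) pairs."""

    centroids: np.ndarray      # [n_entries x feature_dim]
    rep_bpms: np.ndarray       # [n_entries]
    training_meta: dict = field(default_factory=dict)

    @property
    def feature_dim(self) -> int:
        return int(self.centroids.shape[1])

    @property
    def n_entries(self) -> int:
        return int(self.centroids.shape[0])


def euclidean(p: np.ndarray, q: np.ndarray) -> float:
    """Plain Euclidean distance between two equal-length vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise errors.DimensionMismatch(f"{p.shape} vs {q.shape}")
    return float(np.linalg.norm(p - q))


def kmeans(
    features: np.ndarray,
    n: int,
    seed: int,
    labels: np.ndarray | None = None,
    n_init: int = 10,
) -> list[ClusterCandidate]:
    """Cluster feature vectors into ``n`` groups (k-means++, seeded).

    ``labels`` (per-sample bpm values) are carried along so each returned
    candidate knows its member labels; if omitted, members' labels are NaN.

    Raises
    ------
    errors.TooFewSamples
        If there are fewer samples than clusters.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise errors.DimensionMismatch("features must be a 2-D matrix")
    if n < 1 or x.shape[0] < n:
        raise errors.TooFewSamples(f"{x.shape[0]} samples for n={n} clusters")
    if labels is None:
        labels = np.full(x.shape[0], np.nan)
    labels = np.asarray(labels, dtype=float)

    # Tiny instances get many restarts so the seeded run lands on the global
    # optimum (checked against an exhaustive-partition oracle in tests).
    if x.shape[0] <= 12:
        n_init = max(n_init, 50)
    km = KMeans(n_clusters=n, n_init=n_init, random_state=seed % (2**32))
    assign = km.fit_predict(x)
    out = []
    for c in range(n):
        members = assign == c
        if not members.any():
            continue
        out.append(
            ClusterCandidate(
                centroid=km.cluster_centers_[c].copy(),
                member_labels=labels[members].copy(),
            )
        )
    return out


def kmeans_objective(candidates: Sequence[ClusterCandidate],
                     features: np.ndarray, assignment: np.ndarray | None = None
                     ) -> float:
    """Sum of squared distances from each sample to its nearest centroid."""
    x = np.asarray(features, dtype=float)
    cents = np.vstack([c.centroid for c in candidates])
    d2 = ((x[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


def gate_by_kurtosis(
    candidates: Sequence[ClusterCandidate],
) -> list[ClusterCandidate]:
    """Keep clusters whose member-label kurtosis exceeds the Gaussian's.

    Clusters with fewer than :data:`MIN_CLUSTER_SIZE` members are discarded
    outright.  May return an empty list.
    """
    kept = []
    for cand in candidates:
        if cand.member_labels.size < MIN_CLUSTER_SIZE:
            continue
        if cand.kurtosis > GAUSSIAN_KURTOSIS:
            kept.append(cand)
    return kept


def _bin_seed(global_seed: int, bin_index: int, n: int) -> int:
    """Deterministic per-(bin, n) k-means seed derived from the global seed."""
    ss = np.random.SeedSequence([int(global_seed), int(bin_index), int(n)])
    return int(ss.generate_state(1)[0])


def train(dataset: Sequence[LabeledSample], seed: int = 0) -> HRModel:
    """Train the heart-rate model from labeled RPD samples.

    For each 10-bpm bin: sweep the cluster count from 3 to the number of
    distinct labels (rounded to 1 bpm, capped at the bin's sample count),
    gate each clustering's candidates by kurtosis, and register survivors as
    ``(centroid, mean member bpm)`` entries.  The result is deterministic in
    ``seed`` and invariant to sample order.

    Raises
    ------
    errors.EmptyModel
        If no candidate survives any gate.
    """
    if not dataset:
        raise errors.EmptyModel("empty training dataset")
    feats = np.vstack([s.rpd.values for s in dataset])
    labels = np.array([s.label.bpm for s in dataset])

    centroids: list[np.ndarray] = []
    rep_bpms: list[float] = []
    bins_used: list[int] = []
    n_values: dict[int, list[int]] = {}

    for b, (lo, hi) in enumerate(BIN_EDGES_BPM):
        if hi >= 150.0:
            in_bin = (labels >= lo) & (labels <= hi)  # close the top bin
        else:
            in_bin = (labels >= lo) & (labels < hi)
        if in_bin.sum() < MIN_CLUSTER_SIZE:
            continue
        bx, bl = feats[in_bin], labels[in_bin]
        # Sample-order invariance: sort by label, then features.
        order = np.lexsort(tuple(bx.T[::-1]) + (bl,))
        bx, bl = bx[order], bl[order]
        n_max = min(len(np.unique(np.round(bl))), bx.shape[0])
        if n_max < _SWEEP_START:
            continue
        swept = []
        for n in range(_SWEEP_START, n_max + 1):
            cands = kmeans(bx, n, seed=_bin_seed(seed, b, n), labels=bl)
            for cand in gate_by_kurtosis(cands):
                centroids.append(cand.centroid)
                rep_bpms.append(cand.rep_bpm)
            swept.append(n)
        if swept:
            bins_used.append(b)
            n_values[b] = swept

    if not centroids:
        raise errors.EmptyModel("no cluster survived the kurtosis gate")
    return HRModel(
        centroids=np.vstack(centroids),
        rep_bpms=np.asarray(rep_bpms),
        training_meta={
            "seed": int(seed),
            "bins_used": bins_used,
            "n_values": {str(k): v for k, v in n_values.items()},
        },
    )


def save_model(model: HRModel, path: str | Path) -> None:
    """Serialize a model to JSON (schema version checked on load)."""
    if model.n_entries == 0:
        raise errors.SerializationError("refusing to save an empty model")
    payload = {
        "version": MODEL_SCHEMA_VERSION,
        "feature_dim": model.feature_dim,
        "band_hz": [0.75, 2.5],
        "entries": [
            {"centroid": model.centroids[i].tolist(),
             "bpm": float(model.rep_bpms[i])}
            for i in range(model.n_entries)
        ],
        "training_meta": model.training_meta,
    }
    try:
        Path(path).write_text(json.dumps(payload))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise errors.SerializationError(str(exc)) from exc


def load_model(path: str | Path) -> HRModel:
    """Load a model saved by :func:`save_model`.

    Raises
    ------
    errors.SchemaMismatch
        If the version field is absent or unsupported.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise errors.SerializationError(str(exc)) from exc
    if payload.get("version") != MODEL_SCHEMA_VERSION:
        raise errors.SchemaMismatch(
            f"expected schema version {MODEL_SCHEMA_VERSION}, "
            f"got {payload.get('version')!r}"
        )
    entries = payload["entries"]
    return HRModel(
        centroids=np.asarray([e["centroid"] for e in entries], dtype=float),
        rep_bpms=np.asarray([e["bpm"] for e in entries], dtype=float),
        training_meta=payload.get("training_meta", {}),
    )
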