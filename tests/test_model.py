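import itertools

import numpy as np
import pytest

from headbcg import errors
from headbcg.features import HeartRateLabel, LabeledSample, RPDVector
from headbcg.model import (
    ClusterCandidate,
    HRModel,
    euclidean,
    gate_by_kurtosis,
    kmeans,
    kmeans_objective,
    load_model,
    save_model,
    train,
)


def brute_force_kmeans_objective(points: np.ndarray, n: int) -> float:
    """Exhaustive-partition oracle: minimum SSE over all n-labelings."""
    best = np.inf
    for assign in itertools.product(range(n), repeat=len(points)):
        assign = np.asarray(assign)
        sse = 0.0
        for c in range(n):
            members = points[assign == c]
            if len(members):
                sse += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


def make_sample(values: np.ndarray, bpm: float, subject="s") -> LabeledSample:
    return LabeledSample(
        rpd=RPDVector(values=values / values.sum()),
        label=HeartRateLabel(bpm=bpm, beat_times_sec=np.empty(0)),
        subject_id=subject,
    )


def synthetic_binned_dataset(bins, per_bin=40, dim=53, seed=0):
    """Samples whose RPD is a noisy one-hot keyed to their bpm bin."""
    rng = np.random.default_rng(seed)
    samples = []
    for b, center in enumerate(bins):
        hot = 3 + b * 10  # distinct spectral signature per bin
        for j in range(per_bin):
            v = rng.uniform(0, 0.02, size=dim)
            v[hot] = 1.0
            # mostly on-center with a few fixed +/-2 outliers: leptokurtic
            # labels (kurtosis = 10) that stay inside the 10-bpm bin, so the
            # kurtosis gate keeps the clusters and the n-sweep has 3 labels
            offset = {0: -2.0, 1: -2.0, 2: 2.0, 3: 2.0}.get(j, 0.0)
            samples.append(make_sample(v, center + offset))
    rng.shuffle(samples)
    return samples


class TestEuclidean:
    def test_identity(self):
        assert euclidean(np.ones(5), np.ones(5)) == 0.0

    def test_pythagorean(self):
        assert euclidean(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == 5.0

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            p, q = rng.normal(size=(2, 53))
            oracle = sum((a - b) ** 2 for a, b in zip(p, q)) ** 0.5
            assert euclidean(p, q) == pytest.approx(oracle, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(errors.DimensionMismatch):
            euclidean(np.ones(3), np.ones(4))


class TestKmeans:
    def test_two_blobs(self, rng):
        a = rng.normal(0.0, 0.1, size=(30, 2))
        b = rng.normal(10.0, 0.1, size=(30, 2))
        cands = kmeans(np.vstack([a, b]), 2, seed=0)
        centers = sorted(c.centroid[0] for c in cands)
        assert abs(centers[0] - 0.0) < 0.2
        assert abs(centers[1] - 10.0) < 0.2

    def test_degenerate_n_equals_samples(self, rng):
        x = rng.normal(size=(6, 3))
        cands = kmeans(x, 6, seed=0)
        assert kmeans_objective(cands, x) == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("n", [2, 3])
    def test_matches_exhaustive_oracle(self, n, rng):
        for trial in range(5):
            x = np.random.default_rng(trial).normal(size=(8, 2))
            cands = kmeans(x, n, seed=trial)
            obj = kmeans_objective(cands, x)
            assert obj == pytest.approx(brute_force_kmeans_objective(x, n), rel=1e-10)

    def test_deterministic(self, rng):
        x = rng.normal(size=(40, 5))
        a = kmeans(x, 4, seed=9)
        b = kmeans(x, 4, seed=9)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.centroid, cb.centroid)

    def test_too_few_samples(self, rng):
        with pytest.raises(errors.TooFewSamples):
            kmeans(rng.normal(size=(3, 2)), 4, seed=0)

    def test_member_labels_partition(self, rng):
        x = rng.normal(size=(20, 3))
        labels = rng.uniform(50, 100, size=20)
        cands = kmeans(x, 3, seed=0, labels=labels)
        collected = np.sort(np.concatenate([c.member_labels for c in cands]))
        assert np.allclose(collected, np.sort(labels))


class TestKurtosisGate:
    def test_laplace_kept(self):
        kept = 0
        for seed in range(100):
            labels = np.random.default_rng(seed).laplace(70.0, 2.0, size=500)
            cand = ClusterCandidate(centroid=np.zeros(2), member_labels=labels)
            kept += len(gate_by_kurtosis([cand]))
        assert kept >= 95  # Laplace Pearson kurtosis = 6 > 3

    def test_uniform_dropped(self):
        dropped = 0
        for seed in range(100):
            labels = np.random.default_rng(seed).uniform(60.0, 80.0, size=500)
            cand = ClusterCandidate(centroid=np.zeros(2), member_labels=labels)
            dropped += len(gate_by_kurtosis([cand])) == 0
        assert dropped >= 95  # uniform Pearson kurtosis = 1.8 < 3

    def test_small_cluster_dropped(self):
        cand = ClusterCandidate(
            centroid=np.zeros(2), member_labels=np.array([70.0, 70.0, 70.0])
        )
        assert gate_by_kurtosis([cand]) == []

    def test_pure_cluster_kept(self):
        # zero-variance labels = maximally peaked: must survive the gate
        cand = ClusterCandidate(centroid=np.zeros(2), member_labels=np.full(10, 72.0))
        assert len(gate_by_kurtosis([cand])) == 1


class TestTrain:
    def test_bin_coverage(self):
        bins = [60.0, 72.0, 88.0, 97.0]  # +/-2 offsets stay inside each bin
        model = train(synthetic_binned_dataset(bins), seed=0)
        for center in bins:
            assert np.any(np.abs(model.rep_bpms - center) < 5.0)

    def test_single_label_empty_model(self):
        samples = [make_sample(np.ones(10), 72.0) for _ in range(20)]
        with pytest.raises(errors.EmptyModel):
            train(samples, seed=0)

    def test_deterministic(self):
        ds = synthetic_binned_dataset([60.0, 80.0], seed=3)
        a = train(ds, seed=5)
        b = train(ds, seed=5)
        assert np.array_equal(a.centroids, b.centroids)
        assert np.array_equal(a.rep_bpms, b.rep_bpms)

    def test_order_invariance(self):
        ds = synthetic_binned_dataset([60.0, 80.0], seed=3)
        shuffled = list(ds)
        np.random.default_rng(7).shuffle(shuffled)
        a = train(ds, seed=5)
        b = train(shuffled, seed=5)
        assert np.allclose(np.sort(a.rep_bpms), np.sort(b.rep_bpms))

    def test_rep_bpm_inside_source_bin(self):
        model = train(synthetic_binned_dataset([58.0, 71.0, 89.0]), seed=2)
        assert np.all(model.rep_bpms >= 45.0)
        assert np.all(model.rep_bpms <= 150.0)
        edges = np.arange(45.0, 156.0, 10.0)
        for bpm in model.rep_bpms:
            # every entry lies inside one 10-bpm training bin
            assert np.any((bpm >= edges[:-1] - 1e-9) & (bpm <= edges[1:] + 1e-9))


class TestPersistence:
    def test_round_trip(self, tmp_path):
        model = train(synthetic_binned_dataset([60.0, 80.0]), seed=1)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        assert np.allclose(loaded.centroids, model.centroids)
        assert np.allclose(loaded.rep_bpms, model.rep_bpms)
        assert loaded.training_meta["seed"] == model.training_meta["seed"]

    def test_wrong_version(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"version": 99, "entries": []}')
        with pytest.raises(errors.SchemaMismatch):
            load_model(path)

    def test_empty_model_rejected(self, tmp_path):
        empty = HRModel(centroids=np.empty((0, 53)), rep_bpms=np.empty(0))
        with pytest.raises(errors.SerializationError):
            save_model(empty, tmp_path / "m.json")

    def test_garbage_file(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text("not json")
        with pytest.raises(errors.SerializationError):
            load_model(path)
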