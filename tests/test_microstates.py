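"""Clustering, backfitting, smoothing and parameter extraction."""

import itertools

import numpy as np
import pytest

from eegmic import (PrototypeSet, Segmentation, activation, assign_labels,
                    canonical_templates, cosine_similarity,
                    global_explained_variance, modified_kmeans,
                    order_prototypes, segment_statistics, segments_from_labels,
                    smooth_segments)
from eegmic.microstates import _dominant_eigenvector, parameters_from_segments


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@pytest.fixture
def maps3():
    """Three orthonormal maps in 3 channels."""
    return PrototypeSet(maps=np.eye(3))


class TestElementary:
    def test_activation_collinear_orthogonal_and_hand_value(self):
        m = unit([1.0, 0.0, 0.0])
        assert activation(2 * m, m) == pytest.approx(2.0)
        assert activation([0.0, 3.0, 0.0], m) == pytest.approx(0.0)
        assert activation([1.0, 2.0, 2.0], [2 / 3, 2 / 3, 1 / 3]) == \
            pytest.approx(8 / 3)
        with pytest.raises(ValueError):
            activation([1.0, 2.0], [1.0, 0.0, 0.0])

    def test_cosine_closed_forms(self):
        v = np.array([1.0, 2.0, -0.5])
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity(v, -v) == pytest.approx(-1.0)
        assert cosine_similarity([1.0, 0.0], unit([1.0, 1.0])) == \
            pytest.approx(1 / np.sqrt(2))
        with pytest.raises(ValueError):
            cosine_similarity(v, np.zeros(3))


class TestAssignLabels:
    def test_polarity_invariance(self, maps3):
        seg = assign_labels(np.array([-maps3.maps[1]]), maps3)
        assert seg.labels[0] == 1

    def test_tie_goes_to_lowest_index(self, maps3):
        sample = unit(maps3.maps[0] + maps3.maps[2])
        seg = assign_labels(np.array([sample]), maps3)
        assert seg.labels[0] == 0

    def test_matches_bruteforce_argmax(self, rng, orthogonal_prototypes):
        samples = rng.standard_normal((100, 19))
        seg = assign_labels(samples, orthogonal_prototypes)
        expected = [int(np.argmax([(s @ m) ** 2
                                   for m in orthogonal_prototypes.maps]))
                    for s in samples]
        assert seg.labels.tolist() == expected

    def test_empty_input_rejected(self, maps3):
        with pytest.raises(ValueError):
            assign_labels(np.empty((0, 3)), maps3)


class TestGEV:
    def test_perfect_fit_is_one(self, rng, orthogonal_prototypes):
        k = orthogonal_prototypes.k_classes
        labels = rng.integers(0, k, 40)
        scales = rng.uniform(0.5, 2.0, 40) * rng.choice([-1, 1], 40)
        samples = orthogonal_prototypes.maps[labels] * scales[:, None]
        g = global_explained_variance(samples, orthogonal_prototypes, labels)
        assert g == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_fit_is_zero(self, maps3):
        samples = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 2.0]])
        labels = np.array([0, 0])
        g = global_explained_variance(samples, maps3, labels)
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # 3 samples, 2 maps in 2 channels; term-by-term hand computation
        maps = PrototypeSet(maps=np.array([unit([1.0, -1.0]),
                                           unit([2.0, 1.0])]),
                            class_labels=["A", "B"])
        samples = np.array([[1.0, -1.0], [1.0, 1.0], [3.0, 0.0]])
        labels = np.array([0, 1, 1])
        gfp2 = np.array([np.var(s) for s in samples])
        cs2 = np.array([
            (samples[0] @ maps.maps[0]) ** 2 / (samples[0] @ samples[0]),
            (samples[1] @ maps.maps[1]) ** 2 / (samples[1] @ samples[1]),
            (samples[2] @ maps.maps[1]) ** 2 / (samples[2] @ samples[2]),
        ])
        expected = float((cs2 * gfp2).sum() / gfp2.sum())
        got = global_explained_variance(samples, maps, labels)
        assert got == pytest.approx(expected, abs=1e-12)


def brute_force_best_gev(samples):
    """Max GEV over all 2^n binary labelings with optimal eigen-prototypes."""
    n = len(samples)
    best = -1.0
    for bits in itertools.product([0, 1], repeat=n):
        labels = np.array(bits)
        if labels.min() == labels.max():
            continue
        maps = np.array([_dominant_eigenvector(samples[labels == k])
                         for k in (0, 1)])
        try:
            protos = PrototypeSet(maps=maps, class_labels=["A", "B"])
        except ValueError:
            continue
        best = max(best, global_explained_variance(samples, protos, labels))
    return best


class TestModifiedKMeans:
    def test_noiseless_recovery_and_unit_gev(self, rng, orthogonal_prototypes):
        k = orthogonal_prototypes.k_classes
        labels = np.repeat(np.arange(k), 15)
        signs = rng.choice([-1.0, 1.0], labels.size)
        samples = orthogonal_prototypes.maps[labels] * signs[:, None]
        protos, seg, _diag = modified_kmeans(samples, k, n_restarts=10, seed=0)
        assert seg.gev == pytest.approx(1.0, abs=1e-9)
        sim = np.abs(protos.maps @ orthogonal_prototypes.maps.T)
        assert np.allclose(sim.max(axis=1), 1.0, atol=1e-9)

    def test_loss_is_monotone_within_run(self, rng):
        samples = rng.standard_normal((60, 19))
        samples -= samples.mean(axis=1, keepdims=True)
        _p, _s, diag = modified_kmeans(samples, 4, n_restarts=3, seed=1)
        trace = np.array(diag["loss_trace"])
        assert np.all(np.diff(trace) <= 1e-9)

    def test_attains_bruteforce_optimum_on_small_instances(self, rng):
        for _ in range(5):
            n = int(rng.integers(6, 9))
            samples = rng.standard_normal((n, 3))
            samples -= samples.mean(axis=1, keepdims=True)
            bf = brute_force_best_gev(samples)
            _p, seg, _d = modified_kmeans(samples, 2, n_restarts=50,
                                          seed=int(rng.integers(2**31 - 1)))
            assert seg.gev >= bf - 1e-9

    def test_invariance_to_global_sign_flip(self, rng):
        samples = rng.standard_normal((80, 10))
        samples -= samples.mean(axis=1, keepdims=True)
        p1, s1, _ = modified_kmeans(samples, 3, n_restarts=5, seed=4)
        p2, s2, _ = modified_kmeans(-samples, 3, n_restarts=5, seed=4)
        assert s1.gev == pytest.approx(s2.gev, abs=1e-9)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            modified_kmeans(rng.standard_normal((3, 5)), 4)


class TestSmoothing:
    def test_single_intruder_dissolved(self):
        # B is one sample between two A runs; A is that sample's 2nd-best map
        maps = PrototypeSet(maps=np.eye(3), class_labels=["A", "B", "C"])
        a, b = maps.maps[0], maps.maps[1]
        samples = np.array([a, a, a, 0.4 * a + 1.0 * b, a, a, a])
        seg = assign_labels(samples, maps)
        assert seg.labels.tolist() == [0, 0, 0, 1, 0, 0, 0]
        out = smooth_segments(seg, samples, maps, min_duration=3 / 256 * 1000,
                              sampling_rate=256.0)
        assert out.labels.tolist() == [0] * 7

    def test_idempotent_when_no_short_segment(self, rng, orthogonal_prototypes):
        labels = np.repeat(rng.integers(0, 4, 20), 30)
        samples = orthogonal_prototypes.maps[labels]
        seg = assign_labels(samples, orthogonal_prototypes)
        out = smooth_segments(seg, samples, orthogonal_prototypes,
                              min_duration=30.0, sampling_rate=256.0)
        assert np.array_equal(out.labels, seg.labels)

    def test_no_interior_segment_below_threshold_afterwards(self, rng,
                                                            orthogonal_prototypes):
        labels = rng.integers(0, 4, 2000)
        samples = orthogonal_prototypes.maps[labels] + \
            0.1 * rng.standard_normal((2000, 19))
        seg = assign_labels(samples, orthogonal_prototypes)
        out = smooth_segments(seg, samples, orthogonal_prototypes,
                              min_duration=30.0, sampling_rate=256.0)
        min_samples = int(np.ceil(30.0 * 256.0 / 1000.0))
        interior = out.segments[1:-1]
        assert all(length >= min_samples for _c, _s, length in interior)

    def test_overlong_threshold_rejected(self, orthogonal_prototypes):
        samples = orthogonal_prototypes.maps[np.zeros(10, dtype=int)]
        seg = assign_labels(samples, orthogonal_prototypes)
        with pytest.raises(ValueError):
            smooth_segments(seg, samples, orthogonal_prototypes,
                            min_duration=1e5, sampling_rate=256.0)


class TestSegmentStatistics:
    def test_single_class_edge_dominated(self):
        labels = np.zeros(1280, dtype=int)
        seg = Segmentation(labels=labels, activations=np.ones(1280),
                           similarities=np.ones(1280), gev=1.0)
        params = segment_statistics(seg, 128.0, class_labels=["A"], k_classes=1)
        assert params.coverage[0] == pytest.approx(100.0)
        assert params.occurrence[0] == 0.0
        assert np.isnan(params.duration[0])
        assert params.degenerate_classes == ["A"]

    def test_strict_alternation_closed_form(self):
        fs, seconds, run = 128.0, 60, 64
        labels = np.tile(np.repeat([0, 1], run), int(seconds * fs / (2 * run)))
        seg = Segmentation(labels=labels, activations=np.ones(labels.size),
                           similarities=np.ones(labels.size), gev=1.0)
        params = segment_statistics(seg, fs, class_labels=["A", "B"],
                                    k_classes=2)
        assert np.allclose(params.duration, 500.0)
        assert np.allclose(params.occurrence, 1.0, atol=0.02)
        assert np.allclose(params.coverage, 50.0)
        assert params.average_duration == pytest.approx(500.0)

    def test_coverage_identity_with_occurrence_times_duration(
            self, planted_recording, orthogonal_prototypes):
        _spec, truth, rec = planted_recording
        seg = assign_labels(rec.data.T, truth.true_prototypes)
        seg = smooth_segments(seg, rec.data.T, truth.true_prototypes,
                              30.0, rec.sampling_rate)
        params = segment_statistics(seg, rec.sampling_rate)
        product = params.occurrence * params.duration / 10.0
        assert np.all(np.abs(params.coverage - product) < 2.0)


class TestOrderPrototypes:
    def test_templates_map_to_identity(self):
        templates = canonical_templates()
        ordered, score = order_prototypes(templates, templates)
        assert ordered.class_labels == templates.class_labels
        assert np.allclose(ordered.maps, templates.maps)
        assert score == pytest.approx(templates.k_classes)

    def test_shuffled_flipped_templates_recovered(self, rng):
        templates = canonical_templates()
        perm = rng.permutation(4)
        flips = rng.choice([-1.0, 1.0], 4)
        shuffled = PrototypeSet(maps=templates.maps[perm] * flips[:, None])
        ordered, score = order_prototypes(shuffled, templates)
        assert score == pytest.approx(4.0)
        sim = np.abs(ordered.maps @ templates.maps.T)
        assert np.allclose(np.diag(sim), 1.0)

    def test_matches_bruteforce_over_permutations(self, rng):
        templates = canonical_templates()
        raw = rng.standard_normal((4, 19))
        raw -= raw.mean(axis=1, keepdims=True)
        maps = raw / np.linalg.norm(raw, axis=1, keepdims=True)
        protos = PrototypeSet(maps=maps)
        _ordered, score = order_prototypes(protos, templates)
        sim = np.abs(maps @ templates.maps.T)
        best = max(sum(sim[p[j], j] for j in range(4))
                   for p in itertools.permutations(range(4)))
        assert score == pytest.approx(best, abs=1e-12)


def test_segments_round_trip_with_labels(rng):
    labels = rng.integers(0, 4, 500)
    segs = segments_from_labels(labels)
    rebuilt = np.concatenate([[c] * length for c, _s, length in segs])
    assert np.array_equal(rebuilt, labels)
    assert sum(length for _c, _s, length in segs) == labels.size
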