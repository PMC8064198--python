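import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stilquant import types as T
from stilquant.quantize import (
    ChannelGMM,
    QuantizationConfig,
    ThresholdError,
    annotate_segments,
    class_descriptors,
    derive_thresholds,
    dunn_index,
    fit_channel_gmm,
    quantize,
    select_num_classes,
)
from stilquant.types import RGBTile


class TestChannelGMM:
    def test_constant_sample_single_component(self):
        g = fit_channel_gmm(np.full(100, 128.0), n_components=1, variance_floor=1e-2)
        w, m, v = g.components[0]
        assert m == pytest.approx(128.0)
        assert v == pytest.approx(1e-2)
        assert w == pytest.approx(1.0)

    def test_two_mode_parameter_recovery(self, rng):
        sample = np.concatenate(
            [rng.normal(50, 5, 5000), rng.normal(200, 5, 5000)]
        ).round()  # 8-bit-like integer intensities
        g = fit_channel_gmm(sample, n_components=2, seed=0)
        (w1, m1, _), (w2, m2, _) = g.components
        assert m1 == pytest.approx(50, abs=2)
        assert m2 == pytest.approx(200, abs=2)
        assert w1 == pytest.approx(0.5, abs=0.05)
        assert w2 == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_em_loglikelihood_monotone(self, seed):
        rng = np.random.default_rng(seed)
        sample = np.clip(rng.normal(100, 40, 3000), 0, 255).round()
        g = fit_channel_gmm(sample, n_components=3, seed=seed)
        diffs = np.diff(g.loglik_trace)
        assert (diffs >= -1e-7).all()

    def test_components_sorted_by_mean(self, rng):
        sample = np.concatenate([rng.normal(m, 4, 2000) for m in (180, 40, 110)]).round()
        g = fit_channel_gmm(sample, n_components=3)
        means = g.means
        assert (np.diff(means) > 0).all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_channel_gmm(np.arange(15), n_components=2)

    def test_invariant_weights_sum_to_one(self):
        with pytest.raises(ValueError):
            ChannelGMM("R", [(0.6, 10, 1.0), (0.6, 20, 1.0)], 0.0, 1)


def _gmm(means, channel="R"):
    k = len(means)
    return ChannelGMM(channel, [(1.0 / k, float(m), 1.0) for m in means], 0.0, 1)


class TestDeriveThresholds:
    def test_two_cluster_example(self):
        """Means {10,12,200,210} at K=2: the WCSS-optimal partition (checked
        by exhaustive enumeration) gives centers 11 and 205, threshold 108."""
        scheme = derive_thresholds([_gmm([10, 12, 200, 210])], K=2)
        assert scheme.centroids[:, 0] == pytest.approx([11.0, 205.0])
        assert scheme.thresholds["R"] == pytest.approx([108.0])

    def test_matches_exhaustive_partition(self, rng):
        """1-D k-means DP equals brute-force enumeration of all 2-partitions."""
        from itertools import combinations

        means = np.sort(rng.uniform(0, 255, 6))
        scheme = derive_thresholds([_gmm(means)], K=2)
        best = None
        for cut in range(1, 6):
            a, b = means[:cut], means[cut:]
            wcss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            if best is None or wcss < best[0]:
                best = (wcss, a.mean(), b.mean())
        assert scheme.centroids[:, 0] == pytest.approx([best[1], best[2]])

    def test_k_equals_components_each_own_cluster(self):
        scheme = derive_thresholds([_gmm([10, 60, 140, 220])], K=4)
        assert scheme.centroids[:, 0] == pytest.approx([10, 60, 140, 220])
        assert scheme.thresholds["R"] == pytest.approx([35.0, 100.0, 180.0])

    def test_k_exceeding_distinct_means_errors(self):
        with pytest.raises(ThresholdError):
            derive_thresholds([_gmm([50, 50, 50, 50])], K=2)

    def test_deterministic(self):
        gmms = [_gmm([10, 80, 200], c) for c in "RGB"]
        s1 = derive_thresholds(gmms, K=3, seed=1)
        s2 = derive_thresholds(gmms, K=3, seed=1)
        assert (s1.centroids == s2.centroids).all()

    def test_fractions_sum_to_one(self):
        scheme = derive_thresholds([_gmm([10, 80, 200], c) for c in "RGB"], K=3)
        assert scheme.class_fractions.sum() == pytest.approx(1.0)


class TestDunnIndex:
    def test_two_cluster_1d_example(self):
        pts = np.array([0.0, 1.0, 10.0, 11.0])
        labels = np.array([0, 0, 1, 1])
        assert dunn_index(pts, labels) == pytest.approx(9.0)

    def test_singleton_clusters_give_inf(self):
        assert dunn_index(np.array([1.0, 5.0]), np.array([0, 1])) == np.inf

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            dunn_index(np.arange(4.0), np.zeros(4, dtype=int))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        k = int(rng.integers(2, 5))
        pts = rng.normal(size=(n, 3))
        labels = rng.integers(0, k, size=n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        # O(n^2) oracle: enumerate every pair of points
        min_sep, max_diam = np.inf, 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(pts[i] - pts[j])
                if labels[i] == labels[j]:
                    max_diam = max(max_diam, d)
                else:
                    min_sep = min(min_sep, d)
        expected = np.inf if max_diam == 0 else min_sep / max_diam
        assert dunn_index(pts, labels) == pytest.approx(expected)


class TestQuantizeAndAnnotate:
    def test_centroid_pixels_get_their_class(self):
        scheme = derive_thresholds([_gmm([40, 200], c) for c in "RGB"], K=2)
        img = np.full((40, 40, 3), 200, dtype=np.uint8)
        assert (quantize(img, scheme) == 1).all()

    def test_idempotence_on_rendered_centroids(self):
        scheme = derive_thresholds([_gmm([40, 120, 230], c) for c in "RGB"], K=3)
        labels = np.random.default_rng(0).integers(0, 3, size=(32, 32))
        rendered = scheme.centroids[labels].astype(np.uint8)
        assert (quantize(rendered, scheme) == labels).all()

    def test_class_fractions_match_truth_on_synthetic_tile(self, tile_and_truth, scored_tile):
        tile, gt = tile_and_truth
        labels = scored_tile.semantic.labels
        est_nucleus = (labels == T.NUCLEUS).mean()
        true_nucleus = np.isin(gt.semantic, [T.GT_TUMOR_NUCLEUS, T.GT_LYMPH_NUCLEUS]).mean()
        assert est_nucleus == pytest.approx(true_nucleus, abs=0.02)

    def test_dark_blue_class_maps_to_nucleus(self):
        scheme = derive_thresholds([_gmm([60], "R"), _gmm([50], "G"), _gmm([120], "B")], K=1)
        sem = annotate_segments(np.zeros((4, 4), dtype=int), scheme)
        assert sem.provenance[0] == T.NUCLEUS

    def test_near_white_class_maps_to_other(self):
        scheme = derive_thresholds([_gmm([250], "R"), _gmm([250], "G"), _gmm([250], "B")], K=1)
        sem = annotate_segments(np.zeros((4, 4), dtype=int), scheme)
        assert sem.provenance[0] == T.OTHER

    def test_semantic_agreement_with_ground_truth(self, tile_and_truth, scored_tile):
        """Per-pixel semantic agreement >= 95% at the generator's default
        noise level."""
        _, gt = tile_and_truth
        gt2est = {
            T.GT_TUMOR_NUCLEUS: T.NUCLEUS,
            T.GT_LYMPH_NUCLEUS: T.NUCLEUS,
            T.GT_CYTOPLASM: T.CYTOPLASM,
            T.GT_STROMA: T.STROMA,
            T.GT_BACKGROUND: T.OTHER,
        }
        lut = np.zeros(max(gt2est) + 1, dtype=int)
        for k, v in gt2est.items():
            lut[k] = v
        agreement = (lut[gt.semantic] == scored_tile.semantic.labels).mean()
        assert agreement >= 0.95


class TestSelectNumClasses:
    def test_four_prototype_tile_selects_four(self, tile_and_truth):
        tile, _ = tile_and_truth
        K, scheme = select_num_classes(tile, k_range=(2, 6), seed=0)
        assert K == 4
        assert scheme.K == 4

    def test_uniform_tile_exercises_degenerate_path(self):
        tile = RGBTile(np.full((64, 64, 3), 128, dtype=np.uint8))
        with pytest.raises(ThresholdError):
            select_num_classes(tile, seed=0)

    def test_deterministic_given_seed(self, tile_and_truth):
        tile, _ = tile_and_truth
        K1, s1 = select_num_classes(tile, seed=7)
        K2, s2 = select_num_classes(tile, seed=7)
        assert K1 == K2
        assert (s1.centroids == s2.centroids).all()

    def test_k_range_contract(self, tile_and_truth):
        tile, _ = tile_and_truth
        with pytest.raises(ValueError):
            select_num_classes(tile, k_range=(1, 4))
        with pytest.raises(ValueError):
            select_num_classes(tile, subsample_size=10)

    def test_descriptors_cover_all_pixels(self, tile_and_truth, scored_tile):
        tile, _ = tile_and_truth
        K, scheme = select_num_classes(tile, seed=11)
        labels = quantize(tile, scheme)
        _, fracs = class_descriptors(tile, labels, K)
        assert fracs.sum() == pytest.approx(1.0)
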