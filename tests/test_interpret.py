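"""Saliency maps, Score-CAM, class averaging, block attribution."""

import numpy as np
import pytest

from aiopheno.aio import aio_width, snp_position
from aiopheno.interpret import (
    ExplanationMap, saliency_map, score_cam, average_by_class,
    block_attribution_summary, _upsample_nearest,
)
from aiopheno.nn import ArchSpec, Network


def conv_arch(width=12, filters=2, n_classes=3):
    return ArchSpec((6, width, 3), [
        {"type": "conv", "filters": filters, "kernel": [3, 3], "activation": "relu"},
        {"type": "pool", "size": [2, 2]},
        {"type": "flatten"},
        {"type": "dense", "units": n_classes, "activation": "softmax"},
    ])


@pytest.fixture
def image(rng):
    return rng.random((6, 12, 3))


class TestSaliency:
    def test_zero_weight_model_gives_zero_map(self, image):
        net = Network(conv_arch(), seed=0)
        for p in net.params:
            p[:] = 0.0
        emap = saliency_map(net, image, 0)
        np.testing.assert_array_equal(emap.values, 0.0)

    def test_linear_single_pixel_reader(self, image):
        """A dense model reading exactly one pixel channel puts saliency 1
        there and 0 everywhere else."""
        arch = ArchSpec((6, 12, 3), [{"type": "flatten"},
                                     {"type": "dense", "units": 2, "activation": "softmax"}])
        net = Network(arch, seed=0)
        net.params[0][:] = 0.0
        net.params[1][:] = 0.0
        flat_index = np.ravel_multi_index((2, 7, 1), (6, 12, 3))
        net.params[0][flat_index, 0] = 3.0
        emap = saliency_map(net, image, 0)
        assert emap.values[2, 7] == 1.0
        assert emap.values.sum() == 1.0

    def test_matches_finite_difference_gradient(self, image):
        net = Network(conv_arch(), seed=2)
        emap = saliency_map(net, image, 1, channel_reduce="max")
        grad = net.input_gradient(image[None], 1)[0]
        eps = 1e-5
        for idx in [(0, 0, 0), (3, 5, 2), (5, 11, 1)]:
            xp, xm = image.copy(), image.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num = (net.forward(xp[None])[0, 1] - net.forward(xm[None])[0, 1]) / (2 * eps)
            assert abs(num - grad[idx]) < 1e-4

    def test_l2_channel_reduction(self, image):
        net = Network(conv_arch(), seed=3)
        m1 = saliency_map(net, image, 0, channel_reduce="l2")
        assert m1.values.max() == 1.0
        with pytest.raises(ValueError):
            saliency_map(net, image, 0, channel_reduce="sum")


class TestScoreCam:
    def test_single_map_gets_weight_one(self, image):
        net = Network(conv_arch(filters=1), seed=1)
        emap = score_cam(net, image, 0)
        acts = net.conv_activations(image[None])[0][0, :, :, 0]
        up = _upsample_nearest(acts, (6, 12))
        lo, hi = up.min(), up.max()
        expected = (up - lo) / (hi - lo)
        expected = np.maximum(expected, 0)
        expected /= expected.max()
        np.testing.assert_allclose(emap.values, expected, atol=1e-12)

    def test_duplicated_map_splits_weight_but_not_output(self, image):
        net1 = Network(conv_arch(filters=1), seed=4)
        net2 = Network(conv_arch(filters=2), seed=4)
        conv1, conv2 = net1.layers[0], net2.layers[0]
        # duplicate the first filter into both output channels
        W = conv1.W
        conv2.W[:, 0] = W[:, 0]
        conv2.W[:, 1] = W[:, 0]
        conv2.b[:] = conv1.b[0]
        # align the dense layers so class scores match in spirit (values
        # differ, but softmax symmetry makes the two maps equal)
        m1 = score_cam(net1, image, 0)
        m2 = score_cam(net2, image, 0)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)

    def test_matches_brute_force_mask_and_score(self, image):
        """Hand-rolled loop: upsample, normalize, mask, forward, softmax
        weights, combine, ReLU, normalize."""
        net = Network(conv_arch(filters=2), seed=5)
        emap = score_cam(net, image, 1)
        acts = net.conv_activations(image[None])[0][0]
        scores, masks = [], []
        for k in range(2):
            up = _upsample_nearest(acts[:, :, k], (6, 12))
            up = (up - up.min()) / (up.max() - up.min())
            masks.append(up)
            scores.append(net.forward((image * up[:, :, None])[None])[0, 1])
        w = np.exp(scores - np.max(scores))
        w /= w.sum()
        cam = np.maximum(w[0] * masks[0] + w[1] * masks[1], 0)
        cam /= cam.max()
        np.testing.assert_allclose(emap.values, cam, atol=1e-6)

    def test_constant_maps_warn_and_zero(self, image):
        net = Network(conv_arch(filters=2), seed=6)
        conv = net.layers[0]
        conv.W[:] = 0.0
        conv.b[:] = 1.0   # constant positive activations
        with pytest.warns(UserWarning, match="constant"):
            emap = score_cam(net, image, 0)
        np.testing.assert_array_equal(emap.values, 0.0)

    def test_upsample_nearest_blocks(self):
        act = np.array([[1.0, 2.0], [3.0, 4.0]])
        up = _upsample_nearest(act, (4, 4))
        np.testing.assert_array_equal(up, [[1, 1, 2, 2], [1, 1, 2, 2],
                                           [3, 3, 4, 4], [3, 3, 4, 4]])


class TestAveraging:
    def test_single_member_classes_equal_individuals(self, rng):
        maps = [ExplanationMap(rng.random((6, 10)), "saliency", i) for i in range(3)]
        avg = average_by_class(maps, [0, 1, 2])
        for i in range(3):
            np.testing.assert_array_equal(avg[i].values, maps[i].values)
            assert avg[i].accession_id == "class-average"

    def test_identical_maps_average_to_themselves(self, rng):
        base = rng.random((6, 10))
        maps = [ExplanationMap(base, "saliency", 0) for _ in range(4)]
        avg = average_by_class(maps, [0, 0, 0, 0])
        np.testing.assert_allclose(avg[0].values, base)

    def test_matches_elementwise_mean_oracle(self, rng):
        values = rng.random((7, 6, 10))
        labels = np.array([0, 0, 1, 1, 1, 2, 2])
        maps = [ExplanationMap(v, "score_cam", 0) for v in values]
        avg = average_by_class(maps, labels)
        for lab in (0, 1, 2):
            np.testing.assert_allclose(avg[lab].values, values[labels == lab].mean(axis=0))

    def test_shape_mismatch_rejected(self, rng):
        maps = [ExplanationMap(rng.random((6, 10)), "saliency", 0),
                ExplanationMap(rng.random((6, 12)), "saliency", 0)]
        with pytest.raises(ValueError, match="inconsistent"):
            average_by_class(maps, [0, 0])


class TestBlockAttribution:
    def test_genotype_only_map(self):
        K = 12
        values = np.zeros((6, aio_width(K)))
        values[:, :2] = 1.0
        summary = block_attribution_summary(ExplanationMap(values, "saliency", 0), K)
        assert summary["genotype_share"] == 1.0
        assert summary["climate_share"] == 0.0

    def test_uniform_map_splits_by_informative_pixels(self):
        K = 90
        values = np.ones((6, aio_width(K)))
        summary = block_attribution_summary(ExplanationMap(values, "saliency", 0), K)
        assert summary["genotype_share"] == pytest.approx(90 / 240)
        assert summary["climate_share"] == pytest.approx(150 / 240)

    def test_uniform_map_excludes_padding(self):
        K = 17
        values = np.ones((6, aio_width(K)))
        summary = block_attribution_summary(ExplanationMap(values, "saliency", 0), K)
        assert summary["genotype_share"] == pytest.approx(17 / 167)

    def test_top_pixels_annotated(self):
        K = 6
        values = np.zeros((6, aio_width(K)))
        values[2, 0] = 5.0                 # SNP 2
        values[1, 5] = 3.0                 # climate factor row 1, day 5−1−4 = 0
        summary = block_attribution_summary(ExplanationMap(values, "saliency", 0), K, top=2)
        (r1, c1, v1, a1), (r2, c2, v2, a2) = summary["top_pixels"]
        assert a1 == "snp:2" and v1 == 5.0
        assert a2.startswith("temp_min@day") and v2 == 3.0

    def test_width_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            block_attribution_summary(
                ExplanationMap(np.zeros((6, 30)), "saliency", 0), K=90)


class TestClimateIgnoringModel:
    def test_zero_climate_weights_give_zero_climate_share(self, rng):
        """A dense model whose weights on the climate block are zero has no
        saliency mass there."""
        K = 12
        width = aio_width(K)
        arch = ArchSpec((6, width, 3), [{"type": "flatten"},
                                        {"type": "dense", "units": 3, "activation": "softmax"}])
        net = Network(arch, seed=0)
        W = net.params[0].reshape(6, width, 3, 3)
        W[:, width - 25:, :, :] = 0.0      # silence the climate block
        x = rng.random((6, width, 3))
        emap = saliency_map(net, x, 0)
        summary = block_attribution_summary(emap, K)
        assert summary["climate_share"] == 0.0
        assert summary["genotype_share"] == 1.0


def test_planted_snp_pixels_dominate_class_averaged_saliency():
    """Train a small CNN on a task driven by 3 SNPs only; the class-averaged
    saliency's top-5 pixels should hit ≥ 2 planted SNP pixels."""
    from aiopheno.synthetic import SimConfig, generate_genotypes, generate_climate
    from aiopheno.aio import AIOEncoder
    from aiopheno.cnn import AIOClassifier, TrainConfig

    seed = 0
    cfg = SimConfig(n_accessions=360, n_snps=12, n_subpops=1, divergence=0.0,
                    seed=seed, causal_snps=(1, 5, 9), effect_sizes=(1.0, 1.0, 1.0))
    G, _ = generate_genotypes(cfg)
    window = generate_climate(cfg, 0)
    gsum = G.values[:, 1] + G.values[:, 5] + G.values[:, 9]
    y = np.clip((gsum - 1) // 2, 0, 2)
    X = AIOEncoder().fit(G.values).transform(G.values, windows=[window] * G.n_accessions)
    arch = ArchSpec((6, X.shape[2], 3), [
        {"type": "conv", "filters": 12, "kernel": [3, 3], "activation": "relu"},
        {"type": "pool", "size": [2, 2]},
        {"type": "flatten"},
        {"type": "dense", "units": 32, "activation": "relu"},
        {"type": "dense", "units": 3, "activation": "softmax"}])
    clf = AIOClassifier(arch=arch, train_config=TrainConfig(folds=2, epochs=60, seed=seed),
                        cv=False)
    clf.fit(X, y)
    maps = [saliency_map(clf.net_, X[i], int(y[i])) for i in range(200)]
    avg = average_by_class(maps, y[:200])
    planted = {snp_position(k) for k in (1, 5, 9)}
    hits = []
    for emap in avg.values():
        flat = emap.values.ravel()
        top5 = np.argsort(-flat)[:5]
        coords = {divmod(int(t), emap.values.shape[1]) for t in top5}
        hits.append(len(coords & planted))
    assert int(np.median(hits)) >= 2
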