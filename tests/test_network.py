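"""Network architecture arithmetic, loss, sampling, training, inference."""

import numpy as np
import pytest

from carotidseg import metrics, network, phantom
from carotidseg.io_core import ImageVolume, LabelMap
from carotidseg.network import (NetworkConfig, TrainingConfig, build_network,
                                extract_segment, fbeta_loss, predict_volume,
                                receptive_field, sample_training_segments)
from carotidseg.preprocess import znormalize


def micro_config(**overrides):
    defaults = dict(pathway_subsampling=(1, 3), kernel_shapes=((3, 3, 3),),
                    feature_maps=(4,), fc_widths=(6, 6),
                    input_segment_shape=(11, 11, 11))
    defaults.update(overrides)
    return NetworkConfig(**defaults)


class TestReceptiveField:
    def test_two_3cubed_layers(self):
        cfg = micro_config(pathway_subsampling=(1,),
                           kernel_shapes=((3, 3, 3), (3, 3, 3)),
                           feature_maps=(4, 4))
        assert receptive_field(cfg)[1] == (5, 5, 5)

    def test_subsampled_pathway_scales_field(self):
        cfg = micro_config(pathway_subsampling=(1, 3),
                           kernel_shapes=((3, 3, 3), (3, 3, 3)),
                           feature_maps=(4, 4))
        assert receptive_field(cfg)[3] == (15, 15, 15)

    def test_1x1x1_layer_identity(self):
        cfg = micro_config(kernel_shapes=((1, 1, 1),), feature_maps=(4,))
        assert receptive_field(cfg)[1] == (1, 1, 1)

    def test_anisotropic_kernels(self):
        cfg = NetworkConfig.toy()
        rx, ry, rz = receptive_field(cfg)[1]
        assert rz > rx == ry  # kernels elongated along z


class TestBuild:
    def test_three_pathways_required_for_factors(self):
        cfg = NetworkConfig.toy()
        model = build_network(cfg, seed=0)
        assert len(model.pathways) == 3

    def test_output_channels_equal_classes(self):
        model = build_network(micro_config(), seed=0)
        assert model.classifier.W.shape[0] == 4

    def test_forward_probabilities_normalized(self, rng):
        cfg = micro_config()
        model = build_network(cfg, seed=0)
        data = rng.normal(size=(30, 30, 30))
        inputs, phases = extract_segment(data, (3, 4, 5), cfg)
        probs = model.forward([x[None] for x in inputs], phases[None])
        assert probs.shape == (1, 4) + cfg.output_shape()
        assert np.all(np.isfinite(probs))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_shape_incompatible_config_rejected(self):
        with pytest.raises(ValueError, match="input segment too small"):
            micro_config(kernel_shapes=((9, 9, 9),) * 3,
                         feature_maps=(4, 4, 4))

    def test_missing_full_res_pathway_rejected(self):
        with pytest.raises(ValueError, match="full-resolution"):
            micro_config(pathway_subsampling=(3, 5))


class TestFBetaLoss:
    def test_perfect_prediction_zero_loss(self, rng):
        labels = rng.integers(0, 4, (2, 5, 5, 5))
        onehot = network._onehot(labels, 4)
        assert fbeta_loss(onehot, onehot, beta=2.0) == pytest.approx(0.0)

    def test_beta1_hard_masks_equals_one_minus_dice(self, rng):
        pred = rng.integers(0, 2, (1, 6, 6, 6))
        truth = rng.integers(0, 2, (1, 6, 6, 6))
        probs = network._onehot(pred, 2)
        onehot = network._onehot(truth, 2)
        loss = fbeta_loss(probs, onehot, beta=1.0)
        c = metrics.confusion(pred.astype(bool), truth.astype(bool))
        assert 1.0 - loss == pytest.approx(metrics.dice(c), abs=1e-12)

    def test_beta2_prefers_recall(self):
        # fixed counts TP=10, FP=10, FN=0 vs TP=10, FP=0, FN=10 on one class
        base = np.zeros((1, 2, 20, 1, 1))
        truth = base.copy()
        truth[0, 1, :10] = 1
        truth[0, 0] = 1 - truth[0, 1]
        over = base.copy()
        over[0, 1, :20] = 1
        over[0, 0] = 1 - over[0, 1]
        under = base.copy()
        under[0, 1, :5] = 1  # TP=5,FN=5 (same recall/precision trade shape)
        under[0, 0] = 1 - under[0, 1]
        assert fbeta_loss(over, truth, 2.0) < fbeta_loss(under, truth, 2.0)

    def test_loss_bounded(self, rng):
        probs = rng.dirichlet(np.ones(4), size=(2, 4, 4, 4))
        probs = np.moveaxis(probs, -1, 1)
        truth = network._onehot(rng.integers(0, 4, (2, 4, 4, 4)), 4)
        loss = fbeta_loss(probs, truth, 2.0)
        assert 0.0 <= loss <= 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            fbeta_loss(np.zeros((1, 4, 3, 3, 3)), np.zeros((1, 4, 3, 3, 2)))


@pytest.fixture(scope="module")
def small_pair():
    spec = phantom.PhantomSpec(branch_length=15.0, seed=2)
    vol, labels, _ = phantom.generate_phantom(spec)
    return znormalize(vol), labels


class TestSampling:
    def test_foreground_fraction_within_binomial_bound(self, small_pair):
        vol, labels = small_pair
        cfg = micro_config()
        tcfg = TrainingConfig(foreground_fraction=0.5, seed=0)
        inputs, phases, targets = sample_training_segments(
            vol, labels, cfg, tcfg, seed=123, n_segments=1000)
        mid = tuple(o // 2 for o in cfg.output_shape())
        fg_centered = sum(int(t[mid] > 0) for t in targets)
        assert 450 <= fg_centered <= 550

    def test_all_background_rejected(self):
        vol = ImageVolume(np.random.default_rng(0).normal(size=(20, 20, 20)))
        labels = LabelMap(np.zeros((20, 20, 20), np.int16))
        with pytest.raises(ValueError, match="no foreground"):
            sample_training_segments(vol, labels, micro_config(),
                                     TrainingConfig(), seed=0, n_segments=4)

    def test_volume_too_small_reports_minimum(self):
        vol = ImageVolume(np.zeros((4, 4, 4)) + np.arange(4))
        labels = LabelMap(np.ones((4, 4, 4), np.int16))
        with pytest.raises(ValueError, match="minimum extent"):
            sample_training_segments(vol, labels, micro_config(),
                                     TrainingConfig(), seed=0, n_segments=1)

    def test_deterministic_given_seed(self, small_pair):
        vol, labels = small_pair
        cfg = micro_config()
        tcfg = TrainingConfig(seed=0)
        a = sample_training_segments(vol, labels, cfg, tcfg, 5, n_segments=6)
        b = sample_training_segments(vol, labels, cfg, tcfg, 5, n_segments=6)
        for xa, xb in zip(a[0], b[0]):
            np.testing.assert_array_equal(xa, xb)
        np.testing.assert_array_equal(a[2], b[2])


class TestTraining:
    def test_epochs_zero_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(epochs=0)

    def test_identical_seeds_identical_history(self, small_pair):
        tcfg = TrainingConfig(epochs=2, segments_per_volume=8, batch_size=4,
                              seed=3, learning_rate=0.01)
        hists = []
        for _ in range(2):
            model = build_network(micro_config(), seed=3)
            _, hist = network.train(model, [small_pair], tcfg)
            hists.append(hist["train_loss"])
        assert hists[0] == hists[1]
        assert len(hists[0]) == 2


class TestInference:
    def test_tiling_invariance(self, small_pair):
        # same weights run with two different tile sizes must agree exactly
        vol, _ = small_pair
        cfg_small = micro_config()
        model = build_network(cfg_small, seed=1)
        pred_a = predict_volume(model, vol)
        import copy
        model_b = copy.deepcopy(model)
        model_b.config = micro_config(input_segment_shape=(17, 15, 13))
        pred_b = predict_volume(model_b, vol)
        assert np.array_equal(pred_a.labels, pred_b.labels)

    def test_volume_smaller_than_tile_rejected(self):
        vol = ImageVolume(np.zeros((4, 4, 4)) + np.arange(4))
        with pytest.raises(ValueError, match="smaller than minimum tile"):
            predict_volume(build_network(micro_config(), seed=0), vol)

    def test_checkpoint_round_trip(self, tmp_path, small_pair):
        vol, _ = small_pair
        model = build_network(micro_config(), seed=4)
        path = str(tmp_path / "m.npz")
        network.save_checkpoint(model, path)
        back = network.load_checkpoint(path)
        pred_a = predict_volume(model, vol)
        pred_b = predict_volume(back, vol)
        assert np.array_equal(pred_a.labels, pred_b.labels)
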