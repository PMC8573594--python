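import numpy as np
import pytest

from wmhda import model as md
from wmhda import synthgen as sg
from wmhda.nn import Tensor
from wmhda.preproc import PreprocConfig, crop_fov


@pytest.fixture
def tiny_config():
    return md.PlanarUNetConfig(base_channels=4, bottleneck_channels=16)


@pytest.fixture
def tiny_net(tiny_config):
    return md.build_planar_unet(tiny_config, seed=0)


class TestArchitecture:
    def test_depth3_has_two_pooling_stages(self, tiny_net):
        assert len(tiny_net.encoders) == 2  # one pool after each encoder level

    def test_default_channel_ladder_hits_512_bottleneck(self):
        cfg = md.PlanarUNetConfig()
        assert cfg.level_channels() == [128, 256, 512]
        assert cfg.depth == 3

    def test_forward_shape_and_softmax(self, tiny_net, rng=np.random.default_rng(0)):
        x = Tensor(rng.standard_normal((2, 2, 16, 16)).astype(np.float32))
        out = tiny_net(x)
        assert out.shape == (2, 2, 16, 16)
        np.testing.assert_allclose(out.numpy().sum(axis=1), 1.0, atol=1e-5)

    def test_seeded_build_determinism(self, tiny_config):
        a = md.build_planar_unet(tiny_config, seed=3)
        b = md.build_planar_unet(tiny_config, seed=3)
        assert a.num_parameters() == b.num_parameters()
        for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_depth_below_two_rejected(self):
        with pytest.raises(ValueError):
            md.PlanarUNetConfig(depth=1)

    def test_taps_exposed(self, tiny_net):
        x = Tensor(np.random.default_rng(1).standard_normal((1, 2, 16, 16)).astype(np.float32))
        tiny_net(x)
        assert tiny_net.taps["bottleneck"].shape == (1, 16, 4, 4)
        # pre-label-predictor tap: skip-concat feeding the final decoder block
        assert tiny_net.taps["pre_label_predictor"].shape == (1, 8, 16, 16)


def probs_from_lesion_channel(p1):
    """Build an (N,2,H,W) probability tensor from the lesion channel."""
    p1 = np.asarray(p1, dtype=float)
    return Tensor(np.stack([1 - p1, p1], axis=1))


class TestWeightedCrossEntropy:
    def test_perfect_prediction(self):
        labels = np.array([[[0, 1], [1, 0]]])
        probs = probs_from_lesion_channel(labels.astype(float))
        loss = md.weighted_cross_entropy(probs, labels)
        assert loss.item() < 1e-6

    def test_matches_reference_formula(self):
        # hand-computed 2x2 example with uniform weights
        p1 = np.array([[[0.9, 0.2], [0.4, 0.7]]])
        labels = np.array([[[1, 0], [0, 1]]])
        probs = probs_from_lesion_channel(p1)
        expected = -np.mean([np.log(0.9), np.log(0.8), np.log(0.6), np.log(0.7)])
        loss = md.weighted_cross_entropy(probs, labels, np.ones_like(p1))
        assert loss.item() == pytest.approx(expected, rel=1e-10)

    def test_linear_in_weights(self):
        p1 = np.array([[[0.9, 0.2], [0.4, 0.7]]])
        labels = np.array([[[1, 0], [0, 1]]])
        w = np.array([[[1.0, 2.0], [0.5, 1.5]]])
        l1 = md.weighted_cross_entropy(probs_from_lesion_channel(p1), labels, w).item()
        l2 = md.weighted_cross_entropy(probs_from_lesion_channel(p1), labels, 2 * w).item()
        assert l2 == pytest.approx(2 * l1, rel=1e-10)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            md.weighted_cross_entropy(probs_from_lesion_channel(np.zeros((1, 2, 2))),
                                      np.zeros((1, 3, 3), dtype=int))


class TestSoftDice:
    def test_one_hot_near_zero(self):
        labels = np.array([[[1, 0], [0, 1]]])
        loss = md.soft_dice_loss(probs_from_lesion_channel(labels.astype(float)), labels)
        assert loss.item() < 1e-5

    def test_all_zero_prediction(self):
        labels = np.array([[[1, 1], [1, 1]]])
        loss = md.soft_dice_loss(probs_from_lesion_channel(np.zeros((1, 2, 2))), labels)
        assert loss.item() == pytest.approx(1.0, abs=1e-5)

    def test_four_pixel_example(self):
        # p=(1,1,0,0), y=(1,0,0,0) -> 1 - 2/3 = 1/3 as eps -> 0
        p1 = np.array([[[1.0, 1.0], [0.0, 0.0]]])
        labels = np.array([[[1, 0], [0, 0]]])
        loss = md.soft_dice_loss(probs_from_lesion_channel(p1), labels, eps=1e-12)
        assert loss.item() == pytest.approx(1 / 3, abs=1e-9)


class TestCombinedLoss:
    P1 = np.array([[[1.0, 1.0], [0.0, 0.0]]])
    Y = np.array([[[1, 0], [0, 0]]])

    def test_dice_only(self):
        w = md.LossWeights(lambda_ce=0.0, lambda_dice=1.0)
        combined = md.combined_loss(probs_from_lesion_channel(self.P1), self.Y, w)
        dice = md.soft_dice_loss(probs_from_lesion_channel(self.P1), self.Y)
        assert combined.item() == pytest.approx(dice.item())

    def test_ce_only(self):
        p1 = np.array([[[0.9, 0.2], [0.4, 0.7]]])
        w = md.LossWeights(lambda_ce=1.0, lambda_dice=0.0, voxel_weight_mode="uniform")
        combined = md.combined_loss(probs_from_lesion_channel(p1), self.Y, w)
        ce = md.weighted_cross_entropy(probs_from_lesion_channel(p1), self.Y,
                                       np.ones_like(p1))
        assert combined.item() == pytest.approx(ce.item())

    def test_additivity(self):
        p1 = np.array([[[0.9, 0.2], [0.4, 0.7]]])
        probs = probs_from_lesion_channel(p1)
        w = md.LossWeights(voxel_weight_mode="uniform")
        total = md.combined_loss(probs, self.Y, w)
        ce = md.weighted_cross_entropy(probs, self.Y, np.ones_like(p1))
        dice = md.soft_dice_loss(probs, self.Y)
        assert total.item() == pytest.approx(ce.item() + dice.item(), rel=1e-8)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            md.LossWeights(lambda_ce=-1.0)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            md.LossWeights(lambda_ce=0.0, lambda_dice=0.0)


@pytest.fixture
def subject():
    spec = sg.DomainSpec(name="s", volume_shape=(24, 28, 24))
    return sg.generate_subject(spec, seed=0)


@pytest.fixture
def preproc_config():
    return PreprocConfig(resize={"axial": (24, 24), "sagittal": (24, 24),
                                 "coronal": (24, 24)}, crop_margin=2)


def force_constant_output(net, q):
    """Zero the output projection and set its bias to produce softmax prob q."""
    net.outc.weight.data[:] = 0.0
    net.outc.bias.data[:] = np.array([np.log(1 - q), np.log(q)], dtype=np.float32)


class TestPredictVolume:
    def test_constant_q_everywhere_in_crop(self, subject, preproc_config, tiny_config):
        ens = md.build_triplanar_ensemble(tiny_config, seed=0)
        for net in ens.planes().values():
            force_constant_output(net, 0.7)
        vol = md.predict_volume(ens, subject, preproc_config)
        _, box = crop_fov(subject.flair, subject.brain_mask, preproc_config.crop_margin)
        sl = tuple(slice(lo, hi) for lo, hi in box)
        np.testing.assert_allclose(vol[sl], 0.7, atol=1e-5)

    def test_output_in_unit_interval(self, subject, preproc_config, tiny_config):
        ens = md.build_triplanar_ensemble(tiny_config, seed=9)
        vol = md.predict_volume(ens, subject, preproc_config)
        assert vol.shape == subject.flair.shape
        assert vol.min() >= 0.0 and vol.max() <= 1.0

    def test_plane_averaging_permutation_invariant(self, subject, preproc_config, tiny_config):
        ens = md.build_triplanar_ensemble(tiny_config, seed=2)
        a = md.predict_volume(ens, subject, preproc_config,
                              planes=("axial", "sagittal", "coronal"))
        b = md.predict_volume(ens, subject, preproc_config,
                              planes=("coronal", "axial", "sagittal"))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestBinarize:
    def test_above_threshold(self):
        assert md.binarize(np.full((2, 2), 0.6), 0.5).all()

    def test_below_threshold(self):
        assert not md.binarize(np.full((2, 2), 0.4), 0.5).any()

    def test_monotone_in_threshold(self):
        vol = np.random.default_rng(0).random((5, 5, 5))
        low = md.binarize(vol, 0.3)
        high = md.binarize(vol, 0.7)
        assert np.all(high <= low)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            md.binarize(np.ones((2, 2)), 1.5)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, tiny_config):
        ens = md.build_triplanar_ensemble(tiny_config, seed=5)
        path = tmp_path / "ckpt.npz"
        md.save_checkpoint(ens, path, extra={"note": "test"})
        loaded = md.load_checkpoint(path)
        assert loaded.config == tiny_config
        for (na, pa), (nb, pb) in zip(ens.named_parameters(), loaded.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)


class TestOverfitPredictVolume:
    def test_memorised_subject_dice_above_0p9(self):
        """An ensemble overfit to one subject reproduces its own mask."""
        from wmhda import synthgen as sg
        from wmhda import training as tr
        from wmhda.metrics import dice_si
        from wmhda.nn import Adam, Tensor

        spec = sg.DomainSpec(name="o", volume_shape=(24, 28, 24),
                             lesion_radius_range=(2.5, 4.0),
                             lesion_count_range=(3, 5))
        subject = sg.generate_cohort(spec, 1, seed=3)[0]
        pp = PreprocConfig(resize={p: (24, 24) for p in ("axial", "sagittal",
                                                         "coronal")}, crop_margin=1)
        ens = md.build_triplanar_ensemble(
            md.PlanarUNetConfig(base_channels=8, bottleneck_channels=32), seed=0)
        samples = tr.build_plane_dataset([subject], "axial", pp)
        images = np.stack([s[0] for s in samples])
        labels = np.stack([s[1] for s in samples])
        net = ens.net("axial")
        opt = Adam(net.parameters(), lr=5e-3, eps=1e-4)
        for _ in range(250):
            opt.zero_grad()
            loss = md.combined_loss(net(Tensor(images)), labels)
            loss.backward()
            opt.step()
        prob = md.predict_volume(ens, subject, pp, planes=("axial",))
        assert dice_si(md.binarize(prob, 0.5), subject.lesion_mask) > 0.9
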