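import numpy as np
import pytest

from wmhda import adapt_dann as ad
from wmhda import model as md
from wmhda import synthgen as sg
from wmhda import training as tr
from wmhda.metrics import domain_accuracy_probe
from wmhda.nn import Tensor
from wmhda.preproc import PreprocConfig

TINY = md.PlanarUNetConfig(base_channels=4, bottleneck_channels=16)


class TestDomainHead:
    def test_row_stochastic_output(self):
        head = ad.build_domain_head(16, (4, 4), seed=0)
        head.eval()
        x = Tensor(np.random.default_rng(0).standard_normal((5, 16, 4, 4)).astype(np.float32))
        out = head(x)
        assert out.shape == (5, 2)
        np.testing.assert_allclose(out.numpy().sum(axis=1), 1.0, atol=1e-6)

    def test_first_fc_width_1024(self):
        head = ad.build_domain_head(512, (8, 12))
        assert head.fc1.out_features == 1024
        assert head.fc2.out_features == 512
        assert head.fc3.out_features == 32

    def test_projection_channels(self):
        head = ad.build_domain_head(512, (8, 12))
        assert head.proj1.out_channels == 128
        assert head.proj2.out_channels == 64

    def test_dropout_probability(self):
        head = ad.build_domain_head(16, (4, 4))
        assert head.drop1.p == pytest.approx(0.2)
        assert head.drop2.p == pytest.approx(0.2)

    def test_eval_forward_repeatable(self):
        head = ad.build_domain_head(16, (4, 4), seed=1)
        head.eval()
        x = Tensor(np.random.default_rng(1).standard_normal((3, 16, 4, 4)).astype(np.float32))
        np.testing.assert_array_equal(head(x).numpy(), head(x).numpy())

    def test_too_small_tap_rejected(self):
        with pytest.raises(ValueError):
            ad.build_domain_head(16, (1, 1))


class TestSelectSemiSubset:
    def make(self, n):
        spec = sg.DomainSpec(name="t", volume_shape=(16, 18, 16),
                             lesion_count_range=(0, 1), lesion_radius_range=(1.5, 2.0))
        subs = []
        for i in range(n):
            s = sg.generate_subject(spec, seed=i)
            s.subject_id = f"t_{i:03d}"
            subs.append(s)
        return subs

    def test_quarter_of_16_is_4(self):
        assert len(ad.select_semi_subset(self.make(16), 0.25, seed=0)) == 4

    def test_zero_fraction_empty(self):
        assert ad.select_semi_subset(self.make(4), 0.0) == []

    def test_seeded(self):
        subs = self.make(8)
        a = [s.subject_id for s in ad.select_semi_subset(subs, 0.5, seed=3)]
        b = [s.subject_id for s in ad.select_semi_subset(subs, 0.5, seed=3)]
        assert a == b

    def test_without_replacement(self):
        subs = self.make(8)
        chosen = ad.select_semi_subset(subs, 1.0, seed=0)
        assert len({s.subject_id for s in chosen}) == 8


@pytest.fixture(scope="module")
def shifted_cohorts():
    base = sg.DomainSpec(name="d", volume_shape=(20, 24, 20),
                         lesion_radius_range=(1.5, 3.0))
    src_spec, tgt_spec = sg.make_domain_pair(
        base, sg.DomainShift(lesion_contrast_scale=0.45, noise_delta=6.0,
                             bias_delta=0.1))
    return (sg.generate_cohort(src_spec, n=4, seed=0),
            sg.generate_cohort(tgt_spec, n=4, seed=1))


@pytest.fixture
def tiny_preproc():
    return PreprocConfig(resize={"axial": (16, 16), "sagittal": (16, 16),
                                 "coronal": (16, 16)}, crop_margin=1)


FAST = tr.TrainConfig(pretrain_epochs=0, patience=2, max_epochs=2,
                      val_fraction=0.25, seed=0)


class Poison:
    """Stand-in that fails the test if the target lesion mask is ever read."""

    def __getattr__(self, name):
        raise AssertionError("unsupervised DANN read a target lesion mask")

    def __getitem__(self, key):
        raise AssertionError("unsupervised DANN read a target lesion mask")


class TestTrainDann:
    def test_unsupervised_never_reads_target_masks(self, shifted_cohorts, tiny_preproc):
        src, tgt = shifted_cohorts
        tgt = [sg.Subject(s.flair.copy(), s.t1.copy(), s.lesion_mask.copy(),
                          s.brain_mask.copy(), s.domain, s.subject_id) for s in tgt]
        for s in tgt:
            s.lesion_mask = Poison()
        ens = md.build_triplanar_ensemble(TINY, seed=0)
        _, heads, log = ad.train_dann(ens, src, tgt, ad.DannConfig(semi_fraction=0.0),
                                      FAST, preproc=tiny_preproc, planes=("axial",))
        assert "axial" in heads
        assert {"seg_loss", "domain_loss", "domain_accuracy"} <= set(log.columns)

    def test_semi_fraction_selects_subjects(self, shifted_cohorts, tiny_preproc):
        src, tgt = shifted_cohorts
        ens = md.build_triplanar_ensemble(TINY, seed=1)
        _, _, log = ad.train_dann(ens, src, tgt, ad.DannConfig(semi_fraction=0.5),
                                  FAST, preproc=tiny_preproc, planes=("axial",))
        assert not log.empty

    def test_head_learns_when_grl_zero(self, tiny_preproc):
        # head sanity: clearly separable domains, no adversarial pressure
        base = sg.DomainSpec(name="d", volume_shape=(20, 24, 20),
                             lesion_radius_range=(1.5, 3.0))
        s_spec, t_spec = sg.make_domain_pair(
            base, sg.DomainShift(lesion_contrast_scale=0.4, noise_delta=14.0,
                                 anisotropy_delta=(0, 0, 1.5)))
        src = sg.generate_cohort(s_spec, n=4, seed=0)
        tgt = sg.generate_cohort(t_spec, n=4, seed=1)
        ens = md.build_triplanar_ensemble(TINY, seed=2)
        cfg = tr.TrainConfig(pretrain_epochs=0, patience=99, max_epochs=8,
                             val_fraction=0.25, seed=0)
        _, _, log = ad.train_dann(
            ens, src, tgt,
            ad.DannConfig(grl_lambda=0.0, domain_lr=1e-2, dropout=0.0),
            cfg, preproc=tiny_preproc, planes=("axial",))
        assert log["domain_accuracy"].tail(3).max() > 0.9

    def test_empty_cohort_rejected(self, shifted_cohorts):
        src, _ = shifted_cohorts
        ens = md.build_triplanar_ensemble(TINY, seed=0)
        with pytest.raises(ValueError):
            ad.train_dann(ens, src, [])


class TestExtractFeatures:
    def test_feature_rows_match_slices(self, shifted_cohorts, tiny_preproc):
        src, tgt = shifted_cohorts
        ens = md.build_triplanar_ensemble(TINY, seed=0)
        feats, labels = ad.extract_features(ens, src[:1] + tgt[:1],
                                            tap="bottleneck",
                                            preproc=tiny_preproc)
        n_slices = len(tr.build_plane_dataset(src[:1] + tgt[:1], "axial",
                                              tiny_preproc, with_labels=False))
        assert feats.shape[0] == n_slices == len(labels)
        assert feats.shape[1] == 16  # bottleneck channels

    def test_pre_label_predictor_tap(self, shifted_cohorts, tiny_preproc):
        src, _ = shifted_cohorts
        ens = md.build_triplanar_ensemble(TINY, seed=0)
        feats, _ = ad.extract_features(ens, src[:1], tap="pre_label_predictor",
                                       preproc=tiny_preproc)
        assert feats.shape[1] == 8  # skip-concat: 2 x base_channels

    def test_deterministic(self, shifted_cohorts, tiny_preproc):
        src, tgt = shifted_cohorts
        ens = md.build_triplanar_ensemble(TINY, seed=3)
        a, _ = ad.extract_features(ens, src[:1] + tgt[:1], preproc=tiny_preproc)
        b, _ = ad.extract_features(ens, src[:1] + tgt[:1], preproc=tiny_preproc)
        np.testing.assert_array_equal(a, b)

    def test_unknown_tap(self, shifted_cohorts):
        ens = md.build_triplanar_ensemble(TINY, seed=0)
        with pytest.raises(ValueError):
            ad.extract_features(ens, shifted_cohorts[0][:1], tap="nope")

    def test_unadapted_features_separate_shifted_domains(self, shifted_cohorts,
                                                         tiny_preproc):
        src, tgt = shifted_cohorts
        ens = md.build_triplanar_ensemble(TINY, seed=0)
        tr.train_model(ens, src, FAST, augment=None, preproc=tiny_preproc,
                       planes=("axial",))
        feats, labels = ad.extract_features(ens, src + tgt, preproc=tiny_preproc)
        acc = domain_accuracy_probe(feats, labels, seed=0)
        n_test = len(labels) // 2
        assert acc > 0.5 + 3 * 0.5 / np.sqrt(n_test)


class TestConfigValidation:
    def test_bad_semi_fraction(self):
        with pytest.raises(ValueError):
            ad.DannConfig(semi_fraction=1.5)

    def test_bad_dropout(self):
        with pytest.raises(ValueError):
            ad.DannConfig(dropout=1.0)

    def test_negative_lambda(self):
        with pytest.raises(ValueError):
            ad.DannConfig(grl_lambda=-0.1)
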