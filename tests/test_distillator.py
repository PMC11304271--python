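"""Distillator: loss algebra, confusion loss, classifier training, freezing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytomad.backbone import BackboneConfig, TrainConfig, build_backbone, pretrain_backbone
from cytomad.distillator import (
    ClassifierTrainConfig,
    LossWeights,
    assemble_loss,
    batch_confusion_loss,
    classifier_hashes,
    pretrain_classifiers,
    train_cytomad,
)


class TestConfusionLoss:
    def test_uniform_two_batches_gives_ln2(self):
        assert batch_confusion_loss([[0.5, 0.5]]) == pytest.approx(np.log(2), abs=1e-9)

    def test_onehot_with_clamp_closed_form(self):
        # -(1/4) * (ln 1 + 3 ln 1e-12)
        expected = -(3 * np.log(1e-12)) / 4
        assert batch_confusion_loss([[1.0, 0.0, 0.0, 0.0]]) == pytest.approx(
            expected, rel=1e-9
        )
        assert expected == pytest.approx(20.72, abs=0.01)

    @given(
        st.lists(
            st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
            min_size=1, max_size=8,
        )
    )
    def test_jensen_lower_bound(self, raw):
        p = np.asarray(raw)
        p = p / p.sum(axis=1, keepdims=True)
        assert batch_confusion_loss(p) >= np.log(3) - 1e-9

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            batch_confusion_loss([[0.9, 0.3]])


class TestAssembleLoss:
    def test_all_weights_one_hand_value(self):
        w = LossWeights(1, 1, 1, 1, 1, 1)
        bundle = assemble_loss(
            dict(L_gen=0.2, L_dis=0.7, L_Bcnn=0.69, L_Ccnn=0.4, L_Bnn=0.69, L_Cnn=0.5),
            w,
        )
        assert bundle.L_total == pytest.approx(3.18, abs=1e-12)
        assert bundle.L_GAN == pytest.approx(0.9)
        assert bundle.L_cnn == pytest.approx(1.09)
        assert bundle.L_nn == pytest.approx(1.19)

    def test_zero_weights_zero_total(self):
        bundle = assemble_loss(
            dict(L_gen=1, L_dis=1, L_Bcnn=1, L_Ccnn=1, L_Bnn=1, L_Cnn=1),
            LossWeights(0, 0, 0, 0, 0, 0),
        )
        assert bundle.L_total == 0.0

    def test_generator_only_weighting(self):
        bundle = assemble_loss(
            dict(L_gen=0.01, L_dis=0, L_Bcnn=0, L_Ccnn=0, L_Bnn=0, L_Cnn=0),
            LossWeights(100, 0, 0, 0, 0, 0),
        )
        assert bundle.L_total == pytest.approx(1.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(W_gen=-1)

    @given(
        st.lists(st.floats(0, 2), min_size=6, max_size=6),
        st.lists(st.floats(0, 10), min_size=6, max_size=6),
    )
    def test_decomposition_identity(self, comps, ws):
        names = ("L_gen", "L_dis", "L_Bcnn", "L_Ccnn", "L_Bnn", "L_Cnn")
        bundle = assemble_loss(dict(zip(names, comps)), LossWeights(*ws))
        total = sum(w * c for w, c in zip(ws, comps))
        assert bundle.L_total == pytest.approx(
            bundle.L_GAN + bundle.L_cnn + bundle.L_nn, rel=1e-6
        )
        assert bundle.L_total == pytest.approx(total, rel=1e-6, abs=1e-9)


class TestPretrainClassifiers:
    def _separable(self, n=120, d=16, k=3, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.arange(n) % k
        x = rng.normal(0, 0.3, size=(n, d)).astype(np.float32)
        x[np.arange(n), labels] += 3.0  # type encoded in first k coordinates
        return x, labels

    def test_separable_profiles_reach_high_accuracy(self):
        x, labels = self._separable()
        images = np.zeros((len(x), 32, 32), dtype=np.float32)
        images[labels == 1, 8:24, 8:24] = 0.5
        images[labels == 2, 4:12, 4:12] = 0.9
        batches = np.array(["b0", "b1"])[np.arange(len(x)) % 2]
        cs = pretrain_classifiers(
            x, images, batches, [f"t{i}" for i in labels],
            ClassifierTrainConfig(epochs=40, seed=0),
        )
        acc = cs.type_accuracy_on_profiles(x, [f"t{i}" for i in labels])
        assert acc > 0.95

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(150, 16)).astype(np.float32)
        labels = [f"t{i}" for i in rng.integers(0, 3, size=150)]
        images = rng.random((150, 32, 32), dtype=np.float32)
        batches = np.array(["b0", "b1"])[np.arange(150) % 2]
        cs = pretrain_classifiers(
            x, images, batches, labels, ClassifierTrainConfig(epochs=15, seed=0)
        )
        # fresh random profiles: accuracy near 1/K
        x_new = rng.normal(size=(150, 16)).astype(np.float32)
        labels_new = [f"t{i}" for i in rng.integers(0, 3, size=150)]
        acc = cs.type_accuracy_on_profiles(x_new, labels_new)
        assert abs(acc - 1 / 3) < 0.1

    def test_probability_vectors_sum_to_one(self):
        x, labels = self._separable(n=40)
        images = np.random.default_rng(0).random((40, 32, 32), dtype=np.float32)
        batches = np.array(["b0", "b1"])[np.arange(40) % 2]
        cs = pretrain_classifiers(
            x, images, batches, [f"t{i}" for i in labels],
            ClassifierTrainConfig(epochs=2, seed=0),
        )
        p = cs.bottleneck_type.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        p_img = cs.image_batch.predict_proba(images)
        np.testing.assert_allclose(p_img.sum(axis=1), 1.0, atol=1e-6)

    def test_single_class_labels_rejected(self):
        x = np.zeros((10, 16), dtype=np.float32)
        images = np.zeros((10, 32, 32), dtype=np.float32)
        with pytest.raises(ValueError):
            pretrain_classifiers(x, images, ["b0"] * 10, ["t0", "t1"] * 5)
        with pytest.raises(ValueError):
            pretrain_classifiers(x, images, ["b0", "b1"] * 5, ["t0"] * 10)

    def test_mini_segments_partition_the_profile(self):
        x, labels = self._separable(n=30)
        images = np.zeros((30, 32, 32), dtype=np.float32)
        batches = np.array(["b0", "b1"])[np.arange(30) % 2]
        cs = pretrain_classifiers(
            x, images, batches, [f"t{i}" for i in labels],
            ClassifierTrainConfig(epochs=1, n_minis=4, seed=0),
        )
        covered = []
        for a, b in cs.segments:
            covered.extend(range(a, b))
        assert covered == list(range(16))

    def test_balance_downsamples_majority_class(self):
        from cytomad.distillator import _balance_downsample

        labels = np.array(["maj"] * 80 + ["min"] * 20)
        idx = _balance_downsample(labels, np.random.default_rng(0))
        kept = labels[idx]
        assert (kept == "maj").sum() == (kept == "min").sum() == 20


@pytest.fixture(scope="module")
def pretrained(tiny_dataset):
    cfg = BackboneConfig(image_size_px=32, bottleneck_dim=16, n_levels=3, base_filters=4)
    model = build_backbone(cfg, seed=0)
    model, _ = pretrain_backbone(model, tiny_dataset, TrainConfig(epochs=2, seed=0))
    profiles, images = model.infer(tiny_dataset.bf)
    cs = pretrain_classifiers(
        profiles, images,
        tiny_dataset.meta.batch_id.to_numpy(),
        tiny_dataset.meta.cell_type.to_numpy(),
        ClassifierTrainConfig(epochs=3, seed=1),
    )
    return model, cs


class TestTrainCytomad:
    def test_classifiers_frozen_between_scheduled_retrains(self, pretrained, tiny_dataset):
        model, cs = pretrained
        seen = []
        model, hist = train_cytomad(
            model, cs, tiny_dataset, TrainConfig(epochs=2, seed=2),
            retrain_interval_epochs=10, freeze_callback=seen.append,
        )
        assert len(seen) > 2
        assert all(h == seen[0] for h in seen[1:])
        assert model.stage == "cytomad"

    def test_retraining_updates_batch_but_not_type_classifiers(self, pretrained, tiny_dataset):
        model, cs = pretrained
        before = classifier_hashes(cs)
        model, _ = train_cytomad(
            model, cs, tiny_dataset, TrainConfig(epochs=3, seed=3),
            retrain_interval_epochs=2,
        )
        after = classifier_hashes(cs)
        assert after["bottleneck_type"] == before["bottleneck_type"]
        assert after["image_type"] == before["image_type"]
        assert after["mini0"] != before["mini0"]
        assert after["image_batch"] != before["image_batch"]

    def test_history_logs_consistent_loss_decomposition(self, pretrained, tiny_dataset):
        model, cs = pretrained
        w = LossWeights()
        _, hist = train_cytomad(
            model, cs, tiny_dataset, TrainConfig(epochs=2, seed=4), w,
            retrain_interval_epochs=10,
        )
        for _, row in hist.iterrows():
            lgan = w.W_gen * row.L_gen + w.W_dis * row.L_dis
            lcnn = w.W_Bcnn * row.L_Bcnn + w.W_Ccnn * row.L_Ccnn
            lnn = w.W_Bnn * row.L_Bnn + w.W_Cnn * row.L_Cnn
            assert row.L_GAN == pytest.approx(lgan, rel=1e-6)
            assert row.L_total == pytest.approx(lgan + lcnn + lnn, rel=1e-6)

    def test_dimension_mismatch_rejected(self, pretrained, tiny_dataset):
        model, _ = pretrained
        bad = pretrain_classifiers(
            np.random.default_rng(0).normal(size=(20, 24)).astype(np.float32),
            np.zeros((20, 32, 32), dtype=np.float32),
            ["b0", "b1"] * 10, ["t0", "t1"] * 10,
            ClassifierTrainConfig(epochs=1),
        )
        with pytest.raises(ValueError, match="mismatch"):
            train_cytomad(model, bad, tiny_dataset, TrainConfig(epochs=1))
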