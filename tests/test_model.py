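import numpy as np
import pytest

from actimage.cli import build_images
from actimage.imaging import ActivityImage
from actimage.imu_io import ClassSet
from actimage.model import (
    BackboneUnavailableError,
    TrainConfig,
    load_classifier,
    predict,
    save_classifier,
    split_dataset,
    train,
)


def _balanced_images(n_per_class, labels=("walking", "ascent", "descent", "standing"), side=32):
    rng = np.random.default_rng(0)
    return [
        ActivityImage(rng.integers(0, 256, (side, side)).astype(np.uint8), label)
        for label in labels
        for _ in range(n_per_class)
    ]


class TestTrainConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"epochs": 0},
            {"train_fraction": 1.0},
            {"train_fraction": 0.0},
            {"learning_rate": 0.0},
            {"batch_size": 0},
        ],
    )
    def test_invalid_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)


class TestSplitDataset:
    def test_balanced_hundred_images_split_80_20(self):
        images = _balanced_images(25)
        train_set, test_set = split_dataset(images, TrainConfig(seed=0))
        assert len(train_set) == 80 and len(test_set) == 20
        for label in ("walking", "ascent", "descent", "standing"):
            assert sum(im.label == label for im in train_set) == 20
            assert sum(im.label == label for im in test_set) == 5

    def test_same_seed_gives_identical_split(self, hs_clean_images):
        a = split_dataset(hs_clean_images, TrainConfig(seed=3))
        b = split_dataset(hs_clean_images, TrainConfig(seed=3))
        assert [id(x) for x in a[0]] == [id(x) for x in b[0]]
        assert [id(x) for x in a[1]] == [id(x) for x in b[1]]

    def test_199_image_cohort_splits_159_40(self, hs_clean_images):
        # per-class floor of the train fraction: 40+40+39+40 train
        train_set, test_set = split_dataset(hs_clean_images, TrainConfig(seed=0))
        assert len(train_set) == 159 and len(test_set) == 40

    def test_split_is_disjoint_and_exhaustive(self, hs_clean_images):
        train_set, test_set = split_dataset(hs_clean_images, TrainConfig(seed=1))
        ids = {id(x) for x in train_set} | {id(x) for x in test_set}
        assert len(ids) == len(hs_clean_images)

    def test_class_with_single_image_is_a_stratification_error(self):
        images = _balanced_images(3) + [
            ActivityImage(np.zeros((32, 32), dtype=np.uint8), "jogging")
        ]
        with pytest.raises(ValueError, match="jogging"):
            split_dataset(images, TrainConfig())


class TestTrain:
    def test_single_class_input_is_degenerate(self):
        images = _balanced_images(4, labels=("walking",))
        with pytest.raises(ValueError, match="single class"):
            train(images, TrainConfig())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig())

    def test_pretrained_backbones_raise_unavailable(self):
        images = _balanced_images(4)
        with pytest.raises(BackboneUnavailableError, match="resnet50"):
            train(images, TrainConfig(backbone="resnet50"))

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            train(_balanced_images(4), TrainConfig(backbone="lenet"))

    def test_num_classes_mismatch_rejected(self):
        with pytest.raises(ValueError, match="num_classes"):
            train(_balanced_images(4), TrainConfig(num_classes=6))

    def test_training_log_has_one_entry_per_epoch(self, hs_clean_images):
        clf = train(hs_clean_images[::3], TrainConfig(epochs=3, input_side=224))
        assert len(clf.training_log) == 3

    def test_loss_decreases_on_separable_data(self, hs_clean_images):
        clf = train(hs_clean_images, TrainConfig(epochs=5))
        assert clf.training_log[-1] < clf.training_log[0]

    def test_fit_to_convergence_recovers_training_labels(self, hs_clean_images):
        subset = hs_clean_images[::4]
        clf = train(subset, TrainConfig(epochs=60, seed=0))
        assert predict(clf, subset) == [im.label for im in subset]


class TestPredict:
    def test_empty_list_gives_empty_list(self, hs_clean_images):
        clf = train(hs_clean_images[::5], TrainConfig(epochs=1))
        assert predict(clf, []) == []

    def test_permuted_input_gives_permuted_output(self, hs_clean_images):
        clf = train(hs_clean_images, TrainConfig(epochs=2))
        sample = hs_clean_images[:10]
        forward = predict(clf, sample)
        backward = predict(clf, sample[::-1])
        assert forward == backward[::-1]

    def test_wrong_image_size_is_a_contract_error(self, hs_clean_images):
        clf = train(hs_clean_images[::5], TrainConfig(epochs=1))
        bad = ActivityImage(np.zeros((64, 64), dtype=np.uint8), "walking")
        with pytest.raises(ValueError, match="expects"):
            predict(clf, [bad])

    def test_identical_seed_and_data_reproduce_predictions(self, ss_noisy_images):
        cfg = TrainConfig(seed=5)
        tr, te = split_dataset(ss_noisy_images, cfg)
        preds_a = predict(train(tr, cfg), te)
        preds_b = predict(train(tr, cfg), te)
        assert preds_a == preds_b


class TestPersistence:
    def test_checkpoint_round_trip_preserves_predictions(self, hs_clean_images, tmp_path):
        cfg = TrainConfig(epochs=2, seed=1)
        tr, te = split_dataset(hs_clean_images, cfg)
        clf = train(tr, cfg)
        path = tmp_path / "clf.npz"
        save_classifier(clf, path)
        back = load_classifier(path)
        assert back.classes.names == clf.classes.names
        assert predict(back, te) == predict(clf, te)


class TestEndToEndAccuracy:
    def test_noise_free_cohort_reaches_perfect_heldout_accuracy(self, hs_clean_images):
        """A separable, noise-free 4-class cohort is classified
        perfectly by tinycnn under the default training protocol."""
        cfg = TrainConfig(seed=0)
        tr, te = split_dataset(hs_clean_images, cfg)
        classes = ClassSet(tuple(sorted({im.label for im in hs_clean_images})))
        clf = train(tr, cfg, classes)
        preds = predict(clf, te)
        assert preds == [im.label for im in te]
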