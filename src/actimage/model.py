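"""Image classifiers for activity images.

The tested desk-scale backbone, ``tinycnn``, is a small convolutional
network implemented directly on numpy and designed around the structure
of activity images: rows are sensor-channel bands, the horizontal axis
is time, and class identity lives mainly in the temporal frequency
content of each band while the gait phase of a window is arbitrary.
The network is

1. block-mean downsampling of the 224 x 224 grayscale input to 28 x 28;
2. a fixed bank of 8 one-dimensional Gabor-style filters (cosine and
   sine phases at four stripe periods, Hann-windowed, zero-mean)
   convolved along the time axis of every row, followed by ReLU;
3. global average pooling over time, which removes the arbitrary gait
   phase and yields one feature per (row, filter) pair;
4. a whitening layer — regularized ZCA computed on the training
   features and then frozen — that isotropizes the feature geometry so
   the short training schedule converges along fine discriminative
   directions, not only the dominant ones;
5. a dense softmax head with one output per activity class.

Mirroring the fine-tuning paradigm at desk scale, the filter bank acts
as a fixed feature extractor and only the classification head is
trained, by mini-batch SGD with momentum on the cross-entropy loss.
Head initialization and batch order are seeded, so a fit is
bit-reproducible on one device.

The large pretrained backbones used for fine-tuning at scale
(resnet18/resnet50/mobilenet_v2/googlenet) are registered names whose
weights are external artifacts; requesting one raises
:class:`BackboneUnavailableError` stating the expected input contract
(224 x 224, grayscale replicated to 3 channels, replaced K-way head).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .imaging import ActivityImage
from .imu_io import ClassSet

__all__ = [
    "BackboneUnavailableError",
    "FittedClassifier",
    "TrainConfig",
    "load_classifier",
    "predict",
    "save_classifier",
    "split_dataset",
    "train",
]

PRETRAINED_BACKBONES = ("resnet18", "resnet50", "mobilenet_v2", "googlenet")

_POOLED_SIDE = 28  # input side after block-mean downsampling
_KERNEL_W = 7  # 1-D kernel width along the time axis
_GABOR_PERIODS = (4.0, 6.0, 8.0, 12.0)  # stripe periods (pixels at 28-px scale)
_WHITEN_EPS = 0.01  # shrinkage toward the mean eigenvalue


class BackboneUnavailableError(RuntimeError):
    """Requested a pretrained backbone whose weights are not bundled."""


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults: 5 epochs, learning rate 0.001, batch size 32, 80/20
    stratified split, SGD momentum 0.9.
    """

    epochs: int = 5
    learning_rate: float = 0.001
    batch_size: int = 32
    train_fraction: float = 0.8
    seed: int = 0
    backbone: str = "tinycnn"
    num_classes: int | None = None
    momentum: float = 0.9
    input_side: int = 224

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class FittedClassifier:
    """A trained backbone plus its class set and training log."""

    backbone: str
    classes: ClassSet
    params: dict[str, np.ndarray]
    training_log: list[float]  # mean cross-entropy per epoch
    config: TrainConfig


def split_dataset(
    images: Sequence[ActivityImage], cfg: TrainConfig
) -> tuple[list[ActivityImage], list[ActivityImage]]:
    """Stratified, seeded train/test split.

    Per class, ``floor(train_fraction * n)`` images go to training and
    the remainder to test; the within-class assignment is a seeded
    permutation, so the same seed always yields the same split.
    """
    by_class: dict[str, list[int]] = {}
    for i, img in enumerate(images):
        by_class.setdefault(img.label, []).append(i)
    if len(by_class) < 2:
        raise ValueError("need at least 2 classes to split")
    for label, idx in by_class.items():
        if len(idx) < 2:
            raise ValueError(f"class {label!r} has {len(idx)} image(s); need >= 2 to stratify")
    rng = np.random.default_rng(cfg.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_class):
        idx = np.array(by_class[label])
        perm = rng.permutation(len(idx))
        n_train = int(np.floor(cfg.train_fraction * len(idx)))
        train_idx.extend(idx[perm[:n_train]].tolist())
        test_idx.extend(idx[perm[n_train:]].tolist())
    return [images[i] for i in sorted(train_idx)], [images[i] for i in sorted(test_idx)]


def gabor_filter_bank(
    width: int = _KERNEL_W, periods: Sequence[float] = _GABOR_PERIODS
) -> np.ndarray:
    """Fixed 1-D filter bank: cosine- and sine-phase Gabor-style
    filters at the given periods, Hann-windowed, zero-mean, unit-norm.

    Stripe period in an activity image is the step-cycle period, so a
    small set of band-pass filters spanning the plausible periods is a
    complete-enough descriptor of the temporal structure.
    """
    t = np.arange(width) - (width - 1) / 2.0
    window = np.hanning(width + 2)[1:-1]
    rows = []
    for lam in periods:
        for phase_fn in (np.cos, np.sin):
            f = phase_fn(2.0 * np.pi * t / lam) * window
            f -= f.mean()
            f /= np.linalg.norm(f)
            rows.append(f)
    return np.array(rows)


def _to_inputs(images: Sequence[ActivityImage], side: int) -> np.ndarray:
    """Stack images into an (N, 28, 28) array in [0, 1] by block-mean
    pooling (nearest-neighbour subsampling for non-multiple sides)."""
    x = np.empty((len(images), _POOLED_SIDE, _POOLED_SIDE), dtype=np.float64)
    factor, rem = divmod(side, _POOLED_SIDE)
    for n, img in enumerate(images):
        if img.pixels.shape != (side, side):
            raise ValueError(
                f"image {n} has shape {img.pixels.shape}, backbone expects ({side}, {side})"
            )
        px = img.pixels.astype(np.float64) / 255.0
        if rem == 0:
            x[n] = px.reshape(_POOLED_SIDE, factor, _POOLED_SIDE, factor).mean(axis=(1, 3))
        else:
            idx = np.linspace(0, side - 1, _POOLED_SIDE).round().astype(int)
            x[n] = px[np.ix_(idx, idx)]
    return x


def _conv_features(x: np.ndarray, conv_w: np.ndarray) -> np.ndarray:
    """conv along time -> ReLU -> global time pooling: (N, rows*filters)."""
    patches = sliding_window_view(x, conv_w.shape[1], axis=2)  # (N, 28, 22, k)
    act = np.maximum(patches @ conv_w.T, 0.0)
    return act.mean(axis=2).reshape(x.shape[0], -1)


def _forward(x: np.ndarray, p: dict[str, np.ndarray]):
    feat = _conv_features(x, p["conv_w"])
    z = (feat - p["feat_mu"]) @ p["whiten"]
    logits = z @ p["fc_w"] + p["fc_b"]
    return logits, z


def _softmax(logits: np.ndarray) -> np.ndarray:
    s = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def _fit_whitening(feat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Regularized ZCA: (Sigma + eps*I)^(-1/2) with eps a fraction of
    the mean eigenvalue, so near-null directions are tamed while the
    informative ones are equalized."""
    mu = feat.mean(axis=0)
    cov = np.cov(feat - mu, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    eps = _WHITEN_EPS * float(evals.mean()) if evals.mean() > 0 else 1.0
    scale = 1.0 / np.sqrt(np.maximum(evals, 0.0) + eps)
    return mu, (evecs * scale) @ evecs.T


def train(
    images: Sequence[ActivityImage],
    cfg: TrainConfig,
    classes: ClassSet | None = None,
) -> FittedClassifier:
    """Fit a classifier by mini-batch SGD on the cross-entropy loss.

    The filter bank is fixed; the whitening layer is computed from the
    training features and frozen; only the softmax head trains.  Head
    initialization and batch order derive from ``cfg.seed``, so
    identical seed + data reproduce the fit exactly.
    """
    if cfg.backbone in PRETRAINED_BACKBONES:
        raise BackboneUnavailableError(
            f"backbone {cfg.backbone!r} needs externally distributed pretrained weights; "
            "it expects 224 x 224 inputs (grayscale replicated to 3 channels) and a "
            "replaced K-way classification head. Use backbone='tinycnn' for a "
            "self-contained fit."
        )
    if cfg.backbone != "tinycnn":
        raise ValueError(f"unknown backbone {cfg.backbone!r}")
    if len(images) == 0:
        raise ValueError("cannot train on an empty image list")
    labels = [img.label for img in images]
    if len(set(labels)) < 2:
        raise ValueError("training data contains a single class; nothing to learn")
    if classes is None:
        classes = ClassSet(tuple(sorted(set(labels))))
    if cfg.num_classes is not None and cfg.num_classes != len(classes):
        raise ValueError(
            f"cfg.num_classes={cfg.num_classes} but the class set has {len(classes)}"
        )
    x = _to_inputs(images, cfg.input_side)
    y = np.array([classes.index(lab) for lab in labels])
    k = len(classes)
    onehot_all = np.eye(k)[y]

    conv_w = gabor_filter_bank()
    feat = _conv_features(x, conv_w)
    feat_mu, whiten = _fit_whitening(feat)
    z_all = (feat - feat_mu) @ whiten

    rng = np.random.default_rng(cfg.seed)
    params = {
        "conv_w": conv_w,
        "feat_mu": feat_mu,
        "whiten": whiten,
        "fc_w": rng.normal(0.0, 0.01, (z_all.shape[1], k)),
        "fc_b": np.zeros(k),
    }
    velocity = {"fc_w": np.zeros_like(params["fc_w"]), "fc_b": np.zeros_like(params["fc_b"])}
    log: list[float] = []
    n = len(images)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            z = z_all[idx]
            logits = z @ params["fc_w"] + params["fc_b"]
            probs = _softmax(logits)
            losses.append(
                float(-np.mean(np.log(np.maximum(probs[np.arange(len(idx)), y[idx]], 1e-12))))
            )
            dlogits = (probs - onehot_all[idx]) / len(idx)
            grads = {"fc_w": z.T @ dlogits, "fc_b": dlogits.sum(axis=0)}
            for key in ("fc_w", "fc_b"):
                velocity[key] = cfg.momentum * velocity[key] - cfg.learning_rate * grads[key]
                params[key] = params[key] + velocity[key]
        log.append(float(np.mean(losses)))
    return FittedClassifier(
        backbone=cfg.backbone, classes=classes, params=params, training_log=log, config=cfg
    )


def predict(clf: FittedClassifier, images: Sequence[ActivityImage]) -> list[str]:
    """Predicted class name per image, input order preserved."""
    if len(images) == 0:
        return []
    x = _to_inputs(images, clf.config.input_side)
    logits, _ = _forward(x, clf.params)
    return [clf.classes.names[i] for i in logits.argmax(axis=1)]


def save_classifier(clf: FittedClassifier, path) -> None:
    """Persist a fitted classifier (npz with embedded class set/config)."""
    import json

    meta = {
        "backbone": clf.backbone,
        "classes": list(clf.classes),
        "training_log": clf.training_log,
        "config": {
            key: getattr(clf.config, key)
            for key in (
                "epochs", "learning_rate", "batch_size", "train_fraction",
                "seed", "backbone", "num_classes", "momentum", "input_side",
            )
        },
    }
    np.savez(path, meta=json.dumps(meta), **clf.params)


def load_classifier(path) -> FittedClassifier:
    import json

    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        params = {key: archive[key] for key in archive.files if key != "meta"}
    return FittedClassifier(
        backbone=meta["backbone"],
        classes=ClassSet(tuple(meta["classes"])),
        params=params,
        training_log=list(meta["training_log"]),
        config=TrainConfig(**meta["config"]),
    )
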