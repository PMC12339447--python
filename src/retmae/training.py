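"""The two training phases.

Phase 1 — self-supervised pre-training: the autoencoder reconstructs
masked patches of the fused multi-source pool; the checkpoint with the
minimum fused-validation loss is kept (50 epochs at paper scale).

Phase 2 — supervised transfer: the decoder is replaced by a 3-layer dense
head with ReLU activations ending in 2-way softmax; the pre-trained
encoder is frozen (feature extraction) and only the head trains, with
early stopping on validation accuracy (patience 10 at paper scale).

Both phases use Adam with decoupled weight decay, lr 1.5e-4, weight decay
0.05 and betas (0.9, 0.95) by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates, rotate

from .manifest import DatasetManifest, FusionResult
from .mae import MAEConfig, MAEModel, build_mae, sample_mask
from .nn import AdamW, Linear, Module, Parameter, Tensor
from . import synth

__all__ = ["PretrainConfig", "SupervisedConfig", "ClassifierHeadSpec",
           "PretrainResult", "TrainResult", "Classifier", "DivergenceError",
           "pretrain", "build_classifier", "train_classifier",
           "resolve_images", "augment_image", "AUGMENTATIONS"]

AUGMENTATIONS = ("rotation", "hflip", "color_jitter", "gaussian_blur", "elastic")


class DivergenceError(RuntimeError):
    """Raised when a training loss becomes non-finite."""


# ------------------------------------------------------------------ configs
@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 50
    lr: float = 1.5e-4
    weight_decay: float = 0.05
    betas: tuple[float, float] = (0.9, 0.95)
    batch_size: int = 32
    seed: int = 0
    # checkpoint policy is fixed: minimum validation loss

    def __post_init__(self):
        if self.epochs <= 0 or self.lr <= 0 or self.batch_size <= 0:
            raise ValueError("epochs, lr and batch_size must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


@dataclass(frozen=True)
class SupervisedConfig:
    epochs: int = 100
    early_stop_patience: int = 10
    freeze_encoder: bool = True
    augmentations: tuple[str, ...] = AUGMENTATIONS
    batch_size: int = 32
    lr: float = 1.5e-4
    weight_decay: float = 0.05
    betas: tuple[float, float] = (0.9, 0.95)
    seed: int = 0
    # checkpoint policy is fixed: maximum validation accuracy

    def __post_init__(self):
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if not (0 < self.early_stop_patience < self.epochs):
            raise ValueError("patience must lie in (0, epochs)")
        unknown = set(self.augmentations) - set(AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations {sorted(unknown)}")


@dataclass(frozen=True)
class ClassifierHeadSpec:
    """Three successive dense layers (ReLU after the first two), 2 logits."""

    hidden_dims: tuple[int, int] = (512, 256)

    def __post_init__(self):
        if min(self.hidden_dims) <= 0:
            raise ValueError("hidden dims must be positive")

    def n_parameters(self, d_encoder: int) -> int:
        d1, d2 = self.hidden_dims
        return (d_encoder * d1 + d1) + (d1 * d2 + d2) + (d2 * 2 + 2)


# -------------------------------------------------------------------- data
def resolve_images(manifest: DatasetManifest,
                   store: Mapping[str, np.ndarray] | str | Path) -> np.ndarray:
    """Materialize a manifest's images, in record order, as (n, H, W)."""
    if isinstance(store, (str, Path)):
        root = Path(store)
        arrs = [synth.load_image(root / p) for p in manifest.records.image_path]
    else:
        arrs = [store[i] for i in manifest.records.image_id]
    return np.stack(arrs)


BINARY_CODES = {"NORMAL": 0, "AMD": 1}


def binary_labels(manifest: DatasetManifest) -> np.ndarray:
    labels = manifest.records.class_label
    bad = set(labels) - set(BINARY_CODES)
    if bad:
        raise ValueError(f"non-binary labels present: {sorted(bad)}")
    return labels.map(BINARY_CODES).to_numpy()


# ------------------------------------------------------------ augmentations
def augment_image(img: np.ndarray, rng: np.random.Generator,
                  kinds: tuple[str, ...]) -> np.ndarray:
    """Apply the enabled augmentations with fixed mild parameter ranges
    (rotation ≤ 15°, ±0.2 brightness/contrast, blur σ ∈ [0.1, 1.0],
    mild elastic warp).  Evaluation never calls this."""
    out = img
    if "rotation" in kinds:
        angle = rng.uniform(-15.0, 15.0)
        out = rotate(out, angle, reshape=False, order=1, mode="nearest")
    if "hflip" in kinds and rng.random() < 0.5:
        out = out[:, ::-1]
    if "color_jitter" in kinds:
        brightness = rng.uniform(-0.2, 0.2)
        contrast = 1.0 + rng.uniform(-0.2, 0.2)
        out = (out - 0.5) * contrast + 0.5 + brightness
    if "gaussian_blur" in kinds:
        out = gaussian_filter(out, rng.uniform(0.1, 1.0))
    if "elastic" in kinds:
        H, W = out.shape
        alpha, sigma = 4.0, 4.0
        dy = gaussian_filter(rng.uniform(-1, 1, (H, W)), sigma) * alpha
        dx = gaussian_filter(rng.uniform(-1, 1, (H, W)), sigma) * alpha
        yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        out = map_coordinates(out, [yy + dy, xx + dx], order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------- pretraining
@dataclass
class PretrainResult:
    model: MAEModel
    history: pd.DataFrame            # epoch, train_loss, val_loss
    best_epoch: int
    best_val_loss: float

    def write_log(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.history.to_csv(path, index=False)
        return path


def _epoch_loss(model: MAEModel, images: np.ndarray, plans, batch_size: int,
                opt: AdamW | None) -> float:
    """One pass; trains when an optimizer is given, else evaluates."""
    total, count = 0.0, 0
    for start in range(0, len(images), batch_size):
        batch = images[start:start + batch_size]
        batch_plans = plans[start:start + len(batch)]
        loss = model.loss(batch, batch_plans)
        value = float(loss.data)
        if not np.isfinite(value):
            raise DivergenceError(f"non-finite reconstruction loss {value}")
        if opt is not None:
            model.zero_grad()
            loss.backward()
            opt.step()
        total += value * len(batch)
        count += len(batch)
    return total / count


def pretrain(fusion: FusionResult, mae: MAEConfig | MAEModel,
             cfg: PretrainConfig,
             store: Mapping[str, np.ndarray] | str | Path) -> PretrainResult:
    """Self-supervised pre-training on the fused pools (labels ignored).

    Fresh random masks are drawn per image per epoch; validation uses a
    fixed mask set so epoch losses are comparable.  The returned model
    carries the weights of the epoch with minimum validation loss.
    """
    if len(fusion.fused_train) == 0 or len(fusion.fused_val) == 0:
        raise ValueError("fusion train/val must be nonempty")
    model = mae if isinstance(mae, MAEModel) else build_mae(mae, rng_seed=cfg.seed)
    config = model.config
    train_images = resolve_images(fusion.fused_train, store)
    val_images = resolve_images(fusion.fused_val, store)

    ss = np.random.SeedSequence(entropy=int(cfg.seed), spawn_key=(7,))
    val_seeds = np.random.SeedSequence(entropy=int(cfg.seed), spawn_key=(8,)
                                       ).generate_state(len(val_images))
    val_plans = [sample_mask(config.patch_grid, config.mask_ratio, int(s))
                 for s in val_seeds]

    opt = AdamW(model, lr=cfg.lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    rows, best = [], (np.inf, -1, None)
    for epoch in range(1, cfg.epochs + 1):
        epoch_ss = np.random.SeedSequence(entropy=int(cfg.seed),
                                          spawn_key=(7, epoch))
        order_rng = np.random.default_rng(epoch_ss.generate_state(4))
        order = order_rng.permutation(len(train_images))
        mask_seeds = epoch_ss.generate_state(len(train_images) + 1)[1:]
        plans = [sample_mask(config.patch_grid, config.mask_ratio, int(s))
                 for s in mask_seeds]
        train_loss = _epoch_loss(model, train_images[order], plans,
                                 cfg.batch_size, opt)
        val_loss = _epoch_loss(model, val_images, val_plans,
                               cfg.batch_size, None)
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss})
        if val_loss < best[0]:
            best = (val_loss, epoch, model.state_dict())
    model.load_state_dict(best[2])
    return PretrainResult(model, pd.DataFrame(rows), best[1], best[0])


# --------------------------------------------------------------- classifier
class Classifier(Module):
    """Frozen-or-not encoder plus the 3-dense-layer softmax head.

    Encoder features are standardized per dimension with statistics taken
    from the training split before the head sees them (the usual practice
    when probing a frozen encoder; without it the head would have to undo
    arbitrary feature scales on its own).
    """

    def __init__(self, encoder_model: MAEModel, head: ClassifierHeadSpec,
                 freeze: bool, rng_seed: int = 0):
        self.mae = encoder_model
        self.head_spec = head
        self.frozen = bool(freeze)
        d_enc = encoder_model.config.encoder.final_dim
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=int(rng_seed), spawn_key=(11,)).generate_state(4))
        d1, d2 = head.hidden_dims
        self.fc1 = Linear(rng, d_enc, d1)
        self.fc2 = Linear(rng, d1, d2)
        self.fc3 = Linear(rng, d2, 2)
        # feature-standardization statistics (buffers, not trained)
        self.feat_mu = Parameter(np.zeros(d_enc))
        self.feat_sd = Parameter(np.ones(d_enc))
        self.feat_mu.requires_grad = False
        self.feat_sd.requires_grad = False
        if freeze:
            for _, p in self.mae.named_parameters():
                p.requires_grad = False

    def set_feature_stats(self, features: np.ndarray) -> None:
        """Record per-dimension mean/std of training-split features."""
        self.feat_mu.data = features.mean(axis=0)
        self.feat_sd.data = features.std(axis=0) + 1e-8

    def head_parameters(self):
        return ([("fc1.weight", self.fc1.weight), ("fc1.bias", self.fc1.bias),
                 ("fc2.weight", self.fc2.weight), ("fc2.bias", self.fc2.bias),
                 ("fc3.weight", self.fc3.weight), ("fc3.bias", self.fc3.bias)])

    def features(self, images: np.ndarray) -> Tensor:
        return self.mae.encode(images, plans=None)

    def head_logits(self, feats: Tensor) -> Tensor:
        z = (feats - self.feat_mu) * self.feat_sd ** -1.0
        return self.fc3(self.fc2(self.fc1(z).relu()).relu())

    def forward(self, images: np.ndarray) -> Tensor:
        return self.head_logits(self.features(images))

    def predict_proba(self, images: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Softmax probabilities, column 1 = probability of AMD."""
        outs = []
        for start in range(0, len(images), batch_size):
            logits = self.forward(images[start:start + batch_size])
            outs.append(logits.softmax(axis=-1).data)
        return np.concatenate(outs, axis=0)


class _HeadOnly(Module):
    """Optimizer view exposing only the head parameters."""

    def __init__(self, clf: Classifier):
        self.fc1 = clf.fc1
        self.fc2 = clf.fc2
        self.fc3 = clf.fc3


def build_classifier(encoder_ckpt: MAEModel | str | Path | None,
                     head: ClassifierHeadSpec = ClassifierHeadSpec(),
                     freeze: bool = True,
                     config: MAEConfig | None = None,
                     rng_seed: int = 0) -> Classifier:
    """Attach a classification head to a (pre-trained or fresh) encoder.

    With a checkpoint, encoder weights match it bit-exactly; with ``None``
    a randomly initialized encoder of ``config`` is used (the no-SSL arm).
    """
    from .mae import load_checkpoint
    if encoder_ckpt is None:
        if config is None:
            raise ValueError("config required when no checkpoint is given")
        encoder_model = build_mae(config, rng_seed=rng_seed)
    elif isinstance(encoder_ckpt, MAEModel):
        if config is not None and config.encoder.family != \
                encoder_ckpt.config.encoder.family:
            raise ValueError("encoder family mismatch")
        encoder_model = build_mae(encoder_ckpt.config, rng_seed=rng_seed)
        encoder_model.load_state_dict(encoder_ckpt.state_dict())
    else:
        encoder_model = load_checkpoint(encoder_ckpt)
        if config is not None and config.encoder.family != \
                encoder_model.config.encoder.family:
            raise ValueError("encoder family mismatch")
    return Classifier(encoder_model, head, freeze, rng_seed=rng_seed)


@dataclass
class TrainResult:
    classifier: Classifier
    history: pd.DataFrame           # epoch, train_loss, val_acc
    best_epoch: int
    best_val_acc: float
    stopped_epoch: int

    def write_log(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.history.to_csv(path, index=False)
        return path


def _cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


def train_classifier(clf: Classifier, train_manifest: DatasetManifest,
                     val_manifest: DatasetManifest, cfg: SupervisedConfig,
                     store: Mapping[str, np.ndarray] | str | Path
                     ) -> TrainResult:
    """Supervised head training with early stopping on validation accuracy.

    Ties do not reset patience (only a strictly better validation accuracy
    does).  Augmentations perturb training images only; validation images
    pass through untouched.  With a frozen encoder and no augmentations the
    encoder features are computed once and cached.
    """
    if len(val_manifest) == 0:
        raise ValueError("validation manifest must be nonempty")
    y_train = binary_labels(train_manifest)
    y_val = binary_labels(val_manifest)
    if len(set(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    X_train = resolve_images(train_manifest, store)
    X_val = resolve_images(val_manifest, store)

    head_view = _HeadOnly(clf)
    target = head_view if clf.frozen else clf
    opt = AdamW(target, lr=cfg.lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)

    # standardization statistics come from the raw (unaugmented) train split
    feat_train_raw = clf.features(X_train).detach()
    clf.set_feature_stats(feat_train_raw.data)
    cache_features = clf.frozen and not cfg.augmentations
    feat_train = feat_train_raw if cache_features else None
    feat_val = clf.features(X_val).detach() if clf.frozen else None

    aug_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(cfg.seed), spawn_key=(13,)).generate_state(4))
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(cfg.seed), spawn_key=(14,)).generate_state(4))

    def val_accuracy() -> float:
        if clf.frozen:
            logits = clf.head_logits(feat_val)
        else:
            logits = clf.forward(X_val)
        pred = logits.data.argmax(axis=1)
        return float((pred == y_val).mean())

    rows = []
    best_acc, best_epoch, best_state = -1.0, -1, None
    patience_left = cfg.early_stop_patience
    stopped = cfg.epochs
    for epoch in range(1, cfg.epochs + 1):
        order = shuffle_rng.permutation(len(X_train))
        total, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if cache_features:
                feats = Tensor(feat_train.data[idx])
                logits = clf.head_logits(feats)
            else:
                batch = X_train[idx]
                if cfg.augmentations:
                    batch = np.stack([
                        augment_image(im, aug_rng, cfg.augmentations)
                        for im in batch])
                logits = clf.forward(batch)
            loss = _cross_entropy(logits, y_train[idx])
            value = float(loss.data)
            if not np.isfinite(value):
                raise DivergenceError("non-finite classification loss")
            clf.zero_grad()
            loss.backward()
            opt.step()
            total += value * len(idx)
            seen += len(idx)
        acc = val_accuracy()
        rows.append({"epoch": epoch, "train_loss": total / seen,
                     "val_acc": acc})
        if acc > best_acc:
            best_acc, best_epoch = acc, epoch
            best_state = {k: v.data.copy()
                          for k, v in head_view.named_parameters()}
            if not clf.frozen:
                best_state = clf.state_dict()
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left == 0:
                stopped = epoch
                break
    if clf.frozen:
        for name, p in head_view.named_parameters():
            p.data = best_state[name].copy()
    else:
        clf.load_state_dict(best_state)
    return TrainResult(clf, pd.DataFrame(rows), best_epoch, best_acc, stopped)
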