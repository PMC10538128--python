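"""Classifier-based diagnostic-value evaluation.

A convolutional classifier is trained on ground-truth conductivity images
to recognize the 17 phantom classes (16 left x right lung-state
combinations plus the random-ellipse class).  Applying it to reconstructed
images and measuring the macro-averaged one-vs-rest ROC-AUC quantifies how
much diagnostically usable information a reconstruction method preserves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.metrics import auc, roc_curve

from . import nn
from .dataset import split_train_val
from .geometry import FOVMask
from .phantom import N_CLASSES

F32 = np.float32


@dataclass
class ClassifierConfig:
    n_classes: int = N_CLASSES
    channels: tuple = (16, 32, 64)
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    loss: str = "bce"  # "bce" (elementwise on one-hot) or "categorical"


def build_classifier(cfg: ClassifierConfig | None = None) -> nn.Sequential:
    """Convolution + normalization blocks, then an affine layer.

    Input is the 64 x 64 image (FOV vector embedded, zeros outside).  The
    model outputs logits; :func:`predict_proba` applies the softmax.
    """
    if cfg is None:
        cfg = ClassifierConfig()
    rng = np.random.default_rng(cfg.seed)
    c1, c2, c3 = cfg.channels
    return nn.Sequential(
        nn.Conv2d(1, c1, 3, 2, 1, rng),
        nn.BatchNorm(c1),
        nn.ReLU(),
        nn.Conv2d(c1, c2, 3, 2, 1, rng),
        nn.BatchNorm(c2),
        nn.ReLU(),
        nn.Conv2d(c2, c3, 3, 2, 1, rng),
        nn.BatchNorm(c3),
        nn.ReLU(),
        nn.Flatten(),
        nn.Dense(c3 * 8 * 8, cfg.n_classes, rng),
    )


def embed_images(images_fov: np.ndarray, fov: FOVMask) -> np.ndarray:
    """(B, n_fov) vectors -> (B, 1, 64, 64) with zeros outside the FOV."""
    B = images_fov.shape[0]
    n = fov.mask.shape[0]
    out = np.zeros((B, 1, n, n), dtype=F32)
    out[:, 0, fov.mask] = images_fov
    return out


def predict_proba(model: nn.Sequential, images: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Softmax class probabilities, deterministic (eval mode)."""
    outs = []
    for i in range(0, len(images), batch_size):
        logits = model.forward(images[i : i + batch_size].astype(F32), training=False)
        outs.append(nn.softmax(logits))
    return np.concatenate(outs, axis=0)


def _loss_and_grad(logits: np.ndarray, onehot: np.ndarray, kind: str):
    p = nn.softmax(logits)
    if kind == "categorical":
        eps = 1e-12
        loss = float(np.mean(-np.sum(onehot * np.log(p + eps), axis=1)))
        grad = (p - onehot) / logits.shape[0]
        return loss, grad
    # elementwise binary cross-entropy over the class outputs
    loss, dLdp = nn.bce_loss(p, onehot)
    # chain through the softmax: dz_j = p_j (dLdp_j - sum_i dLdp_i p_i)
    inner = np.sum(dLdp * p, axis=1, keepdims=True)
    grad = p * (dLdp - inner)
    return loss, grad


def train_classifier(
    images_fov: np.ndarray,
    labels: np.ndarray,
    fov: FOVMask,
    cfg: ClassifierConfig | None = None,
    val_ratio: float = 0.25,
) -> tuple[nn.Sequential, list]:
    """Train on ground-truth images with a 75:25 learning/validation split.

    ``labels`` are class ids 1..17; the loss is elementwise binary
    cross-entropy against the one-hot encoding (categorical cross-entropy
    behind ``cfg.loss``), optimized with Adam.
    """
    if cfg is None:
        cfg = ClassifierConfig()
    rng = np.random.default_rng(cfg.seed)
    model = build_classifier(cfg)
    opt = nn.Adam(model.params(), lr=cfg.lr)
    x = embed_images(np.asarray(images_fov, dtype=F32), fov)
    t = np.zeros((len(labels), cfg.n_classes), dtype=F32)
    t[np.arange(len(labels)), np.asarray(labels) - 1] = 1.0
    learn_idx, val_idx = split_train_val(len(x), 1.0 - val_ratio, rng)
    history = []
    nb = max(1, len(learn_idx) // cfg.batch_size)
    for _ in range(cfg.epochs):
        perm = rng.permutation(learn_idx)
        total = 0.0
        for b in range(nb):
            idx = perm[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            logits = model.forward(x[idx], training=True)
            loss, grad = _loss_and_grad(logits, t[idx], cfg.loss)
            if not np.isfinite(loss):
                raise RuntimeError("classifier training diverged")
            model.backward(grad)
            opt.step()
            total += loss
        entry = {"train_loss": total / nb}
        if len(val_idx):
            p = predict_proba(model, x[val_idx])
            acc = float(np.mean(np.argmax(p, axis=1) + 1 == labels[val_idx]))
            entry["val_accuracy"] = acc
        history.append(entry)
    return model, history


@dataclass(frozen=True)
class RocResult:
    """Per-class and macro-averaged one-vs-rest ROC curves and AUCs."""

    per_class_auc: dict
    macro_auc: float
    fpr_grid: np.ndarray
    macro_tpr: np.ndarray
    curves: dict = field(default_factory=dict)


def ovr_roc_auc(
    probabilities: np.ndarray, labels: np.ndarray, n_grid: int = 1001
) -> RocResult:
    """One-vs-rest ROC analysis of a multiclass probability matrix.

    Each class in turn is the positive class; the macro curve is the mean
    TPR over a common FPR grid and the macro AUC the mean of per-class
    AUCs.  Classes absent from ``labels`` are skipped with a warning.
    """
    probabilities = np.asarray(probabilities)
    labels = np.asarray(labels)
    n_classes = probabilities.shape[1]
    grid = np.linspace(0.0, 1.0, n_grid)
    per_auc, curves, tprs = {}, {}, []
    for c in range(n_classes):
        pos = labels == c + 1
        if not pos.any() or pos.all():
            warnings.warn(f"class {c + 1} absent from labels; skipped", stacklevel=2)
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), probabilities[:, c])
        per_auc[c + 1] = float(auc(fpr, tpr))
        curves[c + 1] = (fpr, tpr)
        tprs.append(np.interp(grid, fpr, tpr))
    if not per_auc:
        raise ValueError("no class is represented in the labels")
    macro_tpr = np.mean(tprs, axis=0)
    return RocResult(
        per_class_auc=per_auc,
        macro_auc=float(np.mean(list(per_auc.values()))),
        fpr_grid=grid,
        macro_tpr=macro_tpr,
        curves=curves,
    )


def diagnostic_value(
    recon_images_fov: np.ndarray,
    labels: np.ndarray,
    model: nn.Sequential,
    fov: FOVMask,
) -> RocResult:
    """Macro OvR ROC-AUC of the classifier applied to reconstructions."""
    x = embed_images(np.asarray(recon_images_fov, dtype=F32), fov)
    p = predict_proba(model, x)
    return ovr_roc_auc(p, labels)
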