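"""Splitting, augmentation and the training loop.

Training follows the protocol used for leaf-spectra models here: inputs are
per-channel standardized spectra; Gaussian-noise copies (SD 0.01) augment the
training set only; the classifier sees all three P treatments while the
regressor (log10 Pi target) is trained on deficient treatments only; model
selection is by validation loss with early stopping; metrics come from an
untouched test set; stochastic results are summarized over 5 weight
initializations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import ModelConfig, SpectralCNN, build_model

logger = logging.getLogger(__name__)


class TrainError(RuntimeError):
    pass


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    group_by_accession: bool = False
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be >= 0")


def split_data(
    n_samples: int,
    spec: SplitSpec,
    accessions: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test index sets.

    With ``group_by_accession`` every accession's samples land in exactly one
    set (greedy assignment of shuffled accessions to the least-filled set
    relative to its target fraction).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if not spec.group_by_accession or accessions is None:
        perm = rng.permutation(n_samples)
        n_train = int(round(spec.fractions[0] * n_samples))
        n_val = int(round(spec.fractions[1] * n_samples))
        return (np.sort(perm[:n_train]),
                np.sort(perm[n_train:n_train + n_val]),
                np.sort(perm[n_train + n_val:]))

    accessions = np.asarray(accessions)
    if len(accessions) != n_samples:
        raise ValueError("accessions length must equal n_samples")
    uniq, counts = np.unique(accessions, return_counts=True)
    if counts.max() > spec.fractions[0] * n_samples:
        raise ValueError(
            f"accession with {counts.max()} samples exceeds the training fraction"
        )
    order = rng.permutation(len(uniq))
    targets = np.array(spec.fractions) * n_samples
    filled = np.zeros(3)
    assign: dict = {}
    for gi in order:
        # most-underfilled set relative to target
        with np.errstate(divide="ignore", invalid="ignore"):
            deficit = np.where(targets > 0, (targets - filled) / targets, -np.inf)
        s = int(np.argmax(deficit))
        assign[uniq[gi]] = s
        filled[s] += counts[gi]
    sets = [[], [], []]
    for i, acc in enumerate(accessions):
        sets[assign[acc]].append(i)
    return tuple(np.array(sorted(s), dtype=int) for s in sets)


def augment(
    spectra: np.ndarray,
    sd: float = 0.01,
    copies: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Originals plus ``copies`` Gaussian-noise copies per spectrum.

    Returns ``(augmented, is_augmented)`` where the flag marks noise copies
    so they can be excluded from any evaluation.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    rng = np.random.default_rng(seed)
    parts = [spectra]
    flags = [np.zeros(len(spectra), dtype=bool)]
    for _ in range(copies):
        parts.append(spectra + rng.normal(0.0, sd, spectra.shape))
        flags.append(np.ones(len(spectra), dtype=bool))
    return np.vstack(parts), np.concatenate(flags)


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 200
    patience: int = 20
    augment_sd: float = 0.01
    augment_copies: int = 1
    seed: int = 0


@dataclass
class DataSplits:
    """Standardized spectra with targets and index sets.

    ``channel_scale`` records the per-channel SDs used for standardization so
    that augmentation noise specified in reflectance units can be mapped onto
    the standardized scale (noise_std_standardized = sd / channel_scale).
    """

    X: np.ndarray                 # (n, channels), standardized
    y: np.ndarray                 # int labels (classify) or float targets (regress)
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    channel_scale: np.ndarray | None = None


@dataclass
class TrainResult:
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    best_weights: list[np.ndarray] = field(repr=False)
    metrics: dict = field(default_factory=dict)
    seed: int = 0


def _batch_losses(model: SpectralCNN, X: np.ndarray, y: np.ndarray,
                  train: bool) -> tuple[float, dict]:
    """Mean combined loss over a batch; gradients dict alongside.

    Returns the total (task + weighted reconstruction) loss; the task
    component alone is stashed under ``grads["task_loss"]`` for model
    selection.
    """
    cfg = model.config
    out = model.forward(X, train=train)
    n = len(X)
    grads: dict = {}
    if cfg.head == "classify":
        probs = out["probs"]
        p_true = np.clip(probs[np.arange(n), y], 1e-12, 1.0)
        loss = float(-np.log(p_true).mean())
        onehot = np.zeros_like(probs)
        onehot[np.arange(n), y] = 1.0
        grads["head"] = (probs - onehot) / n
    else:
        pred = out["output"]
        resid = pred - y
        loss = float((resid**2).mean())
        grads["head"] = (2.0 * resid / n)[:, None]
    grads["task_loss"] = loss
    if cfg.multitask:
        recon = out["recon"]
        diff = recon - X
        recon_loss = float((diff**2).mean(axis=1).mean())
        loss += cfg.recon_weight * recon_loss
        grads["recon"] = cfg.recon_weight * 2.0 * diff / (diff.shape[1] * n)
    return loss, grads


def _eval_loss(model: SpectralCNN, X: np.ndarray, y: np.ndarray) -> float:
    """Validation loss used for model selection: the task component only
    (reconstruction is an auxiliary regularizer, not a selection target)."""
    _, grads = _batch_losses(model, X, y, train=False)
    return grads["task_loss"]


def evaluate(model: SpectralCNN, X: np.ndarray, y: np.ndarray) -> dict:
    """Test metrics: accuracy + 3x3 confusion matrix, or R^2 + MAE."""
    out = model.forward(X, train=False)
    if model.config.head == "classify":
        pred = out["probs"].argmax(axis=1)
        k = model.config.n_classes
        conf = np.zeros((k, k), dtype=int)
        for t, p in zip(y, pred):
            conf[t, p] += 1
        return {"accuracy": float((pred == y).mean()),
                "confusion_matrix": conf}
    pred = out["output"]
    resid = y - pred
    ss_tot = float(((y - y.mean())**2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return {"r_squared": r2, "mae": float(np.abs(resid).mean())}


def train(model: SpectralCNN, data: DataSplits,
          config: TrainConfig | None = None) -> TrainResult:
    """Mini-batch Adam with per-epoch noise augmentation and early stopping.

    One fresh Gaussian-noise copy per training spectrum is drawn each epoch
    (augmentation never touches validation or test data).  The weights with
    the lowest validation loss are restored before computing test metrics.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    opt = model.make_optimizer(config.lr)

    Xtr, ytr = data.X[data.train_idx], data.y[data.train_idx]
    Xva, yva = data.X[data.val_idx], data.y[data.val_idx]
    Xte, yte = data.X[data.test_idx], data.y[data.test_idx]

    best_val, best_weights, best_epoch = np.inf, model.get_weights(), -1
    train_losses, val_losses = [], []
    stall = 0
    for epoch in range(config.epochs):
        if config.augment_copies > 0 and config.augment_sd > 0:
            if data.channel_scale is not None:
                # noise is specified in reflectance units; rescale per channel
                noise_sd = config.augment_sd / data.channel_scale
                arng = np.random.default_rng(int(rng.integers(2**31)))
                copies = [Xtr + arng.normal(0.0, 1.0, Xtr.shape) * noise_sd
                          for _ in range(config.augment_copies)]
                Xa = np.vstack([Xtr] + copies)
            else:
                Xa, _ = augment(Xtr, config.augment_sd, config.augment_copies,
                                seed=int(rng.integers(2**31)))
            ya = np.concatenate([ytr] * (config.augment_copies + 1))
        else:
            Xa, ya = Xtr, ytr
        perm = rng.permutation(len(Xa))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(Xa), config.batch_size):
            idx = perm[start:start + config.batch_size]
            loss, grads = _batch_losses(model, Xa[idx], ya[idx], train=True)
            if not np.isfinite(loss):
                raise TrainError(
                    f"NaN/inf loss at epoch {epoch}, batch {n_batches}; "
                    f"lr={config.lr}, batch_size={config.batch_size}"
                )
            model.backward(grads["head"], grads.get("recon"))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        train_losses.append(epoch_loss / max(n_batches, 1))
        val_loss = _eval_loss(model, Xva, yva)
        val_losses.append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val, best_weights, best_epoch = val_loss, model.get_weights(), epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    model.set_weights(best_weights)
    metrics = evaluate(model, Xte, yte)
    metrics["val_loss"] = best_val
    return TrainResult(train_losses, val_losses, best_epoch, best_weights,
                       metrics, config.seed)


def train_replicates(model_config: ModelConfig, data: DataSplits,
                     train_config: TrainConfig, n_seeds: int = 5) -> list[TrainResult]:
    """Re-train from ``n_seeds`` weight initializations (same data split)."""
    results = []
    for s in range(n_seeds):
        cfg = ModelConfig(**{**model_config.__dict__, "seed": model_config.seed + s})
        model = build_model(cfg)
        tc = TrainConfig(**{**train_config.__dict__, "seed": train_config.seed + s})
        results.append(train(model, data, tc))
    return results
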