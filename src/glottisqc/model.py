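"""The quality model: build, train, predict, checkpoint.

The regressor takes a two-channel input — the grayscale frame and the
candidate segmentation as a {0, 1} float channel — and emits one raw
score, trained against the exact IoU label with the threshold-aware
combined loss. Scores are clamped to [0, 1] only at reporting time; the
head itself is linear.

Training follows a standard recipe: Adam (β1=0.9, β2=0.999),
learning rate 1e-4 under a triangular cyclic scheduler, batch size 18,
Kaiming initialization, gradient clipping at global norm 1, light
photometric/geometric augmentation, model selection by lowest validation
MSE, and early stopping after epoch 20 once the best model is more than
10 epochs old.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .losses import LossParams, combined_loss, combined_loss_grad
from .metrics import as_frame, as_mask, classify_iou
from .nn import Adam, CyclicLR, ResNetRegressor, clip_grad_norm

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "QualityPrediction",
    "build_model",
    "samples_to_arrays",
    "train",
    "predict",
    "predict_batch",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs; ``width_multiplier`` < 1 gives a desk-scale net."""

    input_size: int = 256
    in_channels: int = 2
    width_multiplier: float = 1.0
    depth: tuple = (2, 2, 2, 2)

    def __post_init__(self):
        if self.in_channels != 2:
            raise ValueError("the quality model takes exactly 2 input channels")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError(f"width_multiplier must be in (0, 1], got {self.width_multiplier}")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 18
    max_epochs: int = 100
    beta1: float = 0.9
    beta2: float = 0.999
    grad_clip_norm: float = 1.0
    cyclic_base_lr: float = 1e-5
    cyclic_cycle_epochs: int = 4
    early_stop_after: int = 20
    early_stop_patience: int = 10
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.grad_clip_norm) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs, grad_clip_norm must be > 0")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")


@dataclass(frozen=True)
class QualityPrediction:
    """Clamped score plus the thresholded accept/decline decision."""

    score: float
    decision: str
    threshold_used: float


def build_model(config: ModelConfig, rng: np.random.Generator | None = None) -> ResNetRegressor:
    model = ResNetRegressor(
        in_channels=config.in_channels,
        width_multiplier=config.width_multiplier,
        depth=tuple(config.depth),
        rng=rng,
    )
    model.config = config
    return model


def samples_to_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    """Stack ScoredSamples into (N, 2, H, W) inputs and (N,) IoU targets."""
    x = np.stack(
        [
            np.stack([s.frame, s.candidate_mask.astype(np.float64)], axis=0)
            for s in samples
        ]
    ).astype(np.float32)
    y = np.array([s.iou for s in samples], dtype=np.float64)
    return x, y


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Light anti-overfitting augmentation of a (B, 2, H, W) batch.

    Geometric transforms (flips, small rotation) act on both channels so
    the frame/mask geometry — and hence the IoU label — is preserved up
    to raster error; photometric transforms (gamma, brightness/contrast,
    noise) act on the frame channel only.
    """
    x = x.copy()
    b = x.shape[0]
    for i in range(b):
        if rng.random() < 0.5:
            x[i] = x[i, :, :, ::-1]
        if rng.random() < 0.5:
            x[i] = x[i, :, ::-1, :]
        if rng.random() < 0.5:
            angle = rng.uniform(-15.0, 15.0)
            x[i, 0] = ndimage.rotate(x[i, 0], angle, reshape=False, order=1, mode="nearest")
            x[i, 1] = ndimage.rotate(x[i, 1], angle, reshape=False, order=0, mode="constant")
        frame = x[i, 0]
        gamma = rng.uniform(0.9, 1.1)
        frame = np.clip(frame, 0.0, 1.0) ** gamma
        frame = (frame - 0.5) * rng.uniform(0.92, 1.08) + 0.5 + rng.uniform(-0.05, 0.05)
        frame = frame + rng.normal(0.0, 0.01, size=frame.shape).astype(np.float32)
        x[i, 0] = np.clip(frame, 0.0, 1.0)
    return x


def train(
    model: ResNetRegressor,
    train_samples,
    val_samples,
    loss_params: LossParams,
    tc: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ResNetRegressor, list[dict]]:
    """Train in place and return (best-validation-MSE model, per-epoch log).

    *train_samples* / *val_samples* are sequences of ScoredSample or
    pre-stacked ``(x, y)`` tuples. The log records per-epoch mean train
    loss, validation MSE and last learning rate. Divergence (non-finite
    loss) aborts with the epoch/batch context.
    """
    rng = rng or np.random.default_rng(tc.seed)
    xtr, ytr = train_samples if isinstance(train_samples, tuple) else samples_to_arrays(train_samples)
    xva, yva = val_samples if isinstance(val_samples, tuple) else samples_to_arrays(val_samples)
    if len(ytr) == 0 or len(yva) == 0:
        raise ValueError("train and validation splits must be non-empty")

    opt = Adam(model.params(), lr=tc.learning_rate, betas=(tc.beta1, tc.beta2))
    steps_per_epoch = max(1, int(np.ceil(len(ytr) / tc.batch_size)))
    sched = CyclicLR(
        base_lr=tc.cyclic_base_lr,
        max_lr=tc.learning_rate,
        step_size=max(1, steps_per_epoch * tc.cyclic_cycle_epochs // 2),
    )
    log: list[dict] = []
    best_state = model.state_dict()
    best_mse = np.inf
    best_epoch = -1
    it = 0
    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(ytr))
        losses = []
        lr = tc.learning_rate
        for start in range(0, len(ytr), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb = xtr[idx]
            if tc.augment:
                xb = _augment_batch(xb, rng)
            yb = ytr[idx]
            pred = model.forward(xb, train=True)
            loss = combined_loss(pred, yb, loss_params)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {start // tc.batch_size}"
                )
            model.zero_grad()
            model.backward(combined_loss_grad(pred, yb, loss_params))
            clip_grad_norm(model.params(), tc.grad_clip_norm)
            lr = sched.lr(it)
            opt.step(lr=lr)
            it += 1
            losses.append(loss)
        val_pred = _forward_eval(model, xva, tc.batch_size)
        val_mse = float(np.mean((val_pred - yva) ** 2))
        log.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_mse": val_mse,
                "lr": float(lr),
            }
        )
        if val_mse < best_mse:
            best_mse = val_mse
            best_epoch = epoch
            best_state = model.state_dict()
        if _should_stop(epoch, best_epoch, tc):
            break
    model.load_state_dict(best_state)
    return model, log


def _should_stop(epoch: int, best_epoch: int, tc: TrainConfig) -> bool:
    """Early-stop rule: from ``early_stop_after`` epochs on, halt once the
    best validation model is more than ``early_stop_patience`` epochs old."""
    return epoch + 1 >= tc.early_stop_after and (epoch - best_epoch) > tc.early_stop_patience


def _forward_eval(model, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    preds = []
    for start in range(0, len(x), batch_size):
        preds.append(model.forward(x[start : start + batch_size], train=False))
    return np.concatenate(preds).astype(np.float64)


def predict(model, frame, mask, threshold: float = 0.6) -> QualityPrediction:
    """Score one frame/segmentation pair and threshold the decision."""
    f = as_frame(frame)
    m = as_mask(mask)
    if f.shape != m.shape:
        raise ValueError(f"frame shape {f.shape} != mask shape {m.shape}")
    x = np.stack([f, m.astype(np.float64)], axis=0)[None].astype(np.float32)
    raw = float(model.forward(x, train=False)[0])
    score = float(np.clip(raw, 0.0, 1.0))
    return QualityPrediction(
        score=score, decision=classify_iou(score, threshold), threshold_used=threshold
    )


def predict_batch(model, samples, threshold: float = 0.6, batch_size: int = 64) -> list[QualityPrediction]:
    x, _ = samples_to_arrays(samples)
    raw = _forward_eval(model, x, batch_size)
    scores = np.clip(raw, 0.0, 1.0)
    return [
        QualityPrediction(float(s), classify_iou(float(s), threshold), threshold)
        for s in scores
    ]


def save_checkpoint(
    model,
    path,
    loss_params: LossParams | None = None,
    seed: int | None = None,
) -> None:
    """Serialize parameters, batch-norm statistics and provenance metadata."""
    config = getattr(model, "config", None)
    meta = {
        "model_config": asdict(config) if config is not None else None,
        "loss_params": asdict(loss_params) if loss_params is not None else None,
        "seed": seed,
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[ResNetRegressor, dict]:
    """Rebuild the model from a checkpoint; returns (model, metadata)."""
    try:
        archive = np.load(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ValueError(f"checkpoint {path} is unreadable or corrupt: {exc}") from exc
    if "__meta__" not in archive:
        raise ValueError(f"checkpoint {path} lacks metadata")
    meta = json.loads(bytes(archive["__meta__"]).decode())
    cfg_dict = meta.get("model_config") or {}
    if "depth" in cfg_dict and cfg_dict["depth"] is not None:
        cfg_dict["depth"] = tuple(cfg_dict["depth"])
    config = ModelConfig(**cfg_dict) if cfg_dict else ModelConfig()
    model = build_model(config, rng=np.random.default_rng(0))
    state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model.load_state_dict(state)
    return model, meta
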