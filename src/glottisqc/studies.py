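"""Desk-scale study recipes: canned experiments over the full pipeline.

Each function wires the synthetic phantom generator, a failure generator
and (where relevant) the quality model into one self-contained,
seed-reproducible experiment and returns plain dictionaries of numbers.
They are the package's own scaled-down analogues of a full clinical
evaluation campaign: phantom corpora stand in for annotated
videolaryngoscopy data, and a width-reduced network trained for a few
epochs stands in for the full-size model. Problem sizes (2000/500
samples, 48 px grid, width multiplier 0.25, ≤ 30 epochs) are chosen so
every study runs in minutes on one CPU core.
"""

from __future__ import annotations

import numpy as np

from .degrade import AugmentationRamp, generate_model_failures, reference_segmenter
from .losses import LossParams
from .metrics import confusion, regression_metrics
from .model import ModelConfig, TrainConfig, build_model, predict_batch, samples_to_arrays, train
from .perturb import PerturbationConfig, perturb_pairs
from .phantom import GlottisPhantomParams, generate_pair

__all__ = [
    "make_phantom_pairs",
    "make_perturbed_corpus",
    "perturbation_integrity_study",
    "degradation_study",
    "train_quality_model",
    "learnability_study",
    "loss_shaping_study",
]


def make_phantom_pairs(n: int, seed: int, image_size: int = 48, closed_probability: float = 0.2):
    params = GlottisPhantomParams(
        image_size=image_size, closed_probability=closed_probability, seed=seed
    )
    rng = np.random.default_rng(seed)
    return [generate_pair(params, rng) for _ in range(n)]


def make_perturbed_corpus(
    n_train: int,
    n_test: int,
    seed: int,
    image_size: int = 48,
    samples_per_pair: int = 4,
    config: PerturbationConfig | None = None,
):
    """Perturbed train/test ScoredSample corpora from fresh phantoms."""
    config = config or PerturbationConfig()
    rng = np.random.default_rng(seed)
    params = GlottisPhantomParams(image_size=image_size, seed=seed)
    n_train_pairs = int(np.ceil(n_train / samples_per_pair))
    n_test_pairs = int(np.ceil(n_test / samples_per_pair))
    train_pairs = [generate_pair(params, rng) for _ in range(n_train_pairs)]
    test_pairs = [generate_pair(params, rng) for _ in range(n_test_pairs)]
    tr = perturb_pairs(train_pairs, config, rng, samples_per_pair)[:n_train]
    te = perturb_pairs(test_pairs, config, rng, samples_per_pair)[:n_test]
    return tr, te


def perturbation_integrity_study(
    n_pairs: int = 500,
    samples_per_pair: int = 10,
    seed: int = 0,
    image_size: int = 256,
    config: PerturbationConfig | None = None,
) -> dict:
    """Label integrity, operator area monotonicity, and bin fidelity.

    Runs the perturbation procedure on non-empty ground truths (empty
    masks admit only IoU 0 or 1, so bin fidelity is undefined for them)
    and checks, per bin, that the achieved-IoU frequency lies within a
    3-sigma binomial band of the configured bin probability, with the
    bin boundaries widened by the target tolerance.
    """
    from .metrics import compute_iou
    from .perturb import GROWING_OPS, SHRINKING_OPS, sample_target_iou, perturb_to_target

    config = config or PerturbationConfig()
    rng = np.random.default_rng(seed)
    params = GlottisPhantomParams(image_size=image_size, closed_probability=0.0, seed=seed)
    pairs = [generate_pair(params, rng) for _ in range(n_pairs)]

    ious, label_exact, mono_violations = [], 0, 0
    log: list = []
    for _, gt in pairs:
        for _ in range(samples_per_pair):
            target = sample_target_iou(config, rng)
            log.clear()
            cand, iou = perturb_to_target(gt, target, config, rng, log=log)
            ious.append(iou)
            if iou != compute_iou(cand, gt):
                label_exact += 1
            for name, before, after in log:
                if (name in SHRINKING_OPS and after > before) or (
                    name in GROWING_OPS and after < before
                ):
                    mono_violations += 1
    ious = np.asarray(ious)
    n = ious.size
    tol = config.target_tolerance
    edges = np.asarray(config.bin_edges)
    probs = np.asarray(config.bin_probabilities)
    bins = []
    for i in range(6):
        lo, hi = edges[i], edges[i + 1]
        wide = int(np.sum((ious >= lo - tol) & (ious <= hi + tol)))
        if hi - lo > 2 * tol:
            narrow = int(np.sum((ious >= lo + tol) & (ious < hi - tol)))
        else:
            narrow = 0  # bin narrower than the tolerance band: vacuous
        sigma = float(np.sqrt(n * probs[i] * (1 - probs[i])))
        bins.append(
            {
                "lo": float(lo),
                "hi": float(hi),
                "expected": float(n * probs[i]),
                "wide_count": wide,
                "narrow_count": narrow,
                "ok": (wide >= n * probs[i] - 3 * sigma)
                and (narrow <= n * probs[i] + 3 * sigma),
            }
        )
    return {
        "n": n,
        "label_mismatches": label_exact,
        "area_monotonicity_violations": mono_violations,
        "mean_iou": float(ious.mean()),
        "std_iou": float(ious.std()),
        "bins": bins,
        "bins_ok": all(b["ok"] for b in bins),
    }


def degradation_study(
    n_phantoms: int = 200,
    amps=(0.0, 1.0, 7.0),
    seed: int = 0,
    image_size: int = 64,
) -> dict:
    """Mean reference-segmenter IoU per augmentation intensity."""
    pairs = make_phantom_pairs(n_phantoms, seed, image_size)
    out = {}
    for amp in amps:
        samples = generate_model_failures(
            reference_segmenter, pairs, AugmentationRamp(amp=amp), np.random.default_rng(seed + 1)
        )
        ious = np.array([s.iou for s in samples])
        out[amp] = {
            "mean_iou": float(ious.mean()),
            "sem": float(ious.std(ddof=1) / np.sqrt(len(ious))),
            "n": len(ious),
        }
    return out


def train_quality_model(
    train_samples,
    test_samples,
    loss_params: LossParams,
    seed: int,
    image_size: int = 48,
    width_multiplier: float = 0.25,
    epochs: int = 15,
    val_fraction: float = 0.15,
) -> dict:
    """Train the width-reduced regressor and report held-out metrics."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_samples))
    n_val = max(1, int(round(val_fraction * len(train_samples))))
    val = [train_samples[i] for i in order[:n_val]]
    trn = [train_samples[i] for i in order[n_val:]]
    net = build_model(
        ModelConfig(input_size=image_size, width_multiplier=width_multiplier),
        rng=np.random.default_rng(seed),
    )
    tc = TrainConfig(max_epochs=epochs, seed=seed)
    net, log = train(
        net,
        samples_to_arrays(trn),
        samples_to_arrays(val),
        loss_params,
        tc,
        rng=np.random.default_rng(seed + 1),
    )
    preds = predict_batch(net, test_samples, threshold=loss_params.t)
    scores = np.array([q.score for q in preds])
    true = np.array([s.iou for s in test_samples])
    mse, mae = regression_metrics(scores, true)
    cm = confusion(scores, true, loss_params.t)
    low = true < loss_params.t
    return {
        "model": net,
        "log": log,
        "scores": scores,
        "true": true,
        "mse": mse,
        "mae": mae,
        "accuracy": cm.accuracy,
        "specificity": cm.specificity,
        "sensitivity": cm.sensitivity,
        "mae_below_t": float(np.mean(np.abs(scores[low] - true[low]))) if low.any() else None,
    }


def learnability_study(seed: int, n_train: int = 2000, n_test: int = 500,
                       epochs: int = 15) -> dict:
    """One seed of the scaled-down learnability experiment (balanced loss)."""
    tr, te = make_perturbed_corpus(n_train, n_test, seed)
    res = train_quality_model(tr, te, LossParams(0.5, 0.5, 0.6), seed, epochs=epochs)
    return {k: res[k] for k in ("mse", "mae", "accuracy", "specificity", "sensitivity")} | {
        "model": res["model"], "scores": res["scores"], "true": res["true"],
    }


def loss_shaping_study(seed: int, n_train: int = 1200, n_test: int = 400,
                       epochs: int = 12) -> dict:
    """Fidelity-weighted vs boundary-only training on matched data/seeds.

    Returns the mean absolute error on the truly-failed stratum
    (true IoU < 0.6) for both loss settings.
    """
    tr, te = make_perturbed_corpus(n_train, n_test, seed)
    ft = train_quality_model(tr, te, LossParams(0.25, 0.0, 0.6), seed, epochs=epochs)
    bn = train_quality_model(tr, te, LossParams(0.0, 1.0, 0.6), seed, epochs=epochs)
    return {"mae_below_t_ft": ft["mae_below_t"], "mae_below_t_bn": bn["mae_below_t"]}
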