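"""Evaluation battery: headline metrics, ablations, threshold sweeps.

``evaluate`` reduces a test set to an :class:`EvalReport` (MSE, binary
accuracy, specificity, sensitivity at the acceptance threshold, ROC
points and per-interval diagnostics). ``ablation_run`` trains one model
per (loss setting, data source) cell on a shared corpus with shared
seeds and tabulates the reports, sorted by accuracy descending.
``threshold_sweep_plot_data`` traces binary accuracy over a grid of
inference thresholds to check whether the best inference threshold
coincides with the target threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .losses import LossParams
from .metrics import confusion, interval_stats, regression_metrics, roc_sweep
from .model import ModelConfig, TrainConfig, build_model, predict_batch, samples_to_arrays, train

__all__ = ["EvalReport", "evaluate", "ablation_run", "threshold_sweep_plot_data"]

DATA_SOURCES = ("model_failures", "procedure", "both")


@dataclass
class EvalReport:
    mse: float
    mae: float
    accuracy: float
    specificity: float
    sensitivity: float
    roc: list = field(default_factory=list)  # (fpr, tpr, threshold)
    intervals: list = field(default_factory=list)
    setting_name: str = ""
    n: int = 0

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _scores(model_or_scores, test_set, t) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([s.iou for s in test_set], dtype=np.float64)
    if callable(getattr(model_or_scores, "forward", None)):
        preds = predict_batch(model_or_scores, test_set, threshold=t)
        p = np.array([q.score for q in preds], dtype=np.float64)
    else:
        p = np.asarray(model_or_scores, dtype=np.float64)
    return p, y


def evaluate(
    model,
    test_set,
    t_ground: float = 0.6,
    roc_thresholds=None,
    interval_edges=None,
    setting_name: str = "",
) -> EvalReport:
    """Full report for a model (or a precomputed score vector) on a test set.

    Positive class = failed segmentation, so sensitivity is the fraction
    of truly failed segmentations that are declined.
    """
    test_set = list(test_set)
    if not test_set:
        raise ValueError("evaluate requires a non-empty test set")
    pred, true = _scores(model, test_set, t_ground)
    mse, mae = regression_metrics(pred, true)
    cm = confusion(pred, true, t_ground)
    if roc_thresholds is None:
        roc_thresholds = np.linspace(0.0, 1.0, 101)
    if interval_edges is None:
        interval_edges = np.linspace(0.0, 1.0, 11)  # deciles
    pos = true < t_ground
    roc = (
        roc_sweep(pred, true, t_ground, roc_thresholds)
        if 0 < pos.sum() < pos.size
        else []
    )
    return EvalReport(
        mse=mse,
        mae=mae,
        accuracy=cm.accuracy,
        specificity=cm.specificity,
        sensitivity=cm.sensitivity,
        roc=roc,
        intervals=interval_stats(pred, true, interval_edges, t=t_ground),
        setting_name=setting_name,
        n=len(test_set),
    )


def threshold_sweep_plot_data(
    model, test_set, t_ground: float = 0.6, grid=None
) -> tuple[pd.DataFrame, float]:
    """Accuracy versus inference threshold, plus the argmax threshold.

    The grid always contains ``t_ground`` so the argmax accuracy is at
    least the accuracy at the target threshold.
    """
    test_set = list(test_set)
    pred, true = _scores(model, test_set, t_ground)
    if grid is None:
        grid = np.linspace(0.05, 0.95, 91)
    grid = np.unique(np.append(np.asarray(grid, dtype=np.float64), t_ground))
    rows = []
    for s in grid:
        acc = float(np.mean((pred >= s) == (true >= t_ground)))
        rows.append({"threshold": float(s), "accuracy": acc})
    df = pd.DataFrame(rows)
    best = float(df.loc[df["accuracy"].idxmax(), "threshold"])
    return df, best


def _concat_sources(corpus: dict, source: str):
    if source == "both":
        return list(corpus["model_failures"]) + list(corpus["procedure"])
    return list(corpus[source])


def ablation_run(
    settings: dict[str, LossParams],
    corpus: dict,
    test_set,
    model_config: ModelConfig,
    train_config: TrainConfig,
    data_sources=DATA_SOURCES,
    t_ground: float = 0.6,
    val_fraction: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/evaluate a grid of (loss setting, data source) cells.

    *corpus* maps ``model_failures`` and ``procedure`` to training
    sample lists; ``both`` trains on their concatenation. Every cell
    shares the same corpus, test set and seeds, so rows are comparable;
    the returned table mirrors the loss-ablation presentation (one row
    per cell with MSE/accuracy/specificity/sensitivity, sorted by
    accuracy descending).
    """
    missing = {s for s in data_sources if s != "both"} - set(corpus)
    if missing:
        raise ValueError(f"corpus lacks data sources {sorted(missing)}")
    test_set = list(test_set)
    rows = []
    for source in data_sources:
        pool = _concat_sources(corpus, source)
        if not pool:
            raise ValueError(f"data source {source!r} is empty")
        rng_split = np.random.default_rng(seed)
        order = rng_split.permutation(len(pool))
        n_val = max(1, int(round(val_fraction * len(pool))))
        val = [pool[i] for i in order[:n_val]]
        tr = [pool[i] for i in order[n_val:]]
        xtr = samples_to_arrays(tr)
        xva = samples_to_arrays(val)
        for name, lp in settings.items():
            model = build_model(model_config, rng=np.random.default_rng(seed))
            model, _ = train(
                model, xtr, xva, lp, train_config, rng=np.random.default_rng(seed + 1)
            )
            rep = evaluate(model, test_set, t_ground, setting_name=f"{name} | {source}")
            rows.append(
                {
                    "setting": name,
                    "source": source,
                    "mse": rep.mse,
                    "accuracy": rep.accuracy,
                    "specificity": rep.specificity,
                    "sensitivity": rep.sensitivity,
                    "n_train": len(tr),
                    "n_test": rep.n,
                }
            )
    df = pd.DataFrame(rows).sort_values("accuracy", ascending=False, ignore_index=True)
    return df
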