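"""Confusion-matrix metrics and the single-task vs multi-task ablation.

Class 1 (illness) is the positive class throughout. Accuracy, sensitivity
TP/(TP+FN) and specificity TN/(TN+FP) follow the usual definitions; a
zero-denominator metric is reported as None with a reason, never as 0 (0
would silently bias arm comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import TaskDataset
from .multitask_model import ModelConfig, MultiTaskModel
from .training import TrainConfig, split_dataset, train


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    counts: ConfusionCounts
    task_name: str = ""
    undefined_reasons: dict = None

    def to_dict(self) -> dict:
        return {
            "task_name": self.task_name,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "counts": {
                "tp": self.counts.tp, "tn": self.counts.tn,
                "fp": self.counts.fp, "fn": self.counts.fn,
            },
            "undefined_reasons": self.undefined_reasons or {},
        }


def confusion(pred_labels, true_labels) -> ConfusionCounts:
    """Count TP/TN/FP/FN with class 1 positive."""
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    for name, arr in (("pred", pred), ("true", true)):
        if not np.all(np.isin(arr, (0, 1))):
            raise ValueError(f"{name} labels must be 0 or 1")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


def metrics(c: ConfusionCounts, task_name: str = "") -> MetricsReport:
    """Accuracy / sensitivity / specificity from counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    reasons: dict[str, str] = {}
    acc = (c.tp + c.tn) / c.total
    if c.tp + c.fn > 0:
        sens = c.tp / (c.tp + c.fn)
    else:
        sens, reasons["sensitivity"] = None, "no positive samples (TP+FN = 0)"
    if c.tn + c.fp > 0:
        spec = c.tn / (c.tn + c.fp)
    else:
        spec, reasons["specificity"] = None, "no negative samples (TN+FP = 0)"
    return MetricsReport(acc, sens, spec, c, task_name, reasons)


def evaluate_model(model: MultiTaskModel, test_sets: list[TaskDataset]) -> list[MetricsReport]:
    """Per-task metrics of a trained model on held-out datasets."""
    reports = []
    for ds in test_sets:
        pred = model.predict(ds.stacked(), ds.task_index)
        reports.append(metrics(confusion(pred, ds.labels()), task_name=ds.name))
    return reports


def ablation_compare(
    datasets: list[TaskDataset],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    n_seeds: int = 1,
) -> list[dict]:
    """Paired single-task vs multi-task comparison over seeds.

    For each seed both arms are trained with identical weights-init seed and
    identical train/test membership (paired design for variance reduction);
    only the sharing matrices differ (frozen identity vs learnable). Returns
    one record per seed with per-arm per-task reports and per-task accuracy
    deltas (multi minus single).
    """
    if n_seeds < 1:
        raise ValueError(f"n_seeds must be >= 1, got {n_seeds}")
    seeds = [
        int(s) for s in
        np.random.SeedSequence(train_cfg.seed).generate_state(n_seeds) % (2**31)
    ]
    results = []
    for seed in seeds:
        cfg = replace(train_cfg, seed=seed)
        splits = [split_dataset(ds, cfg) for ds in datasets]
        train_sets = [tr for tr, _ in splits]
        test_sets = [te for _, te in splits]
        record: dict = {"seed": seed}
        for arm, single in (("single", True), ("multi", False)):
            arm_cfg = replace(cfg, single_task=single)
            model, _ = train(model_cfg, arm_cfg, train_sets)
            record[arm] = [r.to_dict() for r in evaluate_model(model, test_sets)]
        record["delta_accuracy"] = [
            m["accuracy"] - s["accuracy"]
            for m, s in zip(record["multi"], record["single"], strict=True)
        ]
        results.append(record)
    return results


def summarize_ablation(results: list[dict]) -> dict:
    """Mean per-arm accuracy per task and mean delta across seeds."""
    d = len(results[0]["single"])
    out = {"n_seeds": len(results), "tasks": []}
    for t in range(d):
        single = [r["single"][t]["accuracy"] for r in results]
        multi = [r["multi"][t]["accuracy"] for r in results]
        out["tasks"].append(
            {
                "task_name": results[0]["single"][t]["task_name"],
                "single_mean_accuracy": float(np.mean(single)),
                "multi_mean_accuracy": float(np.mean(multi)),
                "mean_delta": float(np.mean(multi) - np.mean(single)),
            }
        )
    out["overall_single_mean_accuracy"] = float(
        np.mean([r["single"][t]["accuracy"] for r in results for t in range(d)])
    )
    out["overall_multi_mean_accuracy"] = float(
        np.mean([r["multi"][t]["accuracy"] for r in results for t in range(d)])
    )
    return out
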