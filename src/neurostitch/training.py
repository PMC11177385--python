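"""Optimization protocol: Adam with step-decayed learning rate, stratified
8:2 splits, per-task alternating mini-batches with a joint summed loss.

Reference defaults: Adam, initial lr 1e-5 halved every 30 epochs, 120
epochs, batch size 16. Each optimizer step accumulates the loss of one
mini-batch from every task (the shorter task's samples are cycled), so the
summed-over-tasks objective is realised exactly. All randomness (weight
init, split membership, batch order) derives from the single config seed
via named substreams.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data import TaskDataset
from .multitask_model import ModelConfig, MultiTaskModel


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    initial_lr: float = 1e-5
    decay_factor: float = 0.5
    decay_every: int = 30
    epochs: int = 120
    batch_size: int = 16
    train_frac: float = 0.8
    seed: int = 0
    single_task: bool = False
    grad_clip: float | None = None  # max global grad norm; None disables

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        for name in ("initial_lr", "decay_factor", "epochs", "batch_size", "decay_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.train_frac < 1:
            raise ValueError(f"train_frac must be in (0, 1), got {self.train_frac}")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Step decay: initial_lr * decay_factor ** floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return cfg.initial_lr * cfg.decay_factor ** (epoch // cfg.decay_every)


def split_dataset(
    ds: TaskDataset, cfg: TrainConfig, rng: np.random.Generator | None = None
) -> tuple[TaskDataset, TaskDataset]:
    """Stratified random train/test split (default 8:2), seeded-deterministic.

    Each class contributes ceil(train_frac * n_class) samples to training;
    the remainder forms the test set. Splits are disjoint. A class absent
    from either side (possible at tiny n) emits a warning, not an error.
    """
    if len(ds) < 5:
        raise ValueError(f"need >= 5 samples to split, got {len(ds)}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, ds.task_index)))
    labels = ds.labels()
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_train = math.ceil(cfg.train_frac * len(idx))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    for side, name in ((train_idx, "train"), (test_idx, "test")):
        present = {labels[i] for i in side}
        if present != {0, 1}:
            warnings.warn(
                f"task {ds.task_index}: class(es) {sorted({0, 1} - present)} "
                f"absent from {name} split", stacklevel=2,
            )
    make = lambda idx: TaskDataset(
        task_index=ds.task_index,
        samples=[ds.samples[i] for i in sorted(idx)],
        name=ds.name,
    )
    return make(train_idx), make(test_idx)


class Adam:
    """Adam over a flat name -> array parameter dict."""

    def __init__(self, names, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.names = list(names)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(params[k]) for k in self.names}
        self.v = {k: np.zeros_like(params[k]) for k in self.names}

    def step(self, params, grads, lr) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k in self.names:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def _clip_grads(grads: dict[str, np.ndarray], names, max_norm: float) -> None:
    total = math.sqrt(sum(float(np.sum(grads[k] ** 2)) for k in names))
    if total > max_norm:
        scale = max_norm / total
        for k in names:
            grads[k] *= scale


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    datasets: list[TaskDataset],
) -> tuple[MultiTaskModel, list[dict]]:
    """Train the multi-task model on already-split training datasets.

    Returns (model, history): one history entry per (epoch, task) with the
    summed training loss and the learning rate in force. ``single_task=True``
    freezes every sharing matrix at the identity, yielding D decoupled
    columns trained jointly — the single-task ablation arm. A non-finite
    loss aborts with a diagnostic (gradient explosion).
    """
    if len(datasets) != model_cfg.D:
        raise ValueError(
            f"model expects D={model_cfg.D} datasets, got {len(datasets)}"
        )
    ss = np.random.SeedSequence(train_cfg.seed)
    init_ss, batch_ss = ss.spawn(2)
    model = MultiTaskModel(
        model_cfg,
        rng=np.random.default_rng(init_ss),
        freeze_sharing=train_cfg.single_task,
    )
    batch_rng = np.random.default_rng(batch_ss)

    stacks = {}
    for ds in datasets:
        x = ds.stacked()
        if x.shape[1:] != (model_cfg.T, model_cfg.N):
            raise ValueError(
                f"task {ds.task_index} samples are {x.shape[1:]}, model wants "
                f"({model_cfg.T}, {model_cfg.N}); harmonize first"
            )
        stacks[ds.task_index] = (x, ds.labels())

    names = model.trainable_names()
    opt = Adam(names, model.params)
    bs = train_cfg.batch_size
    steps_per_epoch = max(
        math.ceil(len(y) / bs) for _, y in stacks.values()
    )
    history: list[dict] = []
    for epoch in range(train_cfg.epochs):
        lr = lr_schedule(epoch, train_cfg)
        # fresh shuffled (cycled) index stream per task per epoch
        orders = {}
        for d, (x, y) in stacks.items():
            n = len(y)
            reps = math.ceil(steps_per_epoch * bs / n)
            idx = np.concatenate([batch_rng.permutation(n) for _ in range(reps)])
            orders[d] = idx
        epoch_loss = {d: 0.0 for d in stacks}
        for step in range(steps_per_epoch):
            batches = {}
            for d, (x, y) in stacks.items():
                take = orders[d][step * bs : (step + 1) * bs]
                batches[d] = (x[take], y[take])
            total, grads, per_task = model.loss_and_grads(batches)
            if not math.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step} "
                    f"(per-task: {per_task}); possible gradient explosion — "
                    "consider grad_clip"
                )
            if train_cfg.grad_clip is not None:
                _clip_grads(grads, names, train_cfg.grad_clip)
            opt.step(model.params, grads, lr)
            for d, v in per_task.items():
                epoch_loss[d] += v
        for d in sorted(stacks):
            history.append(
                {"epoch": epoch, "task": d, "loss": epoch_loss[d], "lr": lr}
            )
    return model, history
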