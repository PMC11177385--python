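"""Multi-task model: D transformer columns coupled by cross-stitch sharing.

Every input sample (after positional encoding) is forwarded through ALL D
task columns simultaneously. After each of the L layers the D feature
stacks are linearly recombined by a learnable D x D mixing matrix M (the
"cross-stitch" operation): column d's next-layer input is

    f_d^{l+1} = sum_j M[j, d] * f~_j^l

so M[j, d] weights the path from column j into column d, and M = I
decouples the columns exactly — the multi-task forward then equals D
independent single-task forwards with the same weights. That identity is
the exactness guarantee behind the single-task/multi-task ablation.

Each task has its own 3-layer fully-connected head (flattened T*N ->
4096 -> 2048 -> 2 by default) ending in a softmax; the joint objective is
the sum over tasks and samples of the negative log probability of the true
class.

The model is plain NumPy; gradients are handwritten reverse-mode and are
checked against finite differences in the test suite.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .encoding import positional_encoding
from .transformer_core import init_layer_params, layer_forward, layer_backward

_EPS = 1e-12
_LAYER_PARAM_NAMES = ("Wq", "bq", "Wk", "bk", "Wv", "bv", "Wf", "bf")
CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference protocol: L = 5 attention layers and a
    4096/2048/2 fully-connected head.
    """

    D: int
    T: int
    N: int
    L: int = 5
    head_dims: tuple[int, int] = (4096, 2048)
    scaled_attention: bool = False
    sharing_init: str = "near_identity"  # or "identity"

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError(f"D must be >= 1, got {self.D}")
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if self.T < 2 or self.N < 2:
            raise ValueError(f"need T >= 2 and N >= 2, got T={self.T}, N={self.N}")
        if self.sharing_init not in ("near_identity", "identity"):
            raise ValueError(f"unknown sharing_init {self.sharing_init!r}")
        self.head_dims = tuple(int(h) for h in self.head_dims)


def share_features(features: list[np.ndarray], m: np.ndarray) -> list[np.ndarray]:
    """Cross-stitch mixing: output d = sum_j m[j, d] * features[j].

    ``features`` is a list of D equally-shaped arrays; ``m`` is D x D.
    Setting an off-diagonal entry to zero removes that cross-task path;
    m = I returns the inputs exactly.
    """
    m = np.asarray(m, dtype=float)
    d = len(features)
    if m.shape != (d, d):
        raise ValueError(f"mixing matrix must be {d}x{d}, got {m.shape}")
    shapes = {np.asarray(f).shape for f in features}
    if len(shapes) > 1:
        raise ValueError(f"feature stacks differ in shape: {shapes}")
    stack = np.stack([np.asarray(f, dtype=float) for f in features])
    mixed = np.einsum("jd,j...->d...", m, stack)
    return [mixed[i] for i in range(d)]


def joint_loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Summed cross-entropy: -sum_i log p_i[y_i], probabilities clamped at 1e-12."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"predictions must be (m, 2), got {p.shape}")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be 0 or 1")
    p_true = np.clip(p[np.arange(len(y)), y.astype(int)], _EPS, 1.0)
    return float(-np.log(p_true).sum())


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class MultiTaskModel:
    """D-column attention network with per-layer cross-stitch sharing.

    Parameters live in a flat name -> ndarray dict (``self.params``) so the
    optimizer and finite-difference checks can treat the model generically:
    ``layer{l}_task{d}_{w}`` for column weights, ``M{l}`` for the sharing
    matrices, ``head{d}_{W|b}{1..3}`` for the prediction heads.
    """

    def __init__(
        self,
        config: ModelConfig,
        rng: np.random.Generator | int | None = None,
        freeze_sharing: bool = False,
    ) -> None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.config = config
        self.freeze_sharing = bool(freeze_sharing)
        self.pe = positional_encoding(config.T, config.N)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(rng)

    # -- initialisation -------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        for layer in range(cfg.L):
            for d in range(cfg.D):
                lp = init_layer_params(cfg.N, rng)
                for name, arr in lp.items():
                    self.params[f"layer{layer}_task{d}_{name}"] = arr
            self.params[f"M{layer}"] = self._init_sharing()
        in_dim = cfg.T * cfg.N
        h1, h2 = cfg.head_dims
        for d in range(cfg.D):
            self.params[f"head{d}_W1"] = self._fan_in(rng, in_dim, (in_dim, h1))
            self.params[f"head{d}_b1"] = np.zeros(h1)
            self.params[f"head{d}_W2"] = self._fan_in(rng, h1, (h1, h2))
            self.params[f"head{d}_b2"] = np.zeros(h2)
            self.params[f"head{d}_W3"] = self._fan_in(rng, h2, (h2, 2))
            self.params[f"head{d}_b3"] = np.zeros(2)

    def _init_sharing(self) -> np.ndarray:
        d = self.config.D
        if self.freeze_sharing or self.config.sharing_init == "identity" or d == 1:
            return np.eye(d)
        # start near single-task; let training discover how much to share
        m = np.full((d, d), 0.1 / (d - 1))
        np.fill_diagonal(m, 0.9)
        return m

    @staticmethod
    def _fan_in(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    def trainable_names(self) -> list[str]:
        """Parameter names updated by the optimizer (sharing skipped if frozen)."""
        return [
            k for k in self.params
            if not (self.freeze_sharing and k.startswith("M"))
        ]

    # -- forward --------------------------------------------------------

    def _columns_forward(self, x: np.ndarray, with_cache: bool = False):
        """Run (B, T, N) inputs through all D columns with per-layer sharing."""
        cfg = self.config
        f = [x + self.pe for _ in range(cfg.D)]
        caches = []  # per layer: (list of column caches, list of pre-share outs)
        for layer in range(cfg.L):
            outs, ccaches = [], []
            for d in range(cfg.D):
                o, c = layer_forward(
                    f[d], self._layer_params(layer, d), cfg.scaled_attention
                )
                outs.append(o)
                ccaches.append(c)
            f = share_features(outs, self.params[f"M{layer}"])
            if with_cache:
                caches.append((ccaches, outs))
        return (f, caches) if with_cache else f

    def _layer_params(self, layer: int, d: int) -> dict[str, np.ndarray]:
        pre = f"layer{layer}_task{d}_"
        return {w: self.params[pre + w] for w in _LAYER_PARAM_NAMES}

    def _head_forward(self, feat: np.ndarray, d: int, with_cache: bool = False):
        flat = feat.reshape(feat.shape[0], -1)
        pre = f"head{d}_"
        z1 = flat @ self.params[pre + "W1"] + self.params[pre + "b1"]
        h1 = np.maximum(z1, 0.0)
        z2 = h1 @ self.params[pre + "W2"] + self.params[pre + "b2"]
        h2 = np.maximum(z2, 0.0)
        logits = h2 @ self.params[pre + "W3"] + self.params[pre + "b3"]
        probs = _softmax_rows(logits)
        if with_cache:
            return probs, {"flat": flat, "z1": z1, "h1": h1, "z2": z2, "h2": h2}
        return probs

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        """Class probabilities from every task head for input(s) ``x``.

        ``x`` is one harmonized T x N matrix or a batch (B, T, N). Returns a
        list of D arrays of shape (B, 2); each row sums to 1.
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[-2:] != (self.config.T, self.config.N):
            raise ValueError(
                f"input shape {x.shape[-2:]} does not match model "
                f"(T={self.config.T}, N={self.config.N}); harmonize first"
            )
        feats = self._columns_forward(x)
        probs = [self._head_forward(feats[d], d) for d in range(self.config.D)]
        if single:
            probs = [p[0] for p in probs]
        return probs

    def predict_proba(self, x: np.ndarray, task: int) -> np.ndarray:
        """Probabilities from task ``task``'s head only."""
        return self.forward(x)[task]

    def predict(self, x: np.ndarray, task: int) -> np.ndarray:
        """Hard labels from task ``task``'s head; a (0.5, 0.5) tie predicts 0."""
        p = np.atleast_2d(self.predict_proba(x, task))
        return (p[:, 1] > 0.5).astype(int)

    def forward_single_column(self, x: np.ndarray, d: int) -> np.ndarray:
        """Forward through column ``d`` alone, ignoring sharing entirely.

        Used to verify the identity-reduction property: with every sharing
        matrix equal to I this matches :meth:`forward`'s task-d output.
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        f = x + self.pe
        for layer in range(self.config.L):
            f, _ = layer_forward(
                f, self._layer_params(layer, d), self.config.scaled_attention
            )
        p = self._head_forward(f, d)
        return p[0] if single else p

    # -- loss and gradients ---------------------------------------------

    def loss_and_grads(
        self, batches: dict[int, tuple[np.ndarray, np.ndarray]]
    ) -> tuple[float, dict[str, np.ndarray], dict[int, float]]:
        """Joint loss and gradients for one optimizer step.

        ``batches`` maps task index -> (X of shape (B, T, N), labels (B,)).
        Each task's batch flows through all D columns; its loss is taken on
        its own head. Returns (total loss, grads keyed like ``params``,
        per-task losses).
        """
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        total = 0.0
        per_task: dict[int, float] = {}
        for d, (x, y) in batches.items():
            loss_d = self._backward_one_task(np.asarray(x, float), np.asarray(y), d, grads)
            per_task[d] = loss_d
            total += loss_d
        return total, grads, per_task

    def _backward_one_task(
        self, x: np.ndarray, y: np.ndarray, d: int, grads: dict[str, np.ndarray]
    ) -> float:
        cfg = self.config
        feats, caches = self._columns_forward(x, with_cache=True)
        probs, hcache = self._head_forward(feats[d], d, with_cache=True)

        y = y.astype(int)
        p_true = np.clip(probs[np.arange(len(y)), y], _EPS, 1.0)
        loss = float(-np.log(p_true).sum())

        # head backward (summed softmax cross-entropy)
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        pre = f"head{d}_"
        grads[pre + "W3"] += hcache["h2"].T @ dlogits
        grads[pre + "b3"] += dlogits.sum(axis=0)
        dh2 = dlogits @ self.params[pre + "W3"].T
        dz2 = dh2 * (hcache["z2"] > 0)
        grads[pre + "W2"] += hcache["h1"].T @ dz2
        grads[pre + "b2"] += dz2.sum(axis=0)
        dh1 = dz2 @ self.params[pre + "W2"].T
        dz1 = dh1 * (hcache["z1"] > 0)
        grads[pre + "W1"] += hcache["flat"].T @ dz1
        grads[pre + "b1"] += dz1.sum(axis=0)
        dflat = dz1 @ self.params[pre + "W1"].T

        # only column d's final stack receives head gradient
        dcols = [np.zeros_like(feats[j]) for j in range(cfg.D)]
        dcols[d] = dflat.reshape(feats[d].shape)

        for layer in range(cfg.L - 1, -1, -1):
            ccaches, outs = caches[layer]
            m = self.params[f"M{layer}"]
            if not self.freeze_sharing:
                gm = grads[f"M{layer}"]
                for j in range(cfg.D):
                    for k in range(cfg.D):
                        gm[j, k] += float(np.vdot(outs[j], dcols[k]))
            douts = [
                sum(m[j, k] * dcols[k] for k in range(cfg.D)) for j in range(cfg.D)
            ]
            new_dcols = []
            for j in range(cfg.D):
                dinp, lg = layer_backward(
                    douts[j], ccaches[j], self._layer_params(layer, j),
                    cfg.scaled_attention,
                )
                for w, g in lg.items():
                    grads[f"layer{layer}_task{j}_{w}"] += g
                new_dcols.append(dinp)
            dcols = new_dcols
        return loss

    # -- checkpointing ---------------------------------------------------

    def save(self, path) -> None:
        """Write a versioned checkpoint (weights + config) to ``path``."""
        meta = {
            "format_version": CHECKPOINT_FORMAT_VERSION,
            "config": asdict(self.config),
            "freeze_sharing": self.freeze_sharing,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "MultiTaskModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {meta['format_version']}"
                )
            cfg_d = meta["config"]
            cfg_d["head_dims"] = tuple(cfg_d["head_dims"])
            model = cls.__new__(cls)
            model.config = ModelConfig(**cfg_d)
            model.freeze_sharing = bool(meta["freeze_sharing"])
            model.pe = positional_encoding(model.config.T, model.config.N)
            model.params = {k: z[k] for k in z.files if k != "__meta__"}
        return model
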