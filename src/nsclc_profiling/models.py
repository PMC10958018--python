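"""Profiling models: MLP encoder with sigmoid prediction heads.

Three model variants share one architecture — an encoder of three ReLU
hidden layers (256, 128, 64 units; the 64-dim layer is the latent
representation) and one or two prediction heads, each a dropout layer
feeding a single sigmoid output neuron:

* the *expression-based* model, trained on expression z-scores;
* the *baseline genomic* model, trained on the binary mutation matrix;
* the *expression-aware genomic* model, a mutation-input model whose latent
  layer is pulled toward the (frozen) expression model's latents by an L2
  alignment penalty, trained in two phases: alignment-only warmup, then the
  task losses switched on with the alignment term kept active.

With two heads, head 0 classifies AD vs. SCC of the lung (LUAD vs. LUSC, on
lung samples only) and head 1 classifies AD vs. SCC irrespective of tissue.
Training uses Adam, class-balanced batch sampling with replacement, and
early stopping on validation loss. Everything is deterministic given the
config seed. Implemented directly on numpy arrays with explicit backprop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .cohort import CohortDataset

__all__ = [
    "ModelConfig",
    "ProfilingModel",
    "TrainingResult",
    "two_head_loss",
    "latent_alignment_loss",
    "make_train_val_split",
    "balanced_sampling_probabilities",
    "train_expression_model",
    "train_baseline_genomic",
    "train_expression_aware_model",
]

_BCE_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    hidden_sizes: tuple[int, int, int] = (256, 128, 64)
    dropout_rate: float = 0.2
    n_heads: int = 2
    learning_rate: float = 1e-4
    batch_size: int = 64
    patience_epochs: int = 20
    max_epochs: int = 500
    warmup_epochs: int = 30
    l2_align_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_heads not in (1, 2):
            raise ValueError("n_heads must be 1 or 2")
        if self.warmup_epochs > self.max_epochs:
            raise ValueError("warmup_epochs must not exceed max_epochs")
        if self.l2_align_weight < 0:
            raise ValueError("l2_align_weight must be nonnegative")

    @property
    def latent_dim(self) -> int:
        return self.hidden_sizes[-1]


class ProfilingModel:
    """MLP encoder + sigmoid heads over a fixed feature space.

    Parameters live in ``self.params``: encoder weights ``W1..W3``/``b1..b3``
    and per-head weights ``v{k}``/``c{k}``. Dropout is applied to the latent
    input of each head during training only; evaluation-mode forward passes
    are deterministic.
    """

    def __init__(
        self,
        n_features: int,
        config: ModelConfig,
        modality: str,
        rng: np.random.Generator,
    ):
        self.n_features = n_features
        self.config = config
        self.modality = modality
        h1, h2, h3 = config.hidden_sizes
        self.params: dict[str, np.ndarray] = {}
        fan_in = n_features
        for i, h in enumerate((h1, h2, h3), start=1):
            # He initialization for the ReLU layers
            self.params[f"W{i}"] = rng.standard_normal((fan_in, h)) * np.sqrt(2.0 / fan_in)
            self.params[f"b{i}"] = np.zeros(h)
            fan_in = h
        for k in range(config.n_heads):
            self.params[f"v{k}"] = rng.standard_normal(h3) * np.sqrt(1.0 / h3)
            self.params[f"c{k}"] = np.zeros(1)

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    # -- forward passes --------------------------------------------------
    def _encode_cache(self, x: np.ndarray) -> dict[str, np.ndarray]:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_features:
            raise ValueError(
                f"expected input with {self.n_features} features, got shape {x.shape}"
            )
        p = self.params
        z1 = x @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        z3 = a2 @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        return {"x": x, "z1": z1, "a1": a1, "z2": z2, "a2": a2, "z3": z3, "a3": a3}

    def encode(self, x: np.ndarray) -> np.ndarray:
        """64-dim latent representation (evaluation mode)."""
        return self._encode_cache(x)["a3"]

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return (latent, per-head scores). Scores are strictly in (0, 1).

        In training mode, inverted dropout masks the latent input of each
        head; ``rng`` is then required.
        """
        cache = self._encode_cache(x)
        latent = cache["a3"]
        scores = []
        for k in range(self.config.n_heads):
            head_in = latent
            if training and self.config.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training-mode forward requires an rng for dropout")
                keep = 1.0 - self.config.dropout_rate
                head_in = latent * (rng.random(latent.shape) < keep) / keep
            logit = head_in @ self.params[f"v{k}"] + self.params[f"c{k}"][0]
            scores.append(_sigmoid(logit))
        return latent, scores

    def predict_lung(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode lung-head (LUAD-vs-LUSC) scores."""
        return self.forward(x)[1][0]

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(scores: np.ndarray, labels: np.ndarray) -> float:
    s = np.clip(scores, _BCE_EPS, 1.0 - _BCE_EPS)
    return float(-np.mean(labels * np.log(s) + (1.0 - labels) * np.log(1.0 - s)))


def two_head_loss(
    scores_lung: np.ndarray | None,
    scores_pan: np.ndarray | None,
    labels: np.ndarray,
    lung_mask: np.ndarray,
) -> float:
    """Sum of the two binary cross-entropy terms.

    The pan-tissue head is averaged over all samples; the lung head over
    lung samples only. A batch with no lung samples contributes only the pan
    term. Labels: 1 = AD/LUAD, 0 = SCC/LUSC.
    """
    labels = np.asarray(labels, dtype=float)
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if labels.size == 0:
        raise ValueError("empty batch")
    loss = 0.0
    if scores_pan is not None:
        loss += _bce(np.asarray(scores_pan, dtype=float), labels)
    if scores_lung is not None and lung_mask.any():
        loss += _bce(np.asarray(scores_lung, dtype=float)[lung_mask], labels[lung_mask])
    return loss


def latent_alignment_loss(latent_mut: np.ndarray, latent_expr: np.ndarray) -> float:
    """Mean over samples of the squared Euclidean distance between paired
    latent vectors (sum over the 64 coordinates, mean over rows)."""
    a = np.asarray(latent_mut, dtype=float)
    b = np.asarray(latent_expr, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"latent shapes differ: {a.shape} vs {b.shape}")
    return float(np.mean(np.sum((a - b) ** 2, axis=1)))


@dataclass
class TrainingResult:
    model: ProfilingModel
    train_loss: list[float]
    val_loss: list[float]
    selected_epoch: int
    config: ModelConfig = field(repr=False, default=None)


def make_train_val_split(
    strata: np.ndarray, val_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split into (train, validation)."""
    idx = np.arange(len(strata))
    train, val = train_test_split(
        idx, test_size=val_fraction, random_state=seed, stratify=strata
    )
    return np.sort(train), np.sort(val)


def balanced_sampling_probabilities(y_train: np.ndarray) -> np.ndarray:
    """Per-sample draw probabilities of the weighted random sampler:
    inverse class frequency, so both classes are drawn equally often in
    expectation regardless of imbalance."""
    y_train = np.asarray(y_train, dtype=float)
    p = np.empty_like(y_train)
    for c in np.unique(y_train):
        p[y_train == c] = 1.0 / np.sum(y_train == c)
    return p / p.sum()


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _batch_step(
    model: ProfilingModel,
    x: np.ndarray,
    y: np.ndarray,
    lung: np.ndarray,
    teacher_latents: np.ndarray | None,
    align_weight: float,
    task_active: bool,
    rng: np.random.Generator,
) -> tuple[float, dict[str, np.ndarray]]:
    """One forward/backward pass; returns (loss, gradients)."""
    cfg = model.config
    p = model.params
    cache = model._encode_cache(x)
    a3 = cache["a3"]
    nb = x.shape[0]

    grads = {k: np.zeros_like(v) for k, v in p.items()}
    d_a3 = np.zeros_like(a3)
    loss = 0.0

    if task_active:
        # head supports: head 0 = lung samples (or all when single-head),
        # head 1 = all samples
        supports = [np.ones(nb, dtype=bool)] if cfg.n_heads == 1 else [lung, np.ones(nb, dtype=bool)]
        keep = 1.0 - cfg.dropout_rate
        for k, support in enumerate(supports):
            if cfg.dropout_rate > 0:
                mask = (rng.random(a3.shape) < keep) / keep
            else:
                mask = None
            if not support.any():
                continue
            head_in = a3 if mask is None else a3 * mask
            logit = head_in @ p[f"v{k}"] + p[f"c{k}"][0]
            s = _sigmoid(logit)
            loss += _bce(s[support], y[support])
            d_logit = np.where(support, (s - y) / support.sum(), 0.0)
            grads[f"v{k}"] += head_in.T @ d_logit
            grads[f"c{k}"] += np.array([d_logit.sum()])
            d_head_in = np.outer(d_logit, p[f"v{k}"])
            d_a3 += d_head_in if mask is None else d_head_in * mask

    if teacher_latents is not None and align_weight > 0:
        diff = a3 - teacher_latents
        loss += align_weight * float(np.mean(np.sum(diff**2, axis=1)))
        d_a3 += align_weight * 2.0 * diff / nb

    d_z3 = d_a3 * (cache["z3"] > 0)
    grads["W3"] += cache["a2"].T @ d_z3
    grads["b3"] += d_z3.sum(axis=0)
    d_a2 = d_z3 @ p["W3"].T
    d_z2 = d_a2 * (cache["z2"] > 0)
    grads["W2"] += cache["a1"].T @ d_z2
    grads["b2"] += d_z2.sum(axis=0)
    d_a1 = d_z2 @ p["W2"].T
    d_z1 = d_a1 * (cache["z1"] > 0)
    grads["W1"] += cache["x"].T @ d_z1
    grads["b1"] += d_z1.sum(axis=0)
    return loss, grads


def _evaluate_loss(
    model: ProfilingModel,
    x: np.ndarray,
    y: np.ndarray,
    lung: np.ndarray,
    teacher_latents: np.ndarray | None,
    align_weight: float,
    task_active: bool,
) -> float:
    latent, scores = model.forward(x)
    loss = 0.0
    if task_active:
        if model.config.n_heads == 1:
            loss += _bce(scores[0], y)
        else:
            loss += two_head_loss(scores[0], scores[1], y, lung)
    if teacher_latents is not None and align_weight > 0:
        loss += align_weight * latent_alignment_loss(latent, teacher_latents)
    return loss


def train_model(
    x: np.ndarray,
    labels: np.ndarray,
    lung_mask: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: ModelConfig,
    modality: str,
    teacher_latents: np.ndarray | None = None,
) -> TrainingResult:
    """Core training loop shared by all three model variants.

    With ``teacher_latents`` and a positive alignment weight, the schedule
    has two phases: alignment-only for ``warmup_epochs``, then the task
    losses are switched on (alignment kept active) and the early-stopping
    clock starts. Without a teacher (or with zero weight) this reduces
    exactly to plain task training — same code path, same random draws.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=float)
    lung_mask = np.asarray(lung_mask, dtype=bool)
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    y_train = labels[train_idx]
    if y_train.min() == y_train.max():
        raise ValueError("training set must contain both classes")
    if teacher_latents is not None and teacher_latents.shape[1] != config.latent_dim:
        raise ValueError(
            f"teacher latent dim {teacher_latents.shape[1]} != student latent dim "
            f"{config.latent_dim}"
        )

    align = teacher_latents is not None and config.l2_align_weight > 0
    warmup = config.warmup_epochs if align else 0
    rng = np.random.default_rng(config.seed)
    model = ProfilingModel(x.shape[1], config, modality, rng)
    opt = _Adam(model.params, config.learning_rate)

    # class-balanced sampling with replacement, epoch size = training size
    n_train = len(train_idx)
    p_draw = balanced_sampling_probabilities(y_train)

    tl = teacher_latents
    train_trace: list[float] = []
    val_trace: list[float] = []
    best_loss = np.inf
    best_epoch = -1
    best_params = model.copy_params()

    for epoch in range(config.max_epochs):
        task_active = epoch >= warmup
        drawn = rng.choice(train_idx, size=n_train, replace=True, p=p_draw)
        epoch_losses = []
        for start in range(0, n_train, config.batch_size):
            batch = drawn[start : start + config.batch_size]
            loss, grads = _batch_step(
                model,
                x[batch],
                labels[batch],
                lung_mask[batch],
                None if tl is None or not align else tl[batch],
                config.l2_align_weight if align else 0.0,
                task_active,
                rng,
            )
            opt.step(model.params, grads)
            epoch_losses.append(loss)
        train_trace.append(float(np.mean(epoch_losses)))
        val_trace.append(
            _evaluate_loss(
                model,
                x[val_idx],
                labels[val_idx],
                lung_mask[val_idx],
                None if tl is None or not align else tl[val_idx],
                config.l2_align_weight if align else 0.0,
                task_active,
            )
        )
        if task_active:
            # early-stopping clock runs only once the task loss is on
            if val_trace[-1] < best_loss:
                best_loss = val_trace[-1]
                best_epoch = epoch
                best_params = model.copy_params()
            elif epoch - best_epoch >= config.patience_epochs:
                break

    model.set_params(best_params)
    return TrainingResult(
        model=model,
        train_loss=train_trace,
        val_loss=val_trace,
        selected_epoch=best_epoch,
        config=config,
    )


# -- model-variant wrappers ------------------------------------------------

def _default_split(data: CohortDataset, seed: int) -> tuple[np.ndarray, np.ndarray]:
    strata = np.asarray(
        [f"{h}|{int(l)}" for h, l in zip(data.histology, data.is_lung)], dtype=object
    )
    return make_train_val_split(strata, 0.2, seed)


def train_expression_model(
    data: CohortDataset,
    config: ModelConfig,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
) -> TrainingResult:
    """Expression-based profiling model (the teacher)."""
    if train_idx is None or val_idx is None:
        train_idx, val_idx = _default_split(data, config.seed)
    return train_model(
        data.expression_matrix, data.labels, data.is_lung,
        train_idx, val_idx, config, modality="expression",
    )


def train_baseline_genomic(
    data: CohortDataset,
    config: ModelConfig,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
) -> TrainingResult:
    """Baseline genomic profiling model on the binary mutation matrix."""
    if train_idx is None or val_idx is None:
        train_idx, val_idx = _default_split(data, config.seed)
    return train_model(
        data.mutation_matrix.astype(float), data.labels, data.is_lung,
        train_idx, val_idx, config, modality="mutation",
    )


def train_expression_aware_model(
    data: CohortDataset,
    teacher: ProfilingModel,
    config: ModelConfig,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
) -> TrainingResult:
    """Expression-aware genomic model: mutation inputs, latents regularized
    toward the frozen expression teacher's latents."""
    if teacher.latent_dim != config.latent_dim:
        raise ValueError(
            f"teacher latent dim {teacher.latent_dim} != student latent dim "
            f"{config.latent_dim}"
        )
    if train_idx is None or val_idx is None:
        train_idx, val_idx = _default_split(data, config.seed)
    teacher_latents = teacher.encode(data.expression_matrix)
    return train_model(
        data.mutation_matrix.astype(float), data.labels, data.is_lung,
        train_idx, val_idx, config, modality="mutation",
        teacher_latents=teacher_latents,
    )
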