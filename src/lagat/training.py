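"""Losses, negative sampling, cross-validation protocol and the optimizer loop.

The evaluation protocol mirrors the standard KG-based DDI setup: negatives
drawn 1:1 from unobserved drug pairs (binary task only), 5-fold
cross-validation where the held-out fold is split in half into validation
and test, Adam with L2 weight decay, and best-epoch selection on the
validation criterion (ROC-AUC for binary, accuracy for multi-class).
Subgraphs are re-sampled freshly for every batch during training (a
stochastic regularizer); evaluation uses one fixed-seed sample per pair so
metrics are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skm

from .autodiff import Tensor, log
from .kg_io import DDIDataset, KnowledgeGraph
from .model import ModelConfig, ModelParams, forward_batch, init_params
from .sampling import sample_subgraph

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "MetricsReport",
    "bce_loss",
    "ce_loss_multiclass",
    "compute_metrics",
    "negative_sample",
    "make_splits",
    "train",
    "train_fold",
    "evaluate",
    "predict_pairs",
]

CLAMP_EPS = 1e-7  # floor/ceiling for log arguments


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published setting)."""

    batch_size: int = 1024
    lr: float = 1e-2
    l2_weight: float = 1e-7
    epochs: int = 50
    n_folds: int = 5
    seed: int = 0
    eval_seed: int = 1234  # fixed subgraph sample used for val/test scoring

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.n_folds) < 1 or self.lr < 0:
            raise ValueError("batch_size, epochs and n_folds must be positive; lr >= 0")
        if self.l2_weight < 0:
            raise ValueError("l2_weight must be >= 0")


@dataclass
class SplitPlan:
    """Per-fold (train, val, test) indices into a dataset's pair list."""

    n_folds: int
    folds: list[dict[str, np.ndarray]]

    def __iter__(self):
        return iter(self.folds)


@dataclass
class MetricsReport:
    """Per-fold metric dicts plus their mean and standard deviation."""

    per_fold: list[dict[str, float]]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_fold and not self.mean:
            keys = self.per_fold[0].keys()
            self.mean = {k: float(np.mean([f[k] for f in self.per_fold])) for k in keys}
            self.sd = {k: float(np.std([f[k] for f in self.per_fold])) for k in keys}


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def bce_loss(predicted: np.ndarray, labels: np.ndarray) -> float:
    """Binary cross-entropy, summed over the batch.

    Predictions are clamped to [eps, 1-eps] before the logarithm.
    """
    p = np.clip(np.atleast_1d(np.asarray(predicted, dtype=np.float64)), CLAMP_EPS, 1 - CLAMP_EPS)
    y = np.atleast_1d(np.asarray(labels, dtype=np.float64))
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {y.shape}")
    return float(np.sum(-y * np.log(p) - (1 - y) * np.log(1 - p)))


def ce_loss_multiclass(predicted: np.ndarray, labels: np.ndarray) -> float:
    """Categorical cross-entropy of softmax outputs, summed over the batch."""
    p = np.asarray(predicted, dtype=np.float64)
    if p.ndim == 1:
        p = p[None, :]
    y = np.atleast_1d(np.asarray(labels))
    if np.any(y < 0) or np.any(y >= p.shape[1]):
        raise ValueError("label out of range")
    picked = np.clip(p[np.arange(len(y)), y], CLAMP_EPS, 1.0)
    return float(-np.log(picked).sum())


def _bce_tensor(score: Tensor, labels: np.ndarray) -> Tensor:
    y = np.asarray(labels, dtype=np.float64)
    p = _clamp(score)
    return -(log(p) * y + log(1.0 - p) * (1.0 - y)).mean()


def _ce_tensor(score: Tensor, labels: np.ndarray) -> Tensor:
    onehot = np.zeros(score.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(log(_clamp(score)) * onehot).sum() * (1.0 / len(labels))


def _clamp(t: Tensor) -> Tensor:
    # straight-through clamp: value clipped, gradient passed where unclipped
    clipped = np.clip(t.data, CLAMP_EPS, 1 - CLAMP_EPS)
    inside = ((t.data > CLAMP_EPS) & (t.data < 1 - CLAMP_EPS)).astype(np.float64)
    return Tensor(clipped, _parents=((t, lambda g: g * inside),))


# ---------------------------------------------------------------------------
# protocol: negatives and folds
# ---------------------------------------------------------------------------


def negative_sample(positives: DDIDataset, rng: np.random.Generator) -> DDIDataset:
    """Add one uniformly drawn unobserved pair (label 0) per positive pair.

    Negatives are unordered drug pairs over the positive set's drugs that are
    not self-pairs, not positives and not already drawn.
    """
    if positives.num_classes != 2:
        raise ValueError("negative sampling applies to the binary task only")
    drugs = np.array(sorted(positives.drug_set), dtype=np.int64)
    n = len(positives.pairs)
    taken = {(i, j) for i, j, _ in positives.pairs}
    capacity = len(drugs) * (len(drugs) - 1) // 2 - len(taken)
    if capacity < n:
        raise ValueError(
            f"cannot draw {n} negatives: only {capacity} unobserved pairs exist"
        )
    negatives: list[tuple[int, int, int]] = []
    while len(negatives) < n:
        a, b = rng.choice(drugs, size=2, replace=False)
        key = (int(min(a, b)), int(max(a, b)))
        if key in taken:
            continue
        taken.add(key)
        negatives.append((key[0], key[1], 0))
    return DDIDataset(
        pairs=list(positives.pairs) + negatives,
        num_classes=2,
        drug_set=set(positives.drug_set),
    )


def make_splits(
    dataset: DDIDataset, n_folds: int = 5, rng: np.random.Generator | None = None
) -> SplitPlan:
    """Random K-fold plan; the held-out fold is halved into val and test.

    When the held-out fold has odd size the validation half gets the extra
    pair.
    """
    rng = rng or np.random.default_rng(0)
    n = len(dataset.pairs)
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} pairs for {n_folds} folds")
    perm = rng.permutation(n)
    chunks = np.array_split(perm, n_folds)
    folds = []
    for f in range(n_folds):
        held = chunks[f]
        train_idx = np.concatenate([chunks[g] for g in range(n_folds) if g != f])
        half = (len(held) + 1) // 2
        folds.append(
            {
                "train": np.sort(train_idx),
                "val": np.sort(held[:half]),
                "test": np.sort(held[half:]),
            }
        )
    return SplitPlan(n_folds=n_folds, folds=folds)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with additive L2 weight decay on every trainable tensor."""

    def __init__(self, params: ModelParams, lr: float, l2: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.tensors.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.tensors.items()}

    def step(self) -> None:
        self.t += 1
        for k, tensor in self.params.tensors.items():
            g = tensor.grad
            if g is None:
                continue
            g = g + self.l2 * tensor.data
            if k == "embedding":
                g[-1] = 0.0  # sentinel row stays frozen
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            tensor.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------


def _batch_subgraphs(kg, pairs, cfg: ModelConfig, rng):
    subs_u = [sample_subgraph(kg, int(p[0]), cfg.hop, cfg.neighbor_samples, rng) for p in pairs]
    subs_v = [sample_subgraph(kg, int(p[1]), cfg.hop, cfg.neighbor_samples, rng) for p in pairs]
    return subs_u, subs_v


def predict_pairs(
    params: ModelParams,
    kg: KnowledgeGraph,
    pairs: list[tuple[int, int, int]],
    seed: int = 1234,
    batch_size: int = 512,
    collect_attention: bool = False,
):
    """Score pairs with one fixed-seed subgraph sample per drug.

    Returns (scores, records): scores is (n,) probabilities for binary
    models or (n, C) distributions for multi-class.
    """
    if not pairs:
        raise ValueError("empty pair list")
    rng = np.random.default_rng(seed)
    cfg = params.config
    out, records = [], []
    arr = np.asarray([(i, j) for i, j, _ in pairs], dtype=np.int64)
    for start in range(0, len(arr), batch_size):
        chunk = arr[start : start + batch_size]
        subs_u, subs_v = _batch_subgraphs(kg, chunk, cfg, rng)
        _, _, score, recs = forward_batch(
            chunk, subs_u, subs_v, params, kg.sentinel, collect_attention
        )
        out.append(score.data)
        records.extend(recs)
    return np.concatenate(out), records


def compute_metrics(scores: np.ndarray, labels: np.ndarray, mode: str) -> dict[str, float]:
    """Task metrics from raw scores.

    Binary: ACC and F1 at threshold 0.5, ROC-AUC, AUPR (scores are
    probabilities). Multi-class: ACC and Macro-F1 over argmax of the (n, C)
    class distributions.
    """
    y = np.asarray(labels)
    if mode == "binary":
        pred = (scores >= 0.5).astype(int)
        out = {
            "acc": float(skm.accuracy_score(y, pred)),
            "f1": float(skm.f1_score(y, pred, zero_division=0)),
        }
        if len(np.unique(y)) > 1:
            out["auc"] = float(skm.roc_auc_score(y, scores))
            out["aupr"] = float(skm.average_precision_score(y, scores))
        return out
    if mode != "multi":
        raise ValueError(f"unknown mode {mode!r}")
    pred = scores.argmax(axis=1)
    return {
        "acc": float(skm.accuracy_score(y, pred)),
        "macro_f1": float(skm.f1_score(y, pred, average="macro", zero_division=0)),
    }


def evaluate(
    params: ModelParams,
    kg: KnowledgeGraph,
    pairs: list[tuple[int, int, int]],
    mode: str | None = None,
    seed: int = 1234,
) -> dict[str, float]:
    """Compute the task metrics on a pair list (fixed-seed subgraph samples)."""
    scores, _ = predict_pairs(params, kg, pairs, seed=seed)
    if mode is None:
        mode = "binary" if params.config.num_classes == 2 else "multi"
    return compute_metrics(scores, np.asarray([lbl for _, _, lbl in pairs]), mode)


def train_fold(
    kg: KnowledgeGraph,
    dataset: DDIDataset,
    split: dict[str, np.ndarray],
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed_offset: int = 0,
    verbose: bool = False,
) -> tuple[ModelParams, dict[str, float], list[float]]:
    """Train on one fold's split; return best-epoch params, test metrics, losses.

    Per-sample mean BCE (or categorical CE) is minimized; epoch-level best
    parameters are selected on the validation criterion.
    """
    cfg = model_config
    binary = cfg.num_classes == 2
    master = np.random.default_rng((train_config.seed + seed_offset) % (2**31))
    init_rng = np.random.default_rng(master.integers(2**31))
    sample_rng = np.random.default_rng(master.integers(2**31))
    shuffle_rng = np.random.default_rng(master.integers(2**31))
    params = init_params(cfg, init_rng)
    opt = Adam(params, lr=train_config.lr, l2=train_config.l2_weight)
    pairs = dataset.pairs
    train_pairs = [pairs[i] for i in split["train"]]
    val_pairs = [pairs[i] for i in split["val"]]
    best_crit, best_state = -np.inf, params.copy()
    criterion = "auc" if binary else "acc"
    epoch_losses: list[float] = []
    for epoch in range(train_config.epochs):
        order = shuffle_rng.permutation(len(train_pairs))
        total, seen = 0.0, 0
        for start in range(0, len(order), train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            batch = [train_pairs[i] for i in idx]
            arr = np.asarray([(i, j) for i, j, _ in batch], dtype=np.int64)
            labels = np.asarray([y for _, _, y in batch])
            subs_u, subs_v = _batch_subgraphs(kg, arr, cfg, sample_rng)
            _, _, score, _ = forward_batch(arr, subs_u, subs_v, params, kg.sentinel)
            loss = _bce_tensor(score, labels) if binary else _ce_tensor(score, labels)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            params.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(batch)
            seen += len(batch)
        epoch_losses.append(total / max(seen, 1))
        val_metrics = evaluate(params, kg, val_pairs, seed=train_config.eval_seed)
        crit = val_metrics.get(criterion, val_metrics["acc"])
        if crit > best_crit:
            best_crit, best_state = crit, params.copy()
        if verbose:
            print(
                f"epoch {epoch:3d}  mean loss {epoch_losses[-1]:.4f}  "
                f"val {criterion} {crit:.4f}"
            )
    test_pairs = [pairs[i] for i in split["test"]]
    test_metrics = evaluate(best_state, kg, test_pairs, seed=train_config.eval_seed)
    return best_state, test_metrics, epoch_losses


def train(
    kg: KnowledgeGraph,
    dataset: DDIDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    folds: list[int] | None = None,
    verbose: bool = False,
) -> tuple[ModelParams, MetricsReport]:
    """Cross-validated training; returns the best fold's params and the report.

    ``folds`` restricts which folds of the plan are run (all by default).
    """
    split_rng = np.random.default_rng(train_config.seed % (2**31))
    plan = make_splits(dataset, n_folds=train_config.n_folds, rng=split_rng)
    results, best = [], None
    for f, split in enumerate(plan):
        if folds is not None and f not in folds:
            continue
        params, test_metrics, _ = train_fold(
            kg, dataset, split, model_config, train_config,
            seed_offset=1000 * f, verbose=verbose,
        )
        results.append(test_metrics)
        crit = "auc" if model_config.num_classes == 2 else "acc"
        score = test_metrics.get(crit, test_metrics["acc"])
        if best is None or score > best[0]:
            best = (score, params)
    return best[1], MetricsReport(per_fold=results)
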