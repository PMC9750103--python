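"""Link-aware graph attention forward pass.

For a drug pair (u, v), each drug's sampled subgraph is propagated for H
rounds. Within u's subgraph the attention query is the *partner* drug's
initial embedding E(v) (and symmetrically E(u) inside v's subgraph), fixed
across hops. A node's attention logit for each sampled neighbor is the plain
inner product ``q . z_j``; logits are normalized with a masked softmax by
default (``raw_attention=True`` keeps the raw inner products). The
attention-weighted neighbor sum z_N is pushed through one of two aggregators,

    neighbor: LeakyReLU_0.1(W z_N + b)
    concat:   LeakyReLU_0.1(W [z_center || z_N] + b)

and with layer-wise aggregation enabled the drug's final representation
concatenates its per-hop root representations z^(0), ..., z^(H). Binary
pairs are scored with a sigmoid of the inner product of the two drug
vectors; multi-class pairs with a softmax over a two-layer perceptron on
their concatenation.

The ``gat_const`` attention mode (uniform weight on every unmasked neighbor)
is the ablation baseline: it removes link awareness while keeping the rest
of the architecture identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .sampling import SubgraphSample

__all__ = [
    "ModelConfig",
    "ModelParams",
    "AttentionRecord",
    "PairOutput",
    "init_params",
    "masked_softmax",
    "attention_weights",
    "aggregate",
    "forward_batch",
    "lagat_forward",
    "score_binary",
    "score_multiclass",
]

LEAKY_ALPHA = 0.1  # slope of LeakyReLU everywhere in the network


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``num_entities`` excludes the padding sentinel; the embedding table has
    one extra all-zero frozen row for it. ``dim``/``neighbor_samples``
    defaults follow the binary-task setting (d=64, K=64); ``hop=1`` is the
    depth used throughout.
    """

    num_entities: int
    dim: int = 64
    hop: int = 1
    neighbor_samples: int = 64
    aggregator: str = "neighbor"  # {"neighbor", "concat"}
    attention: str = "lagat"  # {"lagat", "gat_const"}
    layer_agg: bool = True
    num_classes: int = 2
    raw_attention: bool = False
    tied_weights: bool = False

    def __post_init__(self) -> None:
        if self.aggregator not in ("neighbor", "concat"):
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.attention not in ("lagat", "gat_const"):
            raise ValueError(f"unknown attention mode {self.attention!r}")
        if self.hop < 1 or self.dim < 1 or self.neighbor_samples < 1:
            raise ValueError("hop, dim and neighbor_samples must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")

    @property
    def out_dim(self) -> int:
        """Length of one drug's final vector (Eq.-style layer concatenation)."""
        return (self.hop + 1) * self.dim if self.layer_agg else self.dim


@dataclass
class ModelParams:
    """Embedding table, per-hop aggregator affine maps, optional MLP head."""

    config: ModelConfig
    tensors: dict[str, Tensor]

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def agg_weight(self, hop: int) -> tuple[Tensor, Tensor]:
        if self.config.tied_weights:
            return self.tensors["W_0"], self.tensors["b_0"]
        return self.tensors[f"W_{hop}"], self.tensors[f"b_{hop}"]

    def trainable(self) -> list[Tensor]:
        return list(self.tensors.values())

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def mask_sentinel_grad(self) -> None:
        """Keep the padding row frozen at zero."""
        g = self.tensors["embedding"].grad
        if g is not None:
            g[-1] = 0.0

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.config,
            {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.tensors.items()},
        )

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.tensors.items()}


def _xavier(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    bound = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-bound, bound, size=shape)


def init_params(config: ModelConfig, rng: np.random.Generator) -> ModelParams:
    """Glorot-uniform initialization of every layer, embedding table included."""
    d = config.dim
    tensors: dict[str, Tensor] = {}
    emb = np.zeros((config.num_entities + 1, d))
    emb[:-1] = _xavier(rng, (config.num_entities, d))  # last row = sentinel
    tensors["embedding"] = Tensor(emb, requires_grad=True)
    in_dim = 2 * d if config.aggregator == "concat" else d
    n_mats = 1 if config.tied_weights else config.hop
    for h in range(n_mats):
        tensors[f"W_{h}"] = Tensor(_xavier(rng, (in_dim, d)), requires_grad=True)
        tensors[f"b_{h}"] = Tensor(np.zeros(d), requires_grad=True)
    if config.num_classes > 2:
        width = 2 * config.out_dim
        tensors["head_W1"] = Tensor(_xavier(rng, (width, width)), requires_grad=True)
        tensors["head_b1"] = Tensor(np.zeros(width), requires_grad=True)
        tensors["head_W2"] = Tensor(
            _xavier(rng, (width, config.num_classes)), requires_grad=True
        )
        tensors["head_b2"] = Tensor(np.zeros(config.num_classes), requires_grad=True)
    return ModelParams(config, tensors)


@dataclass
class AttentionRecord:
    """Normalized attention of one center node over its K sampled neighbors."""

    pair: tuple[int, int]
    side: int  # which drug's subgraph the record belongs to
    hop: int  # propagation round (1..H)
    center_depth: int  # distance of the center from the drug
    center: int
    neighbors: np.ndarray
    weights: np.ndarray


@dataclass
class PairOutput:
    """Final drug vectors, interaction score and optional attention trace."""

    pair: tuple[int, int]
    z_u: np.ndarray
    z_v: np.ndarray
    score: float | np.ndarray
    records: list[AttentionRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# attention + aggregation primitives
# ---------------------------------------------------------------------------


def masked_softmax(logits: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Normalized exponential over unmasked entries of the last axis.

    Invariant to adding a constant to all logits; masked entries get weight
    exactly 0; an all-masked row yields the all-zero vector.
    """
    logits = np.asarray(logits, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    shifted = logits - np.max(np.where(mask, logits, -np.inf), axis=-1, initial=-np.inf, keepdims=True)
    e = np.where(mask, np.exp(np.where(mask, shifted, 0.0)), 0.0)
    denom = e.sum(axis=-1, keepdims=True)
    return np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)


def _attention_tensor(
    query: Tensor, neighbor_embs: Tensor, mask: np.ndarray, mode: str, raw: bool
) -> Tensor:
    """Differentiable attention weights; shapes (..., d), (..., K, d) -> (..., K)."""
    maskf = mask.astype(np.float64)
    if mode == "gat_const":
        counts = maskf.sum(axis=-1, keepdims=True)
        uniform = np.divide(
            maskf, counts, out=np.zeros_like(maskf), where=counts > 0
        )
        return Tensor(uniform)  # constant: no gradient through the weights
    logits = (neighbor_embs * query).sum(axis=-1)  # (..., K)
    if raw:
        return logits * maskf
    # masked softmax; the shift is a constant, so gradients are exact
    shift = np.max(np.where(mask, logits.data, -np.inf), axis=-1, initial=-np.inf, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    e = ad.exp((logits - shift) * maskf) * maskf
    denom = e.sum(axis=-1, keepdims=True)
    safe = Tensor((denom.data == 0).astype(np.float64))  # all-masked rows -> 0/1 = 0
    return e / (denom + safe)


def attention_weights(
    query: np.ndarray,
    neighbor_embs: np.ndarray,
    mode: str = "lagat",
    mask: np.ndarray | None = None,
    raw: bool = False,
) -> np.ndarray:
    """Attention of one center over K candidate neighbors.

    ``lagat``: softmax of inner products of the query (the partner drug's
    embedding) with each neighbor embedding. ``gat_const``: uniform over
    unmasked neighbors, ignoring the query.
    """
    query = np.asarray(query, dtype=np.float64)
    neighbor_embs = np.asarray(neighbor_embs, dtype=np.float64)
    if mode not in ("lagat", "gat_const"):
        raise ValueError(f"unknown attention mode {mode!r}")
    if neighbor_embs.ndim != 2 or neighbor_embs.shape[1] != query.shape[-1]:
        raise ValueError(
            f"dimension mismatch: query {query.shape} vs neighbors {neighbor_embs.shape}"
        )
    if mask is None:
        mask = np.ones(neighbor_embs.shape[0], dtype=bool)
    out = _attention_tensor(Tensor(query), Tensor(neighbor_embs), np.asarray(mask), mode, raw)
    return out.data


def aggregate(
    center_emb: np.ndarray,
    neigh_sum: np.ndarray,
    params: ModelParams,
    hop: int = 0,
    aggregator: str | None = None,
) -> np.ndarray:
    """Combine a center representation with its attention-weighted neighbor sum."""
    aggregator = aggregator or params.config.aggregator
    W, b = params.agg_weight(hop)
    center = Tensor(np.asarray(center_emb, dtype=np.float64))
    zn = Tensor(np.asarray(neigh_sum, dtype=np.float64))
    if aggregator == "neighbor":
        out = ad.leaky_relu(ad.matmul(zn.reshape(1, -1), W) + b, LEAKY_ALPHA)
    elif aggregator == "concat":
        out = ad.leaky_relu(
            ad.matmul(ad.concat([center, zn]).reshape(1, -1), W) + b, LEAKY_ALPHA
        )
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    return out.data.reshape(-1)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def _stack_layers(subs: Sequence[SubgraphSample], hops: int, k: int) -> list[np.ndarray]:
    """Node indices per depth, stacked over the batch: depth t -> (B, k**t)."""
    out = [np.array([s.root for s in subs], dtype=np.int64).reshape(-1, 1)]
    for t in range(1, hops + 1):
        out.append(np.stack([s.layers[t - 1].reshape(-1) for s in subs]))
    return out


def _propagate_side(
    params: ModelParams,
    nodes: list[np.ndarray],
    query: Tensor,
    sentinel: int,
    collect: bool,
) -> tuple[list[Tensor], list[tuple[int, int, np.ndarray]]]:
    """Run H propagation rounds over one side's layered node grids.

    Returns the root representation after every round (index 0 is the raw
    embedding) and, when collecting, (hop, depth, weights-array) traces.
    """
    cfg = params.config
    H, k, d = cfg.hop, cfg.neighbor_samples, cfg.dim
    B = nodes[0].shape[0]
    emb = params["embedding"]
    z = [ad.gather(emb, nodes[t]) for t in range(H + 1)]  # (B, k**t, d)
    masks = [nodes[t] != sentinel for t in range(H + 1)]
    root_reps = [z[0]]
    traces: list[tuple[int, int, np.ndarray]] = []
    q = query.reshape(B, 1, 1, d)
    for h in range(1, H + 1):
        new_z: list[Tensor] = []
        for t in range(H - h + 1):
            n_centers = k**t
            nb = z[t + 1].reshape(B, n_centers, k, d)
            nb_mask = masks[t + 1].reshape(B, n_centers, k)
            w = _attention_tensor(q, nb, nb_mask, cfg.attention, cfg.raw_attention)
            if collect:
                traces.append((h, t, w.data.copy()))
            zn = (nb * w.reshape(B, n_centers, k, 1)).sum(axis=2)  # (B, n_centers, d)
            W, b = params.agg_weight(h - 1)
            if cfg.aggregator == "concat":
                pre = ad.matmul(ad.concat([z[t], zn], axis=-1), W) + b
            else:
                pre = ad.matmul(zn, W) + b
            new_z.append(ad.leaky_relu(pre, LEAKY_ALPHA))
        z = new_z
        root_reps.append(z[0])
    return [r.reshape(B, d) for r in root_reps], traces


def forward_batch(
    pairs: np.ndarray,
    subs_u: Sequence[SubgraphSample],
    subs_v: Sequence[SubgraphSample],
    params: ModelParams,
    sentinel: int,
    collect_attention: bool = False,
) -> tuple[Tensor, Tensor, Tensor, list[AttentionRecord]]:
    """Differentiable batched forward pass.

    Returns (z_u, z_v, score, records) where score is a (B,) probability
    tensor for binary configs or a (B, C) softmax tensor for multi-class.
    """
    cfg = params.config
    pairs = np.asarray(pairs, dtype=np.int64)
    B = pairs.shape[0]
    for s in list(subs_u) + list(subs_v):
        if s.hops != cfg.hop or s.k != cfg.neighbor_samples:
            raise ValueError(
                f"subgraph sampled with (H={s.hops}, K={s.k}) does not match "
                f"config (H={cfg.hop}, K={cfg.neighbor_samples})"
            )
    emb = params["embedding"]
    nodes_u = _stack_layers(subs_u, cfg.hop, cfg.neighbor_samples)
    nodes_v = _stack_layers(subs_v, cfg.hop, cfg.neighbor_samples)
    q_for_u = ad.gather(emb, pairs[:, 1])  # partner embedding is the query
    q_for_v = ad.gather(emb, pairs[:, 0])
    reps_u, tr_u = _propagate_side(params, nodes_u, q_for_u, sentinel, collect_attention)
    reps_v, tr_v = _propagate_side(params, nodes_v, q_for_v, sentinel, collect_attention)
    if cfg.layer_agg:
        z_u = ad.concat(reps_u, axis=-1)
        z_v = ad.concat(reps_v, axis=-1)
    else:
        z_u, z_v = reps_u[-1], reps_v[-1]
    if cfg.num_classes == 2:
        score = ad.sigmoid((z_u * z_v).sum(axis=-1))
    else:
        score = _head_softmax(ad.concat([z_u, z_v], axis=-1), params)
    records: list[AttentionRecord] = []
    if collect_attention:
        for side, (nodes, traces) in enumerate(
            [(nodes_u, tr_u), (nodes_v, tr_v)]
        ):
            for h, t, w in traces:
                k = cfg.neighbor_samples
                centers = nodes[t]  # (B, k**t)
                nbrs = nodes[t + 1].reshape(B, k**t, k)
                for b in range(B):
                    for c in range(centers.shape[1]):
                        records.append(
                            AttentionRecord(
                                pair=(int(pairs[b, 0]), int(pairs[b, 1])),
                                side=side,
                                hop=h,
                                center_depth=t,
                                center=int(centers[b, c]),
                                neighbors=nbrs[b, c].copy(),
                                weights=w[b, c].copy(),
                            )
                        )
    return z_u, z_v, score, records


def _head_softmax(features: Tensor, params: ModelParams) -> Tensor:
    hidden = ad.leaky_relu(
        ad.matmul(features, params["head_W1"]) + params["head_b1"], LEAKY_ALPHA
    )
    logits = ad.matmul(hidden, params["head_W2"]) + params["head_b2"]
    shift = logits.data.max(axis=-1, keepdims=True)
    e = ad.exp(logits - shift)
    return e / e.sum(axis=-1, keepdims=True)


def lagat_forward(
    pair: tuple[int, int],
    sub_u: SubgraphSample,
    sub_v: SubgraphSample,
    params: ModelParams,
    sentinel: int | None = None,
    collect_attention: bool = False,
) -> PairOutput:
    """Single-pair forward pass returning plain arrays (no gradient tape)."""
    if sentinel is None:
        sentinel = params.config.num_entities
    z_u, z_v, score, records = forward_batch(
        np.array([pair]), [sub_u], [sub_v], params, sentinel, collect_attention
    )
    s = score.data[0]
    return PairOutput(
        pair=pair,
        z_u=z_u.data[0],
        z_v=z_v.data[0],
        score=float(s) if np.ndim(s) == 0 else s,
        records=records,
    )


def score_binary(z_u: np.ndarray, z_v: np.ndarray) -> float:
    """Interaction probability: sigmoid of the drug-vector inner product."""
    z_u = np.asarray(z_u, dtype=np.float64)
    z_v = np.asarray(z_v, dtype=np.float64)
    if z_u.shape != z_v.shape:
        raise ValueError(f"length mismatch: {z_u.shape} vs {z_v.shape}")
    return float(1.0 / (1.0 + np.exp(-float(z_u @ z_v))))


def score_multiclass(
    z_u: np.ndarray, z_v: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Class distribution: softmax of the MLP head on [z_u || z_v]."""
    if params.config.num_classes == 2 or "head_W1" not in params.tensors:
        raise ValueError("multi-class head not configured (binary model)")
    feats = Tensor(np.concatenate([z_u, z_v], axis=-1)[None, :])
    return _head_softmax(feats, params).data[0]
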