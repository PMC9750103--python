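"""Fixed-size uniform neighbor sampling and H-hop receptive fields.

Each drug's receptive field is a sampled tree of depth ``H``: layer ``h`` is
a ``K^h x K`` integer grid mapping every frontier node at depth ``h`` to
exactly ``K`` sampled neighbors. The grid (rather than an edge list) keeps
the attention layer a dense batched computation. When a node's true degree
is at least ``K`` the draw is uniform without replacement; when it is
smaller, every true neighbor appears at least once and the remaining slots
are resampled uniformly with replacement, so the expected multiplicity of
each neighbor is ``K / degree``. Isolated nodes yield the padding sentinel
index (``kg.sentinel``), whose embedding is frozen at zero and masked out of
the attention normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kg_io import KnowledgeGraph

__all__ = ["SubgraphSample", "sample_neighbors", "sample_subgraph"]


@dataclass
class SubgraphSample:
    """Layered neighbor grids for one drug's H-hop sampled subgraph."""

    root: int
    layers: list[np.ndarray]  # layers[h] has shape (K**h, K)
    node_universe: set[int]

    @property
    def hops(self) -> int:
        return len(self.layers)

    @property
    def k(self) -> int:
        return self.layers[0].shape[1]

    def depth_nodes(self, depth: int) -> np.ndarray:
        """Flattened node indices at a given depth (depth 0 is the root)."""
        if depth == 0:
            return np.array([self.root], dtype=np.int64)
        return self.layers[depth - 1].reshape(-1)


def sample_neighbors(
    kg: KnowledgeGraph, node: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw exactly ``k`` neighbor indices of ``node`` uniformly.

    Without replacement when degree >= k; otherwise every neighbor is
    included once and the remainder drawn with replacement (the order is
    shuffled so position carries no information). A degree-0 node (including
    the sentinel itself) returns ``k`` copies of the sentinel index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sentinel = kg.sentinel
    if node == sentinel:
        return np.full(k, sentinel, dtype=np.int64)
    if not 0 <= node < kg.num_entities:
        raise IndexError(f"entity index {node} out of range")
    nbrs = np.array([n for n, _ in kg.adjacency[node]], dtype=np.int64)
    deg = len(nbrs)
    if deg == 0:
        return np.full(k, sentinel, dtype=np.int64)
    if deg >= k:
        return rng.choice(nbrs, size=k, replace=False)
    extra = rng.choice(nbrs, size=k - deg, replace=True)
    out = np.concatenate([nbrs, extra])
    rng.shuffle(out)
    return out


def sample_subgraph(
    kg: KnowledgeGraph, drug: int, hops: int, k: int, rng: np.random.Generator
) -> SubgraphSample:
    """Build the layered H-hop sample rooted at ``drug``.

    Layer 0 holds the root's ``k`` sampled neighbors; each subsequent
    layer's frontier is the flattened previous layer, so layer ``h`` has
    ``k**h`` rows. Repeated entities are sampled independently at each grid
    position (the receptive field is a tree, not a subgraph with merged
    nodes).
    """
    if hops < 1:
        raise ValueError("hops must be >= 1")
    layers: list[np.ndarray] = []
    frontier = np.array([drug], dtype=np.int64)
    universe: set[int] = {drug}
    for _ in range(hops):
        layer = np.stack([sample_neighbors(kg, int(n), k, rng) for n in frontier])
        layers.append(layer)
        frontier = layer.reshape(-1)
        universe.update(int(n) for n in frontier if n != kg.sentinel)
    return SubgraphSample(root=drug, layers=layers, node_universe=universe)
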