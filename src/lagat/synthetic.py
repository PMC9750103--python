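"""Seeded toy knowledge graphs with a planted, attention-recoverable mechanism.

The generator emulates the shape of real drug KGs at desk scale: drug nodes
attach to a small pool of shared "bridge" entities (enzyme-like hubs, the
analogue of CYP isoforms or target families) and to many uninformative noise
entities. Interaction labels are a function of shared bridges, so both the
predictive signal and the *correct attention target* are known: a model that
conditions attention on the partner drug should place high weight on the
shared bridge, while uniform attention dilutes it among noise neighbors.

Label rules
-----------
``shared_bridge_binary``
    label 1 iff the two drugs share at least one bridge, then flipped with
    probability ``noise_rate``.
``bridge_pair_multiclass``
    class = 1 + lowest-index shared bridge, class 0 = no shared bridge.

Degrees follow the sparser of the two published KG regimes (tens of
neighbors per drug rather than hundreds), which is the regime where
fixed-size sampling covers most of a drug's neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .kg_io import DDIDataset, KnowledgeGraph, build_kg

__all__ = ["SyntheticSpec", "GroundTruth", "generate_kg", "preset", "write_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-mechanism generator."""

    n_drugs: int = 200
    n_bridge_entities: int = 10
    n_noise_entities: int = 100
    n_relations: int = 3
    edges_per_drug: int = 10
    p_bridge: float = 0.3
    label_rule: str = "shared_bridge_binary"
    noise_rate: float = 0.05
    balance: bool = True  # downsample the majority class to a 1:1 ratio
    max_pairs: int | None = None  # optional cap on the pair list size
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_bridge_entities, self.n_noise_entities,
               self.n_relations, self.edges_per_drug) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.p_bridge <= 1 and 0 <= self.noise_rate <= 1):
            raise ValueError("p_bridge and noise_rate must be in [0, 1]")
        if self.label_rule not in ("shared_bridge_binary", "bridge_pair_multiclass"):
            raise ValueError(f"unknown label rule {self.label_rule!r}")


@dataclass
class GroundTruth:
    """Causal annotation per canonical pair, for explanation recovery tests."""

    bridges: dict[tuple[int, int], list[int]]  # shared bridge entity indices
    flipped: set[tuple[int, int]]
    bridge_indices: list[int]  # entity indices of all bridge nodes


def preset(name: str, **overrides) -> SyntheticSpec:
    """Named generator settings.

    ``kegg-like``: binary labels, drug degree ~10 (sparse-KG regime).
    ``drugbank-like``: multi-class labels over a larger bridge pool.
    """
    presets = {
        "kegg-like": SyntheticSpec(),
        "drugbank-like": SyntheticSpec(
            n_drugs=150,
            n_bridge_entities=8,
            n_noise_entities=150,
            edges_per_drug=14,
            p_bridge=0.25,
            label_rule="bridge_pair_multiclass",
            max_pairs=3000,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return replace(presets[name], **overrides)


def generate_kg(spec: SyntheticSpec) -> tuple[KnowledgeGraph, DDIDataset, GroundTruth]:
    """Generate (KnowledgeGraph, DDIDataset, GroundTruth) from a spec."""
    rng = np.random.default_rng(spec.seed)
    drug_names = [f"D{i:04d}" for i in range(spec.n_drugs)]
    bridge_names = [f"B{i:03d}" for i in range(spec.n_bridge_entities)]
    noise_names = [f"N{i:04d}" for i in range(spec.n_noise_entities)]
    rel_names = [f"r{i}" for i in range(spec.n_relations)]

    triples: list[tuple[str, str, str]] = []
    attach: list[set[int]] = []  # bridge ids per drug
    for d in range(spec.n_drugs):
        bridges = set(np.flatnonzero(rng.random(spec.n_bridge_entities) < spec.p_bridge))
        attach.append(bridges)
        for b in sorted(bridges):
            rel = rel_names[rng.integers(spec.n_relations)]
            triples.append((drug_names[d], rel, bridge_names[b]))
        n_noise_edges = max(spec.edges_per_drug - len(bridges), 0)
        targets = rng.choice(
            spec.n_noise_entities,
            size=min(n_noise_edges, spec.n_noise_entities),
            replace=False,
        )
        for t in targets:
            rel = rel_names[rng.integers(spec.n_relations)]
            triples.append((drug_names[d], rel, noise_names[t]))
    kg = build_kg(triples)
    # isolated entities (noise nodes no drug picked) still get vocab slots;
    # they exercise the sentinel path in sampling
    known = set(kg.entities)
    for name in drug_names + bridge_names + noise_names:
        if name not in known:
            kg.entities.append(name)
            kg.adjacency.append([])

    # --- labels -----------------------------------------------------------
    binary = spec.label_rule == "shared_bridge_binary"
    num_classes = 2 if binary else spec.n_bridge_entities + 1
    labeled: list[tuple[int, int, int]] = []
    shared_map: dict[tuple[int, int], list[int]] = {}
    for i in range(spec.n_drugs):
        for j in range(i + 1, spec.n_drugs):
            shared = sorted(attach[i] & attach[j])
            ii, jj = kg.entity_index(drug_names[i]), kg.entity_index(drug_names[j])
            key = (min(ii, jj), max(ii, jj))
            if binary:
                label = int(bool(shared))
            else:
                label = 1 + shared[0] if shared else 0
            labeled.append((key[0], key[1], label))
            if shared:
                shared_map[key] = [kg.entity_index(bridge_names[b]) for b in shared]

    if spec.balance or (spec.max_pairs is not None and len(labeled) > spec.max_pairs):
        target = len(labeled) if spec.max_pairs is None else spec.max_pairs
        labeled = _balanced_subsample(labeled, target, num_classes, rng)

    flipped: set[tuple[int, int]] = set()
    if binary and spec.noise_rate > 0:
        out = []
        for i, j, y in labeled:
            if rng.random() < spec.noise_rate:
                y = 1 - y
                flipped.add((i, j))
            out.append((i, j, y))
        labeled = out

    drug_set = {kg.entity_index(n) for n in drug_names}
    dataset = DDIDataset(pairs=labeled, num_classes=num_classes, drug_set=drug_set)
    truth = GroundTruth(
        bridges=shared_map,
        flipped=flipped,
        bridge_indices=[kg.entity_index(n) for n in bridge_names],
    )
    return kg, dataset, truth


def _balanced_subsample(labeled, max_pairs, num_classes, rng):
    """Draw an (approximately) class-balanced subset of the labeled pairs."""
    by_class: dict[int, list] = {}
    for row in labeled:
        by_class.setdefault(row[2], []).append(row)
    present = sorted(by_class)
    if num_classes == 2:
        # exact 1:1 balance, further capped by max_pairs
        quota = min(len(rows) for rows in by_class.values())
        quota = min(quota, max_pairs // len(present))
        takes = {c: quota for c in present}
    else:
        # cap each class at an equal share; rarer classes keep all rows
        quota = max_pairs // len(present)
        takes = {c: min(quota, len(by_class[c])) for c in present}
    chosen: list = []
    for c in present:
        rows = by_class[c]
        idx = rng.choice(len(rows), size=takes[c], replace=False)
        chosen.extend(rows[i] for i in idx)
    chosen.sort()
    return chosen


def write_dataset(
    kg: KnowledgeGraph,
    dataset: DDIDataset,
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write triples.tsv, pairs.tsv and truth.tsv under ``out_dir``."""
    from .kg_io import save_ddi, save_kg

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_kg(kg, out / "triples.tsv")
    save_ddi(dataset, kg, out / "pairs.tsv")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("drug_u\tdrug_v\tshared_bridges\tflipped\n")
        for i, j, _ in dataset.pairs:
            shared = truth.bridges.get((i, j), [])
            names = ",".join(kg.entities[b] for b in shared) or "-"
            flip = int((i, j) in truth.flipped)
            fh.write(f"{kg.entities[i]}\t{kg.entities[j]}\t{names}\t{flip}\n")
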