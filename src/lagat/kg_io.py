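"""Knowledge-graph and DDI-pair file handling.

File formats follow the conventions of public KG link-prediction datasets:

* triples file — TSV, one ``head<TAB>relation<TAB>tail`` triple per line;
* DDI pair file — TSV, one ``drug<TAB>drug<TAB>label`` row per line;
* optional vocabularies — ``name<TAB>integer`` TSV (entity2id / relation2id).

Entities and relations are indexed to contiguous integers in first-appearance
order, which makes runs reproducible from identical input files. Edges are
treated as undirected for neighborhood construction: the attention layer's
neighborhood function is direction-free and relations are not used as model
features, so each triple contributes one adjacency entry on each endpoint.
Relation indices are kept alongside neighbors purely for labeling exported
attention pathways. Multi-edges between the same entity pair are preserved
(uniform neighbor sampling is therefore triple-weighted); exact duplicate
triples are kept in `triples` but collapse to a single adjacency entry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "KGFormatError",
    "KnowledgeGraph",
    "DDIDataset",
    "build_kg",
    "load_kg",
    "save_kg",
    "load_ddi",
    "save_ddi",
    "load_vocab",
    "save_vocab",
]


class KGFormatError(ValueError):
    """Raised for malformed triple/pair files or inconsistent identifiers."""


@dataclass
class KnowledgeGraph:
    """An indexed triple store with an undirected adjacency view.

    Attributes
    ----------
    entities : list of str
        Entity names; position = entity index.
    relations : list of str
        Relation names; position = relation index.
    triples : list of (int, int, int)
        (head, relation, tail) index triples, duplicates preserved.
    adjacency : list of list of (int, int)
        Per entity, the (neighbor, relation) pairs reachable through any
        unique triple touching it, in both directions.
    """

    entities: list[str]
    relations: list[str]
    triples: list[tuple[int, int, int]]
    adjacency: list[list[tuple[int, int]]]

    @property
    def num_entities(self) -> int:
        return len(self.entities)

    @property
    def num_relations(self) -> int:
        return len(self.relations)

    @property
    def sentinel(self) -> int:
        """Padding index used for isolated nodes; one past the last entity."""
        return len(self.entities)

    def entity_index(self, name: str) -> int:
        try:
            return self._entity_lookup[name]
        except AttributeError:
            self._entity_lookup = {e: i for i, e in enumerate(self.entities)}
            return self.entity_index(name)
        except KeyError:
            raise KGFormatError(f"unknown entity {name!r}") from None

    def degree(self, node: int) -> int:
        return len(self.adjacency[node])


@dataclass
class DDIDataset:
    """Labeled unordered drug pairs over a knowledge graph's entity indices."""

    pairs: list[tuple[int, int, int]]  # (drug_i, drug_j, label), i <= j
    num_classes: int
    drug_set: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        for i, j, y in self.pairs:
            if not 0 <= y < self.num_classes:
                raise KGFormatError(
                    f"label {y} out of range for {self.num_classes} classes"
                )
        if not self.drug_set:
            self.drug_set = {d for i, j, _ in self.pairs for d in (i, j)}

    def __len__(self) -> int:
        return len(self.pairs)


def _canonical(a: int, b: int, label: int) -> tuple[int, int, int]:
    return (a, b, label) if a <= b else (b, a, label)


def build_kg(
    triples: Iterable[tuple[str, str, str]], id_mode: str = "string"
) -> KnowledgeGraph:
    """Index raw (head, relation, tail) string triples into a KnowledgeGraph.

    ``id_mode="string"`` assigns contiguous indices in first-appearance order;
    ``id_mode="integer"`` interprets tokens as the indices themselves (the
    entity count is then max index + 1).
    """
    if id_mode not in ("string", "integer"):
        raise ValueError(f"unknown id_mode {id_mode!r}")
    ent_idx: dict[str, int] = {}
    rel_idx: dict[str, int] = {}
    indexed: list[tuple[int, int, int]] = []
    if id_mode == "string":
        for h, r, t in triples:
            for name in (h, t):
                if name not in ent_idx:
                    ent_idx[name] = len(ent_idx)
            if r not in rel_idx:
                rel_idx[r] = len(rel_idx)
            indexed.append((ent_idx[h], rel_idx[r], ent_idx[t]))
        entities = list(ent_idx)
        relations = list(rel_idx)
    else:
        for h, r, t in triples:
            try:
                indexed.append((int(h), int(r), int(t)))
            except ValueError as err:
                raise KGFormatError(f"non-integer ID in integer mode: {err}") from None
        n_ent = 1 + max(itertools.chain.from_iterable((h, t) for h, _, t in indexed))
        n_rel = 1 + max(r for _, r, _ in indexed)
        entities = [str(i) for i in range(n_ent)]
        relations = [str(i) for i in range(n_rel)]
    if not indexed:
        raise KGFormatError("no triples")
    adjacency: list[list[tuple[int, int]]] = [[] for _ in entities]
    for h, r, t in dict.fromkeys(indexed):  # unique triples, order kept
        adjacency[h].append((t, r))
        if t != h:
            adjacency[t].append((h, r))
    return KnowledgeGraph(entities, relations, indexed, adjacency)


def _parse_tsv3(path: str | Path, what: str) -> list[tuple[str, str, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 3:
                raise KGFormatError(
                    f"{path}: line {lineno}: expected 3 fields for a {what}, "
                    f"got {len(fields)}: {line!r}"
                )
            rows.append(tuple(fields))
    return rows


def load_kg(triples_path: str | Path, id_mode: str = "string") -> KnowledgeGraph:
    """Load a TSV triples file into an indexed KnowledgeGraph."""
    rows = _parse_tsv3(triples_path, "triple")
    if not rows:
        raise KGFormatError(f"{triples_path}: no triples")
    return build_kg(rows, id_mode=id_mode)


def save_kg(kg: KnowledgeGraph, triples_path: str | Path) -> None:
    with open(triples_path, "w") as fh:
        for h, r, t in kg.triples:
            fh.write(f"{kg.entities[h]}\t{kg.relations[r]}\t{kg.entities[t]}\n")


def load_ddi(
    pairs_path: str | Path, kg: KnowledgeGraph, num_classes: int = 2
) -> DDIDataset:
    """Load a drug<TAB>drug<TAB>label TSV, canonicalizing unordered pairs.

    Symmetric duplicates collapse to one canonical pair; a canonical pair
    appearing with two different labels is an error.
    """
    rows = _parse_tsv3(pairs_path, "DDI pair")
    seen: dict[tuple[int, int], int] = {}
    order: list[tuple[int, int]] = []
    for a, b, label_s in rows:
        try:
            label = int(label_s)
        except ValueError:
            raise KGFormatError(f"{pairs_path}: non-integer label {label_s!r}") from None
        if not 0 <= label < num_classes:
            raise KGFormatError(
                f"{pairs_path}: label {label} out of range [0, {num_classes})"
            )
        ia, ib = kg.entity_index(a), kg.entity_index(b)
        key = (ia, ib) if ia <= ib else (ib, ia)
        if key in seen:
            if seen[key] != label:
                raise KGFormatError(
                    f"{pairs_path}: pair ({a}, {b}) has conflicting labels "
                    f"{seen[key]} and {label}"
                )
        else:
            seen[key] = label
            order.append(key)
    pairs = [(i, j, seen[(i, j)]) for i, j in order]
    return DDIDataset(pairs=pairs, num_classes=num_classes)


def save_ddi(dataset: DDIDataset, kg: KnowledgeGraph, pairs_path: str | Path) -> None:
    with open(pairs_path, "w") as fh:
        for i, j, y in dataset.pairs:
            fh.write(f"{kg.entities[i]}\t{kg.entities[j]}\t{y}\n")


def load_vocab(path: str | Path) -> dict[str, int]:
    """Read a name<TAB>integer vocabulary file (entity2id / relation2id)."""
    vocab: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise KGFormatError(f"{path}: line {lineno}: expected name<TAB>id")
            vocab[fields[0]] = int(fields[1])
    return vocab


def save_vocab(names: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(names):
            fh.write(f"{name}\t{i}\n")
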