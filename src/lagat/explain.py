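"""Attention-pathway explanations.

A prediction is explained by the neighbors the attention layer concentrated
on: for each drug in a pair, the top-k (default 3) drug-adjacent neighbors
by attention weight at the final propagation round. Neighbors sampled more
than once (with-replacement resampling) have their weights summed before
ranking, so weights are per-entity. Shared neighbors of the two drugs are
annotated with the maximum of the two weights. Exports are Graphviz DOT
(node size tracks weight, top-k edges bold) and a flat TSV covering every
hop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .kg_io import KnowledgeGraph
from .model import AttentionRecord, PairOutput

__all__ = ["PathwayExport", "top_k_attention", "build_pathway", "export_pathway"]


@dataclass
class PathwayExport:
    """Top-k attention pathways for one drug pair."""

    pair: tuple[int, int]
    score: object  # float (binary) or class distribution (multi-class)
    top: dict[int, list[tuple[int, float]]]  # drug -> [(neighbor, weight)]
    shared: dict[int, float] = field(default_factory=dict)  # neighbor -> max weight
    records: list[AttentionRecord] = field(default_factory=list)


def _merge_weights(record: AttentionRecord, sentinel: int | None) -> dict[int, float]:
    acc: dict[int, float] = {}
    for n, w in zip(record.neighbors, record.weights):
        n = int(n)
        if sentinel is not None and n == sentinel:
            continue
        acc[n] = acc.get(n, 0.0) + float(w)
    return acc


def top_k_attention(
    records: list[AttentionRecord],
    drug: int,
    k: int = 3,
    sentinel: int | None = None,
) -> list[tuple[int, float]]:
    """Rank a drug's own (hop-1) neighbors by final-round attention weight.

    Duplicate sampled neighbors are merged by summing their weights; ties
    break toward the lower entity index. Returns at most ``k`` entries,
    fewer when the drug has fewer distinct sampled neighbors.
    """
    root_recs = [
        r
        for r in records
        if r.center == drug and r.center_depth == 0
    ]
    if not root_recs:
        raise ValueError(f"no attention records for drug {drug}")
    final_hop = max(r.hop for r in root_recs)
    merged: dict[int, float] = {}
    for rec in root_recs:
        if rec.hop != final_hop:
            continue
        for n, w in _merge_weights(rec, sentinel).items():
            merged[n] = merged.get(n, 0.0) + w
    ranked = sorted(merged.items(), key=lambda nw: (-nw[1], nw[0]))
    return ranked[:k]


def build_pathway(
    output: PairOutput, k: int = 3, sentinel: int | None = None
) -> PathwayExport:
    """Assemble the per-drug top-k lists and shared-neighbor annotations."""
    u, v = output.pair
    top = {
        d: top_k_attention(output.records, d, k=k, sentinel=sentinel)
        for d in (u, v)
    }
    weights_u = dict(top[u])
    weights_v = dict(top[v])
    shared = {
        n: max(weights_u[n], weights_v[n]) for n in weights_u.keys() & weights_v.keys()
    }
    return PathwayExport(
        pair=output.pair, score=output.score, top=top, shared=shared,
        records=output.records,
    )


def _relation_label(kg: KnowledgeGraph, a: int, b: int) -> str:
    for n, r in kg.adjacency[a]:
        if n == b:
            return kg.relations[r]
    return "-"


def export_pathway(
    export: PathwayExport,
    path: str | Path,
    fmt: str = "tsv",
    kg: KnowledgeGraph | None = None,
) -> None:
    """Write a pathway export as Graphviz DOT or flat TSV."""
    if fmt == "tsv":
        _export_tsv(export, path, kg)
    elif fmt == "dot":
        _export_dot(export, path, kg)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'dot' or 'tsv'")


def _name(kg: KnowledgeGraph | None, idx: int) -> str:
    return kg.entities[idx] if kg is not None else str(idx)


def _export_tsv(export: PathwayExport, path, kg) -> None:
    u, v = export.pair
    with open(path, "w") as fh:
        fh.write("pair_u\tpair_v\tside\thop\tneighbor\trelation\tweight\n")
        # top-k summary rows (hop-1 frontier)
        for side, drug in enumerate((u, v)):
            for n, w in export.top[drug]:
                rel = _relation_label(kg, drug, n) if kg is not None else "-"
                fh.write(
                    f"{_name(kg, u)}\t{_name(kg, v)}\t{side}\t1\t"
                    f"{_name(kg, n)}\t{rel}\t{w:.6f}\n"
                )
        # deeper hops: full records
        for rec in export.records:
            if rec.center_depth == 0:
                continue
            merged = _merge_weights(rec, None)
            for n, w in sorted(merged.items()):
                rel = _relation_label(kg, rec.center, n) if kg is not None else "-"
                fh.write(
                    f"{_name(kg, u)}\t{_name(kg, v)}\t{rec.side}\t"
                    f"{rec.center_depth + 1}\t{_name(kg, n)}\t{rel}\t{w:.6f}\n"
                )


def _export_dot(export: PathwayExport, path, kg) -> None:
    u, v = export.pair
    lines = ["graph pathway {", "  node [shape=circle];"]
    for d in (u, v):
        lines.append(f'  "{_name(kg, d)}" [shape=doublecircle, penwidth=2];')
    seen: set[int] = set()
    for drug in (u, v):
        for n, w in export.top[drug]:
            if n not in seen:
                seen.add(n)
                weight = export.shared.get(n, w)
                size = 0.4 + 1.6 * weight  # node size tracks attention weight
                lines.append(
                    f'  "{_name(kg, n)}" [width={size:.3f}, height={size:.3f}, '
                    f'label="{_name(kg, n)}\\n{weight:.2f}"];'
                )
            lines.append(
                f'  "{_name(kg, drug)}" -- "{_name(kg, n)}" '
                f"[penwidth={1 + 4 * w:.2f}, style=bold];"
            )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
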