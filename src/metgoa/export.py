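"""Result writers: CSV table, Cytoscape SIF network, node attributes,
impact-plot table.

The SIF network is the is_a subgraph induced by the selected terms plus all
their ancestors up to the root, so every selected term stays connected to
the root of the metabolic subtree (the shape of a GO-tree figure).  Node
size encodes significance as −log10(q) clamped to [0.5, 20]; ancestor nodes
included only for connectivity get the minimum size.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Sequence

from .model import Knowledgebase, ancestors
from .ora import FILTER_NAMES, EnrichmentResult

NODE_SIZE_MIN = 0.5
NODE_SIZE_MAX = 20.0

RESULTS_HEADER = [
    "term_id",
    "name",
    "overlap_x",
    "set_size_y",
    "gene_count",
    "p_value",
    "q_value",
    "neg_log10_p",
    "passes_all",
    *[f"pass_{name}" for name in FILTER_NAMES],
    "overlap_prefixes",
]


def _num(value: float) -> str:
    # repr of a Python float is the shortest string that round-trips exactly
    return repr(float(value))


def write_results_table(
    results: Sequence[EnrichmentResult], destination: str | Path
) -> int:
    """Write the enrichment table as RFC-4180 CSV; returns rows written."""
    destination = Path(destination)
    with open(destination, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULTS_HEADER)
        for r in results:
            writer.writerow(
                [
                    r.term_id,
                    r.term_name,
                    r.overlap_x,
                    r.set_size_y,
                    r.gene_count,
                    _num(r.p_value),
                    _num(r.q_value),
                    _num(r.neg_log10_p),
                    r.passes_all,
                    *[r.passes[name] for name in FILTER_NAMES],
                    ";".join(sorted(r.overlap_prefixes)),
                ]
            )
    return len(results)


def node_size(q_value: float, selected: bool) -> float:
    """Display size for a network node: −log10(q) clamped, or the floor for
    connectivity-only ancestors."""
    if not selected:
        return NODE_SIZE_MIN
    if q_value <= 0:
        return NODE_SIZE_MAX
    return min(max(-math.log10(q_value), NODE_SIZE_MIN), NODE_SIZE_MAX)


def export_go_network(
    kb: Knowledgebase,
    results: Sequence[EnrichmentResult],
    only_passing: bool,
    destination_sif: str | Path,
    destination_attrs: str | Path,
) -> tuple[int, int]:
    """Write the GO tree of selected terms as SIF plus a node-attribute TSV.

    Selected terms are those passing all filters when ``only_passing``,
    otherwise every tested term.  Returns (node count, edge count).
    """
    selected = {r.term_id for r in results if (r.passes_all or not only_passing)}
    nodes: set[str] = set(selected)
    for term_id in selected:
        if term_id in kb.terms:
            nodes |= ancestors(kb, term_id)

    edges: list[tuple[str, str]] = []
    for term_id in sorted(nodes):
        if term_id not in kb.terms:
            continue
        for parent in sorted(kb.terms[term_id].parent_ids):
            if parent in nodes:
                edges.append((term_id, parent))

    by_term = {r.term_id: r for r in results}
    destination_sif = Path(destination_sif)
    with open(destination_sif, "w", encoding="utf-8") as fh:
        for source, target in edges:
            fh.write(f"{source}\tis_a\t{target}\n")

    destination_attrs = Path(destination_attrs)
    with open(destination_attrs, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                "term_id",
                "name",
                "p_value",
                "q_value",
                "overlap_x",
                "set_size_y",
                "selected",
                "node_size",
            ]
        )
        for term_id in sorted(nodes):
            r = by_term.get(term_id)
            is_selected = term_id in selected
            name = (
                r.term_name
                if r is not None
                else (kb.terms[term_id].name if term_id in kb.terms else "")
            )
            writer.writerow(
                [
                    term_id,
                    name,
                    _num(r.p_value) if r else "",
                    _num(r.q_value) if r else "",
                    r.overlap_x if r else "",
                    r.set_size_y if r else "",
                    is_selected,
                    _num(node_size(r.q_value if r else 1.0, is_selected)),
                ]
            )
    return len(nodes), len(edges)


def parse_sif(path: str | Path) -> set[tuple[str, str, str]]:
    """Read a SIF file back as (source, relation, target) triples."""
    triples: set[tuple[str, str, str]] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"SIF line does not have 3 fields: {line!r}")
        triples.add((fields[0], fields[1], fields[2]))
    return triples


def write_impact_table(
    results: Sequence[EnrichmentResult], destination: str | Path
) -> int:
    """Write the impact-plot coordinates (set size vs −log10 p) as TSV."""
    from .ora import impact_table

    frame = impact_table(results)
    frame.to_csv(destination, sep="\t", index=False)
    return len(frame)
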