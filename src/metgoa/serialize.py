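"""Knowledgebase persistence.

Two dialects share one schema: a single JSON document, or a directory of
TSV tables (one file per collection) with a ``meta.json``.  The destination
suffix selects the dialect: ``*.json`` writes the document, anything else is
treated as a directory.  Output is fully deterministic — collections are
sorted — so identical builds serialize byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import ValidationError
from .model import (
    CompoundRecord,
    ECRecord,
    GeneRecord,
    GOTermRecord,
    Knowledgebase,
)

KB_SCHEMA_VERSION = "1"


def _kb_to_doc(kb: Knowledgebase, checksums: dict[str, str] | None) -> dict:
    return {
        "metadata": {
            "schema_version": KB_SCHEMA_VERSION,
            "root_id": kb.root_id,
            "propagate": kb.propagate,
            "source_checksums": dict(sorted((checksums or {}).items())),
        },
        "terms": [
            {
                "term_id": t.term_id,
                "name": t.name,
                "namespace": t.namespace,
                "parent_ids": sorted(t.parent_ids),
                "obsolete": t.obsolete,
                "alt_ids": sorted(t.alt_ids),
            }
            for _, t in sorted(kb.terms.items())
        ],
        "genes": [
            {
                "gene_id": g.gene_id,
                "tax_id": g.tax_id,
                "transcript_accessions": sorted(g.transcript_accessions),
                "protein_accessions": sorted(g.protein_accessions),
            }
            for _, g in sorted(kb.genes.items())
        ],
        "ecs": [
            {"ec": e.ec, "name": e.name, "active": e.active}
            for _, e in sorted(kb.ecs.items())
        ],
        "compounds": [
            {"prefix14": c.prefix14, "full_keys": sorted(c.full_keys), "name": c.name}
            for _, c in sorted(kb.compounds.items())
        ],
        "gene_go_edges": sorted(list(e) for e in kb.gene_go_edges),
        "gene_ec_edges": sorted(list(e) for e in kb.gene_ec_edges),
        "ec_compound_edges": sorted(list(e) for e in kb.ec_compound_edges),
        "term_genes": {t: sorted(v) for t, v in sorted(kb.term_genes.items())},
        "term_compounds": {t: sorted(v) for t, v in sorted(kb.term_compounds.items())},
        "background": sorted(kb.background),
    }


def _kb_from_doc(doc: dict) -> Knowledgebase:
    meta = doc["metadata"]
    kb = Knowledgebase(root_id=meta["root_id"], propagate=meta["propagate"])
    for t in doc["terms"]:
        kb.terms[t["term_id"]] = GOTermRecord(
            term_id=t["term_id"],
            name=t["name"],
            namespace=t["namespace"],
            parent_ids=set(t["parent_ids"]),
            obsolete=t["obsolete"],
            alt_ids=set(t["alt_ids"]),
        )
    for g in doc["genes"]:
        kb.genes[g["gene_id"]] = GeneRecord(
            gene_id=g["gene_id"],
            tax_id=g["tax_id"],
            transcript_accessions=set(g["transcript_accessions"]),
            protein_accessions=set(g["protein_accessions"]),
        )
    for e in doc["ecs"]:
        kb.ecs[e["ec"]] = ECRecord(ec=e["ec"], name=e["name"], active=e["active"])
    for c in doc["compounds"]:
        kb.compounds[c["prefix14"]] = CompoundRecord(
            prefix14=c["prefix14"], full_keys=set(c["full_keys"]), name=c["name"]
        )
    kb.gene_go_edges = {(int(g), t) for g, t in doc["gene_go_edges"]}
    kb.gene_ec_edges = {(int(g), e) for g, e in doc["gene_ec_edges"]}
    kb.ec_compound_edges = {(e, p) for e, p in doc["ec_compound_edges"]}
    kb.term_genes = {t: set(v) for t, v in doc["term_genes"].items()}
    kb.term_compounds = {t: set(v) for t, v in doc["term_compounds"].items()}
    kb.background = set(doc["background"])
    return kb


def save_kb(
    kb: Knowledgebase, destination: str | Path, checksums: dict[str, str] | None = None
) -> Path:
    """Write the KB; returns the path written."""
    destination = Path(destination)
    doc = _kb_to_doc(kb, checksums)
    if destination.suffix == ".json":
        destination.parent.mkdir(parents=True, exist_ok=True)
        destination.write_text(
            json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
        return destination
    return _save_tsv_dir(doc, destination)


def load_kb(source: str | Path) -> Knowledgebase:
    source = Path(source)
    if source.is_dir():
        doc = _load_tsv_dir(source)
    else:
        doc = json.loads(source.read_text(encoding="utf-8"))
    if doc.get("metadata", {}).get("schema_version") != KB_SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported KB schema version in {source}; expected {KB_SCHEMA_VERSION}"
        )
    return _kb_from_doc(doc)


_JOIN = ";"  # separator inside multi-valued TSV cells


def _save_tsv_dir(doc: dict, directory: Path) -> Path:
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "meta.json").write_text(
        json.dumps(doc["metadata"], indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )

    def table(name: str, header: list[str], rows: list[list]) -> None:
        lines = ["\t".join(header)]
        lines += ["\t".join(str(v) for v in row) for row in rows]
        (directory / f"{name}.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )

    table(
        "terms",
        ["term_id", "name", "namespace", "parent_ids", "obsolete", "alt_ids"],
        [
            [
                t["term_id"],
                t["name"],
                t["namespace"],
                _JOIN.join(t["parent_ids"]),
                int(t["obsolete"]),
                _JOIN.join(t["alt_ids"]),
            ]
            for t in doc["terms"]
        ],
    )
    table(
        "genes",
        ["gene_id", "tax_id", "transcript_accessions", "protein_accessions"],
        [
            [
                g["gene_id"],
                g["tax_id"],
                _JOIN.join(g["transcript_accessions"]),
                _JOIN.join(g["protein_accessions"]),
            ]
            for g in doc["genes"]
        ],
    )
    table(
        "ecs",
        ["ec", "name", "active"],
        [[e["ec"], e["name"], int(e["active"])] for e in doc["ecs"]],
    )
    table(
        "compounds",
        ["prefix14", "full_keys", "name"],
        [
            [c["prefix14"], _JOIN.join(c["full_keys"]), c["name"] or ""]
            for c in doc["compounds"]
        ],
    )
    table("gene_go_edges", ["gene_id", "term_id"], doc["gene_go_edges"])
    table("gene_ec_edges", ["gene_id", "ec"], doc["gene_ec_edges"])
    table("ec_compound_edges", ["ec", "prefix14"], doc["ec_compound_edges"])
    table(
        "term_genes",
        ["term_id", "gene_ids"],
        [[t, _JOIN.join(str(g) for g in v)] for t, v in doc["term_genes"].items()],
    )
    table(
        "term_compounds",
        ["term_id", "prefixes"],
        [[t, _JOIN.join(v)] for t, v in doc["term_compounds"].items()],
    )
    table("background", ["prefix14"], [[p] for p in doc["background"]])
    return directory


def _read_table(directory: Path, name: str) -> list[list[str]]:
    lines = (directory / f"{name}.tsv").read_text(encoding="utf-8").splitlines()
    return [line.split("\t") for line in lines[1:]]


def _split(cell: str) -> list[str]:
    return cell.split(_JOIN) if cell else []


def _load_tsv_dir(directory: Path) -> dict:
    metadata = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    return {
        "metadata": metadata,
        "terms": [
            {
                "term_id": r[0],
                "name": r[1],
                "namespace": r[2],
                "parent_ids": _split(r[3]),
                "obsolete": bool(int(r[4])),
                "alt_ids": _split(r[5]) if len(r) > 5 else [],
            }
            for r in _read_table(directory, "terms")
        ],
        "genes": [
            {
                "gene_id": int(r[0]),
                "tax_id": int(r[1]),
                "transcript_accessions": _split(r[2]) if len(r) > 2 else [],
                "protein_accessions": _split(r[3]) if len(r) > 3 else [],
            }
            for r in _read_table(directory, "genes")
        ],
        "ecs": [
            {"ec": r[0], "name": r[1], "active": bool(int(r[2]))}
            for r in _read_table(directory, "ecs")
        ],
        "compounds": [
            {
                "prefix14": r[0],
                "full_keys": _split(r[1]) if len(r) > 1 else [],
                "name": (r[2] if len(r) > 2 and r[2] else None),
            }
            for r in _read_table(directory, "compounds")
        ],
        "gene_go_edges": [
            [int(r[0]), r[1]] for r in _read_table(directory, "gene_go_edges")
        ],
        "gene_ec_edges": [
            [int(r[0]), r[1]] for r in _read_table(directory, "gene_ec_edges")
        ],
        "ec_compound_edges": _read_table(directory, "ec_compound_edges"),
        "term_genes": {
            r[0]: [int(g) for g in _split(r[1] if len(r) > 1 else "")]
            for r in _read_table(directory, "term_genes")
        },
        "term_compounds": {
            r[0]: _split(r[1] if len(r) > 1 else "")
            for r in _read_table(directory, "term_compounds")
        },
        "background": [r[0] for r in _read_table(directory, "background")],
    }
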