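"""Parse the knowledgebase source files and assemble a Knowledgebase.

Sources and their dialects:

* GO ontology — OBO 1.2/1.4 flat file (``[Term]`` stanzas; only the is_a
  relationship contributes to the hierarchy).
* Expasy ENZYME — ``enzyme.dat`` flat file, ``//``-delimited records with
  two-letter line codes; transferred/deleted entries are kept but inactive.
* NCBI ``gene2go`` / ``gene2accession`` — tab-delimited, gzip or plain.
* gene→EC and EC→InChIKey links — plain two-column TSV tables.

Assembly restricts terms to the subtree rooted at the metabolic-process term
(GO:0008152 by default) and genes to a single taxon, resolves alt_ids, drops
edges whose endpoints fall outside the restricted sets, and derives the
per-term annotation sets.  Builds are deterministic for fixed inputs.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd

from .errors import BuildError, NotFoundError, ParseError, ValidationError
from .model import (
    CompoundRecord,
    ECRecord,
    GeneRecord,
    GOTermRecord,
    GO_ID_RE,
    INCHIKEY_FULL_RE,
    INCHIKEY_PREFIX_RE,
    Knowledgebase,
    METABOLIC_PROCESS_ROOT,
    derive_annotation_sets,
)


@dataclass
class BuildConfig:
    """Source locations and restriction parameters for a KB build."""

    obo: str | Path
    enzyme_dat: str | Path
    gene2go: str | Path
    gene2accession: str | Path
    gene2ec_table: str | Path
    ec2compound_table: str | Path
    taxon: int = 9606
    root_id: str = METABOLIC_PROCESS_ROOT
    propagate: bool = True

    def source_paths(self) -> dict[str, Path]:
        return {
            "obo": Path(self.obo),
            "enzyme_dat": Path(self.enzyme_dat),
            "gene2go": Path(self.gene2go),
            "gene2accession": Path(self.gene2accession),
            "gene2ec_table": Path(self.gene2ec_table),
            "ec2compound_table": Path(self.ec2compound_table),
        }

    def validate(self) -> None:
        for name, path in self.source_paths().items():
            if not path.is_file():
                raise BuildError(f"source file for {name} not found: {path}")


@dataclass
class BuildReport:
    """Row/drop accounting for provenance; written next to the KB."""

    rows_read: dict[str, int] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)
    final_counts: dict[str, int] = field(default_factory=dict)
    built_at: str = ""

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n

    def to_text(self) -> str:
        lines = ["# knowledgebase build report"]
        if self.built_at:
            lines.append(f"built_at\t{self.built_at}")
        lines.append("## rows read")
        lines += [f"{k}\t{v}" for k, v in sorted(self.rows_read.items())]
        lines.append("## rows dropped")
        lines += [f"{k}\t{v}" for k, v in sorted(self.dropped.items())]
        lines.append("## final counts")
        lines += [f"{k}\t{v}" for k, v in sorted(self.final_counts.items())]
        return "\n".join(lines) + "\n"


def open_text(path: str | Path) -> TextIO:
    """Open a source file as text, transparently decompressing gzip."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def parse_obo(stream: Iterable[str]) -> dict[str, GOTermRecord]:
    """Read ``[Term]`` stanzas from an OBO flat file.

    Only id, name, namespace, is_a, alt_id and is_obsolete lines are used;
    other stanza types (``[Typedef]``) and tag lines are skipped.  The "!"
    comment after an is_a target is stripped.
    """
    terms: dict[str, GOTermRecord] = {}
    in_term = False
    stanza: dict = {}
    stanza_line = 0

    def flush(at_line: int) -> None:
        nonlocal stanza, in_term
        if in_term:
            if "id" not in stanza:
                raise ParseError("[Term] stanza has no id line", line=stanza_line)
            record = GOTermRecord(
                term_id=stanza["id"],
                name=stanza.get("name", ""),
                namespace=stanza.get("namespace", "biological_process"),
                parent_ids=stanza.get("is_a", set()),
                obsolete=stanza.get("is_obsolete", False),
                alt_ids=stanza.get("alt_id", set()),
            )
            terms[record.term_id] = record
        stanza = {}
        in_term = False

    lineno = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("["):
            flush(lineno)
            in_term = line.strip() == "[Term]"
            stanza_line = lineno
            continue
        if not in_term or not line.strip():
            continue
        if ":" not in line:
            raise ParseError(f"malformed tag line {line!r}", line=lineno)
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            if not GO_ID_RE.match(value):
                raise ParseError(f"malformed GO id {value!r}", line=lineno)
            stanza["id"] = value
        elif tag == "name":
            stanza["name"] = value
        elif tag == "namespace":
            stanza["namespace"] = value
        elif tag == "is_a":
            target = value.split("!")[0].strip()
            if not GO_ID_RE.match(target):
                raise ParseError(f"malformed is_a target {value!r}", line=lineno)
            stanza.setdefault("is_a", set()).add(target)
        elif tag == "alt_id":
            if GO_ID_RE.match(value):
                stanza.setdefault("alt_id", set()).add(value)
        elif tag == "is_obsolete":
            stanza["is_obsolete"] = value.lower() == "true"
    flush(lineno + 1)
    return terms


def metabolic_subset(
    terms: dict[str, GOTermRecord], root_id: str = METABOLIC_PROCESS_ROOT
) -> dict[str, GOTermRecord]:
    """Root plus every non-obsolete term from which root is is_a-reachable.

    Parent sets of the returned records are pruned to targets inside the
    subset, so later traversals cannot escape it.
    """
    if root_id not in terms:
        raise NotFoundError(f"root term {root_id} absent from the ontology")
    # climb from each candidate; memoize reachability
    reaches: dict[str, bool] = {root_id: True}

    def reaches_root(tid: str, trail: set[str]) -> bool:
        if tid in reaches:
            return reaches[tid]
        if tid in trail or tid not in terms:
            return False
        trail.add(tid)
        result = any(reaches_root(p, trail) for p in terms[tid].parent_ids)
        trail.discard(tid)
        reaches[tid] = result
        return result

    keep = {
        tid
        for tid, t in terms.items()
        if not t.obsolete and (tid == root_id or reaches_root(tid, set()))
    }
    subset: dict[str, GOTermRecord] = {}
    for tid in keep:
        t = terms[tid]
        subset[tid] = GOTermRecord(
            term_id=t.term_id,
            name=t.name,
            namespace=t.namespace,
            parent_ids={p for p in t.parent_ids if p in keep},
            obsolete=False,
            alt_ids=set(t.alt_ids),
        )
    return subset


_TRANSFERRED_RE = re.compile(r"^(Transferred entry|Deleted entry)", re.IGNORECASE)


def parse_enzyme_dat(stream: Iterable[str]) -> list[ECRecord]:
    """Read Expasy ENZYME records (``//``-delimited, two-letter line codes).

    Name comes from concatenated DE lines; records whose description starts
    with "Transferred entry" or "Deleted entry" are flagged inactive.
    """
    records: list[ECRecord] = []
    ec: str | None = None
    de_parts: list[str] = []
    saw_content = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        code = line[:2]
        if line.startswith("//"):
            if ec is None:
                if saw_content:
                    raise ParseError("record has no ID line", line=lineno)
                continue  # header block before the first record
            name = " ".join(de_parts).strip()
            records.append(
                ECRecord(ec=ec, name=name, active=not _TRANSFERRED_RE.match(name))
            )
            ec, de_parts, saw_content = None, [], False
        elif code == "ID":
            ec = line[2:].strip()
            saw_content = True
        elif code == "DE":
            de_parts.append(line[2:].strip())
            saw_content = True
        elif code == "CC" and ec is None:
            # Expasy ships a CC-only preamble before the first record
            continue
        elif line.strip():
            saw_content = saw_content or ec is not None
    return records


GENE2GO_COLUMNS = [
    "tax_id",
    "GeneID",
    "GO_ID",
    "Evidence",
    "Qualifier",
    "GO_term",
    "PubMed",
    "Category",
]


def parse_gene2go(
    stream: TextIO, taxon: int, report: BuildReport | None = None
) -> set[tuple[int, str]]:
    """Gene→GO edges for one taxon; NOT-qualified rows are excluded."""
    frame = pd.read_csv(
        stream, sep="\t", dtype=str, names=GENE2GO_COLUMNS, comment=None, header=None
    )
    if len(frame) and str(frame.iloc[0, 0]).startswith("#"):
        frame = frame.iloc[1:]
    if report is not None:
        report.rows_read["gene2go"] = len(frame)
    edges: set[tuple[int, str]] = set()
    for idx, row in frame.iterrows():
        try:
            tax = int(row["tax_id"])
            gene_id = int(row["GeneID"])
        except (TypeError, ValueError):
            raise ParseError(f"gene2go row {idx}: non-integer tax_id/GeneID")
        go_id = str(row["GO_ID"])
        if not GO_ID_RE.match(go_id):
            raise ParseError(f"gene2go row {idx}: malformed GO id {go_id!r}")
        if tax != taxon:
            if report is not None:
                report.drop("gene2go_off_taxon")
            continue
        qualifier = str(row["Qualifier"]) if not pd.isna(row["Qualifier"]) else ""
        if "NOT" in qualifier.split("|"):
            if report is not None:
                report.drop("gene2go_not_qualifier")
            continue
        edges.add((gene_id, go_id))
    return edges


def parse_gene2accession(
    stream: TextIO, taxon: int, report: BuildReport | None = None
) -> dict[int, GeneRecord]:
    """Gene records with accumulated transcript/protein accessions.

    Uses the tax_id, GeneID, RNA_nucleotide_accession.version and
    protein_accession.version columns, located by header name; "-" marks an
    absent accession.
    """
    frame = pd.read_csv(stream, sep="\t", dtype=str)
    frame.columns = [c.lstrip("#") for c in frame.columns]
    required = [
        "tax_id",
        "GeneID",
        "RNA_nucleotide_accession.version",
        "protein_accession.version",
    ]
    for col in required:
        if col not in frame.columns:
            raise ParseError(f"gene2accession is missing column {col!r}")
    if report is not None:
        report.rows_read["gene2accession"] = len(frame)
    genes: dict[int, GeneRecord] = {}
    for idx, row in frame.iterrows():
        try:
            tax = int(row["tax_id"])
            gene_id = int(row["GeneID"])
        except (TypeError, ValueError):
            raise ParseError(f"gene2accession row {idx}: non-integer tax_id/GeneID")
        if tax != taxon:
            if report is not None:
                report.drop("gene2accession_off_taxon")
            continue
        record = genes.setdefault(gene_id, GeneRecord(gene_id=gene_id, tax_id=tax))
        rna = row["RNA_nucleotide_accession.version"]
        prot = row["protein_accession.version"]
        if not pd.isna(rna) and rna != "-":
            record.transcript_accessions.add(str(rna))
        if not pd.isna(prot) and prot != "-":
            record.protein_accessions.add(str(prot))
    return genes


def parse_mapping_table(
    stream: Iterable[str], kind: str
) -> tuple[set[tuple], dict[str, CompoundRecord]]:
    """Two-column TSV links: ``gene_ec`` (gene_id, EC) or ``ec_compound``
    (EC, InChIKey full or prefix).

    Full InChIKeys collapse to their 14-character 2D prefix; referenced
    CompoundRecords are created as needed.  Returns (edges, compounds) —
    compounds is empty for gene_ec tables.
    """
    if kind not in ("gene_ec", "ec_compound"):
        raise ValidationError(f"unknown mapping-table kind {kind!r}")
    edges: set[tuple] = set()
    compounds: dict[str, CompoundRecord] = {}
    bad_rows: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"expected two tab-separated columns", line=lineno)
        left, right = fields[0].strip(), fields[1].strip()
        if kind == "gene_ec":
            try:
                gene_id = int(left)
            except ValueError:
                raise ParseError(f"non-integer gene id {left!r}", line=lineno)
            edges.add((gene_id, right))
        else:
            key = right.upper()
            if INCHIKEY_FULL_RE.match(key):
                prefix = key[:14]
                record = compounds.setdefault(prefix, CompoundRecord(prefix14=prefix))
                record.full_keys.add(key)
            elif INCHIKEY_PREFIX_RE.match(key):
                prefix = key
                compounds.setdefault(prefix, CompoundRecord(prefix14=prefix))
            else:
                bad_rows.append(f"line {lineno}: {right!r}")
                continue
            edges.add((left, prefix))
    if bad_rows:
        raise ValidationError(
            "invalid InChIKey values in ec_compound table: " + "; ".join(bad_rows)
        )
    return edges, compounds


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def assemble_kb(config: BuildConfig) -> tuple[Knowledgebase, BuildReport]:
    """Parse all sources, restrict, link, and derive annotation sets."""
    config.validate()
    report = BuildReport()
    paths = config.source_paths()

    with open_text(paths["obo"]) as fh:
        all_terms = parse_obo(fh)
    report.rows_read["obo_terms"] = len(all_terms)
    terms = metabolic_subset(all_terms, config.root_id)
    report.drop(
        "obo_terms_outside_subtree_or_obsolete", len(all_terms) - len(terms)
    )
    n_obsolete = sum(1 for t in all_terms.values() if t.obsolete)
    if n_obsolete:
        report.drop("obo_obsolete_terms", n_obsolete)

    alt_to_primary: dict[str, str] = {}
    for tid, term in terms.items():
        for alt in term.alt_ids:
            alt_to_primary[alt] = tid

    with open_text(paths["enzyme_dat"]) as fh:
        ec_records = parse_enzyme_dat(fh)
    report.rows_read["enzyme_dat_records"] = len(ec_records)
    ecs = {r.ec: r for r in ec_records}

    with open_text(paths["gene2go"]) as fh:
        raw_gene_go = parse_gene2go(fh, config.taxon, report)
    with open_text(paths["gene2accession"]) as fh:
        genes = parse_gene2accession(fh, config.taxon, report)

    with open_text(paths["gene2ec_table"]) as fh:
        gene_ec_edges, _ = parse_mapping_table(fh, "gene_ec")
    report.rows_read["gene2ec_edges"] = len(gene_ec_edges)
    with open_text(paths["ec2compound_table"]) as fh:
        ec_compound_edges, compounds = parse_mapping_table(fh, "ec_compound")
    report.rows_read["ec2compound_edges"] = len(ec_compound_edges)

    # restrict gene→GO edges to known genes and subtree terms (alt_ids resolved)
    gene_go: set[tuple[int, str]] = set()
    for gene_id, term_id in raw_gene_go:
        term_id = alt_to_primary.get(term_id, term_id)
        if term_id not in terms:
            report.drop("gene_go_term_outside_subtree")
            continue
        if gene_id not in genes:
            report.drop("gene_go_unknown_gene")
            continue
        gene_go.add((gene_id, term_id))

    kept_gene_ec: set[tuple[int, str]] = set()
    for gene_id, ec in gene_ec_edges:
        if gene_id not in genes:
            report.drop("gene_ec_unknown_gene")
            continue
        if ec not in ecs:
            report.drop("gene_ec_unknown_ec")
            continue
        if not ecs[ec].active:
            report.drop("gene_ec_inactive_ec")
            continue
        kept_gene_ec.add((gene_id, ec))

    kept_ec_compound: set[tuple[str, str]] = set()
    kept_compounds: dict[str, CompoundRecord] = {}
    for ec, prefix in ec_compound_edges:
        if ec not in ecs:
            report.drop("ec_compound_unknown_ec")
            continue
        if not ecs[ec].active:
            report.drop("ec_compound_inactive_ec")
            continue
        kept_ec_compound.add((ec, prefix))
        kept_compounds[prefix] = compounds[prefix]

    if not terms:
        raise BuildError("metabolic subtree is empty")

    kb = Knowledgebase(
        terms=terms,
        genes=genes,
        ecs=ecs,
        compounds=kept_compounds,
        gene_go_edges=gene_go,
        gene_ec_edges=kept_gene_ec,
        ec_compound_edges=kept_ec_compound,
        root_id=config.root_id,
        propagate=config.propagate,
    )
    derive_annotation_sets(kb)
    if not kb.background:
        raise BuildError("background is empty: no compound reaches any GO term")

    stats_pairs = {
        "terms": len(kb.terms),
        "genes": len(kb.genes),
        "ecs": len(kb.ecs),
        "compounds": len(kb.compounds),
        "background": len(kb.background),
        "gene_go_edges": len(kb.gene_go_edges),
        "gene_ec_edges": len(kb.gene_ec_edges),
        "ec_compound_edges": len(kb.ec_compound_edges),
    }
    report.final_counts.update(stats_pairs)
    return kb, report


def source_checksums(config: BuildConfig) -> dict[str, str]:
    return {name: _checksum(path) for name, path in config.source_paths().items()}
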