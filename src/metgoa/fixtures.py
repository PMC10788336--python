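"""Deterministic miniature source files for end-to-end testing.

The generator emits the exact dialects the builders consume — an OBO
ontology rooted at the metabolic-process term, an Expasy-style enzyme.dat,
NCBI-style gene2go and gene2accession tables, and the two link tables — at
a scale of tens of terms and hundreds of compounds, together with a ground
truth computed by brute force from the generated structure (per-term
compound sets, the background, expected census counts).  The same seed
produces byte-identical files.

A *planted* term can be given a dedicated block of genes, enzymes and
compounds disjoint from the random fabric; input lists drawing heavily from
that block are enriched for the planted term by construction, which is the
basis of the recovery checks on the over-representation engine.  Optional
contaminants (off-taxon rows, an obsolete term, a transferred EC, malformed
input keys) exercise the build filters; the ground truth records exactly
what was planted.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .errors import ValidationError
from .model import METABOLIC_PROCESS_ROOT


@dataclass
class Contaminants:
    off_taxon_rows: bool = False
    obsolete_terms: bool = False
    transferred_ecs: bool = False
    malformed_keys: bool = False


@dataclass
class FixtureSpec:
    """Parameters of one synthetic knowledgebase.

    Defaults give a background of roughly 500 structures over 50 terms with
    a planted term of set size 20, and an input list of 60 structures of
    which 12 hit the planted set — an enrichment far above the
    hypergeometric expectation of 60·20/500 ≈ 2.4.
    """

    seed: int = 0
    n_terms: int = 50
    n_genes: int = 150
    n_ecs: int = 80
    n_compounds: int = 500
    dag_depth: int = 5
    planted_term: int | None = 25  # index among generated terms; None disables
    planted_set_size: int = 20
    planted_overlap: int = 12
    decoy_prefix_count: int = 48
    taxon: int = 9606
    off_taxon: int = 10090
    contaminants: Contaminants = field(default_factory=Contaminants)

    def __post_init__(self) -> None:
        if self.planted_term is not None:
            if not 0 < self.planted_term < self.n_terms:
                raise ValidationError(
                    "planted_term index must fall among the non-root terms"
                )
            if self.planted_overlap > self.planted_set_size:
                raise ValidationError(
                    "planted_overlap cannot exceed the planted term's set size"
                )


@dataclass
class GroundTruth:
    """What the generator knows it built; the oracle for assemble_kb."""

    counts: dict[str, int]
    term_compounds: dict[str, list[str]]
    term_genes: dict[str, list[int]]
    background: list[str]
    planted_term_id: str | None
    planted_compounds: list[str]
    contaminant_counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True) + "\n"


_N_PLANTED_GENES = 3  # enough to satisfy the gene-count filter
_N_PLANTED_ECS = 2


def _unique_prefixes(rng: random.Random, n: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        p = "".join(rng.choices(string.ascii_uppercase, k=14))
        if p not in seen:
            seen.add(p)
            out.append(p)
    return out


def _full_key(rng: random.Random, prefix: str) -> str:
    # synthetic suffix with a valid 14-10-1 layout; identity lives in the prefix
    return prefix + "-" + "".join(rng.choices(string.ascii_uppercase, k=10)) + "-N"


@dataclass
class _Structure:
    """In-memory fabric of one fixture, shared by writer and ground truth."""

    term_ids: list[str]
    term_parents: dict[str, list[str]]
    term_names: dict[str, str]
    gene_ids: list[int]
    gene_terms: dict[int, list[str]]
    gene_ecs: dict[int, list[str]]
    ecs: list[str]
    ec_compounds: dict[str, list[str]]
    prefixes: list[str]
    full_keys: dict[str, str]
    planted_term_id: str | None
    planted_prefixes: list[str]


def _build_structure(spec: FixtureSpec) -> _Structure:
    rng = random.Random(spec.seed)

    term_ids = [METABOLIC_PROCESS_ROOT] + [
        f"GO:{1000001 + i:07d}" for i in range(spec.n_terms - 1)
    ]
    planted_tid = (
        term_ids[spec.planted_term] if spec.planted_term is not None else None
    )
    depth = {term_ids[0]: 0}
    parents: dict[str, list[str]] = {term_ids[0]: []}
    for tid in term_ids[1:]:
        candidates = [
            t
            for t in parents
            if depth[t] < spec.dag_depth - 1 and t != planted_tid
        ]
        k = 1 if len(candidates) < 2 or rng.random() < 0.6 else 2
        chosen = sorted(rng.sample(candidates, k))
        parents[tid] = chosen
        depth[tid] = max(depth[p] for p in chosen) + 1
    names = {t: f"synthetic process {i}" for i, t in enumerate(term_ids)}
    names[term_ids[0]] = "metabolic process"

    n_random_compounds = spec.n_compounds
    planted_prefixes: list[str] = []
    all_prefixes = _unique_prefixes(
        rng,
        n_random_compounds
        + (spec.planted_set_size if planted_tid else 0),
    )
    if planted_tid:
        planted_prefixes = all_prefixes[n_random_compounds:]
    random_prefixes = all_prefixes[:n_random_compounds]
    full_keys = {p: _full_key(rng, p) for p in all_prefixes}

    ecs = [f"1.{1 + i // 25}.{1 + (i // 5) % 5}.{1 + i % 5}" for i in range(spec.n_ecs)]
    planted_ecs = ecs[-_N_PLANTED_ECS:] if planted_tid else []
    random_ecs = [e for e in ecs if e not in planted_ecs]

    ec_compounds: dict[str, list[str]] = {e: [] for e in ecs}
    for prefix in random_prefixes:
        k_c = min(len(random_ecs), 1 if rng.random() < 0.7 else 2)
        for ec in rng.sample(random_ecs, k=k_c):
            ec_compounds[ec].append(prefix)
    if planted_tid:
        for i, prefix in enumerate(planted_prefixes):
            ec_compounds[planted_ecs[i % _N_PLANTED_ECS]].append(prefix)

    gene_ids = [10001 + i for i in range(spec.n_genes)]
    planted_genes = gene_ids[-_N_PLANTED_GENES:] if planted_tid else []
    random_genes = [g for g in gene_ids if g not in planted_genes]
    annotatable = [t for t in term_ids if t != planted_tid]
    gene_terms: dict[int, list[str]] = {}
    gene_ecs: dict[int, list[str]] = {}
    for gene in random_genes:
        k_t = min(len(annotatable), 1 if rng.random() < 0.7 else 2)
        gene_terms[gene] = sorted(rng.sample(annotatable, k=k_t))
        k_e = min(len(random_ecs), 1 if rng.random() < 0.7 else 2)
        gene_ecs[gene] = sorted(rng.sample(random_ecs, k=k_e))
    # every enzyme is held by at least one gene, so all linked compounds
    # can reach the ontology and the background spans the compound pool
    held = set().union(*gene_ecs.values()) if gene_ecs else set()
    for ec in random_ecs:
        if ec not in held:
            gene = rng.choice(random_genes)
            gene_ecs[gene] = sorted(set(gene_ecs[gene]) | {ec})
    for i, gene in enumerate(planted_genes):
        gene_terms[gene] = [planted_tid]
        gene_ecs[gene] = [planted_ecs[i % _N_PLANTED_ECS]]
    if planted_tid and _N_PLANTED_GENES >= 2:
        # make sure the planted gene block jointly covers both planted ECs
        gene_ecs[planted_genes[0]] = sorted(planted_ecs)

    return _Structure(
        term_ids=term_ids,
        term_parents=parents,
        term_names=names,
        gene_ids=gene_ids,
        gene_terms=gene_terms,
        gene_ecs=gene_ecs,
        ecs=ecs,
        ec_compounds=ec_compounds,
        prefixes=all_prefixes,
        full_keys=full_keys,
        planted_term_id=planted_tid,
        planted_prefixes=planted_prefixes,
    )


def _ground_truth(spec: FixtureSpec, s: _Structure) -> GroundTruth:
    # brute-force reachability: descendants by repeated scanning
    desc: dict[str, set[str]] = {t: set() for t in s.term_ids}
    changed = True
    while changed:
        changed = False
        for tid in s.term_ids:
            for parent in s.term_parents[tid]:
                new = {tid} | desc[tid]
                if not new <= desc[parent]:
                    desc[parent] |= new
                    changed = True

    direct: dict[str, set[int]] = {t: set() for t in s.term_ids}
    for gene, terms in s.gene_terms.items():
        for t in terms:
            direct[t].add(gene)
    gene_comps: dict[int, set[str]] = {
        g: set().union(*(set(s.ec_compounds[e]) for e in s.gene_ecs[g]))
        for g in s.gene_ids
    }
    term_genes = {
        t: direct[t] | set().union(*(direct[d] for d in desc[t]), set())
        for t in s.term_ids
    }
    term_compounds = {
        t: set().union(*(gene_comps[g] for g in term_genes[t]), set())
        for t in s.term_ids
    }
    background = set().union(*term_compounds.values())

    n_edges_gene_go = len(
        {(g, t) for g, terms in s.gene_terms.items() for t in terms}
    )
    n_edges_gene_ec = len({(g, e) for g, el in s.gene_ecs.items() for e in el})
    n_edges_ec_comp = len(
        {(e, p) for e, pl in s.ec_compounds.items() for p in pl}
    )
    contaminant_counts = {
        "off_taxon_gene2go_rows": 2 if spec.contaminants.off_taxon_rows else 0,
        "off_taxon_gene2accession_rows": 2
        if spec.contaminants.off_taxon_rows
        else 0,
        "obsolete_terms": 1 if spec.contaminants.obsolete_terms else 0,
        "transferred_ecs": 1 if spec.contaminants.transferred_ecs else 0,
        "transferred_ec_compound_rows": 2
        if spec.contaminants.transferred_ecs
        else 0,
        "malformed_input_keys": 2 if spec.contaminants.malformed_keys else 0,
    }
    return GroundTruth(
        counts={
            "terms": len(s.term_ids),
            "genes": len(s.gene_ids),
            "ecs": len(s.ecs),
            "compounds": len(s.prefixes),
            "full_inchikeys": len(s.full_keys),
            "background": len(background),
            "gene_go_edges": n_edges_gene_go,
            "gene_ec_edges": n_edges_gene_ec,
            "ec_compound_edges": n_edges_ec_comp,
        },
        term_compounds={t: sorted(v) for t, v in term_compounds.items()},
        term_genes={t: sorted(v) for t, v in term_genes.items()},
        background=sorted(background),
        planted_term_id=s.planted_term_id,
        planted_compounds=sorted(s.planted_prefixes),
        contaminant_counts=contaminant_counts,
    )


def generate_sources(
    spec: FixtureSpec, destination_dir: str | Path
) -> tuple[dict[str, str], GroundTruth]:
    """Write all six source files plus manifest and ground truth.

    Returns (manifest mapping logical name → file path, ground truth).
    """
    dest = Path(destination_dir)
    dest.mkdir(parents=True, exist_ok=True)
    s = _build_structure(spec)
    truth = _ground_truth(spec, s)
    rng = random.Random(spec.seed + 7919)  # stream for contaminant payloads

    # --- OBO ---
    lines = ["format-version: 1.2", ""]
    for tid in s.term_ids:
        lines += [
            "[Term]",
            f"id: {tid}",
            f"name: {s.term_names[tid]}",
            "namespace: biological_process",
        ]
        for parent in s.term_parents[tid]:
            lines.append(f"is_a: {parent} ! {s.term_names[parent]}")
        lines.append("")
    if spec.contaminants.obsolete_terms:
        lines += [
            "[Term]",
            "id: GO:0999001",
            "name: withdrawn synthetic process",
            "namespace: biological_process",
            f"is_a: {s.term_ids[0]} ! metabolic process",
            "is_obsolete: true",
            "",
        ]
    lines += ["[Typedef]", "id: part_of", "name: part of", ""]
    (dest / "go.obo").write_text("\n".join(lines), encoding="utf-8")

    # --- enzyme.dat ---
    ez: list[str] = []
    for i, ec in enumerate(s.ecs):
        ez += [f"ID   {ec}", f"DE   Synthetic enzyme {i}.", "//"]
    if spec.contaminants.transferred_ecs:
        ez += ["ID   9.9.9.9", "DE   Transferred entry: 1.1.1.1.", "//"]
    (dest / "enzyme.dat").write_text("\n".join(ez) + "\n", encoding="utf-8")

    # --- gene2go ---
    g2g = [
        "#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory"
    ]
    for gene in s.gene_ids:
        for t in s.gene_terms[gene]:
            g2g.append(
                f"{spec.taxon}\t{gene}\t{t}\tIEA\t-\t{s.term_names[t]}\t-\tProcess"
            )
    if spec.contaminants.off_taxon_rows:
        for gene in s.gene_ids[:2]:
            t = s.gene_terms[gene][0]
            g2g.append(
                f"{spec.off_taxon}\t{gene}\t{t}\tIEA\t-\t{s.term_names[t]}\t-\tProcess"
            )
    (dest / "gene2go").write_text("\n".join(g2g) + "\n", encoding="utf-8")

    # --- gene2accession ---
    g2a = [
        "#tax_id\tGeneID\tstatus\tRNA_nucleotide_accession.version\tprotein_accession.version"
    ]
    for i, gene in enumerate(s.gene_ids):
        g2a.append(f"{spec.taxon}\t{gene}\t-\tNM_{i:06d}.1\tNP_{i:06d}.1")
    if spec.contaminants.off_taxon_rows:
        for i, gene in enumerate(s.gene_ids[:2]):
            g2a.append(f"{spec.off_taxon}\t{gene}\t-\tXM_{i:06d}.1\tXP_{i:06d}.1")
    (dest / "gene2accession").write_text("\n".join(g2a) + "\n", encoding="utf-8")

    # --- gene→EC ---
    g2e = [f"{g}\t{e}" for g in s.gene_ids for e in s.gene_ecs[g]]
    (dest / "gene2ec.tsv").write_text("\n".join(g2e) + "\n", encoding="utf-8")

    # --- EC→compound (full keys, exercising the prefix reduction) ---
    e2c = [
        f"{ec}\t{s.full_keys[p]}"
        for ec in s.ecs
        for p in s.ec_compounds[ec]
    ]
    if spec.contaminants.transferred_ecs:
        sample = rng.sample(s.prefixes, 2)
        e2c += [f"9.9.9.9\t{s.full_keys[p]}" for p in sample]
    (dest / "ec2compound.tsv").write_text("\n".join(e2c) + "\n", encoding="utf-8")

    manifest = {
        "obo": str(dest / "go.obo"),
        "enzyme_dat": str(dest / "enzyme.dat"),
        "gene2go": str(dest / "gene2go"),
        "gene2accession": str(dest / "gene2accession"),
        "gene2ec_table": str(dest / "gene2ec.tsv"),
        "ec2compound_table": str(dest / "ec2compound.tsv"),
    }
    (dest / "manifest.json").write_text(
        json.dumps({k: Path(v).name for k, v in manifest.items()}, indent=1, sort_keys=True)
        + "\n",
        encoding="utf-8",
    )
    (dest / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")
    return manifest, truth


def generate_input_list(
    spec: FixtureSpec, truth: GroundTruth
) -> tuple[list[str], str | None]:
    """Input metabolite list with a planted enrichment signal.

    Draws ``planted_overlap`` structures from the planted term's compound
    set and ``decoy_prefix_count`` uniformly from the remaining background,
    emitted as full 27-character keys with synthetic suffixes.  Returns
    (keys, expected top term id).
    """
    rng = random.Random(spec.seed + 104729)
    planted = truth.planted_compounds
    if spec.planted_overlap and spec.planted_term is None:
        raise ValidationError("planted_overlap requires a planted term")
    if spec.planted_overlap > len(planted) and spec.planted_term is not None:
        raise ValidationError(
            f"planted_overlap {spec.planted_overlap} exceeds the planted "
            f"term's set size {len(planted)}"
        )
    chosen = rng.sample(planted, spec.planted_overlap) if planted else []
    pool = sorted(set(truth.background) - set(planted))
    decoys = rng.sample(pool, min(spec.decoy_prefix_count, len(pool)))
    keys = [_full_key(rng, p) for p in chosen + decoys]
    rng.shuffle(keys)
    if spec.contaminants.malformed_keys:
        keys += ["NOT-AN-INCHIKEY", "abc123"]
    return keys, truth.planted_term_id
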