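"""Domain model of the metabolic knowledgebase.

The knowledgebase links four entity kinds — GO terms (restricted to the
metabolic-process subtree), NCBI genes, Enzyme Commission numbers, and
compound 2D structures keyed by the first 14 characters of an InChIKey —
through three edge sets (gene–GO, gene–EC, EC–compound).  From these it
derives, per GO term, the set of annotated genes and the set of reachable
compound structures; the union of all per-term compound sets is the
*background* universe against which over-representation is tested.

Annotation propagation follows the true-path rule: an entity annotated to a
term is implicitly annotated to every ancestor of that term.  Propagation is
the default but can be disabled on the :class:`Knowledgebase`.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field

from .errors import CycleError, NotFoundError, ValidationError

GO_ID_RE = re.compile(r"^GO:\d{7}$")
# 14-10-1 hyphenated InChIKey layout; block 1 encodes the 2D skeleton.
INCHIKEY_FULL_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")
INCHIKEY_PREFIX_RE = re.compile(r"^[A-Z]{14}$")
# Four dot-separated fields; digits, preliminary "n"-numbers, or "-" wildcards.
EC_RE = re.compile(r"^(\d+|n\d+|-)(\.(\d+|n\d+|-)){3}$")

METABOLIC_PROCESS_ROOT = "GO:0008152"


@dataclass
class GOTermRecord:
    """One ontology term with its is_a parents."""

    term_id: str
    name: str = ""
    namespace: str = "biological_process"
    parent_ids: set[str] = field(default_factory=set)
    obsolete: bool = False
    alt_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not GO_ID_RE.match(self.term_id):
            raise ValidationError(
                f"term id {self.term_id!r} does not match 'GO:' + 7 digits"
            )
        self.parent_ids.discard(self.term_id)
        if self.obsolete:
            self.parent_ids = set()


@dataclass
class GeneRecord:
    """An NCBI gene with its transcript and protein accessions."""

    gene_id: int
    tax_id: int
    transcript_accessions: set[str] = field(default_factory=set)
    protein_accessions: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.gene_id <= 0:
            raise ValidationError(f"gene_id must be positive, got {self.gene_id}")
        if self.tax_id <= 0:
            raise ValidationError(f"tax_id must be positive, got {self.tax_id}")


@dataclass
class ECRecord:
    """An Enzyme Commission number; inactive when transferred or deleted."""

    ec: str
    name: str = ""
    active: bool = True

    def __post_init__(self) -> None:
        if not EC_RE.match(self.ec):
            raise ValidationError(
                f"EC number {self.ec!r} must have four dot-separated fields"
            )


@dataclass
class CompoundRecord:
    """A 2D chemical structure: the first InChIKey block plus observed full keys."""

    prefix14: str
    full_keys: set[str] = field(default_factory=set)
    name: str | None = None

    def __post_init__(self) -> None:
        if not INCHIKEY_PREFIX_RE.match(self.prefix14):
            raise ValidationError(
                f"prefix {self.prefix14!r} must be 14 uppercase letters"
            )
        for key in self.full_keys:
            if not INCHIKEY_FULL_RE.match(key) or not key.startswith(self.prefix14):
                raise ValidationError(
                    f"full key {key!r} does not extend prefix {self.prefix14}"
                )


@dataclass
class Knowledgebase:
    """Integrated store of terms, genes, ECs, compounds and their links."""

    terms: dict[str, GOTermRecord] = field(default_factory=dict)
    genes: dict[int, GeneRecord] = field(default_factory=dict)
    ecs: dict[str, ECRecord] = field(default_factory=dict)
    compounds: dict[str, CompoundRecord] = field(default_factory=dict)
    gene_go_edges: set[tuple[int, str]] = field(default_factory=set)
    gene_ec_edges: set[tuple[int, str]] = field(default_factory=set)
    ec_compound_edges: set[tuple[str, str]] = field(default_factory=set)
    root_id: str = METABOLIC_PROCESS_ROOT
    propagate: bool = True
    term_compounds: dict[str, set[str]] = field(default_factory=dict)
    term_genes: dict[str, set[int]] = field(default_factory=dict)
    background: set[str] = field(default_factory=set)

    def children_index(self) -> dict[str, set[str]]:
        """Inverse of parent_ids: term -> set of direct is_a children."""
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for term in self.terms.values():
            for parent in term.parent_ids:
                if parent in children:
                    children[parent].add(term.term_id)
        return children


@dataclass
class KBStats:
    n_terms: int
    n_genes: int
    n_ecs: int
    n_compounds: int
    n_full_inchikeys: int
    n_background: int
    n_gene_go_edges: int
    n_gene_ec_edges: int
    n_ec_compound_edges: int


@dataclass
class QueryResult:
    """Outcome of an association query: entity echo plus the linked terms."""

    entity_type: str
    identifier: str
    found: bool
    term_ids: set[str]


def ancestors(kb: Knowledgebase, term_id: str) -> set[str]:
    """All terms reachable from ``term_id`` by following is_a edges upward.

    Excludes ``term_id`` itself; never leaves the metabolic subtree because
    parent sets are pruned at build time.
    """
    if term_id not in kb.terms:
        raise NotFoundError(f"unknown term {term_id}")
    seen: set[str] = set()
    queue = deque(kb.terms[term_id].parent_ids)
    while queue:
        current = queue.popleft()
        if current in seen or current not in kb.terms:
            continue
        seen.add(current)
        queue.extend(kb.terms[current].parent_ids)
    return seen


def descendants(kb: Knowledgebase, term_id: str) -> set[str]:
    """All terms from which ``term_id`` is reachable via is_a edges."""
    if term_id not in kb.terms:
        raise NotFoundError(f"unknown term {term_id}")
    children = kb.children_index()
    seen: set[str] = set()
    queue = deque(children[term_id])
    while queue:
        current = queue.popleft()
        if current in seen:
            continue
        seen.add(current)
        queue.extend(children[current])
    return seen


def topological_order(kb: Knowledgebase) -> list[str]:
    """Terms ordered children-before-parents; raises CycleError on a cycle.

    Kahn's algorithm on the child→parent edge direction.
    """
    out_degree = {t: 0 for t in kb.terms}  # number of unprocessed children
    for term in kb.terms.values():
        for parent in term.parent_ids:
            if parent in out_degree:
                out_degree[parent] += 1
    # start from leaves (no children), deterministic order
    queue = deque(sorted(t for t, d in out_degree.items() if d == 0))
    order: list[str] = []
    while queue:
        current = queue.popleft()
        order.append(current)
        for parent in sorted(kb.terms[current].parent_ids):
            if parent not in out_degree:
                continue
            out_degree[parent] -= 1
            if out_degree[parent] == 0:
                queue.append(parent)
    if len(order) != len(kb.terms):
        member = next(t for t in sorted(kb.terms) if t not in set(order))
        raise CycleError(member)
    return order


def derive_annotation_sets(kb: Knowledgebase) -> Knowledgebase:
    """Fill term_genes, term_compounds and the background universe.

    term_genes[T] holds the genes directly annotated to T, plus — when
    ``kb.propagate`` — the genes of every descendant of T (true-path rule).
    term_compounds[T] is the image of term_genes[T] under the gene→EC→compound
    edge composition.  Deterministic and idempotent for a fixed KB.
    """
    order = topological_order(kb)  # validates acyclicity

    direct: dict[str, set[int]] = {t: set() for t in kb.terms}
    for gene_id, term_id in kb.gene_go_edges:
        if term_id in direct and gene_id in kb.genes:
            direct[term_id].add(gene_id)

    gene_compounds: dict[int, set[str]] = {g: set() for g in kb.genes}
    ec_comps: dict[str, set[str]] = {}
    for ec, prefix in kb.ec_compound_edges:
        ec_comps.setdefault(ec, set()).add(prefix)
    for gene_id, ec in kb.gene_ec_edges:
        if gene_id in gene_compounds:
            gene_compounds[gene_id] |= ec_comps.get(ec, set())

    term_genes: dict[str, set[int]] = {t: set(direct[t]) for t in kb.terms}
    if kb.propagate:
        for term_id in order:  # children come before parents
            for parent in kb.terms[term_id].parent_ids:
                if parent in term_genes:
                    term_genes[parent] |= term_genes[term_id]

    term_compounds: dict[str, set[str]] = {}
    for term_id, genes in term_genes.items():
        comps: set[str] = set()
        for gene_id in genes:
            comps |= gene_compounds[gene_id]
        term_compounds[term_id] = comps

    kb.term_genes = term_genes
    kb.term_compounds = term_compounds
    kb.background = set().union(*term_compounds.values()) if term_compounds else set()
    return kb


def kb_stats(kb: Knowledgebase) -> KBStats:
    """Summary census of the knowledgebase collections."""
    return KBStats(
        n_terms=len(kb.terms),
        n_genes=len(kb.genes),
        n_ecs=len(kb.ecs),
        n_compounds=len(kb.compounds),
        n_full_inchikeys=sum(len(c.full_keys) for c in kb.compounds.values()),
        n_background=len(kb.background),
        n_gene_go_edges=len(kb.gene_go_edges),
        n_gene_ec_edges=len(kb.gene_ec_edges),
        n_ec_compound_edges=len(kb.ec_compound_edges),
    )


def _terms_of_gene(kb: Knowledgebase, gene_id: int) -> set[str]:
    return {t for t, genes in kb.term_genes.items() if gene_id in genes}


def query_associations(kb: Knowledgebase, kind: str, identifier: str) -> QueryResult:
    """Terms associated with a compound, reaction (EC), gene, protein or transcript.

    Compounds match on the 14-character prefix; proteins and transcripts are
    resolved to their owning gene first.  A well-formed identifier that is not
    in the KB yields an empty, found=False result rather than an error.
    """
    identifier = identifier.strip()
    if kind == "compound":
        candidate = identifier.upper()
        if INCHIKEY_FULL_RE.match(candidate):
            prefix = candidate[:14]
        elif INCHIKEY_PREFIX_RE.match(candidate):
            prefix = candidate
        else:
            raise ValidationError(
                f"{identifier!r} is neither a 27-character hyphenated InChIKey "
                "nor a 14-character prefix"
            )
        terms = {t for t, comps in kb.term_compounds.items() if prefix in comps}
        return QueryResult("compound", prefix, prefix in kb.background, terms)

    if kind in ("ec", "reaction"):
        if not EC_RE.match(identifier):
            raise ValidationError(
                f"{identifier!r} is not an EC number (four dot-separated fields)"
            )
        genes = {g for g, ec in kb.gene_ec_edges if ec == identifier}
        terms: set[str] = set()
        for gene_id in genes:
            terms |= _terms_of_gene(kb, gene_id)
        return QueryResult("ec", identifier, identifier in kb.ecs, terms)

    if kind == "gene":
        try:
            gene_id = int(identifier)
        except ValueError:
            raise ValidationError(f"{identifier!r} is not an integer NCBI Gene id")
        if gene_id <= 0:
            raise ValidationError("NCBI Gene ids are positive integers")
        found = gene_id in kb.genes
        return QueryResult("gene", identifier, found, _terms_of_gene(kb, gene_id))

    if kind in ("protein", "transcript"):
        if not identifier or any(ch.isspace() for ch in identifier):
            raise ValidationError(f"{identifier!r} is not a sequence accession")
        attr = "protein_accessions" if kind == "protein" else "transcript_accessions"
        for gene in kb.genes.values():
            if identifier in getattr(gene, attr):
                return QueryResult(
                    kind, identifier, True, _terms_of_gene(kb, gene.gene_id)
                )
        return QueryResult(kind, identifier, False, set())

    raise ValidationError(
        f"unknown entity type {kind!r}; expected compound, ec, gene, "
        "protein or transcript"
    )
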