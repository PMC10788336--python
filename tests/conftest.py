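"""Shared fixtures: a hand-built diamond KB and one generated source set."""

from __future__ import annotations

import random
import string

import pytest

from metgoa.build import BuildConfig, assemble_kb
from metgoa.fixtures import FixtureSpec, generate_input_list, generate_sources
from metgoa.model import (
    CompoundRecord,
    ECRecord,
    GeneRecord,
    GOTermRecord,
    Knowledgebase,
    derive_annotation_sets,
)

ROOT = "GO:0008152"


def prefix(seed: int) -> str:
    """Deterministic 14-letter synthetic InChIKey prefix."""
    rng = random.Random(seed)
    return "".join(rng.choices(string.ascii_uppercase, k=14))


def make_kb(
    parents: dict[str, set[str]],
    gene_terms: dict[int, set[str]],
    gene_ecs: dict[int, set[str]],
    ec_compounds: dict[str, set[str]],
    propagate: bool = True,
    derive: bool = True,
) -> Knowledgebase:
    """Assemble a Knowledgebase directly from adjacency dictionaries."""
    kb = Knowledgebase(propagate=propagate)
    for tid, ps in parents.items():
        kb.terms[tid] = GOTermRecord(term_id=tid, name=f"term {tid}", parent_ids=set(ps))
    for gid, terms in gene_terms.items():
        kb.genes.setdefault(gid, GeneRecord(gene_id=gid, tax_id=9606))
        kb.gene_go_edges |= {(gid, t) for t in terms}
    for gid, ecs in gene_ecs.items():
        kb.genes.setdefault(gid, GeneRecord(gene_id=gid, tax_id=9606))
        for ec in ecs:
            kb.ecs.setdefault(ec, ECRecord(ec=ec))
            kb.gene_ec_edges.add((gid, ec))
    for ec, comps in ec_compounds.items():
        kb.ecs.setdefault(ec, ECRecord(ec=ec))
        for c in comps:
            kb.compounds.setdefault(c, CompoundRecord(prefix14=c))
            kb.ec_compound_edges.add((ec, c))
    if derive:
        derive_annotation_sets(kb)
    return kb


C1, C2, C3 = prefix(1), prefix(2), prefix(3)


@pytest.fixture
def diamond_kb() -> Knowledgebase:
    """Root A with children B, C and grandchild D (is_a diamond).

    Gene 101 on D reaches compounds {C1, C2}; gene 102 on B reaches
    {C2, C3}.  Background = {C1, C2, C3} under propagation.
    """
    return make_kb(
        parents={
            ROOT: set(),
            "GO:0000002": {ROOT},
            "GO:0000003": {ROOT},
            "GO:0000004": {"GO:0000002", "GO:0000003"},
        },
        gene_terms={101: {"GO:0000004"}, 102: {"GO:0000002"}},
        gene_ecs={101: {"1.1.1.1"}, 102: {"2.2.2.2"}},
        ec_compounds={"1.1.1.1": {C1, C2}, "2.2.2.2": {C2, C3}},
    )


@pytest.fixture(scope="session")
def fixture_sources(tmp_path_factory):
    """One generated source set (seed 1) with its ground truth and input list."""
    dest = tmp_path_factory.mktemp("sources")
    spec = FixtureSpec(seed=1)
    manifest, truth = generate_sources(spec, dest)
    keys, top_term = generate_input_list(spec, truth)
    input_path = dest / "input_list.txt"
    input_path.write_text("\n".join(keys) + "\n", encoding="utf-8")
    return {
        "spec": spec,
        "manifest": manifest,
        "truth": truth,
        "input_path": input_path,
        "top_term": top_term,
        "dir": dest,
    }


def config_from_manifest(manifest: dict[str, str], **kwargs) -> BuildConfig:
    return BuildConfig(
        obo=manifest["obo"],
        enzyme_dat=manifest["enzyme_dat"],
        gene2go=manifest["gene2go"],
        gene2accession=manifest["gene2accession"],
        gene2ec_table=manifest["gene2ec_table"],
        ec2compound_table=manifest["ec2compound_table"],
        **kwargs,
    )


@pytest.fixture(scope="session")
def fixture_kb(fixture_sources):
    kb, report = assemble_kb(config_from_manifest(fixture_sources["manifest"]))
    return kb
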