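"""Source-file parsers, subtree restriction, and KB assembly."""

import gzip
import io
import shutil

import pytest

from metgoa.build import (
    BuildConfig,
    assemble_kb,
    metabolic_subset,
    parse_enzyme_dat,
    parse_gene2accession,
    parse_gene2go,
    parse_mapping_table,
    parse_obo,
)
from metgoa.errors import (
    BuildError,
    NotFoundError,
    ParseError,
    ValidationError,
)
from metgoa.model import kb_stats
from metgoa.serialize import load_kb, save_kb

from conftest import ROOT, config_from_manifest

TWO_STANZA_OBO = """\
format-version: 1.2

[Term]
id: GO:0008152
name: metabolic process
namespace: biological_process

[Term]
id: GO:0043174
name: nucleoside salvage
namespace: biological_process
is_a: GO:0008152 ! metabolic process
"""


class TestParseObo:
    def test_two_stanzas_with_is_a_comment_stripped(self):
        terms = parse_obo(io.StringIO(TWO_STANZA_OBO))
        assert set(terms) == {"GO:0008152", "GO:0043174"}
        assert terms["GO:0043174"].parent_ids == {"GO:0008152"}
        assert terms["GO:0043174"].name == "nucleoside salvage"

    def test_obsolete_stanza_flagged_and_parents_dropped(self):
        text = TWO_STANZA_OBO + "is_obsolete: true\n"
        terms = parse_obo(io.StringIO(text))
        assert terms["GO:0043174"].obsolete
        assert terms["GO:0043174"].parent_ids == set()

    def test_alt_id_recorded(self):
        text = TWO_STANZA_OBO + "alt_id: GO:0000003\n"
        terms = parse_obo(io.StringIO(text))
        assert "GO:0000003" in terms["GO:0043174"].alt_ids

    def test_typedef_stanzas_skipped(self):
        text = TWO_STANZA_OBO + "\n[Typedef]\nid: part_of\nname: part of\n"
        assert len(parse_obo(io.StringIO(text))) == 2

    def test_stanza_without_id_reports_line_number(self):
        text = "[Term]\nname: orphan stanza\n\n[Term]\nid: GO:0008152\n"
        with pytest.raises(ParseError, match="line 1"):
            parse_obo(io.StringIO(text))

    def test_agrees_with_obonet_on_generated_ontology(self, fixture_sources):
        obonet = pytest.importorskip("obonet")
        path = fixture_sources["manifest"]["obo"]
        with open(path) as fh:
            mine = parse_obo(fh)
        graph = obonet.read_obo(path)
        active = {t for t, r in mine.items() if not r.obsolete}
        assert active == set(graph.nodes)
        for tid in active:
            theirs = {
                v for _, v, k in graph.out_edges(tid, keys=True) if k == "is_a"
            }
            assert mine[tid].parent_ids == theirs


class TestMetabolicSubset:
    def test_keeps_root_plus_reachable_only(self):
        text = (
            TWO_STANZA_OBO
            + "\n[Term]\nid: GO:0000001\nname: unrelated\n"
            + "\n[Term]\nid: GO:0000002\nname: salvage child\n"
            + "is_a: GO:0043174 ! nucleoside salvage\n"
        )
        subset = metabolic_subset(parse_obo(io.StringIO(text)), ROOT)
        assert set(subset) == {"GO:0008152", "GO:0043174", "GO:0000002"}

    def test_full_closure_when_everything_descends(self):
        terms = parse_obo(io.StringIO(TWO_STANZA_OBO))
        assert set(metabolic_subset(terms, ROOT)) == set(terms)

    def test_obsolete_descendant_excluded(self):
        text = TWO_STANZA_OBO + "is_obsolete: true\n"
        subset = metabolic_subset(parse_obo(io.StringIO(text)), ROOT)
        assert set(subset) == {"GO:0008152"}

    def test_missing_root_is_not_found(self):
        terms = parse_obo(io.StringIO(TWO_STANZA_OBO))
        with pytest.raises(NotFoundError):
            metabolic_subset(terms, "GO:0999999")

    def test_parent_sets_pruned_to_subset(self):
        text = (
            TWO_STANZA_OBO
            + "\n[Term]\nid: GO:0000009\nname: outside\n"
        )
        # give the salvage term an extra parent outside the subtree
        text = text.replace(
            "is_a: GO:0008152 ! metabolic process",
            "is_a: GO:0008152 ! metabolic process\nis_a: GO:0000009 ! outside",
        )
        subset = metabolic_subset(parse_obo(io.StringIO(text)), ROOT)
        assert subset["GO:0043174"].parent_ids == {"GO:0008152"}


ENZYME_DAT = """\
ID   1.1.1.1
DE   Alcohol dehydrogenase.
//
ID   1.1.1.5
DE   Transferred entry: 1.1.1.303 and 1.1.1.304.
//
"""


class TestParseEnzymeDat:
    def test_active_record(self):
        records = parse_enzyme_dat(io.StringIO(ENZYME_DAT))
        assert records[0].ec == "1.1.1.1"
        assert records[0].name == "Alcohol dehydrogenase."
        assert records[0].active

    def test_transferred_entry_inactive_but_present(self):
        records = parse_enzyme_dat(io.StringIO(ENZYME_DAT))
        assert records[1].ec == "1.1.1.5"
        assert not records[1].active

    def test_input_order_preserved(self):
        records = parse_enzyme_dat(io.StringIO(ENZYME_DAT))
        assert [r.ec for r in records] == ["1.1.1.1", "1.1.1.5"]

    def test_record_without_id_reports_line(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_enzyme_dat(io.StringIO("DE   Orphan description.\n//\n"))

    def test_multiline_de_concatenated_and_other_codes_ignored(self):
        text = "ID   2.7.1.1\nDE   Hexo-\nDE   kinase.\nAN   Glucokinase.\nCA   ATP + D-hexose.\n//\n"
        (record,) = parse_enzyme_dat(io.StringIO(text))
        assert record.name == "Hexo- kinase."

    def test_agrees_with_biopython_on_generated_file(self, fixture_sources):
        Enzyme = pytest.importorskip("Bio.ExPASy.Enzyme")
        path = fixture_sources["manifest"]["enzyme_dat"]
        with open(path) as fh:
            mine = parse_enzyme_dat(fh)
        with open(path) as fh:
            theirs = list(Enzyme.parse(fh))
        assert [r.ec for r in mine] == [r["ID"] for r in theirs]


GENE2GO = (
    "#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory\n"
    "9606\t5236\tGO:0043174\tIEA\t-\tnucleoside salvage\t-\tProcess\n"
    "10090\t5236\tGO:0043174\tIEA\t-\tnucleoside salvage\t-\tProcess\n"
)


class TestParseGene2Go:
    def test_taxon_filter(self):
        edges = parse_gene2go(io.StringIO(GENE2GO), taxon=9606)
        assert edges == {(5236, "GO:0043174")}

    def test_not_qualifier_excluded(self):
        text = GENE2GO + "9606\t5236\tGO:0008152\tIDA\tNOT\tmetabolic process\t-\tProcess\n"
        edges = parse_gene2go(io.StringIO(text), taxon=9606)
        assert (5236, "GO:0008152") not in edges

    def test_duplicate_rows_collapse(self):
        text = GENE2GO + "9606\t5236\tGO:0043174\tIDA\t-\tnucleoside salvage\t-\tProcess\n"
        edges = parse_gene2go(io.StringIO(text), taxon=9606)
        assert len(edges) == 1

    def test_malformed_go_id_is_parse_error(self):
        text = GENE2GO + "9606\t5236\tGO:bad\tIEA\t-\tx\t-\tProcess\n"
        with pytest.raises(ParseError):
            parse_gene2go(io.StringIO(text), taxon=9606)

    def test_non_integer_gene_id_is_parse_error(self):
        text = GENE2GO + "9606\tfive\tGO:0043174\tIEA\t-\tx\t-\tProcess\n"
        with pytest.raises(ParseError):
            parse_gene2go(io.StringIO(text), taxon=9606)


GENE2ACC = (
    "#tax_id\tGeneID\tstatus\tRNA_nucleotide_accession.version\tprotein_accession.version\n"
    "9606\t5236\t-\tNM_002629.4\tNP_002620.1\n"
    "9606\t5236\t-\tNM_002629.4\tNP_002620.2\n"
    "9606\t7167\t-\t-\t-\n"
    "10090\t18648\t-\tNM_008828.3\tNP_032854.1\n"
)


class TestParseGene2Accession:
    def test_accessions_accumulate_across_rows(self):
        genes = parse_gene2accession(io.StringIO(GENE2ACC), taxon=9606)
        assert genes[5236].protein_accessions == {"NP_002620.1", "NP_002620.2"}
        assert genes[5236].transcript_accessions == {"NM_002629.4"}

    def test_dash_placeholders_give_empty_sets(self):
        genes = parse_gene2accession(io.StringIO(GENE2ACC), taxon=9606)
        assert genes[7167].protein_accessions == set()
        assert genes[7167].transcript_accessions == set()

    def test_other_taxon_contributes_nothing(self):
        genes = parse_gene2accession(io.StringIO(GENE2ACC), taxon=9606)
        assert 18648 not in genes

    def test_missing_column_is_parse_error(self):
        with pytest.raises(ParseError):
            parse_gene2accession(io.StringIO("#tax_id\tGeneID\n9606\t1\n"), taxon=9606)


class TestParseMappingTable:
    def test_full_key_reduced_to_prefix(self):
        edges, compounds = parse_mapping_table(
            io.StringIO("1.1.1.1\tBQJCRHHNABKAKU-KBQPJGBKSA-N\n"), "ec_compound"
        )
        assert edges == {("1.1.1.1", "BQJCRHHNABKAKU")}
        assert compounds["BQJCRHHNABKAKU"].full_keys == {
            "BQJCRHHNABKAKU-KBQPJGBKSA-N"
        }

    def test_two_stereoisomers_collapse_to_one_edge(self):
        text = (
            "1.1.1.1\tBQJCRHHNABKAKU-KBQPJGBKSA-N\n"
            "1.1.1.1\tBQJCRHHNABKAKU-UHFFFAOYSA-N\n"
        )
        edges, compounds = parse_mapping_table(io.StringIO(text), "ec_compound")
        assert len(edges) == 1
        assert len(compounds["BQJCRHHNABKAKU"].full_keys) == 2

    def test_malformed_key_is_validation_error_listing_row(self):
        with pytest.raises(ValidationError, match="line 1"):
            parse_mapping_table(io.StringIO("1.1.1.1\tABC\n"), "ec_compound")

    def test_gene_ec_rows(self):
        edges, _ = parse_mapping_table(
            io.StringIO("5236\t1.1.1.1\n5236\t1.1.1.1\n"), "gene_ec"
        )
        assert edges == {(5236, "1.1.1.1")}


class TestAssembleKb:
    def test_counts_match_generator_ground_truth(self, fixture_kb, fixture_sources):
        truth = fixture_sources["truth"]
        stats = kb_stats(fixture_kb)
        assert stats.n_terms == truth.counts["terms"]
        assert stats.n_genes == truth.counts["genes"]
        assert stats.n_ecs == truth.counts["ecs"]
        assert stats.n_compounds == truth.counts["compounds"]
        assert stats.n_background == truth.counts["background"]
        assert stats.n_gene_go_edges == truth.counts["gene_go_edges"]

    def test_per_term_compound_sets_match_ground_truth(
        self, fixture_kb, fixture_sources
    ):
        truth = fixture_sources["truth"]
        derived = {t: sorted(v) for t, v in fixture_kb.term_compounds.items()}
        assert derived == truth.term_compounds

    def test_edge_to_term_outside_subtree_dropped_and_counted(
        self, tmp_path, fixture_sources
    ):
        src = fixture_sources["dir"]
        work = tmp_path / "contaminated"
        shutil.copytree(src, work, ignore=shutil.ignore_patterns("*.json", "*.txt"))
        with open(work / "go.obo", "a") as fh:
            fh.write("\n[Term]\nid: GO:0777777\nname: off-subtree\n")
        with open(work / "gene2go", "a") as fh:
            fh.write("9606\t10001\tGO:0777777\tIEA\t-\toff\t-\tProcess\n")
        manifest = {
            k: str(work / name)
            for k, name in {
                "obo": "go.obo",
                "enzyme_dat": "enzyme.dat",
                "gene2go": "gene2go",
                "gene2accession": "gene2accession",
                "gene2ec_table": "gene2ec.tsv",
                "ec2compound_table": "ec2compound.tsv",
            }.items()
        }
        kb, report = assemble_kb(config_from_manifest(manifest))
        assert report.dropped.get("gene_go_term_outside_subtree") == 1
        assert "GO:0777777" not in kb.terms

    def test_gzip_sources_accepted(self, tmp_path, fixture_sources):
        src = fixture_sources["dir"]
        manifest = dict(fixture_sources["manifest"])
        for key, name in (("gene2go", "gene2go"), ("gene2accession", "gene2accession")):
            gz = tmp_path / f"{name}.gz"
            gz.write_bytes(gzip.compress((src / name).read_bytes()))
            manifest[key] = str(gz)
        kb, _ = assemble_kb(config_from_manifest(manifest))
        assert kb_stats(kb).n_genes == fixture_sources["truth"].counts["genes"]

    def test_two_builds_serialize_byte_identically(self, tmp_path, fixture_sources):
        config = config_from_manifest(fixture_sources["manifest"])
        paths = []
        for i in (1, 2):
            kb, _ = assemble_kb(config)
            paths.append(save_kb(kb, tmp_path / f"kb{i}.json"))
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_missing_source_is_build_error(self, tmp_path):
        config = BuildConfig(
            obo=tmp_path / "none.obo",
            enzyme_dat=tmp_path / "none.dat",
            gene2go=tmp_path / "none",
            gene2accession=tmp_path / "none",
            gene2ec_table=tmp_path / "none",
            ec2compound_table=tmp_path / "none",
        )
        with pytest.raises(BuildError):
            assemble_kb(config)


class TestSerializationRoundTrip:
    @pytest.mark.parametrize("dialect", ["json", "tsv_dir"])
    def test_save_load_is_identity(self, tmp_path, fixture_kb, dialect):
        dest = tmp_path / ("kb.json" if dialect == "json" else "kbdir")
        save_kb(fixture_kb, dest)
        loaded = load_kb(dest)
        assert loaded.terms == fixture_kb.terms
        assert loaded.genes == fixture_kb.genes
        assert loaded.ecs == fixture_kb.ecs
        assert loaded.compounds == fixture_kb.compounds
        assert loaded.gene_go_edges == fixture_kb.gene_go_edges
        assert loaded.gene_ec_edges == fixture_kb.gene_ec_edges
        assert loaded.ec_compound_edges == fixture_kb.ec_compound_edges
        assert loaded.term_genes == fixture_kb.term_genes
        assert loaded.term_compounds == fixture_kb.term_compounds
        assert loaded.background == fixture_kb.background
        assert loaded.root_id == fixture_kb.root_id
        assert loaded.propagate == fixture_kb.propagate
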