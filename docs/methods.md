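# Methods

## Model

`metgoa` performs over-representation analysis (ORA) of a metabolite list
against Gene Ontology terms. The underlying model is sampling without
replacement: if the background universe holds *N* compound 2D structures of
which *y* are linked to a GO term, and the user's list contributes *b*
structures drawn from that universe, then under the null hypothesis the
overlap *X* with the term follows a hypergeometric distribution and the
reported p-value is the upper tail P(X ≥ x). The assumptions are the usual
ORA ones: the background is the correct sampling frame for the experiment,
input structures are exchangeable draws from it, and annotations are
independent of selection. Violations (assay chemistry biased toward
particular compound classes, incomplete EC→compound curation) shift the
effective background and can inflate or deflate enrichment.

Compound identity is the first 14-character block of the InChIKey, which
hashes the 2D skeleton; stereoisomers, protonation states and salts of one
skeleton therefore count as a single structure in *N*, *y*, *b* and *x*.

## Knowledgebase construction

Entities and links come from four standard distributions plus two explicit
link tables:

| source | format | contributes |
|---|---|---|
| GO ontology | OBO flat file | terms and is_a hierarchy |
| Expasy ENZYME | enzyme.dat flat file | EC records (active flag) |
| NCBI gene2go | TSV (gzip ok) | gene→GO edges, one taxon |
| NCBI gene2accession | TSV (gzip ok) | gene records with transcript/protein accessions |
| gene→EC table | 2-column TSV | gene→EC edges |
| EC→compound table | 2-column TSV | EC→InChIKey edges |

The gene→EC and EC→compound links are accepted as plain tables because no
single canonical flat-file distribution exists for them; the build report
records per-source row counts for provenance.

Restrictions applied during assembly: terms are the non-obsolete subtree
from which GO:0008152 (*metabolic process*) is is_a-reachable, with parent
sets pruned to the subtree; genes are one taxon (default 9606); gene→GO
rows with a NOT qualifier are excluded (they assert non-membership) while
all evidence codes are kept; alternate GO ids are resolved to their primary
id; edges touching inactive (transferred/deleted) ECs or entities outside
the restricted sets are dropped and counted in the build report. Only is_a
relations shape the hierarchy — part_of and regulates are ignored, matching
the subsumption-tree semantics of the exported GO network.

Per-term annotation sets are then derived: `term_genes[T]` is the set of
genes directly annotated to T plus, under the true-path rule (default), the
genes of all descendants; `term_compounds[T]` is the image of those genes
under the gene→EC→compound composition. The background is the union of all
per-term compound sets. Propagation is exposed as a switch
(`--no-propagate`) because reasonable ORA implementations exist on both
conventions; with propagation off, parents keep only their direct
annotations.

## Statistics and numerics

- The upper tail is evaluated through the hypergeometric survival function
  (scipy), never as 1 − CDF, so p-values of 1e-30 keep full relative
  accuracy. The test suite checks agreement with exact integer/rational
  enumeration of the PMF to within 1e-12 relative error over the full grid
  of populations up to 60.
- x = 0 returns exactly 1.0.
- FDR control is Benjamini–Hochberg step-up (statsmodels), applied across
  **all** testable terms (y ≥ 1) before any filtering; terms with y = 0 are
  untestable and excluded from the adjustment universe. Filters afterwards
  only set flags, preserving the full table.
- −log10 is used for the impact-plot ordinate; p > 0 is guaranteed by the
  test so the value is finite.
- Result ordering is total and deterministic: ascending p, ties broken by
  descending overlap, then ascending term id.
- Exported floats use Python `repr`, the shortest representation that
  round-trips to the identical double.

### Filter parameters

| filter | default | comparison | meaning |
|---|---|---|---|
| min_overlap | 3 | x ≥ 3 | enough observed structures |
| min_genes | 3 | genes ≥ 3 | term backed by several genes |
| max_set_fraction | 0.05 | y < 0.05·N | exclude very broad terms |
| fdr_alpha | 0.05 | q < 0.05 | multiplicity control |
| min_overlap_fraction_of_set | 0.05 | x > 0.05·y | overlap meaningful relative to the set |

The strict/non-strict directions above are part of the contract and are
tested at the exact boundaries (x = 2 vs 3, y at exactly 5 % of N, q at
0.049 vs 0.05, x at exactly 5 % of y).

## Network and table exports

The GO network export selects either all tested terms or only those passing
every filter, closes the selection upward over ancestors so each selected
term stays connected to the root, and writes the induced is_a subgraph as
Cytoscape SIF plus a node-attribute TSV. Node size encodes significance as
−log10(q) clamped to [0.5, 20]; connectivity-only ancestors sit at the
floor. The clamp bounds are a display choice — the source material for this
visualization states only that larger nodes are more significant.

## Synthetic data generator

`metgoa.fixtures` emits miniature but dialect-faithful source files: a
random is_a DAG rooted at GO:0008152 (default 50 terms, depth ≤ 5), 150
genes, 80 ECs and 520 compound structures (500 random + 20 dedicated to a
planted term), with every enzyme held by at least one gene so the
background spans the compound pool (~520). A planted leaf term receives 3
dedicated genes, 2 dedicated ECs and exactly 20 dedicated compounds,
disjoint from the random fabric; input lists draw 12 structures from the
planted set plus 48 uniform decoys from the rest of the background,
emulating a study in which one specific process is genuinely perturbed
(expected chance overlap ≈ 60·20/520 ≈ 2.3 versus the planted 12). These
sizes keep the planted term inside every filter boundary (20 < 5 % of 520;
3 genes; 12 ≥ 3 and 12 > 1) while remaining small enough that hundreds of
full build-and-analyze replicates run in seconds. The generator computes
its own ground truth (per-term compound sets, background, census and edge
counts) by brute-force reachability, independently of the production
derivation code, and records it as JSON.

What the generator does **not** emulate: realistic GO topology (term
fan-out, depth distribution), realistic annotation sparsity, correlated
compound–enzyme structure (substrate promiscuity, pathway chaining),
chemically meaningful InChIKeys (suffixes are random valid-layout strings;
only the 14-character prefix carries identity), or measurement-level noise.
Passing the planted-recovery tests therefore demonstrates correctness of
the counting, testing and filtering machinery under a known signal — not
calibration of the method on real metabolomics data, where background
choice and annotation completeness dominate.

Optional contaminants — off-taxon rows, an obsolete ontology term, a
transferred EC with dangling compound links, malformed input keys — are
planted with recorded counts to verify that the build's restriction and
reporting logic drops exactly what it should. Malformed keys are planted in
the generated input list (where they are rejected and counted during
normalization) rather than in the EC→compound table, where a malformed key
is by contract a fatal validation error rather than a droppable row.

## Degenerate inputs and edge behavior

- A single-term ontology (root only) builds and analyzes normally.
- An input list with no background matches aborts the analysis with an
  advisory error (exit code 2 from the CLI) rather than returning an empty
  table.
- Cycles in the is_a graph are detected during derivation and reported with
  a member term.
- Obsolete terms lose their parents at load time and are excluded from the
  subtree; their annotations are dropped and counted.
- Partial ("1.1.1.-") and preliminary ("1.1.1.n5") EC numbers are accepted.

## Serialization

The knowledgebase round-trips through either a single JSON document or a
directory of TSV tables (chosen by destination suffix), both fully sorted so
identical builds serialize byte-identically. Metadata carries the schema
version, root, propagation flag and SHA-256 checksums of the source files;
the build timestamp lives in the separate plain-text build report so that
determinism of the KB artifact itself is preserved.

## Known limitations

- Coverage is bounded by EC→compound curation: compounds without an EC link
  can never contribute, and the background shifts with curation depth.
- Gene→EC links are consumed as given; no attempt is made to reconcile
  conflicting assignments.
- Term-name redundancy in GO can make several near-duplicate terms pass
  together; the tool reports them all and leaves interpretation to the user.
- Only metabolite-list ORA is implemented; gene/transcript/protein list
  enrichment is out of scope.
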