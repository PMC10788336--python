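# metgoa

Gene Ontology over-representation analysis for **metabolite lists**.

Pathway analysis of metabolomics data usually stops at hand-curated pathway
maps, whose definitions and metabolite coverage differ between databases.
`metgoa` instead interprets a list of significant metabolites against the
Gene Ontology: it builds a metabolism-restricted knowledgebase linking GO
terms → genes → Enzyme Commission (EC) numbers → compound 2D structures,
and then asks which metabolic GO terms are over-represented in the input
list. It is aimed at metabolomics researchers who have a list of InChIKeys
for compounds that changed in an experiment and want process-level
interpretation beyond pathway maps.

## The statistic

Every compound is identified by the **first 14 characters of its InChIKey**
(the block that hashes the 2D skeleton), so stereoisomers and salt forms
collapse to one structure. Let

- *N* — background: distinct 2D structures linked to at least one metabolic
  GO term in the knowledgebase,
- *y* — structures linked to a given GO term (set size),
- *a = N − y* — structures not linked to that term,
- *b* — input structures found in the background,
- *x* — the overlap between the input and the term's set.

The enrichment p-value is the hypergeometric upper tail

```
p = P(X ≥ x),   X ~ Hypergeom(y successes, a failures, b draws)
```

(R's `phyper(x-1, y, a, b, lower.tail = FALSE)`). p-values are adjusted
across all testable terms with Benjamini–Hochberg FDR, and five filters
flag the terms worth reporting: x ≥ 3; at least 3 genes on the term; y <
5 % of *N*; FDR q < 0.05; x > 5 % of y. Filters mark rather than drop rows,
so the full table stays inspectable.

The knowledgebase is restricted to the subtree under *metabolic process*
(GO:0008152) and to one taxon (human by default). Annotations follow the
true-path rule (a gene on a term counts for all its ancestors); propagation
can be disabled with `--no-propagate`.

## Worked example

The package ships a deterministic generator of miniature synthetic sources
(`metgoa make-fixtures`), so the whole pipeline can be exercised without
downloads:

```sh
metgoa make-fixtures --seed 42 --out-dir sources
metgoa build-kb --obo sources/go.obo --enzyme sources/enzyme.dat \
  --gene2go sources/gene2go --gene2accession sources/gene2accession \
  --gene2ec sources/gene2ec.tsv --ec2compound sources/ec2compound.tsv \
  --out kb.json
metgoa run --kb kb.json --input sources/input_list.txt --out-dir results
```

The run reports (standard error):

```
raw_entries = 60
deduplicated_prefixes = 60
matched_b = 60
rejected = 0
background_N = 520
terms_tested = 49
terms_passing_all_filters = 1
```

and the top row of `results/results.csv` is the planted term:

```
GO:1000025,synthetic process 25,12,20,3,1.1790162610081972e-07,...,True
```

i.e. x = 12 of the b = 60 matched structures fall in a term set of y = 20
within N = 520, giving p ≈ 1.18e-07 — far beyond the ~2.3 structures
expected by chance — and the term passes all five filters. `results/` also
contains the Cytoscape network (`network.sif` + `nodes.tsv`, node size
encoding −log10 q), the impact-plot table (`impact.tsv`: set size vs
−log10 p, small sets = specific processes), and `run.log`.

`metgoa query --kb kb.json --compound <InChIKey>` (or `--ec`, `--gene`,
`--protein`, `--transcript`) lists the metabolic GO terms associated with a
single entity; `metgoa stats --kb kb.json` prints the knowledgebase census.

## Layout

- `src/metgoa/model.py` — domain types, DAG traversal, annotation derivation
- `src/metgoa/build.py` — source-format parsers and KB assembly
- `src/metgoa/ora.py` — input normalization, hypergeometric test, FDR, filters
- `src/metgoa/export.py` — results CSV, SIF network, impact table
- `src/metgoa/fixtures.py` — deterministic synthetic sources with ground truth
- `src/metgoa/cli.py` — `metgoa` command-line interface
- `docs/methods.md` — model, parameters, design choices, limitations
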