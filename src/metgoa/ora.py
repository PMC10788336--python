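"""Over-representation analysis for a metabolite list.

Each metabolite is represented by the first 14 characters of its InChIKey —
the block hashing the 2D skeleton — so stereoisomers and salt forms collapse
to one structure.  For a GO term annotated with y of the N background
structures, and an input list of which b structures match the background,
the probability of observing at least the x structures that overlap the term
is the upper tail of the hypergeometric distribution:

    P(X >= x),  X ~ Hypergeometric(N = y + a, y successes, b draws)

with a = N − y the structures not linked to the term (R's
``phyper(x-1, y, a, b, lower.tail = FALSE)``).  p-values are adjusted across
all testable terms with the Benjamini–Hochberg step-up procedure, and five
filters flag the terms worth reporting:

1. overlap x >= 3;
2. at least 3 genes annotated to the term;
3. term set size y < 5% of the background;
4. FDR q < 0.05;
5. overlap x > 5% of the term set size y.

Filters mark results rather than removing them, so the full table remains
inspectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ValidationError
from .model import INCHIKEY_FULL_RE, INCHIKEY_PREFIX_RE, Knowledgebase


@dataclass
class FilterParams:
    """Thresholds of the five reporting filters."""

    min_overlap: int = 3
    min_genes: int = 3
    max_set_fraction: float = 0.05
    fdr_alpha: float = 0.05
    min_overlap_fraction_of_set: float = 0.05

    def __post_init__(self) -> None:
        if self.min_overlap < 0 or self.min_genes < 0:
            raise ValidationError("count thresholds must be nonnegative")
        for name in ("max_set_fraction", "fdr_alpha", "min_overlap_fraction_of_set"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValidationError(f"{name} must lie in (0, 1], got {value}")


@dataclass
class InputList:
    """Normalized user input: 2D-structure prefixes with match bookkeeping."""

    raw_entries: list[str]
    prefixes: set[str]
    rejected: list[tuple[str, str]]  # (entry, reason)
    matched: set[str] = field(default_factory=set)
    unmatched: set[str] = field(default_factory=set)


@dataclass
class EnrichmentResult:
    """Per-term outcome of the over-representation test."""

    term_id: str
    term_name: str
    overlap_x: int
    set_size_y: int
    complement_a: int
    gene_count: int
    p_value: float
    q_value: float
    neg_log10_p: float
    overlap_prefixes: set[str]
    passes: dict[str, bool]

    @property
    def passes_all(self) -> bool:
        return self.passes["all"]


FILTER_NAMES = (
    "min_overlap",
    "min_genes",
    "max_set_fraction",
    "fdr",
    "min_overlap_fraction",
)


def normalize_input(raw: Sequence[str]) -> InputList:
    """Trim, uppercase and reduce entries to 14-character 2D prefixes.

    Full 27-character hyphenated InChIKeys reduce to their first block; bare
    14-letter prefixes pass through; anything else is recorded as rejected
    with a reason.  Duplicate structures collapse.
    """
    raw_entries: list[str] = []
    prefixes: set[str] = set()
    rejected: list[tuple[str, str]] = []
    for entry in raw:
        text = entry.strip()
        if not text:
            continue
        raw_entries.append(entry)
        candidate = text.upper()
        if INCHIKEY_FULL_RE.match(candidate):
            prefixes.add(candidate[:14])
        elif INCHIKEY_PREFIX_RE.match(candidate):
            prefixes.add(candidate)
        else:
            rejected.append(
                (text, "not a 27-character 14-10-1 InChIKey or 14-letter prefix")
            )
    return InputList(raw_entries=raw_entries, prefixes=prefixes, rejected=rejected)


def read_input_file(path: str | Path, column: str | None = None) -> list[str]:
    """Read identifiers from a plain list (one per line, "#" comments) or a
    CSV column."""
    import pandas as pd

    path = Path(path)
    if column is not None or path.suffix.lower() == ".csv":
        frame = pd.read_csv(path)
        if column is None:
            # pick the single column, or a conventionally named one
            candidates = [
                c for c in frame.columns if c.strip().lower() in ("inchikey", "inchikeys")
            ]
            if len(frame.columns) == 1:
                column = frame.columns[0]
            elif candidates:
                column = candidates[0]
            else:
                raise ValidationError(
                    "CSV input needs --column to name the InChIKey column; "
                    f"found columns {list(frame.columns)}"
                )
        if column not in frame.columns:
            raise ValidationError(f"column {column!r} not present in {path}")
        return [str(v) for v in frame[column].dropna()]
    lines = path.read_text(encoding="utf-8").splitlines()
    return [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]


def hypergeom_upper_tail(
    x: int, successes_y: int, failures_a: int, draws_b: int
) -> float:
    """P(X >= x) for X hypergeometric: ``draws_b`` draws without replacement
    from ``successes_y`` successes and ``failures_a`` failures.

    Evaluated through the survival function, so small upper tails are not
    computed as 1 minus a near-1 CDF.
    """
    for name, value in (
        ("x", x),
        ("successes_y", successes_y),
        ("failures_a", failures_a),
        ("draws_b", draws_b),
    ):
        if not isinstance(value, (int, np.integer)) or value < 0:
            raise ValidationError(f"{name} must be a nonnegative integer, got {value!r}")
    if x > draws_b:
        raise ValidationError(f"x={x} exceeds the number of draws b={draws_b}")
    if draws_b > successes_y + failures_a:
        raise ValidationError(
            f"draws_b={draws_b} exceeds the population size "
            f"{successes_y + failures_a}"
        )
    if x == 0:
        return 1.0
    return float(
        hypergeom.sf(x - 1, successes_y + failures_a, successes_y, draws_b)
    )


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted q-values, in input order."""
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        return []
    if np.any((ps < 0) | (ps > 1)) or np.any(np.isnan(ps)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(ps, method="fdr_bh")
    return [float(v) for v in q]


def match_input(kb: Knowledgebase, input_list: InputList) -> InputList:
    """Split the input prefixes into matched/unmatched against the background."""
    input_list.matched = input_list.prefixes & kb.background
    input_list.unmatched = input_list.prefixes - kb.background
    return input_list


def run_ora(
    kb: Knowledgebase,
    input_list: InputList,
    params: FilterParams | None = None,
) -> list[EnrichmentResult]:
    """Test every GO term with a nonempty compound set against the input.

    q-values are adjusted across all tested terms before any filtering;
    the five filters only set flags.  Results are ordered by ascending p,
    ties broken by descending overlap then ascending term id.
    """
    params = params or FilterParams()
    if not kb.term_compounds:
        raise AnalysisError("knowledgebase has no derived annotation sets")
    match_input(kb, input_list)
    matched = input_list.matched
    if not matched:
        raise AnalysisError(
            "no input structure matches the knowledgebase background; check that "
            "entries are InChIKeys (or 14-character prefixes) and that the KB "
            "covers the study's chemistry"
        )
    n_background = len(kb.background)
    b = len(matched)

    rows: list[EnrichmentResult] = []
    p_list: list[float] = []
    for term_id in sorted(kb.term_compounds):
        term_set = kb.term_compounds[term_id]
        y = len(term_set)
        if y == 0:
            continue  # untestable; excluded from the BH universe
        overlap = term_set & matched
        x = len(overlap)
        a = n_background - y
        p = hypergeom_upper_tail(x, y, a, b)
        p_list.append(p)
        rows.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=kb.terms[term_id].name if term_id in kb.terms else "",
                overlap_x=x,
                set_size_y=y,
                complement_a=a,
                gene_count=len(kb.term_genes.get(term_id, ())),
                p_value=p,
                q_value=math.nan,
                neg_log10_p=-math.log10(p) if p > 0 else math.inf,
                overlap_prefixes=overlap,
                passes={},
            )
        )

    q_list = bh_fdr(p_list)
    for row, q in zip(rows, q_list):
        row.q_value = q
        row.passes = evaluate_filters(
            row.overlap_x, row.set_size_y, row.gene_count, q, n_background, params
        )

    rows.sort(key=lambda r: (r.p_value, -r.overlap_x, r.term_id))
    return rows


def evaluate_filters(
    overlap_x: int,
    set_size_y: int,
    gene_count: int,
    q_value: float,
    n_background: int,
    params: FilterParams | None = None,
) -> dict[str, bool]:
    """Filter flags for one candidate term, without running the test.

    The comparisons keep their printed strictness: >= for the overlap and
    gene-count minima, strict < for the set-size and FDR caps, strict > for
    the overlap fraction.
    """
    params = params or FilterParams()
    flags = {
        "min_overlap": overlap_x >= params.min_overlap,
        "min_genes": gene_count >= params.min_genes,
        "max_set_fraction": set_size_y < params.max_set_fraction * n_background,
        "fdr": q_value < params.fdr_alpha,
        "min_overlap_fraction": overlap_x
        > params.min_overlap_fraction_of_set * set_size_y,
    }
    flags["all"] = all(flags.values())
    return flags


def impact_table(results: Sequence[EnrichmentResult]):
    """Set size vs −log10(p) per term, in result order (the impact plot's
    coordinates: small set size means a more specific process)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "set_size_y": [r.set_size_y for r in results],
            "neg_log10_p": [r.neg_log10_p for r in results],
            "passes_all": [r.passes_all for r in results],
        }
    )
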