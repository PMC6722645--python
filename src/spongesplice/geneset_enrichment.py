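"""Generic gene-set over-representation against a user-supplied annotation.

A hypergeometric upper-tail test (equivalently the one-sided Fisher test on
the induced 2x2) asks whether a query gene set overlaps an annotation term
more than expected given the universe.  Term databases are consumed in GMT
format; none are bundled.  The universe should normally be the genes that
could have appeared in the analysis at all (e.g. all genes in any event
table for a cell line), not the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrichment import ContingencyTable, fisher_exact


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    term_name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty gene set")


@dataclass(frozen=True)
class AnnotationTable:
    terms: tuple[GeneSetTerm, ...]

    def __post_init__(self):
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValueError("term_ids must be unique")

    def __iter__(self):
        return iter(self.terms)

    def __len__(self):
        return len(self.terms)


def read_gmt(path, source: str = "") -> AnnotationTable:
    """Read a GMT file: term_id <tab> description <tab> gene1 <tab> gene2..."""
    terms = []
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{line_number}: GMT line needs id, name and >= 1 gene"
                )
            terms.append(
                GeneSetTerm(
                    term_id=fields[0],
                    term_name=fields[1],
                    genes=frozenset(g for g in fields[2:] if g),
                    source=source,
                )
            )
    return AnnotationTable(terms=tuple(terms))


def write_gmt(annotation: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        for term in annotation:
            genes = "\t".join(sorted(term.genes))
            fh.write(f"{term.term_id}\t{term.term_name}\t{genes}\n")


def overrepresentation(
    query: Iterable[str],
    annotation: AnnotationTable,
    universe: Iterable[str],
    alpha: float = 0.05,
    method: str = "BH",
    report_all: bool = False,
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation of ``query`` in ``universe``.

    For each term with gene set T (intersected with the universe), the
    p-value is the upper tail P(overlap >= k) of Hypergeom(|U|, |T|, |q|).
    P-values are BH-adjusted across all tested terms.  By default only terms
    with raw p < ``alpha`` are returned; ``report_all`` keeps every term,
    including zero-overlap ones at p = 1.
    """
    universe_set = set(universe)
    query_set = set(query)
    if not query_set:
        return _empty_results()
    missing = query_set - universe_set
    if missing:
        raise ValueError(
            f"query contains {len(missing)} gene(s) outside the universe, "
            f"e.g. {sorted(missing)[:3]}"
        )

    rows = []
    for term in annotation:
        term_genes = term.genes & universe_set
        if not term_genes:
            continue
        overlap = query_set & term_genes
        k = len(overlap)
        if k == 0 and not report_all:
            continue
        # induced 2x2: query vs rest, in-term vs out-of-term
        table = ContingencyTable(
            x=k,
            y=len(query_set) - k,
            a=len(term_genes) - k,
            b=len(universe_set) - len(query_set) - (len(term_genes) - k),
        )
        _, pvalue = fisher_exact(table, alternative="greater")
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "source": term.source,
                "n_term": len(term_genes),
                "n_query": len(query_set),
                "n_universe": len(universe_set),
                "overlap": k,
                "pvalue": pvalue,
                "genes": ",".join(sorted(overlap)),
            }
        )
    if not rows:
        return _empty_results()
    df = pd.DataFrame(rows)
    method_map = {"BH": "fdr_bh", "bonferroni": "bonferroni", "BY": "fdr_by"}
    _, adjusted, _, _ = multipletests(df["pvalue"].to_numpy(), method=method_map[method])
    df["p_adjusted"] = adjusted
    if not report_all:
        df = df[df["pvalue"] < alpha]
    df = df.sort_values(["pvalue", "term_id"]).reset_index(drop=True)
    return df


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "term_id",
            "term_name",
            "source",
            "n_term",
            "n_query",
            "n_universe",
            "overlap",
            "pvalue",
            "genes",
            "p_adjusted",
        ]
    )
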