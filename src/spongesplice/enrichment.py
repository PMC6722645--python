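"""Fisher's exact enrichment of RBP binding near a lncRNA's splice events.

For each (cell line, lncRNA, RBP) triple a 2x2 contingency table is built
from the bound/unbound flags of proximal regions:

===================  =========  ===========
                     bound      unbound
===================  =========  ===========
this lncRNA          x          y
all other lncRNAs    a          b
===================  =========  ===========

and the one-sided (enrichment) hypergeometric tail probability

    P(K >= x)  with  K ~ Hypergeom(N = x+y+a+b, K_total = x+a, n = x+y)

is computed with log-factorial (lgamma) arithmetic.  P-values are pooled per
cell line and adjusted (Benjamini-Hochberg by default); the heatmap cell is
-log10(adjusted p).

Null-row contract: an RBP with *no unbound region anywhere in the cell line*
admits no informative contrast (every lncRNA's table is degenerate in the
unbound margin), so its cells are NULL — not zero — for every lncRNA.  NULL
is serialized as "NA" and rendered grey in heatmaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .interval_intersect import BindingFlagTable

ALTERNATIVES = ("greater", "less", "two-sided")
ADJUST_METHODS = {"BH": "fdr_bh", "bonferroni": "bonferroni", "BY": "fdr_by"}


class DegenerateTableError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """Bound/unbound counts: x, y for the focal lncRNA; a, b for background."""

    x: int
    y: int
    a: int
    b: int

    def __post_init__(self):
        if min(self.x, self.y, self.a, self.b) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.x + self.y + self.a + self.b

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.a, self.b)


@dataclass
class EnrichmentResult:
    cell_line: str
    lncrna: str
    rbp: str
    table: ContingencyTable
    odds_ratio: float
    pvalue: float | None
    p_adjusted: float | None = None
    neg_log_p_adj: float | None = None

    @property
    def is_null(self) -> bool:
        return self.pvalue is None


# ---------------------------------------------------------------------------
# Fisher's exact test (log-factorial implementation)
# ---------------------------------------------------------------------------


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _hypergeom_log_pmf_support(table: ContingencyTable):
    """Support and log-PMF of x conditional on all margins."""
    n1 = table.x + table.y          # regions of the focal lncRNA
    k_total = table.x + table.a     # bound regions overall
    n = table.n_total
    lo = max(0, n1 - (n - k_total))
    hi = min(n1, k_total)
    log_denom = _log_comb(n, n1)
    support = range(lo, hi + 1)
    log_pmf = [
        _log_comb(k_total, k) + _log_comb(n - k_total, n1 - k) - log_denom
        for k in support
    ]
    return support, log_pmf


def fisher_exact(
    table: ContingencyTable, alternative: str = "greater"
) -> tuple[float, float | None]:
    """Odds ratio and exact hypergeometric p-value for a 2x2 table.

    The odds ratio is (x*b)/(y*a), infinite when y*a == 0 with x*b > 0 and
    NaN when both products vanish.  The p-value conditions on the margins:
    ``greater`` sums the upper tail P(K >= x), ``less`` the lower tail, and
    ``two-sided`` all outcomes with PMF <= PMF(x)*(1 + 1e-7).  An all-zero
    table is undefined and yields a null result (NaN, None).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if table.n_total == 0:
        return (math.nan, None)

    num = table.x * table.b
    den = table.y * table.a
    if den > 0:
        odds_ratio = num / den
    elif num > 0:
        odds_ratio = math.inf
    else:
        odds_ratio = math.nan

    support, log_pmf = _hypergeom_log_pmf_support(table)
    pmf = [math.exp(v) for v in log_pmf]
    x = table.x
    if alternative == "greater":
        p = sum(p_k for k, p_k in zip(support, pmf) if k >= x)
    elif alternative == "less":
        p = sum(p_k for k, p_k in zip(support, pmf) if k <= x)
    else:
        cutoff = pmf[x - support.start] * (1.0 + 1e-7)
        p = sum(p_k for p_k in pmf if p_k <= cutoff)
    return (odds_ratio, min(1.0, max(0.0, p)))


# ---------------------------------------------------------------------------
# Contingency construction and per-cell-line enrichment
# ---------------------------------------------------------------------------


def build_contingency(
    flag_table: BindingFlagTable, lncrna: str, rbp: str
) -> ContingencyTable:
    """Count x, y over the lncRNA's regions; a, b over all other regions."""
    if rbp not in flag_table.flags.columns:
        raise KeyError(f"RBP {rbp!r} has no peaks in cell line {flag_table.cell_line!r}")
    mask = (flag_table.lncrna == lncrna).to_numpy()
    if not mask.any():
        raise DegenerateTableError(
            f"lncRNA {lncrna!r} has no regions in cell line {flag_table.cell_line!r}"
        )
    col = flag_table.flags[rbp].to_numpy()
    x = int(np.count_nonzero(col & mask))
    y = int(np.count_nonzero(~col & mask))
    a = int(np.count_nonzero(col & ~mask))
    b = int(np.count_nonzero(~col & ~mask))
    return ContingencyTable(x=x, y=y, a=a, b=b)


def enrich_cell_line(
    flag_table: BindingFlagTable,
    alternative: str = "greater",
    method: str = "BH",
    per_gene: bool = False,
) -> list[EnrichmentResult]:
    """One Fisher test per (lncRNA, RBP) in a cell line, then adjust p-values.

    With ``per_gene=True`` regions are first collapsed to (lncRNA, gene)
    units (a gene counts as bound if any of its six regions is).  RBPs with
    no unbound region anywhere in the cell line yield NULL results for every
    lncRNA (no test is performed; see module docstring).
    """
    if per_gene:
        flag_table = flag_table.collapse_to_genes()
    results: list[EnrichmentResult] = []
    for rbp in flag_table.rbps:
        saturated = bool(flag_table.flags[rbp].all())
        for lncrna in sorted(flag_table.lncrnas):
            table = build_contingency(flag_table, lncrna, rbp)
            if saturated:
                results.append(
                    EnrichmentResult(
                        cell_line=flag_table.cell_line,
                        lncrna=lncrna,
                        rbp=rbp,
                        table=table,
                        odds_ratio=math.nan,
                        pvalue=None,
                    )
                )
                continue
            odds_ratio, pvalue = fisher_exact(table, alternative=alternative)
            results.append(
                EnrichmentResult(
                    cell_line=flag_table.cell_line,
                    lncrna=lncrna,
                    rbp=rbp,
                    table=table,
                    odds_ratio=odds_ratio,
                    pvalue=pvalue,
                )
            )
    adjust_pvalues(results, method=method)
    return results


def adjust_pvalues(
    results: Sequence[EnrichmentResult], method: str = "BH"
) -> Sequence[EnrichmentResult]:
    """Adjust pooled p-values in place; null results stay null and are
    excluded from the number of tests m."""
    if method not in ADJUST_METHODS:
        raise ValueError(f"method must be one of {sorted(ADJUST_METHODS)}")
    tested = [r for r in results if r.pvalue is not None]
    if not tested:
        return results
    pvals = np.array([r.pvalue for r in tested], dtype=float)
    _, adjusted, _, _ = multipletests(pvals, method=ADJUST_METHODS[method])
    for r, p_adj in zip(tested, adjusted):
        r.p_adjusted = float(p_adj)
        r.neg_log_p_adj = (-math.log10(p_adj) + 0.0) if p_adj > 0 else math.inf
    return results


def enrichment_heatmap_matrix(
    results: Iterable[EnrichmentResult],
    cell_line: str,
    cluster: bool = True,
    linkage_method: str = "average",
) -> pd.DataFrame:
    """lncRNA x RBP matrix of -log10(adjusted p); NULL cells are NaN.

    Rows and columns are ordered by hierarchical clustering with the
    1 - Spearman rank correlation distance (NaNs treated as 0 for distance
    purposes only); pass ``cluster=False`` for sorted-label order.
    """
    rows = [r for r in results if r.cell_line == cell_line]
    if not rows:
        return pd.DataFrame()
    frame = pd.DataFrame(
        [
            {
                "lncrna": r.lncrna,
                "rbp": r.rbp,
                "value": math.nan if r.neg_log_p_adj is None else r.neg_log_p_adj,
            }
            for r in rows
        ]
    )
    matrix = frame.pivot(index="lncrna", columns="rbp", values="value")
    matrix = matrix.loc[sorted(matrix.index), sorted(matrix.columns)]
    if cluster and matrix.shape[0] >= 2 and matrix.shape[1] >= 2:
        from .sponge_analysis import cluster as _cluster

        order = _cluster(matrix.fillna(0.0), linkage_method=linkage_method)
        matrix = matrix.loc[order.row_order, order.col_order]
    return matrix


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Flat results table; NULL p-values serialized as NA."""
    return pd.DataFrame(
        [
            {
                "cell_line": r.cell_line,
                "lncrna": r.lncrna,
                "rbp": r.rbp,
                "x": r.table.x,
                "y": r.table.y,
                "a": r.table.a,
                "b": r.table.b,
                "odds_ratio": r.odds_ratio,
                "pvalue": math.nan if r.pvalue is None else r.pvalue,
                "p_adjusted": math.nan if r.p_adjusted is None else r.p_adjusted,
                "neg_log_p_adj": math.nan
                if r.neg_log_p_adj is None
                else r.neg_log_p_adj,
                "null_result": r.is_null,
            }
            for r in results
        ]
    )


def results_from_frame(df: pd.DataFrame) -> list[EnrichmentResult]:
    out = []
    for rec in df.to_dict("records"):
        null = bool(rec.get("null_result", False)) or (
            isinstance(rec["pvalue"], float) and math.isnan(rec["pvalue"])
        )
        out.append(
            EnrichmentResult(
                cell_line=str(rec["cell_line"]),
                lncrna=str(rec["lncrna"]),
                rbp=str(rec["rbp"]),
                table=ContingencyTable(
                    int(rec["x"]), int(rec["y"]), int(rec["a"]), int(rec["b"])
                ),
                odds_ratio=float(rec["odds_ratio"]),
                pvalue=None if null else float(rec["pvalue"]),
                p_adjusted=None if null else float(rec["p_adjusted"]),
                neg_log_p_adj=None if null else float(rec["neg_log_p_adj"]),
            )
        )
    return out


def plot_heatmap(matrix: pd.DataFrame, path, title: str = "") -> None:
    """Optional PNG/SVG rendering; NULL (NaN) cells are drawn grey."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.shape[1]), max(3, 0.4 * matrix.shape[0]))
    )
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad(color="0.6")
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="-log10(adjusted p)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
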