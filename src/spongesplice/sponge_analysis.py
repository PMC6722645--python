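"""RBP-sponge breadth scoring, Spearman-distance clustering, and the
binding-vs-splicing correlation.

The sponge model posits that an abundant lncRNA titrates many RBPs away from
pre-mRNA targets, so its knockdown releases binding broadly across RBPs.  We
operationalize that as the *breadth* score: the fraction of tested RBPs whose
binding is significantly enriched (adjusted p < alpha) near the splice events
triggered by the knockdown.  NULL enrichment cells are excluded from both the
numerator and the denominator.

Matrices are clustered hierarchically with the 1 - Spearman rank correlation
distance and average linkage (both configurable); vectors with zero variance
have undefined rank correlation and are assigned the maximum distance 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from scipy.spatial.distance import squareform

from .enrichment import EnrichmentResult
from .event_filtering import EventFrequencyMatrix


@dataclass
class SpongeProfile:
    """Binding breadth of one lncRNA knockdown in one cell line."""

    lncrna: str
    cell_line: str
    n_rbps_tested: int
    n_rbps_significant: int
    breadth: float | None
    rank: int | None = None
    flagged: bool = False  # all-null row: breadth undefined


def sponge_scores(
    results: Iterable[EnrichmentResult], alpha: float = 0.05
) -> list[SpongeProfile]:
    """Breadth profiles per lncRNA, ranked within each cell line.

    Sorted by breadth descending; ties broken by n_rbps_significant then
    lncRNA name.  lncRNAs whose row is entirely NULL get an undefined
    (flagged) profile ranked last.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    grouped: dict[str, dict[str, list[EnrichmentResult]]] = {}
    for r in results:
        grouped.setdefault(r.cell_line, {}).setdefault(r.lncrna, []).append(r)

    profiles: list[SpongeProfile] = []
    for cell_line in sorted(grouped):
        cell_profiles = []
        for lncrna in sorted(grouped[cell_line]):
            tested = [r for r in grouped[cell_line][lncrna] if not r.is_null]
            n_sig = sum(
                1 for r in tested if r.p_adjusted is not None and r.p_adjusted < alpha
            )
            if tested:
                profile = SpongeProfile(
                    lncrna=lncrna,
                    cell_line=cell_line,
                    n_rbps_tested=len(tested),
                    n_rbps_significant=n_sig,
                    breadth=n_sig / len(tested),
                )
            else:
                profile = SpongeProfile(
                    lncrna=lncrna,
                    cell_line=cell_line,
                    n_rbps_tested=0,
                    n_rbps_significant=0,
                    breadth=None,
                    flagged=True,
                )
            cell_profiles.append(profile)
        cell_profiles.sort(
            key=lambda p: (
                -(p.breadth if p.breadth is not None else -1.0),
                -p.n_rbps_significant,
                p.lncrna,
            )
        )
        for i, p in enumerate(cell_profiles, start=1):
            p.rank = i
        profiles.extend(cell_profiles)
    return profiles


def profiles_to_frame(profiles: Iterable[SpongeProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_line": p.cell_line,
                "lncrna": p.lncrna,
                "n_rbps_tested": p.n_rbps_tested,
                "n_rbps_significant": p.n_rbps_significant,
                "breadth": np.nan if p.breadth is None else p.breadth,
                "rank": p.rank,
                "undefined": p.flagged,
            }
            for p in profiles
        ]
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering with 1 - Spearman distance
# ---------------------------------------------------------------------------


def spearman_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise d(u, v) = 1 - Spearman rank correlation between rows of X.

    Rows with zero variance have undefined rank correlation; their distance
    to every other row is set to the maximum, 2.0 (with a warning), and the
    diagonal stays 0.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    ranks = np.vstack([stats.rankdata(row) for row in X])
    degenerate = ranks.std(axis=1) == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance vector(s): Spearman "
            "correlation undefined, distance set to 2.0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    dist = 1.0 - rho
    dist[degenerate, :] = 2.0
    dist[:, degenerate] = 2.0
    np.fill_diagonal(dist, 0.0)
    # guard tiny negative values from floating-point round-off
    return np.clip(dist, 0.0, 2.0)


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None
    row_newick: str = ""
    col_newick: str = ""
    row_distance: np.ndarray | None = None
    col_distance: np.ndarray | None = None


def _axis_cluster(frame: pd.DataFrame, linkage_method: str):
    labels = list(frame.index)
    dist = spearman_distance_matrix(frame.to_numpy(dtype=float))
    condensed = squareform(dist, checks=False)
    linkage = sch.linkage(condensed, method=linkage_method)
    order = [labels[i] for i in sch.leaves_list(linkage)]
    newick = _linkage_to_newick(linkage, labels)
    return order, linkage, newick, dist


def cluster(
    matrix: pd.DataFrame | EventFrequencyMatrix,
    axis: str = "both",
    linkage_method: str = "average",
) -> ClusterResult:
    """Hierarchically order matrix rows/columns by 1 - Spearman distance.

    Rows (and/or columns) are pre-sorted by label before distance
    computation so that tied merges resolve deterministically.
    """
    if isinstance(matrix, EventFrequencyMatrix):
        matrix = matrix.counts
    if axis not in ("rows", "columns", "both"):
        raise ValueError("axis must be 'rows', 'columns' or 'both'")
    frame = matrix.loc[sorted(matrix.index), sorted(matrix.columns)]

    result = ClusterResult(
        row_order=list(frame.index), col_order=list(frame.columns)
    )
    if axis in ("rows", "both"):
        if frame.shape[0] < 2:
            raise ValueError("need >= 2 rows to cluster rows")
        order, linkage, newick, dist = _axis_cluster(frame, linkage_method)
        result.row_order, result.row_linkage = order, linkage
        result.row_newick, result.row_distance = newick, dist
    if axis in ("columns", "both"):
        if frame.shape[1] < 2:
            raise ValueError("need >= 2 columns to cluster columns")
        order, linkage, newick, dist = _axis_cluster(frame.T, linkage_method)
        result.col_order, result.col_linkage = order, linkage
        result.col_newick, result.col_distance = newick, dist
    return result


def _linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage as a Newick-like tree with branch lengths."""
    tree = sch.to_tree(linkage)

    def sanitize(label: str) -> str:
        return label.replace("(", "_").replace(")", "_").replace(",", "_").replace(
            ":", "_"
        ).replace(";", "_").replace(" ", "_")

    def recurse(node, parent_dist: float) -> str:
        length = max(0.0, parent_dist - node.dist)
        if node.is_leaf():
            return f"{sanitize(labels[node.id])}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# Binding frequency vs splicing burden
# ---------------------------------------------------------------------------


@dataclass
class CorrelationReport:
    cell_line: str
    n: int
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float
    status: str  # "ok" | "insufficient_data" | "degenerate"
    significant: bool

    @property
    def message(self) -> str:
        if self.status == "insufficient_data":
            return f"{self.cell_line}: insufficient data (n={self.n} < 3)"
        if self.status == "degenerate":
            return f"{self.cell_line}: constant input, correlation undefined"
        verdict = "significant" if self.significant else "not significant"
        return (
            f"{self.cell_line}: Spearman rho={self.spearman_rho:.3f} "
            f"(p={self.spearman_p:.3g}), Pearson r={self.pearson_r:.3f} "
            f"(p={self.pearson_p:.3g}), n={self.n} — {verdict} at 0.05"
        )


def binding_splicing_correlation(
    se_matrix: EventFrequencyMatrix,
    profiles: Iterable[SpongeProfile],
    alpha: float = 0.05,
) -> list[CorrelationReport]:
    """Correlate per-lncRNA SE event counts with significant-RBP counts.

    Per cell line, x = total significant SE events of each knockdown (column
    sum of the SE frequency matrix) and y = that knockdown's
    n_rbps_significant; Spearman and Pearson coefficients are reported with
    p-values and n, explicitly flagging non-significance and the
    insufficient-data case (n < 3).
    """
    se_counts: dict[tuple[str, str], int] = {}
    for column, (lncrna, cell_line) in zip(
        se_matrix.counts.columns, se_matrix.samples
    ):
        se_counts[(lncrna, cell_line)] = int(se_matrix.counts[column].sum())

    by_cell: dict[str, list[tuple[int, int]]] = {}
    for p in profiles:
        key = (p.lncrna, p.cell_line)
        if key in se_counts and not p.flagged:
            by_cell.setdefault(p.cell_line, []).append(
                (se_counts[key], p.n_rbps_significant)
            )

    reports: list[CorrelationReport] = []
    for cell_line in sorted(by_cell):
        pairs = by_cell[cell_line]
        n = len(pairs)
        if n < 3:
            reports.append(
                CorrelationReport(
                    cell_line=cell_line,
                    n=n,
                    spearman_rho=np.nan,
                    spearman_p=np.nan,
                    pearson_r=np.nan,
                    pearson_p=np.nan,
                    status="insufficient_data",
                    significant=False,
                )
            )
            continue
        x = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([p[1] for p in pairs], dtype=float)
        if x.std() == 0 or y.std() == 0:
            reports.append(
                CorrelationReport(
                    cell_line=cell_line,
                    n=n,
                    spearman_rho=np.nan,
                    spearman_p=np.nan,
                    pearson_r=np.nan,
                    pearson_p=np.nan,
                    status="degenerate",
                    significant=False,
                )
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            srho, sp = stats.spearmanr(x, y)
            pr, pp = stats.pearsonr(x, y)
        reports.append(
            CorrelationReport(
                cell_line=cell_line,
                n=n,
                spearman_rho=float(srho),
                spearman_p=float(sp),
                pearson_r=float(pr),
                pearson_p=float(pp),
                status="ok",
                significant=bool(sp < alpha),
            )
        )
    return reports


def correlation_to_frame(reports: Iterable[CorrelationReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_line": r.cell_line,
                "n": r.n,
                "spearman_rho": r.spearman_rho,
                "spearman_p": r.spearman_p,
                "pearson_r": r.pearson_r,
                "pearson_p": r.pearson_p,
                "status": r.status,
                "significant": r.significant,
            }
            for r in reports
        ]
    )
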