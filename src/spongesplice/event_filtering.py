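"""Significance filtering, deduplication, and event-frequency matrices.

A knockdown comparison's rMATS events are first reduced to the significant
ones (strict ``fdr < fdr_max`` and ``pvalue < pvalue_max``), deduplicated on
their genomic identity, and then summarized into a per-event-type gene x
knockdown incidence matrix: how often each gene was alternatively spliced
when a given lncRNA was knocked down in a given cell line.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import SampleSheet, SpliceEvent, event_key


@dataclass(frozen=True)
class FilterConfig:
    """Significance thresholds applied to every comparison, strict inequalities."""

    fdr_max: float = 0.1
    pvalue_max: float = 0.05

    def __post_init__(self):
        for name, value in (("fdr_max", self.fdr_max), ("pvalue_max", self.pvalue_max)):
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")


def filter_events(
    events: Iterable[SpliceEvent], config: FilterConfig = FilterConfig()
) -> list[SpliceEvent]:
    """Retain exactly the events with fdr < fdr_max AND pvalue < pvalue_max.

    Inequalities are strict; input order is preserved.
    """
    return [
        ev
        for ev in events
        if ev.fdr < config.fdr_max and ev.pvalue < config.pvalue_max
    ]


def deduplicate_events(events: Iterable[SpliceEvent]) -> list[SpliceEvent]:
    """Drop repeated events; identity is (type, chrom, strand, six coordinates).

    The first occurrence is kept, so statistics always come from the first
    comparison that reported the event.
    """
    seen: set[tuple] = set()
    out: list[SpliceEvent] = []
    for ev in events:
        key = event_key(ev)
        if key not in seen:
            seen.add(key)
            out.append(ev)
    return out


def gene_label(event: SpliceEvent) -> str:
    """Gene identity used in matrices: symbol, with gene_id fallback."""
    symbol = event.gene_symbol.strip()
    if symbol and symbol.upper() not in ("NA", "NONE", "."):
        return symbol
    return event.gene_id


def sample_label(lncrna: str, cell_line: str) -> str:
    return f"{lncrna}|{cell_line}"


def split_sample_label(label: str) -> tuple[str, str]:
    lncrna, _, cell_line = label.rpartition("|")
    return lncrna, cell_line


@dataclass
class EventFrequencyMatrix:
    """Gene x knockdown-sample incidence counts for one event type.

    ``counts`` is indexed by gene symbol with one column per knockdown
    comparison, labeled ``lncrna|cell_line``.  Entry (g, s) is the number of
    unique significant events of this type in gene g for comparison s.
    """

    event_type: str
    counts: pd.DataFrame
    samples: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.samples:
            self.samples = [split_sample_label(c) for c in self.counts.columns]
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("matrix row/column labels must be duplicate-free")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def to_frame(self) -> pd.DataFrame:
        return self.counts

    @classmethod
    def from_frame(cls, event_type: str, frame: pd.DataFrame) -> "EventFrequencyMatrix":
        return cls(event_type=event_type, counts=frame.astype(int))


def build_frequency_matrix(
    sheet: SampleSheet,
    events_by_comparison: Mapping[str, Sequence[SpliceEvent]],
    event_type: str,
) -> EventFrequencyMatrix:
    """Count unique significant events per gene per comparison.

    ``events_by_comparison`` maps comparison_id to its *already filtered*
    events (all comparisons must use the same :class:`FilterConfig`); events
    of other types are ignored.  Genes whose row is all zero are removed.  A
    comparison in the sheet with no events supplied yields a zero column and
    a warning.
    """
    columns: dict[str, dict[str, int]] = {}
    samples: list[tuple[str, str]] = []
    for row in sheet:
        label = sample_label(row.lncrna, row.cell_line)
        samples.append((row.lncrna, row.cell_line))
        events = events_by_comparison.get(row.comparison_id)
        if events is None:
            warnings.warn(
                f"no {event_type} events for comparison {row.comparison_id!r}; "
                "emitting a zero column",
                stacklevel=2,
            )
            events = []
        counts: dict[str, int] = {}
        for ev in deduplicate_events(
            [e for e in events if e.event_type == event_type]
        ):
            g = gene_label(ev)
            counts[g] = counts.get(g, 0) + 1
        columns[label] = counts
    frame = pd.DataFrame(columns).fillna(0).astype(int)
    frame = frame.reindex(columns=list(columns))
    frame = frame.loc[sorted(frame.index)]
    frame = frame.loc[frame.sum(axis=1) > 0]  # drop unpopulated genes
    return EventFrequencyMatrix(event_type=event_type, counts=frame, samples=samples)


@dataclass
class SpecificitySummary:
    """Cross-cell-line sharing of alternatively spliced genes (Venn counts)."""

    gene_sets: dict[str, set[str]]
    pairwise: dict[tuple[str, str], int]
    venn_exclusive: dict[tuple[str, ...], int]
    n_genes_total: int
    n_shared: int
    shared_fraction: float
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "+".join(combo), "exclusive_genes": n}
            for combo, n in sorted(self.venn_exclusive.items())
        ]
        rows.append(
            {"subset": "shared_by_2plus_fraction", "exclusive_genes": self.shared_fraction}
        )
        return pd.DataFrame(rows)


def specificity_summary(
    matrix: EventFrequencyMatrix, by: str = "cell_line"
) -> SpecificitySummary:
    """Per-cell-line gene sets, Venn intersection counts, and sharing fraction.

    The sharing fraction is the number of genes alternatively spliced in at
    least two cell lines divided by all genes in the matrix.
    """
    if by != "cell_line":
        raise ValueError("only grouping by cell_line is supported")
    gene_sets: dict[str, set[str]] = {}
    for column, (_, cell_line) in zip(matrix.counts.columns, matrix.samples):
        nonzero = set(matrix.counts.index[matrix.counts[column] > 0])
        gene_sets.setdefault(cell_line, set()).update(nonzero)

    cell_lines = sorted(gene_sets)
    note = ""
    if len(cell_lines) < 2:
        note = "single cell line: cross-cell-line sharing is degenerate"

    pairwise = {
        (a, b): len(gene_sets[a] & gene_sets[b])
        for a, b in itertools.combinations(cell_lines, 2)
    }
    venn_exclusive: dict[tuple[str, ...], int] = {}
    for r in range(1, len(cell_lines) + 1):
        for combo in itertools.combinations(cell_lines, r):
            inside = set.intersection(*(gene_sets[c] for c in combo))
            outside: set[str] = set()
            for c in cell_lines:
                if c not in combo:
                    outside |= gene_sets[c]
            venn_exclusive[combo] = len(inside - outside)

    all_genes = set.union(*gene_sets.values()) if gene_sets else set()
    shared = {
        g for g in all_genes if sum(g in s for s in gene_sets.values()) >= 2
    }
    fraction = len(shared) / len(all_genes) if all_genes else 0.0
    return SpecificitySummary(
        gene_sets=gene_sets,
        pairwise=pairwise,
        venn_exclusive=venn_exclusive,
        n_genes_total=len(all_genes),
        n_shared=len(shared),
        shared_fraction=fraction,
        note=note,
    )
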