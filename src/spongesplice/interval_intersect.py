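"""Bespoke interval-overlap engine with bedtools-intersect semantics.

Region x peak overlap queries are answered by a per-chromosome sort-and-sweep
(never an all-pairs scan): both sides are sorted by start, a pointer admits
peaks into an active list as the sweep reaches them, and peaks whose end lies
at or before the current region start are retired.  Because regions are
processed in start order, a retired peak can never overlap a later region,
so the sweep is exact.  Complexity is O((n + m) log(n + m) + k + a) where k
is the output size and a the active-list scans.

Coordinates are 0-based half-open throughout, so abutting intervals
([x, y) and [y, z)) do not overlap — identical to ``bedtools intersect``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import RBPPeak, check_chrom_naming
from .proximal_regions import ProximalRegion


@dataclass(frozen=True)
class OverlapRecord:
    """One overlapping (region, peak) pair and the width of the overlap."""

    region: ProximalRegion
    peak: RBPPeak
    overlap_bp: int


def overlap_width(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Width of [max(starts), min(ends)); <= 0 means no overlap."""
    return min(a_end, b_end) - max(a_start, b_start)


def intersect(
    regions: Sequence[ProximalRegion],
    peaks: Sequence[RBPPeak],
    min_overlap: int = 1,
    stranded: bool = False,
    strict: bool = False,
) -> list[OverlapRecord]:
    """All (region, peak) pairs overlapping by at least ``min_overlap`` bp.

    Pairs on different chromosomes (or different strands, when ``stranded``)
    never match.  Each qualifying pair appears exactly once; output is sorted
    by (chrom, region start, peak start) and is deterministic.  With
    ``strict=True`` mixed ``chr1``/``1`` naming across the two inputs is
    rejected instead of silently yielding empty intersections.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    if strict:
        check_chrom_naming(
            [r.chrom for r in regions] + [p.chrom for p in peaks]
        )

    def group_key(item):
        return (item.chrom, item.strand) if stranded else (item.chrom,)

    regions_by_group: dict[tuple, list[ProximalRegion]] = {}
    for r in regions:
        regions_by_group.setdefault(group_key(r), []).append(r)
    peaks_by_group: dict[tuple, list[RBPPeak]] = {}
    for p in peaks:
        peaks_by_group.setdefault(group_key(p), []).append(p)

    records: list[OverlapRecord] = []
    for group in sorted(set(regions_by_group) & set(peaks_by_group)):
        grp_regions = sorted(regions_by_group[group], key=lambda r: (r.start, r.end))
        grp_peaks = sorted(peaks_by_group[group], key=lambda p: (p.start, p.end))
        active: list[RBPPeak] = []
        next_peak = 0
        for region in grp_regions:
            while next_peak < len(grp_peaks) and grp_peaks[next_peak].start < region.end:
                active.append(grp_peaks[next_peak])
                next_peak += 1
            # peaks ending at or before this region's start can never overlap
            # this or any later region (regions are start-sorted)
            active = [p for p in active if p.end > region.start]
            matches = []
            for peak in active:
                width = overlap_width(region.start, region.end, peak.start, peak.end)
                if width >= min_overlap:
                    matches.append((peak, width))
            matches.sort(key=lambda t: (t[0].start, t[0].end, t[0].rbp))
            records.extend(
                OverlapRecord(region=region, peak=peak, overlap_bp=width)
                for peak, width in matches
            )
    return records


@dataclass
class BindingFlagTable:
    """Per-(region, RBP) bound/unbound flags for one cell line.

    ``flags`` is a boolean DataFrame indexed by region key with one column
    per RBP that has peaks in this cell line (an RBP without peaks has no
    column at all — distinguishable from all-false).  ``lncrna`` and
    ``gene_symbol`` carry the region labels on the same index.
    """

    cell_line: str
    flags: pd.DataFrame
    lncrna: pd.Series
    gene_symbol: pd.Series

    @property
    def rbps(self) -> list[str]:
        return list(self.flags.columns)

    @property
    def lncrnas(self) -> list[str]:
        out: list[str] = []
        for name in self.lncrna:
            if name not in out:
                out.append(name)
        return out

    def collapse_to_genes(self) -> "BindingFlagTable":
        """Per-(lncRNA, gene) flags: a gene is bound if any of its regions is."""
        unit = pd.Series(
            [f"{l}|{g}" for l, g in zip(self.lncrna, self.gene_symbol)],
            index=self.flags.index,
        )
        grouped = self.flags.groupby(unit, sort=True).any()
        labels = pd.DataFrame(
            {"lncrna": self.lncrna.values, "gene": self.gene_symbol.values},
            index=unit.values,
        )
        labels = labels[~labels.index.duplicated()].loc[grouped.index]
        return BindingFlagTable(
            cell_line=self.cell_line,
            flags=grouped,
            lncrna=labels["lncrna"],
            gene_symbol=labels["gene"],
        )


def bound_flags(
    regions: Sequence[ProximalRegion],
    peaks: Sequence[RBPPeak],
    min_overlap: int = 1,
    stranded: bool = False,
    strict: bool = False,
) -> dict[str, BindingFlagTable]:
    """Bound/unbound flag tables, one per cell line.

    Regions are only ever tested against peaks from their own cell line
    (HeLa events vs HeLa eCLIP, K562 vs K562); a cell line without any peaks
    (the U87 situation) yields no table.
    """
    regions_by_cell: dict[str, list[ProximalRegion]] = {}
    for r in regions:
        regions_by_cell.setdefault(r.cell_line, []).append(r)
    peaks_by_cell_rbp: dict[str, dict[str, list[RBPPeak]]] = {}
    for p in peaks:
        peaks_by_cell_rbp.setdefault(p.cell_line, {}).setdefault(p.rbp, []).append(p)

    tables: dict[str, BindingFlagTable] = {}
    for cell_line in sorted(set(regions_by_cell) & set(peaks_by_cell_rbp)):
        cell_regions = regions_by_cell[cell_line]
        index = pd.Index([r.key for r in cell_regions], name="region")
        if index.has_duplicates:
            raise ValueError(
                f"duplicate region keys in cell line {cell_line!r}; region keys "
                "must be unique (event_id|region_type|lncrna)"
            )
        columns: dict[str, pd.Series] = {}
        for rbp in sorted(peaks_by_cell_rbp[cell_line]):
            flags = pd.Series(False, index=index)
            hits = intersect(
                cell_regions,
                peaks_by_cell_rbp[cell_line][rbp],
                min_overlap=min_overlap,
                stranded=stranded,
                strict=strict,
            )
            for rec in hits:
                flags[rec.region.key] = True
            columns[rbp] = flags
        tables[cell_line] = BindingFlagTable(
            cell_line=cell_line,
            flags=pd.DataFrame(columns, index=index),
            lncrna=pd.Series([r.lncrna for r in cell_regions], index=index),
            gene_symbol=pd.Series([r.gene_symbol for r in cell_regions], index=index),
        )
    return tables


def records_to_frame(records: Iterable[OverlapRecord]) -> pd.DataFrame:
    """Export overlap records as a BEDPE-like table."""
    return pd.DataFrame(
        [
            {
                "chrom": rec.region.chrom,
                "region_start": rec.region.start,
                "region_end": rec.region.end,
                "region_key": rec.region.key,
                "peak_start": rec.peak.start,
                "peak_end": rec.peak.end,
                "rbp": rec.peak.rbp,
                "cell_line": rec.peak.cell_line,
                "overlap_bp": rec.overlap_bp,
            }
            for rec in records
        ]
    )


def write_flag_table(table: BindingFlagTable, path) -> None:
    out = table.flags.copy()
    out.insert(0, "lncrna", table.lncrna)
    out.insert(1, "gene_symbol", table.gene_symbol)
    out.to_csv(path, sep="\t")


def read_flag_table(path, cell_line: str) -> BindingFlagTable:
    df = pd.read_csv(path, sep="\t", index_col="region")
    lncrna = df.pop("lncrna").astype(str)
    gene = df.pop("gene_symbol").astype(str)
    return BindingFlagTable(
        cell_line=cell_line, flags=df.astype(bool), lncrna=lncrna, gene_symbol=gene
    )
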