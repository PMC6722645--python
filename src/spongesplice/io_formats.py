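"""Readers and writers for every external format the pipeline touches.

All other modules consume only the domain types defined here.  The single
coordinate convention throughout the package is 0-based half-open (BED-style):
rMATS ``*_0base`` start columns are taken verbatim and end columns are treated
as exclusive, so downstream interval arithmetic needs no conversion.

Supported external formats
--------------------------
* rMATS v3.2.5 per-event-type MATS tables (SE, RI, A5SS, A3SS, MXE), TSV.
* BED6 / ENCODE narrowPeak for RBP binding peaks (columns beyond 6 ignored).
* Sample sheets mapping a knockdown comparison to (lncRNA, cell line) and to
  its per-event-type rMATS tables.
* Gene x sample count matrices, TSV.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")
STRANDS = ("+", "-")

#: rMATS v3.2.5 column names for the six event coordinates, per event type.
#: For A5SS/A3SS the variable ("long") exon is the target and the short /
#: flanking exons play the upstream / downstream roles; for MXE the first
#: alternative exon is taken as the target region.
RMATS_COORD_COLUMNS: dict[str, dict[str, str]] = {
    "SE": {
        "target_start": "exonStart_0base",
        "target_end": "exonEnd",
        "upstream_start": "upstreamES",
        "upstream_end": "upstreamEE",
        "downstream_start": "downstreamES",
        "downstream_end": "downstreamEE",
    },
    "RI": {
        "target_start": "riExonStart_0base",
        "target_end": "riExonEnd",
        "upstream_start": "upstreamES",
        "upstream_end": "upstreamEE",
        "downstream_start": "downstreamES",
        "downstream_end": "downstreamEE",
    },
    "MXE": {
        "target_start": "1stExonStart_0base",
        "target_end": "1stExonEnd",
        "upstream_start": "upstreamES",
        "upstream_end": "upstreamEE",
        "downstream_start": "downstreamES",
        "downstream_end": "downstreamEE",
    },
    "A5SS": {
        "target_start": "longExonStart_0base",
        "target_end": "longExonEnd",
        "upstream_start": "shortES",
        "upstream_end": "shortEE",
        "downstream_start": "flankingES",
        "downstream_end": "flankingEE",
    },
    "A3SS": {
        "target_start": "longExonStart_0base",
        "target_end": "longExonEnd",
        "upstream_start": "shortES",
        "upstream_end": "shortEE",
        "downstream_start": "flankingES",
        "downstream_end": "flankingEE",
    },
}

_RMATS_STAT_COLUMNS = ("PValue", "FDR", "IncLevelDifference")
_RMATS_META_COLUMNS = ("GeneID", "geneSymbol", "chr", "strand")


class FormatError(ValueError):
    """A file does not conform to its declared dialect (e.g. missing column)."""


class RowParseError(ValueError):
    """A single data row could not be parsed; carries the 1-based line number."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class SampleSheetError(ValueError):
    """Sample sheet validation failure (duplicates, unresolvable paths)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpliceEvent:
    """One rMATS-reported differential splicing event.

    ``target_*`` is the cassette exon (SE), retained intron (RI) or variable
    region (A5SS/A3SS/MXE); ``upstream_*`` / ``downstream_*`` are the flanking
    exons.  All coordinates 0-based half-open.
    """

    event_id: str
    event_type: str
    gene_id: str
    gene_symbol: str
    chrom: str
    strand: str
    target_start: int
    target_end: int
    upstream_start: int
    upstream_end: int
    downstream_start: int
    downstream_end: int
    pvalue: float
    fdr: float
    inc_level_diff: float

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type: {self.event_type!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")
        for lo, hi in (
            (self.target_start, self.target_end),
            (self.upstream_start, self.upstream_end),
            (self.downstream_start, self.downstream_end),
        ):
            if not lo < hi:
                raise ValueError(f"interval start >= end: [{lo}, {hi})")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue outside [0, 1]: {self.pvalue}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr outside [0, 1]: {self.fdr}")
        if not -1.0 <= self.inc_level_diff <= 1.0:
            raise ValueError(f"inc_level_diff outside [-1, 1]: {self.inc_level_diff}")

    @property
    def coordinates(self) -> tuple[int, int, int, int, int, int]:
        """The six junction coordinates, upstream -> target -> downstream."""
        return (
            self.upstream_start,
            self.upstream_end,
            self.target_start,
            self.target_end,
            self.downstream_start,
            self.downstream_end,
        )


def event_key(event: SpliceEvent) -> tuple:
    """Identity key used for deduplication and event ids."""
    return (
        event.event_type,
        event.chrom,
        event.strand,
        event.target_start,
        event.target_end,
        event.upstream_start,
        event.upstream_end,
        event.downstream_start,
        event.downstream_end,
    )


def make_event_id(
    event_type: str,
    chrom: str,
    strand: str,
    target_start: int,
    target_end: int,
    upstream_start: int,
    upstream_end: int,
    downstream_start: int,
    downstream_end: int,
) -> str:
    """Deterministic opaque id: md5 over (type, chrom, strand, six coords)."""
    text = "|".join(
        map(
            str,
            (
                event_type,
                chrom,
                strand,
                target_start,
                target_end,
                upstream_start,
                upstream_end,
                downstream_start,
                downstream_end,
            ),
        )
    )
    return hashlib.md5(text.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class RBPPeak:
    """A labeled eCLIP-style binding interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    rbp: str
    cell_line: str
    score: float | None = None
    strand: str = "."

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"peak start >= end: [{self.start}, {self.end})")
        if not self.rbp:
            raise ValueError("peak has empty RBP label")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")


@dataclass(frozen=True)
class SampleComparison:
    """One knockdown-vs-control comparison from the sample sheet."""

    comparison_id: str
    lncrna: str
    cell_line: str
    tables: Mapping[str, Path] = field(default_factory=dict)


@dataclass(frozen=True)
class SampleSheet:
    rows: tuple[SampleComparison, ...]

    def __post_init__(self):
        seen = set()
        for row in self.rows:
            pair = (row.lncrna, row.cell_line)
            if pair in seen:
                raise SampleSheetError(
                    f"duplicate (lncRNA, cell line) pair in sample sheet: {pair}"
                )
            seen.add(pair)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self):
        return len(self.rows)

    @property
    def cell_lines(self) -> tuple[str, ...]:
        out: list[str] = []
        for row in self.rows:
            if row.cell_line not in out:
                out.append(row.cell_line)
        return tuple(out)

    def by_cell_line(self, cell_line: str) -> tuple[SampleComparison, ...]:
        return tuple(r for r in self.rows if r.cell_line == cell_line)


# ---------------------------------------------------------------------------
# rMATS tables
# ---------------------------------------------------------------------------


def detect_count_dialect(columns: Sequence[str]) -> str | None:
    """Which rMATS count flavor a table carries, if its count columns are present.

    rMATS v3.2.x emits two table flavors per event type; they share all
    statistical columns and differ in the read-count column prefix.
    """
    if "IC_SAMPLE_1" in columns:
        return "ReadsOnTargetAndJunctionCounts"
    if "IJC_SAMPLE_1" in columns:
        return "JunctionCountOnly"
    return None


def _strip_quotes(value: str) -> str:
    value = str(value)
    if len(value) >= 2 and value[0] == '"' and value[-1] == '"':
        return value[1:-1]
    return value


def read_rmats_table(
    path,
    event_type: str,
    column_map: Mapping[str, str] | None = None,
) -> list[SpliceEvent]:
    """Read one rMATS MATS output table into :class:`SpliceEvent` records.

    Parameters
    ----------
    path
        Header-bearing TSV in the rMATS v3.2.x dialect for ``event_type``.
    event_type
        One of ``SE, RI, A5SS, A3SS, MXE``; selects the coordinate columns.
    column_map
        Optional override of the canonical-name -> column-name mapping, for
        other rMATS dialects.
    """
    if event_type not in EVENT_TYPES:
        raise ValueError(
            f"unknown event_type {event_type!r}; expected one of {EVENT_TYPES}"
        )
    coord_map = dict(RMATS_COORD_COLUMNS[event_type])
    if column_map:
        coord_map.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = list(_RMATS_META_COLUMNS) + list(coord_map.values()) + list(
        _RMATS_STAT_COLUMNS
    )
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory rMATS column {col!r}")

    dialect = detect_count_dialect(df.columns)
    if dialect is not None:
        logger.debug("rMATS table %s: count dialect %s", path, dialect)

    events: list[SpliceEvent] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_number = i + 2  # 1-based, after the header line
        rec = dict(zip(df.columns, row))
        try:
            coords = {name: int(rec[col]) for name, col in coord_map.items()}
            pvalue = float(rec["PValue"])
            fdr = float(rec["FDR"])
            inc = float(rec["IncLevelDifference"])
        except (TypeError, ValueError) as exc:
            raise RowParseError(path, line_number, f"unparseable field: {exc}") from exc
        chrom = str(rec["chr"])
        strand = str(rec["strand"])
        try:
            events.append(
                SpliceEvent(
                    event_id=make_event_id(
                        event_type,
                        chrom,
                        strand,
                        coords["target_start"],
                        coords["target_end"],
                        coords["upstream_start"],
                        coords["upstream_end"],
                        coords["downstream_start"],
                        coords["downstream_end"],
                    ),
                    event_type=event_type,
                    gene_id=_strip_quotes(rec["GeneID"]),
                    gene_symbol=_strip_quotes(rec["geneSymbol"]),
                    chrom=chrom,
                    strand=strand,
                    pvalue=pvalue,
                    fdr=fdr,
                    inc_level_diff=inc,
                    **coords,
                )
            )
        except ValueError as exc:
            raise RowParseError(path, line_number, str(exc)) from exc
    return events


def write_rmats_table(events: Iterable[SpliceEvent], path, event_type: str) -> None:
    """Write events of one type back out in the rMATS v3.2.5 column dialect."""
    if event_type not in EVENT_TYPES:
        raise ValueError(f"unknown event_type {event_type!r}")
    coord_map = RMATS_COORD_COLUMNS[event_type]
    rows = []
    for i, ev in enumerate(events):
        if ev.event_type != event_type:
            raise ValueError(
                f"event {ev.event_id} has type {ev.event_type}, table is {event_type}"
            )
        row = {
            "ID": i + 1,
            "GeneID": ev.gene_id,
            "geneSymbol": ev.gene_symbol,
            "chr": ev.chrom,
            "strand": ev.strand,
        }
        for name, col in coord_map.items():
            row[col] = getattr(ev, name)
        row["PValue"] = repr(ev.pvalue)
        row["FDR"] = repr(ev.fdr)
        row["IncLevelDifference"] = repr(ev.inc_level_diff)
        rows.append(row)
    columns = (
        ["ID", "GeneID", "geneSymbol", "chr", "strand"]
        + list(coord_map.values())
        + list(_RMATS_STAT_COLUMNS)
    )
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def read_peaks_bed(path, rbp: str | None = None, cell_line: str | None = None) -> list[RBPPeak]:
    """Read BED6 / narrowPeak intervals as :class:`RBPPeak` records.

    When ``rbp`` / ``cell_line`` are not given they are parsed from the BED
    name column, expected as ``RBP_CELLLINE[...]`` (ENCODE eCLIP style).
    Columns beyond the first six are ignored.
    """
    peaks: list[RBPPeak] = []
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{line_number}: BED record has fewer than 3 columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise RowParseError(path, line_number, f"non-integer coordinate: {exc}")
            if start >= end:
                raise RowParseError(path, line_number, f"start >= end: [{start}, {end})")
            name = fields[3] if len(fields) > 3 else ""
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) > 5 else "."
            row_rbp, row_cell = rbp, cell_line
            if row_rbp is None or row_cell is None:
                parts = name.split("_")
                if row_rbp is None:
                    row_rbp = parts[0] if parts and parts[0] else name
                if row_cell is None:
                    row_cell = parts[1] if len(parts) > 1 else ""
            try:
                peaks.append(
                    RBPPeak(
                        chrom=chrom,
                        start=start,
                        end=end,
                        rbp=row_rbp,
                        cell_line=row_cell,
                        score=score,
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise RowParseError(path, line_number, str(exc)) from exc
    return peaks


def write_bed(peaks: Iterable[RBPPeak], path) -> None:
    """Write peaks as BED6 with name ``RBP_CELLLINE`` (round-trips the labels)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = 0 if p.score is None else p.score
            name = f"{p.rbp}_{p.cell_line}" if p.cell_line else p.rbp
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\t{p.strand}\n")


def read_peaks_dir(directory) -> list[RBPPeak]:
    """Read every ``<cell_line>__<rbp>.bed`` file under ``directory``."""
    directory = Path(directory)
    peaks: list[RBPPeak] = []
    for path in sorted(directory.glob("*.bed")):
        stem = path.stem
        if "__" in stem:
            cell_line, rbp = stem.split("__", 1)
            peaks.extend(read_peaks_bed(path, rbp=rbp, cell_line=cell_line))
        else:
            peaks.extend(read_peaks_bed(path))
    return peaks


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

_SHEET_BASE_COLUMNS = ("comparison_id", "lncrna", "cell_line")


def read_sample_sheet(path, check_paths: bool = True) -> SampleSheet:
    """Read a TSV sample sheet.

    Columns: ``comparison_id, lncrna, cell_line`` plus one ``path_<TYPE>``
    column per event type present.  Table paths are resolved relative to the
    sheet's own directory; unresolvable paths raise :class:`SampleSheetError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in _SHEET_BASE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing sample sheet column {col!r}")
    type_cols = {
        c.removeprefix("path_"): c
        for c in df.columns
        if c.startswith("path_") and c.removeprefix("path_") in EVENT_TYPES
    }
    rows = []
    for rec in df.to_dict("records"):
        tables: dict[str, Path] = {}
        for etype, col in type_cols.items():
            raw = rec[col].strip()
            if not raw:
                continue
            table_path = Path(raw)
            if not table_path.is_absolute():
                table_path = path.parent / table_path
            if check_paths and not table_path.exists():
                raise SampleSheetError(
                    f"{path}: table for {rec['comparison_id']}/{etype} not found: "
                    f"{table_path}"
                )
            tables[etype] = table_path
        rows.append(
            SampleComparison(
                comparison_id=rec["comparison_id"],
                lncrna=rec["lncrna"],
                cell_line=rec["cell_line"],
                tables=tables,
            )
        )
    return SampleSheet(rows=tuple(rows))


def write_sample_sheet(sheet: SampleSheet, path, relative_to=None) -> None:
    path = Path(path)
    event_types = sorted(
        {et for row in sheet for et in row.tables}, key=EVENT_TYPES.index
    )
    base = Path(relative_to) if relative_to is not None else path.parent
    records = []
    for row in sheet:
        rec = {
            "comparison_id": row.comparison_id,
            "lncrna": row.lncrna,
            "cell_line": row.cell_line,
        }
        for et in event_types:
            p = row.tables.get(et)
            if p is None:
                rec[f"path_{et}"] = ""
            else:
                p = Path(p)
                try:
                    rec[f"path_{et}"] = str(p.relative_to(base))
                except ValueError:
                    rec[f"path_{et}"] = str(p)
        records.append(rec)
    columns = list(_SHEET_BASE_COLUMNS) + [f"path_{et}" for et in event_types]
    pd.DataFrame(records, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a gene x sample matrix as TSV: genes as rows, header row of samples."""
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


# ---------------------------------------------------------------------------
# Chromosome-name hygiene
# ---------------------------------------------------------------------------


def check_chrom_naming(chroms: Iterable[str]) -> None:
    """Reject mixed ``chr1`` / ``1`` naming rather than silently harmonizing."""
    prefixed = unprefixed = None
    for c in chroms:
        if c.startswith("chr"):
            prefixed = c
        else:
            unprefixed = c
        if prefixed is not None and unprefixed is not None:
            raise FormatError(
                "mixed chromosome naming conventions: "
                f"{prefixed!r} vs {unprefixed!r}; harmonize inputs first"
            )
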