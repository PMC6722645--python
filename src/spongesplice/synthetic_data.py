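"""Seeded generator of rMATS-style tables, eCLIP-style peaks and sample
sheets with fully bookkept planted structure.

The generator emulates the *inputs* of the analysis — the per-comparison
rMATS output tables of a lncRNA-knockdown study (three cell lines, of which
one lacks eCLIP data) and per-RBP binding peaks — not RNA-seq reads:
significance is planted by sampling p/fdr on the correct side of the filter
thresholds, and binding is planted per proximal window with a per-lncRNA
density (high for designated "sponge" lncRNAs, low for the background).
Every planted fact is recorded in a :class:`GroundTruth` object so each
pipeline stage has an exact oracle.

Geometry guarantees that make the bookkeeping exact:

* every event occupies its own genomic slot, with the six anchors spaced
  more than two windows apart, so the six proximal windows of all events are
  pairwise disjoint and never clipped;
* planted peaks are placed strictly inside one window, so a window is bound
  by an RBP if and only if a peak was planted there.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .event_filtering import FilterConfig, filter_events, gene_label
from .geneset_enrichment import AnnotationTable, GeneSetTerm
from .interval_intersect import bound_flags
from .io_formats import (
    RBPPeak,
    SampleComparison,
    SampleSheet,
    SpliceEvent,
    make_event_id,
    read_peaks_dir,
    read_rmats_table,
    read_sample_sheet,
    write_bed,
    write_rmats_table,
    write_sample_sheet,
)
from .proximal_regions import regions_for_comparison


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the emulated study's shape: 3 cell lines x 13 knockdowns
    (39 comparisons), SE and RI tables per comparison, eCLIP peaks for two of
    the three cell lines only, ~7% of alternatively spliced genes shared
    between cell lines, and one designated sponge lncRNA per eCLIP cell line
    binding 80% of its proximal windows per RBP against a 10% background.
    """

    seed: int = 0
    cell_lines: tuple[str, ...] = ("HeLa", "K562", "U87")
    eclip_cell_lines: tuple[str, ...] = ("HeLa", "K562")
    n_lncrnas_per_cell_line: int = 13
    n_genes: int = 120
    n_events_per_comparison: int = 100  # per event type
    event_types: tuple[str, ...] = ("SE", "RI")
    frac_significant: float = 0.4
    cross_cell_line_sharing: float = 0.07
    n_rbps: int = 20
    sponge_lncrnas: tuple[str, ...] | None = None  # None = first lncRNA per eCLIP line
    sponge_density: float = 0.8
    background_density: float = 0.1
    saturated_rbps: tuple[str, ...] = ()  # RBPs planted to bind every window
    window: int = 500
    peak_length: int = 50
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 60_000_000, "chr2": 60_000_000, "chr3": 60_000_000}
    )
    filter_config: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self):
        for name in ("frac_significant", "cross_cell_line_sharing",
                     "sponge_density", "background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {v}")
        if self.window <= 0:
            raise SimulationConfigError("window must be positive")
        if not set(self.eclip_cell_lines) <= set(self.cell_lines):
            raise SimulationConfigError("eclip_cell_lines must be a subset of cell_lines")
        if self.cross_cell_line_sharing > 0 and len(self.cell_lines) < 2:
            raise SimulationConfigError("cross-cell-line sharing needs >= 2 cell lines")
        # slot geometry feasibility (see module docstring)
        gap = self._anchor_gap
        slot = 7 * gap
        n_slots = (
            len(self.cell_lines)
            * self.n_lncrnas_per_cell_line
            * len(self.event_types)
            * self.n_events_per_comparison
        )
        if n_slots * slot > sum(self.chrom_lengths.values()) - 2 * gap * len(
            self.chrom_lengths
        ):
            raise SimulationConfigError(
                "infeasible geometry: event slots exceed total chromosome length"
            )

    @property
    def _anchor_gap(self) -> int:
        # anchors > 2*window apart => disjoint windows; room for interior peaks
        return 2 * self.window + 2 * 100 + self.peak_length

    @property
    def rbp_names(self) -> tuple[str, ...]:
        return tuple(f"RBP{i:02d}" for i in range(self.n_rbps))

    def lncrna_names(self, cell_line: str) -> tuple[str, ...]:
        idx = list(self.cell_lines).index(cell_line)
        base = idx * self.n_lncrnas_per_cell_line
        return tuple(
            f"LNC{base + i:03d}" for i in range(self.n_lncrnas_per_cell_line)
        )

    def sponges(self) -> dict[str, str]:
        """Planted sponge lncRNA per eCLIP cell line."""
        if self.sponge_lncrnas is not None:
            out = {}
            for cell in self.eclip_cell_lines:
                names = set(self.lncrna_names(cell))
                for s in self.sponge_lncrnas:
                    if s in names:
                        out[cell] = s
            return out
        return {cell: self.lncrna_names(cell)[0] for cell in self.eclip_cell_lines}


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A no-sponge configuration: every lncRNA shares one binding density."""
    defaults = dict(
        seed=seed,
        sponge_lncrnas=(),
        sponge_density=0.5,
        background_density=0.5,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class GroundTruth:
    """Exactly what the generator wrote to disk, keyed for each oracle."""

    comparisons: list[dict]  # comparison_id, lncrna, cell_line
    sig_event_ids: dict[str, list[str]]  # "comparison|event_type" -> ids
    gene_counts: dict[str, dict[str, int]]  # "comparison|event_type" -> gene -> n
    bound: dict[str, list[str]]  # cell_line -> "event_id|region_type|lncrna|rbp"
    sponges: dict[str, str]
    gene_cell_lines: dict[str, list[str]]
    rbps: list[str]
    config: dict

    def bound_set(self, cell_line: str) -> set[tuple[str, str]]:
        """Planted (region_key, rbp) pairs for one cell line."""
        out = set()
        for entry in self.bound.get(cell_line, []):
            event_id, region_type, lncrna, rbp = entry.split("|")
            out.add((f"{event_id}|{region_type}|{lncrna}", rbp))
        return out

    def as_gene_sets(self, event_type: str) -> dict[str, set[str]]:
        """Realized alternatively-spliced gene set per cell line."""
        by_comp = {c["comparison_id"]: c["cell_line"] for c in self.comparisons}
        sets: dict[str, set[str]] = {}
        for key, counts in self.gene_counts.items():
            comp, etype = key.rsplit("|", 1)
            if etype != event_type:
                continue
            sets.setdefault(by_comp[comp], set()).update(counts)
        return sets

    def shared_fraction(self, event_type: str) -> float:
        sets = self.as_gene_sets(event_type)
        all_genes = set().union(*sets.values()) if sets else set()
        if not all_genes:
            return 0.0
        shared = {g for g in all_genes if sum(g in s for s in sets.values()) >= 2}
        return len(shared) / len(all_genes)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True, default=str)

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _assign_genes(config: SimConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    """Assign each gene to one cell line, or to a pair for the shared slice."""
    genes = [f"GENE{i:04d}" for i in range(config.n_genes)]
    order = list(rng.permutation(config.n_genes))
    n_shared = round(config.cross_cell_line_sharing * config.n_genes)
    assignment: dict[str, list[str]] = {}
    cells = list(config.cell_lines)
    for j, gi in enumerate(order):
        gene = genes[gi]
        if j < n_shared:
            pair_idx = rng.choice(len(cells), size=2, replace=False)
            assignment[gene] = sorted(cells[i] for i in pair_idx)
        else:
            assignment[gene] = [cells[j % len(cells)]]
    return assignment


class _SlotAllocator:
    """Round-robin allocation of disjoint event slots across chromosomes."""

    def __init__(self, config: SimConfig):
        self.gap = config._anchor_gap
        self.chroms = sorted(config.chrom_lengths)
        self.lengths = dict(config.chrom_lengths)
        self.cursors = {c: 2 * self.gap for c in self.chroms}
        self._next = 0

    def take(self) -> tuple[str, int]:
        for _ in range(len(self.chroms)):
            chrom = self.chroms[self._next % len(self.chroms)]
            self._next += 1
            base = self.cursors[chrom]
            if base + 6 * self.gap < self.lengths[chrom]:
                self.cursors[chrom] = base + 7 * self.gap
                return chrom, base
        raise SimulationConfigError("infeasible geometry: ran out of chromosome space")


def simulate(config: SimConfig, out_dir) -> GroundTruth:
    """Write a complete synthetic dataset under ``out_dir`` and return its truth.

    Layout: ``sample_sheet.tsv``, ``rmats/<comparison>_<TYPE>.txt``,
    ``peaks/<cell_line>__<rbp>.bed``, ``truth.json``.  Identical seed and
    config give byte-identical files.
    """
    out_dir = Path(out_dir)
    (out_dir / "rmats").mkdir(parents=True, exist_ok=True)
    (out_dir / "peaks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    fc = config.filter_config

    gene_assignment = _assign_genes(config, rng)
    pools = {
        cell: sorted(g for g, cls in gene_assignment.items() if cell in cls)
        for cell in config.cell_lines
    }
    gene_ids = {g: f"ENSG{i:08d}" for i, g in enumerate(sorted(gene_assignment))}
    slots = _SlotAllocator(config)
    sponges = config.sponges()

    comparisons: list[dict] = []
    sheet_rows: list[SampleComparison] = []
    sig_event_ids: dict[str, list[str]] = {}
    gene_counts: dict[str, dict[str, int]] = {}
    sig_events_by_comparison: dict[str, list[SpliceEvent]] = {}
    # per (cell, type): infinite cycle over a shuffled pool so every pool gene
    # is covered once before any repeats
    cyclers: dict[tuple[str, str], list] = {}

    def next_gene(cell: str, etype: str) -> str:
        key = (cell, etype)
        if key not in cyclers or not cyclers[key]:
            pool = pools[cell]
            cyclers[key] = [pool[i] for i in rng.permutation(len(pool))]
        return cyclers[key].pop()

    for cell in config.cell_lines:
        for lncrna in config.lncrna_names(cell):
            comparison_id = f"{lncrna}_{cell}"
            comparisons.append(
                {"comparison_id": comparison_id, "lncrna": lncrna, "cell_line": cell}
            )
            tables: dict[str, Path] = {}
            for etype in config.event_types:
                n = config.n_events_per_comparison
                n_sig = round(config.frac_significant * n)
                events: list[SpliceEvent] = []
                for i in range(n):
                    significant = i < n_sig
                    gene = (
                        next_gene(cell, etype)
                        if significant
                        else pools[cell][int(rng.integers(len(pools[cell])))]
                    )
                    chrom, base = slots.take()
                    gap = slots.gap
                    strand = "+" if rng.random() < 0.5 else "-"
                    coords = dict(
                        upstream_start=base,
                        upstream_end=base + gap,
                        target_start=base + 2 * gap,
                        target_end=base + 3 * gap,
                        downstream_start=base + 4 * gap,
                        downstream_end=base + 5 * gap,
                    )
                    if significant:
                        pvalue = float(rng.uniform(0, fc.pvalue_max * 0.5))
                        fdr = float(rng.uniform(0, fc.fdr_max * 0.5))
                    else:
                        pvalue = float(rng.uniform(min(0.99, fc.pvalue_max * 1.2), 1.0))
                        fdr = float(rng.uniform(min(0.99, fc.fdr_max * 1.2), 1.0))
                    events.append(
                        SpliceEvent(
                            event_id=make_event_id(
                                etype, chrom, strand,
                                coords["target_start"], coords["target_end"],
                                coords["upstream_start"], coords["upstream_end"],
                                coords["downstream_start"], coords["downstream_end"],
                            ),
                            event_type=etype,
                            gene_id=gene_ids[gene],
                            gene_symbol=gene,
                            chrom=chrom,
                            strand=strand,
                            pvalue=pvalue,
                            fdr=fdr,
                            inc_level_diff=float(rng.uniform(-1, 1)),
                            **coords,
                        )
                    )
                key = f"{comparison_id}|{etype}"
                sig = events[:n_sig]
                sig_event_ids[key] = [e.event_id for e in sig]
                counts: dict[str, int] = {}
                for e in sig:
                    counts[e.gene_symbol] = counts.get(e.gene_symbol, 0) + 1
                gene_counts[key] = counts
                sig_events_by_comparison.setdefault(comparison_id, []).extend(sig)
                shuffled = [events[i] for i in rng.permutation(n)]
                table_path = out_dir / "rmats" / f"{comparison_id}_{etype}.txt"
                write_rmats_table(shuffled, table_path, etype)
                tables[etype] = table_path
            sheet_rows.append(
                SampleComparison(
                    comparison_id=comparison_id,
                    lncrna=lncrna,
                    cell_line=cell,
                    tables=tables,
                )
            )

    sheet = SampleSheet(rows=tuple(sheet_rows))
    write_sample_sheet(sheet, out_dir / "sample_sheet.tsv", relative_to=out_dir)

    # ---- planted binding ---------------------------------------------------
    bound: dict[str, list[str]] = {}
    peaks_by_file: dict[tuple[str, str], list[RBPPeak]] = {}
    w, plen, margin = config.window, config.peak_length, 100
    for cell in config.eclip_cell_lines:
        bound[cell] = []
        for rbp in config.rbp_names:
            peaks_by_file[(cell, rbp)] = []
        for row in sheet.by_cell_line(cell):
            density_base = (
                config.sponge_density
                if sponges.get(cell) == row.lncrna
                else config.background_density
            )
            regions = regions_for_comparison(
                sig_events_by_comparison[row.comparison_id],
                lncrna=row.lncrna,
                cell_line=cell,
                window=w,
                event_types=config.event_types,
            )
            for region in regions:
                anchor = region.start + w if region.start > 0 else region.end - w
                for rbp in config.rbp_names:
                    density = 1.0 if rbp in config.saturated_rbps else density_base
                    if rng.random() < density:
                        lo = anchor - w + margin
                        hi = anchor + w - margin - plen
                        start = int(rng.integers(lo, hi + 1))
                        peaks_by_file[(cell, rbp)].append(
                            RBPPeak(
                                chrom=region.chrom,
                                start=start,
                                end=start + plen,
                                rbp=rbp,
                                cell_line=cell,
                                score=float(np.round(rng.uniform(1, 1000), 3)),
                                strand=region.strand,
                            )
                        )
                        bound[cell].append(
                            f"{region.event_id}|{region.region_type}|"
                            f"{region.lncrna}|{rbp}"
                        )
    for (cell, rbp), peaks in sorted(peaks_by_file.items()):
        peaks = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        write_bed(peaks, out_dir / "peaks" / f"{cell}__{rbp}.bed")

    truth = GroundTruth(
        comparisons=comparisons,
        sig_event_ids=sig_event_ids,
        gene_counts=gene_counts,
        bound=bound,
        sponges=sponges,
        gene_cell_lines={g: list(c) for g, c in sorted(gene_assignment.items())},
        rbps=list(config.rbp_names),
        config=_config_as_dict(config),
    )
    truth.save(out_dir / "truth.json")
    return truth


def _config_as_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["chrom_lengths"] = dict(config.chrom_lengths)
    d["filter_config"] = dataclasses.asdict(config.filter_config)
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    d["filter_config"] = FilterConfig(**d["filter_config"])
    for key in ("cell_lines", "eclip_cell_lines", "event_types", "saturated_rbps"):
        d[key] = tuple(d[key])
    if d.get("sponge_lncrnas") is not None:
        d["sponge_lncrnas"] = tuple(d["sponge_lncrnas"])
    return SimConfig(**d)


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------


@dataclass
class VerificationReport:
    ok: bool
    failures: list[str]

    def __bool__(self):
        return self.ok


def verify_ground_truth(out_dir, truth: GroundTruth) -> VerificationReport:
    """Re-read a simulated dataset and assert agreement with its truth.

    Checks, field by field: the sample sheet rows, the significant event ids
    recovered by the significance filter, the per-gene event counts, and the
    per-(region, RBP) bound flags recomputed through the interval engine.
    """
    out_dir = Path(out_dir)
    config = config_from_dict(truth.config)
    failures: list[str] = []

    try:
        sheet = read_sample_sheet(out_dir / "sample_sheet.tsv")
    except Exception as exc:  # unreadable sheet invalidates everything
        return VerificationReport(ok=False, failures=[f"sample sheet: {exc}"])

    sheet_rows = [
        {"comparison_id": r.comparison_id, "lncrna": r.lncrna, "cell_line": r.cell_line}
        for r in sheet
    ]
    if sheet_rows != truth.comparisons:
        failures.append("sample sheet rows do not match planted comparisons")

    sig_by_comparison: dict[str, list[SpliceEvent]] = {}
    for row in sheet:
        for etype, path in sorted(row.tables.items()):
            key = f"{row.comparison_id}|{etype}"
            try:
                events = read_rmats_table(path, etype)
            except Exception as exc:
                failures.append(f"{key}: unreadable table: {exc}")
                continue
            sig = filter_events(events, config.filter_config)
            planted = truth.sig_event_ids.get(key, [])
            if sorted(e.event_id for e in sig) != sorted(planted):
                failures.append(
                    f"{key}: significant event ids mismatch "
                    f"({len(sig)} recovered vs {len(planted)} planted)"
                )
            counts: dict[str, int] = {}
            for e in sig:
                g = gene_label(e)
                counts[g] = counts.get(g, 0) + 1
            if counts != truth.gene_counts.get(key, {}):
                failures.append(f"{key}: per-gene significant counts mismatch")
            sig_by_comparison.setdefault(row.comparison_id, []).extend(sig)

    peaks = read_peaks_dir(out_dir / "peaks")
    regions = []
    for row in sheet:
        regions.extend(
            regions_for_comparison(
                sig_by_comparison.get(row.comparison_id, []),
                lncrna=row.lncrna,
                cell_line=row.cell_line,
                window=config.window,
                event_types=config.event_types,
            )
        )
    tables = bound_flags(regions, peaks)
    for cell in truth.bound:
        if truth.bound[cell] and cell not in tables:
            failures.append(f"{cell}: planted binding but no flag table recovered")
    for cell, table in tables.items():
        recovered = {
            (region_key, rbp)
            for rbp in table.rbps
            for region_key in table.flags.index[table.flags[rbp]]
        }
        planted = truth.bound_set(cell)
        if recovered != planted:
            missing = len(planted - recovered)
            extra = len(recovered - planted)
            failures.append(
                f"{cell}: binding flags mismatch ({missing} planted flags lost, "
                f"{extra} unplanted flags gained)"
            )
    return VerificationReport(ok=not failures, failures=failures)


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


def simulate_annotation(
    universe: Sequence[str],
    n_terms: int = 10,
    term_size: tuple[int, int] = (5, 30),
    seed: int = 0,
    planted_query: Sequence[str] | None = None,
) -> AnnotationTable:
    """Random GMT-style annotation over ``universe``; optionally plant the
    first term as a subset of ``planted_query`` so it must test as enriched."""
    rng = np.random.default_rng(seed)
    universe = sorted(universe)
    terms = []
    for i in range(n_terms):
        if i == 0 and planted_query:
            genes = sorted(planted_query)[: max(term_size[0], 1)]
        else:
            size = int(rng.integers(term_size[0], term_size[1] + 1))
            size = min(size, len(universe))
            picks = rng.choice(len(universe), size=size, replace=False)
            genes = [universe[j] for j in sorted(picks)]
        terms.append(
            GeneSetTerm(
                term_id=f"TERM{i:03d}",
                term_name=f"synthetic term {i}",
                genes=frozenset(genes),
                source="synthetic",
            )
        )
    return AnnotationTable(terms=tuple(terms))
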