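from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spongesplice.io_formats import RBPPeak, SpliceEvent, make_event_id
from spongesplice.proximal_regions import ProximalRegion
from spongesplice.synthetic_data import SimConfig, simulate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_event(
    event_type="SE",
    chrom="chr1",
    strand="+",
    upstream=(100, 200),
    target=(300, 400),
    downstream=(500, 600),
    gene_id="ENSG00000000001",
    gene_symbol="GENE1",
    pvalue=0.01,
    fdr=0.01,
    inc_level_diff=0.2,
) -> SpliceEvent:
    return SpliceEvent(
        event_id=make_event_id(
            event_type, chrom, strand, target[0], target[1],
            upstream[0], upstream[1], downstream[0], downstream[1],
        ),
        event_type=event_type,
        gene_id=gene_id,
        gene_symbol=gene_symbol,
        chrom=chrom,
        strand=strand,
        target_start=target[0],
        target_end=target[1],
        upstream_start=upstream[0],
        upstream_end=upstream[1],
        downstream_start=downstream[0],
        downstream_end=downstream[1],
        pvalue=pvalue,
        fdr=fdr,
        inc_level_diff=inc_level_diff,
    )


def make_region(
    chrom="chr1", start=500, end=1500, strand="+", event_id="ev",
    region_type="target_start", lncrna="LNC0", cell_line="HeLa", gene="GENE1",
) -> ProximalRegion:
    return ProximalRegion(
        event_id=event_id,
        region_type=region_type,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        lncrna=lncrna,
        cell_line=cell_line,
        gene_symbol=gene,
    )


def make_peak(
    chrom="chr1", start=1400, end=1600, rbp="QKI", cell_line="HeLa",
    score=None, strand="+",
) -> RBPPeak:
    return RBPPeak(
        chrom=chrom, start=start, end=end, rbp=rbp,
        cell_line=cell_line, score=score, strand=strand,
    )


def random_events(rng: np.random.Generator, n: int, event_type="SE"):
    """n distinct events with random coordinates and statistics."""
    events = []
    for i in range(n):
        base = int(rng.integers(0, 10_000_000)) + i * 5000
        gaps = sorted(rng.integers(50, 900, size=5).tolist())
        coords = [base]
        for g in gaps:
            coords.append(coords[-1] + int(g) + 1)
        events.append(
            make_event(
                event_type=event_type,
                chrom=f"chr{int(rng.integers(1, 4))}",
                strand="+" if rng.random() < 0.5 else "-",
                upstream=(coords[0], coords[1]),
                target=(coords[2], coords[3]),
                downstream=(coords[4], coords[5]),
                gene_symbol=f"GENE{int(rng.integers(0, 30)):03d}",
                pvalue=float(rng.uniform(0, 1)),
                fdr=float(rng.uniform(0, 1)),
                inc_level_diff=float(rng.uniform(-1, 1)),
            )
        )
    return events


def random_fixture(seed, n_regions, n_peaks, n_chroms=3, span=100_000,
                   region_width=1000, max_peak_width=400):
    """Random region and peak lists for engine-vs-oracle comparisons."""
    rng = np.random.default_rng(seed)
    regions = []
    for i in range(n_regions):
        start = int(rng.integers(0, span))
        regions.append(
            make_region(
                chrom=f"chr{int(rng.integers(1, n_chroms + 1))}",
                start=start,
                end=start + region_width,
                strand="+" if rng.random() < 0.5 else "-",
                event_id=f"ev{i}",
                region_type="target_start",
                lncrna=f"LNC{i % 5}",
            )
        )
    peaks = []
    for j in range(n_peaks):
        start = int(rng.integers(0, span))
        width = int(rng.integers(10, max_peak_width))
        peaks.append(
            make_peak(
                chrom=f"chr{int(rng.integers(1, n_chroms + 1))}",
                start=start,
                end=start + width,
                rbp=f"RBP{j % 7}",
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return regions, peaks


SIM_CONFIG = SimConfig(
    seed=7,
    n_lncrnas_per_cell_line=4,
    n_genes=40,
    n_events_per_comparison=25,
    n_rbps=8,
)


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """One moderate synthetic dataset shared by generator-oracle tests."""
    out = tmp_path_factory.mktemp("sim_dataset")
    truth = simulate(SIM_CONFIG, out)
    return SIM_CONFIG, out, truth
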