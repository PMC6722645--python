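import math

import numpy as np
import pandas as pd
import pytest

from _oracles import naive_spearman_distance
from spongesplice.enrichment import ContingencyTable, EnrichmentResult
from spongesplice.event_filtering import EventFrequencyMatrix
from spongesplice.sponge_analysis import (
    binding_splicing_correlation,
    cluster,
    spearman_distance_matrix,
    sponge_scores,
)


def result(lncrna, rbp, p_adj, cell_line="HeLa", null=False):
    return EnrichmentResult(
        cell_line=cell_line,
        lncrna=lncrna,
        rbp=rbp,
        table=ContingencyTable(1, 1, 1, 1),
        odds_ratio=1.0,
        pvalue=None if null else p_adj / 2,
        p_adjusted=None if null else p_adj,
        neg_log_p_adj=None if null else -math.log10(p_adj),
    )


class TestSpongeScores:
    def test_breadth_fraction(self):
        results = [
            result("L1", f"R{j}", 0.01 if j < 7 else 0.5) for j in range(10)
        ]
        (profile,) = sponge_scores(results)
        assert profile.breadth == pytest.approx(0.7)
        assert profile.n_rbps_tested == 10 and profile.n_rbps_significant == 7

    def test_null_cells_excluded_from_both_sides(self):
        results = [result("L1", "R0", 0.01), result("L1", "R1", 0.5, null=True)]
        (profile,) = sponge_scores(results)
        assert profile.n_rbps_tested == 1 and profile.breadth == 1.0

    def test_all_null_row_flagged_undefined(self):
        results = [result("L1", "R0", 0.5, null=True)]
        (profile,) = sponge_scores(results)
        assert profile.flagged and profile.breadth is None

    def test_ranking_and_tie_breaks(self):
        results = (
            [result("LB", f"R{j}", 0.01) for j in range(4)]
            + [result("LA", f"R{j}", 0.01 if j < 2 else 0.5) for j in range(4)]
            + [result("LC", f"R{j}", 0.01 if j < 2 else 0.5) for j in range(4)]
        )
        profiles = sponge_scores(results)
        assert [p.lncrna for p in profiles] == ["LB", "LA", "LC"]
        assert [p.rank for p in profiles] == [1, 2, 3]

    def test_rank_invariant_under_rbp_relabeling(self):
        rng = np.random.default_rng(17)
        results = [
            result(f"L{i}", f"R{j}", float(rng.uniform(0.001, 0.5)))
            for i in range(5)
            for j in range(6)
        ]
        baseline = [(p.lncrna, p.rank) for p in sponge_scores(results)]
        relabeled = [
            EnrichmentResult(
                cell_line=r.cell_line, lncrna=r.lncrna, rbp=f"Z{r.rbp}",
                table=r.table, odds_ratio=r.odds_ratio, pvalue=r.pvalue,
                p_adjusted=r.p_adjusted, neg_log_p_adj=r.neg_log_p_adj,
            )
            for r in results
        ]
        assert [(p.lncrna, p.rank) for p in sponge_scores(relabeled)] == baseline

    def test_planted_sponge_ranks_first(self, sim_pipeline_results):
        truth, results = sim_pipeline_results
        profiles = sponge_scores(results)
        for cell_line, sponge in truth.sponges.items():
            top = next(p for p in profiles if p.cell_line == cell_line and p.rank == 1)
            assert top.lncrna == sponge


@pytest.fixture(scope="module")
def sim_pipeline_results(sim_dataset):
    """Run filter -> regions -> intersect -> enrich on the shared dataset."""
    from spongesplice.enrichment import enrich_cell_line
    from spongesplice.event_filtering import filter_events
    from spongesplice.interval_intersect import bound_flags
    from spongesplice.io_formats import read_peaks_dir, read_rmats_table, read_sample_sheet
    from spongesplice.proximal_regions import regions_for_comparison

    config, out, truth = sim_dataset
    sheet = read_sample_sheet(out / "sample_sheet.tsv")
    regions = []
    for row in sheet:
        for etype in config.event_types:
            events = filter_events(
                read_rmats_table(row.tables[etype], etype), config.filter_config
            )
            regions.extend(
                regions_for_comparison(
                    events, lncrna=row.lncrna, cell_line=row.cell_line,
                    window=config.window,
                )
            )
    tables = bound_flags(regions, read_peaks_dir(out / "peaks"))
    results = []
    for table in tables.values():
        results.extend(enrich_cell_line(table))
    return truth, results


class TestCluster:
    def test_identical_rows_distance_zero_merged_first(self):
        frame = pd.DataFrame(
            [[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]],
            index=["a", "b", "c"],
            columns=list("wxyz"),
        )
        res = cluster(frame, axis="rows")
        dist = pd.DataFrame(res.row_distance, index=frame.index, columns=frame.index)
        assert dist.loc["a", "b"] == pytest.approx(0.0)
        assert dist.loc["a", "c"] == pytest.approx(2.0)  # perfectly anti-ranked
        first_merge = res.row_linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    def test_distance_matrix_matches_naive_oracle(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(6, 6))
        X[2] = X[0] * 2 + 1  # monotone transform: rho exactly 1
        dist = spearman_distance_matrix(X)
        expected = naive_spearman_distance(X)
        assert np.allclose(dist, expected, atol=1e-12)
        assert dist[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(dist, dist.T) and np.allclose(np.diag(dist), 0.0)

    def test_zero_variance_row_warns_with_max_distance(self):
        X = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            dist = spearman_distance_matrix(X)
        assert dist[0, 1] == 2.0 and dist[0, 2] == 2.0 and dist[0, 0] == 0.0

    def test_leaf_order_deterministic_and_label_sorted_input(self):
        rng = np.random.default_rng(29)
        frame = pd.DataFrame(
            rng.integers(0, 5, size=(8, 5)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"s{i}" for i in range(5)],
        )
        shuffled = frame.sample(frac=1, random_state=1)
        a = cluster(frame, axis="both")
        b = cluster(shuffled, axis="both")
        assert a.row_order == b.row_order and a.col_order == b.col_order

    def test_newick_output_well_formed(self):
        frame = pd.DataFrame(
            np.arange(20).reshape(4, 5) % 7, index=list("abcd"), columns=list("vwxyz")
        )
        res = cluster(frame, axis="rows")
        assert res.row_newick.endswith(";")
        assert res.row_newick.count("(") == res.row_newick.count(")") == 3
        for label in "abcd":
            assert label in res.row_newick

    def test_too_small_matrix_rejected(self):
        frame = pd.DataFrame([[1, 2]], index=["a"], columns=["x", "y"])
        with pytest.raises(ValueError, match="2 rows"):
            cluster(frame, axis="rows")


def _se_matrix(counts_by_lnc, cell_line="HeLa"):
    frame = pd.DataFrame(
        {f"{l}|{cell_line}": [c] for l, c in counts_by_lnc.items()}, index=["G1"]
    )
    return EventFrequencyMatrix(event_type="SE", counts=frame)


def _profiles(n_sig_by_lnc, cell_line="HeLa"):
    from spongesplice.sponge_analysis import SpongeProfile

    return [
        SpongeProfile(
            lncrna=l, cell_line=cell_line, n_rbps_tested=10,
            n_rbps_significant=n, breadth=n / 10, rank=i + 1,
        )
        for i, (l, n) in enumerate(n_sig_by_lnc.items())
    ]


class TestCorrelation:
    def test_proportional_counts_give_rho_one(self):
        matrix = _se_matrix({"L1": 1, "L2": 2, "L3": 3, "L4": 4})
        profiles = _profiles({"L1": 1, "L2": 2, "L3": 3, "L4": 4})
        (report,) = binding_splicing_correlation(matrix, profiles)
        assert report.spearman_rho == pytest.approx(1.0)
        assert report.status == "ok"

    def test_insufficient_data_below_three(self):
        matrix = _se_matrix({"L1": 1, "L2": 2})
        profiles = _profiles({"L1": 1, "L2": 2})
        (report,) = binding_splicing_correlation(matrix, profiles)
        assert report.status == "insufficient_data" and report.n == 2
        assert "insufficient" in report.message

    def test_constant_input_reported_degenerate(self):
        matrix = _se_matrix({"L1": 5, "L2": 5, "L3": 5})
        profiles = _profiles({"L1": 1, "L2": 2, "L3": 3})
        (report,) = binding_splicing_correlation(matrix, profiles)
        assert report.status == "degenerate"

    def test_independent_counts_rarely_significant(self):
        """Null simulation: unrelated counts give p >= 0.05 in >= 90% of reps."""
        rng = np.random.default_rng(37)
        non_significant = 0
        reps = 100
        for _ in range(reps):
            lncs = {f"L{i}": int(rng.integers(1, 50)) for i in range(8)}
            sigs = {f"L{i}": int(rng.integers(0, 10)) for i in range(8)}
            (report,) = binding_splicing_correlation(_se_matrix(lncs), _profiles(sigs))
            if report.status != "ok" or not report.significant:
                non_significant += 1
        assert non_significant >= 90
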