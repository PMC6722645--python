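import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from _oracles import bh_step_up, fisher_enumeration
from spongesplice.enrichment import (
    ContingencyTable,
    DegenerateTableError,
    EnrichmentResult,
    adjust_pvalues,
    build_contingency,
    enrich_cell_line,
    enrichment_heatmap_matrix,
    fisher_exact,
    results_from_frame,
    results_to_frame,
)
from spongesplice.interval_intersect import BindingFlagTable


def flag_table(lncrna_labels, columns, cell_line="HeLa"):
    """Build a BindingFlagTable from per-region labels and bool columns."""
    index = pd.Index([f"r{i}" for i in range(len(lncrna_labels))], name="region")
    return BindingFlagTable(
        cell_line=cell_line,
        flags=pd.DataFrame({k: list(v) for k, v in columns.items()}, index=index),
        lncrna=pd.Series(list(lncrna_labels), index=index),
        gene_symbol=pd.Series([f"G{i}" for i in range(len(lncrna_labels))], index=index),
    )


class TestContingency:
    def test_counting_example(self):
        """4 focal regions (3 bound) vs 10 background (2 bound) -> (3,1,2,8)."""
        labels = ["L1"] * 4 + ["L2"] * 5 + ["L3"] * 5
        bound = [True, True, True, False] + [True, False, False, False, False] + [
            True, False, False, False, False,
        ]
        table = build_contingency(flag_table(labels, {"X": bound}), "L1", "X")
        assert table.as_tuple() == (3, 1, 2, 8)

    def test_rbp_binding_nothing(self):
        labels = ["L1"] * 3 + ["L2"] * 7
        table = build_contingency(
            flag_table(labels, {"X": [False] * 10}), "L1", "X"
        )
        assert table.as_tuple() == (0, 3, 0, 7)

    def test_zero_region_lncrna_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            build_contingency(flag_table(["L1"], {"X": [True]}), "L9", "X")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_matches_naive_per_region_loop(self):
        rng = np.random.default_rng(12)
        labels = [f"L{int(i)}" for i in rng.integers(0, 4, size=60)]
        bound = list(rng.random(60) < 0.3)
        table = build_contingency(flag_table(labels, {"X": bound}), "L2", "X")
        x = sum(1 for l, f in zip(labels, bound) if l == "L2" and f)
        y = sum(1 for l, f in zip(labels, bound) if l == "L2" and not f)
        a = sum(1 for l, f in zip(labels, bound) if l != "L2" and f)
        b = sum(1 for l, f in zip(labels, bound) if l != "L2" and not f)
        assert table.as_tuple() == (x, y, a, b)


class TestFisherExact:
    def test_small_table_exact_values(self):
        """(3,1,1,3): two-sided p = 34/70, OR = 9; one-sided greater = 17/70."""
        table = ContingencyTable(3, 1, 1, 3)
        odds, p_two = fisher_exact(table, alternative="two-sided")
        assert odds == pytest.approx(9.0)
        assert p_two == pytest.approx(34 / 70, abs=1e-12)
        _, p_greater = fisher_exact(table, alternative="greater")
        assert p_greater == pytest.approx(17 / 70, abs=1e-12)

    def test_degenerate_margins_give_p_one(self):
        odds, p = fisher_exact(ContingencyTable(0, 5, 0, 5), alternative="greater")
        assert p == 1.0 and math.isnan(odds)

    def test_all_zero_table_is_null(self):
        odds, p = fisher_exact(ContingencyTable(0, 0, 0, 0))
        assert p is None and math.isnan(odds)

    def test_infinite_odds_ratio(self):
        odds, _ = fisher_exact(ContingencyTable(3, 0, 1, 3))
        assert odds == math.inf

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_matches_scipy_on_random_tables(self, alternative):
        rng = np.random.default_rng(21)
        for _ in range(200):
            x, y, a, b = (int(v) for v in rng.integers(0, 40, size=4))
            if x + y + a + b == 0:
                continue
            table = ContingencyTable(x, y, a, b)
            _, p = fisher_exact(table, alternative=alternative)
            scipy_alt = alternative.replace("two-sided", "two-sided")
            expected = scipy.stats.fisher_exact(
                [[x, y], [a, b]], alternative=scipy_alt
            ).pvalue
            assert p == pytest.approx(expected, abs=1e-10)

    def test_matches_enumeration_small_margins(self):
        """Spot version of the exhaustive check (full sweep in acceptance)."""
        for x in range(0, 8):
            for y in range(0, 8):
                for a in range(0, 8):
                    for b in range(0, 8):
                        if x + y + a + b == 0:
                            continue
                        table = ContingencyTable(x, y, a, b)
                        pg, pl, pt = fisher_enumeration(x, y, a, b)
                        assert fisher_exact(table, "greater")[1] == pytest.approx(pg, abs=1e-12)
                        assert fisher_exact(table, "less")[1] == pytest.approx(pl, abs=1e-12)
                        assert fisher_exact(table, "two-sided")[1] == pytest.approx(pt, abs=1e-12)


def _results(pvalues, cell_line="HeLa"):
    out = []
    for i, p in enumerate(pvalues):
        out.append(
            EnrichmentResult(
                cell_line=cell_line,
                lncrna=f"L{i}",
                rbp="X",
                table=ContingencyTable(1, 1, 1, 1),
                odds_ratio=1.0,
                pvalue=p,
            )
        )
    return out


class TestAdjustment:
    def test_hand_step_up_example(self):
        results = _results([0.01, 0.02, 0.03, 0.04])
        adjust_pvalues(results)
        assert [r.p_adjusted for r in results] == pytest.approx([0.04] * 4)

    def test_single_test_unchanged(self):
        results = _results([0.03])
        adjust_pvalues(results)
        assert results[0].p_adjusted == pytest.approx(0.03)

    def test_matches_step_up_oracle_and_rank_monotone(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            pvals = rng.uniform(0, 1, size=int(rng.integers(2, 30))).tolist()
            results = _results(pvals)
            adjust_pvalues(results)
            expected = bh_step_up(pvals)
            assert [r.p_adjusted for r in results] == pytest.approx(expected, abs=1e-12)
            ranked = sorted(results, key=lambda r: r.pvalue)
            adj = [r.p_adjusted for r in ranked]
            assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))

    def test_nulls_excluded_from_m(self):
        results = _results([0.01, 0.02])
        results.append(
            EnrichmentResult(
                cell_line="HeLa", lncrna="L9", rbp="X",
                table=ContingencyTable(1, 0, 1, 0), odds_ratio=math.nan, pvalue=None,
            )
        )
        adjust_pvalues(results)
        # m = 2, not 3: adjusted = (0.02, 0.02)
        assert results[0].p_adjusted == pytest.approx(0.02)
        assert results[2].p_adjusted is None

    def test_bonferroni_and_by_supported(self):
        results = _results([0.01, 0.04])
        adjust_pvalues(results, method="bonferroni")
        assert [r.p_adjusted for r in results] == pytest.approx([0.02, 0.08])
        with pytest.raises(ValueError):
            adjust_pvalues(results, method="holm")


class TestEnrichCellLine:
    def test_conservation_of_region_counts(self):
        rng = np.random.default_rng(41)
        labels = [f"L{int(i)}" for i in rng.integers(0, 3, size=48)]
        cols = {f"R{j}": list(rng.random(48) < 0.4) for j in range(4)}
        results = enrich_cell_line(flag_table(labels, cols))
        for r in results:
            assert r.table.n_total == 48

    def test_saturated_rbp_yields_null_row(self):
        """An RBP bound in 100% of regions admits no test: NULL for every lncRNA."""
        labels = ["L1"] * 4 + ["L2"] * 4
        cols = {"SAT": [True] * 8, "OK": [True, False] * 4}
        results = enrich_cell_line(flag_table(labels, cols))
        sat = [r for r in results if r.rbp == "SAT"]
        ok = [r for r in results if r.rbp == "OK"]
        assert len(sat) == 2 and all(r.is_null for r in sat)
        assert all(not r.is_null for r in ok)

    def test_type_one_error_calibration_under_label_permutation(self):
        """With binding independent of lncRNA labels, raw p < 0.05 happens at
        roughly the nominal rate (within 3 binomial SE, allowing the exact
        test's conservativeness)."""
        rng = np.random.default_rng(51)
        n_regions, n_rbps, n_lnc, n_seeds = 240, 6, 4, 6
        hits = total = 0
        for _ in range(n_seeds):
            labels = [f"L{i % n_lnc}" for i in range(n_regions)]
            cols = {f"R{j}": list(rng.random(n_regions) < 0.5) for j in range(n_rbps)}
            results = enrich_cell_line(flag_table(labels, cols))
            hits += sum(1 for r in results if r.pvalue is not None and r.pvalue < 0.05)
            total += sum(1 for r in results if r.pvalue is not None)
        rate = hits / total
        se = math.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * se
        assert rate >= 0.05 - 3 * se - 0.02  # discreteness makes the test conservative

    def test_results_frame_round_trip(self):
        labels = ["L1"] * 4 + ["L2"] * 4
        cols = {"SAT": [True] * 8, "OK": [True, False] * 4}
        results = enrich_cell_line(flag_table(labels, cols))
        frame = results_to_frame(results)
        restored = results_from_frame(frame)
        assert [(r.lncrna, r.rbp, r.is_null) for r in restored] == [
            (r.lncrna, r.rbp, r.is_null) for r in results
        ]
        for a, b in zip(restored, results):
            if not a.is_null:
                assert a.pvalue == pytest.approx(b.pvalue)
                assert a.p_adjusted == pytest.approx(b.p_adjusted)


class TestHeatmapMatrix:
    def test_neg_log_arithmetic_and_nulls(self):
        results = [
            EnrichmentResult(
                cell_line="HeLa", lncrna="L1", rbp="X",
                table=ContingencyTable(1, 1, 1, 1), odds_ratio=1.0,
                pvalue=0.005, p_adjusted=0.01, neg_log_p_adj=2.0,
            ),
            EnrichmentResult(
                cell_line="HeLa", lncrna="L1", rbp="SAT",
                table=ContingencyTable(2, 0, 2, 0), odds_ratio=math.nan, pvalue=None,
            ),
        ]
        matrix = enrichment_heatmap_matrix(results, "HeLa", cluster=False)
        assert matrix.loc["L1", "X"] == pytest.approx(2.0)
        assert math.isnan(matrix.loc["L1", "SAT"])

    def test_other_cell_lines_excluded(self):
        results = [
            EnrichmentResult(
                cell_line="K562", lncrna="L1", rbp="X",
                table=ContingencyTable(1, 1, 1, 1), odds_ratio=1.0,
                pvalue=0.01, p_adjusted=0.01, neg_log_p_adj=2.0,
            )
        ]
        assert enrichment_heatmap_matrix(results, "HeLa").empty
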