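import itertools

import numpy as np
import pandas as pd
import pytest

import screenconsensus as sc
from .conftest import make_scores


def expr_matrix(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    genes = genes or [f"G{i:03d}" for i in range(m)]
    cells = cells or [f"C{j:02d}" for j in range(n)]
    return sc.ScreenMatrix(pd.DataFrame(values, index=genes, columns=cells),
                           kind="expression")


def call_set(mapping, platform="CRISPR", cls="E"):
    return sc.EssentialCallSet(platform=platform, label_class=cls, x_frac=0.1,
                               calls={c: frozenset(g) for c, g in mapping.items()})


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        series, mean = sc.per_cellline_correlation(make_scores(x),
                                                   make_scores(-x))
        assert np.allclose(series.to_numpy(), -1.0)
        assert mean == pytest.approx(-1.0)

    def test_constant_column_excluded_from_mean(self):
        x = np.arange(12, dtype=float).reshape(4, 3)
        y = x.copy()
        y[:, 1] = 5.0                                    # zero variance
        series, mean = sc.per_cellline_correlation(make_scores(x),
                                                   make_scores(y))
        assert np.isnan(series.iloc[1])
        assert mean == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=(10, 3))
        series, _ = sc.per_cellline_correlation(make_scores(x), make_scores(y))
        for j in range(3):
            a, b = x[:, j], y[:, j]
            r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
                np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
            assert series.iloc[j] == pytest.approx(r)

    def test_subset_restricts_genes(self):
        x = np.array([[1.0, 1], [2, 2], [3, 3], [4, 4]])
        y = np.array([[1.0, 4], [2, 3], [3, 2], [4, 1]])
        subset = {"C00": frozenset({"G000", "G001", "G002"})}
        series, _ = sc.per_cellline_correlation(make_scores(x), make_scores(y),
                                                subset=subset)
        assert series["C00"] == pytest.approx(1.0)
        assert np.isnan(series["C01"])               # empty subset there

    def test_pairwise_complete(self):
        x = np.array([[1.0], [2], [3], [np.nan], [5]])
        y = np.array([[2.0], [4], [6], [8], [np.nan]])
        series, _ = sc.per_cellline_correlation(make_scores(x), make_scores(y))
        assert series.iloc[0] == pytest.approx(1.0)


class TestStrataCounts:
    def test_calls_outside_stratum_count_zero(self):
        expr = expr_matrix(np.arange(10, dtype=float).reshape(-1, 1))
        calls_E = call_set({"C00": {"G008", "G009"}})       # highest expressed
        calls_NE = call_set({"C00": set()}, cls="NE")
        out = sc.expression_strata_counts(calls_E, calls_NE, expr, 0.2, "low")
        assert out["count"].tolist() == [0, 0]

    def test_hand_tally_low_stratum(self):
        # 30 genes; stratum = 3 lowest expressed; two of them called E
        expr = expr_matrix(np.arange(30, dtype=float).reshape(-1, 1))
        calls_E = call_set({"C00": {"G000", "G002", "G020"}})
        calls_NE = call_set({"C00": {"G001"}}, cls="NE")
        out = sc.expression_strata_counts(calls_E, calls_NE, expr, 0.1, "low")
        by_class = dict(zip(out["class"], out["count"]))
        assert by_class == {"E": 2, "NE": 1}

    def test_high_side(self):
        expr = expr_matrix(np.arange(10, dtype=float).reshape(-1, 1))
        calls_E = call_set({"C00": {"G009", "G000"}})
        calls_NE = call_set({"C00": set()}, cls="NE")
        out = sc.expression_strata_counts(calls_E, calls_NE, expr, 0.2, "high")
        assert dict(zip(out["class"], out["count"]))["E"] == 1


class TestGroup8:
    def test_paper_semantics_crispr_e_shrna_ne_is_group4(self):
        asn = sc.group8_classify(
            call_set({"C00": {"G000"}}), call_set({"C00": set()}, cls="NE"),
            call_set({"C00": set()}, platform="SHRNA"),
            call_set({"C00": {"G000"}}, platform="SHRNA", cls="NE"))
        assert asn.iloc[0]["group"] == 4

    def test_uncalled_pairs_absent(self):
        asn = sc.group8_classify(
            call_set({"C00": {"G000"}}), call_set({"C00": set()}, cls="NE"),
            call_set({"C00": set()}, platform="SHRNA"),
            call_set({"C00": set()}, platform="SHRNA", cls="NE"))
        assert len(asn) == 1                     # only the one called pair

    def test_overlapping_calls_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            sc.group8_classify(
                call_set({"C00": {"G000"}}),
                call_set({"C00": {"G000"}}, cls="NE"),
                call_set({"C00": set()}, platform="SHRNA"),
                call_set({"C00": set()}, platform="SHRNA", cls="NE"))

    def test_random_callsets_match_state_table(self):
        # independent oracle: exhaustive 3x3 status enumeration per pair
        table = {("E", "E"): 1, ("E", None): 2, (None, "E"): 3,
                 ("E", "NE"): 4, ("NE", "E"): 5, ("NE", "NE"): 6,
                 (None, "NE"): 7, ("NE", None): 8}
        rng = np.random.default_rng(3)
        genes = [f"G{i:03d}" for i in range(25)]
        cells = [f"C{j:02d}" for j in range(4)]
        status = {(g, c): (rng.choice(["E", "NE", "none"]),
                           rng.choice(["E", "NE", "none"]))
                  for g, c in itertools.product(genes, cells)}
        maps = {("C", "E"): {}, ("C", "NE"): {}, ("S", "E"): {}, ("S", "NE"): {}}
        for c in cells:
            for key in maps:
                maps[key][c] = set()
        for (g, c), (cs, ss) in status.items():
            if cs != "none":
                maps[("C", cs)][c].add(g)
            if ss != "none":
                maps[("S", ss)][c].add(g)
        asn = sc.group8_classify(
            call_set(maps[("C", "E")]), call_set(maps[("C", "NE")], cls="NE"),
            call_set(maps[("S", "E")], platform="SHRNA"),
            call_set(maps[("S", "NE")], platform="SHRNA", cls="NE"))
        got = {(g, c): grp for g, c, grp in
               zip(asn["gene"], asn["cell_line"], asn["group"])}
        for (g, c), (cs, ss) in status.items():
            key = (None if cs == "none" else cs, None if ss == "none" else ss)
            if key == (None, None):
                assert (g, c) not in got
            else:
                assert got[(g, c)] == table[key]
        # classified pairs plus uncalled pairs partition everything
        n_uncalled = sum(1 for s in status.values() if s == ("none", "none"))
        assert len(asn) + n_uncalled == len(genes) * len(cells)


class TestGroupSummary:
    def _assignment(self, rows):
        return pd.DataFrame(rows, columns=["gene", "cell_line", "group"])

    def test_single_member_group(self):
        expr = expr_matrix([[5.0]], genes=["G000"], cells=["C00"])
        out = sc.group_expression_summary(
            self._assignment([("G000", "C00", 1)]), expr)
        assert (out.loc[1] == 5.0).all()

    def test_median_of_five(self):
        expr = expr_matrix(np.array([[1.0, 2, 3, 4, 5]]).T,
                           genes=[f"G{i}" for i in range(5)], cells=["C00"])
        rows = [(f"G{i}", "C00", 2) for i in range(5)]
        out = sc.group_expression_summary(self._assignment(rows), expr)
        assert out.loc[2, "median"] == 3.0
        assert out.loc[2, "min"] == 1.0 and out.loc[2, "max"] == 5.0

    def test_random_group_matches_sort_oracle(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(100, 1)) + 5
        expr = expr_matrix(vals, genes=[f"G{i:03d}" for i in range(100)],
                           cells=["C00"])
        rows = [(f"G{i:03d}", "C00", 3) for i in range(100)]
        out = sc.group_expression_summary(self._assignment(rows), expr)
        srt = np.sort(vals.ravel())
        assert out.loc[3, "min"] == srt[0]
        assert out.loc[3, "max"] == srt[-1]
        assert out.loc[3, "median"] == pytest.approx(np.median(srt))

    def test_empty_group_is_nan(self):
        expr = expr_matrix([[5.0]], genes=["G000"], cells=["C00"])
        out = sc.group_expression_summary(
            self._assignment([("G000", "C00", 1)]), expr)
        assert out.loc[5].isna().all()


class TestDensity:
    def test_two_separated_clusters_two_peaks(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(1.0, 0.1, 200),
                               rng.normal(6.0, 0.1, 200)])
        d = sc.expression_density(vals)
        assert d.peaks.size == 2
        assert abs(d.peaks[0] - 1.0) < 0.2 and abs(d.peaks[1] - 6.0) < 0.2

    def test_single_cluster_one_peak(self):
        rng = np.random.default_rng(6)
        d = sc.expression_density(rng.normal(3.0, 0.5, 300))
        assert d.peaks.size == 1

    def test_density_normalized_on_grid(self):
        rng = np.random.default_rng(7)
        d = sc.expression_density(rng.normal(size=400))
        step = d.grid[1] - d.grid[0]
        assert d.density.sum() * step == pytest.approx(1.0, abs=0.01)
        assert (d.density >= 0).all()

    def test_identical_values_error(self):
        with pytest.raises(ValueError, match="point mass"):
            sc.expression_density([2.0, 2.0, 2.0])


class TestLowExpressionReport:
    def test_all_above_threshold(self):
        expr = expr_matrix(np.full((3, 2), 5.0))
        calls = call_set({"C00": {"G000"}, "C01": {"G001"}})
        assert sc.low_expression_report(calls, expr, 1.8) == (0, 0)

    def test_infinite_threshold_equals_plain_counts(self):
        expr = expr_matrix(np.full((3, 2), 5.0))
        calls = call_set({"C00": {"G000", "G002"}, "C01": {"G000"}})
        assert sc.low_expression_report(calls, expr, np.inf) == \
            sc.count_unique_and_overlap(calls)

    def test_hand_tally(self):
        # 3 sub-threshold call pairs over 2 unique genes
        vals = np.full((30, 2), 5.0)
        vals[0, :] = 1.0                 # G000 low in both cell lines
        vals[1, 0] = 0.5                 # G001 low in C00 only
        expr = expr_matrix(vals)
        calls = call_set({"C00": {"G000", "G001"}, "C01": {"G000", "G002"}})
        assert sc.low_expression_report(calls, expr, 1.8) == (2, 3)


class TestProfile:
    def test_unanimous_gene(self):
        labels = sc.assign_labels(
            make_scores(np.tile(np.arange(10.0).reshape(-1, 1), (1, 4))), 0.10)
        prof = sc.essentiality_profile(labels, ["G000"])
        top = prof.iloc[0]
        assert top["gene"] == "G000"
        assert top["n_essential_lines"] == 4
        assert top["n_nonessential_lines"] == 0

    def test_random_labels_match_tally(self):
        rng = np.random.default_rng(8)
        labels = sc.assign_labels(make_scores(rng.normal(size=(20, 5))), 0.2)
        prof = sc.essentiality_profile(labels, list(labels.gene_ids[:3]))
        codes = labels.codes()
        by_gene = prof.set_index("gene")
        for i, g in enumerate(labels.gene_ids):
            assert by_gene.at[g, "n_essential_lines"] == (codes[i] == 0).sum()
            assert by_gene.at[g, "n_nonessential_lines"] == (codes[i] == 1).sum()

    def test_order_top_first_then_rest_sorted(self):
        labels = sc.assign_labels(
            make_scores(np.random.default_rng(9).normal(size=(6, 3))), 0.2)
        prof = sc.essentiality_profile(labels, ["G004", "G001"])
        assert prof["gene"].tolist() == ["G004", "G001", "G000", "G002",
                                         "G003", "G005"]
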