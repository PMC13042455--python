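"""Recovery-curve AUC scoring, group z-scores and group tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import sparse

from tcrdyn.scoring import (
    ExpressionMatrix,
    aucell_score,
    clone_size_strata,
    compare_groups,
    pdcd1_groups,
    read_expression_bundle,
    read_gmt,
    significance_tier,
    write_gmt,
    zscore_group_means,
)


def expr_from_rows(rows, genes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n_cells, n_genes = rows.shape
    genes = genes or [f"g{j + 1}" for j in range(n_genes)]
    return ExpressionMatrix(
        matrix=sparse.csr_matrix(rows),
        cells=[f"cell{i}" for i in range(n_cells)],
        genes=genes,
    )


class TestAucellScore:
    def test_single_top_gene_full_recovery(self):
        # 10 genes, g1 highest, set {g1}, k = 5 -> AUC 1
        expr = expr_from_rows([np.arange(10, 0, -1)])
        out = aucell_score(expr, ["g1"], top_fraction=0.5)
        assert out["auc"].iloc[0] == pytest.approx(1.0)
        assert out["threshold_rank"].iloc[0] == 5

    def test_set_outside_top_k_scores_zero(self):
        expr = expr_from_rows([np.arange(10, 0, -1)])
        out = aucell_score(expr, ["g10"], top_fraction=0.5)
        assert out["auc"].iloc[0] == 0.0

    def test_worked_recovery_curve_value(self):
        # set genes at ranks 1 and 4 of 10, k = 5:
        # c = [1,1,1,2,2] sums to 7; c_max = [1,2,2,2,2] sums to 9
        expr = expr_from_rows([np.arange(10, 0, -1)])
        out = aucell_score(expr, ["g1", "g4"], top_fraction=0.5)
        assert out["auc"].iloc[0] == pytest.approx(7 / 9)

    def test_empty_overlap_names_missing_genes(self):
        expr = expr_from_rows([np.arange(5, 0, -1)])
        with pytest.raises(ValueError, match="gX"):
            aucell_score(expr, ["gX"])

    def test_invalid_top_fraction_rejected(self):
        expr = expr_from_rows([np.arange(5, 0, -1)])
        with pytest.raises(ValueError, match="top_fraction"):
            aucell_score(expr, ["g1"], top_fraction=0.0)

    def test_ties_resolved_by_gene_name_deterministically(self):
        expr = expr_from_rows([[1.0, 1.0, 1.0, 0.0]], genes=["gb", "ga", "gc", "gd"])
        out1 = aucell_score(expr, ["ga"], top_fraction=0.25)
        assert out1["auc"].iloc[0] == pytest.approx(1.0)  # ga first among ties
        out2 = aucell_score(expr, ["gc"], top_fraction=0.25)
        assert out2["auc"].iloc[0] == 0.0

    @given(st.integers(0, 2**32 - 1))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((5, 40))
        expr_a = expr_from_rows(x)
        expr_b = expr_from_rows(np.expm1(3 * x))  # strictly increasing map
        gene_set = [f"g{j}" for j in rng.choice(np.arange(1, 41), size=6, replace=False)]
        a = aucell_score(expr_a, gene_set, top_fraction=0.25)["auc"]
        b = aucell_score(expr_b, gene_set, top_fraction=0.25)["auc"]
        assert np.allclose(a, b)

    @given(st.integers(0, 2**32 - 1))
    def test_monotone_in_rank_of_set_genes(self, seed):
        """Raising a set gene's expression (moving it up in rank) never
        decreases the AUC."""
        rng = np.random.default_rng(seed)
        x = rng.random(30)
        expr = expr_from_rows([x])
        gene = f"g{int(rng.integers(1, 31))}"
        before = aucell_score(expr, [gene], top_fraction=0.3)["auc"].iloc[0]
        x2 = x.copy()
        x2[int(gene[1:]) - 1] = x.max() + 1.0
        after = aucell_score(expr_from_rows([x2]), [gene], top_fraction=0.3)["auc"].iloc[0]
        assert after >= before - 1e-12


class TestZscoreGroupMeans:
    def _scores(self, means, n=4):
        rows = []
        grouping = {}
        for g, mu in means.items():
            for i in range(n):
                cell = f"{g}_{i}"
                rows.append({"cell": cell, "gene_set": "s", "auc": mu, "threshold_rank": 5})
                grouping[cell] = g
        return pd.DataFrame(rows), grouping

    def test_three_groups_sample_sd_normalization(self):
        scores, grouping = self._scores({"a": 1.0, "b": 2.0, "c": 3.0})
        out = {s.group: s.z_mean for s in zscore_group_means(scores, grouping)}
        assert out["a"] == pytest.approx(-1.0)
        assert out["b"] == pytest.approx(0.0)
        assert out["c"] == pytest.approx(1.0)

    def test_equal_means_all_zero(self):
        scores, grouping = self._scores({"a": 0.5, "b": 0.5})
        assert all(s.z_mean == 0.0 for s in zscore_group_means(scores, grouping))

    def test_two_groups_symmetric(self):
        scores, grouping = self._scores({"a": 0.2, "b": 0.8})
        out = {s.group: s.z_mean for s in zscore_group_means(scores, grouping)}
        assert out["a"] == pytest.approx(-out["b"])

    def test_single_group_mean_returned_z_undefined(self):
        scores, grouping = self._scores({"a": 0.4})
        (summary,) = zscore_group_means(scores, grouping)
        assert summary.mean_auc == pytest.approx(0.4)
        assert np.isnan(summary.z_mean)


class TestCompareGroups:
    def _scores(self, a, b):
        cells = [f"a{i}" for i in range(len(a))] + [f"b{i}" for i in range(len(b))]
        scores = pd.DataFrame(
            {"cell": cells, "gene_set": "s", "auc": list(a) + list(b), "threshold_rank": 5}
        )
        grouping = {c: c[0] for c in cells}
        return scores, grouping

    def test_identical_scores_p_one_ns(self):
        scores, grouping = self._scores([0.3] * 5, [0.3] * 5)
        result = compare_groups(scores, grouping, ("a", "b"))
        assert result.p_value == 1.0 and result.tier == "ns"

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(0)
        ok = 0
        for _ in range(20):
            a = rng.normal(0, 1, 200)
            b = rng.normal(2, 1, 200)
            scores, grouping = self._scores(a, b)
            ok += compare_groups(scores, grouping, ("a", "b")).p_value < 0.001
        assert ok >= 20 * 0.99

    def test_label_swap_negates_statistic(self):
        rng = np.random.default_rng(1)
        scores, grouping = self._scores(rng.normal(0, 1, 30), rng.normal(1, 2, 40))
        fwd = compare_groups(scores, grouping, ("a", "b"))
        rev = compare_groups(scores, grouping, ("b", "a"))
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.statistic == pytest.approx(-rev.statistic)

    def test_tiny_group_rejected(self):
        scores, grouping = self._scores([0.1], [0.2, 0.3])
        with pytest.raises(ValueError, match="2 cells"):
            compare_groups(scores, grouping, ("a", "b"))

    def test_tier_thresholds(self):
        assert significance_tier(0.004) == "**"
        assert significance_tier(0.04) == "*"
        assert significance_tier(0.4) == "ns"


class TestGroupingHelpers:
    def test_pdcd1_positive_is_strictly_above_zero(self):
        expr = expr_from_rows([[0, 3], [0, 0], [1, 2]], genes=["other", "PDCD1"])
        groups = pdcd1_groups(expr)
        assert groups == {"cell0": "PDCD1+", "cell1": "PDCD1-", "cell2": "PDCD1+"}

    def test_pdcd1_gene_must_exist(self):
        with pytest.raises(ValueError, match="PDCD1"):
            pdcd1_groups(expr_from_rows([[1.0]], genes=["other"]))

    def test_clone_size_strata_thresholds(self):
        strata = clone_size_strata({"c1": 1, "c2": 2, "c3": 3, "c4": 50})
        assert strata == {
            "c1": "novel_nonexpanded",
            "c2": "intermediate",
            "c3": "expanded",
            "c4": "expanded",
        }


def test_gmt_round_trip_and_expression_bundle(tmp_path):
    sets = {"setA": ["g1", "g2"], "setB": ["g3"]}
    gmt = tmp_path / "sets.gmt"
    write_gmt(sets, gmt)
    assert read_gmt(gmt) == sets

    from scipy.io import mmwrite

    m = sparse.csr_matrix(np.array([[1, 0, 2], [0, 3, 0]]))  # genes x cells? no: 2x3
    mmwrite(str(tmp_path / "m.mtx"), m.T.tocoo(), field="integer")  # genes(3) x cells(2)
    (tmp_path / "genes.tsv").write_text("g1\tg1\ng2\tg2\ng3\tg3\n")
    (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
    expr = read_expression_bundle(
        tmp_path / "m.mtx", tmp_path / "genes.tsv", tmp_path / "barcodes.tsv"
    )
    assert expr.matrix.shape == (2, 3)  # cells x genes internally
    assert expr.matrix.toarray().tolist() == [[1, 0, 2], [0, 3, 0]]
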