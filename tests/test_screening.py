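"""Rank-sum screening, BH adjustment, normalization and DE selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ikcscore as ik
from ikcscore.core_io import ValidationError
from ikcscore.screening import (
    UP_IN_NR,
    UP_IN_R,
    bh_adjust,
    differential_expression,
    filter_pseudogenes,
    normalize_counts,
    pool_signature_genes,
    rank_sum_test,
    screen_gene_candidates,
    screen_signatures,
)
from ikcscore.ssgsea import ScoreMatrix


class TestRankSumTest:
    def test_exact_enumeration_small_groups(self):
        """x={1,2} vs y={3,4}: U_x=0, exact two-sided p = 1/3."""
        u, p = rank_sum_test([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_give_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_full_separation_large_groups(self):
        x = np.arange(1, 51)
        y = np.arange(51, 101)
        _, p = rank_sum_test(x, y)
        assert p < 1e-10

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x, y = rng.normal(size=9), rng.normal(1.0, 1.0, size=12)
            _, p = rank_sum_test(x, y)
            _, p2 = rank_sum_test(np.exp(x), np.exp(y))
            assert p == pytest.approx(p2, abs=1e-12)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.25], [0.25]),
            ([0.5, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_computed_step_up(self, raw, expected):
        assert bh_adjust(raw) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_never_decreases_and_preserves_order(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


def _score_matrix_from(frame: pd.DataFrame) -> ScoreMatrix:
    return ScoreMatrix(frame, normalized=True, alpha=0.25)


def _clinical(n_r: int, n_nr: int) -> ik.ClinicalTable:
    labels = ["PR"] * n_r + ["PD"] * n_nr
    df = pd.DataFrame({"response": labels},
                      index=pd.Index([f"s{i}" for i in range(n_r + n_nr)], name="sample_id"))
    return ik.core_io.make_clinical(df)


class TestScreenSignatures:
    def test_top_k_rule_per_direction(self):
        """20 up-in-R and 5 up-in-NR separated signatures -> 15 + 5 selected."""
        rng = np.random.default_rng(2)
        n_r, n_nr = 10, 10
        clinical = _clinical(n_r, n_nr)
        rows = {}
        for i in range(20):
            rows[f"UPR{i:02d}"] = np.r_[rng.normal(5, 0.3, n_r), rng.normal(0, 0.3, n_nr)]
        for i in range(5):
            rows[f"UPN{i:02d}"] = np.r_[rng.normal(0, 0.3, n_r), rng.normal(5, 0.3, n_nr)]
        for i in range(10):
            rows[f"NULL{i:02d}"] = rng.normal(0, 1.0, n_r + n_nr)
        frame = pd.DataFrame(rows, index=clinical.sample_ids).T
        result = screen_signatures(_score_matrix_from(frame), clinical, top_k=15)
        assert len(result.selected_by_direction(UP_IN_R)) == 15
        assert len(result.selected_by_direction(UP_IN_NR)) == 5
        assert all(s.startswith("UPN") for s in result.selected_by_direction(UP_IN_NR))

    def test_no_passers_empty_selection(self):
        rng = np.random.default_rng(3)
        clinical = _clinical(5, 5)
        frame = pd.DataFrame(rng.normal(size=(4, 10)),
                             index=[f"S{i}" for i in range(4)], columns=clinical.sample_ids)
        result = screen_signatures(_score_matrix_from(frame), clinical, p_max=1e-6)
        assert result.selected.empty

    def test_identical_signatures_tie_broken_by_name(self):
        clinical = _clinical(4, 4)
        row = np.r_[np.ones(4) * 5, np.zeros(4)]
        frame = pd.DataFrame([row, row], index=["ZED", "ABLE"], columns=clinical.sample_ids)
        result = screen_signatures(_score_matrix_from(frame), clinical)
        assert result.selected_features == ["ABLE", "ZED"]

    def test_empty_response_group_rejected(self):
        clinical = _clinical(8, 0)
        frame = pd.DataFrame(np.ones((2, 8)), index=["A", "B"], columns=clinical.sample_ids)
        with pytest.raises(ValidationError):
            screen_signatures(_score_matrix_from(frame), clinical)


class TestPoolGenes:
    def test_union_deduplicated_sorted(self):
        coll = ik.GeneSetCollection([
            ik.GeneSet("A", "", frozenset({"g1", "g2"})),
            ik.GeneSet("B", "", frozenset({"g2", "g3"})),
        ])
        assert pool_signature_genes(["A", "B"], coll) == ["G1", "G2", "G3"]
        assert pool_signature_genes(["A"], coll) == ["G1", "G2"]

    def test_disjoint_sets_add_up(self):
        a = ik.GeneSet("A", "", frozenset(f"x{i}" for i in range(16)))
        b = ik.GeneSet("B", "", frozenset(f"y{i}" for i in range(70)))
        coll = ik.GeneSetCollection([a, b])
        assert len(pool_signature_genes(["A", "B"], coll)) == 86

    def test_missing_signature_rejected(self):
        coll = ik.GeneSetCollection([ik.GeneSet("A", "", frozenset({"g1"}))])
        with pytest.raises(ValidationError):
            pool_signature_genes(["A", "NOPE"], coll)


class TestNormalizeCounts:
    def test_proportional_samples_equalized(self):
        """s2 = 2*s1 -> size factors 1:2 and identical normalized columns."""
        data = pd.DataFrame({"s1": [2.0, 4.0, 8.0], "s2": [4.0, 8.0, 16.0]},
                            index=["a", "b", "c"])
        norm = normalize_counts(ik.ExpressionMatrix(data, "counts"))
        assert norm.value_kind == "normalized"
        assert norm.data["s1"].tolist() == pytest.approx(norm.data["s2"].tolist())
        # ratio of implied size factors is 1:2
        assert (data["s2"] / norm.data["s2"]).iloc[0] == pytest.approx(
            2 * (data["s1"] / norm.data["s1"]).iloc[0]
        )

    def test_identical_samples_unchanged(self):
        data = pd.DataFrame({"s1": [3.0, 7.0], "s2": [3.0, 7.0]}, index=["a", "b"])
        norm = normalize_counts(ik.ExpressionMatrix(data, "counts"))
        pd.testing.assert_frame_equal(norm.data, data)

    def test_all_zero_sample_rejected(self):
        data = pd.DataFrame({"s1": [1.0, 2.0], "s2": [0.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="all-zero"):
            normalize_counts(ik.ExpressionMatrix(data, "counts"))

    def test_normalized_input_rejected(self, toy_expression):
        with pytest.raises(ValidationError):
            normalize_counts(toy_expression)


class TestDifferentialExpression:
    def _cohort(self, seed=0, n_r=30, n_nr=30, planted_fold=4.0):
        rng = np.random.default_rng(seed)
        n_genes = 40
        base = rng.uniform(50, 500, n_genes)
        counts = rng.poisson(np.tile(base[:, None], (1, n_r + n_nr))).astype(float)
        counts[0, :n_r] = rng.poisson(base[0] * planted_fold, n_r)  # planted up-in-R
        frame = pd.DataFrame(counts, index=[f"G{i:02d}" for i in range(n_genes)],
                             columns=[f"s{i}" for i in range(n_r + n_nr)])
        return ik.ExpressionMatrix(frame, "counts"), _clinical(n_r, n_nr)

    def test_planted_gene_selected_up_in_r(self):
        expr, clinical = self._cohort()
        result = differential_expression(expr, clinical)
        assert "G00" in result.selected_by_direction(UP_IN_R)

    def test_identical_groups_gene_excluded(self):
        expr, clinical = self._cohort(planted_fold=1.0)
        result = differential_expression(expr, clinical)
        table = result.table.set_index("feature")
        assert abs(table.loc["G00", "effect"]) < 1.0 or table.loc["G00", "p"] > 0.005

    def test_pseudocount_fold_change_formula(self):
        """Normalized means 8 (R) vs 0 (NR) -> log2FC = log2(9)."""
        n = 6
        data = pd.DataFrame(
            {f"s{i}": [8.0 if i < 3 else 0.0, 100.0, 50.0] for i in range(n)},
            index=["TARGET", "REF1", "REF2"],
        )
        expr = ik.ExpressionMatrix(data, "counts")
        clinical = _clinical(3, 3)
        result = differential_expression(expr, clinical, top_k=None)
        lfc = result.table.set_index("feature").loc["TARGET", "effect"]
        assert lfc == pytest.approx(np.log2(9.0))

    def test_small_group_rejected(self):
        expr, _ = self._cohort()
        with pytest.raises(ValidationError):
            differential_expression(expr, _clinical(2, 58))


class TestScreenGeneCandidates:
    def test_planted_genes_recovered_exactly(self):
        """With 7 strongly shifted genes out of 50, exactly those pass p<0.05."""
        rng = np.random.default_rng(8)
        n_r, n_nr = 25, 25
        clinical = _clinical(n_r, n_nr)
        n_genes = 50
        vals = rng.normal(100, 5, size=(n_genes, n_r + n_nr))
        planted = [f"G{i:02d}" for i in range(7)]
        vals[:7, :n_r] += 60
        frame = pd.DataFrame(vals, index=[f"G{i:02d}" for i in range(n_genes)],
                             columns=clinical.sample_ids)
        expr = ik.ExpressionMatrix(frame, "normalized")
        result = screen_gene_candidates(expr, clinical, list(frame.index), top_k=None)
        strong = result.selected[result.selected["p"] < 1e-6]
        assert sorted(strong["feature"]) == planted

    def test_constant_gene_never_selected(self):
        clinical = _clinical(5, 5)
        frame = pd.DataFrame(
            {s: [7.0, i] for i, s in enumerate(clinical.sample_ids)},
            index=["CONST", "VARY"],
        ).T.T
        expr = ik.ExpressionMatrix(frame, "normalized")
        result = screen_gene_candidates(expr, clinical, ["CONST", "VARY"], top_k=None)
        table = result.table.set_index("feature")
        assert table.loc["CONST", "p"] == pytest.approx(1.0)
        assert "CONST" not in result.selected_features

    def test_all_missing_rejected(self, toy_expression, clinical_rnr):
        with pytest.raises(ValidationError):
            screen_gene_candidates(toy_expression, clinical_rnr, ["nope1", "nope2"])


class TestPseudogeneFilter:
    def test_biotype_removal_preserves_order(self):
        table = {"B": "processed_pseudogene"}
        assert filter_pseudogenes(["A", "B", "C"], table) == ["A", "C"]

    def test_empty_table_passthrough(self):
        assert filter_pseudogenes(["A", "B"], None) == ["A", "B"]
        assert filter_pseudogenes(["A", "B"], {}) == ["A", "B"]

    def test_all_pseudogenes_empty_result(self):
        table = {"A": "unprocessed_pseudogene", "B": "pseudogene"}
        assert filter_pseudogenes(["A", "B"], table) == []


def test_screen_invariant_to_column_permutation_and_monotone_transform(
    default_cohort, default_library
):
    """Rank-based screens ignore sample order and per-gene monotone rescaling."""
    expr, clinical, _ = default_cohort
    genes = expr.gene_ids[:30]
    base = screen_gene_candidates(expr, clinical, genes, top_k=None)

    perm = list(np.random.default_rng(4).permutation(expr.sample_ids))
    permuted = ik.ExpressionMatrix(expr.data[perm], "counts")
    again = screen_gene_candidates(permuted, clinical, genes, top_k=None)
    pd.testing.assert_frame_equal(base.table, again.table)

    scaled = ik.ExpressionMatrix(np.sqrt(expr.data * 3.0), "normalized")
    third = screen_gene_candidates(scaled, clinical, genes, top_k=None)
    assert third.table["p"].tolist() == pytest.approx(base.table["p"].tolist())


def test_null_screen_false_positive_rate_calibrated():
    """Over 2000 null features, ~5% reach p<0.05 (binomial 3-sigma band)."""
    rng = np.random.default_rng(909)
    clinical = _clinical(48, 72)
    frame = pd.DataFrame(rng.normal(size=(2000, 120)),
                         index=[f"F{i:04d}" for i in range(2000)],
                         columns=clinical.sample_ids)
    result = screen_signatures(_score_matrix_from(frame), clinical, top_k=None)
    rate = (result.table["p"] < 0.05).mean()
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)
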