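"""Co-IP enrichment: normalisation, NB testing, BH, classification, regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1quant import synthetic_data as sd
from l1quant.rip_enrichment import (
    association_regression,
    bh_adjust,
    classify_bound,
    collapse_repeats,
    nb_wald_test,
    size_factors,
)


class TestSizeFactors:
    def test_identical_columns_are_unit(self):
        x = np.tile(np.arange(1, 6)[:, None], (1, 2))
        assert size_factors(x) == pytest.approx([1.0, 1.0])

    def test_doubled_column_splits_geometrically(self):
        a = np.arange(1, 11, dtype=float)
        x = np.column_stack([a, 2 * a])
        assert size_factors(x) == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample_is_unit(self):
        assert size_factors(np.array([3, 0, 9])) == pytest.approx([1.0])

    def test_no_common_feature_errors(self):
        x = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(x)


def _bh_oracle(p):
    """Step-up BH by definition: sort, scale by m/rank, enforce monotone."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return np.minimum(adj, 1.0)


class TestBhAdjust:
    def test_textbook_vector(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_values_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(_bh_oracle(p))


class TestNbWaldTest:
    def test_identical_groups_are_null(self):
        x = np.tile([[10, 12, 11], [100, 90, 95]], (1, 1))
        res = nb_wald_test(x, x, np.ones(3), np.ones(3))
        assert res.log2_fold_change == pytest.approx([0, 0], abs=1e-12)
        assert (res.p_value >= 0.9).all()

    def test_all_zero_feature_flagged_untested(self):
        a = np.array([[0, 0, 0], [5, 6, 7]])
        b = np.array([[0, 0, 0], [5, 6, 7]])
        res = nb_wald_test(a, b, np.ones(3), np.ones(3))
        assert not res.tested[0]
        assert res.p_value[0] == 1.0 and res.log2_fold_change[0] == 0.0

    def test_simulated_fold_recovered(self):
        counts, _, _, truth = sd.simulate_counts(seed=1)
        ip = [c for c in counts.columns if c.startswith("IP")]
        ref = [c for c in counts.columns if c.startswith("INPUT")]
        sf = size_factors(counts)
        cols = list(counts.columns)
        res = nb_wald_test(
            counts[ip].to_numpy(), counts[ref].to_numpy(),
            sf[[cols.index(s) for s in ip]], sf[[cols.index(s) for s in ref]],
        )
        bound = truth["entity_class"].eq("bound_mrna").to_numpy()
        assert 1.7 <= np.median(res.log2_fold_change[bound]) <= 2.3


class TestClassifyBound:
    def _frame(self, bo, input_, total):
        return pd.DataFrame(
            {
                "lfc_bo": [bo[0]], "padj_bo": [bo[1]],
                "lfc_input": [input_[0]], "padj_input": [input_[1]],
                "lfc_total": [total[0]], "padj_total": [total[1]],
            }
        )

    @pytest.mark.parametrize(
        "bo, input_, total, expected",
        [
            ((2, 0.001), (2, 0.001), (1.5, 0.01), "bound_enriched"),
            ((2, 0.001), (2, 0.001), (-2, 0.001), "bound_depleted"),
            ((0.5, 0.001), (3, 0.001), (3, 0.001), "unbound"),
            ((2, 0.001), (2, 0.001), (0.2, 0.5), "bound_not_enriched"),
        ],
    )
    def test_rule_application(self, bo, input_, total, expected):
        cat = classify_bound(self._frame(bo, input_, total))
        assert cat.iloc[0] == expected

    def test_missing_contrast_errors(self):
        with pytest.raises(ValueError, match="contrast"):
            classify_bound(pd.DataFrame({"lfc_bo": [1.0]}))


class TestCollapseRepeats:
    def test_subfamily_additivity_and_gene_passthrough(self):
        counts = pd.DataFrame(
            {"s1": [3, 4, 10], "s2": [1, 2, 5]},
            index=pd.Index(["L1MdA_1", "L1MdA_2", "Actb"], name="feature_id"),
        )
        fc = pd.Series(["repeat_locus", "repeat_locus", "gene"], index=counts.index)
        sub = pd.Series(["L1MdA", "L1MdA", ""], index=counts.index)
        out = collapse_repeats(counts, fc, sub)
        assert out.loc["L1MdA"].tolist() == [7, 3]
        assert out.loc["Actb"].tolist() == [10, 5]

    def test_no_repeats_is_identity(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=pd.Index(["a", "b"], name="feature_id"))
        fc = pd.Series(["gene", "gene"], index=counts.index)
        out = collapse_repeats(counts, fc, pd.Series(["", ""], index=counts.index))
        pd.testing.assert_frame_equal(out, counts)

    def test_unmapped_locus_errors(self):
        counts = pd.DataFrame({"s1": [1]}, index=pd.Index(["rep1"], name="feature_id"))
        fc = pd.Series(["repeat_locus"], index=counts.index)
        with pytest.raises(ValueError, match="rep1"):
            collapse_repeats(counts, fc, pd.Series([""], index=counts.index))

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=30)
    def test_column_sums_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 20))
        counts = pd.DataFrame(
            rng.integers(0, 100, size=(n, 3)),
            index=pd.Index([f"f{i}" for i in range(n)], name="feature_id"),
            columns=["a", "b", "c"],
        )
        is_rep = rng.random(n) < 0.5
        fc = pd.Series(np.where(is_rep, "repeat_locus", "gene"), index=counts.index)
        sub = pd.Series(
            np.where(is_rep, rng.choice(["X", "Y", "Z"], n), ""), index=counts.index
        )
        out = collapse_repeats(counts, fc, sub)
        assert out.sum().tolist() == counts.sum().tolist()


class TestAssociationRegression:
    def test_perfect_line(self):
        x = np.arange(10.0)
        fit = association_regression(x, x)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_independent_variables_have_no_association(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert association_regression(x, y).r_squared < 0.01

    def test_two_points_warn_degenerate(self):
        with pytest.warns(UserWarning, match="two-point"):
            fit = association_regression([0.0, 1.0], [3.0, 5.0])
        assert fit.r_squared == pytest.approx(1.0)

    def test_zero_x_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            association_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_expression_drives_binding_in_simulation(self):
        """IP abundance of bound mRNAs tracks their expression level, the
        dominant association the co-IP data show."""
        counts, _, _, truth = sd.simulate_counts(seed=3)
        bound = truth["entity_class"].eq("bound_mrna").to_numpy()
        ip = counts[[c for c in counts.columns if c.startswith("IP")]].mean(axis=1)
        total = counts[[c for c in counts.columns if c.startswith("TOTAL")]].mean(axis=1)
        fit = association_regression(
            np.log2(total[bound] + 0.5), np.log2(ip[bound] + 0.5)
        )
        assert fit.r_squared > 0.8
        assert fit.p_value < 1e-10
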