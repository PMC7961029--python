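"""QC filters, region correlation/merging, and cohort statistics."""
import numpy as np
import pandas as pd
import pytest

import braintx as bt
from braintx import preprocess as pp


def _meta_one_region(samples):
    return pd.DataFrame(
        {
            "subject": [f"s{i}" for i in range(len(samples))],
            "region": "r1",
            "diagnosis": "case",
        },
        index=samples,
    )


class TestCpm:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([10, 90], [1e5, 9e5]),
            ([1, 1, 2], [2.5e5, 2.5e5, 5e5]),
        ],
    )
    def test_hand_examples(self, column, expected):
        counts = pd.DataFrame({"s1": column}, index=[f"g{i}" for i in range(len(column))])
        np.testing.assert_allclose(pp.cpm(counts)["s1"], expected)

    def test_columns_sum_to_million_and_zero_rows_stay_zero(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 100, (30, 4)))
        counts.iloc[5] = 0
        out = pp.cpm(counts)
        np.testing.assert_allclose(out.sum(axis=0), 1e6)
        assert (out.iloc[5] == 0).all()

    def test_preserves_within_sample_rank_order(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 1000, (50, 3)))
        out = pp.cpm(counts)
        for c in counts.columns:
            assert (out[c].rank() == counts[c].rank()).all()

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            pp.cpm(counts)


class TestFilterExpressed:
    def test_half_of_region_passes(self):
        cpm_mat = pd.DataFrame([[1.2, 0.5, 3.0, 0.9]], index=["g1"], columns=list("abcd"))
        meta = _meta_one_region(list("abcd"))
        assert pp.filter_expressed(cpm_mat, meta) == ["g1"]

    def test_all_zero_gene_dropped(self):
        cpm_mat = pd.DataFrame(
            [[0, 0, 0, 0], [2, 2, 2, 2]], index=["dead", "alive"], columns=list("abcd")
        )
        meta = _meta_one_region(list("abcd"))
        assert pp.filter_expressed(cpm_mat, meta) == ["alive"]

    def test_single_passing_region_suffices(self):
        # fails in region A (1/4 >= 1 CPM) but passes in region B (3/4)
        cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        vals = [[2.0, 0.1, 0.2, 0.3, 1.5, 1.5, 1.5, 0.2]]
        cpm_mat = pd.DataFrame(vals, index=["g1"], columns=cols)
        meta = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(8)],
                "region": ["A"] * 4 + ["B"] * 4,
                "diagnosis": "case",
            },
            index=cols,
        )
        assert pp.filter_expressed(cpm_mat, meta) == ["g1"]

    def test_ceiling_at_odd_region_size(self):
        # 3 samples: "at least half" means >= 2
        cpm_mat = pd.DataFrame([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0]], columns=list("abc"))
        meta = _meta_one_region(list("abc"))
        assert pp.filter_expressed(cpm_mat, meta) == [0]

    def test_idempotent_and_order_independent(self, small_study):
        _, counts, meta, _ = small_study
        cpm_mat = pp.cpm(counts)
        kept = pp.filter_expressed(cpm_mat, meta)
        again = pp.filter_expressed(cpm_mat.loc[kept], meta)
        assert again == kept
        shuffled = cpm_mat.sample(frac=1.0, random_state=0)
        assert sorted(pp.filter_expressed(shuffled, meta)) == sorted(kept)


class TestFilterCV:
    @staticmethod
    def _matrix_with_cvs(cvs, mean=100.0):
        # base pattern with exact mean 0 and sd 1 (ddof=1) over 4 samples
        base = np.array([-1.5, -0.5, 0.5, 1.5])
        base = base / base.std(ddof=1)
        rows = [mean * (1.0 + cv * base) for cv in cvs]
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(cvs))])

    def test_outlier_gene_removed(self):
        """100 genes at CV=0.1 and one at CV=10: the cutoff lands ~3.15
        and removes exactly the outlier."""
        expr = self._matrix_with_cvs([0.1] * 100 + [10.0])
        kept = pp.filter_cv(expr)
        assert "g100" not in kept
        assert len(kept) == 100

    def test_identical_cvs_all_retained(self):
        expr = self._matrix_with_cvs([0.2] * 10)
        assert len(pp.filter_cv(expr)) == 10

    def test_single_gene_retained(self):
        expr = self._matrix_with_cvs([0.3])
        assert pp.filter_cv(expr) == ["g0"]

    def test_zero_mean_gene_excluded_with_warning(self):
        expr = self._matrix_with_cvs([0.1, 0.1])
        expr.loc["g0"] = 0.0
        with pytest.warns(UserWarning, match="zero mean"):
            kept = pp.filter_cv(expr)
        assert kept == ["g1"]

    def test_order_independent(self, small_study):
        _, counts, _, _ = small_study
        cpm_mat = pp.cpm(counts)
        kept = pp.filter_cv(cpm_mat)
        shuffled = pp.filter_cv(cpm_mat.sample(frac=1.0, random_state=1))
        assert sorted(shuffled) == sorted(kept)


class TestConsensusCorrelation:
    @staticmethod
    def _two_region_data(n_genes=2000, n_subj=6, seed=0, permute=False):
        rng = np.random.default_rng(seed)
        cols, meta_rows = {}, []
        for i in range(n_subj):
            x = rng.lognormal(3, 1, n_genes)
            cols[f"s{i}_A"] = x
            y = rng.permutation(x) if permute else x
            cols[f"s{i}_B"] = y
            for r in "AB":
                meta_rows.append(
                    {"sample": f"s{i}_{r}", "subject": f"s{i}", "region": r, "diagnosis": "case"}
                )
        return pd.DataFrame(cols), pd.DataFrame(meta_rows).set_index("sample")

    def test_identical_regions_give_one(self):
        expr, meta = self._two_region_data()
        assert pp.consensus_correlation(expr, meta, "A", "B") == pytest.approx(1.0)

    def test_permuted_region_gives_near_zero(self):
        expr, meta = self._two_region_data(permute=True)
        assert abs(pp.consensus_correlation(expr, meta, "A", "B")) < 0.1

    def test_requires_two_shared_subjects(self):
        expr, meta = self._two_region_data(n_subj=1)
        with pytest.raises(ValueError, match="fewer than 2"):
            pp.consensus_correlation(expr, meta, "A", "B")


class TestMergeRegions:
    @staticmethod
    def _dataset():
        meta = pd.DataFrame(
            {
                "subject": ["s1", "s1", "s2", "s2", "s3", "s1"],
                "region": ["A", "B", "A", "B", "A", "C"],
                "diagnosis": "case",
            },
            index=["s1_A", "s1_B", "s2_A", "s2_B", "s3_A", "s1_C"],
        )
        expr = pd.DataFrame(
            {"s1_A": [2.0], "s1_B": [4.0], "s2_A": [1.0], "s2_B": [5.0], "s3_A": [7.0], "s1_C": [9.0]},
            index=["g1"],
        )
        return expr, meta

    def test_mean_of_two_regions(self):
        expr, meta = self._dataset()
        out, out_meta = pp.merge_regions(expr, meta, ["A", "B"], "AB")
        assert out.loc["g1", "s1_AB"] == 3.0
        assert out.loc["g1", "s2_AB"] == 3.0

    def test_single_region_passes_through(self):
        expr, meta = self._dataset()
        out, _ = pp.merge_regions(expr, meta, ["A", "B"], "AB")
        assert out.loc["g1", "s3_AB"] == 7.0  # s3 has region A only

    def test_cardinality_and_metadata(self):
        expr, meta = self._dataset()
        out, out_meta = pp.merge_regions(expr, meta, ["A", "B"], "AB")
        assert sorted(out.columns) == ["s1_AB", "s1_C", "s2_AB", "s3_AB"]
        assert (out_meta.loc[["s1_AB", "s2_AB", "s3_AB"], "region"] == "AB").all()
        assert out_meta.loc["s1_C", "region"] == "C"
        assert list(out_meta.index) == list(out.columns)


class TestCohortTable:
    def test_summary_pooled_t_hand_example(self):
        res = pp.pooled_two_sample_t(10, 1, 2, 12, 1, 2)
        assert res.t == pytest.approx(-2.0)
        assert res.df == 2

    def test_matched_cohort_summaries(self):
        """Age summaries of a 7-vs-8 matched cohort: t=0.03, p=0.98, df=13."""
        res = pp.pooled_two_sample_t(47.4, 14.7, 7, 47.6, 13.4, 8)
        assert res.df == 13
        assert round(abs(res.t), 2) == 0.03
        assert round(res.p, 2) == 0.98

    def test_identical_groups(self, two_group_meta):
        meta = two_group_meta.copy()
        meta[["age", "PMI", "pH", "RIN"]] = 1.0
        tab = pp.cohort_table(meta)
        assert (tab["t"] == 0).all()
        assert (tab["p"] == 1).all()

    def test_raw_equals_summary_computation(self, two_group_meta):
        tab = pp.cohort_table(two_group_meta)
        case = two_group_meta[two_group_meta["diagnosis"] == "case"]
        comp = two_group_meta[two_group_meta["diagnosis"] != "case"]
        res = pp.pooled_two_sample_t(
            case["age"].mean(), case["age"].std(ddof=1), len(case),
            comp["age"].mean(), comp["age"].std(ddof=1), len(comp),
        )
        assert tab.loc["age", "t"] == pytest.approx(abs(res.t), abs=1e-12)
        assert tab.loc["age", "df"] == len(two_group_meta) - 2

    def test_small_group_rejected(self, two_group_meta):
        meta = two_group_meta[two_group_meta["subject"] != "s00"]
        meta = meta[~meta["subject"].isin([f"s{i:02d}" for i in range(1, 5)])]
        with pytest.raises(ValueError, match="at least 2"):
            pp.cohort_table(meta)
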