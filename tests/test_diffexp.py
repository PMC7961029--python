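"""Differential-expression model: oracles, calibration, BH, classification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import braintx as bt
from braintx import diffexp as de


class TestNormalizeLog:
    def test_cpm_values(self):
        counts = pd.DataFrame({"s1": [0, 3, 997_997 * 0 + 999_997]}, index=list("abc"))
        # library total 1e6 after scaling: use explicit counts summing nicely
        counts = pd.DataFrame({"s1": [0, 3_000_000, 997_000_000]}, index=list("abc"))
        out = de.normalize_log(counts, prior=1.0)
        assert out.loc["a", "s1"] == 0.0
        assert out.loc["b", "s1"] == pytest.approx(np.log2(3000 + 1))

    def test_prior_must_be_positive(self):
        with pytest.raises(ValueError, match="prior"):
            de.normalize_log(pd.DataFrame({"s": [1]}), prior=0.0)

    def test_monotone_in_counts(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"s": rng.integers(0, 10_000, 200)})
        out = de.normalize_log(counts)
        assert (out["s"].rank() == counts["s"].rank()).all()


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(de.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(de.bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de.bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            de.bh_fdr([-0.1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_dominates_p_and_is_permutation_equivariant(self, pvals):
        p = np.array(pvals)
        q = de.bh_fdr(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(de.bh_fdr(p[perm]), q[perm])


def _one_region_dataset(n_genes=40, n_per_group=8, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(2 * n_per_group)]
    meta = pd.DataFrame(
        {
            "subject": samples,
            "region": "r1",
            "diagnosis": ["case"] * n_per_group + ["comparison"] * n_per_group,
        },
        index=samples,
    )
    expr = pd.DataFrame(
        rng.normal(8.0, 1.0, (n_genes, len(samples))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=samples,
    )
    expr.iloc[:, :n_per_group] += effect
    return expr, meta


class TestFitGlobal:
    def test_single_gene_matches_pooled_t(self):
        """With diagnosis as the only term, OLS reduces to the two-sample
        pooled t-test: same effect, same p."""
        expr, meta = _one_region_dataset(n_genes=5, effect=0.7, seed=1)
        spec = de.ModelSpec(fixed=("diagnosis",), candidates=())
        res = de.fit_global(expr, meta, spec)
        case_cols = meta.index[meta["diagnosis"] == "case"]
        comp_cols = meta.index[meta["diagnosis"] == "comparison"]
        for g in expr.index:
            x, y = expr.loc[g, case_cols], expr.loc[g, comp_cols]
            t, p = stats.ttest_ind(x, y, equal_var=True)
            assert res.loc[g, "log2fc"] == pytest.approx(x.mean() - y.mean(), abs=1e-10)
            assert res.loc[g, "p"] == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels_with_covariates(self, small_study):
        import statsmodels.api as sm

        _, counts, meta, _ = small_study
        expr = de.normalize_log(counts).iloc[:5]
        spec = de.ModelSpec(fixed=("diagnosis", "sex", "pH"), candidates=())
        res = de.fit_global(expr, meta, spec)
        X = de._design(meta, spec.fixed, include_region=True)
        for g in expr.index:
            fit = sm.OLS(expr.loc[g].to_numpy(), X.to_numpy()).fit()
            j = list(X.columns).index("diagnosis")
            assert res.loc[g, "log2fc"] == pytest.approx(fit.params[j], abs=1e-8)
            assert res.loc[g, "p"] == pytest.approx(fit.pvalues[j], abs=1e-8)

    def test_shift_invariance_of_effect(self):
        expr, meta = _one_region_dataset(n_genes=10, seed=2)
        spec = de.ModelSpec(fixed=("diagnosis",), candidates=())
        res1 = de.fit_global(expr, meta, spec)
        res2 = de.fit_global(expr + 57.0, meta, spec)
        np.testing.assert_allclose(res1["log2fc"], res2["log2fc"], atol=1e-10)

    def test_type_one_error_calibrated(self, null_independent_study):
        _, counts, meta, _ = null_independent_study
        res = de.fit_global(de.normalize_log(counts), meta, de.ModelSpec())
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.07

    def test_planted_effect_recovered(self, small_study):
        _, counts, meta, truth = small_study
        res = de.fit_global(de.normalize_log(counts), meta, de.ModelSpec())
        signed = [
            res.loc[g, "log2fc"] * np.sign(e) for g, e in truth.de_genes["global"].items()
        ]
        assert 0.85 <= np.mean(signed) <= 1.15

    def test_rank_deficient_design_rejected(self):
        expr, meta = _one_region_dataset(n_genes=3)
        meta["dup"] = (meta["diagnosis"] == "case").astype(float)
        spec = de.ModelSpec(fixed=("diagnosis", "dup"), candidates=())
        with pytest.raises(ValueError, match="rank"):
            de.fit_global(expr, meta, spec)


class TestFitRegional:
    def test_single_region_equals_global_without_region_term(self):
        expr, meta = _one_region_dataset(n_genes=30, effect=0.4, seed=3)
        spec = de.ModelSpec(fixed=("diagnosis",), candidates=())
        reg = de.fit_regional(expr, meta, spec)["r1"]
        glob = de.fit_global(expr, meta, spec)
        np.testing.assert_allclose(reg["log2fc"], glob["log2fc"], atol=1e-10)
        np.testing.assert_allclose(reg["p"], glob["p"], atol=1e-10)

    def test_planted_region_is_the_significant_one(self):
        cfg = bt.StudyConfig(
            n_genes=1000,
            n_de_global=0,
            n_de_regional={"caudate": 40},
            de_log2fc=2.0,
            cortical_corr=0.0,
            between_region_corr=0.0,
            seed=21,
        )
        counts, meta, truth = bt.generate_study(cfg)
        res = de.fit_regional(de.normalize_log(counts), meta, de.ModelSpec())
        n_sig = {r: int((df["q"] < 0.05).sum()) for r, df in res.items()}
        assert n_sig["caudate"] >= 20
        assert all(n_sig[r] <= 2 for r in n_sig if r != "caudate")

    def test_permuted_labels_yield_no_discoveries(self, null_independent_study):
        """Label permutation at the subject level: BH keeps the family-wise
        null rejection rate near alpha, so most permutations find nothing."""
        _, counts, meta, _ = null_independent_study
        expr = de.normalize_log(counts.iloc[:400])
        sub = meta[meta["region"] == "caudate"]
        expr_sub = expr[sub.index]
        rng = np.random.default_rng(0)
        clean = 0
        spec = de.ModelSpec(fixed=("diagnosis", "sex", "pH"), candidates=())
        for _ in range(50):
            perm = sub.copy()
            perm["diagnosis"] = rng.permutation(perm["diagnosis"].to_numpy())
            res = de.fit_regional(expr_sub, perm, spec)["caudate"]
            clean += int((res["q"] < 0.05).sum() == 0)
        assert clean >= 45

    def test_too_few_samples_rejected(self):
        expr, meta = _one_region_dataset(n_genes=3, n_per_group=1)
        spec = de.ModelSpec(fixed=("diagnosis",), candidates=())
        with pytest.raises(ValueError):
            de.fit_regional(expr, meta, spec)


class TestSelectModel:
    def test_planted_covariate_retained(self, small_study):
        """pH carries planted per-gene effects, so the PC screen keeps it
        when offered as a candidate."""
        _, counts, meta, _ = small_study
        expr = de.normalize_log(counts)
        spec = de.ModelSpec(fixed=("diagnosis", "sex"), candidates=("pH",))
        out = de.select_model(expr, meta, spec)
        assert "pH" in out.fixed
        assert out.candidates == ()

    def test_noise_candidate_usually_dropped(self, small_study):
        _, counts, meta, _ = small_study
        expr = de.normalize_log(counts)
        rng = np.random.default_rng(0)
        dropped = 0
        for _ in range(100):
            m = meta.copy()
            m["noise"] = rng.normal(size=len(m))
            out = de.select_model(expr, m, de.ModelSpec(fixed=("diagnosis",), candidates=("noise",)))
            dropped += int("noise" not in out.fixed)
        assert dropped >= 95

    def test_empty_candidates_returns_spec_unchanged(self, small_study):
        _, counts, meta, _ = small_study
        spec = de.ModelSpec(fixed=("diagnosis", "sex", "pH"), candidates=())
        assert de.select_model(de.normalize_log(counts), meta, spec) is spec

    def test_collinear_pair_rejected(self, small_study):
        _, counts, meta, _ = small_study
        m = meta.copy()
        m["pH2"] = m["pH"]
        spec = de.ModelSpec(fixed=("diagnosis", "pH", "pH2"), candidates=("age",))
        with pytest.raises(ValueError, match="[cC]ollinear|ill-conditioned"):
            de.select_model(de.normalize_log(counts), m, spec)


class TestClassifyAndOverlap:
    @staticmethod
    def _results():
        a = pd.DataFrame(
            {"log2fc": [0.3, -0.1, 0.5], "q": [0.04, 0.2, 0.01]}, index=["a", "b", "c"]
        )
        b = pd.DataFrame(
            {"log2fc": [-0.4, 0.9, 0.2], "q": [0.01, 0.03, 0.5]}, index=["b", "c", "d"]
        )
        return {"s1": a, "s2": b}

    def test_classification_rules(self):
        out = bt.classify_and_overlap(self._results(), alpha=0.05, fc_line=0.26)
        cls = out["classes"]["s1"]
        assert cls.loc["a", "cls"] == "up" and cls.loc["a", "beyond_fc"]
        assert cls.loc["b", "cls"] == "ns"
        assert cls.loc["c", "cls"] == "up"

    def test_intersection_counts(self):
        out = bt.classify_and_overlap(self._results(), alpha=0.05)
        # significant: s1 -> {a, c}; s2 -> {b, c}
        assert out["intersections"][("s1", "s2")] == 1
        assert out["venn_exclusive"][("s1",)] == 1

    def test_alpha_validated(self):
        with pytest.raises(ValueError, match="alpha"):
            bt.classify_and_overlap(self._results(), alpha=1.5)
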