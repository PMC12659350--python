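"""Differential abundance: filtering, imputation, models, BH, labels, priority."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cazlearn import (
    CD_RULES,
    IGG4_RULES,
    CountMatrix,
    bh_adjust,
    fit_gene_models,
    log_fold_change,
    percentile_rank,
    prevalence_filter,
    prioritize,
    run_differential_abundance,
    volcano_labels,
    zero_impute,
)
from cazlearn.diffabund import DiffAbundanceError, LabelClause, LabelRuleSet
from cazlearn.simulate import simulate_counts


def tiny_matrix(counts, n_disease=None):
    counts = pd.DataFrame(counts)
    counts.columns = [f"s{i}" for i in range(counts.shape[1])]
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    n_d = n_disease if n_disease is not None else counts.shape[1] // 2
    meta = pd.DataFrame(
        {"disease": [1] * n_d + [0] * (counts.shape[1] - n_d)},
        index=counts.columns,
    )
    return CountMatrix(counts=counts, metadata=meta)


class TestPrevalenceFilter:
    def test_strict_boundary(self):
        row_9 = [1.0] * 9 + [0.0] * 91
        row_10 = [1.0] * 10 + [0.0] * 90
        m = tiny_matrix([row_9, row_10])
        out = prevalence_filter(m)
        assert list(out.counts.index) == ["g1"]

    def test_all_zero_gene_removed(self):
        m = tiny_matrix([[0.0] * 10, [1.0] * 10])
        assert list(prevalence_filter(m).counts.index) == ["g1"]

    def test_planted_low_prevalence_counts(self):
        fx = simulate_counts(500, 25, 25, seed=42, frac_low_prevalence=0.12,
                             low_prevalence=0.05)
        out = prevalence_filter(fx.matrix)
        assert out.counts.shape[0] == 500 - int(fx.truth["low_prevalence"].sum()) == 440

    def test_invalid_threshold(self):
        with pytest.raises(DiffAbundanceError):
            prevalence_filter(tiny_matrix([[1.0] * 4]), min_prev=0.0)


class TestZeroImpute:
    def test_printed_rule(self):
        m = prevalence_filter(tiny_matrix([[0.0, 4.0, 8.0]]), min_prev=0.3)
        out = zero_impute(m)
        assert list(out.counts.iloc[0]) == [2.0, 4.0, 8.0]

    def test_rows_without_zeros_untouched(self):
        m = prevalence_filter(tiny_matrix([[3.0, 4.0, 8.0]]), min_prev=0.3)
        assert list(zero_impute(m).counts.iloc[0]) == [3.0, 4.0, 8.0]

    def test_matches_loop_oracle_on_sparse_matrix(self, rng):
        counts = rng.poisson(2.0, size=(50, 20)).astype(float)
        counts[0] += 1.0  # guarantee at least one nonzero per gene overall
        m = tiny_matrix(counts.T.T)
        filtered = prevalence_filter(m, min_prev=0.05)
        out = zero_impute(filtered)
        for g in filtered.counts.index:
            row = filtered.counts.loc[g].to_numpy()
            mn = min(v for v in row if v > 0)
            expected = [v if v > 0 else mn / 2 for v in row]
            assert list(out.counts.loc[g]) == expected

    def test_requires_filtered_input(self):
        with pytest.raises(DiffAbundanceError, match="prevalence-filtered"):
            zero_impute(tiny_matrix([[1.0, 0.0]]))


class TestLogFoldChange:
    def test_simple_ratio(self):
        m = zero_impute(prevalence_filter(
            tiny_matrix([[8.0, 8.0, 2.0, 2.0]], n_disease=2), min_prev=0.1))
        assert log_fold_change(m)["g0"] == pytest.approx(2.0)

    def test_identical_groups_zero(self):
        m = zero_impute(prevalence_filter(
            tiny_matrix([[5.0, 3.0, 5.0, 3.0]], n_disease=2), min_prev=0.1))
        assert log_fold_change(m)["g0"] == pytest.approx(0.0)

    def test_recovers_planted_effect(self):
        fx = simulate_counts(400, 40, 40, seed=7, frac_diff=0.25, log2fc=2.0)
        m = zero_impute(prevalence_filter(fx.matrix))
        logfc = log_fold_change(m)
        planted = fx.truth.index[fx.truth["is_diff"]]
        planted = [g for g in planted if g in logfc.index]
        assert np.mean(logfc[planted]) == pytest.approx(2.0, abs=0.3)

    def test_requires_imputed_input(self):
        with pytest.raises(DiffAbundanceError, match="imputed"):
            log_fold_change(prevalence_filter(tiny_matrix([[1.0, 2.0]])))


class TestFitGeneModels:
    def test_null_pvalues_uniform(self):
        # depth factors off: they are a nuisance shared across genes, which
        # correlates p-values and invalidates a pooled KS uniformity check
        fx = simulate_counts(2000, 30, 30, seed=101, frac_diff=0.0,
                             depth_log_sd=0.0)
        m = zero_impute(prevalence_filter(fx.matrix))
        res = fit_gene_models(m, covariates=["age", "cov1"])
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_collinear_design_rejected(self):
        fx = simulate_counts(10, 10, 10, seed=3)
        m = zero_impute(prevalence_filter(fx.matrix))
        m.metadata["dup"] = m.metadata["disease"]
        with pytest.raises(DiffAbundanceError, match="collinear"):
            fit_gene_models(m, covariates=["dup"])

    def test_missing_metadata_rejected(self):
        fx = simulate_counts(10, 10, 10, seed=3)
        m = zero_impute(prevalence_filter(fx.matrix))
        m.metadata.loc[m.metadata.index[0], "age"] = np.nan
        with pytest.raises(DiffAbundanceError, match="missing"):
            fit_gene_models(m, covariates=["age"])

    def test_power_on_planted_standardized_effect(self):
        # lognormal counts: planted shift = 1.5 within-gene SDs, n=40/group
        fx = simulate_counts(
            200, 40, 40, seed=11, frac_diff=1.0, log2fc=1.5,
            family="lognormal", noise_log2_sd=1.0, depth_log_sd=0.0,
        )
        m = zero_impute(prevalence_filter(fx.matrix))
        res = fit_gene_models(m)
        assert np.mean(res["p"] < 0.01) >= 0.9

    def test_unknown_covariate(self):
        fx = simulate_counts(5, 5, 5, seed=3)
        m = zero_impute(prevalence_filter(fx.matrix))
        with pytest.raises(DiffAbundanceError, match="covariate"):
            fit_gene_models(m, covariates=["bmi"])


def bh_oracle(pvals):
    """Literal step-up definition: q_(i) = min_{j >= i} p_(j) * n / j."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * n / j for j in range(rank, n + 1)), 1.0
        )
    return q


class TestBhAdjust:
    def test_textbook_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_matches_step_up_oracle(self, rng):
        p = rng.uniform(size=1000)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_sm)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DiffAbundanceError):
            bh_adjust([0.5, 1.5])


class TestVolcanoLabels:
    @pytest.mark.parametrize(
        "logfc,p,expected",
        [
            (0.5, 0.9, True),        # logFC > 0
            (-1.0, 1e-7, False),     # needs p < 1e-8 when logFC < 0
            (-1.0, 1e-9, True),
            (-5.0, 5e-4, True),      # logFC < -4.5 and p < 1e-3
            (-5.0, 5e-3, False),
        ],
    )
    def test_cd_preset(self, logfc, p, expected):
        df = pd.DataFrame({"logFC": [logfc], "p": [p]}, index=["g"])
        assert volcano_labels(df, CD_RULES)["g"] == expected

    @pytest.mark.parametrize(
        "logfc,p,expected",
        [
            (2.5, 1e-6, True),       # logFC > 2 and p < 1e-5
            (2.5, 1e-4, False),
            (3.5, 1e-3, True),       # logFC > 3 and p < 10^-2.5
            (-2.5, 1e-4, True),      # logFC < -2 and p < 10^-3.5
            (-2.5, 1e-3, False),
            (-4.0, 5e-3, True),      # logFC < -3.5 and p < 1e-2
        ],
    )
    def test_igg4_preset(self, logfc, p, expected):
        df = pd.DataFrame({"logFC": [logfc], "p": [p]}, index=["g"])
        assert volcano_labels(df, IGG4_RULES)["g"] == expected

    def test_custom_ruleset_disjunction(self):
        rules = LabelRuleSet(clauses=(LabelClause(logfc_gt=1.0),
                                      LabelClause(p_lt=1e-4)))
        df = pd.DataFrame({"logFC": [2.0, 0.0, 0.0], "p": [0.5, 1e-5, 0.5]},
                          index=["a", "b", "c"])
        assert list(volcano_labels(df, rules)) == [True, True, False]


class TestPrioritize:
    def test_extremes(self):
        df = pd.DataFrame({"logFC": [5.0, -5.0, 0.0]}, index=["top", "bottom", "mid"])
        prio = prioritize(df, {"top": 1.0, "bottom": 0.0})
        assert prio["top"] == pytest.approx(1.0)
        assert prio["bottom"] == pytest.approx(0.0)

    def test_matches_mean_of_ranks_oracle(self, rng):
        genes = [f"g{i}" for i in range(100)]
        logfc = pd.Series(rng.normal(size=100), index=genes)
        probs = {g: float(rng.uniform()) for g in genes[:60]}
        df = pd.DataFrame({"logFC": logfc})
        prio = prioritize(df, probs)
        # hand-computed oracle: average ranks, (rank-1)/(n-1), mean with prob
        ranks = stats.rankdata(logfc.to_numpy(), method="average")
        pct = (ranks - 1) / (len(genes) - 1)
        for g in probs:
            expected = (pct[genes.index(g)] + probs[g]) / 2
            assert prio[g] == pytest.approx(expected)
        assert list(prio) == sorted(prio, reverse=True)
        assert set(prio.index) == set(probs)

    def test_monotone_in_both_components(self):
        df = pd.DataFrame({"logFC": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        base = prioritize(df, {"a": 0.5})["a"]
        assert prioritize(df, {"a": 0.7})["a"] > base
        df_higher = pd.DataFrame({"logFC": [4.0, 2.0, 3.0]}, index=["a", "b", "c"])
        assert prioritize(df_higher, {"a": 0.5})["a"] > base

    def test_percentile_rank_tie_handling(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0])
        np.testing.assert_allclose(percentile_rank(s), [0.0, 0.5, 0.5, 1.0])


class TestFullPipeline:
    def test_end_to_end_with_priority(self):
        fx = simulate_counts(300, 30, 30, seed=17, frac_diff=0.2, log2fc=3.0,
                             frac_low_prevalence=0.1)
        probs = {g: 0.9 for g in fx.truth.index[fx.truth["is_diff"]]}
        res = run_differential_abundance(
            fx.matrix, covariates=["age", "cov1"], family_probability=probs
        )
        assert {"logFC", "estimate", "p", "q", "significant",
                "volcano_label", "priority"} <= set(res.columns)
        assert (res["q"] >= res["p"] - 1e-12).all()
        # planted up-regulated genes should dominate significant calls
        sig = res.index[res["significant"]]
        if len(sig) > 0:
            frac_planted = fx.truth.loc[sig, "is_diff"].mean()
            assert frac_planted > 0.5

    def test_stage_enforcement_out_of_order(self):
        fx = simulate_counts(20, 10, 10, seed=5)
        with pytest.raises(DiffAbundanceError):
            fit_gene_models(fx.matrix)
        with pytest.raises(DiffAbundanceError):
            log_fold_change(fx.matrix)
        with pytest.raises(DiffAbundanceError):
            zero_impute(fx.matrix)
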