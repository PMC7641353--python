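import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmtme import (
    PipelineConfig,
    ValidationError,
    bh_fdr,
    chisq_independence,
    cox_lasso,
    fisher_exact,
    km_restricted_mean,
    logrank_test,
    quartile_hazard_ratio,
    relapse_comparison,
    stepwise_cox,
    survival_tree,
    wilcoxon_de,
)
from mmtme.deconvolution import CellProportions
from mmtme.io_config import ClinicalRecord


class TestKmRestrictedMean:
    def test_single_subject_event_at_horizon(self):
        fit = km_restricted_mean([10.0], [True], horizon=10)
        assert fit.restricted_mean == pytest.approx(10.0)

    def test_three_uncensored_events_hand_integral(self):
        fit = km_restricted_mean([1.0, 2.0, 3.0], [1, 1, 1], horizon=3)
        assert fit.restricted_mean == pytest.approx(2.0)  # 1 + 2/3 + 1/3
        assert fit.n_events == 3

    def test_exponential_matches_closed_form(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, 5000)
        fit = km_restricted_mean(t, np.ones(5000, bool), horizon=20)
        closed = (1 - np.exp(-2)) / 0.1
        mc_se = np.std(np.minimum(t, 20)) / np.sqrt(5000)
        assert abs(fit.restricted_mean - closed) < 3 * mc_se

    def test_matches_survfit_reference_values(self):
        """Frozen oracle: R survival::survfit rmean and se(rmean)."""
        rng = np.random.default_rng(7)
        t = rng.exponential(24.0, 200)
        c = rng.exponential(30.0, 200)
        fit = km_restricted_mean(np.minimum(t, c), t <= c, horizon=36)
        assert fit.restricted_mean == pytest.approx(19.1059427945, abs=1e-6)
        assert fit.restricted_mean_se == pytest.approx(1.0175633838, abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_restricted_mean([], [])


def _manual_logrank(g1, g2):
    """Observed-minus-expected tabulation over event times (all events)."""
    times = sorted(set(g1) | set(g2))
    O = E = V = 0.0
    n1, n2 = len(g1), len(g2)
    for t in times:
        d1 = g1.count(t)
        d2 = g2.count(t)
        d, n = d1 + d2, n1 + n2
        if n <= 1:
            break
        O += d1
        E += d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
        n1 -= d1
        n2 -= d2
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_null(self):
        g = ([1.0, 2, 3], [True, True, True])
        out = logrank_test([g, g])
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_matches_hand_tabulation(self):
        g1, g2 = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        out = logrank_test([(g1, [1, 1, 1]), (g2, [1, 1, 1])])
        assert out["chi2"] == pytest.approx(_manual_logrank(g1, g2), rel=1e-10)
        assert out["df"] == 1

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        groups = [(rng.exponential(5, 30), rng.random(30) < 0.7) for _ in range(3)]
        a = logrank_test(groups)
        b = logrank_test(groups[::-1])
        assert a["chi2"] == pytest.approx(b["chi2"], rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([([1.0], [True])])


class TestQuartileHazardRatio:
    def test_binary_feature_passes_through(self):
        rng = np.random.default_rng(2)
        x = (rng.random(200) < 0.5).astype(float)
        t = rng.exponential(10 / (1 + x))
        e = np.ones(200, bool)
        m = quartile_hazard_ratio(x, t, e)
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"time": t, "event": 1, "high": x})
        ref = CoxPHFitter().fit(df, "time", "event")
        assert m.coefficients[0] == pytest.approx(ref.params_["high"], rel=1e-8)

    def test_planted_q4_vs_q1_effect_recovered(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.normal(size=n)
        q3 = np.quantile(x, 0.75)
        rate = 0.1 * np.exp(np.log(2.0) * (x > q3))
        t = rng.exponential(1 / rate)
        m = quartile_hazard_ratio(x, t, np.ones(n, bool))
        se = (m.ci_95[0, 1] - m.ci_95[0, 0]) / (2 * 1.96)
        assert abs(m.coefficients[0] - np.log(2.0)) < 2 * se

    def test_constant_feature_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            quartile_hazard_ratio(np.ones(30), np.arange(1.0, 31), np.ones(30, bool))


class TestCoxLasso:
    def _sim(self, seed=4, n=600, p_null=10):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, p_null + 1)),
            columns=["true"] + [f"null{i}" for i in range(p_null)],
        )
        rate = 0.05 * np.exp(1.0 * X["true"].to_numpy())
        t = rng.exponential(1 / rate)
        c = rng.exponential(30, n)
        return X, np.minimum(t, c), t <= c

    def test_huge_penalty_zeroes_everything(self):
        X, t, e = self._sim()
        m = cox_lasso(X, t, e, penalty=1e6)
        assert (m.coefficients == 0).all()

    def test_zero_penalty_matches_unpenalized_fit(self):
        X, t, e = self._sim(n=300, p_null=3)
        m0 = cox_lasso(X, t, e, penalty=0.0)
        m_small = cox_lasso(X, t, e, penalty=1e-6)
        np.testing.assert_allclose(m_small.coefficients, m0.coefficients, atol=1e-3)

    def test_true_covariate_retained_across_replicates(self):
        kept = 0
        for rep in range(10):
            X, t, e = self._sim(seed=100 + rep)
            m = cox_lasso(X, t, e, seed=rep)
            coefs = dict(zip(m.features, m.coefficients))
            kept += coefs["true"] != 0
        assert kept >= 9

    def test_too_few_events_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3]})
        with pytest.raises(ValidationError, match="events"):
            cox_lasso(X, [1.0, 2, 3], [True, False, False])


class TestStepwiseCox:
    def _sim(self, seed, n=800, effect=1.0, p_null=6):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n, p_null + 3)),
            columns=["strong"] + [f"null{i}" for i in range(p_null)] + ["age", "sex"],
        )
        X["sex"] = (X["sex"] > 0).astype(float)
        rate = 0.05 * np.exp(effect * X["strong"].to_numpy())
        t = rng.exponential(1 / rate)
        return X, t, np.ones(n, bool)

    def test_strong_covariate_selected_nulls_excluded(self):
        X, t, e = self._sim(5)
        m = stepwise_cox(X, t, e)
        assert "strong" in m.features
        assert not any(f.startswith("null") for f in m.features)

    def test_all_null_keeps_only_protected(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(400, 4)),
                         columns=["null0", "null1", "age", "sex"])
        t = rng.exponential(10, 400)
        m = stepwise_cox(X, t, np.ones(400, bool))
        assert set(m.features) <= {"age", "sex", "null0", "null1"}
        # seeded variable with p > removal threshold would be dropped unless protected
        assert "age" in m.features and "sex" in m.features

    def test_protected_variables_survive_any_p(self):
        X, t, e = self._sim(7)
        m = stepwise_cox(X, t, e, always_keep=("age", "sex"))
        assert "age" in m.features and "sex" in m.features


class TestSurvivalTree:
    def test_planted_binary_split_found_and_nulls_ignored(self):
        rng = np.random.default_rng(8)
        n = 500
        X = pd.DataFrame({
            "risk": (rng.random(n) < 0.4).astype(float),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        rate = 0.05 * np.exp(np.log(3.0) * X["risk"].to_numpy())
        t = rng.exponential(1 / rate)
        tree = survival_tree(X, t, np.ones(n, bool), alpha=0.01,
                             n_permutations=2000, seed=0)
        assert tree.root.split_feature == "risk"
        assert tree.root.permutation_p <= 0.01
        for child in (tree.root.left, tree.root.right):
            assert child.is_leaf or child.split_feature == "risk"

    def test_all_null_features_give_single_leaf(self):
        rng = np.random.default_rng(9)
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        tree = survival_tree(X, rng.exponential(10, n), np.ones(n, bool),
                             alpha=0.01, n_permutations=2000, seed=1)
        assert tree.root.is_leaf

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        n = 200
        X = pd.DataFrame({"x": rng.normal(size=n)})
        rate = 0.05 * np.exp(0.8 * (X["x"] > 0))
        t = rng.exponential(1 / rate)
        a = survival_tree(X, t, np.ones(n, bool), n_permutations=500, seed=3)
        b = survival_tree(X, t, np.ones(n, bool), n_permutations=500, seed=3)
        assert a.split_sequence() == b.split_sequence()
        assert (a.root.permutation_p is None) == (b.root.permutation_p is None)
        if a.root.permutation_p is not None:
            assert a.root.permutation_p == b.root.permutation_p

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValidationError):
            survival_tree(pd.DataFrame({"x": [1.0] * 40}), np.arange(1.0, 41),
                          np.ones(40, bool), alpha=1.5)


class TestWilcoxonDe:
    def test_identical_groups_nothing_passes(self):
        m = pd.DataFrame([[1.0, 2, 3, 1, 2, 3]] * 4,
                         columns=[f"s{i}" for i in range(6)])
        res = wilcoxon_de(m, ["a"] * 3 + ["b"] * 3)
        assert (res.table["p_value"] == 1.0).all()
        assert not res.table["passes"].any()

    def test_exact_rank_sum_p_for_separated_triples(self):
        m = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], columns=[f"s{i}" for i in range(6)])
        res = wilcoxon_de(m, ["a"] * 3 + ["b"] * 3)
        assert res.table["p_value"].iloc[0] == pytest.approx(0.1)  # 2/20 arrangements

    def test_fold_change_filter_gates_passing(self):
        rng = np.random.default_rng(11)
        n = 8
        lo = rng.uniform(9.5, 10.5, n)
        # strong rank separation in both features; only f1 clears |log2FC| > 0.66
        f1 = np.concatenate([lo * 1.9, lo])       # log2FC ~ 0.92
        f2 = np.concatenate([lo * 1.3, lo])       # log2FC ~ 0.38
        m = pd.DataFrame([f1, f2], index=["f1", "f2"],
                         columns=[f"s{i}" for i in range(2 * n)])
        res = wilcoxon_de(m, ["a"] * n + ["b"] * n, fc_filter=True,
                          fdr_threshold=0.05, abs_log2fc_threshold=0.66)
        assert res.table.loc["f1", "fdr"] <= 0.05
        assert res.table.loc["f2", "fdr"] <= 0.05
        assert bool(res.table.loc["f1", "passes"])
        assert not bool(res.table.loc["f2", "passes"])

    def test_paired_uses_signed_rank(self):
        rng = np.random.default_rng(12)
        base = rng.uniform(5, 10, 10)
        m = pd.DataFrame([np.concatenate([base + 1.0, base])],
                         columns=[f"s{i}" for i in range(20)])
        res = wilcoxon_de(m, ["a"] * 10 + ["b"] * 10, paired=True)
        from scipy.stats import wilcoxon

        assert res.table["p_value"].iloc[0] == pytest.approx(
            wilcoxon(base + 1.0, base).pvalue
        )

    def test_small_group_rejected(self):
        m = pd.DataFrame([[1.0, 2, 3, 4]], columns=list("wxyz"))
        with pytest.raises(ValidationError, match="n >= 3"):
            wilcoxon_de(m, ["a", "a", "b", "b"])


def _make_clin(sample_id, timepoint, offset=None, remission=None):
    return ClinicalRecord(
        patient_id=sample_id, sample_id=sample_id, timepoint=timepoint,
        pfs_months=10, pfs_event=True, os_months=20, os_event=False,
        relapse_date_offset_days=offset, complete_remission=remission,
    )


class TestRelapseComparison:
    def _setup(self, depleted=True, seed=13):
        rng = np.random.default_rng(seed)
        types = ["Mast.cells", "Monocytes", "Neutrophils", "B.cells"]
        rows, clin, idx = [], [], []
        for i in range(15):  # relapse-window samples
            sid = f"R{i}"
            comp = rng.dirichlet([5, 8, 15, 5])
            if depleted:
                comp[1] *= 0.3
                comp = comp / comp.sum()
            rows.append(comp * 100)
            idx.append(sid)
            clin.append(_make_clin(sid, "postinduction", offset=int(rng.integers(0, 180))))
        for i in range(30):  # remission samples
            sid = f"C{i}"
            rows.append(rng.dirichlet([5, 8, 15, 5]) * 100)
            idx.append(sid)
            clin.append(_make_clin(sid, "postmaintenance", remission=True))
        pct = pd.DataFrame(rows, index=idx, columns=types)
        props = CellProportions(pct.copy(), pct)
        return props, clin

    def test_window_boundaries(self):
        props, clin = self._setup()
        clin.append(_make_clin("far", "postinduction", offset=200))      # excluded
        clin.append(_make_clin("near", "postinduction", offset=100))     # included
        clin.append(_make_clin("base", "pretreatment", offset=100))      # baseline excluded
        pct = props.percentages
        for sid in ("far", "near", "base"):
            pct.loc[sid] = pct.iloc[0]
        props2 = CellProportions(pct.copy(), pct)
        res = relapse_comparison(props2, clin, PipelineConfig())
        # included window samples: 15 + "near" = 16 vs 30 remission + "far"? far has
        # offset outside the window and no remission flag, so it is dropped entirely
        assert res.table.shape[0] == 4

    def test_planted_depletion_flagged_at_fdr05(self):
        props, clin = self._setup(depleted=True)
        res = relapse_comparison(props, clin)
        assert bool(res.table.loc["Monocytes", "passes_fdr05"])

    def test_identical_distributions_pass_nothing(self):
        props, clin = self._setup(depleted=False)
        res = relapse_comparison(props, clin)
        assert not res.table["passes_fdr05"].any()

    def test_empty_window_rejected(self):
        props, clin = self._setup()
        clin = [c for c in clin if c.relapse_date_offset_days is None]
        with pytest.raises(ValidationError, match="empty"):
            relapse_comparison(props, clin)


class TestContingency:
    def test_equal_proportions_give_null(self):
        out = chisq_independence([[10, 20, 30], [20, 40, 60]])
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            m = rng.integers(1, 50, size=(3, 4)).astype(float)
            out = chisq_independence(m)
            exp = np.outer(m.sum(1), m.sum(0)) / m.sum()
            assert out["chi2"] == pytest.approx(((m - exp) ** 2 / exp).sum(), rel=1e-10)

    def test_low_expected_count_warning_flag(self):
        out = chisq_independence([[1, 2], [50, 60]])
        assert out["low_expected_warning"]

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            chisq_independence([[1.5, 2], [3, 4]])


class TestFisherExact:
    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]])["p_two_sided"] == pytest.approx(1.0)

    def test_hypergeometric_enumeration_value(self):
        assert fisher_exact([[3, 1], [1, 3]])["p_two_sided"] == pytest.approx(34 / 70)

    def test_non_2x2_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_uniform_ladder_collapses_to_max(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_hand_computed_pair(self):
        np.testing.assert_allclose(bh_fdr([0.001, 0.5]), [0.002, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_never_below_raw_and_capped(self, ps):
        adj = bh_fdr(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0).all()
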