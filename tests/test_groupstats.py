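"""ANCOVA, BH-FDR, Tukey-Kramer, one-way ANOVA and chi-square tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

import mddsubtypes as m
from mddsubtypes.groupstats import roi_results_to_frame


def ancova_f_oracle(y, groups, covariates):
    """Normal-equations least-squares oracle for the group F statistic."""
    y = np.asarray(y, dtype=float)
    names = sorted(set(groups))
    dummies = np.column_stack([
        (np.asarray(groups) == g).astype(float) for g in names[1:]
    ])
    x_red = np.column_stack([np.ones(len(y)), covariates])
    x_full = np.column_stack([x_red, dummies])

    def rss(x):
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        return float(resid @ resid)

    rss_full, rss_red = rss(x_full), rss(x_red)
    df_num = x_full.shape[1] - x_red.shape[1]
    df_den = len(y) - x_full.shape[1]
    return ((rss_red - rss_full) / df_num) / (rss_full / df_den)


def fdr_oracle(p):
    """Step-up definition: adj_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    mlen = p.size
    order = np.argsort(p, kind="stable")
    candidates = p[order] * mlen / np.arange(1, mlen + 1)
    out = np.empty(mlen)
    for i in range(mlen):
        out[order[i]] = min(1.0, candidates[i:].min())
    return out


def _roi_table(n_per_group=40, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.repeat(["SIA", "SDA", "MOD", "HC"], n_per_group)
    specs = ([m.RoiEffectSpec("anterior_insula_area", "SIA", effect)]
             if effect else None)
    return m.generate_roi_cohort(labels, specs, seed=int(rng.integers(2**31)))


class TestAncova:
    def test_identical_groups_f_near_zero(self):
        n = 40
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "group": np.repeat(["a", "b"], n // 2),
            "age": np.tile(np.linspace(15, 25, n // 2), 2),
            "sex": np.tile([0, 1], n // 2),
            "icv": np.tile(rng.normal(1.5e6, 1e5, n // 2), 2),
            "amygdala_volume": np.tile(rng.normal(1760, 100, n // 2), 2),
        })
        res = m.ancova_group_test(table, "amygdala_volume")
        assert res.F == pytest.approx(0.0, abs=1e-10)
        assert res.p_raw == pytest.approx(1.0)

    def test_thickness_excludes_icv(self):
        table = _roi_table(seed=1)
        thick = m.ancova_group_test(table, "anterior_insula_thickness")
        area = m.ancova_group_test(table, "anterior_insula_area")
        # one fewer covariate -> one more error df
        assert thick.df[1] == area.df[1] + 1
        # and the result is invariant to the ICV values entirely
        shuffled = table.copy()
        shuffled["icv"] = shuffled["icv"].sample(frac=1, random_state=0).values
        thick2 = m.ancova_group_test(shuffled, "anterior_insula_thickness")
        assert thick.F == pytest.approx(thick2.F, rel=1e-12)

    def test_matches_normal_equations_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 50
            table = pd.DataFrame({
                "group": rng.choice(["a", "b", "c"], n),
                "age": rng.uniform(15, 25, n),
                "sex": rng.integers(0, 2, n),
                "icv": rng.normal(1.5e6, 1e5, n),
                "hippocampus_volume": rng.normal(4500, 300, n),
            })
            res = m.ancova_group_test(table, "hippocampus_volume")
            oracle = ancova_f_oracle(
                table["hippocampus_volume"], table["group"],
                table[["age", "sex", "icv"]].to_numpy())
            assert res.F == pytest.approx(oracle, abs=1e-6, rel=1e-6)

    def test_planted_deficit_detected_with_fdr(self):
        table = _roi_table(n_per_group=60, effect=-40.0, seed=2)
        results = m.run_roi_analysis(table)
        by_name = {r.roi_name: r for r in results}
        hit = by_name["anterior_insula_area"]
        assert hit.p_fdr < 0.05
        assert hit.posthoc is not None
        assert min(p for (a, b), p in hit.posthoc.items()
                   if "SIA" in (a, b)) < 0.05

    def test_collinear_covariates_rejected(self):
        table = _roi_table(seed=3)
        table["icv"] = table["age"] * 1e5  # exact collinearity
        with pytest.raises(ValueError, match="collinear|condition"):
            m.ancova_group_test(table, "anterior_insula_area")

    def test_report_frame_shape(self):
        table = _roi_table(n_per_group=30, seed=4)
        frame = roi_results_to_frame(m.run_roi_analysis(table))
        assert len(frame) == 13
        assert {"roi", "F", "p_raw", "p_fdr"} <= set(frame.columns)
        assert (frame["p_fdr"] >= frame["p_raw"] - 1e-15).all()


class TestFdrBh:
    def test_all_equal_unchanged(self):
        assert np.allclose(m.fdr_bh([0.2, 0.2, 0.2]), 0.2)

    def test_step_up_hand_example(self):
        assert np.allclose(m.fdr_bh([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert m.fdr_bh([0.123])[0] == pytest.approx(0.123)

    def test_matches_definition_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 25))
            mine = m.fdr_bh(p)
            assert np.array_equal(mine, fdr_oracle(p))
            assert np.allclose(
                mine, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_order_invariance_and_dominates_raw(self, rng):
        p = rng.uniform(0, 1, 13)
        perm = rng.permutation(13)
        assert np.allclose(m.fdr_bh(p)[perm], m.fdr_bh(p[perm]))
        assert (m.fdr_bh(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.fdr_bh([0.5, 1.2])


class TestTukeyHsd:
    def test_identical_groups_p_near_one(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        groups = np.repeat(["a", "b"], 4)
        p = m.tukey_hsd(vals, groups)[("a", "b")]
        assert p > 0.99

    def test_separated_groups_tiny_p(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(50, 1, 20)])
        groups = np.repeat(["a", "b"], 20)
        assert m.tukey_hsd(vals, groups)[("a", "b")] < 0.001

    def test_matches_monte_carlo_range_oracle(self, rng):
        # three balanced groups, printed toy data; oracle simulates the
        # studentized range distribution directly
        vals = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 5.0, 8.0, 9.0, 7.0])
        groups = np.repeat(["a", "b", "c"], 3)
        res = m.tukey_hsd(vals, groups)
        k, n = 3, 9
        df = n - k
        mse = np.mean([np.var(vals[groups == g], ddof=1) for g in "abc"])
        sim = 200_000
        z = rng.normal(size=(sim, k))
        s2 = rng.chisquare(df, size=sim) / df
        qdist = (z.max(axis=1) - z.min(axis=1)) / np.sqrt(s2)
        for ga, gb in [("a", "b"), ("a", "c"), ("b", "c")]:
            diff = abs(vals[groups == ga].mean() - vals[groups == gb].mean())
            q = diff / np.sqrt(mse / 3)
            p_mc = (qdist >= q).mean()
            assert res[(ga, gb)] == pytest.approx(p_mc, abs=0.005)

    def test_unequal_n_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        vals = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.8, 1, 20),
                               rng.normal(1.6, 1, 7)])
        groups = np.repeat(["a", "b", "c"], [12, 20, 7])
        mine = m.tukey_hsd(vals, groups)
        sm_res = pairwise_tukeyhsd(vals, groups)
        for (pair, p_mine), p_sm in zip(sorted(mine.items()),
                                        sm_res.pvalues):
            assert p_mine == pytest.approx(p_sm, abs=1e-6)

    def test_covariate_adjusted_comparison(self):
        # strong covariate masks the group difference unless adjusted
        rng = np.random.default_rng(5)
        n = 60
        groups = np.repeat(["a", "b"], n // 2)
        age = rng.uniform(15, 25, n)
        y = 2.0 * age + np.where(groups == "b", 5.0, 0.0) + rng.normal(0, 1, n)
        adj = m.tukey_hsd(y, groups, adjust_for=pd.DataFrame({"age": age}))
        assert adj[("a", "b")] < 0.001

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            m.tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestOnewayAnova:
    def test_printed_severity_summary_stats(self):
        # group means 18.4/19.5/14.1, sds 2.7/2.4/2.8, ns 59/105/111
        res = m.oneway_anova(means=[18.4, 19.5, 14.1], sds=[2.7, 2.4, 2.8],
                             ns=[59, 105, 111])
        assert res.p < 0.001

    def test_constant_data_degenerate(self):
        res = m.oneway_anova([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
        assert res.degenerate

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        res = m.oneway_anova(np.concatenate([a, b]),
                             ["a"] * 15 + ["b"] * 12)
        t = stats.ttest_ind(a, b).statistic
        assert res.F == pytest.approx(t * t, rel=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        a, b, c = (rng.normal(m_, 1, 20) for m_ in (0.0, 0.4, 0.9))
        res = m.oneway_anova(np.concatenate([a, b, c]),
                             np.repeat(["a", "b", "c"], 20))
        ref = stats.f_oneway(a, b, c)
        assert res.F == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestChiSquare:
    # printed demographic contingency rows: (females per subtype, totals)
    @pytest.mark.parametrize("row,totals,expected_p", [
        ((43, 59, 59), (59, 105, 111), 0.04),   # sex
        ((1, 2, 3), (59, 105, 111), 0.89),      # anorexia nervosa
        ((2, 3, 2), (59, 105, 111), 0.80),      # bulimia nervosa
    ])
    def test_printed_rows_reproduce(self, row, totals, expected_p):
        observed = np.array([row, [t - r for r, t in zip(row, totals)]])
        res = m.chi_square_test(observed)
        # agreement at the printed two-decimal precision; the anorexia row
        # computes to 0.8850, exactly the rounding midpoint of the printed
        # 0.89, so the band is half a printed unit plus 10% slack
        assert abs(res.p - expected_p) <= 0.0055

    def test_expected_table_gives_zero(self):
        observed = np.array([[10.0, 20.0], [20.0, 40.0]])
        res = m.chi_square_test(observed)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            m.chi_square_test([[0, 0], [3, 4]])
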