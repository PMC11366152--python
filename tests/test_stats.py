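import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import ppcv
from ppcv.errors import InputError
from ppcv.stats import (cohen_kappa, fit_linear_model, gee_group_comparison,
                        icc_two_rater, lsd_vs_baseline, quartile_bins,
                        snk_test, studentized_range_quantile, two_sample_t)


def _pooled_t_oracle(a, b):
    """Textbook pooled-variance t statistic and two-sided P."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


class TestTwoSampleT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        res = two_sample_t(a, a)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_constant_equal_groups_convention(self):
        res = two_sample_t([5.0, 5.0], [5.0, 5.0])
        assert res.p_value == 1.0

    def test_large_separation_tiny_variance(self):
        a = np.array([1.0, 2.0, 3.0])
        res = two_sample_t(a, a + 1e3)
        assert res.p_value < 1e-6
        assert res.significant

    def test_matches_formula_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 2, size=rng.integers(3, 30))
            b = rng.normal(0.5, 1.5, size=rng.integers(3, 30))
            t, p = _pooled_t_oracle(a, b)
            res = two_sample_t(a, b)
            assert res.statistic == pytest.approx(t, rel=1e-10)
            assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            two_sample_t([1.0], [1.0, 2.0])


class TestSNK:
    def test_published_q_table_values(self):
        """Spot-check studentized-range quantiles against printed tables."""
        table = {(2, 10): 3.15, (3, 10): 3.88, (4, 10): 4.33, (5, 10): 4.65,
                 (2, 20): 2.95, (3, 20): 3.58, (4, 20): 3.96, (5, 20): 4.23,
                 (2, 60): 2.83, (3, 60): 3.40, (4, 60): 3.74, (5, 60): 3.98}
        for (r, df), q in table.items():
            assert studentized_range_quantile(0.05, r, df) == pytest.approx(q, abs=0.01)

    def test_identical_groups_single_subset(self):
        g = [np.array([1.0, 2.0, 3.0])] * 4
        res = snk_test(g, labels=list("abcd"))
        assert len(res.subsets) == 1
        assert res.subsets[0] == frozenset("abcd")
        assert not res.any_significant

    def test_two_groups_equivalent_to_t_test(self, rng):
        """For k = 2, q(α,2,df) = √2·t_crit, so the SNK decision matches
        the pooled t test exactly."""
        for _ in range(50):
            a = rng.normal(0, 1, size=8)
            b = rng.normal(rng.uniform(0, 1.5), 1, size=11)
            snk = snk_test([a, b], labels=["a", "b"], alpha=0.05)
            t = two_sample_t(a, b, alpha=0.05)
            assert snk.any_significant == t.significant

    def test_clearly_separated_groups(self, rng):
        groups = [rng.normal(mu, 0.1, size=10) for mu in (0.0, 5.0, 10.0)]
        res = snk_test(groups, labels=["lo", "mid", "hi"])
        assert res.subsets == (frozenset(["hi"]), frozenset(["mid"]),
                               frozenset(["lo"]))

    def test_subset_contiguity(self, rng):
        """Homogeneous subsets are contiguous in the mean ordering."""
        for _ in range(30):
            groups = [rng.normal(rng.uniform(0, 2), 1, size=6) for _ in range(5)]
            labels = list("abcde")
            res = snk_test(groups, labels=labels)
            order = list(res.means)  # descending means
            for s in res.subsets:
                idx = sorted(order.index(l) for l in s)
                assert idx == list(range(idx[0], idx[-1] + 1))
            covered = set().union(*res.subsets)
            assert covered == set(labels)

    def test_input_validation(self):
        with pytest.raises(InputError):
            snk_test([np.array([1.0, 2.0])])
        with pytest.raises(InputError):
            snk_test([np.array([1.0]), np.array([1.0, 2.0])])


class TestLSD:
    def test_equal_baseline_and_followup(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        res = lsd_vs_baseline(base, {"w1": base.copy()})
        assert res[0].p_value == pytest.approx(1.0)
        assert res[0].estimate == 0.0

    def test_two_visit_case_equals_pooled_t(self, rng):
        """With baseline + one follow-up, LSD is exactly the pooled t."""
        base = rng.normal(0, 1, 12)
        w1 = rng.normal(0.8, 1, 9)
        lsd = lsd_vs_baseline(base, {"w1": w1})[0]
        t, p = _pooled_t_oracle(w1, base)
        assert lsd.statistic == pytest.approx(t, rel=1e-10)
        assert lsd.p_value == pytest.approx(p, rel=1e-10)

    def test_uses_pooled_anova_df(self, rng):
        base = rng.normal(0, 1, 10)
        follow = {f"v{i}": rng.normal(0, 1, 10) for i in range(4)}
        res = lsd_vs_baseline(base, follow)
        assert all(r.df == 50 - 5 for r in res)

    def test_treatment_dip_detected_reliably(self):
        """Anti-VEGF week-1 dip at design effect sizes is detected in
        >= 95% of replicates."""
        design = ppcv.CohortDesign(n_healthy=0, n_prp_eyes=0, n_surgery_eyes=0)
        hits = 0
        reps = 40
        for i in range(reps):
            c = ppcv.generate_cohort(design, seed=1000 + i)
            av = c[c["group"] == "anti_vegf"]
            base = av[av["timepoint"] == "baseline"]["ppcv_um3"].to_numpy()
            follow = {t: av[av["timepoint"] == t]["ppcv_um3"].to_numpy()
                      for t in ("w1", "w2", "m1", "m2", "m3")}
            res = lsd_vs_baseline(base, follow)
            by = {r.label: r for r in res}
            hits += (by["w1 vs baseline"].significant and
                     by["w1 vs baseline"].estimate < 0)
        assert hits >= 0.95 * reps


class TestRegression:
    def test_orthogonal_balanced_design_unit_vifs(self):
        # 2x2x2 balanced factorial: exactly orthogonal predictors
        rows = []
        rng = np.random.default_rng(0)
        for age in (40.0, 60.0):
            for sex in ("M", "F"):
                for q in ("TS", "NS"):
                    for _ in range(5):
                        rows.append(dict(age_years=age, sex=sex, quadrant=q,
                                         ppcv_um3=rng.normal(5e6, 1e5)))
        fit = fit_linear_model(pd.DataFrame(rows), "ppcv_um3",
                               ["age_years", "sex", "hemisphere"])
        for v in fit.vif.values():
            assert v == pytest.approx(1.000, abs=1e-9)

    def test_duplicated_predictor_raises_naming_collinear(self):
        df = pd.DataFrame({"age_years": [1.0, 2, 3, 4, 5, 6],
                           "age_copy": [1.0, 2, 3, 4, 5, 6],
                           "y": [1.0, 2, 1, 2, 1, 2]})
        with pytest.raises(InputError, match="age"):
            fit_linear_model(df, "y", ["age_years", "age_copy"])

    def test_recovers_design_coefficients_single_cohort(self):
        d = ppcv.CohortDesign(n_antivegf_eyes=0, n_prp_eyes=0, n_surgery_eyes=0)
        c = ppcv.generate_cohort(d, seed=42)
        fit = ppcv.fit_linear_model(c, "ppcv_um3", ["age_years", "sex", "hemisphere"])
        assert fit.params["age_years"] == pytest.approx(d.beta_age, rel=0.5)
        assert fit.params["hemisphere"] == pytest.approx(d.beta_nasal, rel=0.2)
        assert fit.pvalues["age_years"] < 0.001
        assert fit.pvalues["hemisphere"] < 0.001
        assert fit.n == 404


class TestGEE:
    @staticmethod
    def _clustered(rng, n_subj=20, rho=0.6, diff=0.0, eyes=2):
        rows = []
        for grp_i, grp in enumerate(("A", "B")):
            for s in range(n_subj):
                b = rng.normal(0, np.sqrt(rho))
                for e in range(eyes):
                    y = diff * (grp == "A") + b + rng.normal(0, np.sqrt(1 - rho))
                    rows.append((f"{grp}{s}", grp, y))
        return pd.DataFrame(rows, columns=["subject_id", "group", "ppcv_um3"])

    def test_single_eye_clusters_reduce_to_two_sample(self, rng):
        df = self._clustered(rng, n_subj=30, eyes=1)
        res = gee_group_comparison(df, "A", "B")
        ya = df.loc[df["group"] == "A", "ppcv_um3"].to_numpy()
        yb = df.loc[df["group"] == "B", "ppcv_um3"].to_numpy()
        assert res.estimate == pytest.approx(ya.mean() - yb.mean(), rel=1e-9)
        # closed-form HC0 sandwich with the small-sample factor
        ea, eb = ya - ya.mean(), yb - yb.mean()
        m, N, p = 60, 60, 2
        se = np.sqrt(((ea**2).sum() / len(ya)**2 + (eb**2).sum() / len(yb)**2)
                     * (m / (m - 1)) * ((N - 1) / (N - p)))
        assert res.estimate / res.statistic == pytest.approx(se, rel=1e-9)
        # and it is close to the ordinary Welch SE
        welch = np.sqrt(np.var(ya, ddof=1) / len(ya) + np.var(yb, ddof=1) / len(yb))
        assert res.estimate / res.statistic == pytest.approx(welch, rel=0.05)

    def test_duplication_does_not_shrink_se(self, rng):
        """Duplicating every record (within-cluster correlation 1) must not
        shrink the SE by √2; it stays essentially unchanged."""
        df = self._clustered(rng, n_subj=15, eyes=1)
        r1 = gee_group_comparison(df, "A", "B")
        r2 = gee_group_comparison(pd.concat([df, df]), "A", "B")
        se1 = r1.estimate / r1.statistic
        se2 = r2.estimate / r2.statistic
        assert r2.estimate == pytest.approx(r1.estimate, rel=1e-9)
        assert se2 == pytest.approx(se1, rel=0.02)

    def test_matches_statsmodels_gee(self, rng):
        """Cross-check the estimate against the independent GEE fitter."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        df = self._clustered(rng, n_subj=25, diff=0.7)
        df["g"] = (df["group"] == "A").astype(float)
        res = gee_group_comparison(df, "A", "B")
        fit = smf.gee("ppcv_um3 ~ g", groups="subject_id", data=df,
                      cov_struct=sm.cov_struct.Exchangeable(),
                      family=sm.families.Gaussian()).fit()
        assert res.estimate == pytest.approx(fit.params["g"], rel=0.01)
        assert res.estimate / res.statistic == pytest.approx(
            fit.bse["g"], rel=0.15)  # small-sample corrections differ

    def test_single_cluster_group_rejected(self, rng):
        df = self._clustered(rng, n_subj=10)
        df.loc[df["group"] == "A", "subject_id"] = "A0"
        with pytest.raises(InputError):
            gee_group_comparison(df, "A", "B")


class TestICC:
    def test_identical_columns_icc_one(self):
        x = np.arange(10.0)
        res = icc_two_rater(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)

    def test_independent_noise_icc_near_zero(self, rng):
        data = rng.normal(size=(20000, 2))
        res = icc_two_rater(data)
        assert abs(res.icc) < 0.02

    def test_matches_independent_icc2_oracle(self, rng):
        """Cross-check against pingouin's ICC2 on random datasets."""
        pingouin = pytest.importorskip("pingouin")
        for i in range(20):
            data = rng.normal(0, 1, size=(rng.integers(5, 40), 2)) + \
                rng.normal(0, 1, size=(1, 2))
            res = icc_two_rater(data)
            n = data.shape[0]
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(n), 2),
                "raters": np.tile([0, 1], n),
                "scores": data.ravel()})
            icc2 = pingouin.intraclass_corr(
                df, targets="targets", raters="raters",
                ratings="scores").set_index("Type").loc["ICC(A,1)", "ICC"]
            assert res.icc == pytest.approx(icc2, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            icc_two_rater(np.ones((5, 2)))


class TestKappa:
    def test_perfect_agreement(self):
        res = cohen_kappa(["a", "b", "a", "c"], ["a", "b", "a", "c"])
        assert res.kappa == pytest.approx(1.0)

    def test_confusion_table_closed_form(self):
        """2x2 table {a=45, b=5, c=5, d=45}: hand-expanded κ = 0.8."""
        a = ["x"] * 50 + ["y"] * 50
        b = ["x"] * 45 + ["y"] * 5 + ["x"] * 5 + ["y"] * 45
        res = cohen_kappa(a, b)
        assert res.kappa == pytest.approx(0.8)

    def test_independent_labels_near_zero(self, rng):
        a = rng.choice(["p", "q"], size=20000)
        b = rng.choice(["p", "q"], size=20000)
        assert abs(cohen_kappa(a, b).kappa) < 0.02

    def test_single_category_rejected(self):
        with pytest.raises(InputError):
            cohen_kappa(["a", "a"], ["a", "a"])

    def test_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(10):
            a = rng.choice(list("abc"), size=100)
            b = np.where(rng.uniform(size=100) < 0.7, a,
                         rng.choice(list("abc"), size=100))
            if len(np.unique(np.concatenate([a, b]))) < 2:
                continue
            res = cohen_kappa(a, b)
            assert res.kappa == pytest.approx(
                sklearn_metrics.cohen_kappa_score(a, b), abs=1e-12)

    def test_quartile_binning_helper(self, rng):
        v = rng.normal(size=1000)
        bins = quartile_bins(v, 4)
        counts = np.bincount(bins)
        assert len(counts) == 4
        assert counts.min() > 200  # roughly balanced quartiles
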