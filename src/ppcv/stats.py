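"""Cohort statistics for PPCV analyses.

Implements the study-style toolbox: pooled/Welch two-sample t,
Student–Newman–Keuls (SNK) homogeneous subsets, Fisher LSD comparisons
against baseline, OLS regression with variance-inflation factors,
GEE-style cluster-robust group comparison (exchangeable working
correlation — two eyes of one subject are not independent), ICC(2,1)
inter-rater agreement, and Cohen's κ.

Conventions: all P values are two-sided; "Student's t" defaults to the
pooled-variance variant; SNK uses studentized-range quantiles from
``scipy.stats.studentized_range`` with a Tukey–Kramer-style harmonic-mean
allowance for unequal group sizes; LSD and t are unadjusted, SNK controls
error stepwise — no additional multiplicity layer is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import InputError
from .geometry import NASAL_QUADRANTS


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonResult:
    label: str
    estimate: float          # mean difference (first − second)
    statistic: float
    p_value: float
    method: str              # "t" | "welch" | "LSD" | "SNK" | "GEE"
    alpha: float = 0.05
    df: float | None = None
    conf_int: tuple[float, float] | None = None
    n: tuple[int, int] | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class SNKGrouping:
    """Group means (sorted descending) and SNK homogeneous subsets."""

    means: dict          # label -> mean, insertion order = descending mean
    subsets: tuple       # tuple of frozensets of labels
    alpha: float
    ms_within: float
    df_error: float

    def same_subset(self, a, b) -> bool:
        return any(a in s and b in s for s in self.subsets)

    @property
    def any_significant(self) -> bool:
        """True iff some pair of groups is separated (not all in one subset)."""
        return not any(len(s) == len(self.means) for s in self.subsets)


@dataclass(frozen=True)
class RegressionFit:
    params: dict             # predictor -> coefficient (incl. "intercept")
    bse: dict
    tvalues: dict
    pvalues: dict
    r_squared: float
    vif: dict                # predictor -> VIF (no intercept)
    n: int
    coding: dict             # how categorical predictors were coded


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float | None = None
    variance_components: dict | None = None
    kappa: float | None = None
    categories: tuple | None = None
    n: int = 0


# ---------------------------------------------------------------------------
# two-sample t
# ---------------------------------------------------------------------------

def two_sample_t(a, b, variant: str = "pooled", alpha: float = 0.05,
                 label: str = "A vs B") -> ComparisonResult:
    """Two-sided two-sample t test; ``variant`` is "pooled" (Student's,
    default) or "welch".  Two constant, equal groups give t = 0, P = 1 by
    convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise InputError("variant must be 'pooled' or 'welch'")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            df = len(a) + len(b) - 2
            return ComparisonResult(label, 0.0, 0.0, 1.0, variant, alpha, df,
                                    n=(len(a), len(b)))
        raise InputError("both groups are constant with different means; "
                         "t is undefined")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = float(res.df)
    return ComparisonResult(label, float(np.mean(a) - np.mean(b)),
                            float(res.statistic), float(res.pvalue),
                            variant, alpha, df, n=(len(a), len(b)))


# ---------------------------------------------------------------------------
# SNK
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1024)
def studentized_range_quantile(alpha: float, r: int, df: float) -> float:
    """Upper-α quantile q(α, r, df) of the studentized range of r means."""
    return float(sps.studentized_range.ppf(1.0 - alpha, r, df))


def snk_test(groups, labels=None, alpha: float = 0.05) -> SNKGrouping:
    """Student–Newman–Keuls stepwise multiple comparison.

    Means are sorted; the range of each stretch of r adjacent means is
    compared against q(α, r, df_error)·√(MS_within/2·(1/n_i + 1/n_j))
    (harmonic-mean allowance for unequal n).  A stretch declared
    non-significant is not subdivided and forms a homogeneous subset.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise InputError("each group needs n >= 2")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df_error = float(ns.sum() - k)
    ms_within = float(sum((len(g) - 1) * g.var(ddof=1) for g in groups) / df_error)

    order = np.argsort(means)  # ascending
    m_sorted = means[order]
    n_sorted = ns[order]
    lab_sorted = [labels[i] for i in order]

    subsets: list[frozenset] = []

    def test_range(lo: int, hi: int):
        r = hi - lo + 1
        if r < 2:
            return
        if ms_within == 0:
            significant = m_sorted[hi] > m_sorted[lo]
        else:
            se = np.sqrt(ms_within / 2.0 * (1.0 / n_sorted[lo] + 1.0 / n_sorted[hi]))
            q_crit = studentized_range_quantile(alpha, r, df_error)
            significant = (m_sorted[hi] - m_sorted[lo]) > q_crit * se
        if not significant:
            subsets.append(frozenset(lab_sorted[lo:hi + 1]))
        else:
            test_range(lo, hi - 1)
            test_range(lo + 1, hi)

    test_range(0, k - 1)

    # groups not covered by any non-significant stretch stand alone
    covered = set().union(*subsets) if subsets else set()
    for lab in lab_sorted:
        if lab not in covered:
            subsets.append(frozenset([lab]))
    # drop subsets nested inside others
    subsets = [s for s in subsets
               if not any(s < t for t in subsets)]
    # de-duplicate, keep deterministic order by (min mean within subset)
    uniq = []
    for s in subsets:
        if s not in uniq:
            uniq.append(s)
    mean_by_label = dict(zip(labels, means))
    uniq.sort(key=lambda s: -max(mean_by_label[l] for l in s))

    desc = np.argsort(-means)
    means_desc = {labels[i]: float(means[i]) for i in desc}
    return SNKGrouping(means_desc, tuple(uniq), alpha, ms_within, df_error)


# ---------------------------------------------------------------------------
# LSD
# ---------------------------------------------------------------------------

def lsd_vs_baseline(baseline, followups: dict, alpha: float = 0.05) -> list[ComparisonResult]:
    """Fisher least-significant-difference comparisons of each follow-up
    visit against baseline, using the pooled within-group mean square and
    error degrees of freedom from the one-way ANOVA over all visits;
    unadjusted two-sided P values."""
    baseline = np.asarray(baseline, dtype=float)
    if len(baseline) < 2 or any(len(np.asarray(v)) < 2 for v in followups.values()):
        raise InputError("each visit needs n >= 2")
    all_groups = [baseline] + [np.asarray(v, dtype=float) for v in followups.values()]
    k = len(all_groups)
    if k < 2:
        raise InputError("need at least one follow-up visit")
    N = sum(len(g) for g in all_groups)
    df_error = float(N - k)
    ms_within = float(sum((len(g) - 1) * g.var(ddof=1) for g in all_groups) / df_error)

    out = []
    for name, v in followups.items():
        v = np.asarray(v, dtype=float)
        diff = float(v.mean() - baseline.mean())
        if ms_within == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            se = np.sqrt(ms_within * (1.0 / len(baseline) + 1.0 / len(v)))
            t = diff / se
            p = 2.0 * float(sps.t.sf(abs(t), df_error))
        out.append(ComparisonResult(f"{name} vs baseline", diff, float(t), p,
                                    "LSD", alpha, df_error,
                                    n=(len(v), len(baseline))))
    return out


# ---------------------------------------------------------------------------
# OLS + VIF
# ---------------------------------------------------------------------------

def _code_predictors(table: pd.DataFrame, predictors) -> tuple[pd.DataFrame, dict]:
    """Build the numeric design matrix; sex and hemisphere become 0/1."""
    X = pd.DataFrame(index=table.index)
    coding: dict = {}
    for p in predictors:
        if p == "sex":
            X[p] = (table["sex"].astype(str) == "F").astype(float)
            coding[p] = {"M": 0, "F": 1}
        elif p == "hemisphere":
            if "hemisphere" in table.columns:
                src = table["hemisphere"].astype(str).str.lower()
                X[p] = (src == "nasal").astype(float)
            else:
                X[p] = table["quadrant"].isin(NASAL_QUADRANTS).astype(float)
            coding[p] = {"temporal": 0, "nasal": 1}
        else:
            if p not in table.columns:
                raise InputError(f"unknown predictor {p!r}")
            X[p] = pd.to_numeric(table[p])
    return X, coding


def fit_linear_model(table: pd.DataFrame, response: str, predictors) -> RegressionFit:
    """OLS with intercept plus per-predictor VIFs.

    ``sex`` is coded F=1 and ``hemisphere`` nasal=1 (derived from the
    quadrant column when absent: TS/TI → temporal, NS/NI → nasal).  A
    rank-deficient design raises an error naming the collinear predictors.
    """
    predictors = list(predictors)
    y = pd.to_numeric(table[response]).to_numpy(dtype=float)
    X, coding = _code_predictors(table, predictors)
    n, p = X.shape
    if n <= p + 1:
        raise InputError(f"need n > {p + 1} observations, got {n}")

    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # name the offending predictors via pairwise correlation of columns
        bad = set()
        corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
        corr = np.atleast_2d(corr)
        for i in range(p):
            if np.isclose(X.iloc[:, i].std(), 0.0):
                bad.add(predictors[i])
            for j in range(i + 1, p):
                if abs(corr[i, j]) > 1 - 1e-10:
                    bad.update((predictors[i], predictors[j]))
        raise InputError(f"design matrix is rank-deficient; collinear predictors: "
                         f"{sorted(bad) or predictors}")

    fit = sm.OLS(y, Xc).fit()
    names = ["intercept"] + predictors

    vif = {}
    Xv = X.to_numpy(dtype=float)
    for j, name in enumerate(predictors):
        others = np.delete(Xv, j, axis=1)
        aux = sm.OLS(Xv[:, j], sm.add_constant(others, has_constant="add")).fit()
        r2 = min(aux.rsquared, 1 - 1e-12)
        vif[name] = max(1.0, float(1.0 / (1.0 - r2)))

    return RegressionFit(
        params=dict(zip(names, map(float, fit.params))),
        bse=dict(zip(names, map(float, fit.bse))),
        tvalues=dict(zip(names, map(float, fit.tvalues))),
        pvalues=dict(zip(names, map(float, fit.pvalues))),
        r_squared=float(fit.rsquared),
        vif=vif, n=n, coding=coding)


# ---------------------------------------------------------------------------
# GEE group comparison
# ---------------------------------------------------------------------------

def gee_group_comparison(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    cluster_col: str = "subject_id",
    value_col: str = "ppcv_um3",
    group_col: str = "group",
    alpha: float = 0.05,
    label: str | None = None,
) -> ComparisonResult:
    """Mean difference (A − B) with cluster-robust inference.

    Marginal mean model y = β₀ + β₁·1{group A}, identity link, fitted by
    GEE with an exchangeable working correlation (moment estimate of the
    within-cluster correlation), sandwich covariance with the small-sample
    factor m/(m−1)·(N−1)/(N−p), and a t reference on m − p degrees of
    freedom (m = number of clusters).  With one observation per cluster
    this reduces to the ordinary two-sample comparison.
    """
    sub = table[table[group_col].isin([group_a, group_b])]
    if sub.empty:
        raise InputError("no rows for the requested groups")
    y = pd.to_numeric(sub[value_col]).to_numpy(dtype=float)
    g = (sub[group_col] == group_a).to_numpy(dtype=float)
    clusters = sub[cluster_col].to_numpy()
    for grp in (group_a, group_b):
        n_cl = sub.loc[sub[group_col] == grp, cluster_col].nunique()
        if n_cl < 2:
            raise InputError(f"group {grp!r} has {n_cl} cluster(s); need >= 2")

    X = np.column_stack([np.ones_like(y), g])
    N, p = X.shape
    uniq, inv = np.unique(clusters, return_inverse=True)
    m = len(uniq)
    idx_by_cluster = [np.where(inv == c)[0] for c in range(m)]

    beta = np.linalg.lstsq(X, y, rcond=None)[0]  # working-independence start
    rho = 0.0
    for _ in range(25):
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / (N - p)
        num, cnt = 0.0, 0
        for idx in idx_by_cluster:
            e = resid[idx]
            mi = len(e)
            if mi > 1:
                num += (e.sum() ** 2 - (e ** 2).sum()) / 2.0
                cnt += mi * (mi - 1) // 2
        rho_new = 0.0 if cnt <= p else float(np.clip(num / ((cnt - p) * sigma2),
                                                     0.0, 0.99))
        B = np.zeros((p, p))
        rhs = np.zeros(p)
        for idx in idx_by_cluster:
            Xc, yc = X[idx], y[idx]
            mi = len(idx)
            # V^{-1} for exchangeable correlation (unit variance scale)
            Vinv = (np.eye(mi) - (rho_new / (1.0 + (mi - 1) * rho_new))
                    * np.ones((mi, mi))) / (1.0 - rho_new)
            B += Xc.T @ Vinv @ Xc
            rhs += Xc.T @ Vinv @ yc
        beta_new = np.linalg.solve(B, rhs)
        done = np.allclose(beta_new, beta, rtol=1e-10, atol=1e-12) and \
            np.isclose(rho_new, rho, atol=1e-10)
        beta, rho = beta_new, rho_new
        if done:
            break

    resid = y - X @ beta
    Bmat = np.zeros((p, p))
    M = np.zeros((p, p))
    for idx in idx_by_cluster:
        Xc, ec = X[idx], resid[idx]
        mi = len(idx)
        Vinv = (np.eye(mi) - (rho / (1.0 + (mi - 1) * rho))
                * np.ones((mi, mi))) / (1.0 - rho)
        Bmat += Xc.T @ Vinv @ Xc
        s = Xc.T @ Vinv @ ec
        M += np.outer(s, s)
    c_small = (m / (m - 1)) * ((N - 1) / (N - p))
    cov = np.linalg.solve(Bmat, np.linalg.solve(Bmat, M).T).T * c_small
    se = float(np.sqrt(cov[1, 1]))
    df = float(m - p)
    t = float(beta[1] / se) if se > 0 else 0.0
    pval = 2.0 * float(sps.t.sf(abs(t), df)) if se > 0 else 1.0
    tcrit = float(sps.t.ppf(1 - alpha / 2, df))
    ci = (float(beta[1] - tcrit * se), float(beta[1] + tcrit * se))
    return ComparisonResult(label or f"{group_a} vs {group_b}", float(beta[1]),
                            t, pval, "GEE", alpha, df, conf_int=ci,
                            n=(int(g.sum()), int(N - g.sum())))


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def icc_two_rater(pairs) -> ReliabilityResult:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, from the two-way ANOVA mean squares.

    ``pairs`` is an (n, 2) array or a DataFrame with columns rater1/rater2.
    """
    if isinstance(pairs, pd.DataFrame):
        cols = [c for c in ("rater1", "rater2") if c in pairs.columns]
        data = pairs[cols].to_numpy(dtype=float) if len(cols) == 2 \
            else pairs.to_numpy(dtype=float)
    else:
        data = np.asarray(pairs, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise InputError("pairs must be (n, 2): two raters")
    n, k = data.shape
    if n < 3:
        raise InputError("need at least 3 subjects")

    gm = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(((data - gm) ** 2).sum())
    if ss_total == 0:
        raise InputError("zero total variance; ICC undefined")
    ss_rows = k * float(((row_means - gm) ** 2).sum())
    ss_cols = n * float(((col_means - gm) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    comps = {
        "ms_rows": msr, "ms_cols": msc, "ms_error": mse,
        "var_subjects": max(0.0, (msr - mse) / k),
        "var_raters": max(0.0, (msc - mse) / n),
        "var_error": mse,
    }
    return ReliabilityResult(icc=float(icc), variance_components=comps, n=n)


def cohen_kappa(labels_a, labels_b) -> ReliabilityResult:
    """Cohen's κ = (p_o − p_e)/(1 − p_e) with marginal-product chance
    agreement; requires >= 2 observed categories overall."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("label vectors must be 1-D and the same length")
    if len(a) == 0:
        raise InputError("empty label vectors")
    cats = np.union1d(np.unique(a), np.unique(b))
    if len(cats) < 2:
        raise InputError("need >= 2 observed categories; chance agreement is 1")
    n = len(a)
    idx = {c: i for i, c in enumerate(cats)}
    conf = np.zeros((len(cats), len(cats)))
    for x, yv in zip(a, b):
        conf[idx[x], idx[yv]] += 1
    po = np.trace(conf) / n
    pe = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if pe >= 1.0:
        raise InputError("chance agreement is 1; kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    return ReliabilityResult(kappa=float(kappa), categories=tuple(cats), n=n)


def quartile_bins(values, n_bins: int = 4) -> np.ndarray:
    """Quantile-bin a continuous measurement into ordinal categories —
    the documented way to apply κ to repeated continuous PPCV readings."""
    values = np.asarray(values, dtype=float)
    if len(values) < n_bins:
        raise InputError("need at least n_bins values")
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right")
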