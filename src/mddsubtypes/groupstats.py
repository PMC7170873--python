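"""Group comparisons of ROI measures and clinical variables across subtypes.

Each of the 13 ROI measures is compared across groups (subtypes plus healthy
controls) by ANCOVA: a linear model with group indicators and the covariates
age and sex, plus intracranial volume (ICV) for surface-area and volume
measures but not for thickness (thickness does not scale with head size).
The group F statistic comes from the extra-sum-of-squares comparison of the
full model against the covariates-only model.  Raw p-values are
Benjamini-Hochberg FDR-adjusted across the 13 measures, and Tukey-Kramer post
hoc comparisons of covariate-adjusted group means are run for measures whose
FDR-adjusted omnibus p passes the gate.  One-way ANOVA (raw data or printed
summary statistics) and Pearson chi-square cover the clinical/demographic
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .items import ROI_KINDS, ROI_NAMES

COVARIATES = ("age", "sex", "icv")
CONDITION_NUMBER_GATE = 1e10


@dataclass
class RoiGroupResult:
    roi_name: str
    measure_kind: str
    F: float
    df: tuple[int, int]
    p_raw: float
    p_fdr: float | None = None
    posthoc: dict[tuple[str, str], float] | None = None
    adjusted_means: dict[str, float] = field(default_factory=dict)
    raw_means: dict[str, float] = field(default_factory=dict)
    n_excluded: int = 0


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    degenerate: bool = False


@dataclass
class ContingencyResult:
    observed: np.ndarray
    chi_square: float
    df: int
    p: float


def _design(df: pd.DataFrame, roi_name: str):
    """Full-model design matrix (intercept, group dummies, covariates)."""
    kind = ROI_KINDS.get(roi_name)
    if kind is None:
        raise KeyError(f"unknown ROI measure: {roi_name!r}")
    covs = ["age", "sex"] + (["icv"] if kind != "thickness" else [])
    cols = [roi_name, "group", *covs]
    sub = df[cols].dropna()
    n_excluded = len(df) - len(sub)
    groups = sorted(sub["group"].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = sub.groupby("group").size()
    if (counts < 2).any():
        raise ValueError(f"groups with < 2 subjects: "
                         f"{counts[counts < 2].index.tolist()}")
    y = sub[roi_name].to_numpy(dtype=float)
    dummies = np.column_stack([
        (sub["group"].astype(str) == g).to_numpy(dtype=float)
        for g in groups[1:]
    ])
    x_cov = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in covs]
    )
    x_full = np.column_stack([x_cov, dummies])
    # collinearity gate on the column-normalized design so raw covariate
    # scales (ICV ~1e6 mm^3) do not masquerade as rank deficiency
    norms = np.linalg.norm(x_full, axis=0)
    if (norms == 0).any() or np.linalg.cond(x_full / norms) > CONDITION_NUMBER_GATE:
        raise ValueError(f"collinear design for {roi_name} "
                         f"(condition number gate {CONDITION_NUMBER_GATE:g})")
    return y, x_full, x_cov, groups, covs, sub, n_excluded


def ancova_group_test(table: pd.DataFrame, roi_name: str) -> RoiGroupResult:
    """Covariate-adjusted group F test for one ROI measure.

    F is the extra-sum-of-squares statistic comparing the full model
    (covariates + group) with the covariates-only model; for thickness
    measures the design excludes ICV.
    """
    y, x_full, x_cov, groups, covs, sub, n_excl = _design(table, roi_name)
    full = sm.OLS(y, x_full).fit()
    reduced = sm.OLS(y, x_cov).fit()
    df_num = x_full.shape[1] - x_cov.shape[1]
    df_den = int(full.df_resid)
    f_stat = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    # adjusted means: group predictions at the covariate means
    cov_means = [sub[c].mean() for c in covs]
    adj = {}
    params = full.params
    for i, g in enumerate(groups):
        row = np.concatenate([[1.0], cov_means,
                              np.eye(len(groups) - 1)[i - 1]
                              if i > 0 else np.zeros(len(groups) - 1)])
        adj[g] = float(row @ params)
    raw = sub.groupby("group")[roi_name].mean().astype(float).to_dict()
    return RoiGroupResult(
        roi_name=roi_name,
        measure_kind=ROI_KINDS[roi_name],
        F=float(f_stat),
        df=(df_num, df_den),
        p_raw=p,
        adjusted_means=adj,
        raw_means=raw,
        n_excluded=n_excl,
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def tukey_hsd(values, groups, adjust_for: pd.DataFrame | None = None
              ) -> dict[tuple[str, str], float]:
    """Tukey(-Kramer) studentized-range p for every group pair.

    Without covariates this is the classical Tukey-Kramer test on group means
    with the pooled within-group variance.  With covariates the comparison is
    between covariate-adjusted means from the ANCOVA model, using the model's
    residual variance, error df, and the coefficient covariance for the
    standard error of each pairwise difference.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray([str(v) for v in groups])
    names = sorted(np.unique(g))
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = {name: int((g == name).sum()) for name in names}
    if min(counts.values()) < 2:
        raise ValueError("every group needs at least 2 members")
    dummies = np.column_stack([(g == name).astype(float)
                               for name in names[1:]])
    if adjust_for is not None:
        covs = np.asarray(adjust_for, dtype=float)
        x = np.column_stack([np.ones(y.size), covs, dummies])
        n_cov = covs.shape[1]
    else:
        x = np.column_stack([np.ones(y.size), dummies])
        n_cov = 0
    fit = sm.OLS(y, x).fit()
    df_err = int(fit.df_resid)
    mse = fit.ssr / df_err
    # contrast for the (i, j) adjusted-mean difference in coefficient space
    pcov = np.linalg.inv(x.T @ x) * mse
    out: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(x.shape[1])
            if i > 0:
                c[n_cov + i] = 1.0
            if j > 0:
                c[n_cov + j] = -1.0
            diff = float(c @ fit.params)
            se = float(np.sqrt(c @ pcov @ c))
            q = abs(diff) * np.sqrt(2.0) / se
            p = float(stats.studentized_range.sf(q, k, df_err))
            out[(names[i], names[j])] = min(max(p, 0.0), 1.0)
    return out


def oneway_anova(values=None, groups=None, *, means=None, sds=None,
                 ns=None) -> AnovaResult:
    """Classical one-way ANOVA from raw data or printed summary statistics."""
    if means is not None:
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        ns = np.asarray(ns, dtype=float)
        if (ns < 2).any():
            raise ValueError("every group needs n >= 2")
        grand = (ns * means).sum() / ns.sum()
        ssb = float((ns * (means - grand) ** 2).sum())
        ssw = float(((ns - 1) * sds ** 2).sum())
        df_b = means.size - 1
        df_w = int(ns.sum() - means.size)
    else:
        y = np.asarray(values, dtype=float)
        g = np.asarray([str(v) for v in groups])
        names = np.unique(g)
        if names.size < 2:
            raise ValueError("need at least 2 groups")
        if min(int((g == n).sum()) for n in names) < 2:
            raise ValueError("every group needs at least 2 members")
        grand = y.mean()
        ssb = sum(((g == n).sum()) * (y[g == n].mean() - grand) ** 2
                  for n in names)
        ssw = sum(((y[g == n] - y[g == n].mean()) ** 2).sum() for n in names)
        df_b = names.size - 1
        df_w = y.size - names.size
    if ssw == 0.0:
        return AnovaResult(F=float("nan"), df=(df_b, df_w), p=float("nan"),
                           degenerate=True)
    f_stat = (ssb / df_b) / (ssw / df_w)
    return AnovaResult(F=float(f_stat), df=(df_b, df_w),
                       p=float(stats.f.sf(f_stat, df_b, df_w)))


def chi_square_test(observed) -> ContingencyResult:
    """Pearson chi-square on an r x c contingency table (no continuity
    correction); expected counts from the margins."""
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or (obs < 0).any() or obs.sum() == 0:
        raise ValueError("observed must be a nonnegative 2-D table with "
                         "positive total")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(observed=obs, chi_square=float(chi2),
                             df=int(df), p=float(p))


def run_roi_analysis(table: pd.DataFrame, roi_names=ROI_NAMES,
                     fdr_gate: float = 0.05) -> list[RoiGroupResult]:
    """Full ROI battery: per-measure ANCOVA, BH-FDR across measures, and
    Tukey-Kramer post hoc (on covariate-adjusted means) where the
    FDR-corrected omnibus p passes the gate."""
    results = [ancova_group_test(table, roi) for roi in roi_names]
    adj = fdr_bh([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_fdr = float(pa)
        if r.p_fdr < fdr_gate:
            covs = ["age", "sex"] + (["icv"] if r.measure_kind != "thickness"
                                     else [])
            sub = table[[r.roi_name, "group", *covs]].dropna()
            r.posthoc = tukey_hsd(
                sub[r.roi_name], sub["group"], adjust_for=sub[covs]
            )
    return results


def roi_results_to_frame(results: list[RoiGroupResult]) -> pd.DataFrame:
    """Report table: one row per ROI with means, F, raw/FDR p, post hoc."""
    rows = []
    for r in results:
        row = {
            "roi": r.roi_name,
            "kind": r.measure_kind,
            "F": r.F,
            "df_num": r.df[0],
            "df_den": r.df[1],
            "p_raw": r.p_raw,
            "p_fdr": r.p_fdr,
        }
        for g, m in sorted(r.raw_means.items()):
            row[f"mean_{g}"] = m
        for g, m in sorted(r.adjusted_means.items()):
            row[f"adj_mean_{g}"] = m
        if r.posthoc:
            row["posthoc"] = "; ".join(
                f"{a} vs {b}: p={p:.4g}" for (a, b), p in sorted(r.posthoc.items())
            )
        rows.append(row)
    return pd.DataFrame(rows)
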