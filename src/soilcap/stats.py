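"""Stratified descriptive statistics, normality testing and group comparisons.

Workflow mirrors standard practice for stratified soil-geochemistry
surveys: per-stratum mean/SD/CV%, a Kolmogorov–Smirnov normality check
(Lilliefors-corrected, since the normal's parameters are estimated from
the data), Box–Cox transformation of non-normal metals, one-way ANOVA
across land uses with a Levene pre-test choosing Tukey HSD (homogeneous
variances) or Games–Howell (heterogeneous) post-hoc comparisons, and
per-stratum Pearson correlation matrices with two-tailed p-values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

ALPHA = 0.05  # two-tailed significance threshold used throughout


def describe(survey) -> pd.DataFrame:
    """Per-(land_use, metal) mean, unbiased SD and CV% = 100*sd/mean."""
    rows = []
    for lu in dict.fromkeys(survey.land_use):
        sub = survey.subset(lu)
        if sub.n < 2:
            raise ValueError(f"stratum {lu!r} has n={sub.n} < 2: sd undefined")
        for m in survey.metals:
            v = sub.values(m)
            mean = v.mean()
            sd = v.std(ddof=1)
            rows.append({"land_use": lu, "metal": m, "n": sub.n,
                         "mean": mean, "sd": sd,
                         "cv_percent": 100.0 * sd / mean if mean != 0 else np.nan})
    return pd.DataFrame(rows)


def normality_and_transform(values, alpha: float = ALPHA
                            ) -> tuple[float, float | None, np.ndarray]:
    """KS normality p-value, Box–Cox lambda, and the working values.

    The KS test uses the Lilliefors correction (normal parameters estimated
    from the sample). The Box–Cox transform (maximum-likelihood lambda) is
    applied only when normality is rejected at ``alpha``; otherwise the
    original values are returned with ``lambda = None``. Non-positive
    inputs are shifted by ``-min + eps`` before Box–Cox.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 observations for a normality test")
    if np.ptp(v) == 0:
        raise ValueError("zero-variance input: normality test undefined")
    ks_p = float(lilliefors(v, dist="norm")[1])
    if ks_p >= alpha:
        return ks_p, None, v
    shifted = v
    if v.min() <= 0:
        shifted = v - v.min() + 1e-6 * max(np.ptp(v), 1.0)
    transformed, lam = sps.boxcox(shifted)
    return ks_p, float(lam), transformed


@dataclass
class AnovaResult:
    F: float
    p: float
    levene_p: float
    posthoc_method: str  # "tukey_hsd" or "games_howell"
    posthoc: pd.DataFrame  # columns: group1, group2, p_adj


def oneway_anova(survey, metal: str, use_boxcox: bool = False,
                 alpha: float = ALPHA) -> AnovaResult:
    """Classical one-way ANOVA of one metal across land-use strata.

    A Levene pre-test (mean-centred) decides the post-hoc family: Tukey HSD
    under homogeneous variances, Games–Howell otherwise. With
    ``use_boxcox`` the test runs on Box–Cox-normalized values when the raw
    pooled sample fails the KS normality check.
    """
    strata = [lu for lu in dict.fromkeys(survey.land_use)]
    if len(strata) < 2:
        raise ValueError("one-way ANOVA requires at least two strata")
    values = survey.values(metal).astype(float)
    if use_boxcox:
        _, lam, work = normality_and_transform(values, alpha)
        if lam is not None:
            # re-apply one shared monotone transform to keep groups comparable
            values = work
    groups = [values[survey.land_use == lu] for lu in strata]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every stratum needs n >= 2")

    F, p = sps.f_oneway(*groups)
    lev_p = float(sps.levene(*groups, center="mean")[1])

    pairs = list(itertools.combinations(range(len(strata)), 2))
    if lev_p >= alpha:
        method = "tukey_hsd"
        res = sps.tukey_hsd(*groups)
        rows = [{"group1": strata[i], "group2": strata[j],
                 "p_adj": float(res.pvalue[i, j])} for i, j in pairs]
    else:
        method = "games_howell"
        import pingouin as pg

        df = pd.DataFrame({"value": values, "group": survey.land_use})
        gh = pg.pairwise_gameshowell(data=df, dv="value", between="group")
        key = {(str(a), str(b)): float(pv)
               for a, b, pv in zip(gh["A"], gh["B"], gh["pval"])}
        rows = [{"group1": strata[i], "group2": strata[j],
                 "p_adj": key.get((strata[i], strata[j]),
                                  key.get((strata[j], strata[i]), np.nan))}
                for i, j in pairs]
    return AnovaResult(F=float(F), p=float(p), levene_p=lev_p,
                       posthoc_method=method, posthoc=pd.DataFrame(rows))


def correlations(survey, land_use: str | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-tailed p per metal pair, optionally in one stratum.

    Zero-variance metals yield NaN (r undefined). Returns (r, p) DataFrames
    indexed by metal, symmetric with unit diagonal.
    """
    sub = survey if land_use is None else survey.subset(land_use)
    if sub.n < 3:
        raise ValueError("correlation needs at least 3 samples")
    metals = list(sub.metals)
    k = len(metals)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = sub.values(metals[i]), sub.values(metals[j])
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rr, pp = sps.pearsonr(a, b)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return (pd.DataFrame(r, index=metals, columns=metals),
            pd.DataFrame(p, index=metals, columns=metals))


def stats_report(survey, use_boxcox: bool = False) -> dict:
    """Full report: descriptives, per-metal normality/ANOVA, per-stratum correlations."""
    per_metal = []
    for m in survey.metals:
        v = survey.values(m)
        try:
            ks_p, lam, _ = normality_and_transform(v)
        except ValueError:
            ks_p, lam = np.nan, None
        res = oneway_anova(survey, m, use_boxcox=use_boxcox)
        per_metal.append({"metal": m, "ks_p": ks_p,
                          "boxcox_lambda": np.nan if lam is None else lam,
                          "anova_F": res.F, "anova_p": res.p,
                          "levene_p": res.levene_p,
                          "posthoc_method": res.posthoc_method})
    corr = {}
    for lu in dict.fromkeys(survey.land_use):
        if survey.subset(lu).n >= 3:
            corr[lu] = correlations(survey, lu)
    return {"describe": describe(survey),
            "per_metal": pd.DataFrame(per_metal),
            "correlations": corr}
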