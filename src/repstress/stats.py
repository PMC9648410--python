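"""Downstream association statistics for score tables.

Covers the analyses run on scored cohorts: clustered Spearman correlation
panels, high-vs-low quartile drug-sensitivity screens with BH FDR, paired
pre/post treatment score dynamics (Wilcoxon signed-rank), group comparisons
(one-way ANOVA, Holm-adjusted pairwise Welch tests, linear trend), and
Kaplan–Meier survival with a two-sided log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import (
    f_oneway,
    kendalltau,
    linregress,
    mannwhitneyu,
    spearmanr,
    ttest_ind,
    wilcoxon,
)
from statsmodels.stats.multitest import multipletests

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

EXACT_MW_MAX_GROUP = 8   # exact Mann–Whitney when the smaller group is <= this
EXACT_WSR_MAX_N = 25     # exact signed-rank up to this many nonzero pairs


def spearman_panel(
    features: pd.DataFrame, target: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Spearman rho and BH-adjusted p of each feature vs the target.

    ``features`` is samples × features.  Constant features get NA rho/p.
    The returned order is from complete-linkage clustering of Euclidean
    distances between the features' pairwise Spearman-correlation profiles.
    """
    common = features.index.intersection(target.index)
    if len(common) < 3:
        raise ValueError("need >= 3 paired observations")
    x = features.loc[common]
    t = target.loc[common].to_numpy(float)
    rows = {}
    for col in x.columns:
        v = x[col].to_numpy(float)
        if np.unique(v).size == 1:
            rows[col] = (np.nan, np.nan)
        else:
            rho, p = spearmanr(v, t)
            rows[col] = (rho, p)
    out = pd.DataFrame(rows, index=["rho", "p_raw"]).T
    ok = out["p_raw"].notna()
    out["p_adj"] = np.nan
    out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p_raw"].to_numpy())

    usable = [c for c in x.columns if x[c].std(ddof=1) > 0]
    if len(usable) > 2:
        corr = x[usable].corr(method="spearman").to_numpy()
        order_idx = leaves_list(linkage(pdist(corr), method="complete"))
        order = [usable[i] for i in order_idx]
    else:
        order = usable
    return out, order


@dataclass
class ContrastResult:
    feature: str
    effect: float  # median(high) - median(low)
    p_raw: float
    p_adj: float
    direction: Literal["up", "down", "none"]
    significant: bool


def _mw_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    method = "exact" if min(a.size, b.size) <= EXACT_MW_MAX_GROUP else "asymptotic"
    if method == "exact" and (np.unique(np.concatenate([a, b])).size < a.size + b.size):
        method = "asymptotic"  # ties: exact null invalid, use tie-corrected normal
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def drug_contrast(
    activity: pd.DataFrame, groups: pd.Series, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-drug high-vs-low two-group contrast with BH FDR.

    ``activity`` is samples × drugs; ``groups`` maps samples to
    "high"/"low" (other labels are ignored).  Drugs observed in fewer than
    two samples of either group are skipped with a log entry.
    """
    groups = groups.reindex(activity.index)
    hi_ids = groups.index[groups == "high"]
    lo_ids = groups.index[groups == "low"]
    if len(hi_ids) < 2 or len(lo_ids) < 2:
        raise ValueError("need >= 2 samples in both the high and low groups")
    results: list[ContrastResult] = []
    for drug in activity.columns:
        a = activity.loc[hi_ids, drug].dropna().to_numpy(float)
        b = activity.loc[lo_ids, drug].dropna().to_numpy(float)
        if a.size < 2 or b.size < 2:
            logger.info("drug %s skipped: observed in one group only", drug)
            continue
        p = _mw_two_sided(a, b)
        eff = float(np.median(a) - np.median(b))
        results.append(ContrastResult(drug, eff, p, 1.0, "none", False))
    if not results:
        return pd.DataFrame(
            columns=["effect", "p_raw", "p_adj", "direction", "significant"]
        )
    adj = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adj):
        r.p_adj = float(q)
        r.significant = bool(q < fdr)
        if r.significant:
            r.direction = "up" if r.effect > 0 else ("down" if r.effect < 0 else "none")
    return pd.DataFrame(
        {
            r.feature: {
                "effect": r.effect,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "direction": r.direction,
                "significant": r.significant,
            }
            for r in results
        }
    ).T


def paired_dynamics(pre: pd.Series, post: pd.Series) -> tuple[float, float]:
    """Median post−pre delta and two-sided Wilcoxon signed-rank p.

    Zero differences are dropped (Wilcoxon convention); exact p for up to
    25 nonzero pairs, normal approximation beyond.
    """
    common = pre.index.intersection(post.index)
    d = (post.loc[common] - pre.loc[common]).to_numpy(float)
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("no signal: all paired differences are zero")
    if nz.size < 3:
        raise ValueError("need >= 3 pairs with nonzero differences")
    method = "exact" if nz.size <= EXACT_WSR_MAX_N else "approx"
    res = wilcoxon(nz, zero_method="wilcox", alternative="two-sided", method=method)
    return float(np.median(d)), float(res.pvalue)


def group_compare(
    values: pd.Series,
    groups: pd.Series,
    mode: Literal["omnibus", "pairwise", "trend"] = "omnibus",
    group_order: Sequence[str] | None = None,
    trend_method: Literal["regression", "jonckheere"] = "regression",
) -> dict:
    """Compare a value across labelled groups.

    omnibus — one-way ANOVA F and p; pairwise — all group pairs by Welch
    t-test with Holm adjustment (a Tukey-flavoured post hoc); trend —
    least-squares slope of the value on the ordinal group index (per
    ``group_order``) with its t-test p, or a Jonckheere–Terpstra-style
    Kendall tau test behind ``trend_method="jonckheere"``.
    """
    groups = groups.reindex(values.index)
    labels = group_order if group_order is not None else sorted(groups.dropna().unique())
    arrays = [values[groups == g].dropna().to_numpy(float) for g in labels]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if mode in ("omnibus", "pairwise") and any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 samples")
    if mode == "omnibus":
        if all(np.var(a) == 0 for a in arrays) and np.unique(np.concatenate(arrays)).size == 1:
            raise ValueError("F undefined: zero variance everywhere with equal means")
        f, p = f_oneway(*arrays)
        return {"F": float(f), "p": float(p)}
    if mode == "pairwise":
        pairs, praw = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                t, p = ttest_ind(arrays[i], arrays[j], equal_var=False)
                pairs.append((labels[i], labels[j], float(t)))
                praw.append(float(p))
        padj = multipletests(praw, method="holm")[1]
        return {
            "pairs": [
                {"a": a, "b": b, "t": t, "p_raw": p, "p_adj": float(q)}
                for (a, b, t), p, q in zip(pairs, praw, padj)
            ]
        }
    # trend
    if len(labels) < 3:
        raise ValueError("trend test needs >= 3 ordered groups")
    idx = np.concatenate([np.full(a.size, i, float) for i, a in enumerate(arrays)])
    y = np.concatenate(arrays)
    if trend_method == "jonckheere":
        tau, p = kendalltau(idx, y)
        return {"tau": float(tau), "p": float(p)}
    res = linregress(idx, y)
    return {"slope": float(res.slope), "p": float(res.pvalue)}


def km_logrank(
    surv: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    group_col: str = "group",
) -> tuple[Mapping[str, pd.DataFrame], float, float]:
    """Kaplan–Meier curves per group and a two-sided log-rank test.

    Expects exactly two non-empty groups and at least one event overall (a
    fully censored group is allowed: it contributes risk-set shrinkage
    only).  Returns ({group: survival-curve DataFrame}, chi-square with
    1 df, p).
    """
    if (surv[time_col] < 0).any():
        raise ValueError("negative survival times")
    if not surv[event_col].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    labels = list(pd.unique(surv[group_col].dropna()))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    if surv[event_col].sum() == 0:
        raise ValueError("no events")
    curves: dict[str, pd.DataFrame] = {}
    for g in labels:
        sub = surv[surv[group_col] == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        curves[g] = kmf.survival_function_
    a = surv[surv[group_col] == labels[0]]
    b = surv[surv[group_col] == labels[1]]
    res = logrank_test(
        a[time_col], b[time_col], event_observed_A=a[event_col], event_observed_B=b[event_col]
    )
    return curves, float(res.test_statistic), float(res.p_value)
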