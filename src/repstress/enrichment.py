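"""Ranked-list enrichment machinery.

Implements the weighted Kolmogorov–Smirnov running-sum statistic of classic
two-group GSEA (enrichment score, leading-edge subset, permutation
significance) and the single-sample variant (ssGSEA), plus Benjamini–Hochberg
multiple-testing adjustment.  These primitives drive both the neuroendocrine
status call (two 25-gene ssGSEA scores per sample) and the signature
derivation (Hallmark-style enrichment per characteristic contrast with
leading-edge extraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankedList",
    "GeneSet",
    "EnrichmentResult",
    "gsea_es",
    "gsea_leading_edge",
    "gsea_significance",
    "ssgsea_es",
    "bh_adjust",
    "rank_by_signal_to_noise",
    "rank_by_mean_difference",
]


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a real-valued metric, best (largest) first.

    ``genes`` must be unique and ``metric`` non-increasing; equal metrics are
    broken by gene identifier upstream so the ordering is deterministic.
    """

    genes: tuple[str, ...]
    metric: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric must have equal length")
        if len(self.genes) < 2:
            raise ValueError("ranked list needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list genes must be unique")
        if any(a < b for a, b in zip(self.metric, self.metric[1:])):
            raise ValueError("metric must be sorted non-increasing")

    @classmethod
    def from_metric(cls, metric: pd.Series) -> "RankedList":
        """Build a ranked list from an unordered gene → metric mapping.

        Ties are broken by gene identifier (ascending) for determinism.
        """
        s = metric.dropna()
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return cls(tuple(order), tuple(float(s[g]) for g in order))


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(members))


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float | None
    p_raw: float
    p_adj: float
    leading_edge: tuple[str, ...] = field(default_factory=tuple)


def _hit_mask(ranked: RankedList, s: GeneSet) -> np.ndarray:
    mask = np.fromiter((g in s.members for g in ranked.genes), bool, len(ranked.genes))
    if not mask.any():
        raise ValueError("empty gene set on list")
    if mask.all():
        raise ValueError("no complement")
    return mask


def _running_sum(metric: np.ndarray, hits: np.ndarray, exponent: float) -> np.ndarray:
    """Running sum of the weighted KS statistic over ranked positions.

    Hit steps are |metric|^exponent normalised to total 1; miss steps are
    uniform decrements of 1/(N - #hits).
    """
    w = np.abs(metric) ** exponent
    hit_total = w[hits].sum()
    steps = np.where(hits, 0.0, -1.0 / (len(metric) - hits.sum()))
    if hit_total > 0:
        steps = np.where(hits, w / hit_total, steps)
    else:  # all hit weights zero: fall back to unweighted steps
        steps = np.where(hits, 1.0 / hits.sum(), steps)
    return np.cumsum(steps)


def gsea_es(ranked: RankedList, s: GeneSet, exponent: float = 1.0) -> float:
    """Signed maximum deviation of the GSEA running sum."""
    hits = _hit_mask(ranked, s)
    rs = _running_sum(np.asarray(ranked.metric), hits, exponent)
    i = int(np.argmax(np.abs(rs)))
    return float(np.clip(rs[i], -1.0, 1.0))  # guard cumsum round-off


def gsea_leading_edge(
    ranked: RankedList, s: GeneSet, exponent: float = 1.0
) -> tuple[str, ...]:
    """Set members at/before the running-sum peak (ES>0) or at/after the
    trough (ES<0), in rank order."""
    hits = _hit_mask(ranked, s)
    rs = _running_sum(np.asarray(ranked.metric), hits, exponent)
    i = int(np.argmax(np.abs(rs)))
    if rs[i] >= 0:
        keep = np.zeros_like(hits)
        keep[: i + 1] = True
    else:
        keep = np.zeros_like(hits)
        keep[i:] = True
    return tuple(g for g, h, k in zip(ranked.genes, hits, keep) if h and k)


def rank_by_signal_to_noise(
    expr: pd.DataFrame, labels: pd.Series, sd_floor_frac: float = 0.1
) -> pd.Series:
    """Per-gene signal-to-noise ratio (positive minus negative group).

    ``expr`` is genes × samples; ``labels`` is boolean per sample.  Group
    standard deviations are floored at ``sd_floor_frac``·|group mean| (and a
    small absolute floor) following GSEA convention, keeping the metric
    finite for near-constant genes.
    """
    labels = labels.reindex(expr.columns).astype(bool)
    pos, neg = expr.loc[:, labels.values], expr.loc[:, ~labels.values]
    if pos.shape[1] == 0 or neg.shape[1] == 0:
        raise ValueError("both label groups must be non-empty")
    m1, m0 = pos.mean(axis=1), neg.mean(axis=1)
    s1 = np.maximum(pos.std(axis=1, ddof=1), np.maximum(sd_floor_frac * m1.abs(), 1e-8))
    s0 = np.maximum(neg.std(axis=1, ddof=1), np.maximum(sd_floor_frac * m0.abs(), 1e-8))
    return (m1 - m0) / (s1 + s0)


def rank_by_mean_difference(expr: pd.DataFrame, labels: pd.Series) -> pd.Series:
    labels = labels.reindex(expr.columns).astype(bool)
    pos, neg = expr.loc[:, labels.values], expr.loc[:, ~labels.values]
    if pos.shape[1] == 0 or neg.shape[1] == 0:
        raise ValueError("both label groups must be non-empty")
    return pos.mean(axis=1) - neg.mean(axis=1)


def _batch_es(metric: np.ndarray, hit_idx: np.ndarray, exponent: float) -> np.ndarray:
    """ES for many same-size gene sets given by ranked-position indices.

    ``hit_idx`` is (n_sets, k) integer positions into the ranked metric.
    Vectorised over sets: one cumulative sum per batch.
    """
    n_sets, k = hit_idx.shape
    n = metric.size
    w = np.abs(metric) ** exponent
    steps = np.full((n_sets, n), -1.0 / (n - k))
    rows = np.repeat(np.arange(n_sets), k)
    hw = w[hit_idx]
    tot = hw.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    steps[rows, hit_idx.ravel()] = (hw / tot).ravel()
    rs = np.cumsum(steps, axis=1)
    i = np.argmax(np.abs(rs), axis=1)
    return np.clip(rs[np.arange(n_sets), i], -1.0, 1.0)


def gsea_significance(
    expr: pd.DataFrame,
    labels: pd.Series,
    sets: Sequence[GeneSet],
    n_perm: int = 1000,
    scheme: Literal["gene_set", "phenotype"] = "gene_set",
    seed: int | None = None,
    exponent: float = 1.0,
    metric: Literal["signal_to_noise", "mean_difference"] = "signal_to_noise",
) -> list[EnrichmentResult]:
    """Two-group GSEA over a set collection with permutation p-values.

    Expression is genes × samples; ``labels`` marks the positive group.
    ``gene_set`` permutation redraws random sets of matching size from the
    ranked genes; ``phenotype`` permutation reshuffles sample labels.  Raw
    p-values use the add-one estimator (1 + #{|ES*| ≥ |ES|}) / (1 + n_perm)
    and are BH-adjusted across sets.  NES divides ES by the mean |null ES| of
    the same sign (None if no same-sign nulls).  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("seed is required for permutation significance")
    labels = labels.reindex(expr.columns).astype(bool)
    if scheme == "phenotype" and (labels.sum() < 2 or (~labels).sum() < 2):
        raise ValueError("phenotype permutation needs >= 2 samples per group")
    rank_fn = (
        rank_by_signal_to_noise if metric == "signal_to_noise" else rank_by_mean_difference
    )
    ranked = RankedList.from_metric(rank_fn(expr, labels))
    metric_arr = np.asarray(ranked.metric)
    pos_of = {g: i for i, g in enumerate(ranked.genes)}
    rng = np.random.default_rng(seed)

    results: list[EnrichmentResult] = []
    perm_labels = None
    if scheme == "phenotype":
        lab = labels.values
        perm_labels = [rng.permutation(lab) for _ in range(n_perm)]
    for s in sets:
        es = gsea_es(ranked, s, exponent)
        le = gsea_leading_edge(ranked, s, exponent)
        k = sum(1 for g in s.members if g in pos_of)
        if scheme == "gene_set":
            u = rng.random((n_perm, len(ranked.genes)))
            idx = np.argpartition(u, k, axis=1)[:, :k]
            null = _batch_es(metric_arr, idx, exponent)
        else:
            null = np.empty(n_perm)
            for i, pl in enumerate(perm_labels):
                r = RankedList.from_metric(
                    rank_fn(expr, pd.Series(pl, index=expr.columns))
                )
                null[i] = gsea_es(r, s, exponent)
        p_raw = (1 + np.sum(np.abs(null) >= abs(es))) / (1 + n_perm)
        same_sign = null[null > 0] if es > 0 else null[null < 0]
        nes = float(es / np.abs(same_sign).mean()) if same_sign.size else None
        results.append(EnrichmentResult(s.name, float(es), nes, float(p_raw), 1.0, le))

    adj = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adj):
        r.p_adj = float(q)
    return results


def _ssgsea_sum(ranks: np.ndarray, hits: np.ndarray, exponent: float) -> float:
    """Raw ssGSEA statistic: summed gap between the rank-weighted hit ECDF
    and the uniform miss ECDF along the ranking (largest rank first)."""
    order = np.argsort(-ranks, kind="stable")
    h = hits[order]
    w = ranks[order] ** exponent
    hit_cdf = np.cumsum(np.where(h, w, 0.0)) / w[h].sum()
    miss_cdf = np.cumsum(~h) / (h.size - h.sum())
    return float(np.sum(hit_cdf - miss_cdf))


def ssgsea_es(
    sample_expr: pd.Series, s: GeneSet, exponent: float = 0.25
) -> float:
    """Single-sample GSEA enrichment score in [-1, 1].

    Genes are ranked by expression within the sample (average ranks for
    ties), so the score is invariant to any strictly increasing transform of
    the expression values.  The raw ECDF-difference sum is scaled by the
    extreme sum attainable for the same list length / set size / exponent
    (all hits at the top for positive sums, at the bottom for negative ones),
    which bounds the score to [-1, 1].
    """
    sample_expr = sample_expr.dropna()
    members = [g in s.members for g in sample_expr.index]
    hits = np.array(members, dtype=bool)
    if not hits.any():
        raise ValueError("empty gene set on list")
    if hits.all():
        raise ValueError("no complement")
    vals = sample_expr.to_numpy(float)
    if np.unique(vals).size == 1:
        raise ValueError("degenerate ranks")
    ranks = rankdata(vals)  # average ranks; 1 = lowest expression
    raw = _ssgsea_sum(ranks, hits, exponent)

    n, k = hits.size, int(hits.sum())
    ideal = np.arange(n, 0, -1.0)  # tie-free ranks, descending
    top = np.zeros(n, bool)
    top[:k] = True
    d_pos = _ssgsea_sum(ideal, top, exponent)
    bottom = np.zeros(n, bool)
    bottom[-k:] = True
    d_neg = abs(_ssgsea_sum(ideal, bottom, exponent))
    denom = d_pos if raw >= 0 else d_neg
    return float(raw / denom) if denom > 0 else 0.0


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
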