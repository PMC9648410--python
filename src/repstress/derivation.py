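"""Signature discovery pipeline.

Stages, mirroring the derivation of the packaged 17-gene signature:

1. per-characteristic two-group GSEA over a Hallmark-style collection;
2. gene sets positively enriched (adjusted P below cutoff) in *every*
   characteristic contrast ("shared sets");
3. genes in the leading edge of every shared set in every contrast
   ("shared leading-edge genes");
4. genes up in NE-high samples at Mann–Whitney BH-FDR < 10% in every
   supplied cohort, intersected with a DNA-damage-repair gene list;
5. prevalence-based exclusion of genes rarely expressed outside the
   derivation lineage (the KPNA2-style rule);
6. PC1-loading weights from a joint PCA over the four characteristic scores
   and the candidate genes' expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator

from .enrichment import EnrichmentResult, GeneSet, bh_adjust, gsea_significance

__all__ = [
    "DerivationConfig",
    "SignatureDeriver",
    "shared_enriched_sets",
    "shared_leading_edge_genes",
    "ne_de_genes",
    "prevalence_filter",
    "derive_pca_weights",
    "pc1_loadings",
    "assemble_signature",
]


@dataclass
class DerivationConfig:
    adj_p_cutoff: float = 0.05
    de_fdr_cutoff: float = 0.10
    prevalence_floor: float = 1.0        # log2 expression units
    prevalence_min_fraction: float = 0.10
    ddr_genes: tuple[str, ...] = ()
    exclusions: tuple[str, ...] = ()
    n_perm: int = 1000
    perm_scheme: Literal["gene_set", "phenotype"] = "gene_set"
    gsea_exponent: float = 1.0
    min_support: int | None = None       # relax the strict leading-edge intersection
    pca_mode: Literal["joint", "supplementary"] = "joint"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.adj_p_cutoff < 1) or not (0 < self.de_fdr_cutoff < 1):
            raise ValueError("cutoffs must lie in (0, 1)")
        if not (0 <= self.prevalence_min_fraction <= 1):
            raise ValueError("prevalence_min_fraction must lie in [0, 1]")


def shared_enriched_sets(
    results: Mapping[str, Sequence[EnrichmentResult]], adj_p_cutoff: float = 0.05
) -> list[str]:
    """Set names positively enriched at p_adj < cutoff in every contrast."""
    if not results:
        return []
    collections = [frozenset(r.set_name for r in res) for res in results.values()]
    if len(set(collections)) > 1:
        raise ValueError("contrasts cover different set collections")
    shared: set[str] | None = None
    for res in results.values():
        ok = {r.set_name for r in res if r.p_adj < adj_p_cutoff and r.es > 0}
        shared = ok if shared is None else shared & ok
    first = next(iter(results.values()))
    order = [r.set_name for r in first]
    return [s for s in order if s in shared]


def shared_leading_edge_genes(
    results: Mapping[str, Sequence[EnrichmentResult]],
    shared_sets: Sequence[str],
    min_support: int | None = None,
) -> list[str]:
    """Genes in the leading edge of every shared set in every contrast.

    ``min_support`` relaxes the strict rule: a gene is kept when it appears
    in at least that many of the (set, contrast) leading edges.
    """
    if len(shared_sets) < 2:
        raise ValueError("nothing to intersect: need >= 2 shared sets")
    edges: list[tuple[str, ...]] = []
    order: list[str] = []
    for res in results.values():
        by_name = {r.set_name: r for r in res}
        for s in shared_sets:
            le = by_name[s].leading_edge
            edges.append(le)
            for g in le:
                if g not in order:
                    order.append(g)
    need = len(edges) if min_support is None else min(min_support, len(edges))
    counts = {g: sum(g in e for e in edges) for g in order}
    return [g for g in order if counts[g] >= need]


def ne_de_genes(
    cohorts: Sequence[tuple[pd.DataFrame, pd.Series]],
    fdr_cutoff: float = 0.10,
    ddr_genes: Sequence[str] | None = None,
) -> list[str]:
    """Genes up in NE-high at Mann–Whitney BH-FDR < cutoff in every cohort.

    Each cohort is (genes × samples expression, boolean NE-high labels).
    Only genes with a higher NE-high median qualify; the surviving
    intersection is further intersected with ``ddr_genes`` when given.
    """
    if not cohorts:
        raise ValueError("need >= 1 cohort")
    kept: set[str] | None = None
    order: list[str] = []
    for expr, labels in cohorts:
        labels = labels.reindex(expr.columns).astype(bool)
        if labels.sum() < 2 or (~labels).sum() < 2:
            raise ValueError("each cohort needs >= 2 samples per NE class")
        hi = expr.loc[:, labels.values].to_numpy()
        lo = expr.loc[:, (~labels).values].to_numpy()
        _, p = mannwhitneyu(hi, lo, axis=1, alternative="two-sided")
        p_adj = bh_adjust(p)
        up = np.median(hi, axis=1) > np.median(lo, axis=1)
        hits = set(expr.index[(p_adj < fdr_cutoff) & up])
        kept = hits if kept is None else kept & hits
        for g in expr.index:
            if g not in order:
                order.append(g)
    if ddr_genes is not None:
        kept &= set(ddr_genes)
    return [g for g in order if g in kept]


def prevalence_filter(
    expr_panels: Mapping[str, pd.DataFrame],
    candidates: Sequence[str],
    floor: float = 1.0,
    min_fraction: float = 0.10,
    derivation_lineage: str | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop candidates rarely expressed outside the derivation lineage.

    A gene is retained iff the fraction of non-derivation-lineage samples
    expressing it above ``floor`` is at least ``min_fraction``.  Returns the
    retained genes and a per-gene report (fraction, retained flag).
    """
    other = {k: v for k, v in expr_panels.items() if k != derivation_lineage}
    if not other:
        raise ValueError("no non-derivation lineage panel provided")
    pooled = pd.concat(other.values(), axis=1)
    rows = []
    retained = []
    for g in candidates:
        if g in pooled.index:
            frac = float((pooled.loc[g] > floor).mean())
        else:
            frac = 0.0
        keep = frac >= min_fraction
        rows.append({"gene": g, "expressed_fraction": frac, "retained": keep})
        if keep:
            retained.append(g)
    return retained, pd.DataFrame(rows).set_index("gene")


def pc1_loadings(x: pd.DataFrame, orient_cols: Sequence[str]) -> pd.Series:
    """Unit-norm first-principal-component loadings of a column-z-scored
    matrix, with PC1 signed so the ``orient_cols`` loadings sum positive."""
    if x.shape[0] < 3:
        raise ValueError("need >= 3 samples for PCA")
    sd = x.std(ddof=1)
    if (sd == 0).any() or sd.isna().any():
        raise ValueError(f"constant variable: {list(sd.index[(sd == 0) | sd.isna()])}")
    z = (x - x.mean()) / sd
    _, _, vt = np.linalg.svd(z.to_numpy(float), full_matrices=False)
    load = pd.Series(vt[0], index=x.columns)
    if load.loc[list(orient_cols)].sum() < 0:
        load = -load
    return load


def derive_pca_weights(
    char_scores: pd.DataFrame,
    candidate_expr: pd.DataFrame,
    mode: Literal["joint", "supplementary"] = "joint",
) -> pd.Series:
    """PC1-loading weight per candidate gene.

    ``char_scores`` is samples × 4 characteristic scores and
    ``candidate_expr`` samples × genes; both are z-scored per column.  In
    ``joint`` mode the PCA runs over the concatenated matrix and the gene
    weights are the gene-variable PC1 loadings; in ``supplementary`` mode the
    PCA runs over the characteristics only and each gene is projected onto
    PC1 as a supplementary variable (its correlation-weighted loading).  PC1
    is oriented so the four characteristic loadings sum positive.
    """
    common = char_scores.index.intersection(candidate_expr.index)
    if len(common) < 3:
        raise ValueError("need >= 3 shared samples for PCA")
    chars = char_scores.loc[common]
    genes = candidate_expr.loc[common]
    overlap = chars.columns.intersection(genes.columns)
    if len(overlap):
        raise ValueError(f"characteristic/gene name collision: {list(overlap)}")
    if mode == "joint":
        combined = pd.concat([chars, genes], axis=1)
        load = pc1_loadings(combined, chars.columns)
        return load.loc[genes.columns].rename("weight")
    # supplementary: PCA on characteristics, genes projected afterwards
    load = pc1_loadings(chars, chars.columns)
    sd = chars.std(ddof=1)
    z = (chars - chars.mean()) / sd
    pc1 = z.to_numpy(float) @ load.to_numpy()
    gsd = genes.std(ddof=1)
    if (gsd == 0).any():
        raise ValueError(f"constant variable: {list(gsd.index[gsd == 0])}")
    gz = (genes - genes.mean()) / gsd
    denom = float(pc1 @ pc1)
    w = gz.to_numpy(float).T @ pc1 / denom
    return pd.Series(w, index=genes.columns, name="weight")


def assemble_signature(
    leading_edge: Sequence[str],
    ne_repair: Sequence[str],
    exclusions: Sequence[str],
    weights: pd.Series,
    provenance: dict | None = None,
) -> tuple[pd.Series, dict]:
    """Ordered union of the two gene lists minus exclusions, with weights.

    Returns (gene → weight series in signature order, provenance dict).
    Raises when a retained gene lacks a weight.
    """
    seen: list[str] = []
    for g in list(leading_edge) + list(ne_repair):
        if g not in seen and g not in set(exclusions):
            seen.append(g)
    missing = [g for g in seen if g not in weights.index]
    if missing:
        raise ValueError(f"retained gene(s) without weight: {missing}")
    sig = weights.loc[seen].astype(float).rename("weight")
    if len(sig) and not (sig != 0).any():
        raise ValueError("signature has no nonzero weight")
    prov = dict(provenance or {})
    prov.setdefault("n_leading_edge", len(set(leading_edge)))
    prov.setdefault("n_ne_repair", len(set(ne_repair)))
    prov.setdefault("exclusions", sorted(exclusions))
    return sig, prov


@dataclass
class _DerivationReport:
    shared_sets: list[str] = field(default_factory=list)
    leading_edge: list[str] = field(default_factory=list)
    ne_repair: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


class SignatureDeriver(BaseEstimator):
    """End-to-end signature derivation as an sklearn-style estimator.

    ``fit`` consumes a derivation cohort — genes × samples expression, one
    boolean label series per characteristic contrast, a Hallmark-style set
    collection, NE-labelled differential-expression cohorts and a
    DNA-damage-repair gene list — and exposes the derived signature and the
    intermediate gene lists as fitted attributes.
    """

    def __init__(self, config: DerivationConfig | None = None) -> None:
        self.config = config

    def fit(
        self,
        expr: pd.DataFrame,
        contrasts: Mapping[str, pd.Series] = None,
        hallmark_sets: Sequence[GeneSet] = (),
        de_cohorts: Sequence[tuple[pd.DataFrame, pd.Series]] = (),
        expr_panels: Mapping[str, pd.DataFrame] | None = None,
        derivation_lineage: str | None = None,
        char_scores: pd.DataFrame | None = None,
    ) -> "SignatureDeriver":
        cfg = self.config or DerivationConfig()
        if not contrasts:
            raise ValueError("need >= 1 characteristic contrast")
        results: dict[str, list[EnrichmentResult]] = {}
        for name, labels in contrasts.items():
            results[name] = gsea_significance(
                expr,
                labels,
                hallmark_sets,
                n_perm=cfg.n_perm,
                scheme=cfg.perm_scheme,
                seed=cfg.seed,
                exponent=cfg.gsea_exponent,
            )
        report = _DerivationReport()
        report.shared_sets = shared_enriched_sets(results, cfg.adj_p_cutoff)
        report.leading_edge = shared_leading_edge_genes(
            results, report.shared_sets, cfg.min_support
        )
        report.ne_repair = (
            ne_de_genes(de_cohorts, cfg.de_fdr_cutoff, cfg.ddr_genes or None)
            if de_cohorts
            else []
        )
        candidates = list(dict.fromkeys(report.leading_edge + report.ne_repair))
        exclusions = list(cfg.exclusions)
        if expr_panels:
            _, prev = prevalence_filter(
                expr_panels,
                candidates,
                cfg.prevalence_floor,
                cfg.prevalence_min_fraction,
                derivation_lineage,
            )
            exclusions += list(prev.index[~prev["retained"]])
        report.excluded = sorted(set(exclusions) & set(candidates))
        retained = [g for g in candidates if g not in set(exclusions)]
        if char_scores is None:
            raise ValueError("char_scores (samples × 4) are required for weighting")
        weights = derive_pca_weights(
            char_scores, expr.loc[retained].T, mode=cfg.pca_mode
        )
        prov = {
            "adj_p_cutoff": cfg.adj_p_cutoff,
            "de_fdr_cutoff": cfg.de_fdr_cutoff,
            "n_perm": cfg.n_perm,
            "perm_scheme": cfg.perm_scheme,
            "seed": cfg.seed,
            "pca_mode": cfg.pca_mode,
            "shared_sets": report.shared_sets,
        }
        self.signature_, self.provenance_ = assemble_signature(
            report.leading_edge, report.ne_repair, exclusions, weights, prov
        )
        self.enrichment_results_ = results
        self.shared_sets_ = report.shared_sets
        self.leading_edge_ = report.leading_edge
        self.ne_repair_genes_ = report.ne_repair
        self.excluded_genes_ = report.excluded
        return self
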