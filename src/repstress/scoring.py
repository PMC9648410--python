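"""Replication-stress score computation.

The score for a sample is the weighted sum of its signature-gene z-scores,
where the z-scoring runs *within the sample across all measured genes* —
this makes the score invariant to per-sample affine shifts/scalings of
log-expression (array vs RNA-seq scale differences).  Scores are then
z-normalised across the samples of the analysis cohort.  Extremes are
classified by the >= 75th / < 25th percentile rule used for drug-sensitivity
and survival contrasts, and lineage enrichment is counted against the 95%
confidence interval of the cohort mean score.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RepstressScorer",
    "zscore_within_sample",
    "repstress_raw",
    "normalize_scores",
    "classify_extremes",
    "ci_enrichment_fraction",
    "score_cohort",
]


def zscore_within_sample(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each sample (column) across all of its genes, sd with n−1."""
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes per sample")
    sd = expr.std(axis=0, ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = list(sd.index[(sd == 0) | sd.isna()])
        raise ValueError(f"degenerate sample: {bad}")
    return (expr - expr.mean(axis=0)) / sd


def repstress_raw(
    zexpr: pd.DataFrame,
    weights: pd.Series,
    missing_policy: Literal["error", "renormalize"] = "error",
) -> pd.Series:
    """Weighted sum of signature-gene z-scores per sample.

    Under ``renormalize`` the weights of the present genes are rescaled so
    their absolute sum matches the full signature's, with a warning; under
    ``error`` any absent signature gene aborts with the missing symbols.
    """
    present = weights.index.intersection(zexpr.index)
    missing = weights.index.difference(zexpr.index)
    if len(present) == 0:
        raise ValueError("no signature gene present in the expression matrix")
    w = weights.loc[present]
    if len(missing) > 0:
        if missing_policy == "error":
            raise ValueError(
                f"signature genes absent from matrix: {sorted(missing)}"
            )
        scale = weights.abs().sum() / w.abs().sum()
        warnings.warn(
            f"{len(missing)} signature gene(s) absent; weights renormalized",
            stacklevel=2,
        )
        w = w * scale
    return zexpr.loc[present].mul(w, axis=0).sum(axis=0).rename("raw_score")


def normalize_scores(raw: pd.Series) -> pd.Series:
    """Z-normalise scores across the analysis cohort (sd with n−1)."""
    if len(raw) < 2:
        raise ValueError("need >= 2 samples")
    sd = raw.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("degenerate score distribution")
    return ((raw - raw.mean()) / sd).rename("norm_score")


def classify_extremes(
    scores: pd.Series, hi_pct: float = 75.0, lo_pct: float = 25.0
) -> pd.Series:
    """high iff score >= hi_pct percentile, low iff strictly below the
    lo_pct percentile, else mid.  Percentiles use linear interpolation."""
    if len(scores) < 4:
        raise ValueError("need >= 4 samples to classify extremes")
    q_hi = float(np.percentile(scores, hi_pct))
    q_lo = float(np.percentile(scores, lo_pct))
    if q_hi <= q_lo:
        raise ValueError("degenerate score distribution")
    out = pd.Series("mid", index=scores.index, name="group")
    out[scores >= q_hi] = "high"
    out[scores < q_lo] = "low"
    return out


def ci_enrichment_fraction(
    scores: pd.Series,
    subgroup: list[str] | pd.Index,
    side: Literal["above", "below"] = "above",
    ci_mode: Literal["mean", "reference"] = "mean",
) -> tuple[int, float]:
    """Count subgroup samples beyond the cohort 95% confidence bound.

    ``mean`` mode (default) uses the CI of the cohort mean,
    mean ± 1.96·sd/√n; ``reference`` mode uses a 95% reference interval of
    the score distribution, mean ± 1.96·sd.  Returns (count, fraction of the
    subgroup beyond the bound).
    """
    subgroup = pd.Index(subgroup)
    if len(subgroup) == 0:
        raise ValueError("empty subgroup")
    if not subgroup.isin(scores.index).all():
        raise ValueError("subgroup contains samples outside the cohort")
    if len(scores) < 3:
        raise ValueError("cohort too small")
    mean, sd = scores.mean(), scores.std(ddof=1)
    half = 1.96 * sd / np.sqrt(len(scores)) if ci_mode == "mean" else 1.96 * sd
    vals = scores.loc[subgroup]
    hits = vals >= mean + half if side == "above" else vals <= mean - half
    count = int(hits.sum())
    return count, count / len(subgroup)


class RepstressScorer(BaseEstimator, TransformerMixin):
    """Score samples with a weighted gene signature, sklearn-style.

    Parameters
    ----------
    signature : pd.Series or None
        Gene → weight mapping.  ``None`` loads the packaged 17-gene
        replication-stress signature.
    missing_policy : {"error", "renormalize"}
        What to do when signature genes are absent from the matrix.
    hi_pct, lo_pct : float
        Percentile cutoffs for the high/low extreme groups.

    ``fit`` validates the signature against the cohort's gene universe;
    ``transform`` returns per-sample raw scores (within-sample z-scored
    expression times weights).  ``score_table`` adds the cohort-normalised
    score and the extreme-group label, which are cohort-level quantities and
    therefore live outside ``transform``.

    X is samples × features (sklearn orientation); the library-level
    functions in this module use the genes × samples domain convention.
    """

    def __init__(
        self,
        signature: pd.Series | None = None,
        missing_policy: Literal["error", "renormalize"] = "error",
        hi_pct: float = 75.0,
        lo_pct: float = 25.0,
    ) -> None:
        self.signature = signature
        self.missing_policy = missing_policy
        self.hi_pct = hi_pct
        self.lo_pct = lo_pct

    def _weights(self) -> pd.Series:
        if self.signature is None:
            from .datasets import repstress_signature

            return repstress_signature()
        return pd.Series(self.signature, dtype=float)

    def fit(self, X: pd.DataFrame, y=None) -> "RepstressScorer":
        X = self._validate(X)
        w = self._weights()
        present = w.index.intersection(X.columns)
        if self.missing_policy == "error" and len(present) < len(w):
            raise ValueError(
                "signature genes absent from matrix: "
                f"{sorted(w.index.difference(X.columns))}"
            )
        if len(present) == 0:
            raise ValueError("no signature gene present in the expression matrix")
        self.weights_ = w
        self.genes_used_ = list(present)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        check_is_fitted(self, "weights_")
        X = self._validate(X)
        zexpr = zscore_within_sample(X.T)
        return repstress_raw(zexpr, self.weights_, self.missing_policy)

    def score_table(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full per-cohort score table: raw, cohort-normalised, group."""
        raw = self.transform(X)
        norm = normalize_scores(raw)
        group = classify_extremes(norm, self.hi_pct, self.lo_pct)
        out = pd.DataFrame(
            {"raw_score": raw, "norm_score": norm, "group": group}
        )
        out.index.name = "sample_id"
        return out

    @staticmethod
    def _validate(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples × genes DataFrame")
        if X.isna().any().any():
            raise ValueError("expression matrix contains NaN")
        return X


def score_cohort(
    expr: pd.DataFrame,
    weights: pd.Series,
    missing_policy: Literal["error", "renormalize"] = "error",
    hi_pct: float = 75.0,
    lo_pct: float = 25.0,
) -> pd.DataFrame:
    """Score a genes × samples cohort; thin wrapper over RepstressScorer."""
    scorer = RepstressScorer(weights, missing_policy, hi_pct, lo_pct)
    return scorer.fit(expr.T).score_table(expr.T)
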