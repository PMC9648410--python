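"""The four replication-stress characteristics of a cell-line cohort.

Each characteristic pairs a continuous per-sample score with a binary call:

* MYC-paralog amplification — max copy-number score over MYC/MYCL/MYCN,
  amplified at >= 0.7;
* checkpoint-inhibitor sensitivity — max drug-activity z-score over a CHK1
  and a WEE1 inhibitor, sensitive at strictly > 6;
* phospho-Chk1 (S345) — RPPA value, high at strictly > 0.15;
* neuroendocrine differentiation — ssGSEA score of 25 high-NE genes minus
  ssGSEA score of 25 low-NE genes, NE-high when the difference is > 0
  (ties classify low).
"""

from __future__ import annotations

import pandas as pd

from .enrichment import GeneSet, ssgsea_es

MYC_PARALOGS = ("MYC", "MYCL", "MYCN")
CHECKPOINT_DRUGS = ("AZD-7762", "MK-1775")
PCHK1_ANTIBODY = "Chk1_pS345"

MYC_CN_CUTOFF = 0.7       # inclusive (>=)
CPI_ACTIVITY_CUTOFF = 6.0  # strict (>)
PCHK1_CUTOFF = 0.15        # strict (>)

CHARACTERISTICS = ("myc_cn_score", "cpi_activity", "pchk1_value", "ne_delta")


def call_myc_amplified(
    cn: pd.DataFrame, paralogs: tuple[str, ...] = MYC_PARALOGS
) -> pd.DataFrame:
    """Max copy-number score over MYC paralogs; amplified at >= 0.7."""
    present = [g for g in paralogs if g in cn.columns]
    if not present:
        raise ValueError(f"no MYC paralog column among {paralogs}")
    score = cn[present].max(axis=1)
    return pd.DataFrame(
        {"myc_cn_score": score, "myc_amp": score >= MYC_CN_CUTOFF}
    )


def call_checkpoint_sensitive(
    activity: pd.DataFrame, drugs: tuple[str, ...] = CHECKPOINT_DRUGS
) -> pd.DataFrame:
    """Max activity z over the checkpoint inhibitors; sensitive at > 6.

    Samples with no observed activity for any configured drug get a missing
    call (NA), never an imputed one.
    """
    present = [d for d in drugs if d in activity.columns]
    if not present:
        raise ValueError(f"no checkpoint-inhibitor column among {drugs}")
    score = activity[present].max(axis=1)
    call = (score > CPI_ACTIVITY_CUTOFF).astype("boolean")
    call[score.isna()] = pd.NA
    return pd.DataFrame({"cpi_activity": score, "cpi_sensitive": call})


def call_pchk1_high(
    rppa: pd.DataFrame, antibody: str = PCHK1_ANTIBODY
) -> pd.DataFrame:
    """Phospho-Chk1 RPPA value; high at strictly > 0.15."""
    if antibody not in rppa.columns:
        raise ValueError(f"RPPA column {antibody!r} absent")
    value = rppa[antibody]
    return pd.DataFrame(
        {"pchk1_value": value, "pchk1_high": value > PCHK1_CUTOFF}
    )


def ne_status(
    expr: pd.DataFrame,
    ne_high_set: GeneSet,
    ne_low_set: GeneSet,
    exponent: float = 0.25,
) -> pd.DataFrame:
    """Per-sample NE call from the two-set ssGSEA contrast.

    ``expr`` is genes × samples.  ne_delta = ES(high set) − ES(low set);
    NE-high iff ne_delta > 0 (a tie classifies low).
    """
    if ne_high_set.members & ne_low_set.members:
        raise ValueError("high- and low-NE sets must be disjoint")
    rows = {}
    for sample in expr.columns:
        col = expr[sample]
        hi = ssgsea_es(col, ne_high_set, exponent)
        lo = ssgsea_es(col, ne_low_set, exponent)
        rows[sample] = hi - lo
    delta = pd.Series(rows, name="ne_delta")
    return pd.DataFrame({"ne_delta": delta, "ne_high": delta > 0})


def build_characteristic_table(
    cn: pd.DataFrame,
    activity: pd.DataFrame,
    rppa: pd.DataFrame,
    expr: pd.DataFrame,
    ne_high_set: GeneSet,
    ne_low_set: GeneSet,
) -> pd.DataFrame:
    """Join the four characteristic calls/scores over the shared samples."""
    parts = [
        call_myc_amplified(cn),
        call_checkpoint_sensitive(activity),
        call_pchk1_high(rppa),
        ne_status(expr, ne_high_set, ne_low_set),
    ]
    table = pd.concat(parts, axis=1, join="inner")
    table.index.name = "sample_id"
    return table


def characteristic_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Samples × 4 matrix of z-scored continuous characteristic scores.

    Samples missing any characteristic are dropped (never imputed); a
    characteristic constant across the remaining samples is an error.
    """
    cols = list(CHARACTERISTICS)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"characteristic columns absent: {missing}")
    x = table[cols].dropna().astype(float)
    sd = x.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"degenerate characteristic: {bad}")
    return (x - x.mean()) / sd
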