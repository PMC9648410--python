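"""Packaged gene lists and the 17-gene replication-stress signature.

The gene symbols are the published signature components: 11 shared
leading-edge genes of the two commonly enriched cell-cycle Hallmark sets
(E2F targets, G2–M checkpoint) and 7 DNA-damage-repair genes up-regulated
with neuroendocrine differentiation, with KPNA2 excluded for its poor
prevalence outside SCLC.  The numeric weights are NOT the published ones
(those live in a supplementary table that is not redistributed): they are
synthetic, derived once from a fixed-seed reference cohort generated by
:mod:`repstress.simulate` via the package's own PCA-loading weighting, and
carry the published sign structure (all positive except POLD4 and POLE4).
"""

from __future__ import annotations

import pandas as pd

#: Shared leading-edge genes of the two cell-cycle Hallmark sets.
LEADING_EDGE_GENES: tuple[str, ...] = (
    "AURKB", "CCNA2", "GINS1", "KPNA2", "LIG3", "MTF2",
    "ORC6", "PRPS1", "SRSF1", "SUV39H1", "TNPO2",
)

#: DNA-damage-repair genes up-regulated in neuroendocrine-high samples.
NE_REPAIR_GENES: tuple[str, ...] = (
    "GADD45G", "POLA1", "POLD4", "POLE4", "RFC5", "RMI1", "RRM1",
)

#: Excluded for low expression prevalence outside the derivation lineage.
EXCLUDED_GENES: tuple[str, ...] = ("KPNA2",)

#: Genes whose published weights are negative.
NEGATIVE_WEIGHT_GENES: tuple[str, ...] = ("POLD4", "POLE4")

#: The 17 signature genes, in derivation order.
SIGNATURE_GENES: tuple[str, ...] = tuple(
    g for g in LEADING_EDGE_GENES if g not in EXCLUDED_GENES
) + NE_REPAIR_GENES

# Fixture-derived weights (synthetic reference cohort, seed 20240, joint
# PCA over the four characteristic scores and the 17 genes).  Regenerate
# with ``python -m repstress.datasets``.
_FIXTURE_WEIGHTS: dict[str, float] = {
    "AURKB": 0.2264,
    "CCNA2": 0.2048,
    "GINS1": 0.2247,
    "LIG3": 0.1996,
    "MTF2": 0.1745,
    "ORC6": 0.2071,
    "PRPS1": 0.2050,
    "SRSF1": 0.1898,
    "SUV39H1": 0.2180,
    "TNPO2": 0.1948,
    "GADD45G": 0.2096,
    "POLA1": 0.2059,
    "POLD4": -0.2050,
    "POLE4": -0.2142,
    "RFC5": 0.1961,
    "RMI1": 0.1918,
    "RRM1": 0.2087,
}


def repstress_signature() -> pd.Series:
    """The packaged 17-gene signature as a gene → weight series."""
    return pd.Series(
        {g: _FIXTURE_WEIGHTS[g] for g in SIGNATURE_GENES}, name="weight"
    )


def _regenerate_fixture_weights(seed: int = 20240) -> pd.Series:
    """Re-derive the packaged synthetic weights from the reference cohort."""
    from .derivation import derive_pca_weights
    from .simulate import GeneratorConfig, simulate_cohort
    from .stratification import build_characteristic_table, characteristic_scores

    cohort = simulate_cohort(GeneratorConfig(seed=seed))
    table = build_characteristic_table(
        cohort.cn, cohort.drugs, cohort.rppa, cohort.expr,
        cohort.ne_high_set, cohort.ne_low_set,
    )
    chars = characteristic_scores(table)
    return derive_pca_weights(
        chars, cohort.expr.loc[list(SIGNATURE_GENES)].T
    ).round(4)


if __name__ == "__main__":
    print(_regenerate_fixture_weights().to_string())
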