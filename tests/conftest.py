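import pandas as pd
import pytest

from repstress.enrichment import gsea_significance
from repstress.simulate import GeneratorConfig, simulate_cohort
from repstress.stratification import build_characteristic_table

CONTRAST_COLS = ("myc_amp", "cpi_sensitive", "pchk1_high", "ne_high")


@pytest.fixture(scope="session")
def default_cohort():
    """The stated-world cohort at seed 1 (n=60, 2000 genes)."""
    return simulate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_characteristics(default_cohort):
    c = default_cohort
    return build_characteristic_table(
        c.cn, c.drugs, c.rppa, c.expr, c.ne_high_set, c.ne_low_set
    )


def contrast_labels(table: pd.DataFrame) -> dict[str, pd.Series]:
    return {k: table[k].fillna(False).astype(bool) for k in CONTRAST_COLS}


@pytest.fixture(scope="session")
def derivation_results(default_cohort, default_characteristics):
    """Per-characteristic GSEA over the mock collection (seed 1, 1000 perms).

    Shared by the derivation-recovery acceptance checks.
    """
    c = default_cohort
    labels = contrast_labels(default_characteristics)
    return {
        name: gsea_significance(
            c.expr, lab, c.hallmark_sets, n_perm=1000, scheme="gene_set", seed=1
        )
        for name, lab in labels.items()
    }
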