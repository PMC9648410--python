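"""Seeded synthetic cohorts with a planted replication-stress factor.

The generator emulates the statistical structure of a characterized
cell-line cohort: a latent per-sample factor f ~ N(0, 1) drives (i)
expression of planted signature genes, (ii) the four characteristic
annotations (MYC-paralog copy number, checkpoint-inhibitor activity,
phospho-Chk1 RPPA, neuroendocrine marker expression), (iii) drug-activity
panels with signed class effects, and (iv) survival hazard.  Every stage of
the pipeline — derivation, scoring, association statistics, survival — can
therefore be tested against recorded ground truth with no external data.

Defaults state the emulated world: 60 samples (near the 67-line derivation
panel), 2,000 genes, unit expression noise, planted signal-gene loading 1.0
(≈ +1.5 SD shift between characteristic-positive and -negative samples),
two "signal" mock hallmark sets carrying the candidate genes plus disjoint
fillers, 20 decoy sets, and a log-2 hazard ratio per SD of factor for
survival.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .datasets import LEADING_EDGE_GENES, NE_REPAIR_GENES, NEGATIVE_WEIGHT_GENES
from .enrichment import GeneSet

SIGNAL_SET_NAMES = ("SIGNAL_E2F_LIKE", "SIGNAL_G2M_LIKE")


@dataclass(kw_only=True)
class GeneratorConfig:
    """Stated world of the synthetic cohort; ``seed`` is mandatory."""

    seed: int
    n_samples: int = 60
    n_genes: int = 2000
    noise_sd: float = 1.0
    signal_loading: float = 1.0
    ne_loading: float = 0.8
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    fillers_per_signal_set: int = 14
    n_decoy_sets: int = 20
    decoy_set_size: int = 25
    n_rs_drugs: int = 5
    n_mapk_drugs: int = 5
    n_inert_drugs: int = 10
    drug_effect: float = 1.0
    drug_noise_sd: float = 1.0
    char_noise: dict = field(
        default_factory=lambda: {"cn": 0.10, "drug": 0.30, "rppa": 0.03}
    )
    baseline_hazard: float = 0.1
    log_hazard_per_sd: float = float(np.log(2))
    censor_max: float = 30.0

    def __post_init__(self) -> None:
        n_planted = (
            len(LEADING_EDGE_GENES) + len(NE_REPAIR_GENES) + 50
        )
        if self.n_genes < n_planted + 2 * self.fillers_per_signal_set + 100:
            raise ValueError("n_genes too small for the planted structure")


@dataclass
class CohortTruth:
    """Ground truth recorded at generation time."""

    factor: pd.Series
    loadings: pd.Series
    signal_sets: tuple[str, ...]
    planted_leading_edge: tuple[str, ...]
    signature_genes: tuple[str, ...]
    ddr_genes: tuple[str, ...]
    drug_classes: dict[str, str]


@dataclass
class SyntheticCohort:
    expr: pd.DataFrame            # genes × samples
    cn: pd.DataFrame              # samples × MYC paralogs
    drugs: pd.DataFrame           # samples × drug columns
    rppa: pd.DataFrame            # samples × antibody columns
    hallmark_sets: list[GeneSet]  # 2 signal + decoys
    ne_high_set: GeneSet
    ne_low_set: GeneSet
    survival: pd.DataFrame | None
    truth: CohortTruth


def _gene_universe(cfg: GeneratorConfig) -> tuple[list[str], pd.Series]:
    """Gene names and latent-factor loadings of the stated world."""
    ne_high = [f"NEHI{i:03d}" for i in range(1, 26)]
    ne_low = [f"NELO{i:03d}" for i in range(1, 26)]
    planted = list(LEADING_EDGE_GENES) + list(NE_REPAIR_GENES)
    n_fill = cfg.n_genes - len(planted) - 50
    fillers = [f"G{i:05d}" for i in range(1, n_fill + 1)]
    genes = planted + ne_high + ne_low + fillers
    loadings = pd.Series(0.0, index=genes)
    for g in planted:
        loadings[g] = (
            -cfg.signal_loading if g in NEGATIVE_WEIGHT_GENES else cfg.signal_loading
        )
    loadings[ne_high] = cfg.ne_loading
    loadings[ne_low] = -cfg.ne_loading
    return genes, loadings


def _mock_sets(cfg: GeneratorConfig, fillers: list[str]) -> list[GeneSet]:
    """Two signal sets sharing the candidate genes (disjoint fillers) plus
    decoy sets of null genes."""
    sets = []
    k = cfg.fillers_per_signal_set
    for i, name in enumerate(SIGNAL_SET_NAMES):
        extra = fillers[i * k : (i + 1) * k]
        sets.append(GeneSet.from_iterable(name, list(LEADING_EDGE_GENES) + extra))
    pool = fillers[2 * k :]
    for d in range(cfg.n_decoy_sets):
        members = pool[d * cfg.decoy_set_size : (d + 1) * cfg.decoy_set_size]
        if len(members) < cfg.decoy_set_size:
            raise ValueError("not enough filler genes for decoy sets")
        sets.append(GeneSet.from_iterable(f"DECOY_{d + 1:02d}", members))
    return sets


def simulate_cohort(
    cfg: GeneratorConfig, with_survival: bool = False
) -> SyntheticCohort:
    """Generate a full synthetic cohort; bit-reproducible given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]
    genes, loadings = _gene_universe(cfg)
    f = pd.Series(rng.standard_normal(cfg.n_samples), index=samples, name="factor")

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    noise = rng.normal(0.0, cfg.noise_sd, size=(len(genes), cfg.n_samples))
    expr = pd.DataFrame(
        baseline[:, None] + np.outer(loadings.to_numpy(), f.to_numpy()) + noise,
        index=genes,
        columns=samples,
    )

    nz = cfg.char_noise
    cn = pd.DataFrame(
        {
            "MYC": 0.65 + 0.40 * f + rng.normal(0, nz["cn"], cfg.n_samples),
            "MYCL": 0.30 + rng.normal(0, nz["cn"], cfg.n_samples),
            "MYCN": 0.30 + rng.normal(0, nz["cn"], cfg.n_samples),
        },
        index=samples,
    )
    drug_cols = {
        "AZD-7762": 6.0 + 1.2 * f + rng.normal(0, nz["drug"], cfg.n_samples),
        "MK-1775": 5.8 + 1.0 * f + rng.normal(0, nz["drug"], cfg.n_samples),
    }
    classes: dict[str, str] = {}
    for i in range(cfg.n_rs_drugs):
        name = f"RS_DRUG_{i + 1:02d}"
        drug_cols[name] = cfg.drug_effect * f + rng.normal(
            0, cfg.drug_noise_sd, cfg.n_samples
        )
        classes[name] = "rs_targeting"
    for i in range(cfg.n_mapk_drugs):
        name = f"MAPK_DRUG_{i + 1:02d}"
        drug_cols[name] = -cfg.drug_effect * f + rng.normal(
            0, cfg.drug_noise_sd, cfg.n_samples
        )
        classes[name] = "mapk_like"
    for i in range(cfg.n_inert_drugs):
        name = f"INERT_DRUG_{i + 1:02d}"
        drug_cols[name] = rng.normal(0, cfg.drug_noise_sd, cfg.n_samples)
        classes[name] = "inert"
    drugs = pd.DataFrame(drug_cols, index=samples)
    rppa = pd.DataFrame(
        {"Chk1_pS345": 0.15 + 0.10 * f + rng.normal(0, nz["rppa"], cfg.n_samples)},
        index=samples,
    )

    ne_high = GeneSet.from_iterable(
        "NE_HIGH_25", [g for g in genes if g.startswith("NEHI")]
    )
    ne_low = GeneSet.from_iterable(
        "NE_LOW_25", [g for g in genes if g.startswith("NELO")]
    )
    fillers = [g for g in genes if g.startswith("G")]
    sets = _mock_sets(cfg, fillers)

    truth = CohortTruth(
        factor=f,
        loadings=loadings,
        signal_sets=SIGNAL_SET_NAMES,
        planted_leading_edge=LEADING_EDGE_GENES,
        signature_genes=tuple(
            list(LEADING_EDGE_GENES) + list(NE_REPAIR_GENES)
        ),
        ddr_genes=tuple(NE_REPAIR_GENES),
        drug_classes=classes,
    )
    surv = None
    if with_survival:
        surv = simulate_survival(cfg, f, seed=cfg.seed + 1)
    return SyntheticCohort(
        expr, cn, drugs, rppa, sets, ne_high, ne_low, surv, truth
    )


def simulate_treatment_dynamics(
    cfg: GeneratorConfig,
    drug_class: Literal["rs_inducer", "kinase_inhibitor"],
    n_pairs: int = 30,
    effect: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired pre/post expression matrices for a treatment class.

    ``rs_inducer`` shifts signature-gene expression along each gene's weight
    sign (raising the score post-treatment); ``kinase_inhibitor`` shifts
    opposite.  Returns (pre, post), both genes × samples with matching ids.
    """
    if drug_class not in ("rs_inducer", "kinase_inhibitor"):
        raise ValueError(f"unknown drug class: {drug_class!r}")
    rng = np.random.default_rng(cfg.seed + 7)
    samples = [f"P{i:03d}" for i in range(1, n_pairs + 1)]
    genes, loadings = _gene_universe(cfg)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    f = rng.standard_normal(n_pairs)
    base = baseline[:, None] + np.outer(loadings.to_numpy(), f)
    pre = base + rng.normal(0, cfg.noise_sd, (len(genes), n_pairs))
    sign = 1.0 if drug_class == "rs_inducer" else -1.0
    shift = np.zeros(len(genes))
    planted = list(LEADING_EDGE_GENES) + list(NE_REPAIR_GENES)
    gidx = {g: i for i, g in enumerate(genes)}
    for g in planted:
        direction = -1.0 if g in NEGATIVE_WEIGHT_GENES else 1.0
        shift[gidx[g]] = sign * effect * direction
    post = base + shift[:, None] + rng.normal(0, cfg.noise_sd, (len(genes), n_pairs))
    pre_df = pd.DataFrame(pre, index=genes, columns=samples)
    post_df = pd.DataFrame(post, index=genes, columns=samples)
    return pre_df, post_df


def simulate_survival(
    cfg: GeneratorConfig,
    factor: pd.Series,
    seed: int | None = None,
    beta: float | None = None,
) -> pd.DataFrame:
    """Exponential survival with hazard baseline·exp(beta·f) and independent
    uniform censoring on [0, censor_max]."""
    beta = cfg.log_hazard_per_sd if beta is None else beta
    if beta is None:
        raise ValueError("beta unspecified")
    if cfg.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    rng = np.random.default_rng(cfg.seed + 13 if seed is None else seed)
    f = factor.to_numpy(float)
    rate = cfg.baseline_hazard * np.exp(beta * f)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, cfg.censor_max, size=f.size)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if event.sum() == 0:
        raise ValueError("no events: everything censored")
    return pd.DataFrame(
        {"time": time, "event": event}, index=factor.index
    ).rename_axis("sample_id")
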