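"""Synthetic tumor-cohort generator with known ground truth.

The generator emulates the statistical structure of a bulk RNA-Seq cohort of
lung adenocarcinoma tumors with matched normals:

* log-normal expression (gene-specific baselines) — the pipeline consumes
  normalized values, not raw counts;
* a latent per-sample B-cell infiltration factor that co-upregulates the
  B-cell signature genes, and an analogous CD8+ T-cell factor (mildly
  correlated with the B factor, as infiltrates co-occur);
* PD-L1 (reserved gene ID ``CD274``, excluded from the signatures) generated
  as a linear function of the B factor plus Gaussian noise;
* proportional-hazards overall survival: exponential event times with hazard
  ``baseline_hazard * exp(log_hr_bcell*B + log_hr_stage*(stage-1))`` and
  independent exponential censoring;
* tumor stage thinned against the B factor (higher infiltration → earlier
  stage);
* optional group-wise pathway shifts (A → D → C fold ladder) as positive
  controls for the ΔNES and sequential fold-filter stages.

Every draw comes from one :class:`numpy.random.Generator`, so a fixed seed
reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection

__all__ = [
    "CohortSimulationParams",
    "simulate_cohort",
    "embed_group_pathway_shift",
    "published_pathway_table",
    "PDL1_GENE",
]

PDL1_GENE = "CD274"


@dataclass
class CohortSimulationParams:
    """Knobs of the synthetic cohort; defaults describe a TCGA-LUAD-like
    cohort (479 tumors with clinical data, 58 paired normals)."""

    n_tumor: int = 479
    n_normal_pairs: int = 58
    n_genes: int = 2000
    seed: int = 0
    bcell_set_size: int = 25
    tcell_set_size: int = 25
    infiltration_effect: float = 1.0  # log2-fold per unit latent factor
    pdl1_b_coefficient: float = 5.0
    pdl1_noise_sd: float = 12.0  # gives a moderate (~0.35) PD-L1/B correlation
    baseline_hazard: float = 1.0 / 1500.0  # events/day
    log_hr_bcell: float = float(np.log(0.6))
    log_hr_stage: float = float(np.log(1.7))
    censor_rate: float = 1.0 / 1800.0
    stage_b_coefficient: float = 0.8  # latent-stage shift per unit B factor
    bt_correlation: float = 0.3
    baseline_log2_range: tuple[float, float] = (5.0, 10.0)
    log2_noise_sd: float = 0.35
    pathway_shift_sets: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal_pairs", "n_genes", "bcell_set_size", "tcell_set_size"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        reserved = self.bcell_set_size + self.tcell_set_size + 1  # +1 for PD-L1
        if self.n_genes <= reserved:
            raise ValueError(
                f"n_genes={self.n_genes} leaves no background genes after "
                f"reserving {reserved} signature/PD-L1 genes"
            )
        if self.n_normal_pairs > self.n_tumor:
            raise ValueError("cannot pair more normals than tumors")
        for fold_pair in self.pathway_shift_sets:
            if fold_pair[1] <= 0 or fold_pair[2] <= 0:
                raise ValueError("pathway shift folds must be > 0")


# Baseline stage mix for synthetic tumors (stage I dominant, IV rare),
# consistent with typical TCGA-like adenocarcinoma cohorts.
_STAGE_PROBS = np.array([0.54, 0.25, 0.16, 0.05])


def simulate_cohort(
    params: CohortSimulationParams,
) -> tuple[ExpressionMatrix, ClinicalTable, GeneSetCollection, dict]:
    """Generate (expression, clinical, signatures, truth) for one cohort."""
    rng = np.random.default_rng(params.seed)
    n_t, n_n = params.n_tumor, params.n_normal_pairs
    n_samples = n_t + n_n

    tumor_ids = [f"T{i:04d}" for i in range(n_t)]
    normal_ids = [f"N{i:04d}" for i in range(n_n)]
    sample_ids = tumor_ids + normal_ids

    b_genes = [f"BSIG{i:03d}" for i in range(params.bcell_set_size)]
    t_genes = [f"TSIG{i:03d}" for i in range(params.tcell_set_size)]
    n_bg = params.n_genes - len(b_genes) - len(t_genes) - 1
    bg_genes = [f"G{i:05d}" for i in range(n_bg)]
    gene_ids = b_genes + t_genes + [PDL1_GENE] + bg_genes

    # Latent infiltration factors: tumors ~ N(0,1); normals get a lower
    # B factor and a higher T factor, the tumor-vs-normal contrast the
    # pipeline's paired tests are meant to detect.
    cov = np.array([[1.0, params.bt_correlation], [params.bt_correlation, 1.0]])
    chol = np.linalg.cholesky(cov)
    latents = rng.standard_normal((n_samples, 2)) @ chol.T
    b_latent = latents[:, 0].copy()
    t_latent = latents[:, 1].copy()
    b_latent[n_t:] -= 1.0
    t_latent[n_t:] += 1.0

    # Log-normal expression with signature genes tied to the latents.
    baselines = rng.uniform(*params.baseline_log2_range, size=params.n_genes)
    log2x = baselines[:, None] + rng.normal(0.0, params.log2_noise_sd, size=(params.n_genes, n_samples))
    eff = params.infiltration_effect
    log2x[: len(b_genes)] += eff * b_latent[None, :]
    log2x[len(b_genes) : len(b_genes) + len(t_genes)] += eff * t_latent[None, :]
    values = np.exp2(log2x)

    # PD-L1: linear in the B factor with Gaussian noise, shifted so the
    # intercept keeps the value non-negative for all but extreme draws.
    intercept = 4.0 * abs(params.pdl1_b_coefficient) + 4.0 * params.pdl1_noise_sd
    pdl1 = (
        intercept
        + params.pdl1_b_coefficient * b_latent
        + rng.normal(0.0, params.pdl1_noise_sd, size=n_samples)
    )
    values[len(b_genes) + len(t_genes)] = np.clip(pdl1, 0.0, None)

    # Stage: ordinal thinning against the B factor (higher infiltration →
    # earlier stage); cutpoints fixed by the baseline stage mix.
    cuts = np.quantile(rng.standard_normal(20000), np.cumsum(_STAGE_PROBS)[:-1])
    stage_score = rng.standard_normal(n_t) - params.stage_b_coefficient * b_latent[:n_t]
    stage_num = 1 + np.searchsorted(cuts, stage_score)

    # Proportional-hazards survival with independent exponential censoring.
    log_hazard = (
        np.log(params.baseline_hazard)
        + params.log_hr_bcell * b_latent[:n_t]
        + params.log_hr_stage * (stage_num - 1)
    )
    event_time = rng.exponential(1.0 / np.exp(log_hazard))
    censor_time = (
        rng.exponential(1.0 / params.censor_rate, size=n_t)
        if params.censor_rate > 0
        else np.full(n_t, np.inf)
    )
    os_days = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    stage_labels = np.array(["I", "II", "III", "IV"])[stage_num - 1]
    egfr = rng.choice(["mutation", "non-mutation", "unknown"], size=n_t, p=[0.1, 0.4, 0.5])
    kras = rng.choice(["mutation", "non-mutation", "unknown"], size=n_t, p=[0.13, 0.31, 0.56])
    sex = rng.choice(["female", "male"], size=n_t, p=[0.52, 0.48])
    age = np.round(np.clip(rng.normal(65.3, 9.9, size=n_t), 30, 90), 1)

    paired = [normal_ids[i] if i < n_n else "" for i in range(n_t)]
    clin_tumor = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "os_days": np.round(os_days, 1),
            "event": event.astype(int),
            "age_years": age,
            "sex": sex,
            "stage": stage_labels,
            "egfr_status": egfr,
            "kras_status": kras,
            "tissue": "tumor",
            "paired_sample_id": paired,
        }
    )
    clin_normal = pd.DataFrame(
        {
            "sample_id": normal_ids,
            "os_days": 0.0,
            "event": 0,
            "age_years": age[:n_n],
            "sex": sex[:n_n],
            "stage": [None] * n_n,
            "egfr_status": "unknown",
            "kras_status": "unknown",
            "tissue": "normal",
            "paired_sample_id": tumor_ids[:n_n],
        }
    )
    clinical = ClinicalTable(pd.concat([clin_tumor, clin_normal], ignore_index=True))

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    signatures = GeneSetCollection(
        {"B_cells": list(b_genes), "CD8_T_cells": list(t_genes)},
        {"B_cells": "synthetic B-cell signature", "CD8_T_cells": "synthetic CD8 T-cell signature"},
    )
    truth = {
        "b_latent": dict(zip(sample_ids, b_latent)),
        "t_latent": dict(zip(sample_ids, t_latent)),
        "stage": dict(zip(tumor_ids, stage_labels)),
        "pdl1_gene": PDL1_GENE,
        "b_signature": list(b_genes),
        "t_signature": list(t_genes),
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(params).items()
            if not k.startswith("_")
        },
        "pathway_shift_sets": list(params.pathway_shift_sets),
    }
    return expr, clinical, signatures, truth


def embed_group_pathway_shift(
    expr: ExpressionMatrix,
    groups: pd.Series | dict,
    gene_set: list[str],
    fold_ad: float,
    fold_dc: float,
) -> ExpressionMatrix:
    """Multiply ``gene_set`` rows by 1 in group A, ``fold_ad`` in D and
    ``fold_ad * fold_dc`` in C; all other genes and samples untouched.

    ``groups`` maps sample ID → quadrant label; labels other than A/D/C are
    left unchanged.
    """
    if fold_ad <= 0 or fold_dc <= 0:
        raise ValueError("folds must be > 0")
    groups = pd.Series(groups)
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in gene_set if g not in gene_index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    multiplier = np.ones(expr.n_samples)
    for j, sid in enumerate(expr.sample_ids):
        label = groups.get(sid)
        if label == "D":
            multiplier[j] = fold_ad
        elif label == "C":
            multiplier[j] = fold_ad * fold_dc
    values = expr.values.copy()
    rows = [gene_index[g] for g in gene_set]
    values[rows] = values[rows] * multiplier[None, :]
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), values)


def published_pathway_table() -> pd.DataFrame:
    """The twelve published hallmark-pathway rows (NES and FDR for the
    C-vs-A and D-vs-A contrasts, plus the printed ΔNES).

    The D-vs-A FDR printed as "<0.01" is stored as 0.005.
    """
    rows = [
        ("Apoptosis", 1.98, 0.02, 1.49, 0.18, 0.49),
        ("TNF-a signaling via NF-kB", 1.85, 0.02, 1.46, 0.19, 0.38),
        ("Apical surface", 1.83, 0.03, 1.45, 0.19, 0.38),
        ("Interferon-a response", 1.77, 0.03, 1.51, 0.19, 0.26),
        ("KRAS signaling upregulation", 1.94, 0.02, 1.68, 0.09, 0.25),
        ("Complement", 2.04, 0.01, 1.86, 0.04, 0.18),
        ("Inflammatory response", 1.91, 0.02, 1.77, 0.06, 0.14),
        ("IL6/JAK/STAT3 signaling", 1.90, 0.02, 1.77, 0.05, 0.13),
        ("Interferon-g response", 1.94, 0.02, 1.86, 0.04, 0.08),
        ("Allograft rejection", 1.93, 0.02, 1.97, 0.02, -0.03),
        ("IL-2/STAT5 signaling", 2.04, 0.02, 2.12, 0.01, -0.08),
        ("PI3K/AKT/mTOR signaling", 2.22, 0.01, 2.36, 0.005, -0.14),
    ]
    return pd.DataFrame(
        rows, columns=["pathway", "nes_ca", "fdr_ca", "nes_da", "fdr_da", "printed_delta"]
    )
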