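"""End-to-end orchestration of the analysis stages.

Stage order follows the study narrative: infiltration scoring →
quadrant stratification → survival → variant-gene clustering →
GSEA (C-vs-A and D-vs-A) → ΔNES selection → candidate genes →
drug-target enrichment. Group B (high PD-L1 / low B infiltration) is
carried through stratification but excluded from the GSEA and candidate
stages. Every threshold applied is recorded in the run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .candidates import collect_core_genes, sequential_fold_filter
from .cluster import anova_like_test, cluster_composition, top_k_genes, ward_cluster
from .drug_enrichment import overlap_permutation_test
from .gsea import delta_nes_select, gsea_permutation, results_to_frame
from .io import (
    read_clinical_tsv,
    read_expression_tsv,
    read_gene_list,
    read_gmt,
    write_results_table,
)
from .ssgsea import score_cell_types, scores_wide
from .stats import cox_regression, km_logrank, stratify_quadrants

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = [
    "infiltration",
    "stratification",
    "survival",
    "clustering",
    "gsea_ca",
    "gsea_da",
    "candidates",
    "drug_enrichment",
]


@dataclass
class PipelineConfig:
    expression: str
    clinical: str
    signature_gmt: str
    pathway_gmt: str
    targets: str
    universe: str | None = None  # default: the expression matrix's genes
    pdl1_gene_id: str = "CD274"
    bcell_signature: str = "B_cells"
    ssgsea_alpha: float = 0.25
    fdr_gsea: float = 0.05
    delta_nes: float = 0.25
    fold: float = 1.5
    fdr_candidates: float = 0.01
    top_genes: int = 100
    kmax: int = 10
    n_perm_gsea: int = 1000
    n_perm_drug: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)

    def thresholds(self) -> dict:
        return {
            "fdr_gsea": self.fdr_gsea,
            "delta_nes": self.delta_nes,
            "fold": self.fold,
            "fdr_candidates": self.fdr_candidates,
            "top_genes": self.top_genes,
            "kmax": self.kmax,
            "n_perm_gsea": self.n_perm_gsea,
            "n_perm_drug": self.n_perm_drug,
            "ssgsea_alpha": self.ssgsea_alpha,
        }


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage, writing per-stage TSV/JSON outputs and a manifest.

    Returns the run directory; a stage failure aborts with the stage name
    while preserving the outputs of completed stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "stages_completed": completed,
    }

    def _save_manifest():
        with open(out / "manifest.json", "w", encoding="utf-8") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)

    stage = "load_inputs"
    try:
        expr = read_expression_tsv(config.expression)
        clinical = read_clinical_tsv(config.clinical)
        signatures = read_gmt(config.signature_gmt)
        pathways = read_gmt(config.pathway_gmt)
        targets = read_gene_list(config.targets)
        universe = read_gene_list(config.universe) if config.universe else list(expr.gene_ids)

        stage = "infiltration"
        scores = score_cell_types(expr, signatures, alpha=config.ssgsea_alpha)
        write_results_table(scores, out / "scores.tsv", sort_by="sample_id")
        completed.append(stage)

        stage = "stratification"
        tumors = [s for s in clinical.tumor_samples() if s in set(expr.sample_ids)]
        wide = scores_wide(scores)
        pdl1 = expr.gene_values(config.pdl1_gene_id).loc[tumors]
        bscore = wide[config.bcell_signature].loc[tumors]
        groups = stratify_quadrants(pdl1, bscore)
        write_results_table(groups, out / "groups.tsv", sort_by="sample_id")
        group_map = groups.set_index("sample_id")["group"]
        completed.append(stage)

        stage = "survival"
        clin = clinical.data.set_index("sample_id").loc[tumors]
        b_high = (bscore > bscore.median()).map({True: "high", False: "low"})
        comparison = km_logrank(clin["os_days"], clin["event"], b_high.loc[clin.index])
        km_rows = []
        for label, curve in comparison.km_curves.items():
            c = curve.copy()
            c.insert(0, "group", label)
            km_rows.append(c)
        write_results_table(pd.concat(km_rows, ignore_index=True), out / "km.tsv", sort_by="group")
        with open(out / "logrank.json", "w", encoding="utf-8") as handle:
            json.dump(
                {
                    "chi2": comparison.logrank_chi2,
                    "p": comparison.logrank_p,
                    "mean_survival": comparison.mean_survival,
                    "mean_survival_difference_days": comparison.mean_survival_difference_days,
                },
                handle,
                indent=2,
                sort_keys=True,
            )
        covars = pd.DataFrame(
            {
                "bcell": b_high.loc[clin.index].to_numpy(),
                "age_years": clin["age_years"].to_numpy(),
                "sex": clin["sex"].to_numpy(),
                "stage": clin["stage"].astype(str).to_numpy(),
                "egfr_status": clin["egfr_status"].to_numpy(),
                "kras_status": clin["kras_status"].to_numpy(),
            }
        )
        cox = cox_regression(clin["os_days"], clin["event"], covars, mode="multivariate")
        write_results_table(cox.table, out / "cox.tsv", sort_by="covariate")
        completed.append(stage)

        stage = "clustering"
        expr_tumor = expr.subset_samples(tumors)
        variant = anova_like_test(expr_tumor, group_map)
        write_results_table(variant, out / "variant_genes.tsv", sort_by="gene_id")
        top = top_k_genes(variant, min(config.top_genes, len(variant)))
        clustering = ward_cluster(expr_tumor.subset_genes(top), k_max=config.kmax)
        labels = clustering.labels_per_k[clustering.chosen_k]
        clusters = pd.DataFrame({"sample_id": tumors, "cluster": labels})
        write_results_table(clusters, out / "clusters.tsv", sort_by="sample_id")
        write_results_table(
            pd.DataFrame(
                {
                    "k": sorted(clustering.silhouette_per_k),
                    "mean_silhouette": [
                        clustering.silhouette_per_k[k] for k in sorted(clustering.silhouette_per_k)
                    ],
                }
            ),
            out / "silhouette.tsv",
            sort_by="k",
        )
        composition = cluster_composition(labels, group_map.loc[tumors].to_numpy())
        write_results_table(composition, out / "cluster_composition.tsv", sort_by="cluster")
        completed.append(stage)

        # group B excluded from here on
        samples_by_group = {
            g: list(groups.loc[groups["group"] == g, "sample_id"]) for g in ("A", "C", "D")
        }

        stage = "gsea_ca"
        res_ca = gsea_permutation(
            expr,
            samples_by_group["C"],
            samples_by_group["A"],
            pathways,
            n_perm=config.n_perm_gsea,
            seed=config.seed,
        )
        write_results_table(results_to_frame(res_ca), out / "gsea_CA.tsv", sort_by="pathway")
        completed.append(stage)

        stage = "gsea_da"
        res_da = gsea_permutation(
            expr,
            samples_by_group["D"],
            samples_by_group["A"],
            pathways,
            n_perm=config.n_perm_gsea,
            seed=config.seed + 1,
        )
        write_results_table(results_to_frame(res_da), out / "gsea_DA.tsv", sort_by="pathway")
        delta = delta_nes_select(
            results_to_frame(res_ca),
            results_to_frame(res_da),
            fdr_max=config.fdr_gsea,
            delta_min=config.delta_nes,
        )
        write_results_table(delta, out / "delta_nes.tsv", sort_by="pathway")
        completed.append(stage)

        stage = "candidates"
        core = collect_core_genes(delta, res_ca)
        records = (
            sequential_fold_filter(
                expr,
                group_map,
                core,
                fold_min=config.fold,
                fdr_max=config.fdr_candidates,
            )
            if core
            else pd.DataFrame(
                columns=["gene_id", "mean_a", "mean_d", "mean_c", "fold_da", "fold_cd", "fdr", "passes", "error"]
            )
        )
        write_results_table(records, out / "candidates.tsv", sort_by="gene_id")
        passing = sorted(records.loc[records["passes"], "gene_id"]) if len(records) else []
        manifest["n_core_genes"] = len(core)
        manifest["n_candidates"] = len(passing)
        completed.append(stage)

        stage = "drug_enrichment"
        if passing:
            enrich = overlap_permutation_test(
                passing, targets, universe, n_perm=config.n_perm_drug, seed=config.seed + 2
            )
            payload = {
                k: (v if not isinstance(v, np.generic) else v.item())
                for k, v in vars(enrich).items()
            }
        else:
            logger.warning("no passing candidates; drug enrichment skipped")
            payload = {"skipped": "no passing candidate genes"}
        with open(out / "enrichment.json", "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
        completed.append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _save_manifest()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _save_manifest()
    return out
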