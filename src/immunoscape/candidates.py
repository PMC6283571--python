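"""Candidate-gene nomination from selected pathways.

Core-enrichment (leading-edge) genes of the ΔNES-selected pathways are
pooled, then filtered for genes whose group means rise sequentially
A → D → C, each step by at least a 1.5-fold ratio (with pseudocount 1 on the
normalized scale), at an ANOVA FDR < 0.01 computed over the candidate list
restricted to groups A, D and C.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cluster import anova_like_test
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["collect_core_genes", "sequential_fold_filter"]


def collect_core_genes(selected: pd.DataFrame, results_ca) -> list[str]:
    """Union of leading-edge genes of the selected pathways (C-vs-A run).

    ``selected`` is the ΔNES record frame (pathway/selected columns);
    ``results_ca`` the GseaPathwayResult list or frame with a comma-joined
    ``leading_edge`` column.
    """
    chosen = set(selected.loc[selected["selected"], "pathway"])
    if not chosen:
        logger.warning("no pathways selected; empty core-gene list")
        return []
    if isinstance(results_ca, pd.DataFrame):
        edges = {
            row["pathway"]: [g for g in str(row["leading_edge"]).split(",") if g]
            for _, row in results_ca.iterrows()
        }
    else:
        edges = {r.pathway: list(r.leading_edge) for r in results_ca}
    missing = chosen - set(edges)
    if missing:
        raise KeyError(f"selected pathways missing from the C-vs-A results: {sorted(missing)}")
    pool: set[str] = set()
    for p in chosen:
        pool.update(edges[p])
    return sorted(pool)


def sequential_fold_filter(
    expr: ExpressionMatrix,
    groups: pd.Series | dict,
    genes: list[str],
    fold_min: float = 1.5,
    fdr_max: float = 0.01,
    pseudocount: float = 1.0,
    cumulative: bool = False,
) -> pd.DataFrame:
    """Flag genes rising sequentially A → D → C.

    Group means are taken on the normalized scale with ``pseudocount`` added
    before each ratio. A gene passes when both steps (A→D and D→C) reach
    ``fold_min`` and the three-group ANOVA FDR (BH over the supplied gene
    list) is below ``fdr_max``. With ``cumulative=True`` the rule is instead
    C/A >= fold_min with monotone means. Genes absent from the matrix are
    returned with ``error=True``.
    """
    groups = pd.Series(groups)
    present = [g for g in genes if g in set(expr.gene_ids)]
    absent = [g for g in genes if g not in set(expr.gene_ids)]
    if absent:
        logger.warning("%d candidate genes absent from the matrix", len(absent))
    if len(present) == 0:
        raise ValueError("no candidate gene present in the matrix")

    adc = groups[groups.isin(["A", "D", "C"])]
    for label in ("A", "D", "C"):
        if (adc == label).sum() < 2:
            raise ValueError(f"group {label} has < 2 samples")
    sub = expr.subset_genes(present).subset_samples(list(adc.index))

    anova = anova_like_test(sub, adc).set_index("gene_id")

    means = {}
    vals = sub.values
    sample_groups = adc.reindex(sub.sample_ids).to_numpy()
    for label in ("A", "D", "C"):
        means[label] = vals[:, sample_groups == label].mean(axis=1)

    fold_da = (means["D"] + pseudocount) / (means["A"] + pseudocount)
    fold_cd = (means["C"] + pseudocount) / (means["D"] + pseudocount)
    fold_ca = (means["C"] + pseudocount) / (means["A"] + pseudocount)
    fdr = anova.loc[present, "fdr"].to_numpy()
    if cumulative:
        monotone = (means["D"] >= means["A"]) & (means["C"] >= means["D"])
        passes = (fold_ca >= fold_min) & monotone & (fdr < fdr_max)
    else:
        passes = (fold_da >= fold_min) & (fold_cd >= fold_min) & (fdr < fdr_max)

    records = pd.DataFrame(
        {
            "gene_id": present,
            "mean_a": means["A"],
            "mean_d": means["D"],
            "mean_c": means["C"],
            "fold_da": fold_da,
            "fold_cd": fold_cd,
            "fdr": fdr,
            "passes": passes,
            "error": False,
        }
    )
    if absent:
        records = pd.concat(
            [
                records,
                pd.DataFrame(
                    {
                        "gene_id": absent,
                        "mean_a": np.nan,
                        "mean_d": np.nan,
                        "mean_c": np.nan,
                        "fold_da": np.nan,
                        "fold_cd": np.nan,
                        "fdr": np.nan,
                        "passes": False,
                        "error": True,
                    }
                ),
            ],
            ignore_index=True,
        )
    return records.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
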