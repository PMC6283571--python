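"""Two-group gene set enrichment analysis.

Genes are ranked by a signal-to-noise ratio (group-mean difference over the
sum of floored group standard deviations, computed on log2(x+1) expression);
the enrichment score of a pathway is the signed maximum deviation of the
weighted Kolmogorov–Smirnov running sum over the ranked list. Significance
comes from phenotype permutation: group labels are reshuffled ``n_perm``
times, the ranking and per-pathway ES recomputed, the normalized enrichment
score (NES) taken as ES over the mean magnitude of same-sign permuted ES,
and the FDR estimated by the sign-matched ratio of pooled permuted-NES and
observed-NES tail fractions.

The ΔNES rule then contrasts two such analyses (C-vs-A minus D-vs-A) to pick
pathways over-represented specifically when PD-L1 is high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "signal_to_noise",
    "enrichment_score",
    "gsea_permutation",
    "delta_nes_select",
    "GseaPathwayResult",
    "results_to_frame",
]


def _snr_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Signal-to-noise per gene row: (mean_x - mean_y)/(sd_x + sd_y), with
    each group's sd floored at 0.2*|mean| (absolute floor 0.2 at mean 0)."""
    mx, my = x.mean(axis=1), y.mean(axis=1)
    sx = x.std(axis=1, ddof=1)
    sy = y.std(axis=1, ddof=1)

    def _floor(sd, mu):
        fl = 0.2 * np.abs(mu)
        fl = np.where(mu == 0, 0.2, fl)
        return np.maximum(sd, fl)

    return (mx - my) / (_floor(sx, mx) + _floor(sy, my))


def signal_to_noise(expr: ExpressionMatrix, group_x: list[str], group_y: list[str]) -> pd.DataFrame:
    """Ranked gene list for group_x vs group_y (descending metric).

    The metric is computed on the expression values as supplied (apply
    log2(x+1) upstream for normalized expression); ties in the metric are
    broken deterministically by gene ID.
    """
    if len(group_x) < 2 or len(group_y) < 2:
        raise ValueError("each group needs >= 2 samples")
    x = expr.subset_samples(list(group_x)).values
    y = expr.subset_samples(list(group_y)).values
    metric = _snr_matrix(x, y)
    frame = pd.DataFrame({"gene_id": expr.gene_ids, "metric": metric})
    return frame.sort_values(
        ["metric", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def enrichment_score(
    ranked: pd.DataFrame, gene_set: list[str], weight: float = 1.0
) -> tuple[float, np.ndarray, int, list[str]]:
    """Weighted KS enrichment score of ``gene_set`` over a ranked list.

    Returns (ES, running sum over all positions, peak position, leading-edge
    genes). Hits increment the running sum by |metric|^weight normalized
    over in-set hits; misses decrement by 1/(N - Nh). The leading edge is
    the in-set genes at or before the peak for ES > 0 (at or after for
    ES < 0).
    """
    genes = ranked["gene_id"].to_numpy()
    metric = ranked["metric"].to_numpy(dtype=float)
    n = len(genes)
    hit = np.isin(genes, np.asarray(list(gene_set)))
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has no genes in the ranked list")
    if nh == n:
        raise ValueError("gene set covers the whole ranked list")

    w = np.where(hit, np.abs(metric) ** weight, 0.0)
    wsum = w.sum()
    if wsum == 0:  # all hit metrics are exactly 0: fall back to equal weights
        w = hit.astype(float)
        wsum = w.sum()
    step = np.where(hit, w / wsum, -1.0 / (n - nh))
    running = np.cumsum(step)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es, peak = float(running[i_max]), i_max
    else:
        es, peak = float(running[i_min]), i_min
    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], hit[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], hit[peak:]) if h]
    return es, running, peak, leading


def _es_from_positions(positions: np.ndarray, hit_weights: np.ndarray, n: int) -> float:
    """ES evaluated only at the hit positions (equivalent to the full walk).

    ``positions``: sorted 0-based ranks of the set genes; ``hit_weights``:
    |metric|^weight at those positions.
    """
    nh = len(positions)
    wsum = hit_weights.sum()
    if wsum == 0:
        hit_weights = np.ones(nh)
        wsum = float(nh)
    miss = 1.0 / (n - nh)
    cumw = np.cumsum(hit_weights) / wsum
    misses_before = positions - np.arange(nh)
    after_hit = cumw - misses_before * miss
    before_hit = np.concatenate(([0.0], cumw[:-1])) - misses_before * miss
    top = after_hit.max()
    bottom = before_hit.min()
    return float(top) if top >= -bottom else float(bottom)


@dataclass
class GseaPathwayResult:
    pathway: str
    es: float
    nes: float
    nominal_p: float
    fdr: float
    leading_edge: list[str]
    n_permutations: int
    seed: int


def results_to_frame(results: list[GseaPathwayResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "nominal_p": [r.nominal_p for r in results],
            "fdr": [r.fdr for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
            "n_permutations": [r.n_permutations for r in results],
            "seed": [r.seed for r in results],
        }
    )


def gsea_permutation(
    expr: ExpressionMatrix,
    group_x: list[str],
    group_y: list[str],
    pathways: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> list[GseaPathwayResult]:
    """Phenotype-permutation GSEA of group_x vs group_y over all pathways.

    Expression is log2(x+1)-transformed before ranking. NES, nominal p and
    FDR follow the standard sign-matched permutation scheme; results are
    deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    nx, ny = len(group_x), len(group_y)
    if min(nx, ny) < 2:
        raise ValueError("each group needs >= 2 samples")
    if min(nx, ny) < 7:
        logger.warning("fewer than 7 samples in a group; phenotype permutation is coarse")

    sub = expr.subset_samples(list(group_x) + list(group_y))
    log2x = np.log2(sub.values + 1.0)
    genes = np.asarray(sub.gene_ids)
    n_genes = len(genes)

    # pathway gene indices (restricted to tested genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    path_names: list[str] = []
    path_idx: list[np.ndarray] = []
    path_sizes: list[int] = []
    for name, members in pathways:
        idx = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=int)
        if len(idx) == 0 or len(idx) == n_genes:
            logger.warning("pathway %r has no usable genes; skipped", name)
            continue
        path_names.append(name)
        path_idx.append(idx)
        path_sizes.append(len(idx))
    if not path_names:
        return []

    # deterministic tie-break by gene ID within equal metrics
    id_order = np.argsort(genes, kind="mergesort")

    def _ranked_order(metric: np.ndarray) -> np.ndarray:
        return id_order[np.argsort(-metric[id_order], kind="mergesort")]

    def _all_es(metric: np.ndarray) -> np.ndarray:
        order = _ranked_order(metric)
        rank_of = np.empty(n_genes, dtype=int)
        rank_of[order] = np.arange(n_genes)
        absw = np.abs(metric) ** weight
        out = np.empty(len(path_idx))
        for i, idx in enumerate(path_idx):
            pos = np.sort(rank_of[idx])
            out[i] = _es_from_positions(pos, absw[order[pos]], n_genes)
        return out

    labels = np.zeros(nx + ny, dtype=bool)
    labels[:nx] = True
    observed_metric = _snr_matrix(log2x[:, labels], log2x[:, ~labels])
    observed_es = _all_es(observed_metric)

    rng = np.random.default_rng(seed)
    perm_es = np.empty((n_perm, len(path_idx)))
    for p in range(n_perm):
        perm = rng.permutation(nx + ny)
        metric = _snr_matrix(log2x[:, perm[:nx]], log2x[:, perm[nx:]])
        perm_es[p] = _all_es(metric)

    # NES: ES over mean |same-sign permuted ES| per pathway
    nes = np.empty(len(path_idx))
    nominal_p = np.empty(len(path_idx))
    norm_perm = np.full_like(perm_es, np.nan)
    for i in range(len(path_idx)):
        es_i = observed_es[i]
        col = perm_es[:, i]
        pos, neg = col[col >= 0], col[col < 0]
        mean_pos = pos.mean() if len(pos) else np.abs(col).mean()
        mean_neg = np.abs(neg).mean() if len(neg) else np.abs(col).mean()
        if len(pos):
            norm_perm[col >= 0, i] = pos / mean_pos
        if len(neg):
            norm_perm[col < 0, i] = neg / mean_neg
        if es_i >= 0:
            nes[i] = es_i / mean_pos if mean_pos > 0 else 0.0
            same = pos
            n_extreme = int((same >= es_i).sum())
        else:
            nes[i] = -abs(es_i) / mean_neg if mean_neg > 0 else 0.0
            same = neg
            n_extreme = int((same <= es_i).sum())
        denom = max(len(same), 1)
        nominal_p[i] = max(n_extreme / denom, 1.0 / n_perm)

    # FDR: sign-matched pooled-NES ratio estimator, capped at 1
    pooled = norm_perm[np.isfinite(norm_perm)]
    pooled_pos = pooled[pooled >= 0]
    pooled_neg = pooled[pooled < 0]
    obs_pos = nes[nes >= 0]
    obs_neg = nes[nes < 0]
    fdr = np.empty(len(path_idx))
    for i, v in enumerate(nes):
        if v >= 0:
            num = (pooled_pos >= v).sum() / max(len(pooled_pos), 1)
            den = (obs_pos >= v).sum() / max(len(obs_pos), 1)
        else:
            num = (pooled_neg <= v).sum() / max(len(pooled_neg), 1)
            den = (obs_neg <= v).sum() / max(len(obs_neg), 1)
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0

    # leading edges from the observed ranking
    ranked = (
        pd.DataFrame({"gene_id": genes, "metric": observed_metric})
        .sort_values(["metric", "gene_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    results = []
    for i, name in enumerate(path_names):
        _, _, _, leading = enrichment_score(ranked, [genes[j] for j in path_idx[i]], weight)
        results.append(
            GseaPathwayResult(
                pathway=name,
                es=float(observed_es[i]),
                nes=float(nes[i]),
                nominal_p=float(nominal_p[i]),
                fdr=float(fdr[i]),
                leading_edge=leading,
                n_permutations=n_perm,
                seed=seed,
            )
        )
    return results


def delta_nes_select(
    results_ca: pd.DataFrame,
    results_da: pd.DataFrame,
    fdr_max: float = 0.05,
    delta_min: float = 0.25,
    absolute: bool = False,
) -> pd.DataFrame:
    """Contrast two GSEA runs and flag pathways by the ΔNES rule.

    Restricts to pathways with FDR <= ``fdr_max`` in the first (C-vs-A)
    comparison; delta = NES(C-vs-A) − NES(D-vs-A); a pathway is selected
    when delta >= ``delta_min`` (or |delta| >= delta_min with
    ``absolute=True``). Inputs are frames with at least columns
    pathway / nes / fdr (``results_to_frame`` output or the printed-table
    fixture with its columns renamed).
    """
    ca = results_ca.set_index("pathway")
    da = results_da.set_index("pathway")
    only = set(ca.index).symmetric_difference(da.index)
    if only:
        logger.warning("pathways present in only one comparison excluded: %s", sorted(only))
    common = [p for p in ca.index if p in da.index]
    rows = []
    for p in common:
        if ca.loc[p, "fdr"] > fdr_max:
            continue
        delta = float(ca.loc[p, "nes"] - da.loc[p, "nes"])
        passed = abs(delta) >= delta_min if absolute else delta >= delta_min
        rows.append(
            {
                "pathway": p,
                "nes_ca": float(ca.loc[p, "nes"]),
                "nes_da": float(da.loc[p, "nes"]),
                "delta": delta,
                "selected": bool(passed),
            }
        )
    return pd.DataFrame(rows, columns=["pathway", "nes_ca", "nes_da", "delta", "selected"])
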