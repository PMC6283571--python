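"""Variant-gene selection and unsupervised patient clustering.

The four PD-L1 × B-infiltration groups are compared gene by gene with a
one-way ANOVA F test on log2(x+1) expression, BH-adjusted across genes.
Patients are then hierarchically clustered (Euclidean distance on the
top-FDR genes, rows standardized, Ward linkage) and the cluster number is
chosen by the mean silhouette over k = 2..10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "anova_like_test",
    "top_k_genes",
    "ward_cluster",
    "silhouette_select_k",
    "cluster_composition",
    "ClusteringResult",
]


def anova_like_test(expr: ExpressionMatrix, groups: pd.Series | dict) -> pd.DataFrame:
    """Per-gene one-way ANOVA F on log2(x+1) across groups, with BH FDR.

    ``groups`` maps sample ID → group label; samples absent from the mapping
    are ignored, and groups with a single sample are excluded with a warning.
    Genes with zero variance everywhere get F = 0, p = 1.
    """
    groups = pd.Series(groups)
    labels = groups.reindex(expr.sample_ids)
    masks = []
    group_names = []
    for lv in pd.unique(labels.dropna()):
        mask = (labels == lv).to_numpy()
        if mask.sum() < 2:
            logger.warning("group %r has < 2 samples; excluded from ANOVA", lv)
            continue
        masks.append(mask)
        group_names.append(str(lv))
    if len(masks) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")

    log2x = np.log2(expr.values + 1.0)
    n_total = sum(int(m.sum()) for m in masks)
    k = len(masks)
    used = np.logical_or.reduce(masks)
    grand = log2x[:, used].mean(axis=1)

    ssb = np.zeros(expr.n_genes)
    ssw = np.zeros(expr.n_genes)
    group_means = {}
    for name, mask in zip(group_names, masks):
        sub = log2x[:, mask]
        mu = sub.mean(axis=1)
        group_means[name] = mu
        ssb += mask.sum() * (mu - grand) ** 2
        ssw += ((sub - mu[:, None]) ** 2).sum(axis=1)

    df_between = k - 1
    df_within = n_total - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / df_between) / (ssw / df_within)
    degenerate = ssw == 0
    zero_signal = degenerate & (ssb == 0)
    f_stat = np.where(zero_signal, 0.0, f_stat)
    f_stat = np.where(degenerate & ~zero_signal, np.inf, f_stat)
    p = sps.f.sf(f_stat, df_between, df_within)
    p = np.where(zero_signal, 1.0, p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")

    out = pd.DataFrame(
        {"gene_id": expr.gene_ids, "F_statistic": f_stat, "p_value": p, "fdr": fdr}
    )
    for name in group_names:
        out[f"mean_{name}"] = group_means[name]
    return out


def top_k_genes(results: pd.DataFrame, k: int) -> list[str]:
    """The k genes with smallest FDR (ties: smaller p, then gene ID)."""
    if k > len(results):
        raise ValueError(f"k={k} exceeds {len(results)} tested genes")
    ordered = results.sort_values(
        ["fdr", "p_value", "gene_id"], kind="mergesort"
    )
    return list(ordered["gene_id"].head(k))


@dataclass
class ClusteringResult:
    linkage_matrix: np.ndarray
    sample_ids: list[str]
    labels_per_k: dict[int, np.ndarray]
    silhouette_per_k: dict[int, float]
    chosen_k: int
    distances: np.ndarray  # condensed


def ward_cluster(
    expr_subset: ExpressionMatrix, k_max: int = 10, standardize: bool = True
) -> ClusteringResult:
    """Ward-linkage hierarchical clustering of samples on a gene subset.

    Distances are Euclidean between samples on log2(x+1) expression with
    genes standardized to zero mean / unit variance (toggle with
    ``standardize``); labels are extracted for k = 2..k_max (bounded by the
    sample count) and the k with the largest mean silhouette is chosen
    (ties -> smaller k).
    """
    if expr_subset.n_samples < 3:
        raise ValueError("need >= 3 samples to cluster")
    log2x = np.log2(expr_subset.values + 1.0)
    if standardize:
        mu = log2x.mean(axis=1, keepdims=True)
        sd = log2x.std(axis=1, keepdims=True)
        keep = sd[:, 0] > 0
        if not keep.all():
            logger.warning("dropping %d constant genes before standardizing", int((~keep).sum()))
        log2x = (log2x[keep] - mu[keep]) / sd[keep]
        if log2x.shape[0] == 0:
            raise ValueError("no non-constant genes to cluster on")
    points = log2x.T  # samples as points
    dist = pdist(points, metric="euclidean")
    Z = linkage(points, method="ward")

    labels_per_k: dict[int, np.ndarray] = {}
    ks = [k for k in range(2, k_max + 1) if k <= expr_subset.n_samples]
    for k in ks:
        labels_per_k[k] = fcluster(Z, t=k, criterion="maxclust")
    chosen_k, sil = silhouette_select_k(labels_per_k, dist)
    return ClusteringResult(
        linkage_matrix=Z,
        sample_ids=list(expr_subset.sample_ids),
        labels_per_k=labels_per_k,
        silhouette_per_k=sil,
        chosen_k=chosen_k,
        distances=dist,
    )


def silhouette_select_k(
    labels_per_k: dict[int, np.ndarray], distances: np.ndarray
) -> tuple[int, dict[int, float]]:
    """Mean silhouette per k on a condensed distance vector; argmax wins,
    ties to the smaller k. Points in singleton clusters get silhouette 0."""
    if np.all(distances == 0):
        raise ValueError("degenerate distances: all points identical")
    square = squareform(distances)
    sil: dict[int, float] = {}
    for k in sorted(labels_per_k):
        labels = np.asarray(labels_per_k[k])
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) < 2 or len(uniq) >= len(labels):
            # silhouette undefined with a single cluster or all-singleton labels
            continue
        if (counts == 1).any():
            logger.warning("k=%d produced singleton clusters; silhouette 0 for those points", k)
        vals = silhouette_samples(square, labels, metric="precomputed")
        vals = np.where(np.isin(labels, uniq[counts == 1]), 0.0, vals)
        sil[k] = float(vals.mean())
    if not sil:
        raise ValueError("no k yielded >= 2 clusters")
    chosen = min(sil, key=lambda k: (-sil[k], k))
    return chosen, sil


def cluster_composition(cluster_labels, group_labels) -> pd.DataFrame:
    """Percentage of each quadrant group inside each cluster."""
    cl = np.asarray(cluster_labels)
    gr = np.asarray(group_labels)
    if len(cl) != len(gr):
        raise ValueError("label vectors must align")
    rows = []
    for c in pd.unique(cl):
        mask = cl == c
        total = int(mask.sum())
        for g in pd.unique(gr):
            n = int((mask & (gr == g)).sum())
            rows.append(
                {"cluster": c, "group": g, "n": n, "percent": 100.0 * n / total}
            )
    return pd.DataFrame(rows)
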