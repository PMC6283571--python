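"""Variant-gene selection and unsupervised clustering of the four quadrants.

Runs the one-way ANOVA across quadrants on the positive-control cohort
(whose embedded pathway gives the quadrants a real expression signature),
clusters patients on the top-100 FDR genes with Ward linkage, picks the
cluster number by silhouette and reports the quadrant composition of each
cluster.

Writes results/clustering/{variant_genes.tsv,silhouette.tsv,composition.tsv}.
"""

import pandas as pd

import immunoscape as im
from cohort_common import control_cohort, outdir


def main() -> None:
    expr, clinical, pathways, gmap, _ = control_cohort()
    out = outdir("clustering")

    expr_tumor = expr.subset_samples(list(gmap.index))
    variant = im.anova_like_test(expr_tumor, gmap)
    im.write_results_table(variant, out / "variant_genes.tsv", sort_by="gene_id")
    top = im.top_k_genes(variant, 100)
    n_shifted = len(set(top) & set(pathways["SHIFTED"]))
    print(f"top-100 FDR genes include {n_shifted}/40 genes of the embedded pathway")

    clustering = im.ward_cluster(expr_tumor.subset_genes(top))
    sil = pd.DataFrame(
        {"k": sorted(clustering.silhouette_per_k),
         "mean_silhouette": [clustering.silhouette_per_k[k] for k in sorted(clustering.silhouette_per_k)]}
    )
    im.write_results_table(sil, out / "silhouette.tsv", sort_by="k")
    print(f"silhouette chooses k = {clustering.chosen_k}")

    labels = clustering.labels_per_k[clustering.chosen_k]
    comp = im.cluster_composition(labels, gmap.to_numpy())
    im.write_results_table(comp, out / "composition.tsv", sort_by="cluster")
    for cluster, block in comp.groupby("cluster"):
        share = block.set_index("group")["percent"]
        cd = float(share.get("C", 0) + share.get("D", 0))
        print(f"cluster {cluster}: C+D share {cd:.0f}%")


if __name__ == "__main__":
    main()
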