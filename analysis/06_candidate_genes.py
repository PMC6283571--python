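"""Candidate-gene nomination: core-enrichment pooling plus the sequential
A -> D -> C 1.5-fold / FDR < 0.01 filter.

Re-runs the two GSEA contrasts of the positive-control cohort, pools the
leading-edge genes of the ΔNES-selected pathways and filters them; every
passing candidate should come from the embedded pathway.

Writes results/candidates/candidates.tsv and core_genes.txt.
"""

import immunoscape as im
from cohort_common import CONTROL_SEED, control_cohort, outdir


def main() -> None:
    expr, clinical, pathways, gmap, _ = control_cohort()
    out = outdir("candidates")

    by_group = {g: list(gmap[gmap == g].index) for g in ("A", "C", "D")}
    res_ca = im.gsea_permutation(
        expr, by_group["C"], by_group["A"], pathways, n_perm=1000, seed=CONTROL_SEED
    )
    res_da = im.gsea_permutation(
        expr, by_group["D"], by_group["A"], pathways, n_perm=1000, seed=CONTROL_SEED + 1
    )
    delta = im.delta_nes_select(
        im.results_to_frame(res_ca), im.results_to_frame(res_da), fdr_max=0.05, delta_min=0.25
    )
    core = im.collect_core_genes(delta, res_ca)
    (out / "core_genes.txt").write_text("\n".join(core) + "\n")
    print(f"{len(core)} core-enrichment genes pooled from "
          f"{int(delta['selected'].sum())} selected pathway(s)")

    records = im.sequential_fold_filter(expr, gmap, core, fold_min=1.5, fdr_max=0.01)
    im.write_results_table(records, out / "candidates.tsv", sort_by="gene_id")
    passing = records.loc[records["passes"], "gene_id"].tolist()
    in_truth = len(set(passing) & set(pathways["SHIFTED"]))
    print(f"{len(passing)} candidates pass the sequential 1.5-fold / FDR<0.01 filter; "
          f"{in_truth} of them belong to the embedded pathway")


if __name__ == "__main__":
    main()
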