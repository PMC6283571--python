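"""Pathway GSEA for the C-vs-A and D-vs-A contrasts and ΔNES selection.

Runs phenotype-permutation GSEA (1,000 permutations) on the positive-control
cohort for both quadrant contrasts, then applies the ΔNES >= 0.25 rule after
gating on C-vs-A FDR <= 0.05. The embedded pathway should be selected; the
untouched pathways should not.

Also recomputes the ΔNES arithmetic of the twelve published hallmark-pathway
rows from their printed NES values.

Writes results/gsea/{gsea_CA.tsv,gsea_DA.tsv,delta_nes.tsv,published_delta.tsv}.
"""

import immunoscape as im
from cohort_common import CONTROL_SEED, control_cohort, outdir


def main() -> None:
    expr, clinical, pathways, gmap, _ = control_cohort()
    out = outdir("gsea")

    by_group = {g: list(gmap[gmap == g].index) for g in ("A", "C", "D")}
    res_ca = im.gsea_permutation(
        expr, by_group["C"], by_group["A"], pathways, n_perm=1000, seed=CONTROL_SEED
    )
    res_da = im.gsea_permutation(
        expr, by_group["D"], by_group["A"], pathways, n_perm=1000, seed=CONTROL_SEED + 1
    )
    fca, fda = im.results_to_frame(res_ca), im.results_to_frame(res_da)
    im.write_results_table(fca, out / "gsea_CA.tsv", sort_by="pathway")
    im.write_results_table(fda, out / "gsea_DA.tsv", sort_by="pathway")

    delta = im.delta_nes_select(fca, fda, fdr_max=0.05, delta_min=0.25)
    im.write_results_table(delta, out / "delta_nes.tsv", sort_by="pathway")
    for _, row in delta.sort_values("delta", ascending=False).iterrows():
        flag = "SELECTED" if row["selected"] else ""
        print(
            f"{row['pathway']:>8}: NES {row['nes_ca']:.2f} (C-A) vs {row['nes_da']:.2f} (D-A), "
            f"ΔNES {row['delta']:+.2f} {flag}"
        )

    t4 = im.published_pathway_table()
    ca = t4.rename(columns={"nes_ca": "nes", "fdr_ca": "fdr"})[["pathway", "nes", "fdr"]]
    da = t4.rename(columns={"nes_da": "nes", "fdr_da": "fdr"})[["pathway", "nes", "fdr"]]
    published = im.delta_nes_select(ca, da, fdr_max=0.05, delta_min=0.25)
    im.write_results_table(published, out / "published_delta.tsv", sort_by="pathway")
    chosen = sorted(published.loc[published["selected"], "pathway"])
    print(f"published table: {len(published)} pathways pass the FDR gate, "
          f"{len(chosen)} selected by ΔNES >= 0.25: {', '.join(chosen)}")


if __name__ == "__main__":
    main()
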