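"""Generate the default synthetic cohort and summarize its structure.

Writes results/cohort/summary.json with cohort sizes, the stage mix, the
PD-L1–B-latent regression and the quadrant sizes implied by the generating
latents.
"""

import json

import numpy as np
import pandas as pd

import immunoscape as im
from cohort_common import default_cohort, outdir


def main() -> None:
    params, expr, clinical, signatures, truth = default_cohort()
    tumors = clinical.tumor_samples()
    clin = clinical.data.set_index("sample_id").loc[tumors]

    pdl1 = expr.gene_values(im.PDL1_GENE).loc[tumors]
    b_latent = pd.Series(truth["b_latent"]).loc[tumors]
    ols = im.ols_pdl1_association(pdl1.to_numpy(), b_latent.to_numpy()).set_index("term")

    summary = {
        "n_tumor": len(tumors),
        "n_normal_pairs": params.n_normal_pairs,
        "n_genes": expr.n_genes,
        "seed": params.seed,
        "stage_counts": clin["stage"].value_counts().sort_index().to_dict(),
        "event_rate": float(clin["event"].mean()),
        "median_followup_days": float(clin["os_days"].median()),
        "pdl1_on_b_latent": {
            "coefficient": float(ols.loc["bscore", "coefficient"]),
            "true_coefficient": params.pdl1_b_coefficient,
            "p_value": float(ols.loc["bscore", "p_value"]),
        },
        "pdl1_b_pearson_r": float(np.corrcoef(pdl1, b_latent)[0, 1]),
    }
    out = outdir("cohort")
    with open(out / "summary.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True)

    print(f"cohort: {expr.n_genes} genes x {expr.n_samples} samples (seed {params.seed})")
    print(f"stage mix: {summary['stage_counts']}; event rate {summary['event_rate']:.2f}")
    print(
        "PD-L1 ~ B latent: coefficient "
        f"{summary['pdl1_on_b_latent']['coefficient']:.2f} "
        f"(generating value {params.pdl1_b_coefficient}), "
        f"r = {summary['pdl1_b_pearson_r']:.2f}"
    )


if __name__ == "__main__":
    main()
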