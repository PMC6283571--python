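"""Quadrant stratification and survival analysis of the default cohort.

Reports the PD-L1 x B-score quadrant sizes, the high-vs-low B-score
Kaplan–Meier / log-rank comparison, the D-vs-A comparison (high B without
PD-L1 elevation against the double-low reference), and univariate plus
multivariate Cox models with age, sex, stage and mutation covariates.

Writes results/survival/{groups.tsv,km.tsv,logrank.json,cox_*.tsv}.
"""

import json

import pandas as pd

import immunoscape as im
from cohort_common import default_cohort, outdir, quadrants


def main() -> None:
    _, expr, clinical, signatures, _ = default_cohort()
    out = outdir("survival")

    scores, wide, pdl1, groups = quadrants(expr, clinical, signatures)
    im.write_results_table(groups, out / "groups.tsv", sort_by="sample_id")
    sizes = groups["group"].value_counts().sort_index()
    print("quadrant sizes:", sizes.to_dict())

    tumors = list(groups["sample_id"])
    clin = clinical.data.set_index("sample_id").loc[tumors]
    bscore = groups.set_index("sample_id")["bscore"]
    b_high = (bscore > bscore.median()).map({True: "high", False: "low"})

    comp = im.km_logrank(clin["os_days"], clin["event"], b_high.loc[clin.index])
    km_rows = []
    for label, curve in comp.km_curves.items():
        c = curve.copy()
        c.insert(0, "group", label)
        km_rows.append(c)
    im.write_results_table(pd.concat(km_rows, ignore_index=True), out / "km.tsv", sort_by="group")
    print(
        f"high vs low B score: log-rank p = {comp.logrank_p:.2e}, "
        f"restricted-mean survival difference = {comp.mean_survival_difference_days:.0f} days"
    )

    gmap = groups.set_index("sample_id")["group"]
    da = gmap[gmap.isin(["D", "A"])]
    clin_da = clin.loc[da.index]
    comp_da = im.km_logrank(clin_da["os_days"], clin_da["event"], da.to_numpy())
    print(
        f"group D vs A: log-rank p = {comp_da.logrank_p:.2e}, "
        f"mean survival difference = {comp_da.mean_survival_difference_days:.0f} days"
    )
    with open(out / "logrank.json", "w") as handle:
        json.dump(
            {
                "b_high_vs_low": {"chi2": comp.logrank_chi2, "p": comp.logrank_p,
                                  "mean_difference_days": comp.mean_survival_difference_days},
                "group_D_vs_A": {"chi2": comp_da.logrank_chi2, "p": comp_da.logrank_p,
                                 "mean_difference_days": comp_da.mean_survival_difference_days},
            },
            handle, indent=2, sort_keys=True,
        )

    covariates = pd.DataFrame(
        {
            "bcell": b_high.loc[clin.index].to_numpy(),
            "age_years": clin["age_years"].to_numpy(),
            "sex": clin["sex"].to_numpy(),
            "stage": clin["stage"].astype(str).to_numpy(),
            "egfr_status": clin["egfr_status"].to_numpy(),
            "kras_status": clin["kras_status"].to_numpy(),
        }
    )
    for mode in ("univariate", "multivariate"):
        fit = im.cox_regression(clin["os_days"], clin["event"], covariates, mode=mode)
        im.write_results_table(fit.table, out / f"cox_{mode}.tsv", sort_by="covariate")
    hr = fit.table.set_index("covariate").loc["bcell[high]"]
    print(
        f"multivariate Cox, high vs low B score: HR = {hr['hazard_ratio']:.2f} "
        f"(p = {hr['p_value']:.2e}) adjusting for age, sex, stage, EGFR, KRAS"
    )


if __name__ == "__main__":
    main()
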