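"""Shared cohort constructions for the numbered analysis drivers.

Two synthetic cohorts are used throughout:

* the *default cohort* — full-size (479 tumors, 58 paired normals, 2,000
  genes) with the default latent-infiltration, PD-L1 and survival couplings;
* the *positive-control cohort* — a smaller, more dispersed cohort
  (200 tumors, 800 genes, log2 noise SD 2.5) with one 40-gene pathway
  multiplied 1.6x in quadrant D and 1.6 x 3.0 = 4.8x in quadrant C, plus
  five untouched pathways, used to exercise the GSEA ΔNES / candidate /
  drug-enrichment chain end to end.

Expression matrices are rebuilt in memory from fixed seeds rather than kept
on disk.
"""

from pathlib import Path

import pandas as pd

import immunoscape as im

RESULTS = Path(__file__).resolve().parent.parent / "results"

DEFAULT_SEED = 17
CONTROL_SEED = 6

SHIFTED_PATHWAY = [f"G{i:05d}" for i in range(40)]
NULL_PATHWAYS = {
    f"NULL{j}": [f"G{i:05d}" for i in range(40 * (j + 1), 40 * (j + 2))] for j in range(5)
}


def default_cohort():
    params = im.CohortSimulationParams(seed=DEFAULT_SEED)
    return params, *im.simulate_cohort(params)


def quadrants(expr, clinical, signatures):
    """ssGSEA B-cell scores and the median-quadrant assignment of tumors."""
    tumors = [s for s in clinical.tumor_samples() if s in set(expr.sample_ids)]
    scores = im.score_cell_types(expr, signatures)
    wide = im.scores_wide(scores)
    pdl1 = expr.gene_values(im.PDL1_GENE).loc[tumors]
    groups = im.stratify_quadrants(pdl1, wide["B_cells"].loc[tumors])
    return scores, wide, pdl1, groups


def control_cohort():
    """The positive-control cohort with the embedded A < D < C pathway."""
    params = im.CohortSimulationParams(
        n_tumor=200, n_normal_pairs=10, n_genes=800, seed=CONTROL_SEED, log2_noise_sd=2.5
    )
    expr, clinical, signatures, truth = im.simulate_cohort(params)
    scores, wide, pdl1, groups = quadrants(expr, clinical, signatures)
    gmap = groups.set_index("sample_id")["group"]
    expr = im.embed_group_pathway_shift(expr, gmap, SHIFTED_PATHWAY, 1.6, 3.0)
    pathways = im.GeneSetCollection({"SHIFTED": list(SHIFTED_PATHWAY), **NULL_PATHWAYS})
    return expr, clinical, pathways, gmap, truth


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
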