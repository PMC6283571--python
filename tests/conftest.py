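import logging

import numpy as np
import pandas as pd
import pytest

import immunoscape as im

logging.getLogger("immunoscape").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with the default effect sizes (fast stand-in for the
    full-size default cohort in tests that only need the structure)."""
    params = im.CohortSimulationParams(n_tumor=120, n_normal_pairs=20, n_genes=400, seed=11)
    expr, clinical, signatures, truth = im.simulate_cohort(params)
    return params, expr, clinical, signatures, truth


@pytest.fixture(scope="session")
def small_cohort_groups(small_cohort):
    """Quadrant assignment for the small cohort's tumor samples."""
    _, expr, clinical, signatures, truth = small_cohort
    tumors = clinical.tumor_samples()
    scores = im.score_cell_types(expr, signatures)
    bscore = im.scores_wide(scores)["B_cells"].loc[tumors]
    pdl1 = expr.gene_values(im.PDL1_GENE).loc[tumors]
    groups = im.stratify_quadrants(pdl1, bscore)
    return groups, bscore, pdl1


@pytest.fixture()
def toy_expression():
    """5 genes x 4 samples with hand-checkable values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [5.0, 6.0, 7.0, 8.0],
            [0.0, 0.5, 1.5, 2.0],
            [10.0, 10.0, 10.0, 10.0],
            [2.0, 4.0, 8.0, 16.0],
        ]
    )
    return im.ExpressionMatrix(
        [f"g{i}" for i in range(5)], [f"s{i}" for i in range(4)], values
    )


def make_expression(gene_ids, sample_ids, values):
    return im.ExpressionMatrix(list(gene_ids), list(sample_ids), np.asarray(values, float))


@pytest.fixture(scope="session")
def endtoend_inputs(tmp_path_factory):
    """On-disk inputs for the full-pipeline positive control: a heterogeneous
    cohort with one pathway shifted 1.6x (A to D) and 3.0x (D to C)."""
    out = tmp_path_factory.mktemp("endtoend")
    params = im.CohortSimulationParams(
        n_tumor=200, n_normal_pairs=10, n_genes=800, seed=6, log2_noise_sd=2.5
    )
    expr, clinical, signatures, truth = im.simulate_cohort(params)
    tumors = clinical.tumor_samples()
    bscore = im.scores_wide(im.score_cell_types(expr, signatures))["B_cells"].loc[tumors]
    pdl1 = expr.gene_values(im.PDL1_GENE).loc[tumors]
    gmap = im.stratify_quadrants(pdl1, bscore).set_index("sample_id")["group"]
    shifted = [f"G{i:05d}" for i in range(40)]
    null_sets = {
        f"NULL{j}": [f"G{i:05d}" for i in range(40 * (j + 1), 40 * (j + 2))] for j in range(5)
    }
    expr2 = im.embed_group_pathway_shift(expr, gmap, shifted, 1.6, 3.0)
    im.write_expression_tsv(expr2, out / "expression.tsv")
    im.write_clinical_tsv(clinical, out / "clinical.tsv")
    im.write_gmt(signatures, out / "sets.gmt")
    im.write_gmt(im.GeneSetCollection({"SHIFTED": shifted, **null_sets}), out / "pathways.gmt")
    targets = shifted[:20] + [f"G{i:05d}" for i in range(700, 740)]
    (out / "targets.txt").write_text("\n".join(targets) + "\n")
    config = im.PipelineConfig(
        expression=str(out / "expression.tsv"),
        clinical=str(out / "clinical.tsv"),
        signature_gmt=str(out / "sets.gmt"),
        pathway_gmt=str(out / "pathways.gmt"),
        targets=str(out / "targets.txt"),
        n_perm_gsea=200,
        n_perm_drug=2000,
        seed=6,
    )
    return out, config, shifted
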