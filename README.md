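# immunoscape

Tools for asking how tumor-infiltrating B cells and the immune checkpoint
ligand PD-L1 (CD274) jointly shape outcomes in bulk tumor transcriptomes, in
the style of TCGA lung-adenocarcinoma analyses. The package covers the whole
chain from an expression matrix to drug-target candidates:

1. **Infiltration scoring** — per-sample single-sample GSEA (ssGSEA) over
   cell-type signature gene sets: genes are ranked by decreasing expression
   within each sample and the score is the summed difference between a
   rank-weighted in-set ECDF (weight `rank^α`, α = 0.25) and the uniform
   out-of-set ECDF.
2. **Quadrant stratification** — tumors are split at the medians of PD-L1
   expression and the B-cell score into groups A (low/low), B (high
   PD-L1/low B), C (high/high) and D (low PD-L1/high B).
3. **Survival** — Kaplan–Meier curves, log-rank tests and univariate /
   multivariate Cox proportional-hazards models (age, sex, stage, EGFR and
   KRAS status as covariates).
4. **Expression landscape** — one-way ANOVA on log2(x+1) across the
   quadrants with Benjamini–Hochberg FDR, Ward clustering of patients on the
   top-100 FDR genes, and silhouette-based choice of the cluster number.
5. **Pathway selection** — two-group GSEA (signal-to-noise ranking,
   weighted Kolmogorov–Smirnov enrichment score, phenotype permutation for
   NES and FDR) for the C-vs-A and D-vs-A contrasts, then the ΔNES rule:
   among pathways with C-vs-A FDR ≤ 0.05, select those with
   `NES(C vs A) − NES(D vs A) ≥ 0.25`.
6. **Candidate genes** — pool the leading-edge (core-enrichment) genes of
   the selected pathways and keep genes whose group means rise sequentially
   A → D → C by ≥ 1.5-fold per step (pseudocount 1) at ANOVA FDR < 0.01.
7. **Drug-target enrichment** — permutation test of the candidate list's
   overlap with a drug-target gene list: fold enrichment = observed overlap
   over the mean overlap of random candidate-sized draws from a gene
   universe, with a one-sided permutation p and an exact hypergeometric
   cross-check.

A synthetic-cohort generator (`immunoscape.simulate`) provides TCGA-like
data with known ground truth — latent infiltration factors, a PD-L1–B-cell
coupling, proportional-hazards survival and embeddable A < D < C pathway
shifts — so every stage is testable without downloads.

## Worked example

The numbered scripts under `analysis/` run the full chain on the synthetic
cohorts and write their tables under `results/`. For example:

```bash
cd analysis
python 03_stratify_survival.py
```

prints (seed 17 default cohort, 479 tumors, 2,000 genes):

```
quadrant sizes: {'A': 157, 'B': 83, 'C': 156, 'D': 83}
high vs low B score: log-rank p = 1.26e-23, restricted-mean survival difference = 1435 days
group D vs A: log-rank p = 2.44e-10, mean survival difference = 1080 days
multivariate Cox, high vs low B score: HR = 0.44 (p = 2.10e-09) adjusting for age, sex, stage, EGFR, KRAS
```

The diagonal quadrants (A and C) outnumber the off-diagonal ones because
PD-L1 is positively coupled to the B-cell factor; the hazard ratio below 1
reflects the protective B-infiltration effect built into the generator. And

```bash
python 05_pathway_gsea.py
```

```
 SHIFTED: NES 2.64 (C-A) vs 2.24 (D-A), ΔNES +0.40 SELECTED
published table: 12 pathways pass the FDR gate, 5 selected by ΔNES >= 0.25: Apical surface,
Apoptosis, Interferon-a response, KRAS signaling upregulation, TNF-a signaling via NF-kB
```

shows the ΔNES rule recovering the pathway embedded with an A < D < C
expression ladder, and the same rule applied to the twelve published
hallmark-pathway NES pairs selecting exactly the five reported pathways.

There is also a CLI (`immunoscape simulate|infiltrate|stratify|gsea|
delta-nes|candidates|drug-enrich|run`) for running the stages on files; see
`immunoscape --help`.

## Layout

- `src/immunoscape/` — the library (I/O, simulator, ssGSEA, clinical
  statistics, clustering, GSEA, candidates, drug enrichment, pipeline, CLI)
- `analysis/` — numbered narrative drivers writing `results/`
- `tests/` — pytest suite, including brute-force oracles for every core
  statistic
- `docs/methods.md` — the methods note
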