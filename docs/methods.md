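# Methods

## Scope and data model

The package analyzes a genes × samples matrix of non-negative, already
normalized bulk RNA-seq expression (RSEM-like units). It never re-normalizes;
stages that need log scale apply `log2(x + 1)` internally. Gene identity is
exact string match — no alias resolution. Clinical records carry overall
survival (days), the event indicator, age, sex, ordinal stage I–IV
(sub-stages IA/IB/… are collapsed by prefix), EGFR/KRAS mutation status and
tumor/normal pairing.

## ssGSEA infiltration scores

For each sample, all genes are ranked by decreasing expression with average
ranks for ties (walk order among ties fixed by gene ID, so results are
deterministic and independent of input order). Walking the ranked list, the
score accumulates the difference between a weighted in-set ECDF — weight
`rank^α` at each in-set gene, normalized to sum 1 over the set — and the
uniform out-of-set ECDF, summed over all positions. α defaults to 0.25, the
weighting commonly used for this statistic. Because only ranks enter, the
score is exactly invariant under any strictly increasing transform of one
sample's values; the tests assert this. Min-max rescaling of each cell
type's scores to [0, 1] across samples is available (`rescale=True`) but off
by default, since whether to rescale before median dichotomization is a
user-level choice; both behaviors are exposed.

## Quadrant stratification

High = value > median, low = value ≤ median, with both medians computed over
all tumor samples. The tie side was chosen so that both halves are non-empty
for odd n; it is deterministic under ties. Labels: A = low PD-L1/low B,
B = high PD-L1/low B, C = high/high, D = low PD-L1/high B. Constant PD-L1 or
B scores make the split meaningless and raise an error.

## Survival

Kaplan–Meier estimation, the log-rank test and Cox proportional-hazards
regression are delegated to `lifelines` (partial likelihood maximized by
Newton–Raphson, Breslow tie handling — adequate at day-granularity data).
Categorical covariates expand against fixed reference levels: stage I, male,
non-mutation, low. "Mean survival difference" between groups is the
difference of restricted means — the area under each KM curve up to the
largest observed time — because a mean is otherwise undefined under
censoring. Univariate mode fits each covariate alone; a rank-deficient
design (duplicated or constant covariates) is rejected before fitting, and
fewer than five events per coefficient triggers a warning.

## Group comparisons

Tumor-vs-paired-normal score differences use the Wilcoxon signed-rank test
(exact null for ≤ 25 non-zero differences, normal approximation with
continuity correction above; zero differences dropped); the unpaired
rank-sum test is exposed as an alternative. Stage trends use the
tie-corrected Kruskal–Wallis H with chi-square p. The post-hoc pairwise
comparisons are Dunn rank tests with a Tukey-style familywise adjustment:
each pairwise z statistic, scaled by √2, is referred to the studentized
range distribution over the k groups. "Tukey after Kruskal–Wallis" is not a
uniquely defined procedure; this interpretation keeps the rank-based test
and the familywise control and is implemented by hand (no installed package
provides Dunn tests). The PD-L1 ~ B-score (+ T-score) association is
ordinary least squares with t-based p-values.

## Variant genes and clustering

Differential expression across the quadrants is a fully specified one-way
ANOVA F test per gene on `log2(x + 1)`, with Benjamini–Hochberg FDR across
genes. (A count-model quasi-likelihood test would be mis-specified here: the
input is normalized expression, not raw counts.) Genes with zero variance
everywhere report p = 1; groups with one sample are excluded with a warning.
The top-k genes are the k smallest FDR values, ties broken by smaller p and
then gene ID. Patients are clustered on those genes with Euclidean
distances, genes standardized to zero mean/unit variance first (row scaling,
as heat-map clustering conventionally does; `standardize=False` disables
it), Ward linkage, and labels extracted for k = 2…10. The cluster number is
the k with the largest mean silhouette (same Euclidean distances; ties go to
the smaller k; points in singleton clusters get silhouette 0).

## GSEA and the ΔNES rule

Genes are ranked by signal-to-noise: `(μ₁ − μ₂)/(σ₁ + σ₂)` on log2(x+1)
values, with each group's standard deviation floored at `0.2·|μ|` (absolute
floor 0.2 when μ = 0), the classical variance regularization for small
groups. The enrichment score is the signed maximum of the weighted KS
running sum — hits add `|metric|^w` normalized over in-set hits, misses
subtract `1/(N − N_h)` — with weight w = 1 (the standard "weighted" choice;
w = 0 reduces the statistic to the classical two-sample KS on set positions,
which the tests check against an independent KS oracle). Leading-edge
(core-enrichment) genes are the in-set genes at or before the peak for
positive ES, at or after it for negative ES.

Significance uses phenotype permutation (group labels reshuffled, default
1,000 times), which is appropriate at these group sizes; NES = ES divided by
the mean magnitude of same-sign permuted ES, the nominal p is the same-sign
tail fraction floored at 1/n_perm, and the FDR is the sign-matched ratio of
pooled permuted-NES and observed-NES tail fractions, capped at 1. Fixed
seeds make runs bit-reproducible.

The ΔNES rule first gates on C-vs-A FDR ≤ 0.05, then computes
ΔNES = NES(C vs A) − NES(D vs A) and selects pathways with ΔNES ≥ 0.25 on
the positive side (an `absolute=True` flag selects on |ΔNES| instead; the
one-sided rule is the default because the selection targets pathways *more*
active when PD-L1 is high). Applied to the twelve published
hallmark-pathway NES pairs, the recomputed ΔNES column matches the printed
one within the 0.01 rounding of two NES decimals and reproduces the five
selected pathways exactly.

A caveat the positive-control experiments make explicit: with phenotype
permutation, a pathway shifted strongly and uniformly in *both* contrasts
saturates the ES and inflates its own permutation null, compressing NES
toward a ceiling (~2–2.5 at 10³ permutations); ΔNES then loses its sign
information. The ΔNES rule discriminates in the regime the published values
occupy — moderate NES (1.5–2.4), with the D-vs-A contrast clearly weaker —
and the end-to-end positive control is therefore built in that regime (a
dispersed cohort, log2 SD 2.5, with a 1.6× A→D and 3.0× D→C ladder).

## Candidate genes

The leading-edge genes of the selected pathways (C-vs-A run) are pooled,
deduplicated and sorted. "Sequential 1.5-fold increases in the order A, D,
C" is interpreted as each step (A→D and D→C) reaching the threshold on the
normalized scale with pseudocount 1 added before each ratio (folds stay
finite at zero means); a `cumulative=True` flag implements the alternative
reading (C/A ≥ 1.5 with monotone means). The FDR gate comes from a
three-group (A, D, C) ANOVA over the pooled gene list with BH adjustment —
a list-scoped test, since the filter is applied to the pooled core genes
only.

## Drug-target enrichment

The observed candidate ∩ target overlap is compared with the overlaps of
`n_perm` random draws of |candidates| genes, uniform without replacement
from the universe (default: the expression matrix's gene list; a count-only
mode accepts the four counts directly for reproducing published numbers).
Fold enrichment = observed / mean null overlap; one-sided
p = (#null ≥ observed)/n_perm, reported as an upper bound `1/n_perm` when no
null draw reaches the observed overlap, with no +1 correction (the
+1-corrected estimator is a documented alternative; the uncorrected count
matches the convention behind the published p at 10⁴ permutations). The
hypergeometric closed form (expectation `nK/N`, exact upper tail) serves as
an analytic cross-check; at 10⁵ permutations the permutation null matches it
within Monte-Carlo error in the tests. Candidates are not removed from the
universe before drawing.

## Synthetic cohorts

The generator emulates the statistical structure of a TCGA-like
adenocarcinoma cohort (defaults: 479 tumors, 58 paired normals, 2,000
genes):

- **Expression**: log-normal per gene — baseline log2 levels uniform on
  [5, 10], patient-to-patient log2 SD 0.35 (a moderately variable gene;
  chosen so a 1.6-fold group shift is reliably detectable by the 1.5-fold
  filter at the cohort's group sizes, where the sampling CV of a group-mean
  ratio is ≈ 4%).
- **Infiltration**: latent B and CD8 T factors, standard normal in tumors
  with correlation 0.3; normals sit one SD lower on B and one SD higher on
  T, giving the tumor-vs-normal contrast in both directions. Signature genes
  (25 per cell type) shift by `infiltration_effect` (default 1.0)
  log2-units per latent unit.
- **PD-L1**: the reserved gene `CD274` (never in a signature set) is linear
  in the B factor (coefficient 5, Gaussian noise SD 12 — a correlation of
  ≈ 0.35, which reproduces the ~30/20/30/20 quadrant occupancy of a
  moderately coupled checkpoint) plus an intercept keeping values
  non-negative.
- **Stage**: an ordinal thinned against the B factor (higher infiltration →
  earlier stage), cutpoints set by a baseline mix of ~54/25/16/5% for
  I/II/III/IV.
- **Survival**: exponential event times with hazard
  `h₀·exp(β_B·B + β_stage·(stage−1))` (defaults h₀ = 1/1500 per day,
  β_B = log 0.6, β_stage = log 1.7) and independent exponential censoring
  (rate 1/1800 per day) — proportional hazards by construction, so Cox
  recovery is a meaningful check.
- **Pathway shifts**: `embed_group_pathway_shift` multiplies a gene set by
  1 in quadrant A, `fold_AD` in D and `fold_AD·fold_DC` in C — exact,
  deterministic multipliers.

One `numpy` Generator drives everything; a fixed seed reproduces the cohort
bit for bit.

What the generator does *not* emulate: negative-binomial count noise,
batch effects, gene–gene correlation beyond the latent factors,
non-proportional hazards, B-cell subtype structure, or realistic mutation
spectra. Passing tests therefore demonstrate that the pipeline's statistics
behave correctly under their own model assumptions, not that the biological
conclusions transfer to any particular real cohort.

## Problem sizes used in tests and drivers

The test suite runs compact configurations chosen for coverage: cohorts of
60–500 tumors, 60–2,000 genes, 100–200 label permutations for GSEA, 10³–10⁵
draws for overlap permutation, and 100 replicate fits for the Cox-recovery
coverage check. The analysis drivers use the full-size default cohort and
1,000 GSEA permutations. The published drug-enrichment statistic is
recomputed at its original size (10⁴ permutations over a 19,035-gene
universe).

## Numerical and degenerate-input conventions

- Ties: average ranks in ssGSEA; metric ties in GSEA rankings broken by gene
  ID; FDR ties in top-k broken by p then gene ID; silhouette ties by smaller
  k.
- Errors over silent misbehavior: empty effective gene sets, sets covering
  the whole matrix, constant stratification variables, all-zero paired
  differences, rank-deficient designs and inconsistent overlap counts all
  raise with location-bearing messages.
- Warnings with graceful degradation: set genes missing from the matrix,
  stages/groups with < 2 samples, pathways with no testable genes,
  candidates outside the universe, singleton silhouette clusters.
- Floats are written at 6 significant digits with deterministic row order,
  so repeated runs produce byte-identical outputs.
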