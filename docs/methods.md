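# Methods

## Overview

`rgepdeconv` implements a complete benchmark pipeline for reference-based
bulk expression deconvolution: a generative model of multi-source
single-cell cohorts, the preprocessing and cell-classification workflow that
turns annotated single cells into reference gene expression profiles
(RGEPs), four mixture solvers with unknown-fraction handling, accuracy
benchmarking across five reference configurations, and tumour-profile
purification. This note records the model assumptions, the parameters that
matter, and the numerical decisions taken where the design was genuinely
open.

## Generative model of the synthetic cohort

The generator emulates a three-source design — peripheral blood plus two
tumour sites — with, by default, 4 + 19 + 4 = 27 patient samples and one
sample per patient.

Expression is modelled log-normally: every cell type × source pair has a
mean profile in log2(TPM+1) space, and a cell adds i.i.d. Gaussian noise
(`noise_sd`, default 0.3 log2 units) to its type's mean before being
exponentiated, subjected to Bernoulli dropout (`dropout_rate`, default
0.05), and rescaled so each cell sums to 10⁶ (TPM). A negative-binomial
count layer is deliberately omitted: the entire downstream pipeline operates
on TPM/log2 values, so count-level realism would add cost without touching
any quantity the analysis consumes. Dropout is likewise a post-hoc zeroing,
standing in for the zero inflation of real single-cell data.

Structure in the mean profiles:

- **Background programmes.** Each type expresses a random ~45 % of the
  background genes at levels drawn from N(4, 1.5) (log2 units, clipped at
  zero). The three T-cell subsets perturb one shared T-cell base programme
  (`subset_shift_sd`, default 1.0) instead of drawing independent
  programmes, so they form a correlated continuum rather than distinct
  islands — deliberately the hardest case for the classifier's second stage.
- **Marker genes.** Every cell type (and the T-cell parent) owns 2 AND and
  2 OR genes expressed at base + 4 log2 units in the owning population and
  silent elsewhere; NOT lists are populated with the AND markers of sibling
  types. The default panel uses 44 marker genes, matching the scale of a
  curated 45-gene panel.
- **Housekeeping genes.** 10 % of genes share one fixed log2 level across
  all types, sources and patients; they anchor the housekeeping
  normalization and contribute the shared signal that creates a baseline
  correlation between unrelated cell-type profiles.
- **Source shifts.** Non-blood sources add a per-gene N(0, `source_shift_sd`)
  log2 shift (default 0.5) to every non-housekeeping gene, independently per
  (type, source). This is the knob that separates RGEP1/2/3.
- **Patient effects.** Malignant types receive an additional per-patient
  N(0, `patient_shift_sd`) shift (default 0.4), making the malignant profile
  patient-specific — the raison d'être of the CNTR configurations and of
  purification.
- **Compositions.** Per-sample mixing proportions are Dirichlet draws with
  source-specific concentrations (tumour-associated types are structurally
  absent from blood). The stored ground truth is the *realized* label
  frequency of the multinomial cell draw, not the Dirichlet parameter, so
  truth and data are exactly consistent at any cell count.

Per-sample cell counts are configurable (default 100 cells/sample for the
benchmark cohort, 220 for the classification fixture); they were chosen as
the smallest sizes at which every population still forms a dense t-SNE
cluster under the default DBSCAN parameters.

What the generator does **not** emulate: UMI counting noise, doublets,
ambient RNA, batch effects within a source, cell-cycle structure, and
cross-platform quantification biases. Passing tests therefore demonstrate
the internal consistency and calibration of the pipeline under its own model
assumptions, not performance on real cross-platform data.

## Preprocessing

Processing order is fixed: TPM → log2(TPM+1) → housekeeping rescaling
(ỹᵢ = yᵢ·H̄K/HKᵢ, with HKᵢ the column's mean log2 expression over the
housekeeping set and H̄K the grand mean over all housekeeping genes and
columns). The grand mean is computed jointly over whatever matrix is being
normalized; an external `reference_mean` can be supplied so independently
processed data sets share one scale. The operation is idempotent and
equalizes per-column housekeeping means to the grand mean exactly.
Quantile-based alternatives are not offered: single-cell columns contain too
many zeros for upper-quartile or median statistics to be stable.

Gene identifiers corrupted by spreadsheet date auto-conversion ("1-Mar",
"Sep-2", "1.3.2016") are mapped back to their symbols (MARCH1, SEPT2, …) via
the known corrupted families (MARCH1–11, SEPT1–12/14, DEC1); the repair
aborts if it would create duplicate identifiers.

## Cell classification

One stage = PCA (50 components) → Barnes–Hut t-SNE (perplexity 30, fixed
seed) → DBSCAN (MinPts 25, Eps 1.5) → marker scoring → cluster labelling →
decision tree → posterior thresholding. The marker score per cell and type
is

mean(normalized AND genes) · 1[all AND genes > 0] + max(normalized OR genes)
− mean(normalized NOT genes), floored at 0,

with every marker gene min-max normalized to [0, 1] across all cells of the
run. The three categories are specified semantically (all AND genes
required, one OR gene sufficient, NOT genes count against); this algebra is
the simplest rule satisfying those semantics, and the exact combination is a
package design choice. Cluster-level labels use summed member scores: a
cluster is labelled only if exactly one type exceeds 75 % of the cluster's
maximal total, which leaves ambiguous clusters (e.g. NK vs T) unlabelled
rather than guessing. The decision tree (Gini, unpruned, leaf class
fractions as posteriors) is trained on these sparse labels and applied to
all cells; cells below a 0.99 posterior are reported "unknown". Accuracy is
assessed by stratified 5-fold cross-validation over the labelled cells.

The T-subset stage reruns the identical pipeline on the cells labelled
"T cell", with only DBSCAN's radius widened to 1.75 (the subset map is
sparser). The 0.99 rule applies at both stages; a cell whose subset
posterior stays below threshold keeps its established major label "T cell"
instead of reverting to "unknown".

## Reference profiles and deconvolution

A signature column is the cell-weighted consensus of annotated cells from a
configuration-specific pool (blood only / all sources / target source /
patient-specific malignant column / fully patient-specific). "Unknown"
cells never contribute; a type with no cells in the requested pool is
dropped with a warning, and its mass then surfaces in the unknown fraction.
Consensus averaging is log-space by default in `build_rgep` and linear in
`run_benchmark`: pseudobulks aggregate transcripts linearly, so linear
averaging makes a patient's pseudobulk an exact mixture of its own consensus
columns, whereas log-averaging introduces a Jensen bias that penalizes
precisely the configurations built from the fewest cells.

Solvers operate on the **linear TPM scale**. This is a deliberate choice:
the mixture identity m = B·w holds for transcript abundances, not for their
logarithms, and the housekeeping rescaling — a multiplication of *log*
values — acts as a per-column power transform on linear values that would
destroy the identity. Within a single-pipeline cohort all columns already
share the TPM scale, so the deconvolution path omits the housekeeping step;
it remains in the classification path and is available (with a shared
reference mean) for harmonizing bulk data measured on a different pipeline.
A `space="log"` option exists for exploration.

The four solvers:

- **ν-SVR** (default): linear kernel, ν = 0.5, C = 1, on per-gene
  standardized data (rows of B centred/scaled by their own mean and s.d.,
  the same affine map applied to m). Per-gene centring makes every
  standardized row sum to zero, so the all-ones direction of the weight
  vector is unidentified and the SVR returns weights shifted by a constant;
  the gauge is pinned afterwards by a one-parameter least-squares fit in the
  original scale. This restores absolute calibration while keeping the
  ε-insensitive loss's robustness to noisy genes.
- **Pseudo-inverse**: minimum-norm least squares, w = pinv(B)·m.
- **Least squares with intercept**: the intercept is reported separately and
  excluded from the weights.
- **Regularized NNLS**: min ‖Bw − m‖² + λ‖w‖² s.t. w ≥ 0 with λ = 1, solved
  exactly as an augmented non-negative least-squares system
  [B; √λ·I]w = [m; 0] (an active-set NNLS solve of the same convex QP).

Post-processing follows the reference convention: negative weights are set
to zero and w̃ = 1 − Σw. If Σw exceeds one (possible after noise), the
weights are renormalized to sum one and w̃ = 0, keeping the conservation
invariant Σw + w̃ = 1, w ≥ 0, w̃ ≥ 0 unconditionally. With λ = 1 on
TPM-scale values the ridge bias of the NNLS solver is negligible (‖B‖ is of
order 10²–10⁴ per gene).

## Benchmarking

For every sample the pseudobulk (per-gene mean of the TPM cells, rescaled to
10⁶) is deconvolved against the configuration-appropriate signature on the
"merged" gene set (all marker genes plus the 400 most variable background
genes across type profiles). Accuracy per cell type is the Pearson ρ between
estimated and true fractions across samples; uncertainty comes from
bootstrap resampling of the *samples* (100 replications, degenerate
resamples redrawn), summarized as median and quartiles. RMSD is reported
alongside. A type whose true fraction is constant across samples is reported
missing rather than zero — correlation is not a meaningful accuracy measure
there. T subsets are evaluated individually, as a summed total, and through
the ratios Treg/CD4, CD8/Treg, CD4/CD8, with samples whose denominator falls
below 10⁻⁴ excluded. Configuration orderings are compared as the median
per-type ρ over the types estimated by *all* configurations, since the
blood-only configuration estimates no tumour-associated types at all.
Leave-one-type-out robustness drops one signature column at a time,
re-deconvolves every sample, and reports the change in per-type ρ.

## Tumour-profile purification

t = (m − B₍non-tumour₎·w₍non-tumour₎)/w₍tumour₎ is applied genewise on the
linear TPM scale, with estimated (not true) weights; negative
post-subtraction values are floored at zero (expression cannot be negative)
and the floored count is reported. Purification requires w₍tumour₎ > 0.01;
below ~20 % tumour content the result is known to be noise-dominated and is
reported but not trusted. Accuracy is the Pearson ρ between the purified
profile and the true patient-specific malignant profile in log2 space over
all genes, compared per sample with the uncorrected bulk's ρ. On noiseless
data with fully known composition the recovery is exact; under noise,
accuracy rises monotonically with tumour content, and at intermediate
content (20–70 %) purification beats the uncorrected bulk.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration objects; cohorts, embeddings, classifiers and bootstraps
  are bit-reproducible given a seed (ν-SVR is reproducible to optimizer
  tolerance, ~10⁻⁵, under gene reordering).
- Zero-variance gene rows are dropped before SVR standardization; a
  signature whose rows are all constant is rejected as degenerate.
- All-zero cells stay all-zero under TPM rescaling; empty samples are legal
  (empty matrix, empty annotation).
- Housekeeping normalization refuses columns with non-positive housekeeping
  means, naming the columns.
- DBSCAN noise cells and ambiguous clusters simply contribute no training
  labels; classification requires at least two labelled classes and errors
  otherwise.

## Problem sizes

Default analyses use 1000 genes, 27 samples × 100 cells for benchmarking,
1320 cells for the classification fixture, and 9-sample sweeps for the
tumour-content analysis. These sizes were chosen so that every population is
represented well enough for the pipeline's density-based steps while keeping
a full benchmark run under a minute; all of them are configuration
parameters, and the pipeline scales to larger cohorts unchanged.

## Known limitations

- The unknown-fraction calibration is exact only when the missing type's
  profile is near-orthogonal to the retained columns; shared programmes
  (housekeeping genes above all) let part of the missing mass be absorbed by
  known types.
- ν-SVR's absolute calibration relies on the gauge-pinning step; the raw
  libSVM coefficients alone are only determined up to a constant shift under
  per-gene standardization.
- The synthetic marker model makes AND genes essentially clean; real marker
  panels contain genes with graded, overlapping expression, so real-data
  classification accuracy will be lower than the fixture's.
- Correlation-based accuracy saturates: with only source-level shifts
  separating configurations, the orderings are reproducible but the gaps
  between RGEP2 and RGEP3 are small.
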