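# Methods

## The model

An enhancer's transcriptional state is treated as a binary outcome: eRNA⁺
(bidirectionally transcribed) or eRNA⁻. The classifier is a binomial-logit
GLM on chromatin-mark signal,

    logit p_j = β₀ + Σ_i β_i x_ij ,

where `x_ij = log₂(d_ij + 1)` and `d_ij` is the depth-normalized average
read density of mark *i* in the signal window of enhancer *j*:
reads whose midpoint falls in the window, per kb of window, per million
mapped reads in the track. Midpoint assignment guarantees each read counts
in at most one window; depth normalization makes coefficients and
predictions comparable across datasets and cell types, which the transfer
analysis relies on. GRO-seq sense and antisense densities `y⁺_j`, `y⁻_j`
are computed the same way, per strand.

Assumptions worth stating: within each latent state the log densities are
roughly Gaussian (true by construction in the simulator, approximately true
for deeply sequenced real tracks); marks act additively on the log-odds; and
the labeled classes are separable enough that a linear boundary is useful.

## Enhancer catalog

Candidate peaks become signal windows of ±1,000 bp around the peak midpoint
(configurable; the window matches the < 2 kb span of eRNAs). Windows are
kept only if the peak overlaps no gene body, the window is at least
`tss_exclusion_bp` = 3,000 bp (edge-to-edge) from every TSS and every
H3K4me3-enriched region, and the length-weighted mean mappability of the
window is at least 0.85 — strictly-below drops, so a window at exactly 0.85
survives. Bases not covered by the mappability track count as 0, the
conservative reading. All coordinates are 0-based half-open; distances are
edge-to-edge gaps (0 when overlapping). TSS means the strand-aware 5′ base
(txStart for +, txEnd − 1 for −). An H3K4me1⁺me3⁻ catalog (for cell types
lacking P300 data) uses the same filter with a provenance flag, not separate
code.

## eRNA labeling

The histogram of log GRO-seq density across enhancers is bimodal (high- and
low-expression modes), so each strand is partitioned by 2-means. One-
dimensional 2-means has contiguous optimal clusters in sorted order, so the
implementation scans all n−1 splits of the sorted values with prefix sums
and returns the exact global optimum — no Lloyd iterations, no
initialization randomness. The threshold is the midpoint between the
boundary members; values at the threshold fall in the low cluster
(conservative toward eRNA⁻). Labels combine per-strand calls: high/high →
positive, low/low → negative, mixed → ambiguous. Ambiguous enhancers are
excluded from supervised training and testing but remain scorable by a
fitted model; this matches the observed arithmetic of such datasets, where
positives plus negatives fall short of the filtered catalog.

## Fitting

Penalized maximum likelihood by Newton–Raphson on standardized features
(per-mark mean/sd learned from the training rows and stored on the model).
A small L2 penalty on the slopes (λ = 10⁻⁶ by default, configurable to 0)
guards against complete separation at negligible bias; step-halving enforces
a non-decreasing penalized log-likelihood; convergence is max |score| <
10⁻⁸ or 100 iterations, with diagnostics recorded. Standardization makes
coefficients comparable across marks; raw-scale coefficients are recovered
as β_i/sd_i and exported alongside. Refits on identical data are
bit-identical.

## Evaluation

MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0 when a
denominator factor vanishes; reported at threshold 0.5 by default, with a
max-over-thresholds variant also available, since printed MCC values in the
literature rarely state their threshold. AUC is the normalized Mann–Whitney
statistic (ties half credit), identical to the trapezoidal area under the
ROC curve; a perfect ranking scores 1 and label-independent scoring averages
0.5. Both implementations are checked against brute-force pair counting /
direct formula evaluation and against scikit-learn in the test suite.

## Nested cross-validation and subset selection

The labeled set is split into K = 10 stratified outer folds (shuffled
positives and negatives dealt round-robin; deterministic under the run
seed). Within each outer-training split, a 10-fold inner CV ranks all
candidate subsets by mean validation AUC; the top `top_n_inner` = 10
subsets are refit on the full outer-training split and scored on the
held-out fold. Inner selection never sees outer test data. Subsets that
never reach an inner top list carry no outer score and are dropped; the
rest are ranked by mean outer AUC (ties: mean MCC, then lexicographic
order). `top_n_inner` is a genuinely open knob — carrying more models
widens the scored population at proportional cost; 10 keeps the outer
scoring cheap while letting near-ties survive to the outer loop.

Two selection rules are implemented and always labeled in output:
`top_fraction` (intersection of the top 5% by mean AUC and by mean MCC) and
`relative` (subsets reaching ≥ 95% of the full-model AUC **and** MCC).
Mark enrichment among selected models uses a one-sided upper-tail
hypergeometric test with the evaluated subsets as population; p-values are
reported raw (no multiplicity correction), as is conventional for this
descriptive statistic. The pipeline computes enrichment over the
relative-rule selection, which is larger and more stable than the 5%
intersection at desk scale. Best-model performance across subset sizes is
compared with a paired two-sided Wilcoxon signed-rank test on the shared
outer-fold AUCs (exact null for ≤ 25 folds, no-tie case); pairing is
appropriate because the compared models share folds.

## Activity stratification

Enhancer-to-gene assignment: nearest TSS to the window center, at most
100 kb, equidistant ties to the lower-coordinate TSS. H3K27ac⁺ means an
edge-to-edge gap ≤ 2,000 bp to any H3K27ac peak. Crossing eRNA status
(measured or predicted) with H3K27ac status yields four subgroups whose
associated-gene FPKM distributions are compared with two-sided Mann–Whitney
tests (exact for small tie-free samples, normal approximation with
continuity correction otherwise). A gene linked by several enhancers of one
group counts once in that group, avoiding pseudo-replication. Cross-cell
transfer re-standardizes the model's marks on the target cell type by
default (training-cell standardization is selectable), so the linear
predictor sees comparably scaled inputs.

## The synthetic data generator

The generator emulates exactly the features the analysis depends on, on a
two-chromosome toy genome (genes of 5–20 kb alternating with intergenic
blocks):

* a latent per-enhancer state `A_j ~ Bernoulli(π)`, π = 0.55 by default
  (matching the roughly 4.9:3.6 positive:negative ratio such catalogs show);
* per-mark counts Poisson(depth · exp(effect_i·A_j + ε_ij)) with ε Gaussian
  (sd 1.0), so log densities are approximately Gaussian per state and the
  2-means labeling assumption holds by construction. Acetylations share a
  latent factor (ρ = 0.10) so subset selection faces genuine redundancy;
* planted effects (natural-log units): H3K27ac 1.8, H3K9ac 1.6, H2BK120ac
  1.5, H3K27me3 −1.6, all six remaining marks 0 — i.e. exactly four
  informative marks among ten. Effect sizes and ρ were calibrated once so
  that the generator meets its own recoverability targets (end-to-end
  full-model AUC ≥ 0.95 and reliable recovery of the informative subset by
  nested CV); with stronger redundancy the weakest acetylation carries too
  little marginal signal for any method to distinguish it from noise marks,
  which defeats the purpose of a planted-truth benchmark;
* GRO-seq effect 4.0 at noise sd 1.0 on both strands (bidirectionality),
  giving the bimodal log histogram and ≈ 4-sd class separation;
* mappability 1.0 everywhere except planted 0.5 segments over 5% of
  enhancers (deterministically exercising the < 0.85 filter), plus optional
  planted gene-body / TSS-proximal violator sites in stated numbers for
  exact filter tests;
* gene expression log-normal, with genes linked to an active enhancer
  shifted up by 2.0 natural-log units.

What the generator does **not** emulate: fragment-length and PCR-duplicate
structure, chromatin-domain autocorrelation along the genome, copy-number
and GC biases, overlapping genes, and genome-scale track sizes. Passing
recovery tests therefore demonstrates correctness of the pipeline's
inference under its stated assumptions, not performance on real tracks.

## Numerical choices and degenerate inputs

Log transform log₂ with pseudocount 1 (the exact base/pseudocount used on
real data varies between studies; both are configurable). 2-means on
identical values raises a degenerate-input error. Zero-denominator MCC → 0.
Constant features cannot be standardized and are rejected at fit time
(inner CV folds replace a zero sd by 1, yielding a zero column and a ~0
slope, so exhaustive enumeration never aborts mid-scan). A track with zero
total reads cannot be depth-normalized and raises. Identical paired score
vectors short-circuit the Wilcoxon test to p = 1.

## Reproducibility

One global seed fans out to per-stage seeds by hashing the stage name (all
below 2³¹), so stages rerun independently yet reproducibly; two `run-all`
executions under one seed write byte-identical data outputs. The manifest
records SHA-256 digests of every stage output; its timestamps are the only
non-deterministic bytes in a run directory, so determinism checks compare
the data files and digest columns, not the manifest's clock.

## Problem sizes

Default study conditions: 2,000 enhancers, 2,400 genes, 10 marks,
10×10 nested CV, subset sizes 1–4 (385 models). The code path is identical
for larger enumerations (e.g. all C(24,4) = 10,626 four-mark models of a
24-mark compendium); the defaults simply keep a full experiment at a few
minutes on one CPU. Tests use 150–2,000 enhancers depending on what the
property needs.
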