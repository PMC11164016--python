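# Methods notes

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Compositional statistics

Counts are treated as compositions: after adding a pseudocount (default 0.5,
a common Bayes-multiplicative choice; the source data never states one) each
sample is closed to proportions, log-transformed and row-centered (clr).
Aitchison distance is the Euclidean distance between clr rows. PERMANOVA
follows Anderson's direct formulation — total and within-group sums of
squared distances give the pseudo-F — with the permutation p computed as
(1 + #{F_perm ≥ F_obs}) / (n_perm + 1), the unbiased convention that counts
the observed statistic in its own null set. Permutations shuffle raw labels
with no strata. Wilcoxon rank-sum comparisons use the exact null when both
groups have ≤ 10 observations and no ties, otherwise the tie-corrected
normal approximation; Bonferroni correction multiplies by the stated number
of tests and caps at 1.

Ward grouping implements classic Ward.D — the Lance–Williams update applied
to *unsquared* Euclidean distances, matching R's `hclust(method="ward.D")`
(SciPy only offers the Ward.D2 variant). Ties break to the lowest pair of
cluster indices, so the dendrogram is deterministic. Merge heights were
verified against R `hclust`/`cutree` on a fixed dataset and frozen into the
test suite.

## Topic model

LDA is fitted by batch variational EM. The E-step runs mean-field updates
for all samples simultaneously; responsibilities are never materialized —
with `t = exp(E[log θ])` and `denom = t @ β`, both the γ update and the
M-step sufficient statistics reduce to matrix products, and the z/w part of
the bound collapses to `Σ W·log denom`. Topic–genus rows carry a fixed
smoothing η = 0.1 (MAP under a symmetric Dirichlet prior); the tracked
objective includes the smoothing term so the trace is monotone by
construction. The symmetric document concentration α is estimated by
safeguarded Newton steps in log α, but only **after** the topics have
converged under the fixed prior 1/k: joint updates from the first iteration
collapse α early and drag the whole fit into a visibly worse bound (we
measured a lower final ELBO and badly biased topics when α is free from the
start). Five seeded restarts are kept by best bound; all reporting is
invariant to topic permutation. The number of topics minimizes the Cao
density criterion — the mean pairwise cosine similarity between topic–genus
rows — over k = 2…10, ties to the smaller k.

## Zero-sum log-ratio lasso

The taxon-level outcome model minimizes
`(1/n)·binomial NLL + λ·Σ pf_j |β_j|` subject to `Σ β_j = 0` over the
penalized features. Features are per-sample log relative abundances
(`log((count + 0.5)/(total + 0.5·G))`); under the constraint the linear
predictor is a combination of pairwise log-ratios, hence invariant to
sequencing depth (tested end-to-end from counts). The constraint is
enforced by an augmented Lagrangian: multiplier updates
`μ ← μ + ρ·Σβ` with ρ escalating ×10 per outer round (capped at 1e6) until
the residual is ≤ 1e-6; each subproblem is solved by IRLS with cyclic
coordinate descent and soft thresholding. The kernel precomputes
per-coordinate curvatures, alternates full passes with active-set passes,
and is numba-compiled. Near separation the penalized objective is flat
while coefficients creep, so IRLS also stops on objective stagnation; paths
warm-start coefficients *and* the multiplier across the λ grid and stop
early once essentially all deviance is explained. The solution matches an
SLSQP split-variable oracle to ~1e-8 in objective on toy problems.

λ grids are log-spaced from λ_max (the largest penalized gradient magnitude
at the covariate-only null fit) down 4 decades by default; stability runs
use a reduced grid (25–30 points over 3 decades) since λ_min never lands in
the bottom decade in practice. Folds are stratified by outcome — with few
events, unstratified 4-fold splits can produce single-class folds.
Per stability run the fold partition is re-randomized, λ_min re-selected,
and the full data refit at λ_min; the selection probability is the fraction
of runs with a nonzero coefficient. The null-calibration mode re-permutes
the outcome *per run*: a single fixed permutation has a fixed strongest
chance correlate which cross-validation legitimately treats as signal, so
only per-run permutation can certify that no feature accumulates selections
under the null. The same solver with the constraint off and a zero penalty
factor on the covariate is the metabolite logistic lasso; there the
per-fold coefficient vectors at λ_min are averaged (10-fold), matching the
fold-averaging description of the original analysis, and a feature counts
as selected when the averaged coefficient is nonzero.

## Metabolome QC

Stage order: batch adjustment → detection filter → collinearity pruning →
half-minimum imputation → log transform, each idempotent on its own output.
The anchor-ratio factor is computed **per metabolite** (the median of
reference/target ratios over anchor pairs with both values detected), with
a global-median fallback when fewer than three clean pairs exist, and a
`mode="global"` option. Collinearity is assessed on the signed Spearman ρ
(the stated threshold is "> 0.5", not absolute; an absolute mode exists);
within each connected component of the ρ > 0.5 graph the member with the
highest log-variance is kept (ties lexicographic). Representatives of
*different* components may still correlate above the threshold — the
invariant only covers former components — and such pairs are logged.
Natural log is assumed; standardization uses the n−1 denominator.

## sPLS-DA

Per component the weight vector keeps the top-keepX entries (by magnitude)
of the deflated covariance direction X'ỹ, renormalized to unit norm;
X and the response are deflated by the score regression. Classification is
by nearest class centroid in score space; tuning picks the
(n_components, keepX) pair minimizing mean balanced error rate over
repeated stratified 4-fold CV (ties prefer fewer components, then smaller
keepX) and reports the Monte-Carlo sd. This is the standard sparse-PLS
soft-thresholding scheme; bit-level equivalence with any particular
reference implementation is not claimed — acceptance is behavioral (BER ≈
0.5 under permuted labels, → 0 with a perfectly separating variable whose
loading dominates component 1).

## Engraftment

"Binary similarity" is the Jaccard index on ASV presence sets restricted to
one genus (presence = any nonzero count after filtering): joint absences
carry no information about shared colonization, which matches the
fraction-of-shared-ASVs reading; Dice is available behind a flag. Both the
post-FMT abundance and the pre-to-post change variants of the correlation
are reported.

## The synthetic trial generator

The generator emulates the *structure* of the trial, not its raw sequences:

- **Cohort**: 74 patients randomized 2:1 (49/25), 4 donors, PTCy-based
  prophylaxis probability 0.554, stool timepoints with per-timepoint
  retention tuned to the reported per-timepoint sample counts and serum
  timepoints likewise. Missingness is completely at random.
- **Composition**: three latent subcommunities with the anchor genera the
  trial describes (commensal: *Alistipes*, *Faecalibacterium*, *Blautia*;
  *Bacteroides*-type; oral/enteric: *Streptococcus*, *Veillonella*,
  *Escherichia-Shigella*) over 170 genera (≈ 160 survive the prevalence
  filter, matching the 162 analyzed in the trial). Sample topic weights are
  Dirichlet draws (concentration 60) around group means: donors and
  post-FMT samples lean on the commensal topic, pre-dose and post-placebo
  samples on a per-patient dysbiosis topic (so every topic dominates some
  samples), baseline samples on a random per-patient topic. Genus
  probabilities get Dirichlet-multinomial overdispersion (concentration
  400) — without it genera within a topic are almost perfectly collinear,
  which no regression method should be benchmarked against. Depth is
  log-uniform on [5k, 50k] with 3 % of samples shallow (< 1000 reads) to
  exercise the read filter.
- **Engraftment**: each donor owns 24 unique planted-genus ASVs plus 2 from
  a shared pool of 20 that recipients also draw from (so zero-engraftment
  similarity is small but not degenerate). Each FMT patient engrafts each
  donor ASV once with probability `engraftment_rate` (default 0.5); the
  engrafted fraction multiplies into the planted genus's abundance
  (boost 0.75), so similarity and abundance are coupled by construction.
  The planted genus keeps a deliberately small share (0.08) of its topic
  and is exempt from the overdispersion noise: its outcome-relevant
  variation is engraftment-driven and patient-specific, mirroring the
  trial's account of *Faecalibacterium* expansion through donor
  engraftment — and preventing its fellow anchors from acting as
  interchangeable proxies in regression.
- **Outcome**: Bernoulli with logit α + 1.5·(log-ratio of the planted genus
  to two designated stable reference genera, centered) + 0.5·PTCy, with α
  calibrated by root-finding so the marginal event rate is 0.35. A log-ratio
  (rather than clr) link keeps the generative signal *exactly sparse* in
  the zero-sum coefficient class; a clr-driven outcome is representable
  only densely (+β on the genus, −β/G on everything else), in which regime
  cross-validated λ_min legitimately selects near-dense models and no
  sparse-recovery benchmark is meaningful.
- **Metabolome**: 250 log-normal metabolites; 30 % sit in 5-member blocks
  sharing a latent factor (within-block Spearman ≈ 0.85); non-detections at
  5 % (45 % for a 30 % "poorly detected" subset, so the detection filter
  has work); two batches with per-metabolite multiplicative factors drawn
  log-uniform on [0.5, 2] and 18 reference samples re-run in the target
  batch as anchors; one planted metabolite (never zero, outside the
  collinear blocks) whose log level is 1.0 SD lower in patients with the
  event.

Everything is deterministic given the seed; each generator stage draws from
its own `SeedSequence` spawn key so disabling one stage cannot shift
another's stream.

**What the generator does not emulate:** read-level noise and chimeras
(counts are drawn at the ASV level), strain phylogenies, informative
missingness, time-varying antibiotic exposures, batch effects beyond a
multiplicative shift, and any real metabolite chemistry. Passing tests
demonstrate that the *methods* recover known planted structure under the
stated statistical assumptions — not that the trial's biological findings
are reproduced from raw data.

## Validation problem sizes

The test suite scales replicate counts to keep a full run fast: topic-model
recovery uses 12 replicates of 200 samples at depth 10k; taxa stability
recovery uses 4 simulated trials (plus 3 outcome-permuted) at 100 CV runs
each on a 25-point, 3-decade λ grid; metabolite stability uses 3 trials
(plus 3 permuted) at 100 repeats of 10-fold CV on a 20-point grid;
PERMANOVA calibration uses 500 null simulations at 199 permutations. The
acceptance script runs one full trial at the generator defaults (999
permutations, 100 stability runs/repeats, k searched over 2…10).

## Known limitations

- The stepwise two-stage ratio refinement offered by some log-ratio lasso
  implementations is deliberately not implemented; selection here is
  one-stage at λ_min. One-stage λ_min selection is known to overselect
  when the feature count is close to the sample count.
- PCoA reports only positive-eigenvalue axes and truncates (with a
  warning) when asked for more.
- The PERMANOVA is one-way with freely exchangeable labels; no strata or
  covariate adjustment.
- The sPLS-DA tunes a single keepX shared across components.
- BIOM-format I/O is not included; count tables are read and written as
  TSV.
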