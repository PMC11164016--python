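# fmtomics

Multi-omics analysis toolkit for randomized fecal microbiota transplantation
(FMT) trials in allogeneic hematopoietic cell transplantation (alloHCT),
built around the question: *which gut microbes and circulating metabolites
track the risk of grade II–IV acute graft-versus-host disease (aGVHD) after
prophylactic FMT?*

It is written for microbiome/metabolome analysts who want the full inference
stack of such a trial as tested, reusable library code:

- **Compositional statistics** — centered log-ratio (clr) transform,
  Aitchison distances, principal coordinates, one-way PERMANOVA (adonis-style
  pseudo-F with seeded permutations), Wilcoxon group comparisons with
  Bonferroni correction, and classic Ward.D hierarchical grouping.
- **Microbial subcommunity discovery** — latent Dirichlet allocation over
  genus counts (samples = documents, genera = words) fitted by variational
  EM with Newton estimation of the Dirichlet concentration, and data-driven
  selection of the topic count by the Cao density criterion (minimum mean
  pairwise cosine similarity between topic–genus rows, searched over
  k = 2…10).
- **Zero-sum log-ratio lasso** — L1-penalized logistic regression on log
  relative abundances under the constraint Σβ = 0, solved by an augmented
  Lagrangian outer loop with coordinate-descent inner loops. Under the
  constraint the linear predictor depends only on log-ratios between taxa,
  so predictions are invariant to sequencing depth. Penalty selection by
  stratified 4-fold cross-validation (λ_min), and **stability selection**:
  100 re-randomized CV runs, each refit at its λ_min, ranking taxa by how
  often they stay in the model.
- **Serum metabolome QC** — anchor-sample batch normalization (the median of
  reference/target ratios over samples run in both LC-MS batches rescales
  the target batch), a >25 % non-detection filter, collinearity pruning
  (one representative per connected component of the Spearman ρ > 0.5
  graph), half-minimum imputation, and log transformation.
- **Metabolite outcome models** — glmnet-style 10-fold cross-validated
  logistic lasso with the GVHD-prophylaxis regimen (PTCy vs other) as an
  unpenalized covariate, fold-averaged coefficients at λ_min, repeated 100
  times for selection probabilities; sparse PLS-DA tuned by balanced error
  rate; PCA scores.
- **Donor engraftment** — Jaccard similarity between the ASV-level
  presence sets of a genus in a recipient's early post-FMT sample and the
  assigned donor's sample, correlated with the genus's post-FMT abundance.
- **Cross-omics mapping** — Spearman correlations between each cluster's top
  taxa (plus the clusters themselves) and the 50 highest-variance
  metabolites, masked at unadjusted p < 0.05.
- **Synthetic trial generator** — a fully seeded simulator of the trial's
  structure (74 patients randomized 2:1, 4 donors, longitudinal stool and
  serum timepoints with realistic missingness, three latent subcommunities,
  an ASV-level engraftment process, an outcome driven by a planted genus,
  and a two-batch metabolome with 18 anchor samples and one planted
  protective metabolite) with the ground truth recorded, so every stage is
  testable without external data.

## Worked example

```python
from fmtomics.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
print(report["topics"]["k_star"])                      # 3
print(report["topics"]["permanova_arm_p"])             # 0.001
print(report["taxa_lasso"]["top_features"][0])
# {'feature': 'Faecalibacterium', 'probability': 1.0, 'sign': '+'}
print(round(report["engraftment"]["rho_post_abundance"], 3))   # 0.866
print(report["metabolome"]["top_metabolite"],
      report["metabolome"]["top_metabolite_sign"])     # M0001 -
```

Reading the numbers: the Cao criterion selects **3** microbial
subcommunities; the PERMANOVA on clr-transformed cluster abundances
separates the FMT and placebo arms at the smallest attainable permutation p
(**0.001** with 999 permutations); the zero-sum lasso ranks the planted
genus (*Faecalibacterium*) first with a **positive** aGVHD association in
every one of the 100 stability runs; donor-similarity and post-FMT
abundance of that genus are strongly rank-correlated (**ρ ≈ 0.87** here;
0.9–0.97 across seeds),
i.e. its expansion is carried by donor-derived ASVs; and the metabolite
stability lasso singles out the planted protective metabolite with a
**negative** coefficient.

The same stages are exposed on the command line:

```bash
fmtomics simulate --seed 1 --out-dir data/
fmtomics prep --counts data/asv_counts.tsv --taxonomy data/taxonomy.tsv --out-dir prep/
fmtomics topics --counts prep/genus_counts.tsv --out-dir topics/
fmtomics run config.yaml --out-dir results/
```

## Layout

```
src/fmtomics/
  simulate.py      # synthetic trial generator + ground truth
  prep.py          # sample/ASV/genus filters, timepoint selection
  compositions.py  # clr, Aitchison, PCoA, PERMANOVA, Wilcoxon, Ward.D
  topics.py        # LDA (VEM), Cao k-selection, top taxa
  zerosum.py       # zero-sum log-ratio lasso + stability selection
  metabolome.py    # batch adjustment, filters, pruning, imputation
  outcomes.py      # metabolite lasso stability, sPLS-DA, PCA
  engraftment.py   # ASV-level donor similarity
  multiomics.py    # taxa x metabolite Spearman map
  pipeline.py      # orchestration, artifacts, report
  cli.py           # `fmtomics` command line
docs/methods.md    # model and design notes
```
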