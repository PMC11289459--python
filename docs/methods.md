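# Methods

`trilayer` implements a multilayer association pipeline for studying how
genetic variation, DNA methylation and gene expression jointly relate to a
binary disease-course phenotype (modelled on the primary-progressive vs
bout-onset multiple sclerosis contrast). This note documents the models,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter.

## 1. Differential methylation (bump hunting)

**Model.** For each CpG probe *j* with beta values β<sub>ij</sub> ∈ [0,1],
an OLS model

  β<sub>ij</sub> = α<sub>j</sub> + δ<sub>j</sub>·case<sub>i</sub> + γ<sub>j</sub>ᵀ·covariates<sub>i</sub> + ε<sub>ij</sub>

yields a per-probe group coefficient δ̂<sub>j</sub> in Δβ units. Covariates
default to age, sex, smoking status, batch, and the first two principal
components of the cell-composition fractions. The analysis runs on beta
values directly; an M-value (logit2) transform is available but off by
default.

**Regions.** Probes are clustered by genomic gap (`max_gap` = 500 bp,
conventional and configurable). Within each cluster, candidate regions are
maximal runs of ≥ 2 probes whose coefficients all exceed +cutoff or all
fall below −cutoff. The default cutoff is the 0.975 quantile of
|δ̂| across all probes in the run, overridable by a fixed Δβ. This
quantile rule assumes genome-scale input where true regions occupy a
negligible probe fraction; on small synthetic panels the background must
be ≥ a few hundred probes for the quantile to estimate the null scale
(our simulations use 500), otherwise a fixed cutoff should be supplied.
Optional running-mean smoothing over k = 3 probes is off by default.

**FWER.** Family-wise error control uses Freedman–Lane residual
permutation: fit the covariate-only model, permute its residuals, re-add
fitted values, and re-run the entire candidate pipeline (including cutoff
selection) on each of B resamples (default B = 1000; B ≥ 100 enforced).
Each observed region's FWER p is the add-one rank of its |area| (sum of
|coefficients|) in the null distribution of per-resample maximum |area|,
so p is never exactly 0. Residual permutation preserves the covariate
structure that naive label permutation would destroy. Simulations at
n = 60/60 with a planted Δβ = 0.24 × 8-probe region give sensitivity 1.0
at FWER < 0.05 (50 replicates, B = 200) and a null FWER-significant rate
of 0.05 (200 replicates).

**Replication test.** The per-CpG two-group comparison is a two-sided
Mann–Whitney U test: exact when n₁·n₂ ≤ 400 (the exact U distribution
when there are no ties; full enumeration of group assignments when there
are), otherwise a tie-corrected normal approximation with continuity
correction, whose worst-case discrepancy from enumeration at 4 vs 4 is
0.031. The rank-based inverse-normal transform Φ⁻¹((rank − 0.5)/n) with
average ranks for ties is provided for locus-specific scans.

## 2. Case-control genetics

**QC.** SNPs with call rate < 98% are removed; the exact Hardy–Weinberg
test sums the conditional probabilities (given allele counts) of all
heterozygote counts no more probable than observed, with monomorphic SNPs
returning p = 1 (flagged). Default exclusion threshold p < 0.05.

**Association.** Per-SNP logistic regression of case status on additive
minor-allele dosage (0/1/2) plus covariates, fitted by IRLS. Separation
and non-convergence are flagged and estimates withheld rather than
penalised — transparent behaviour at desk scale.

**LD blocks.** Pairwise LD is the squared Pearson correlation of dosage
vectors over pairwise-complete samples. Blocks are built by greedy
significance-seeded clumping at r² > 0.8: the most significant unassigned
SNP seeds a block that absorbs every unassigned SNP with r² > 0.8 against
it. Ties in significance break by (chromosome, position, id), making the
partition invariant to input order. The block count sets the Bonferroni
threshold α / #blocks (0.05 / 69 = 7.2 × 10⁻⁴ at the published block
count).

**Meta-analysis.** Fixed-effect inverse-variance pooling of per-study log
odds ratios (weights 1/SE², pooled SE = 1/√Σw); DerSimonian–Laird τ² for
the random-effects option; Q and I² always reported. When only printed OR
and two-sided P are available, the SE is reconstructed as
|ln OR| / Φ⁻¹(1 − P/2). Reconstructed pooling of the published two-cohort
rows reproduces the printed pooled ORs within one unit in the last printed
digit (the printed inputs are themselves rounded).

## 3. QTL scans and concordance triage

meQTL and eQTL models are OLS of the feature (CpG beta or log expression)
on dosage plus covariates, one test per (SNP, feature) pair, restricted by
an explicit pair list or a genomic window (±500 kb default, bounds
inclusive, 1-based positions). Multiple-testing adjustment defaults to
Bonferroni over the tests actually performed in the scan (the ambiguity
between per-feature and whole-scan families is resolved in favour of the
whole scan; per-feature and BH are options).

Concordance triage is sign-only: disease direction from a significant
odds ratio (> 1 risk, < 1 protective), meQTL direction from a significant
dosage-methylation sign, eQTL direction from an external annotation's
sign. Risk & meQTL+ & eQTL− is "concordant-repressive" (risk allele →
hypermethylation → lower expression); protective & meQTL− & eQTL+ is
"concordant-protective"; any missing direction gives "incomplete";
anything else "discordant". Labels are scale-invariant by construction.
Records carry their LD-block id; block-level direction is read from the
block's seed SNP.

## 4. Co-expression network

**Edges.** Gene-gene Spearman correlations (average ranks; zero-variance
genes excluded). The permutation filter builds a pooled null of |rho| from
B ≥ 100 whole-matrix permutations (each gene's samples shuffled
independently), assigns each pair an add-one empirical p against the pool,
and keeps edges with Benjamini–Hochberg q < 0.05. Pooling across pairs
buys p-value resolution at feasible B; per-pair nulls are an option.

**PMFG.** The planar maximally filtered graph inserts edges in decreasing
|rho| order (ties by lexicographic node pair) iff the graph stays planar,
stopping at the planar bound 3(n − 2). Implementation detail: union-find
component tracking skips the planarity check for bridges between
components (always safe) and rejects intra-component edges beyond the
3c − 6 Euler bound without a check; remaining checks run on the touched
component's subgraph only. The result is identical to the naive greedy
scan (property-tested) but runs in a fraction of the time.

**Modules.** Multiscale module detection is a defined stand-in for
MEGENA-style clustering, not a reproduction of it: all-pairs shortest-path
distances with edge length 1 − |rho| + 10⁻⁶, seeded PAM k-medoids for
k = 2..8, k chosen by maximum mean silhouette, recursion into children
while the best silhouette ≥ 0.3 and the module has ≥ 2·min_size members
(min_size = 10). Leaves are the reported non-overlapping module set and
are asserted to partition the clustered nodes on every run. The
silhouette acceptance threshold was set to 0.3 after observing that 0.2
accepts spurious splits of homogeneous planted modules: shortest-path
distances within a planar triangulation of a clique are non-uniform
enough (hub vs periphery) to support geometric sub-splits with silhouette
0.2–0.3, halving the adjusted Rand index against planted truth, while
genuine module boundaries in the same data score well above 0.3.

**Module-trait relevance.** Each leaf's eigengene is the first principal
component of its gene × sample submatrix (columns standardised; PC1 sign
fixed so its correlation with the sample-wise mean profile is ≥ 0).
Relevance to each binary trait indicator is the Spearman correlation of
the eigengene with the indicator (Pearson by flag), with BH control
across the full module × trait family and q < 0.05 flagging.

**Overlap enrichment.** Two-sided Fisher exact test on the 2×2
cross-classification of two gene sets over a universe; odds ratio from
the table with Haldane 0.5 correction iff any cell is zero (flagged).

## 5. Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
one causal layer at a time, under a single seed with named per-layer
substreams (identical configs are bit-reproducible):

* **Genotypes** are built haplotype-wise: each LD block has an anchor SNP
  whose two haplotypes are Bernoulli(maf); other SNPs copy each anchor
  haplotype with the block's copy probability (default 0.95) and redraw
  at the same maf otherwise. Dosage r² therefore decays mechanistically
  with copy probability (0.95 gives r² ≈ 0.9). Missing calls are injected
  completely at random at a configurable rate (default 0).
* **Phenotype** labels (case vs bout-onset control) are drawn from a
  logistic model with log-odds Σ log(OR)·dosage over the configured risk
  SNPs; the intercept is calibrated by root-finding so the expected case
  fraction matches the configured cohort ratio. Covariates (age, sex,
  smoking, batch, Dirichlet cell fractions, ancestry PCs) are independent
  of genotype by default; a confounding flag couples age and smoking to
  the genetic risk burden so adjustment can be tested both ways.
* **Methylation** is base level + dosage·shift at meQTL CpGs (full-strength
  targets place the dosage 0/1/2 group means at the tri-modal levels
  0.2/0.5/0.8) + a case-group Δβ (default 0.24 over 8 consecutive probes)
  + Gaussian noise (SD 0.03 on the beta scale), clipped to (0.001, 0.999).
  Configurations whose pre-noise group means leave (0,1) are rejected.
* **Expression** is gene baseline + slope·(linked CpG beta) + module
  structure + Gaussian noise. Module genes load on a shared latent factor
  with loading √rho (within-module correlation rho, default 0.7 for the
  general config, 0.8 in the module-recovery condition), an optional
  shared background factor sets between-module correlation, and a
  trait-coupled factor is shifted by 1 SD in the coupled trait's samples.
  The methylation→expression slope defaults to ±2 log-units per beta unit.
  These effect sizes are free parameters chosen once as realistic for
  the power properties the tests state; the source analyses report only
  effect signs for the expression layer.

**What it does not emulate:** array probe chemistry and batch artefacts,
genome-wide probe density, realistic LD decay beyond the block-copy
mechanism, imputation uncertainty (dosages are hard calls), cell-type
deconvolution (fractions are supplied directly), and count-level RNA-seq
noise (expression is Gaussian on the log scale). Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
structure, not robustness to real-data artefacts.

## 6. Problem sizes used in validation

Simulation studies are sized for reproducibility at desk scale: DMR
sensitivity/calibration at n = 60/60, 500 probes, B = 200 resamples, 50
planted and 200 null replicates; module recovery at 200 genes in four
50-gene modules over 25 replicates with B = 100 permutations; QTL
recovery at n = 300 over 50 replicates with null calibration over 500
permuted pairs; association recovery at n ≈ 4000. The published
cohort-scale results (a genome-wide 450K scan, thousands of imputed SNPs,
a 27k-gene brain network with 757 modules) are not reproducible here —
the underlying data are restricted-access — which is why validation
combines printed-table worked examples with ground-truth recovery on
synthetic data.

## 7. Coordinates and formats

Positions are 1-based inclusive everywhere in memory and in TSV output;
BED export converts to 0-based half-open (start = first probe − 1,
end = last probe) with score −log10(FWER p), capped. TSV is the canonical
interchange; VCF input is read-only, biallelic, GT-only. Every pipeline
output table carries the run seed in a header comment, and the run
manifest records per-output SHA-256 hashes; a fixed seed reproduces every
table bit-for-bit.

## 8. Known limitations

* The multiscale clustering is a defined alternative to MEGENA, selected
  for determinism and testability; module boundaries need not coincide
  with MEGENA's on real data.
* The pooled permutation null for edge filtering is slightly conservative
  for genes with unusual marginal rank distributions; per-pair nulls
  address this at higher B.
* Logistic fits withhold estimates under separation rather than applying
  Firth-type penalisation; rare-variant analyses at small n will report
  non-convergence.
* The PMFG greedy construction is order-deterministic but, like all
  greedy maximum-planar-subgraph heuristics, not guaranteed to find the
  globally heaviest planar subgraph.
* Scalability targets desk scale (~10⁴ SNPs × 10⁴ samples for genetics,
  a few hundred genes for the network stage); the PMFG step is the
  bottleneck beyond ~10³ nodes.
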