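# Methods

`ginet` infers *directed* gene–gene networks from population genotype and
whole-blood RNA-seq data. The central idea is borrowed from Mendelian
randomization: a gene's local (cis) genetic component is free of
non-genetic confounding, so a weighted sum of nearby SNP dosages that
predicts the gene's expression — its *genetic instrument* (GI) — can serve
as a causal anchor. If the GI of an index gene associates with the
expression of a gene more than 10 Mb away (or on another chromosome), and
the association survives conditioning on the GIs of the index gene's
neighbours, the index gene is implicated as a driver of the target.

## Model

### Preprocessing

* **Variant QC.** Variants are dropped when the minor allele frequency
  (mean non-missing dosage / 2, folded to ≤ 0.5) is below 0.01, when the
  Hardy–Weinberg exact test on hard-rounded genotypes gives P < 1e-4, or
  when the call rate is below 95%. The HWE test is the exact conditional
  test (probability, given the allele counts, of all heterozygote
  configurations no more probable than the observed one); it is exercised
  against full enumeration for all tables with ≤ 50 samples.
* **Expression.** Counts are normalized to counts per million; genes are
  kept when their median CPM exceeds 1 (equivalently median log CPM > 0,
  whatever the log base — stored log-CPM uses the natural log). Kept genes
  are mapped to normal quantiles by a rank-based inverse normal transform
  within each cohort, with the Blom offset c = 3/8 and mid-ranks for ties.
  The within-cohort transform removes cohort location/scale differences
  and caps the influence of outliers.
* **Cell counts.** Missing red/white blood cell counts are imputed by
  least squares from the top 10 principal components of the transformed
  expression matrix plus cohort, sex and age, provided at least half the
  samples are observed. Observed values are never modified and keep an
  `observed` flag so downstream confounding checks use measured values
  only. (A partial-least-squares imputation would serve equally; the
  PCA+OLS formulation has the same rank and a directly testable recovery
  contract.)

### Latent covariates

Unknown structure (batch, cell composition beyond the measured counts) is
estimated by residualizing every gene on the known covariates and taking
the top *k* = 5 left singular vectors of the residual samples × genes
matrix, standardized, with the sign fixed so each factor's
largest-magnitude entry is positive. Since the factors only enter the
models as unpenalized covariates, any deterministic basis of the
confounder subspace is equivalent; the SVD formulation is deterministic
and dependency-free, and its columns are exactly uncorrelated with every
known covariate by construction. *k* is a fixed configuration constant
(no automatic selection).

### Genetic instruments

Samples are split once into a training third and a test two-thirds,
systematically within cohort × sex strata after sorting by age (seeded
offset), which balances cohort, sex and age across the split. On the
training samples, each gene's transformed expression is regressed on the
standardized dosages of all QC-passing variants within its gene body
± 100 kb, with an L1 penalty on the SNP coefficients and the known +
latent covariates unpenalized. Because the covariate block is
unpenalized, the SNP coefficients equal the lasso of covariate-residualized
expression on covariate-residualized dosages (Frisch–Waugh–Lovell), which
is how the fit is computed (scikit-learn coordinate descent). The penalty
grid is 100 log-spaced values descending from the smallest penalty that
zeroes all SNP coefficients (span 1e-3), and the chosen penalty minimizes
five-fold cross-validated error; folds are cohort-stratified and keyed on
sample IDs, so instruments are invariant to row order. Genes with no
surviving SNP weight have no instrument. Standardization statistics are
frozen at training time and reused whenever the instrument is scored.

Instrument strength is assessed on the held-out test set as the one-degree
ANOVA F for the GI's added predictive power over the covariates plus the
GIs of neighbouring genes (closest gene-boundary distance < 1 Mb), with
all nuisance coefficients re-estimated on the test samples. Instruments
are kept when F > 10 (strict), the conventional weak-instrument rule.
Conditioning on neighbours here matters: an instrument that predicts its
gene only through variance shared with a neighbour's instrument is useless
for assigning direction and is discarded.

### Trans scan

For every kept index gene, every expressed gene with gene-boundary
distance > 10 Mb (strict; other chromosomes always) is a candidate
target. The target's expression is regressed on the index GI, the
covariates, and the index gene's neighbour GIs; the GI coefficient is
tested with a two-sided Wald z. Conditioning on the neighbour GIs blocks
the back-door path *index GI ← LD/pleiotropy → neighbour GI → target*
without opening the collider path that conditioning on observed neighbour
expression would create. All samples are used in the scan (the instrument
weights, not the samples, carry the anchoring). Since the design matrix is
shared by all targets of one index gene, the scan solves one QR per index
gene against all targets at once.

Residual bias and inflation of the z statistics are removed with an
empirical null: a three-component Gaussian mixture whose largest-weight
component is the null, fitted by MAP-EM. An unconstrained mixture is not
identifiable when the data are nearly pure null — the flanking components
drift into the central bulk and shrink the estimated null spread (on
10,000 standard-normal draws the drifted null SD reached 0.91) — so light
conjugate priors (strength 0.1·n) anchor the null mean at the median, the
null variance at the squared scaled MAD, and the weights at
(0.9, 0.05, 0.05), mirroring the prior structure of Bayesian
implementations of this estimator. If EM fails to converge the median/MAD
estimates are used directly (`converged=False`). Adjusted statistics are
z_adj = (z − bias)/inflation with two-sided normal p. The null can be
fitted per index gene (each association family separately, ≥ 100 tests
required) or pooled globally; scans below 100 tests fall back to raw
statistics with a warning.

Family-wise error is controlled by Bonferroni over the full
n_index × n_target grid (each index gene actually has slightly fewer
candidates; using the full grid matches the conventional, conservative
derivation). Network assembly reports per-index degree statistics and the
number of targets claimed by more than one index gene lying within 1 Mb
of each other — the ambiguity signature that neighbour conditioning is
designed to remove. Transcription-factor (or any set) enrichment among
index genes uses Fisher's exact test with the conditional-MLE odds ratio.
As a confounding check, each GI is regressed against each *observed*
(never imputed) cell count, Bonferroni-corrected over the grid.

### Mediation

For each significant edge, the Sobel test asks whether the GI → target
effect runs through observed index expression: path *a* is the GI
coefficient for index expression, path *b* the index-expression
coefficient for the target adjusted for the GI; both regressions carry the
full covariate and neighbour-GI adjustment so the mediated and total
models stay nested. The statistic is the classic Sobel form
z = a·b / √(a² se_b² + b² se_a²); a zero indirect effect returns z = 0,
p = 1.

### Power simulation

The simulation strips the design to four observed variables: two GIs
correlated at r_gi (LD/pleiotropy), index and nearby expression correlated
r_gi,index and r_gi,nearby with their GIs, and a target driven either by
the index gene (alternative scenario) or by the nearby gene (null
scenario), each generated as y = r·x + √(1−r²)·ε. For every correlation
tuple, both scenarios are simulated and the index-GI coefficient is tested
in a corrected model (GI_nearby included) and an uncorrected one, giving
four power curves; power is the fraction of 500 replicates with p < 0.05.
Both models are evaluated on the same realizations, so corrected and
uncorrected estimates are paired. An intercept is included in both fits
(the variables are mean-zero only in expectation). A data-derived grid (quantiles of the real correlation estimates) is not
recoverable without the original cohort; the default grid {0.1, 0.25, 0.4, 0.6, 0.8} for r_gi with the
remaining correlations at 0.3 preserves the experiment's shape and is
configurable. The default n is 3072, a realistic biobank-scale cohort.

Note that corrected and uncorrected fits do *not* coincide realization by
realization when r_gi = 0 — the nearby GI is still correlated with the
index GI in sample — so their agreement is checked on rejection rates, not
on individual p-values.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, at
sizes a desk machine can afford:

* **Genotypes.** Per haplotype, a latent AR(1) Gaussian (correlation ρ
  between adjacent variants, blocks independent) thresholded at each
  variant's target MAF quantile; dosage = sum of two haplotypes. LD blocks
  are aligned with gene cis windows.
* **Gene map.** Genes 200 kb apart on 2–4 chromosomes, so every gene has
  several < 1 Mb neighbours and plenty of trans candidates; adjacent cis
  windows overlap by ~10 kb, so boundary variants are visible to two
  genes' instruments.
* **Expression.** Per gene, a standardized cis score scaled to a target
  cis R² (default drawn from (0.35, 0.45)), latent confounders (k = 5,
  loading SD 0.25), two cell-count axes (loading SD 0.15, reported as RBC/
  WBC with 10% missingness), and independent noise filling the variance
  to ≈ 1. *Local pleiotropy:* consecutive same-chromosome gene pairs share
  one cis variant carrying 70% of both genes' cis variance, which
  correlates their fitted GIs at ≈ 0.7 — the confound the corrected scan
  must defeat. *Trans edges:* a target's expression is rebuilt as
  √(1−s)·(own structure) + √s·(index expression), default variance share
  s = 0.2; injected edges always satisfy the > 10 Mb rule. Output is
  within-cohort inverse-normal transformed (or negative-binomial counts
  for exercising the CPM path).
* **Presets.** `tiny` (200 samples × 500 variants × 30 genes, 2 edges,
  counts layer on) runs the full pipeline in seconds and is the smoke/
  fixture scale; `desk` (2000 × 5000 × 200, 5 edges) is the recovery-
  experiment scale.

The effect sizes deserve a note. A trans effect detectable at the
genome-wide family-wise threshold (z ≳ 6 at n = 3072 through a cis R² ≈ 0.1
instrument) explains on the order of 10–15% of target variance, so the
desk preset's s = 0.2 with cis R² ≈ 0.4 at n = 2000 reproduces the
signal-to-threshold regime of the *detected* effects, not of a typical
gene pair. The generator's confounder count matches the five latent
factors the analysis estimates; this is a deliberate idealization — with
only 200 genes, a strong trans edge is itself among the largest residual
variance directions, and surplus factors would absorb exactly the causal
signal being probed (with 10,000+ genes, as in real data, broad technical
axes dominate instead).

What passing the synthetic suite does **not** show about real data: the
generator has Gaussian LD blocks rather than human haplotype structure, a
uniform allele-frequency spectrum, linear confounding, no population
stratification or relatedness, and pleiotropy of exactly one shared
variant per gene pair. Recovery rates on the desk preset therefore
validate the *logic* of the correction (assignment to the right member of
a confounded pair), not genome-wide sensitivity on human data.

## Numerical choices and degenerate inputs

* OLS throughout is pivoted-QR; rank-deficient designs raise an error
  naming the collinear columns (single tests) or drop the offending
  columns with a warning (genome-wide scan). A numerically perfect fit
  (RSS ≤ 1e-12 × total SS) is treated as exact: the tested coefficient
  reports z = 0, p = 1 rather than 0/0.
* The F-keep rule and both distance rules (< 1 Mb neighbours, > 10 Mb
  trans) are strict inequalities; gene–gene distance is the closest
  gene-boundary distance, 0 for overlapping genes.
* p-values are floored at the smallest positive double; Bonferroni
  adjustments are capped at 1.
* Monomorphic variants standardize to zero and are dropped from
  instrument fitting; missing dosages standardize to the training mean.
* All randomness (splits, CV folds, simulations, generators) flows through
  explicit integer seeds; the documented default seed is 2018.

## Problem sizes used by the checks

The acceptance computations use the analysis' full scale wherever it is
self-contained: the 6600 × 10,781 Bonferroni grid, 500 simulation
replicates at n = 3072, and the reference 156-edge/49-index network
summary. The scan-calibration check runs a 400-sample × 120-gene null
scan (≥ 5000 trans tests), and the recovery experiment runs the desk
preset across 20 seeds. These sizes were chosen so the whole suite is a
coffee-break run on one CPU while keeping every Monte-Carlo band at least
three standard errors wide.

## Known limitations

* Reverse-edge leakage: instrument weights are fitted on training samples
  whose expression already contains incoming trans effects, so the
  instrument of a *target* gene can overfit its driver's contribution and
  produce a spurious reverse association when scanned against the driver.
  The effect is confined to true edge pairs and does not disturb
  forward-assignment recovery; scanning only held-out samples would remove
  it at a power cost.
* The empirical-null priors trade a small bias toward the median/MAD
  estimates for identifiability; heavy contamination (≫ 10% non-null
  tests) will inflate the null component and make the correction
  conservative.
* Cell-count imputation assumes the counts are linearly encoded in the
  leading expression PCs; gross violations degrade silently into noisier
  imputations (the recovery contract in the tests bounds this at 1.2× the
  noise SD under the linear model).
* The CLI's `mediate` subcommand refits the pipeline to rebuild
  instruments rather than deserializing them; at desk scale this is
  seconds, at biobank scale one would persist the weights.
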