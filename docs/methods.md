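# Methods

This note records the models implemented in `curdpred`, the defaults and the
reasoning behind the choices that were genuinely open. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic panels

`simulate.simulate_population` builds diploid dosages from two haplotypes
per individual.

* **Differentiation.** Individuals belong to `n_clusters` groups of
  near-equal size. Per-cluster allele frequencies follow the
  Balding–Nichols model around an ancestral frequency `p ~ U(0.1, 0.9)`:
  marginally `p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`.
* **Linkage disequilibrium.** Each haplotype is a first-order Markov
  process: a latent AR(1) Gaussian field thresholded at the cluster allele
  frequency. The AR coefficient between adjacent markers is
  `ld_correlation^(gap/median_gap)`, so correlation decays geometrically
  with map distance and restarts at chromosome boundaries. Crucially, the
  cluster-frequency *drift deviations* are also AR(1) along the chromosome
  (a Gaussian copula that leaves the Beta marginals untouched): drift rides
  on haplotypes, so differentiated panels carry long-range LD the way real
  populations do. With independent per-marker drift — the naive
  construction — strong differentiation *destroys* local LD.
* **Calibration.** Defaults (`n_individuals=174`, 9 chromosomes × 500
  markers over 45 Mb, 5 clusters, `F=0.45`, `ld_correlation=0.72`) were
  calibrated once so the default panel reproduces the LD summaries measured
  on the real gene-bank panel this generator emulates: inter-chromosomal
  background r² ≈ 0.17 and a decay/background crossing on the 150–200 kb
  scale at n = 174. The study reports no per-cluster F_ST, so `F` is pinned
  by the background-LD level (which is structure-driven), not by a
  differentiation target. Note the LD model is marker-density-relative
  (adjacent-marker correlation ≈ `ld_correlation` at the panel's median
  gap); sparser maps therefore stretch LD over more base pairs.
* **MAF floor.** Markers whose realized sample MAF falls below `maf_floor`
  (default 0.05) are re-thresholded with frequencies redrawn toward 0.5;
  the latent haplotype field is kept so LD is unaffected. Extreme shared
  drift quantiles are refreshed after a few attempts.
* **Missingness** (`inject_missingness`) is missing-completely-at-random
  with a per-individual rate drawn uniformly from `missing_range` (default
  0.1902–0.7673, the GBS-like band). Real GBS missingness is additionally
  concentrated by marker (shared restriction sites) — which is why a real
  panel can retain hundreds of fully observed markers while MCAR at these
  rates retains none. Complete-case comparisons in the tests therefore use
  low missingness; this is a known limitation of the mechanism, which the
  design deliberately keeps simple.
* **Phenotypes** follow `y_ijk = μ + g_i + E_j + GE_ij + e_ijk`. The
  genetic value is the sum of `n_qtl` planted marker effects plus an
  optional genome-wide polygenic term (`qtl_variance_fraction` splits the
  two, the polygenic part orthogonalized against the QTL part so the split
  is exact). `g` is scaled to the target σ²_g *exactly*, giving recovery
  tests a stable truth; E, GE and the residual are drawn at their target
  variances. Given a target H², components are set as σ²_g = 1 and
  σ²_ge = σ²_e solving the entry-mean formula. The default six-trait
  battery spans H² = 0.94 … 0.10, the range seen for curd morphology and
  development traits.

What passing tests on these panels do **not** show: behaviour under
marker-concentrated missingness, family/pedigree relatedness inside
clusters (Balding–Nichols clusters are exchangeable), selection or
migration, or allele-frequency spectra with an excess of rare variants.

## Genotype handling

Dosages live in {0, 1, 2, NaN}; markers are strictly sorted by
(chromosome, 1-based position) and coordinates follow VCF conventions.
Multi-allelic and indel records are dropped on read (biallelic SNPs only).
MAF is computed over non-missing calls — required at GBS missingness levels
and standard practice. The strict pipeline removes markers with MAF < 0.05
or any missing call; the imputation pipeline fills first and filters after.

The imputer is a declared surrogate for haplotype-cluster HMM methods
(fastPHASE/BEAGLE-class), which are deliberately not reimplemented: a
windowed k-nearest-neighbour concordance vote (defaults w = 20 flanking
markers, k = 5 most concordant individuals, majority dosage,
frequency-weighted draw on ties, seed-deterministic). It honours the
contract downstream stages rely on — complete matrix, observed calls
untouched — and beats frequency draws whenever local LD exists, but it does
not model haplotype mosaics and will underperform a true HMM at high
missingness.

## Phenotype model

EM-REML on the mixed-model equations for the three random factors
(genotype, environment, genotype×environment; intercept fixed). The
environment main-effect variance is estimated but does not enter H².
Convergence: maximum relative change < 1e-8, at most 500 sweeps, error with
the iteration trace otherwise. Components collapsing below 1e-10·var(y) are
clamped to zero and frozen; the residual keeps a 1e-12·var(y) floor so the
equations stay well posed in the noiseless limit. For balanced data the
estimates match the closed-form ANOVA (Henderson method-3) estimators to
1e-6, which the tests verify as an independent oracle; the same code path
handles unbalanced tables. For Eq-style H², `e` is the number of
environment levels and `r` the median replicate count per cell. Genetic
correlations are Pearson correlations of BLUPs; phenotypic correlations use
per-genotype means over environments and replicates (the basis is not
uniquely defined in the field; means are the transparent choice).

## Population structure

PCA operates on mean-filled, centered dosages scaled by √(2p(1−p)).
`find_clusters` runs k-means (20 restarts per K) over the retained PCs
(default: 90% variance) and picks K at the minimum of
`BIC(K) = n·d·ln(WSS/(n·d)) + K·d·ln(n)` — the spherical-Gaussian
convention used with DAPC-style cluster finding. DAPC loadings compose the
PCA rotation with the LDA discriminant coefficients and are normalized to
unit squared sum per function.

The structure-corrected kinship regresses each centered marker on the top
PCs and builds the VanRaden cross-product from the residuals — an
individual-specific-allele-frequency correction in spirit, declared as a
surrogate for the full PC-Relate estimator. The number of PCs removed
defaults to the count of eigenvalues above the Marchenko–Pastur bulk edge
(×1.1 margin): an unstructured panel then loses nothing (a fixed PC count
would always remove ≈ √(k/n) of the matrix in Frobenius norm). In
simulated panels the corrected matrix can retain almost no relatedness —
within a Balding–Nichols cluster individuals are exchangeable — so
corrected-kinship prediction ability drops sharply on structured traits;
real panels with family structure degrade more gently.

## Linkage disequilibrium

Haplotype frequencies for unphased pairs come from the classic two-locus
EM (only double heterozygotes are ambiguous; convergence 1e-10), the
convention used by standard LD software; the composite-LD shortcut was
rejected for fidelity. Signed `r = D/√(p_a(1−p_a)p_b(1−p_b))` with
orientation fixed by the alternate allele of the marker map, so phase is
comparable across subpopulations; `r²` is its square by construction.

Background LD is the 95th percentile of r² over randomly sampled
inter-chromosomal pairs. The source phrase "correlation of the 95%
percentiles of all pairwise markers between chromosomes" is grammatically
ambiguous; this implementation reads it as the 95th percentile of the
inter-chromosomal r² distribution, the quantity that behaves like a chance
threshold. Decay uses the Hill–Weir drift expectation with the
finite-sample term, fitted by nonlinear least squares (the standard choice
where only "nonlinear regression" is specified); the crossing with the
background level is solved by bracketing and flagged absent when the curve
never descends to it. Phase persistence correlates signed `r` of adjacent
shared pairs between two panels, overall and within 50-marker groups
ordered by distance; the alternative "expectation value of independent
segregation (50%)" framing is not a defined statistic and is left unmapped.

## Association

Kinship is VanRaden centered/scaled (the construction is not stated in the
source analysis; VanRaden is the field default), ridged by 1e-6. EMMAX
fits the null REML once via the kinship eigendecomposition (1-D search over
log δ: 64-point grid plus Brent refinement) and tests each marker by GLS
with components fixed. The default statistic is the Wald χ²₁ at the
null-model scale; `stat="f"` re-estimates the scale per marker and reduces
exactly to the single-marker OLS F-test at identity kinship (verified to
1e-10). Covariates default to the intercept only. MLMM re-estimates
variance components at every forward step, selects the step by extended
BIC (γ = 1), and prunes backward at the Bonferroni level 0.05/m.

FDR is Benjamini–Hochberg step-up at Q = 0.2, applied per trait and data
set. The contradictory prose about "FDR of 0.05 … implies that 20%" in the
source is resolved in favour of Q = 0.2, the value its methods fix for all
data sets. λ is the observed/expected median χ²₁ ratio. Variance explained:
`R²_adj = R² − z(1−R²)/(N−z−1)` from the joint significant-SNP fit,
truncated at 0, and `ρ̂ = R²_adj/Ĥ²`, reported (and flagged) even above 1 —
values above 1 do occur when small-sample R² outruns a low heritability
estimate.

## Genomic prediction

GBLUP solves the BLUP in the kinship eigenbasis; out-of-sample individuals
are predicted through the kinship cross-block,
`ĝ_new = K_nt (K_tt + δI)⁻¹ (y_t − μ̂)`. RRBLUP estimates the variance
ratio on the marker-derived relationship matrix and then solves the m×m
ridge normal equations — a genuinely different linear system whose
predictions coincide with GBLUP exactly; the test suite asserts the
identity at 1e-8 across 50 simulated data sets, turning the empirically
reported equivalence into an exact check.

BayesB is a Gibbs sampler (numba kernel) over marker effects with a point
mass at zero and a scaled-t slab: per-marker inclusion indicators with
marginal-likelihood odds, per-marker variances from scaled inverse-χ²
updates, π ~ Beta posterior, and a scaled inverse-χ² residual. Hyper
defaults follow the usual default-rule construction: df_β = 5, prior
inclusion π₀ = 0.5 with prior count p₀ = 10, slab scale solved from an
R²_prior = 0.5 split of the trait variance against Σ var(x_j), residual
df 5; chain 5000 iterations, 1000 burn-in, thinning 5, seed-deterministic.
Two independent chains correlate above 0.99 in genetic values on the test
problems.

Cross-validation draws a fresh random 5-way partition per replication (10
replications), refits everything — including variance components — inside
each training fold, and reports the Pearson correlation per held-out fold,
averaged (a pooled-per-replication variant is available by flag; the
per-fold average is the declared default where the source is ambiguous).
Effect ranking orders markers by |effect| with ties broken by smaller
association p-value, then marker order — fully deterministic. The
marker-subset curve repeats GBLUP cross-validation on random subsets of
10–500 markers (100 runs by default).

Model agreement: on polygenic simulated traits (≈100 QTL) BayesB and GBLUP
mean abilities agree within 0.05; on oligogenic traits BayesB's variable
selection genuinely wins, so the agreement property is asserted for the
polygenic regime that matches complex-trait data.

## Pipeline

`run_pipeline` executes filter → impute → pheno → structure → LD → GWAS →
prediction from one YAML/JSON config, failing fast on invalid configs and
naming the failing stage otherwise. Every artifact enters a JSON manifest
with parameters, sub-seed and sha256; sub-seeds derive from the global seed
by a fixed counter over the canonical stage order, so stages can be rerun
in isolation and a repeated run reproduces checksums for deterministic
stages (the pipeline's default model set is deterministic given the seed).

## Problem sizes in the test suite

The heavier scientific checks run at desk scale by design: heritability
recovery uses 200 simulations of 40 genotypes × 6 environments × 2
replicates; the GBLUP/RRBLUP identity 50 panels of n = 200, m = 1000;
calibration one 174 × 2700 panel; detectability 100 panels of 174 × 675
(the size of a strict complete-case GBS set); the prediction envelope five
panels of n = 300, m ≈ 2000; BayesB sanity 20 panels of 200 × 1000 with
shortened chains (1500/500). These sizes give stable Monte-Carlo estimates
for the assertions made while keeping the whole suite in the minutes range.

## Known limitations

* MCAR missingness and exchangeable clusters, as discussed above.
* The knn imputer is a surrogate, not an HMM; imputation-accuracy claims
  transfer to real GBS data only qualitatively.
* The EM-REML phenotype fit assumes homoscedastic residuals across
  environments.
* MLMM's extended-BIC selection is one of several published stopping rules;
  the Bonferroni variant is available but both can differ from other
  implementations at marginal signals.
* Background-LD and decay-crossing estimates are Monte-Carlo and fit-form
  dependent; the crossing is only defined when the fitted curve actually
  descends to the background level.
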