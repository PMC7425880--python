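# Methods

This note documents the statistical models implemented in `stiffpipe`, the
synthetic cohort the tests run on, and the numerical and design choices
behind both.

## Phenotype model and preparation

Each PWV mode is measured twice. The selection rule keeps the first reading
for baPWV and cfPWV, the average of both readings for bfPWV (the mode with
the largest measurement variance), and discards the pair when the readings
disagree by more than 5 m/s (ba), 10 m/s (cf) or 25 m/s (bf). When the
second reading is missing the first is kept — the discard rule cannot be
evaluated on a single reading; this is logged. PWV and blood pressures are
natural-log transformed; the base is a convention (it only rescales slopes)
and is stated here once.

Partial correlation is computed as the Pearson correlation of OLS residuals,
which for a single control equals the closed form
(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)). Adjusted R² uses the standard
(n−1)/(n−p−1) correction.

## Association scan

The scan fits, per variant, OLS of the log phenotype on the dosage plus
covariates (default sex, age, log-SBP; the covariate list is configurable,
so principal components can be passed when wanted). The fit is evaluated
through the Frisch–Waugh–Lovell projection — residualize dosage and
phenotype on the covariate design, then regress residual on residual — which
is algebraically identical to the joint fit and vectorizes across variants.
Two-sided p-values come from the t distribution with residual degrees of
freedom (exact for OLS; indistinguishable from the normal Wald p at cohort
sizes). Variants whose residualized dosage is numerically constant are
skipped with a recorded reason. p-values that underflow are floored at the
smallest positive double.

SNP QC keeps a variant iff min(EAF, 1−EAF) ≥ 0.01, info ≥ 0.5, exact-HWE
p ≥ 1e-6 and call rate ≥ 0.97. The kept set is a conjunction, hence
order-independent and idempotent; the report records both the first and the
complete set of failing filters. The info score is the dosage-variance
ratio var(d)/(2p(1−p)) clipped to (0, 1] — the imputation-quality statistic
available when per-genotype probabilities are not modelled; the exact
IMPUTE formula requires those probabilities, but the threshold semantics
(poorly imputed variants score low) are preserved. The HWE exact test uses
the Levene–Haldane conditional distribution of the heterozygote count,
evaluated by a mode-anchored recurrence for numerical stability; the
p-value sums all configurations no more probable than the observed one
(with a 1e-10 relative tolerance against ties lost to rounding).

Genomic inflation λ is the median association χ² divided by 0.4549364 (the
1-df χ² median); the estimator choice (median-based) is the standard one.

### Power

Power of the 1-df additive test is the upper tail of a noncentral χ² beyond
the central (1−α) quantile. Two noncentrality conventions exist: the
small-effect form ncp = n·q² and the exact form ncp = n·q²/(1−q²), where q²
is the fraction of phenotypic variance explained. The package defaults to
the small-effect form, which is the convention under which published
GWAS power statements for sub-percent q² are quoted (at n = 6,430,
α = 5e-8, 80% power it gives a detectable variance of 0.62%; the exact
form gives 0.61%); `ncp="exact"` selects the other. `detectable_variance`
inverts the power function by Brent root-finding to 1e-14, so the
composition with `gwas_power` is the identity to numerical precision.

## Loci

LD is the squared Pearson correlation of dosages over complete cases.
Priority pruning is greedy by ascending p; ties are broken by chromosome,
then position, then lexicographic id, making the output invariant to input
order. Loci are closed ±500 kb intervals in 1-based coordinates; loci of
different leads may overlap and are not merged. For the combined-panel
overlap analysis, regions are seeded greedily from the SNP with the best
local PWV p-value and each panel SNP is assigned to the first region whose
window covers it; a locus is cross-trait overlapping when it contains SNPs
of both panels, and PWV-overlapping when its lead clears p < 0.05/3 for at
least one mode. The greedy window assignment is an assumption — the
alternatives (merging overlapping windows) change counts only when published
SNPs sit 0.5–1 Mb apart.

## Replication

A candidate replicates when its best local p across the three modes is
strictly below 0.05/3 ≈ 0.016667 (so a local p of 1.69e-2 does not
replicate). Local effects are harmonized to the reported effect allele
(beta negated and EAF complemented when the local effect allele equals the
reported other allele); A/T and G/C pairs are flagged strand-ambiguous.
Candidates whose source modelled a reciprocal phenotype (1000/cfPWV) carry
an inversion flag: for them, opposite signs are the concordant outcome.
Best phenotype is the mode with minimal p; ties break in the fixed order
ba, cf, bf. The packaged panel `data/known_pwv_snps.tsv` transcribes the 14
published candidate SNPs (sources: Mitchell 2012, Tarasov 2009, Park 2015)
together with the association statistics reported for them in a
population-based three-mode PWV cohort GWAS; applying the rule to that
table yields 7 replications.

## Enrichment

The observed statistic is the number of panel SNPs whose best
covariate-adjusted p across the three modes clears 0.05/3. The permutation
unit is the genotype block: sample rows of the genotypes are permuted
against the jointly intact (phenotypes + covariates) block. This choice —
the phrase "permuting phenotypes and genotypes" admits several readings —
preserves the cross-phenotype and phenotype–covariate correlation structure
and therefore the covariate-adjusted null. Each permutation refits the
adjusted regressions exactly (via the FWL projection, identical to refitting
the joint model); a faster approximate mode that permutes pre-residualized
genotypes is available opt-in. The empirical p uses the add-one estimator
(1 + #{null ≥ obs})/(B + 1); the Poisson upper tail at the null mean is
reported alongside, computed through the regularized incomplete gamma
function. Because the count is a small discrete statistic, its empirical p
is valid (super-uniform) but not uniform; the calibration tests therefore
check super-uniformity and the uniformity of the tie-randomized PIT, which
is the property a discrete permutation p can and must satisfy.

## LD-score regression

LD scores sum bias-adjusted squared correlations r² − (1−r²)/(n−2) over a
1 Mb window (self term included), from in-sample dosages — a desk-scale
substitute for precomputed reference-panel scores. Heritability is the
slope of χ²_j on N·ℓ_j/M by weighted least squares with weights
1/max(ℓ_j, 1) and one re-weighting step that divides by the squared fitted
expectation (heteroskedasticity correction); full iterative weighting
changes estimates negligibly at these scales. Standard errors are
delete-a-block jackknife over 20 contiguous blocks (configurable; 200 is
the common large-scale choice, 20 keeps desk-scale variance estimates
stable). The QC gates — h² Z > 1.5, mean χ² > 1.02, intercept in
(0.9, 1.1), all strict — are applied before any interpretation. Genetic
correlation regresses z₁z₂ on √(N₁N₂)·ℓ/M; the entire pipeline (both h²
fits and the covariance fit) is re-run in each jackknife block so the r_g
standard error reflects denominator uncertainty; r_g is clamped to [−1, 1]
with the clamp recorded.

## Mendelian randomization

Per instrument the Wald ratio β_y/β_x with first-order standard error
se_y/|β_x| (the second-order form including se_x is available behind a
flag); the IVW estimate is the inverse-variance-weighted mean of ratios.
The random-effect model — the default — multiplies the fixed-effect SE by
max(1, √(Q/(J−1))), a multiplicative heterogeneity inflation; it is used in
both directions. Confidence intervals use z = 1.96 exactly. Cochran's Q is
referred to χ²(J−1).

Forward instruments (BP → PWV) are published blood-pressure SNPs filtered
in order: available locally; no nominal PWV association (potential direct
outcome effect); nominal local SBP association; not in LD (r² ≥ 0.1) with
any PWV lead. Every exclusion is written to a machine-readable ledger.
Reverse instruments are the independent suggestive PWV leads with nominal
significance for the mode under study, excluding SNPs in LD with published
BP hits; a designated lead can be dropped for a sensitivity rerun. The
outcome scans for MR (and the heritability scans) adjust for sex and age
only — conditioning the outcome on the exposure would absorb the causal
path being estimated. The design is one-sample (both sides estimated in
the same cohort): the estimator is unchanged, but weak-instrument bias then
points toward the observational association, which is why the nominal-SBP
instrument gate matters.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes, at
configurable scale, with every random draw flowing through one seed.

**Genotypes.** Haplotype alleles are indicators that a block-correlated
standard normal (one factor per block) falls below the allele-frequency
quantile; dosage is the sum of two independent haplotypes, so hard calls
are in HWE by construction. The threshold model attenuates the latent
correlation on the dosage scale (a latent 0.99 yields dosage r² ≈ 0.8), so
block r² targets are approximate — this is the documented price of the
simplest controllable-LD construction. One synthetic chromosome, 1-based
positions at 10 kb spacing, so a ±500 kb window spans exactly 101 variants
and locus tests are enumerable. Imputation noise shrinks dosages toward 2p
and adds Gaussian perturbation scaled so the realized info statistic
approaches a target; the fresh-noise share is reduced as the target
approaches 1 so clipping to [0, 2] does not erode variance.

**Phenotypes.** Age is uniform on 40–79, sex Bernoulli(1/2). On the log
scale, SBP is driven by age, sex, a 60-SNP medium-effect panel (30% of its
covariate-free residual variance genetic) and noise, with total log-SBP
variance 0.0169 (SD ≈ 0.13, i.e. ≈ 17 mmHg at a 129 mmHg mean). Each PWV
mode is mu + age/sex effects + θ·(centred log-SBP) + direct genetic effects
+ shared latent factor + noise, with default causal effects θ = 0.612 /
0.481 / 0.715 for ba/cf/bf — the published scale for this causal
relationship. The shared-factor loadings are set in closed form so the
pairwise partial correlations given SBP, age and sex land on 0.37 / 0.49 /
0.51 (three pairwise targets determine three loadings exactly); the
empirical partials on a 2,000-sample cohort land within ±0.02 of these.
The designated heritability mode (baPWV) receives a polygenic background
over 10% of variants scaled by closed-form variance bookkeeping so that the
genetic share of its age/sex-adjusted variance is h² = 0.28, counting both
the direct effects and the genetic component inherited through the SBP
path. Non-positive residual variances raise an error rather than being
silently truncated. Duplicate raw measurements add measurement error such
that a configured fraction (default 3%) violates the discard thresholds;
for bfPWV the pair is centred on the true value because that mode is
averaged downstream.

What the generator does **not** emulate: realistic recombination maps or
haplotype panels, population structure and relatedness, mode-specific
missingness patterns, X-chromosome dosage coding, genotyping-batch
artefacts. Tests passing on this cohort show the estimators correct under
the stated model, not robustness to those real-data complications.

**Summary-statistic fixtures.** Two-sample MR sets draw true exposure
effects around |β_x| = 0.04 (SE 0.005, so instrument F ≈ 60) with outcome
effects θ·β_x plus optional pleiotropy and independent noise. The
polygenic LDSC fixture draws z-scores exactly from their sampling
distribution z = √N·Rβ + MVN(0, R) in 50-SNP blocks whose equicorrelation
cycles through 0.1–0.8; the cycling is structural, not cosmetic — constant
LD scores would make the regression's slope and intercept collinear.
Confounding is injected as independent z-noise, which raises the intercept
by exactly its variance while leaving the slope unchanged.

## Problem sizes and defaults

The packaged demo configuration runs 2,000 samples × 2,000 variants with
B = 200 permutations, completing in well under a minute on one CPU while
leaving every stage with real work (QC drops ~4% of variants, three loci
reach suggestive significance, forward MR retains ~40 instruments).
Recovery tests for LDSC use M = 20,000 simulated summary statistics;
calibration tests use 200 replicates at B = 200 (enrichment) and 1,000
replicates at J = 49 (IVW size). Sample sizes of 5,000–10,000 appear where
a derived quantity (realized info, allele frequency, causal-effect
recovery) needs tight sampling error.

## Known limitations

- In-sample LD for pruning and LD scores; no external reference panels.
- The λ of a *non-null* polygenic scan on a dense synthetic panel exceeds 1
  by design (true signal, small M); the [0.95, 1.05] calibration band
  applies to null phenotypes.
- The enrichment empirical p is conservative at very small panel sizes
  (discreteness); the Poisson tail is reported alongside.
- No MR-Egger / weighted-median estimators, no multivariable MR, no
  sample-overlap intercept modelling for genetic correlation.
- The one-sample MR caveat above applies to any real single-cohort use.
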