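# Methods

## Generative model

The simulator works at the haplotype level. Each of the `2n` haplotypes
carries one functional ABO allele drawn i.i.d. from the configured
frequencies `(f_O, f_A, f_B)`; the three-allele model deliberately ignores
the >100 curated *ABO* suballeles (A1/A2 and friends) because the classical
O/A/B alleles suffice to generate the four serotypes and their Mendelian
logic. Haplotypes pair into individuals; serotype follows dominance (O
recessive, A/B codominant) and is then mis-recorded with probability
`typing_error_rate`, uniformly over the three wrong types — no error
structure is assumed because none is known.

Tag SNPs are attached per haplotype conditionally on an anchor indicator
(the O, A or B allele). For anchor frequency `p`, tag-allele frequency `q`
and target r², the haplotype covariance is fixed at
`D = sign·√(r²·p(1−p)q(1−q))`, i.e. `P(tag=1|anchor=1) = q + D/p` and
`P(tag=1|anchor=0) = q − D/(1−p)`, so the target r² is exact in
expectation; feasibility (`D ≤ D_max`) is checked against the usual bound
and violated targets raise an error naming `D_max`. This is the
population-genetic definition of r², so genotype-dosage r² matches it in
expectation under Hardy–Weinberg equilibrium (verified by simulation at
n = 10⁵ haplotypes, tolerance ±0.02). Because tag bits are conditionally
independent given the anchor, two tags of the same anchor at r² `a` and `b`
have mutual r² `a·b` — attaching tags at 1.0, 0.95 and 0.98 to the O
indel reproduces the familiar 0.93–0.98 block structure of the ABO region.

Null background SNPs are independent `Binomial(2, maf)` with MAF uniform on
a configured range (default 0.05–0.5), placed on rotating autosomes.
Duplicate pairs copy both haplotypes of a donor; sib pairs are bred from
two fresh simulated parents, with the ABO locus transmitted as one block
and null SNPs transmitted independently (free recombination genome-wide),
giving the Mendelian expectation pi-hat ≈ 0.5.

Traits: systolic/diastolic pressure are Gaussian with an age slope
(0.5 and 0.25 mmHg/year around age 50), a male shift (4 / 3 mmHg), noise
SD 12 / 8 mmHg, and an optional additive shift (mmHg) for carriers of one
configured blood type; a binary outcome uses a logistic link with
configurable intercept (default −2.0, ≈12% prevalence) and log-OR shift.
Sex is Bernoulli(0.5), age Uniform(30, 70) years. All of these are
configuration, not estimates.

### Defaults and why

* `AlleleSystem(0.55, 0.22, 0.23)` gives a serotype distribution
  (≈30% O, 29% A, 31% B, 10% AB) qualitatively similar to East-Asian
  cohorts. The values live in config only; no logic depends on them.
* Default `typing_error_rate = 0.02`: genotype-vs-serology discordance of
  the order seen when serological types are checked against genetic
  predictions (a few per-cent). It also keeps the association fits away
  from complete separation, which perfect (r² = 1) tags otherwise cause —
  see "Separation" below. The idealized generator
  `noiseless_three_tag_config()` sets it to 0 for exact-performance
  bounds.
* Default cohort: n = 1008 founders, five locus tags (O-indel at r² 1.0,
  two redundant O-tags at 0.95/0.98, A- and B-tags at 1.0), 2000 null
  SNPs, 5 duplicate + 10 sib pairs, background genotype missingness
  0.001 and one deliberately low-call-rate sample.

### What the simulator does and does not emulate

It emulates the LD architecture of a single causal locus, Mendelian
phenotype logic, serology noise, cryptic relatedness and call-rate
failure. It does not emulate population stratification (founders are one
panmictic population — the PCA stage is exercised by dedicated two-
subpopulation fixtures in the tests), genotyping-intensity artifacts,
imputation uncertainty, or other blood-group systems. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to confounding structures the generator never
produces.

## QC

Sample call-rate filter (default ≥ 0.95) runs before the SNP call-rate
filter (≥ 0.95), then MAF ≥ 0.01 and a Hardy–Weinberg exact test (the
standard conditional-on-allele-count enumeration) at p ≥ 1e-6. These
thresholds are conventional GWAS practice, exposed in config.

Relatedness uses method-of-moments IBS→IBD estimation: per-pair counts of
IBS 0/1/2 over jointly non-missing SNPs are equated to allele-frequency
expectations under the IBD states (`P(IBS0|IBD0)=2p²q²`,
`P(IBS1|IBD0)=4p³q+4pq³`, `P(IBS1|IBD1)=2pq`, `P(IBS2|IBD2)=1`) and solved
for the state probabilities; `pi-hat = P2 + P1/2`. Two numerical choices
matter at the few-thousand-SNP scale this package runs at:

* the per-SNP expectation terms use unbiased factorial-moment estimators
  (`p²q² → x(x−1)y(y−1)/T(T−1)(T−2)(T−3)` with allele counts `x`, `y`,
  `T = x+y`) rather than plug-in frequencies, and
* only the final pi-hat is clamped to [0,1]; clamping the intermediate
  state probabilities censors estimation noise one-sidedly and inflates
  pi-hat by several points at 1–2k SNPs, enough to trigger spurious
  relatedness drops.

Pruning is greedy, worst pair first, dropping the member with greater
missingness (ties: lexicographically larger id), default threshold 0.1875
(midpoint between second- and third-degree expectations). Greedy is
standard practice and deterministic; it does not attempt a minimum vertex
cover.

PCA (default K = 10) runs on SNPs greedily LD-pruned at r² < 0.2 in
descending-MAF order, mean-imputes missing dosages (for PCA only — never
for association fits), standardizes columns and takes the SVD; each
component's largest-magnitude loading is made positive so signs are
reproducible.

## Association scans

Dosages are recoded to count the in-sample minor allele (exact 50/50 ties:
lexicographically smaller allele string). The binomial scan fits four
logistic regressions per SNP (one per dichotomized type); the multinomial
scan fits one joint quaternary log-linear model per SNP with type O as the
reference, not three separate logistic fits. Covariates (sex, age, top
PCs) enter linearly. P-values are two-sided Wald; the likelihood-ratio
alternative was not chosen because per-SNP OR + Wald p is what GWAS
summary tables report. Missing dosages are handled per SNP as complete
cases and `n_used` is recorded. Genome-wide screening uses α = 5×10⁻⁸
(−log₁₀ ≈ 7.3), sorted ascending by p with |beta| then (chrom, pos) as tie
breaks.

### Separation

A tag SNP in complete LD with a functional allele makes some contrasts
perfectly or quasi-perfectly separable (e.g. type O ⇔ O-tag dosage 2), and
the maximum-likelihood estimate does not exist. The fits first attempt
unpenalized Newton; divergence (|linear predictor| > 30, singular
information, or non-convergence) triggers one refit with a fixed ridge of
1e-6 and a `converged=False` flag. The ridge keeps the coefficient finite
but the Wald SE is then of order `1/√ridge`, so separated SNPs do not
screen as hits — this is a property of Wald inference under separation,
not a bug. Consequently meaningful GWAS behavior requires the data to
break separation, which any realistic serotyping error or imperfect LD
does; the default simulation's 2% typing error plays that role, and the
type-I error of the Wald p under the null is calibrated (5% nominal,
verified over 1000 simulations).

## LD selection

LD is composite r² — squared Pearson correlation of dosage vectors,
pairwise-complete — because inputs are unphased; users comparing to
phased/EM estimates should expect small discrepancies. Selection walks
hits in screening order and accepts a SNP iff r² < 0.8 (configurable)
against everything already selected; a brute-force restatement of the rule
is tested against the implementation on hundreds of random ≤8-SNP
configurations. "Strong OR" is operationalized as p-ordering with |OR| as
a tie-break only, since no OR cutoff is defensible a priori. The
common-tag pass replaces a selected pair with mutual r² ≥ 0.9 by a
candidate correlated ≥ 0.9 with both and < 0.8 with every other selected
SNP, preferring the candidate with the larger min-r² (ties: smaller p).

## Blood-type classifier

`ABOGenotypeClassifier` is the same quaternary log-linear model fit with a
mandatory ridge (default 1e-4, config-exposed): with noiseless tags the
classes are linearly separable, so an unpenalized fit has no maximum. The
penalized Newton iterations converge slowly once the class probabilities
saturate (curvature collapses to the ridge), so the iteration cap is
large (3000) rather than the ridge being inflated. Conventions:

* multi-class assignment is argmax probability, exact ties resolved toward
  the more prevalent training type;
* the per-type binary battery thresholds the type's probability at its
  training prevalence, boundary inclusive (prob ≥ threshold ⇒ positive);
* zero-denominator metrics are reported missing (NaN), never 0; macro-F1
  averages only the defined per-type F1 values, with a warning;
* micro-F1 pools the one-vs-rest argmax tables and therefore equals
  accuracy for single-label assignment;
* AUC is the Mann–Whitney rank statistic with midrank ties (all-tied
  scores give exactly 0.5);
* prediction on a joint genotype combination never seen in training is
  allowed (the linear model defines it) but flagged as extrapolation.

## Mendelian randomization

Per instrument, the Wald ratio is `β_out/β_exp` with first-order SE
`se_out/|β_exp|`. Fixed-effect IVW pools ratios with weights `1/se²`;
with three instruments a random-effects heterogeneity parameter is not
estimable, so fixed-effect is the only sensible pooling. The weighted
median orders ratios, accumulates standardized weights with the midpoint
convention `s_j − w_j/2` and interpolates at 0.5; its SE is a parametric
bootstrap (default 1000 seeded draws of `N(ratio_j, se_j)`). One-sample MR
builds instruments inside the cohort: logistic regression of the
blood-type indicator on dosage (+ covariates) for the exposure, linear
(or logistic, for binary traits) regression for the outcome, both on the
log-odds / raw-trait scale with no rescaling. Two-sample MR inner-joins
two summary tables on snp_id, flips the outcome beta when effect/other
alleles are swapped, and drops strand-ambiguous (A/T, C/G) SNPs and
allele-incompatible rows with warnings.

Known limitation: the three ABO instruments are same-locus and mutually
correlated (dosage r² ≈ 0.08–0.37 under the default allele frequencies —
an unavoidable property of mutually exclusive allele indicators). Plain
IVW assumes independent instruments, so its SE understates the sampling
variance of the pooled estimate and the 95% CI covers the null slightly
below nominal; the coverage simulation in the test suite measures this
gap, and it does not shrink with sample size. With a single instrument, or
instruments from independent loci, coverage is nominal (also verified by
simulation). A generalized IVW weighting by the instrument correlation
matrix would remove the gap but is a different estimator from the plain
IVW/weighted-median pair this package implements; it is deliberately out
of scope.

## Reproducibility and problem sizes

All randomness derives from one root seed, split per stage by fixed
offsets; identical configuration gives byte-identical artifacts. The
bundled simulations are desk-scale by design: cohorts of 350–1100 samples,
null backgrounds of 600–10⁴ SNPs, 500-replicate calibration studies —
sizes chosen so the full suite and the acceptance script each run in
minutes on a single CPU while keeping every sampling-error tolerance
derivable from first principles (binomial bounds at the stated n).
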