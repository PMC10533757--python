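# Methods

`shuttlegp` evaluates genomic-prediction calibration strategies for a
shuttle-breeding recurrent-selection program: a selfing crop population is
advanced at a favorable surrogate location (PAL) while selection targets a
stress-prone location (SRO), and the question is which combination of
subpopulations, selfing generations, locations and phenotyping fractions
calibrates the best genomic prediction model per unit cost.  Everything
runs on synthetic data; the package reproduces the statistical machinery of
such a study, not any particular dataset.

## Synthetic population

**Genotypes.** S0 plants are simulated as unions of two gametes drawn from
a founder pool with Beta(0.7, 0.7) allele frequencies truncated so every
realized sample MAF is at least 2.5%.  This yields a U-shaped frequency
spectrum in which rare alleles are present but not enriched, and S0 plants
with mean observed heterozygosity well above 0.2.  The two subpopulations
(training A, default 384 including 50 temporal checks; validation B,
default 334) are random fractions of the same pool, so the sample carries
no structure.  SNPs (default 2000 at desk scale; the design emulated has
~10k) are spread evenly over 12 chromosomes at ~1 per 40 kb.  Loci are
simulated independently: linkage matters only to the descriptive LD
summary, which reports the near-null r² this implies, and no map distances
are asserted anywhere.

**Selfing dynamics.** Families are advanced by bulk selfing in expectation:
after t steps the per-locus heterozygosity is the S0 value times (1/2)^t
and the expected dosage is unchanged.  With 15-20 plants bulked per family
per step, drift is small and ignored (`FamilyGenotypeState` tracks expected
genotype frequencies, not individual plants).  Realized plant genotypes can
be sampled from those frequencies (`sample_family_genotypes`) for
marker-level checks; plot *phenotypes*, however, are built from the
family's expected genetic value.  This keeps the plot-level model exactly
the nested variance model the analysis stage assumes, so variance-component
recovery is a clean test of the estimator rather than of an extra
Mendelian-sampling term.  Consequence: a family's genetic value does not
change across generations — consistent with no selection during advance,
and the reason generation enters scenarios only through *which phenotypes
exist*, not through changed genetics.

**Trait architecture.** Each trait has additive effects at all SNPs for a
main genetic value g and per-location deviations d_loc.  Realized values
are standardized in-sample so that var(g) = 1 − w and var(d_loc) = w, where
w (`gxe_share`) is the fraction of genetic variance that is
location-specific; the between-location genetic correlation is therefore
1 − w by construction.  The plot residual variance solves the entry-mean
heritability identity H² = s²_g / (s²_g + s²_gxl/NE + s²_e/NR) at the
reference design (NE = 2 locations, NR = 6 plots), so `target_h2` is an
entry-mean H², not a plot-level ratio.  A per-trait `residual_var` override
bypasses that calculation when a simulation needs exact variance inputs.
Default trait settings (four traits: flowering FL, height PH, yield YLD,
zinc ZN) use heritabilities 0.02–0.51 and G×E shares 0.57–0.98 typical of
multi-location upland rice trials, with location mean offsets and scales in
trait units.

**Trials.** Each trial is a lattice-style design: 3 replicates × 8
incomplete blocks, entries assigned to blocks at random per replicate and
as evenly as possible.  Plot value = location mean + fixed replicate offset
+ random block effect (variance `block_var`) + g + d_loc + residual, all on
the trait scale.  Temporal checks appear in every trial at generation 2.
Year effects default to zero — in the emulated design year is confounded
with generation, so simulating them by default would only inject
unidentifiable variance; a config switch (`year_effect_sd`) enables them
for temporal-check experiments.

What the generator does **not** emulate: linkage disequilibrium and its
decay, selection or drift during advance, spatial field trends, genotype
missingness patterns of real GBS data (missingness enters only through the
filtering/imputation API), or location-specific error variances.  Passing
tests therefore demonstrate that the machinery is correct under the stated
model, not that any particular real dataset would give the same numbers.

## Genotype processing

Markers are filtered by missingness (< 20%), MAF (> 2.5%) and biallelic
status (enforced at VCF read time), with removals attributed to the first
failing rule.  Missing calls are mean-imputed per SNP; the genomic
relationship is VanRaden's G = ZZ'/(2Σp(1−p)) with Z the dosage centered
at twice the observed allele frequency (observed, not founder, frequencies
— the common GBLUP practice).  Monomorphic SNPs are dropped.  G receives a
ridge of 1e-6 × mean diagonal so every downstream factorization
(mixed-model equations, CDmean, kernel eigendecompositions) meets a
positive-definite matrix.  A read-depth filter is not applicable to dosage
data and is recorded as such in the filter report.

## Stage 1: phenotype analysis

Outlier screening uses Tukey hinges (box-plot semantics) with a 1.5 × IQR
fence, flags only — nothing is removed.  The hinge convention matters
because quartile definitions differ between tools; hinges are the median of
each half with the median included when n is odd.

The variance decomposition fits

y = mu + Loc + Rep(Loc) + Bl(Rep(Loc)) + g + g(Loc) + e

with Loc and Rep(Loc) fixed and block, genotype and genotype-within-
location random, by EM-REML on Henderson's mixed-model equations.  The
coefficient matrix is assembled once from indicator cross-products; each
iteration Cholesky-factorizes it, updates each variance from the BLUP
sum-of-squares plus the trace of the corresponding inverse block, and the
residual from the weighted residual sum of squares.  Convergence is
declared when the relative change of the REML log-likelihood (computed
from the same Cholesky factor) falls below 1e-6; maximum 500 iterations;
variances are kept positive by projection to a small floor and reported as
0 when they finish there.  An Aitken-accelerated variant was tried and
rejected: the vector extrapolation could launch a component toward the zero
boundary on this nested design, while plain EM converges in a few dozen
iterations under the log-likelihood rule.  Entry-mean heritability uses
harmonic-mean location and plot counts per family.

Per-trial adjusted genotype means (BLUEs) come from the same machinery
with genotype and replicate fixed and blocks random: the block variance is
estimated by REML, then the genotype means are the GLS solutions at those
variances, re-centred so their mean equals the trial mean.  Standard errors
are the GLS contrast standard deviations.  Stage 2 uses these BLUEs
unweighted — the two-stage scheme deliberately keeps the stages decoupled.

## Stage 2: genomic prediction

Records are (individual, environment) pairs.  Genetic covariance is a sum
of kernels built from G:

- **SM** — single environment, one kernel;
- **MM** — two environments sharing one main-effect kernel (no G×E);
- **MDs** — MM plus one G×E deviation kernel, block-diagonal copies of G
  within environment, a single deviation variance;
- **MDe** — one deviation kernel per environment, each with its own
  variance.

Fitting is Gibbs sampling in the eigenbasis of each kernel (components
with eigenvalue < 1e-8 dropped), where the effective design has diagonal
cross-product and each kernel's effects are drawn jointly.  Fixed effects
(intercept + environment) use a flat prior; variances use
scaled-inverse-chi-square conjugate updates with df 5 and scale set by
partitioning the sample variance of y equally across kernels plus
residual — proper but weakly informative.  Records with missing phenotypes
(the prediction targets) are handled by data augmentation.  Posterior-mean
genetic values are accumulated in Rao-Blackwellized form (the conditional
mean of each kernel effect rather than its draw), which removes most Monte
Carlo noise from the reported GEBVs.  Variances can be clamped
(`fixed_variances`) — that mode turns the sampler into an exact match for
the closed-form GBLUP u = K(K+λI)⁻¹(y−ȳ) at a fixed variance ratio, which
the test suite exploits as an analytic oracle alongside a direct
Henderson-equation solve.

Sampler presets: `desk` (burn-in 500, 5000 iterations, thin 5) for
replicated scenario runs on one CPU; `full` (2000 / 70000 / 100) for
production analyses.  Chains are reproducible from a single integer seed.

## Training-set optimization

CDmean scores a training set by the expected reliability of predicting
each target's contrast with the population mean: CD(c) =
c'(G − λC²²)c / (c'Gc), with C²² the genetic block of the inverse
mixed-model coefficient matrix for an intercept-plus-TS design and λ the
residual/genetic variance ratio (default 1, i.e. h² = 0.5).  The contrast
c_i = e_i − 1/n over all individuals is the single supported choice.
Families already phenotyped elsewhere can be pinned into the training set
(`fixed_ts_ids`, environment-collapsed records); by default the sparse-
testing scenario includes them, since the optimization chooses which
*additional* phenotypes to buy.

The subset search is a genetic algorithm over fixed-size index sets:
tournament selection (size 3), uniform membership crossover with repair,
single-member swap mutation (rate 0.1), elitism (defaults 200 iterations,
population 300, 10 elites; scenario runs use a reduced 30/40/4 setting
since the selection is computed once per scenario and G is small at desk
scale).  Criterion values are cached per subset; the best-so-far trajectory
is non-decreasing by elitism.

## Scenarios, comparison, economics

Five scenario archetypes compose training and validation sets from
(subpopulation, generation, location, fraction, sampling rule): a 70/30
cross-validation within the validation subpopulation at the target site
(Uni1); deterministic early-generation calibrations on the training
subpopulation (Uni2, Uni3 — one replicate, no random draw); a two-location
G×E scenario holding out 30% of the target-site phenotypes (Multi1); and a
sparse-testing scenario with all surrogate-site phenotypes plus a
25/50/75% fraction of target-site phenotypes chosen randomly or by CDmean
(Multi2).  Per replicate, training membership is drawn from a
replicate-indexed seed stream, the model is fitted, and predictive ability
is the Pearson correlation between predicted genetic values and the
validation families' trial BLUEs.  A hard assertion guarantees that a
validation family's phenotype in the prediction environment never enters
the training response.  Kernel eigendecompositions are computed once per
scenario and shared across replicates, since membership only toggles which
records carry observed phenotypes.

Scenario comparison transforms replicate PAs with Fisher's Z, fits a
one-way fixed-effect linear model and assigns compact letters from Tukey
HSD pairwise tests at alpha = 0.05 (Tukey chosen as the standard multiple-
comparison companion of a one-way fixed-effect model).  Deterministic
scenarios enter as reference rows without letters.  Top-k ranking overlap
between two scenario runs is computed on mean predicted genetic values.

The cost module is a deterministic ledger in location-specific phenotyping
units (1 X$ = one full 1200-plot evaluation trial; generation advance =
0.4 X$_PAL).  Costs are exact decimals summed per currency, never floats
and never added across locations.  One known quirk of the reference
schedule is preserved: the early-calibration scenario's entries sum to
0.85 X$_PAL while its published total rounds to 0.9; the ledger reports
the exact sum.  The half-population target-site evaluation is costed at
0.6 (not 0.5), as scheduled — plausibly because check entries are always
phenotyped.

## Problem sizes and numerical choices

Defaults mirror the emulated design (384 + 334 individuals, 2000 SNPs,
3 × 8 lattice, two locations).  The test suite and the acceptance script
size their simulations for a single CPU: variance-component recovery runs
the full 334-family × 2-location × 3-replicate design over 20 seeds;
sampler-vs-oracle checks use 100 individuals and 20000 iterations;
scenario trend checks use a reduced study (120 + 100 individuals, 500
SNPs) with the desk sampler preset and 6–100 replicates.  These sizes are
the package's own desk-scale choices; all of them can be raised through
`SimConfig` and `McmcSettings`.

Key numerical constants: G ridge 1e-6 × mean diagonal; kernel eigenvalue
cutoff 1e-8; REML tolerance 1e-6 (relative log-likelihood), max 500
iterations, variance floor 1e-8 × var(y); sampler prior df 5; CDmean λ
default 1.  Ties in block filling are broken by the replicate's random
permutation; collinear fixed-effect columns are dropped by QR rank check.

## Limitations

- Independent loci: LD-based phenomena (marker density requirements, LD
  decay) cannot be studied with this generator.
- Expectation-based family values: within-family Mendelian variance and
  its decay across selfing generations do not enter phenotypes.
- Mean imputation stands where a haplotype-based imputer would be used on
  real GBS data; G is robust to this below ~20% missingness, but imputed
  dosages are not genotypes.
- The Gibbs sampler estimates variances under weakly informative priors;
  with very small training sets the posterior variance means shrink toward
  the prior scale.
- Predictive abilities on synthetic data depend on the simulated
  architecture and are not comparable to any published real-data values;
  only their trends (more target-site phenotypes → higher PA; zero
  heritability → null PA) are meaningful checks.
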