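# Methods

This note documents the models implemented in `driftwatch`, the
numerical choices behind them, and what the synthetic-data validations
do and do not demonstrate.

## Scope and data model

All analyses start from a rectangular diploid genotype matrix (samples
× loci, two integer allele codes per cell, `-1` missing) plus a
sample→population map. Within each population, analyses use only loci
scored in every individual of that population and polymorphic within it
("complete polymorphic" matrices); this keeps every estimator free of
missing-data imputation at the cost of discarding loci, which mirrors
how conservative RADSeq panels for small populations are usually built.
Raw read processing and genotype calling are upstream of this package.

## Diversity summaries

Observed heterozygosity `Ho` is the mean over loci of the heterozygote
proportion. Expected heterozygosity `He` is unbiased gene diversity,
`(n/(n-1))·(1-Σp̂²)` with `n` the number of sampled chromosomes —
the small-sample correction standard in Arlequin-style summaries.
`Fis = 1 - Ho/He` is computed from the locus-averaged quantities
(a per-locus-averaged variant would weight loci differently; the
locus-averaged form is simpler and directly testable by hand).
Allelic richness is hypergeometric rarefaction: the expected number of
distinct alleles in a subsample of `2·g` chromosomes, `Σ_alleles
(1 - C(n-k, 2g)/C(n, 2g))`, evaluated with `scipy.stats.hypergeom`.
Because monomorphic-within-population loci are filtered out first,
`He > 0` always holds and `Fis` is well defined.

## Weir–Cockerham Fst

Differentiation uses the Weir & Cockerham (1984) variance components
`a` (among populations), `b` (among individuals within populations) and
`c` (within individuals), computed per locus and allele from sample
sizes, allele frequencies and heterozygote frequencies, and combined as
the ratio of sums `Σa / Σ(a+b+c)` over loci (and alleles, so
multiallelic input is supported). The estimator is not range-bound:
slightly negative values are the expected outcome under zero
differentiation. The test suite checks the implementation to 1e-12
against an independent nested random-effects ANOVA on allele
indicators, which is the algebraic origin of the WC84 components.

Cross-marker agreement between two pairwise-Fst matrices is summarized
by the plain Pearson correlation of the vectorized upper triangles with
its parametric two-sided p-value, plus a coefficient of variation
(100·sd/mean) per matrix. This deliberately reproduces the common
applied practice of correlating pairwise values directly rather than a
Mantel permutation; the p-value therefore inherits the usual
non-independence caveat and should be read qualitatively.

The outlier-sensitivity filter ranks loci by per-locus pairwise WC84
Fst and removes the top `ceil(fraction·n_loci)` (default 5%), ties at
the cutoff broken by input order. It supports the standard robustness
argument: if Ne and demographic estimates are unchanged after removal,
undetected divergently selected loci are unlikely to drive them.

## LD-based contemporary Ne

For each pair of loci the Burrows composite disequilibrium is

    Δ̂ = (1/2S)·Σ_k X_k Y_k − 2 p̂ q̂,
    r̂² = Δ̂² / [(p̂(1−p̂) + D̂_A)(q̂(1−q̂) + D̂_B)],

with `X_k, Y_k ∈ {0,1,2}` the individual allele-copy counts and `D̂`
the homozygote-excess adjustment — estimable without phase. The mean
r̂² over pairs is compared with the expected pure-sampling contribution
(`1/S + 3.19/S²` for S ≥ 30, else `0.0018 + 0.907/S + 4.44/S²`) and the
excess is inverted through the Waples (2006) / Waples & Do (2008)
random-mating relations (the NeEstimator v2 defaults):

    N̂e = (1/3 + √(1/9 − 2.76 r²'))/(2 r²')        S ≥ 30,
    N̂e = (0.308 + √(0.308² − 2.08 r²'))/(2 r²')    S < 30.

`r²' ≤ 0` (or a negative discriminant) legitimately yields +infinity:
no drift signal is separable from sampling noise. The rare-allele
screen drops alleles observed fewer than `min_allele_copies` times
(default 2, i.e. singletons excluded — the recommended setting for
sample sizes ≤ 25); loci left with fewer than two usable alleles are
dropped. Locus pairs receive equal weight: on complete-data matrices
the per-pair sample size is constant, so harmonic-mean weighting would
reduce to this anyway.

Confidence intervals are parametric: `r̄²·df/χ²` quantiles mapped
through the same transform. The degrees of freedom are the number of
usable **loci**, not the number of pairs. The L(L-1)/2 pairwise values
are built from only L loci and are strongly positively correlated;
treating them as independent overstates the information content by
orders of magnitude at genomic scale and collapses the interval to a
sliver that essentially never covers the truth. The locus count is a
deliberately conservative effective-df choice; on Wright–Fisher
validation data (true Ne = 50, S = 50, 500 loci) it gives slightly
wide intervals with near-complete coverage. A locus-jackknife variance
would be the natural refinement and is left as future work.

Known limitation: with samples that mix adult age classes of an
overlapping-generations species, the method estimates roughly the
effective number of breeders scaled by generation time and can
underestimate true Ne by up to ~25%; no age-structure correction is
applied.

## Demographic inference from the folded SFS

Two single-population demographies are compared: constant size
(`NCURR`) and one instantaneous size change (`NCURR`, `NANCES`,
`TBOT` generations ago; direction unconstrained). The data are a folded
SFS with an explicit monomorphic-site count; sites are treated as
independent draws, giving the multinomial composite log-likelihood
`n_mono·ln p_0 + Σ_b n_b·ln p_b`.

Expected class probabilities use the linear approximation
`p_b = μ·E[L_b]` with `E[L_b]` the expected genealogy branch length
subtending `b` of the `n` sampled chromosomes (valid for `μ·L ≪ 1`; a
guard rejects parameter regimes where the total polymorphism
probability would reach 1). Two engines provide `E[L_b]`:

* **analytic** (constant size only): `E[L_b] = 4N/b`, folded;
* **Monte Carlo** (both models): single-population coalescent
  genealogies with pairwise coalescence rate `k(k−1)/(4N(t))` per
  generation, `N(t)` piecewise constant. Topologies and the unit-rate
  exponential level waiting variables are drawn once per sampler;
  evaluating a demography only rescales the waiting times through the
  epochs. Because topology and coalescence times are independent under
  the single-population coalescent, expected branch lengths are
  accumulated as batchwise products of mean level durations and mean
  lineage-size counts (10 batches by default); the spread across
  batches gives the Monte-Carlo standard error. The engines agree
  within 3 SE across an (N, n_chrom) grid, and the Monte-Carlo engine
  is cross-checked against msprime branch-mode expectations for a
  bottleneck history.

Fitting is multi-start maximum composite likelihood: each of `n_runs`
(default 100) runs draws a start log-uniformly from the prior box
(NCURR, NANCES ∈ [10, 5e4]; TBOT ∈ [1, 1e4]; upper bounds bound only
the starting box) and runs Nelder–Mead on log-parameters against a
per-run fixed genealogy sample (common random numbers), so each run's
objective is deterministic and noise-driven pseudo-optima are avoided.
The original ECM machinery of SFS fitters is intentionally replaced by
this simpler scheme: the contract is "the maximum-likelihood run out of
many", not a particular optimizer. The winning parameters are then
re-scored with an evaluation sampler whose seed depends only on the
config seed, so competing models under the same config share genealogy
noise and AIC differences reflect fit, not Monte-Carlo luck.

Model choice is by AIC (`k` = 1 or 3) with Akaike weights; exact ties
resolve to the 1-parameter model. Uncertainty comes from a site
bootstrap: 50 replicates, each a multinomial redraw of 90% of the total
sites from the observed class proportions (monomorphic class included),
refitted; a point estimate of `TBOT` outside the central 90% of the
replicate distribution flags a population where the timing of the size
change cannot be inferred with confidence. "Central-90% containment" is
this package's operationalization of that qualitative judgement.

The folded SFS is identical for `b` and `n−b`, so a recent decline and
certain growth histories can be hard to separate; with moderate data
the likelihood surface for strong recent declines has a ridge along
`TBOT/NCURR` (the recent epoch measured in coalescent units), which is
why bootstrap TBOT distributions are wide and why the package reports
the distribution rather than a standard error. Mutation rate is a fixed
input (default 2.5e-8/site/generation, the "high" vertebrate rate;
2.1e-9 is the common "low" alternative — rerunning the fit under both
is the supported way to compare them). Times are fitted in generations
and converted to years only at reporting, using a generation time of
2.03 years (configuration constant derived from age at first
reproduction 2 y and annual survival 0.67). Inferred change times ≤ 100
generations (≈ 200 years) are labelled as falling in the
"anthropogenic window".

Monomorphic-site counts are a user input (total genotyped sites minus
polymorphic sites) because genotype matrices carry only polymorphic
loci; the synthetic generator always emits the count.

## Heterozygosity–fitness correlation

Individual heterozygosity is the fraction of heterozygous loci in the
individual's complete polymorphic matrix. Body condition is the Scaled
Mass Index `SMI_i = M_i (L0/L_i)^b` with `L0` the arithmetic mean SVL
and `b` a model-II slope of ln(mass) on ln(SVL). Both standardized
major axis (`b = sign(r)·sd_y/sd_x`; the slope the SMI method itself
specifies, and the default here) and major axis (leading principal axis
of the ln–ln covariance; the default for the HFC regression itself) are
implemented; they coincide at |r| = 1. The HFC test reports the squared
Pearson correlation between SMI and heterozygosity and a two-sided
permutation p-value on |r| (default 9,999 label permutations, seeded).
A permutation test replaces the usual parametric p-value because the
sample sizes in this setting are small and the permutation null is
exact and assumption-free. The allometric exponent is pooled across
populations by default; per-population exponents are a caller choice.

## Forward projection of heterozygosity loss

The simulator is individual-based with overlapping generations at fixed
census size `N`: each individual carries `n_loci` independent biallelic
loci (defaults: 1000 loci at `p0 = 0.81`, initial He = 2p(1−p) ≈ 0.3078,
matching the observed ~0.30 at polymorphic RAD loci). Each annual step:
ages increment; individuals older than `max_age = 5` are removed; while
the census is below `N`, two distinct adults (age ≥ 2) are drawn
uniformly (pairs redrawn with replacement across births) and produce
one offspring, inheriting one uniformly chosen allele per parent per
locus; mean individual heterozygosity is recorded after the births.
Mortality is by aging out only — the field annual survival estimate
(0.67) motivates the 5-year cap but is not applied as stochastic death.
There is no mutation, migration, selection or sex structure (a two-sex
variant changes the effective size only marginally at these census
sizes and is omitted). Initial ages are uniform on 0..5, which is the
stationary age distribution for this life table; an all-newborn mode
exists for short-horizon experiments but collapses once the founding
cohort ages out. Ten replicate iterations give a mean trajectory and a
mean ± 1.96·SD band.

The analytic comparison is the discrete-generation decay
`Ht = H0·(1 − 1/(2Ne))^t`. At equal nominal size the simulation loses
variation substantially more slowly, because several adult cohorts
overlap and buffer allele-frequency change — the central argument for
using demographically realistic projections when planning genetic
rescue.

**Time-axis convention.** The simulator's mechanics run in one-year
steps (maturation at 2 years, removal after 5). For calendar-time
summaries, however, each recorded step is mapped to one generation of
2.03 years: the century-scale loss is read at step
`ceil(100/2.03) = 50` and time-to-loss crossings are converted as
`steps × 2.03`. This convention is what makes the package's summaries
directly comparable to published century-scale projections for this
system, which report heterozygosity "at 50 generations" as the
~100-year outcome; reading the same trajectories at step 100 instead
would roughly double the stated losses. Both readings are available
(`loss_at_year` is step-indexed; `century_projection` applies the
convention), and the choice is isolated in `century_projection`.

With the default seeds the package obtains century losses of roughly
19–22% (N = 50), 30–33% (N = 30) and 66–71% (N = 10), a 50%-loss
crossing for N = 10 around 60–70 calendar years, and no 50% crossing
for N = 50 within the horizon — against analytic losses of 63%, 81%
and 99% at `t = 100`.

## Synthetic data

The generators produce every input with known truth:

* **island_fst** — ancestral frequencies Beta(0.8, 0.8) clipped to
  [0.01, 0.99]; population frequencies Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F) at target Fst `F`; Hardy–Weinberg
  genotypes. Balding–Nichols is the standard closed-form calibration
  target for Fst estimators.
* **divergence_pair** — frequencies evolved by discrete Wright–Fisher
  binomial drift for `T` generations in populations of fixed size.
* **wf_known_ne** — an individual-based Wright–Fisher population: one
  random-mating pedigree of `true_ne` diploids is recorded for
  `burn_in` generations (default `min(4·Ne, 200)`), and unlinked loci
  at founder frequency 0.5 are gene-dropped through it; loci that fix
  are re-dropped through the *same* pedigree, because the shared
  pedigree is precisely what generates the drift LD the Ne estimator
  measures. A sample is drawn without replacement.
* **sfs_truth** — multinomial site draws from the Monte-Carlo expected
  spectrum of a known demography.
* **body_condition** — log-normal SVL, power-law mass with a residual
  whose correlation with Beta(6, 14) heterozygosity is the `hfc_effect`
  (0 = exact null).

What passing the validations shows — and does not. The generators make
the idealizations the estimators themselves assume (free recombination,
Hardy–Weinberg, no genotyping error, no missing data, no selection).
Passing therefore demonstrates internal correctness and calibration
under those assumptions, not robustness to the linked loci, allele
dropout, age-structure mixtures, or non-equilibrium spatial structure
of real RADSeq datasets. The conditioning of `wf_known_ne` on
post-burn-in polymorphism slightly depletes drift LD, which is visible
as a modest upward bias of the Ne estimates in validation (median ≈ 60–70
at true Ne = 50 after a 4Ne-generation burn-in); the factor-2 recovery
and CI-coverage checks are run under exactly those conditions.

## Problem sizes and numerical settings

Validation suites run at deliberately reduced sizes chosen to keep the
whole test battery desk-scale while leaving the conclusions
statistically meaningful: demographic-fit validations use 6 multi-start
runs with 3,000 genealogies per sampler (200,000 sites, n = 40 or 20
chromosomes), bootstrap experiments use 12 replicates × 3 runs, the
Monte-Carlo/analytic agreement grid uses 10,000 genealogies, and the
HFC type-I-error study uses 200 datasets × 499 permutations. Production
defaults (100 runs, 1e5 genealogies, 9,999 permutations, 50 bootstrap
replicates) are the package defaults shown throughout the API.
Optimization tolerances: Nelder–Mead on log-parameters, `xatol` 1e-3,
`fatol` 1e-4, 100–200 iterations. Expected-SFS classes with zero
probability are floored at 1e-12 inside the likelihood with a warning.
Degenerate inputs (zero-variance regressors, populations of one
individual, loci failing the allele screen) raise or warn explicitly
rather than returning silent NaNs.
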