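# driftwatch

Conservation population genetics for species persisting in small,
isolated populations. Given diploid SNP genotypes (VCF or TSV), a
population map and optional body-size records, `driftwatch` answers the
questions a recovery plan needs answered:

* How differentiated are the populations? — per-population diversity
  summaries (Ho, unbiased He, Fis, rarefied allelic richness) and
  Weir–Cockerham Fst (pairwise, overall, and cross-marker correlation).
* How strong is drift right now? — contemporary effective population
  size from genome-wide linkage disequilibrium (Burrows composite r̂²
  with sample-size bias correction and parametric CIs).
* Did the populations decline, and when? — constant-size vs
  instantaneous-size-change demographies fitted to the folded site
  frequency spectrum by composite likelihood, compared by AIC, with
  site-bootstrap uncertainty and conversion of change times to years.
* Is there a measurable cost of inbreeding? — heterozygosity–fitness
  correlation using the Scaled Mass Index as a condition proxy, with a
  permutation test.
* How fast will variation disappear? — an individual-based forward
  simulation of heterozygosity loss with overlapping generations at
  fixed census size, against the analytic decay
  `Ht = H0 (1 − 1/2Ne)^t`.

A seeded synthetic-data module generates every input with known ground
truth (island-model and divergence-pair genotypes, Wright–Fisher
populations of known Ne, SFS datasets from known demographies, body
condition with a tunable heterozygosity effect), so the whole pipeline
is testable without any external data.

## The core quantities

Contemporary Ne inverts the Waples / Waples–Do random-mating relation
between drift LD and effective size: after subtracting the expected
sampling contribution E[r̂²|S] from the mean composite r̂² over locus
pairs, `N̂e = (1/3 + √(1/9 − 2.76 r²'))/(2 r²')` (S ≥ 30 form).
Demographic inference maximizes the multinomial composite likelihood
`lnL = n₀ ln p₀ + Σ_b n_b ln p_b` of the folded SFS, with expected class
probabilities `p_b = μ·E[L_b]` from coalescent branch lengths
(closed-form for constant size, Monte-Carlo genealogies for the
size-change model), and selects models by AIC = 2k − 2 lnL̂. The
forward simulator ages individuals annually, removes them after age 5,
and refills the census with offspring of random adult pairs; the Scaled
Mass Index is `SMI_i = M_i (SVL₀/SVL_i)^b` with `b` a model-II
(standardized major axis) ln–ln slope.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Validate the LD-based Ne estimator on a Wright–Fisher population of
known size, then project heterozygosity loss at census size 50:

```python
import driftwatch as dw

g = dw.gen_wf_population(true_ne=50, n_loci=500, sample_size=50, seed=7)
result = dw.LDNe(g, dw.LdNeConfig(min_allele_copies=2)).fit()
print(result.summary())

traj = dw.simulate_overlapping(
    dw.LifeHistory(),
    dw.SimConfig(pop_size=50, n_loci=1000, p_init=0.81,
                 n_years=100, n_iterations=10, seed=7),
)
c = dw.century_projection(traj, pop_size=50)
print(f"loss over ~100 yr : {100 * c.loss:.1f}%")
```

prints

```
LD-based contemporary Ne (random mating)
  individuals (S)       : 50
  locus pairs           : 121278
  mean r^2              : 0.025390
  E[r^2 | sampling]     : 0.021276
  Ne point estimate     : 78.9
  CI                    : (41.6, 271.2)
loss over ~100 yr : 21.5%
```

The mean pairwise r̂² (0.0254) exceeds the pure-sampling expectation at
S = 50 (0.0213); the excess is drift LD, and inverting it gives an Ne
estimate whose CI comfortably covers the true value of 50. The
projection says a census-50 population starting at He ≈ 0.31 loses
about 21% of its heterozygosity over roughly a century — far less than
the 63% predicted by the discrete-generation formula at Ne = 50,
because overlapping adult cohorts buffer drift.

A full end-to-end run (filtering → diversity → Fst → Ne → SFS →
demographic model choice + bootstrap → outlier-sensitivity rerun → HFC
→ projections) is one call, `driftwatch.pipeline.run_all(RunConfig(...))`,
or from a shell:

```bash
driftwatch synth --scenario divergence_pair --out-prefix sim/demo --seed 7
driftwatch run --config run.yaml
driftwatch project --pop-size 10 --seed 7 --out traj.tsv
driftwatch project-analytic --h0 0.3 --ne 10 --t 100
```

Every stage derives its RNG stream from the master seed; rerunning a
config reproduces the JSON report byte for byte.

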