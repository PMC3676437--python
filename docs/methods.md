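# Methods

## Sampling model

A pool contains the DNA of *n* diploid individuals (*N* = 2*n* chromosomes).
At a bi-allelic site with population allele frequency *p*, the observed data
for the pool are a read depth *R* and a non-reference read count *X*; the
frequency estimate is *p̂ = X/R*.  Three sampling stages separate *p* from
*p̂*:

1. **Population sampling.** Each individual's genotype dose is
   *g*ⱼ ~ Binomial(2, *p*)/2.
2. **Pool construction.** Individual *j* contributes a relative amount
   *c*ⱼ of DNA (scaled so that mean(*c*) = 1).  The allele frequency of the
   pooled DNA is the weighted mean *f* = Σ *c*ⱼ *g*ⱼ / *n*.
3. **Sequencing.** Reads sample molecules from the pool:
   *X* ~ Binomial(*R*, *f*).

Conditioning on the weights and applying the law of total variance gives

Var(*p̂*) = *p*(1−*p*) · [ 1/*R* + (1+*k*)/*N* − (1+*k*)/(*NR*) ],

where *k* = Var(*c*) (with the 1/*n* convention).  The −(1+*k*)/(*NR*) term
is the interaction of read sampling with the two pool stages; it is exact,
small at realistic depths, and can be dropped (`include_interaction=False`).
Setting *k* = 0 recovers the observed-variance model, and letting *R* → ∞
recovers the naive binomial-in-chromosomes variance.  The inflation factor
(1+*k*) multiplies the population component uniformly, so the ratio of full
to observed variance does not depend on *p* — the property that makes a
single genome-wide *k* estimable.

A subtlety the test suite leans on: for one physically constructed pool the
(1+*k*) inflation is **exact conditionally on the realized weights**, with
*k* the realized variance of the normalised weights, since
Var(*f* | *c*) = *p*(1−*p*)/*N* · Σ*c*ⱼ²/*n* and Σ*c*ⱼ²/*n* = 1 + Var(*c*).
Averaging instead over hypothetical re-draws of the weights would give a
slightly different constant (for fresh Gamma weights,
E[Σ*u*ⱼ²] = (1+*k*)/(*n*+*k*) by Dirichlet algebra, a ~13% discrepancy at
*n* = 20, *k* = 3).  The Monte-Carlo oracle therefore fixes one weight vector
per cell and evaluates the formula at its realized variance, and the
simulator records realized variances; the recovery target for calibration is
the mean of the two pools' realized variances, because the statistic sums
both pools' variances under a single shared *k*.

## Test statistic and ranking

*T* = (*p̂*₁ − *p̂*₂)² / (Var₁ + Var₂) is referred to χ²₁.  The variance is
evaluated by default at the depth-weighted combined frequency of both pools
(the null-hypothesis pooling of the classic two-proportion test); a per-pool
option exists.  Sites with zero depth in either pool are untestable; sites
where both pools are monomorphic for the same allele have zero variance and
are excluded from ranking.  Ranking is by ascending p-value, ties broken by
descending |*p̂*₁ − *p̂*₂|, then input order; p-values are reported raw
(the use case is prioritisation for follow-up genotyping, and any
multiple-testing rule can be applied downstream).  The statistic is invariant
under relabelling reference/alternate alleles in both pools.

## Filtering

The χ² approximation needs common alleles: the operative filter keeps sites
with minor allele frequency strictly greater than 1% (configurable) in both
pools.  The textbook rule of thumb — sample size × min(*p̂*, 1−*p̂*) > 5 — is
exposed as an advisory check, using min(*R*, *N*) as the binding sample size
because the tighter of the two sampling stages limits the normal
approximation; it flags but does not exclude, since the MAF rule is the
practical criterion for pools of several hundred individuals.

## Calibration of k

With sites assumed predominantly null after MAF filtering, *k* is chosen so
that the median full-model statistic equals the χ²₁ median, computed from
`scipy.stats.chi2.ppf(0.5, 1)` at run time.  The median statistic is strictly
decreasing in *k* (every variance is strictly increasing), so bisection on
*k* ∈ [0, 100] converges monotonically; the solver stops at a bracket width
of 1e−8 or a relative median mismatch of 1e−10 (both recorded in the
iteration trace), in well under the 200-iteration cap.  Degenerate cases: a
median already below target at *k* = 0 means deflated data — *k* is clamped
to 0 with a warning (a variance cannot be negative); a median still above
target at the ceiling raises an error carrying the partial result.  Fewer
than 50 sites triggers a low-confidence warning.  λ before (at *k* = 0,
i.e. the observed-variance model) and after calibration are reported; the
latter equals 1 by construction when converged off the boundary.

## Variance decomposition and blood pooling

The full-variance bracket splits into three non-negative shares: read
sampling (1/*R*)(1 − (1+*k*)/*N*), ideal population sampling 1/*N*, and
pool-construction excess *k*/*N*, each divided by the bracket; they sum to 1
and are independent of *p* (the interaction term is folded into the read
share, which keeps the partition non-negative whenever *k* ≤ *n* − 1, the
physical maximum for mean-one non-negative contributions).  Pooling equal
blood volumes rather than quantitated DNA adds an independent contribution
variance σ²_b (typically ≈0.25); since volume and concentration multiply,
the inflation factors compose multiplicatively, (1+*k*′) = (1+*k*)(1+σ²_b).
An additive option (*k*′ = *k* + σ²_b) is exposed behind a flag for
comparison.

## Simulator

`simulate_study` draws population frequencies uniformly on [0.05, 0.5]
(common variants, the regime where the test is valid), optionally shifts the
case frequency of designated effect sites by δ, then runs the three sampling
stages per site.  Contribution weights use a mean-one Gamma family (shape
1/*k*, scale *k*; lognormal available) normalised to mean exactly one, drawn
**once per pool and shared across sites** — the correlation structure of a
real physical pool, and the reason realized-variance recovery is testable; a
per-site-independent mode exists for oracle unit tests.  Depth is fixed or
Poisson (truncated at ≥1 by redraw) per site per pool.  A per-read error
rate *e* maps the pool frequency to *q* = *f*(1−*e*) + (1−*f*)*e* before the
read draw; the default is 0 and error is never modelled inside the test
statistic itself.  All randomness derives from one seed through named
`SeedSequence` child streams (frequencies; per pool: weights, depths,
genotypes, reads), so studies are bit-reproducible across platforms.

What the simulator does not emulate: linkage disequilibrium between sites
(sites are independent, so QQ confidence bands computed under independence
are optimistic for real sequence data), sequencing error that varies by base
or position, mapping bias, and variant-calling artefacts.  Passing tests
therefore demonstrate the statistical machinery under the stated sampling
model, not robustness to upstream bioinformatics.

## Default problem sizes in tests and scripts

The statistical checks run at sizes chosen to make Monte-Carlo error small
relative to the tolerances while staying quick on a single CPU: the
calibration loop-closure and type-I-error checks use 5,000 sites with 300
individuals per pool at depth 2,000 and contribution variance 3; the
formula-vs-simulation grid uses 2×10⁵ replicates per cell over
*p* ∈ {0.05, 0.2, 0.5}, *N* ∈ {40, 640}, *R* ∈ {50, 2000}, *k* ∈ {0, 1, 3}
(3 Monte-Carlo standard errors); parameter recovery repeats the full
simulate-calibrate procedure over 50 seeds at 2,000 sites, 200 individuals
per pool, depth 1,000.

## Known limitations

* One shared *k* for both pools; separately constructed pools with very
  different quantitation accuracy would violate this.
* Calibration assumes most filtered sites are null; a region saturated with
  true associations biases *k* upward and costs power.  Population
  stratification is likewise absorbed into *k* rather than corrected.
* The test is for bi-allelic sites (indels treated identically to SNPs;
  allele strings are opaque labels); multi-allelic records are skipped on
  input.
* p-values rely on the large-sample χ² approximation and are unreliable for
  rare variants — hence the MAF filter, which is part of the method, not an
  optional convenience.
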