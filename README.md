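# poolassoc

Case-control association testing from DNA sequencing of sample pools.

Sequencing a single library made from the mixed DNA of hundreds of cases (and
another from controls) is a cheap way to survey all variation in a candidate
region, but only aggregate allele counts are observed.  At each site a pool
yields a read depth *R* and a non-reference read count *X*, so the allele
frequency estimate is *p̂ = X/R*.  Testing *p̂*<sub>case</sub> against
*p̂*<sub>ctrl</sub> naively ignores two extra layers of sampling — the draw of
individuals from the population and the unequal amounts of DNA each individual
contributes to the pool — which inflates test statistics and, less obviously,
scrambles the ranking of variants for follow-up genotyping.

`poolassoc` implements a χ² test for the frequency difference between two
pools,

> *T* = (*p̂*<sub>case</sub> − *p̂*<sub>ctrl</sub>)² / (Var<sub>case</sub> + Var<sub>ctrl</sub>),  *T* ~ χ²₁ under the null,

with three nested estimators of Var(*p̂*) for a pool of *N* chromosomes
(*N* = 2*n* diploid individuals) sequenced to depth *R*:

| model | Var(*p̂*) / *p*(1−*p*) | corrects for |
|---|---|---|
| naive | 1/*N* | pool size only |
| observed | 1/*R* + 1/*N* − 1/(*NR*) | + read depth (and their interaction) |
| full | 1/*R* + (1+*k*)/*N* − (1+*k*)/(*NR*) | + unequal DNA contributions |

Here *k* is the variance of the per-individual relative contributions (scaled
to mean 1); *k* = 0 for a perfect equimolar pool.  Because *k* is
unobservable, it is estimated genomic-control style: *k* is adjusted by
bisection until the median test statistic equals the χ²₁ median (≈0.4549).
Unlike classical genomic control this cannot be done by rescaling the
statistics once, because the variance contains a site-specific read-depth
term — every candidate *k* re-computes every statistic.

The package also provides MAF filtering (>1% in both pools, the practical
validity rule for the χ² approximation), a variance decomposition into
read-sampling / population-sampling / pool-construction shares, an adjustment
for pooling from blood (σ²_b ≈ 0.25), and a fully seeded simulator of pooled
studies for power, type-I-error and calibration-recovery experiments.

## Worked example

Simulate a null study with badly quantitated pools (contribution variance 3),
then calibrate and test:

```sh
poolassoc simulate --n-case 300 --n-ctrl 300 --n-sites 2000 --depth 2000 \
    --contribution-variance 3.0 --seed 42 --out-prefix demo
# wrote 2000 sites to demo.counts.tsv (realized contribution variance: case 3.004, ctrl 3.881)

poolassoc test --input demo.counts.tsv --case-n 300 --ctrl-n 300 \
    --model full --k calibrate --seed 42 --out-prefix demo_run
```

```
      Pooled case-control association test
==========================================================
Variance model:                     full
Case pool (individuals / chrom):    300 / 600
Control pool (individuals / chrom): 300 / 600
Sites (input / passed MAF filter):  2000 / 2000
MAF threshold:                      0.01
k (contribution variance):          3.552
lambda before calibration:          3.7319
lambda after calibration:           1.0000
calibration iterations:             36
----------------------------------------------------------
 rank  site_id  p_hat_case  p_hat_ctrl  statistic   p_value
    1 site0142       0.094      0.2595      11.64 0.0006439
    2 site0249       0.197      0.0665       9.21  0.002408
...
```

The uncorrected statistics are inflated 3.7-fold relative to the null χ²₁
median; calibration recovers a contribution variance of 3.55 — close to the
realized weight variances the simulator reports (3.00 and 3.88) — and brings
the inflation factor to 1.0.  The run writes `demo_run.results.tsv` (ranked
sites), `demo_run.qq.tsv` (expected vs observed −log₁₀ *p* for a QQ plot) and
`demo_run.log.json` (machine-readable parameters and diagnostics).

Variance shares at a typical design (320 individuals, depth 6000, *k* = 2.34),
with and without the extra variance from pooling blood instead of quantitated
DNA:

```sh
poolassoc decompose --n-individuals 320 --depth 6000 --k 2.34 --sigma-b2 0.25
```

```
pool: 320 individuals (640 chromosomes), depth 6000, k=2.34
  read sampling        0.0308
  population           0.2902
  pool construction    0.6790
with blood pooling (sigma_b2=0.25; k -> 3.175):
  read sampling        0.0248
  population           0.2336
  pool construction    0.7417
```

At realistic depths, pool construction — not sequencing — dominates the
variance of the frequency difference, which is why accurate equimolar pooling
matters more than extra reads.

The same analysis is available as a library with a model/results API:

```python
from poolassoc import PooledAssociation

res = PooledAssociation.from_tsv("demo.counts.tsv", n_case=300, n_ctrl=300).fit(k="calibrate")
print(res.summary())
res.table          # per-site DataFrame: frequencies, variances, chi2, p, rank
res.calibration    # k_hat, lambda before/after, iteration trace
```

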