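"""Independent Monte-Carlo oracles for the variance formulas.

These simulate the staged sampling process directly with plain numpy calls
(no use of the package's own simulator), so they can serve as an external
check on the closed-form variance estimators:

* one stage:   chromosomes only — f ~ Binomial(N, p) / N
* two stages:  reads on top     — X ~ Binomial(R, f), p_hat = X / R
* three stages: unequal contributions — genotypes per diploid individual,
  contribution-weighted pool frequency, then reads.

The three-stage oracle holds one contribution-weight vector fixed across
replicates (a physical pool is constructed once) and reports the realized
excess variance of the normalised weights, which is the value the
closed-form bracket should be evaluated at.
"""

from __future__ import annotations

import numpy as np


def mc_variance_se(x: np.ndarray) -> float:
    """Monte-Carlo standard error of the sample variance of ``x``."""
    x = np.asarray(x, dtype=float)
    m = x.size
    mu = x.mean()
    s2 = x.var(ddof=1)
    m4 = np.mean((x - mu) ** 4)
    return float(np.sqrt(max(m4 - s2 * s2 * (m - 3) / (m - 1), 0.0) / m))


def one_stage_freqs(p, n_chrom, reps, rng) -> np.ndarray:
    """Frequencies from sampling chromosomes only."""
    return rng.binomial(n_chrom, p, size=reps) / n_chrom


def two_stage_freqs(p, n_chrom, depth, reps, rng) -> np.ndarray:
    """p_hat from chromosome sampling followed by read sampling."""
    f = rng.binomial(n_chrom, p, size=reps) / n_chrom
    return rng.binomial(depth, f) / depth


def gamma_weights(n, k, rng) -> tuple[np.ndarray, float]:
    """A mean-one gamma weight vector and its realized excess variance."""
    if k == 0:
        return np.ones(n), 0.0
    w = rng.gamma(shape=1.0 / k, scale=k, size=n)
    w = w / w.mean()
    return w, float(np.mean(w * w) - 1.0)


def three_stage_freqs(
    p, weights, depth, reps, rng, chunk: int = 20000
) -> np.ndarray:
    """p_hat from genotype sampling, weighted pooling and read sampling."""
    w = np.asarray(weights, dtype=float)
    n = w.size
    out = np.empty(reps)
    done = 0
    while done < reps:
        c = min(chunk, reps - done)
        genotypes = rng.binomial(2, p, size=(c, n))
        f = genotypes @ w / (2.0 * w.sum())
        out[done : done + c] = rng.binomial(depth, f) / depth
        done += c
    return out
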