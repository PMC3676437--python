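"""Generative model of pooled case-control sequencing.

Each simulated study draws, per site, a population allele frequency; per
pool, a set of per-individual contribution weights (drawn once and shared
across sites, as in a physically constructed pool); then, per site and pool,

1. diploid genotype doses ``g_j ~ Binomial(2, p) / 2`` for each individual,
2. the pool allele frequency as the contribution-weighted mean of the doses,
3. observed alt reads ``X ~ Binomial(R, q)`` with
   ``q = f (1 - e) + (1 - f) e`` for a per-read misread probability ``e``.

Contribution weights come from a mean-one Gamma (or lognormal) family with a
target variance ``k`` and are normalised to mean exactly one; the *realized*
variance of the normalised weights is recorded, because it — not the
generative target — is what inflates the pool-frequency variance of the
actual pool that was built.

Sites are simulated independently (no linkage disequilibrium).  All
randomness flows from a single seed through named child streams (one per
pool per sampling stage), so a study is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PoolSpec, SiteCounts
from .io_pools import CountTable

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "ErrorRates",
    "draw_contributions",
    "realized_excess_variance",
    "simulate_pool_site",
    "simulate_study",
    "evaluate_error_rates",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic pooled case-control study.

    Defaults emulate a large targeted-resequencing pool study: a few hundred
    individuals per pool sequenced to depth in the thousands, common variants
    (population frequency uniform on [0.05, 0.5]), equimolar pools unless a
    contribution variance is requested, and error-free reads.
    """

    n_case: int = 320
    n_ctrl: int = 320
    n_sites: int = 1000
    freq_low: float = 0.05
    freq_high: float = 0.5
    n_effect_sites: int = 0
    effect_size: float = 0.0  # case-control difference delta in frequency
    depth_case: float = 6000
    depth_ctrl: float = 6000
    depth_mode: str = "fixed"  # or "poisson" (truncated at >= 1 by redraw)
    contribution_variance: float = 0.0
    contribution_distribution: str = "gamma"  # or "lognormal"
    shared_weights: bool = True
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_ctrl, self.n_sites) < 1:
            raise ValueError("pool sizes and site count must be positive")
        if self.contribution_variance < 0:
            raise ValueError("contribution_variance must be non-negative")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.depth_mode not in ("fixed", "poisson"):
            raise ValueError("depth_mode must be 'fixed' or 'poisson'")
        if self.n_effect_sites > self.n_sites:
            raise ValueError("n_effect_sites cannot exceed n_sites")


@dataclass
class SimulatedStudy:
    """A simulated count table together with its generating truth."""

    count_table: CountTable
    truth: pd.DataFrame
    weights_case: np.ndarray
    weights_ctrl: np.ndarray
    realized_k_case: float
    realized_k_ctrl: float
    config: SimulationConfig

    @property
    def realized_k(self) -> float:
        """Average realized contribution variance of the two pools — the
        recovery target for calibration, since the test sums both pools'
        variances with a single shared k."""
        return 0.5 * (self.realized_k_case + self.realized_k_ctrl)


def realized_excess_variance(weights: np.ndarray) -> float:
    """Variance (1/n convention) of mean-normalised contribution weights.

    For mean-one weights this equals ``mean(w^2) - 1``, which is exactly the
    factor by which the pool-frequency variance of the constructed pool is
    inflated over the equimolar case.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.mean()
    return float(np.mean(w * w) - 1.0)


def draw_contributions(
    n: int,
    k: float,
    distribution: str = "gamma",
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` positive per-individual contribution weights of mean one.

    For ``k > 0`` the gamma family uses shape ``1/k`` and scale ``k`` (mean 1,
    variance ``k``); the lognormal alternative matches the same mean and
    variance.  Weights are normalised to mean exactly one after drawing;
    ``k = 0`` returns exact ones.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return np.ones(n)
    rng = np.random.default_rng(rng)
    if distribution == "gamma":
        w = rng.gamma(shape=1.0 / k, scale=k, size=n)
    elif distribution == "lognormal":
        sigma2 = np.log1p(k)
        w = rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=n)
    else:
        raise ValueError("distribution must be 'gamma' or 'lognormal'")
    return w / w.mean()


def simulate_pool_site(
    p: float,
    weights: np.ndarray,
    depth: int,
    error_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[int, int]:
    """Simulate one pool at one site; returns ``(alt_count, depth)``."""
    rng = np.random.default_rng(rng)
    w = np.asarray(weights, dtype=float)
    n = w.size
    genotypes = rng.binomial(2, p, size=n)
    pool_freq = float(w @ genotypes / (2.0 * w.sum()))
    q = pool_freq * (1.0 - error_rate) + (1.0 - pool_freq) * error_rate
    alt = int(rng.binomial(int(depth), q))
    return alt, int(depth)


def _draw_depths(mode: str, mean: float, n: int, rng: np.random.Generator):
    if mode == "fixed":
        return np.full(n, int(mean), dtype=np.int64)
    depths = rng.poisson(mean, size=n)
    while np.any(depths < 1):  # truncate at >= 1 by redraw
        zero = depths < 1
        depths[zero] = rng.poisson(mean, size=int(zero.sum()))
    return depths


def _pool_counts(
    freqs: np.ndarray,
    n_indiv: int,
    weights: np.ndarray | None,
    depths: np.ndarray,
    error_rate: float,
    rng_geno: np.random.Generator,
    rng_reads: np.random.Generator,
    contribution_variance: float,
    distribution: str,
    shared: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Alt counts and pool frequencies for all sites of one pool."""
    n_sites = freqs.size
    genotypes = rng_geno.binomial(2, freqs[:, None], size=(n_sites, n_indiv))
    if shared:
        w = weights
        pool_freq = genotypes @ w / (2.0 * w.sum())
    else:
        pool_freq = np.empty(n_sites)
        for i in range(n_sites):
            w = draw_contributions(
                n_indiv, contribution_variance, distribution, rng_geno
            )
            pool_freq[i] = genotypes[i] @ w / (2.0 * w.sum())
    q = pool_freq * (1.0 - error_rate) + (1.0 - pool_freq) * error_rate
    alt = rng_reads.binomial(depths, q)
    return alt, pool_freq


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate a full case-control pooled study from a config.

    The first ``n_effect_sites`` sites are effect sites: the case pool's
    population frequency is shifted by ``effect_size`` (clipped to
    [0.005, 0.995]); all other sites are null.  Returns a
    :class:`SimulatedStudy` whose count table feeds directly into the test
    pipeline and whose truth record allows scoring.
    """
    ss = np.random.SeedSequence(config.seed)
    (
        s_freq,
        s_wcase,
        s_wctrl,
        s_dcase,
        s_dctrl,
        s_gcase,
        s_gctrl,
        s_rcase,
        s_rctrl,
    ) = ss.spawn(9)
    rng_freq = np.random.default_rng(s_freq)

    freqs = rng_freq.uniform(config.freq_low, config.freq_high, size=config.n_sites)
    is_effect = np.zeros(config.n_sites, dtype=bool)
    is_effect[: config.n_effect_sites] = True
    p_case = np.where(
        is_effect, np.clip(freqs + config.effect_size, 0.005, 0.995), freqs
    )
    p_ctrl = freqs

    w_case = draw_contributions(
        config.n_case,
        config.contribution_variance,
        config.contribution_distribution,
        np.random.default_rng(s_wcase),
    )
    w_ctrl = draw_contributions(
        config.n_ctrl,
        config.contribution_variance,
        config.contribution_distribution,
        np.random.default_rng(s_wctrl),
    )
    d_case = _draw_depths(
        config.depth_mode, config.depth_case, config.n_sites, np.random.default_rng(s_dcase)
    )
    d_ctrl = _draw_depths(
        config.depth_mode, config.depth_ctrl, config.n_sites, np.random.default_rng(s_dctrl)
    )

    alt_case, f_case = _pool_counts(
        p_case,
        config.n_case,
        w_case,
        d_case,
        config.error_rate,
        np.random.default_rng(s_gcase),
        np.random.default_rng(s_rcase),
        config.contribution_variance,
        config.contribution_distribution,
        config.shared_weights,
    )
    alt_ctrl, f_ctrl = _pool_counts(
        p_ctrl,
        config.n_ctrl,
        w_ctrl,
        d_ctrl,
        config.error_rate,
        np.random.default_rng(s_gctrl),
        np.random.default_rng(s_rctrl),
        config.contribution_variance,
        config.contribution_distribution,
        config.shared_weights,
    )

    width = len(str(config.n_sites))
    sites = [
        SiteCounts(
            site_id=f"site{str(i + 1).zfill(width)}",
            chrom="sim1",
            pos=i + 1,
            ref="A",
            alt="G",
            depth_case=int(d_case[i]),
            alt_case=int(alt_case[i]),
            depth_ctrl=int(d_ctrl[i]),
            alt_ctrl=int(alt_ctrl[i]),
        )
        for i in range(config.n_sites)
    ]
    truth = pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "p_case": p_case,
            "p_ctrl": p_ctrl,
            "pool_freq_case": f_case,
            "pool_freq_ctrl": f_ctrl,
            "is_effect": is_effect,
        }
    )
    table = CountTable(
        sites=sites,
        case_spec=PoolSpec(config.n_case),
        ctrl_spec=PoolSpec(config.n_ctrl),
        source=f"simulate(seed={config.seed})",
        format="simulated",
    )
    return SimulatedStudy(
        count_table=table,
        truth=truth,
        weights_case=w_case,
        weights_ctrl=w_ctrl,
        realized_k_case=realized_excess_variance(w_case),
        realized_k_ctrl=realized_excess_variance(w_ctrl),
        config=config,
    )


@dataclass
class ErrorRates:
    """Rejection fractions among null and effect sites, with exact 95% CIs."""

    type1: float | None
    type1_ci: tuple[float, float] | None
    n_null: int
    power: float | None
    power_ci: tuple[float, float] | None
    n_effect: int
    alpha: float


def _rate_and_ci(n_reject: int, n: int):
    if n == 0:
        return None, None
    ci = stats.binomtest(n_reject, n).proportion_ci(confidence_level=0.95)
    return n_reject / n, (float(ci.low), float(ci.high))


def evaluate_error_rates(
    study: SimulatedStudy, results: pd.DataFrame, alpha: float = 0.05
) -> ErrorRates:
    """Score test results against the simulation truth.

    ``results`` must carry ``site_id`` and ``p_value`` columns (the output
    of the test pipeline); sites absent from it (filtered out or untestable)
    are not counted.
    """
    merged = results.merge(
        study.truth[["site_id", "is_effect"]], on="site_id", how="inner"
    )
    merged = merged[np.isfinite(merged["p_value"])]
    reject = merged["p_value"] <= alpha
    null_mask = ~merged["is_effect"]
    t1, t1_ci = _rate_and_ci(int(reject[null_mask].sum()), int(null_mask.sum()))
    pw, pw_ci = _rate_and_ci(int(reject[~null_mask].sum()), int((~null_mask).sum()))
    return ErrorRates(
        type1=t1,
        type1_ci=t1_ci,
        n_null=int(null_mask.sum()),
        power=pw,
        power_ci=pw_ci,
        n_effect=int((~null_mask).sum()),
        alpha=alpha,
    )
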