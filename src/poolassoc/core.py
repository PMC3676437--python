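"""Allele-frequency estimation and the two-pool chi-square test.

Pooled sequencing observes, at each variant site and for each pool, a read
depth ``R`` and a non-reference read count ``X``.  The frequency estimate is
``p_hat = X / R``.  Its variance depends on three nested sampling stages:

* reads sampled from the DNA molecules in the pool (depends on ``R``),
* chromosomes sampled from the population when the pool was assembled
  (depends on ``N``, the number of chromosomes, i.e. twice the number of
  diploid individuals),
* unequal DNA contributions of the individuals to the pool, summarised by
  ``k``, the variance of the per-individual relative contributions scaled
  to mean one (``k = 0`` for a perfect equimolar pool).

Three estimators of ``Var(p_hat)`` are provided, each nested in the next:

* naive:    ``p(1-p) / N``
* observed: ``p(1-p) * [1/R + 1/N - 1/(N R)]``
* full:     ``p(1-p) * [1/R + (1+k)/N - (1+k)/(N R)]``

The ``1/(N R)`` term is an interaction correcting the non-independence of
read sampling and population sampling; it is small and can be dropped with
``include_interaction=False``.  The case-control test statistic for a site is

    T = (p_hat_case - p_hat_ctrl)^2 / (Var_case + Var_ctrl)

which is compared against a chi-square distribution with one degree of
freedom.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class VarianceModel(str, enum.Enum):
    """Which variance estimator to plug into the test statistic."""

    NAIVE = "naive"
    OBSERVED = "observed"
    FULL = "full"


#: valid policies for the frequency at which the variance is evaluated
P_FOR_VARIANCE = ("combined", "per-pool")


@dataclass(frozen=True)
class PoolSpec:
    """Metadata for one DNA pool.

    Parameters
    ----------
    n_individuals
        Number of (diploid) individuals pooled.
    n_chromosomes
        Number of chromosomes in the pool; defaults to ``2 * n_individuals``.
    k_excess
        Variance of the per-individual relative DNA contributions, scaled to
        mean 1.  ``0`` means an equimolar pool; ``None`` means unknown (to be
        calibrated).
    """

    n_individuals: int
    n_chromosomes: int | None = None
    k_excess: float | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be a positive integer")
        if self.n_chromosomes is None:
            object.__setattr__(self, "n_chromosomes", 2 * self.n_individuals)
        elif self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be a positive integer")
        if self.k_excess is not None and self.k_excess < 0:
            raise ValueError("k_excess must be non-negative")

    def with_k(self, k: float) -> "PoolSpec":
        return PoolSpec(self.n_individuals, self.n_chromosomes, k)


@dataclass(frozen=True)
class SiteCounts:
    """Observed read counts at one site in the case and control pools."""

    site_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth_case: int
    alt_case: int
    depth_ctrl: int
    alt_ctrl: int

    def __post_init__(self) -> None:
        for depth, count, pool in (
            (self.depth_case, self.alt_case, "case"),
            (self.depth_ctrl, self.alt_ctrl, "ctrl"),
        ):
            if depth < 0 or count < 0:
                raise ValueError(f"negative count at {self.site_id} ({pool})")
            if count > depth:
                raise ValueError(
                    f"alt count {count} exceeds depth {depth} at "
                    f"{self.site_id} ({pool})"
                )

    @property
    def testable(self) -> bool:
        """A site is testable when both pools have at least one read."""
        return self.depth_case >= 1 and self.depth_ctrl >= 1


@dataclass
class TestResult:
    """Per-site outcome of the two-pool chi-square test."""

    site_id: str
    p_hat_case: float
    p_hat_ctrl: float
    var_case: float
    var_ctrl: float
    statistic: float
    p_value: float
    components: dict[str, dict[str, float]] = field(default_factory=dict)
    rank: int | None = None
    testable: bool = True


def estimate_freq(alt_count, depth):
    """Allele-frequency estimate ``X / R`` for one pool.

    Accepts scalars or arrays; entries with zero depth yield ``nan`` (the
    site is untestable, not an error, in batch use).
    """
    alt = np.asarray(alt_count, dtype=float)
    dep = np.asarray(depth, dtype=float)
    if np.any(alt < 0) or np.any((dep > 0) & (alt > dep)):
        raise ValueError("require 0 <= alt_count <= depth")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(dep >= 1, alt / np.where(dep >= 1, dep, 1.0), np.nan)
    if np.ndim(alt_count) == 0 and np.ndim(depth) == 0:
        return float(out)
    return out


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequency must lie in [0, 1]")
    return p


def variance_naive(p, n_chromosomes):
    """Binomial variance ``p(1-p)/N``, as if individuals were sequenced."""
    p = _check_p(p)
    n = np.asarray(n_chromosomes, dtype=float)
    if np.any(n < 1):
        raise ValueError("n_chromosomes must be >= 1")
    out = p * (1.0 - p) / n
    return float(out) if out.ndim == 0 else out


def variance_observed(p, n_chromosomes, depth, include_interaction: bool = True):
    """Variance correcting for pool size and read depth.

    ``p(1-p) * [1/R + 1/N - 1/(N R)]``; without the interaction term the
    ``1/(N R)`` part is dropped.
    """
    return variance_full(p, n_chromosomes, depth, 0.0, include_interaction)


def variance_full(p, n_chromosomes, depth, k_excess, include_interaction: bool = True):
    """Variance additionally inflating the population-sampling component.

    ``p(1-p) * [1/R + (1+k)/N - (1+k)/(N R)]`` — the factor ``1+k`` multiplies
    both the population term and its interaction with read sampling, so the
    inflation over the observed-variance model is constant in ``p``.
    """
    p = _check_p(p)
    n = np.asarray(n_chromosomes, dtype=float)
    r = np.asarray(depth, dtype=float)
    k = np.asarray(k_excess, dtype=float)
    if np.any(n < 1):
        raise ValueError("n_chromosomes must be >= 1")
    if np.any(r < 1):
        raise ValueError("depth must be >= 1")
    if np.any(k < 0):
        raise ValueError("k_excess must be non-negative")
    bracket = 1.0 / r + (1.0 + k) / n
    if include_interaction:
        bracket = bracket - (1.0 + k) / (n * r)
    out = p * (1.0 - p) * bracket
    return float(out) if out.ndim == 0 else out


def variance_shares(
    n_chromosomes, depth, k_excess: float = 0.0, include_interaction: bool = True
) -> dict[str, float]:
    """Fractional contribution of each term to the full-variance bracket.

    Returns the shares of read sampling (``1/R``), ideal population sampling
    (``1/N``), pool-construction excess (``k/N``) and the interaction term
    (``-(1+k)/(N R)``, negative).  Shares sum to one and are independent of
    the allele frequency.
    """
    n = float(n_chromosomes)
    r = float(depth)
    k = float(k_excess)
    seq = 1.0 / r
    pop = 1.0 / n
    pool = k / n
    inter = -(1.0 + k) / (n * r) if include_interaction else 0.0
    total = seq + pop + pool + inter
    return {
        "sequencing": seq / total,
        "population": pop / total,
        "pooling": pool / total,
        "interaction": inter / total,
    }


def _variance_for_model(
    p, model: VarianceModel, n_chromosomes, depth, k, include_interaction
):
    model = VarianceModel(model)
    if model is VarianceModel.NAIVE:
        return variance_naive(p, n_chromosomes)
    if model is VarianceModel.OBSERVED:
        return variance_observed(p, n_chromosomes, depth, include_interaction)
    if k is None:
        raise ValueError("FULL variance model requires a k_excess value")
    return variance_full(p, n_chromosomes, depth, k, include_interaction)


def chisq_statistics(
    alt_case,
    depth_case,
    alt_ctrl,
    depth_ctrl,
    case_spec: PoolSpec,
    ctrl_spec: PoolSpec,
    model: VarianceModel = VarianceModel.FULL,
    k: float | None = None,
    include_interaction: bool = True,
    p_for_variance: str = "combined",
):
    """Vectorised test statistics for arrays of per-site counts.

    Returns ``(statistic, p_hat_case, p_hat_ctrl, var_case, var_ctrl)`` as
    arrays.  Untestable sites (zero depth in either pool) and degenerate
    sites (zero total variance, i.e. both pools monomorphic for the same
    allele) yield ``nan`` statistics.

    The variance is evaluated at the frequency chosen by ``p_for_variance``:
    ``"combined"`` (default) uses the depth-weighted frequency of the two
    pools together, as in the classic two-proportion test under the null;
    ``"per-pool"`` evaluates each pool's variance at its own estimate.
    """
    if p_for_variance not in P_FOR_VARIANCE:
        raise ValueError(f"p_for_variance must be one of {P_FOR_VARIANCE}")
    if k is None:
        k = case_spec.k_excess if case_spec.k_excess is not None else ctrl_spec.k_excess

    xc = np.asarray(alt_case, dtype=float)
    rc = np.asarray(depth_case, dtype=float)
    xt = np.asarray(alt_ctrl, dtype=float)
    rt = np.asarray(depth_ctrl, dtype=float)

    testable = (rc >= 1) & (rt >= 1)
    rc_safe = np.where(testable, rc, 1.0)
    rt_safe = np.where(testable, rt, 1.0)
    p_case = np.where(testable, xc / rc_safe, np.nan)
    p_ctrl = np.where(testable, xt / rt_safe, np.nan)

    if p_for_variance == "combined":
        p_var_case = p_var_ctrl = np.where(
            testable, (xc + xt) / (rc_safe + rt_safe), np.nan
        )
    else:
        p_var_case, p_var_ctrl = p_case, p_ctrl

    with np.errstate(invalid="ignore", divide="ignore"):
        var_case = _variance_for_model(
            np.nan_to_num(p_var_case),
            model,
            case_spec.n_chromosomes,
            rc_safe,
            k,
            include_interaction,
        )
        var_ctrl = _variance_for_model(
            np.nan_to_num(p_var_ctrl),
            model,
            ctrl_spec.n_chromosomes,
            rt_safe,
            k,
            include_interaction,
        )
        var_case = np.where(testable, var_case, np.nan)
        var_ctrl = np.where(testable, var_ctrl, np.nan)
        total_var = var_case + var_ctrl
        ok = testable & (total_var > 0)
        stat = np.where(
            ok, (p_case - p_ctrl) ** 2 / np.where(ok, total_var, 1.0), np.nan
        )
    return stat, p_case, p_ctrl, var_case, var_ctrl


def site_test(
    site: SiteCounts,
    case_spec: PoolSpec,
    ctrl_spec: PoolSpec,
    model: VarianceModel = VarianceModel.FULL,
    k: float | None = None,
    include_interaction: bool = True,
    p_for_variance: str = "combined",
) -> TestResult:
    """Run the two-pool test on a single site."""
    stat, pc, pt, vc, vt = chisq_statistics(
        site.alt_case,
        site.depth_case,
        site.alt_ctrl,
        site.depth_ctrl,
        case_spec,
        ctrl_spec,
        model=model,
        k=k,
        include_interaction=include_interaction,
        p_for_variance=p_for_variance,
    )
    stat = float(stat)
    testable = bool(np.isfinite(stat))
    pval = float(stats.chi2.sf(stat, df=1)) if testable else float("nan")
    model = VarianceModel(model)
    k_eff = 0.0
    if model is VarianceModel.FULL:
        k_eff = k if k is not None else (case_spec.k_excess or 0.0)
    components = {
        "case": variance_shares(
            case_spec.n_chromosomes, max(site.depth_case, 1), k_eff, include_interaction
        ),
        "ctrl": variance_shares(
            ctrl_spec.n_chromosomes, max(site.depth_ctrl, 1), k_eff, include_interaction
        ),
    }
    return TestResult(
        site_id=site.site_id,
        p_hat_case=float(pc),
        p_hat_ctrl=float(pt),
        var_case=float(vc),
        var_ctrl=float(vt),
        statistic=stat,
        p_value=pval,
        components=components,
        testable=testable,
    )


def rank_sites(p_values, p_case, p_ctrl) -> np.ndarray:
    """Prioritisation rank: ascending p-value, ties broken by descending
    absolute frequency difference, then input order.  Untestable sites
    (``nan`` p-value) receive rank 0 (meaning unranked)."""
    p = np.asarray(p_values, dtype=float)
    diff = np.abs(np.asarray(p_case, dtype=float) - np.asarray(p_ctrl, dtype=float))
    ok = np.isfinite(p)
    idx = np.arange(p.size)
    # lexsort: last key is primary
    order = np.lexsort((idx[ok], -diff[ok], p[ok]))
    ranks = np.zeros(p.size, dtype=int)
    ranks[idx[ok][order]] = np.arange(1, ok.sum() + 1)
    return ranks


def run_site_tests(
    sites,
    case_spec: PoolSpec,
    ctrl_spec: PoolSpec,
    model: VarianceModel = VarianceModel.FULL,
    k: float | None = None,
    include_interaction: bool = True,
    p_for_variance: str = "combined",
) -> pd.DataFrame:
    """Run the test over a collection of :class:`SiteCounts`.

    Returns a DataFrame with one row per input site, carrying frequencies,
    variances, the chi-square statistic, p-value and prioritisation rank.
    """
    sites = list(sites)
    cols = {
        "site_id": [s.site_id for s in sites],
        "chrom": [s.chrom for s in sites],
        "pos": [s.pos for s in sites],
        "ref": [s.ref for s in sites],
        "alt": [s.alt for s in sites],
        "depth_case": [s.depth_case for s in sites],
        "alt_case": [s.alt_case for s in sites],
        "depth_ctrl": [s.depth_ctrl for s in sites],
        "alt_ctrl": [s.alt_ctrl for s in sites],
    }
    df = pd.DataFrame(cols)
    stat, pc, pt, vc, vt = chisq_statistics(
        df["alt_case"].to_numpy(),
        df["depth_case"].to_numpy(),
        df["alt_ctrl"].to_numpy(),
        df["depth_ctrl"].to_numpy(),
        case_spec,
        ctrl_spec,
        model=model,
        k=k,
        include_interaction=include_interaction,
        p_for_variance=p_for_variance,
    )
    df["p_hat_case"] = pc
    df["p_hat_ctrl"] = pt
    df["var_case"] = vc
    df["var_ctrl"] = vt
    df["statistic"] = stat
    with np.errstate(invalid="ignore"):
        df["p_value"] = np.where(
            np.isfinite(stat), stats.chi2.sf(np.nan_to_num(stat), df=1), np.nan
        )
    df["testable"] = np.isfinite(stat)
    df["rank"] = rank_sites(df["p_value"], pc, pt)
    return df
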