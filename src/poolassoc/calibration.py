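"""Iterative genomic-control-style calibration of the contribution variance.

The per-individual DNA contributions to a pool are never observed, so the
excess-variance parameter ``k`` of the full variance model cannot be computed
directly.  Following the genomic-control idea, ``k`` is instead chosen so that
the median test statistic over a (null-dominated, MAF-filtered) set of sites
equals the median of the chi-square distribution with one degree of freedom.

Unlike classical genomic control, which rescales all statistics by a single
factor, every candidate ``k`` requires re-computing each site's statistic,
because the variance contains a site-specific read-depth term that does not
rescale uniformly.  The median statistic is strictly decreasing in ``k``
(the variance bracket is strictly increasing), so the root is found by
bisection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import PoolSpec, chisq_statistics

__all__ = [
    "CalibrationError",
    "CalibrationResult",
    "BloodPoolingParams",
    "chi2_median",
    "genomic_lambda",
    "estimate_k",
    "blood_adjust",
    "decompose_variance",
]


def chi2_median() -> float:
    """Median of the chi-square distribution with 1 df (~0.454936)."""
    return float(stats.chi2.ppf(0.5, df=1))


def genomic_lambda(statistics) -> float:
    """Genomic inflation factor: median statistic over the null chi2(1) median.

    Values above 1 indicate systematic overdispersion of the test statistics
    relative to the null distribution.
    """
    arr = np.asarray(statistics, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("genomic_lambda requires a non-empty collection of statistics")
    if np.any(arr < 0):
        raise ValueError("test statistics must be non-negative")
    return float(np.median(arr) / chi2_median())


@dataclass(frozen=True)
class BloodPoolingParams:
    """Extra contribution variance incurred by pooling equal blood volumes.

    ``sigma_b2`` is the variance of per-individual DNA contributions caused by
    sampling from blood, with contributions scaled to mean 1; a typical value
    is around 0.25.
    """

    sigma_b2: float = 0.25

    def __post_init__(self) -> None:
        if self.sigma_b2 < 0:
            raise ValueError("sigma_b2 must be non-negative")


@dataclass
class CalibrationResult:
    """Outcome of the iterative estimation of ``k``."""

    k_hat: float
    lambda_before: float
    lambda_after: float
    n_sites_used: int
    iterations: int
    converged: bool
    boundary_hit: bool
    trace: list[tuple[float, float]] = field(default_factory=list, repr=False)


class CalibrationError(RuntimeError):
    """Raised when the calibration target cannot be bracketed.

    Carries the partial :class:`CalibrationResult` as ``.result``.
    """

    def __init__(self, message: str, result: CalibrationResult):
        super().__init__(message)
        self.result = result


def _count_arrays(sites):
    """Extract (alt_case, depth_case, alt_ctrl, depth_ctrl) arrays from a
    list of SiteCounts, a CountTable, or a DataFrame with the count columns."""
    if hasattr(sites, "sites"):  # CountTable
        sites = sites.sites
    if hasattr(sites, "columns"):  # DataFrame
        return (
            sites["alt_case"].to_numpy(float),
            sites["depth_case"].to_numpy(float),
            sites["alt_ctrl"].to_numpy(float),
            sites["depth_ctrl"].to_numpy(float),
        )
    sites = list(sites)
    return (
        np.array([s.alt_case for s in sites], float),
        np.array([s.depth_case for s in sites], float),
        np.array([s.alt_ctrl for s in sites], float),
        np.array([s.depth_ctrl for s in sites], float),
    )


def estimate_k(
    sites,
    case_spec: PoolSpec,
    ctrl_spec: PoolSpec,
    k_max: float = 100.0,
    tol_k: float = 1e-8,
    tol_median: float = 1e-10,
    max_iter: int = 200,
    min_sites: int = 50,
    include_interaction: bool = True,
    p_for_variance: str = "combined",
) -> CalibrationResult:
    """Estimate the contribution-variance parameter by median matching.

    Bisects ``k`` on ``[0, k_max]`` until the median full-model statistic
    equals the chi2(1) median.  Sites should already be MAF-filtered; fewer
    than ``min_sites`` sites triggers a low-confidence warning.  If the
    median at ``k = 0`` is already below the target the data are deflated:
    ``k_hat`` is clamped at 0 with ``boundary_hit=True``.  If even ``k_max``
    cannot bring the median down to the target a :class:`CalibrationError`
    is raised.
    """
    xc, rc, xt, rt = _count_arrays(sites)
    n_sites = int(xc.size)
    if n_sites == 0:
        raise ValueError("estimate_k requires at least one site")
    if n_sites < min_sites:
        warnings.warn(
            f"calibrating on only {n_sites} sites (< {min_sites}); "
            "the estimate of k is low-confidence",
            UserWarning,
            stacklevel=2,
        )

    target = chi2_median()

    def median_stat(k: float) -> float:
        stat, *_ = chisq_statistics(
            xc,
            rc,
            xt,
            rt,
            case_spec,
            ctrl_spec,
            model="full",
            k=k,
            include_interaction=include_interaction,
            p_for_variance=p_for_variance,
        )
        return float(np.nanmedian(stat))

    trace: list[tuple[float, float]] = []
    med0 = median_stat(0.0)
    trace.append((0.0, med0))
    lambda_before = med0 / target

    if med0 <= target * (1.0 + tol_median):
        if med0 < target * (1.0 - tol_median):
            warnings.warn(
                "median statistic at k=0 is already below the chi2(1) median; "
                "the data appear deflated, k clamped at 0",
                UserWarning,
                stacklevel=2,
            )
        return CalibrationResult(
            k_hat=0.0,
            lambda_before=lambda_before,
            lambda_after=med0 / target,
            n_sites_used=n_sites,
            iterations=1,
            converged=True,
            boundary_hit=True,
            trace=trace,
        )

    med_hi = median_stat(k_max)
    trace.append((k_max, med_hi))
    if med_hi > target:
        result = CalibrationResult(
            k_hat=k_max,
            lambda_before=lambda_before,
            lambda_after=med_hi / target,
            n_sites_used=n_sites,
            iterations=2,
            converged=False,
            boundary_hit=True,
            trace=trace,
        )
        raise CalibrationError(
            f"median statistic at k_max={k_max} is still above the chi2(1) "
            "median; raise k_max or inspect the data",
            result,
        )

    lo, hi = 0.0, k_max
    iterations = 2
    k_mid, med_mid = k_max, med_hi
    while hi - lo > tol_k and iterations < max_iter:
        k_mid = 0.5 * (lo + hi)
        med_mid = median_stat(k_mid)
        iterations += 1
        trace.append((k_mid, med_mid))
        if abs(med_mid - target) <= tol_median * target:
            break
        if med_mid > target:  # statistic too large -> need more variance
            lo = k_mid
        else:
            hi = k_mid

    converged = (hi - lo) <= tol_k or abs(med_mid - target) <= tol_median * target
    return CalibrationResult(
        k_hat=k_mid,
        lambda_before=lambda_before,
        lambda_after=med_mid / target,
        n_sites_used=n_sites,
        iterations=iterations,
        converged=converged,
        boundary_hit=False,
        trace=trace,
    )


def blood_adjust(
    k: float, blood: BloodPoolingParams | float, mode: str = "multiplicative"
) -> float:
    """Compose pipetting and blood-sampling contribution variances.

    The two sources act on independent multiplicative components of the
    per-individual contribution (volume pipetted x DNA concentration in the
    volume), so by default the inflation factors multiply:
    ``1 + k' = (1 + k)(1 + sigma_b2)``.  ``mode="additive"`` instead returns
    ``k + sigma_b2``.
    """
    if isinstance(blood, (int, float)):
        blood = BloodPoolingParams(float(blood))
    if k < 0:
        raise ValueError("k must be non-negative")
    if blood.sigma_b2 == 0:  # exact identity, no float round-off
        return k
    if mode == "multiplicative":
        return (1.0 + k) * (1.0 + blood.sigma_b2) - 1.0
    if mode == "additive":
        return k + blood.sigma_b2
    raise ValueError("mode must be 'multiplicative' or 'additive'")


@dataclass(frozen=True)
class VarianceDecomposition:
    """Fractions of the full variance attributable to each sampling stage."""

    read_sampling: float
    population: float
    pool_construction: float

    def as_dict(self) -> dict[str, float]:
        return {
            "read_sampling": self.read_sampling,
            "population": self.population,
            "pool_construction": self.pool_construction,
        }


def decompose_variance(
    p: float, n_chromosomes: int, depth: float, k_excess: float
) -> VarianceDecomposition:
    """Partition the full variance into three non-negative shares.

    The bracket ``1/R + (1+k)/N - (1+k)/(N R)`` splits into read sampling
    ``(1/R)(1 - (1+k)/N)``, ideal population sampling ``1/N`` and the
    pool-construction excess ``k/N`` (each divided by the bracket).  The
    shares sum to one and do not depend on the allele frequency, which must
    nevertheless be non-degenerate for the variance itself to be non-zero.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly between 0 and 1")
    if k_excess < 0:
        raise ValueError("k_excess must be non-negative")
    n = float(n_chromosomes)
    r = float(depth)
    bracket = 1.0 / r + (1.0 + k_excess) / n - (1.0 + k_excess) / (n * r)
    read = (1.0 / r) * (1.0 - (1.0 + k_excess) / n)
    pop = 1.0 / n
    pool = k_excess / n
    return VarianceDecomposition(read / bracket, pop / bracket, pool / bracket)
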