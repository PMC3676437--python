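"""Site-eligibility rules applied before testing and calibration.

The chi-square test relies on a normal approximation that breaks down for
rare alleles, so sites are screened by minor allele frequency: a site passes
when its estimated minor allele frequency exceeds the threshold (default 1%)
in both pools.  A classical rule-of-thumb check (sample size times the minor
frequency greater than five) is available as an advisory diagnostic; the MAF
filter is the operative rule in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import PoolSpec, SiteCounts

__all__ = ["FilterReport", "maf_filter", "large_sample_check"]


@dataclass
class FilterReport:
    """Bookkeeping for a filtering pass; the counts partition the input."""

    n_input: int = 0
    n_passed: int = 0
    n_failed_maf: int = 0
    n_failed_large_sample: int = 0
    n_untestable: int = 0

    def __post_init__(self) -> None:
        total = (
            self.n_passed
            + self.n_failed_maf
            + self.n_failed_large_sample
            + self.n_untestable
        )
        if total != self.n_input:
            raise ValueError("filter counts must partition the input")

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _minor_freq(alt: int, depth: int) -> float:
    p = alt / depth
    return min(p, 1.0 - p)


def maf_filter(
    sites,
    threshold: float = 0.01,
    require_both_pools: bool = True,
) -> tuple[list[SiteCounts], FilterReport]:
    """Keep sites whose minor allele frequency strictly exceeds ``threshold``.

    With ``require_both_pools`` (default, matching common practice) the
    condition must hold in both the case and the control pool; otherwise one
    pool suffices.  Sites with zero depth in either pool are untestable and
    counted separately.  Monomorphic sites have minor frequency 0 and are
    removed by any non-negative threshold under the strict comparison.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    sites = list(sites)
    passed: list[SiteCounts] = []
    n_untestable = 0
    n_failed = 0
    for s in sites:
        if not s.testable:
            n_untestable += 1
            continue
        maf_case = _minor_freq(s.alt_case, s.depth_case)
        maf_ctrl = _minor_freq(s.alt_ctrl, s.depth_ctrl)
        if require_both_pools:
            ok = maf_case > threshold and maf_ctrl > threshold
        else:
            ok = maf_case > threshold or maf_ctrl > threshold
        if ok:
            passed.append(s)
        else:
            n_failed += 1
    report = FilterReport(
        n_input=len(sites),
        n_passed=len(passed),
        n_failed_maf=n_failed,
        n_untestable=n_untestable,
    )
    return passed, report


def large_sample_check(
    site: SiteCounts,
    case_spec: PoolSpec,
    ctrl_spec: PoolSpec,
    multiplier_floor: float = 5.0,
) -> tuple[bool, bool]:
    """Advisory large-sample rule of thumb, per pool.

    A pool passes when ``min(R, N) * min(p_hat, 1 - p_hat)`` is strictly
    greater than ``multiplier_floor``.  The binding sample size is the
    smaller of the read depth and the chromosome count, since the tighter of
    the two sampling stages limits the normal approximation.  Failing pools
    are flagged, not excluded; the MAF filter is the operative rule.
    """
    if not site.testable:
        return False, False
    out = []
    for depth, alt, spec in (
        (site.depth_case, site.alt_case, case_spec),
        (site.depth_ctrl, site.alt_ctrl, ctrl_spec),
    ):
        maf = _minor_freq(alt, depth)
        out.append(min(depth, spec.n_chromosomes) * maf > multiplier_floor)
    return tuple(out)


def large_sample_flags(
    sites, case_spec: PoolSpec, ctrl_spec: PoolSpec, multiplier_floor: float = 5.0
) -> np.ndarray:
    """Vector of advisory flags: True where *both* pools pass the rule."""
    return np.array(
        [
            all(large_sample_check(s, case_spec, ctrl_spec, multiplier_floor))
            for s in sites
        ],
        dtype=bool,
    )
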