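"""Readers and writers for pooled count tables, pooled VCFs and results.

Two input formats are supported:

* a tab-separated count table with columns ``chrom, pos, ref, alt,
  case_depth, case_alt, ctrl_depth, ctrl_alt`` (an optional ``site_id``
  column is honoured, otherwise identifiers are built as
  ``chrom:pos:ref:alt``);
* a VCF with two pooled "samples" carrying per-allele depths (``AD``) and
  total depth (``DP``) — the typical output of calling variants on pooled
  alignments.

Outputs are a ranked results TSV (with a commented header recording the
calibration, filter report and seed) and a companion QQ table of expected
versus observed -log10 p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PoolSpec, SiteCounts
from .filters import FilterReport

__all__ = [
    "CountTable",
    "read_count_table",
    "read_vcf_pools",
    "write_results",
    "read_results",
    "qq_table",
]

COUNT_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "case_depth",
    "case_alt",
    "ctrl_depth",
    "ctrl_alt",
)


@dataclass
class CountTable:
    """An ordered collection of per-site counts plus pool metadata."""

    sites: list[SiteCounts]
    case_spec: PoolSpec | None = None
    ctrl_spec: PoolSpec | None = None
    source: str | None = None
    format: str | None = None
    filter_report: FilterReport | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            dupes = pd.Series(ids).value_counts()
            dupes = dupes[dupes > 1].index.tolist()[:5]
            raise ValueError(f"duplicate site identifiers: {dupes}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": [s.site_id for s in self.sites],
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "alt": [s.alt for s in self.sites],
                "depth_case": [s.depth_case for s in self.sites],
                "alt_case": [s.alt_case for s in self.sites],
                "depth_ctrl": [s.depth_ctrl for s in self.sites],
                "alt_ctrl": [s.alt_ctrl for s in self.sites],
            }
        )


def _make_site_id(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def read_count_table(
    path,
    n_case: int | None = None,
    n_ctrl: int | None = None,
    k_excess: float | None = None,
) -> CountTable:
    """Read the TSV count-table dialect.

    Pool sizes are not part of the file format and must be supplied (here or
    later) before testing.  Malformed rows are reported with their line
    numbers; any row with an alt count exceeding its depth is a hard error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} is missing columns: {missing}")
    if df.empty:
        warnings.warn(f"count table {path} contains no sites", UserWarning, stacklevel=2)

    errors: list[str] = []
    # +2: one for the header line, one for 1-based numbering
    for col_r, col_x, pool in (
        ("case_depth", "case_alt", "case"),
        ("ctrl_depth", "ctrl_alt", "ctrl"),
    ):
        bad = df.index[df[col_x] > df[col_r]]
        errors.extend(
            f"line {i + 2}: {pool} alt count {df.at[i, col_x]} exceeds depth "
            f"{df.at[i, col_r]}"
            for i in bad
        )
        neg = df.index[(df[col_x] < 0) | (df[col_r] < 0)]
        errors.extend(f"line {i + 2}: negative {pool} count" for i in neg)
    if errors:
        raise ValueError(
            f"count table {path} has {len(errors)} malformed row(s):\n"
            + "\n".join(errors)
        )

    if "site_id" in df.columns:
        ids = df["site_id"].astype(str).tolist()
    else:
        ids = [
            _make_site_id(c, p, r, a)
            for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
        ]
    sites = [
        SiteCounts(
            site_id=ids[i],
            chrom=str(df.at[i, "chrom"]),
            pos=int(df.at[i, "pos"]),
            ref=str(df.at[i, "ref"]),
            alt=str(df.at[i, "alt"]),
            depth_case=int(df.at[i, "case_depth"]),
            alt_case=int(df.at[i, "case_alt"]),
            depth_ctrl=int(df.at[i, "ctrl_depth"]),
            alt_ctrl=int(df.at[i, "ctrl_alt"]),
        )
        for i in df.index
    ]
    return CountTable(
        sites=sites,
        case_spec=PoolSpec(n_case, k_excess=k_excess) if n_case else None,
        ctrl_spec=PoolSpec(n_ctrl, k_excess=k_excess) if n_ctrl else None,
        source=str(path),
        format="tsv",
    )


def read_vcf_pools(
    path,
    case_sample: str,
    ctrl_sample: str,
    n_case: int | None = None,
    n_ctrl: int | None = None,
) -> CountTable:
    """Read a two-sample pooled VCF into a :class:`CountTable`.

    Depth is taken from ``DP`` (falling back to the sum of ``AD``); the alt
    count from the alternate entry of ``AD``.  Multi-allelic records and
    records with missing ``AD`` are skipped and counted in the table's
    metadata.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    for name in (case_sample, ctrl_sample):
        if name not in samples:
            raise ValueError(f"sample {name!r} not found in {path} (has {samples})")
    i_case = samples.index(case_sample)
    i_ctrl = samples.index(ctrl_sample)

    sites: list[SiteCounts] = []
    n_multiallelic = 0
    n_missing = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        ad = v.format("AD")
        if ad is None:
            n_missing += 1
            continue
        ad = np.asarray(ad)
        if ad.shape[1] < 2 or np.any(ad[[i_case, i_ctrl]] < 0):
            n_missing += 1
            continue
        dp = v.format("DP")
        if dp is not None:
            dp = np.asarray(dp).reshape(len(samples), -1)[:, 0]
            depth_case = int(dp[i_case])
            depth_ctrl = int(dp[i_ctrl])
        else:
            depth_case = int(ad[i_case].sum())
            depth_ctrl = int(ad[i_ctrl].sum())
        sites.append(
            SiteCounts(
                site_id=v.ID or _make_site_id(v.CHROM, v.POS, v.REF, v.ALT[0]),
                chrom=v.CHROM,
                pos=int(v.POS),
                ref=v.REF,
                alt=v.ALT[0],
                depth_case=depth_case,
                alt_case=int(ad[i_case, 1]),
                depth_ctrl=depth_ctrl,
                alt_ctrl=int(ad[i_ctrl, 1]),
            )
        )
    if n_multiallelic or n_missing:
        warnings.warn(
            f"skipped {n_multiallelic} multi-allelic and {n_missing} "
            f"missing-AD record(s) in {path}",
            UserWarning,
            stacklevel=2,
        )
    return CountTable(
        sites=sites,
        case_spec=PoolSpec(n_case) if n_case else None,
        ctrl_spec=PoolSpec(n_ctrl) if n_ctrl else None,
        source=path,
        format="vcf",
        metadata={"n_multiallelic": n_multiallelic, "n_missing_ad": n_missing},
    )


def qq_table(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p-values, sorted for QQ plotting.

    Expected quantiles use the ``(i - 0.5) / m`` convention over the ``m``
    finite p-values.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    m = p.size
    obs = -np.log10(np.sort(p)[::-1])  # ascending -log10
    exp = -np.log10((np.arange(m, 0, -1) - 0.5) / m)
    return pd.DataFrame({"expected_neglog10_p": exp, "observed_neglog10_p": obs})


def write_results(
    results: pd.DataFrame,
    path,
    calibration=None,
    filter_report: FilterReport | None = None,
    seed: int | None = None,
    qq_path=None,
) -> None:
    """Write the ranked results TSV (and optionally the companion QQ TSV).

    The header comment lines record the calibrated k, the inflation factors
    before and after calibration, the filter report and the seed, so a run
    is reproducible from its outputs.  Statistics are written with 12
    significant digits; p-values in scientific notation with 6.
    """
    from . import __version__

    path = Path(path)
    lines = [f"# poolassoc {__version__}"]
    if calibration is not None:
        lines.append(
            f"# k_hat={calibration.k_hat:.10g}"
            f" lambda_before={calibration.lambda_before:.10g}"
            f" lambda_after={calibration.lambda_after:.10g}"
            f" n_sites_used={calibration.n_sites_used}"
            f" converged={calibration.converged}"
            f" boundary_hit={calibration.boundary_hit}"
        )
    if filter_report is not None:
        lines.append(
            "# filter: "
            + " ".join(f"{k}={v}" for k, v in filter_report.as_dict().items())
        )
    if seed is not None:
        lines.append(f"# seed={seed}")

    out = results.copy()
    float_cols = [c for c in out.columns if out[c].dtype.kind == "f"]
    for c in float_cols:
        if c == "p_value":
            out[c] = out[c].map(lambda v: f"{v:.6e}" if np.isfinite(v) else "NA")
        else:
            out[c] = out[c].map(lambda v: f"{v:.12g}" if np.isfinite(v) else "NA")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        out.to_csv(fh, sep="\t", index=False)

    if qq_path is not None and "p_value" in results.columns:
        qq = qq_table(results["p_value"])
        qq.to_csv(qq_path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Re-read a results TSV; returns the table and the parsed header fields."""
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split():
                if "=" in token:
                    key, val = token.split("=", 1)
                    header[key] = val
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    return df, header
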