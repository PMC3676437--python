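"""Model/results interface for the pooled case-control association test.

:class:`PooledAssociation` wraps a count table with the analysis options
(variance model, MAF threshold, interaction term, variance-frequency
policy); its :meth:`~PooledAssociation.fit` runs the filter, optionally
calibrates the contribution-variance parameter ``k``, tests every retained
site and returns a :class:`PooledAssociationResults` carrying the per-site
table, the calibration, the inflation diagnostics and a ``summary()``.

Typical use::

    model = PooledAssociation.from_tsv("counts.tsv", n_case=369, n_ctrl=357)
    res = model.fit(k="calibrate")
    print(res.summary())
    res.save("run1")
"""

from __future__ import annotations

import pandas as pd

from . import calibration as _calib
from . import core, filters, io_pools

__all__ = ["PooledAssociation", "PooledAssociationResults"]


class PooledAssociation:
    """Two-pool allele-frequency association model over a count table.

    Parameters
    ----------
    count_table
        A :class:`~poolassoc.io_pools.CountTable` with both pool specs set.
    variance_model
        ``"naive"``, ``"observed"`` or ``"full"`` (default).
    maf_threshold
        Minor-allele-frequency filter applied (in both pools) before
        calibration and testing; default 0.01.
    include_interaction
        Keep the ``1/(N R)`` interaction term in the variance (default).
    p_for_variance
        Frequency at which the variance is evaluated: ``"combined"``
        (default) or ``"per-pool"``.
    """

    def __init__(
        self,
        count_table: io_pools.CountTable,
        variance_model: str | core.VarianceModel = core.VarianceModel.FULL,
        maf_threshold: float = 0.01,
        include_interaction: bool = True,
        p_for_variance: str = "combined",
    ):
        if count_table.case_spec is None or count_table.ctrl_spec is None:
            raise ValueError("count table must carry both pool specs before testing")
        self.count_table = count_table
        self.variance_model = core.VarianceModel(variance_model)
        self.maf_threshold = maf_threshold
        self.include_interaction = include_interaction
        self.p_for_variance = p_for_variance

    # ---------------------------------------------------------------- constructors
    @classmethod
    def from_tsv(cls, path, n_case: int, n_ctrl: int, **kwargs) -> "PooledAssociation":
        """Build from the TSV count-table dialect."""
        table = io_pools.read_count_table(path, n_case=n_case, n_ctrl=n_ctrl)
        return cls(table, **kwargs)

    @classmethod
    def from_vcf(
        cls,
        path,
        case_sample: str,
        ctrl_sample: str,
        n_case: int,
        n_ctrl: int,
        **kwargs,
    ) -> "PooledAssociation":
        """Build from a two-sample pooled VCF with AD/DP fields."""
        table = io_pools.read_vcf_pools(
            path, case_sample, ctrl_sample, n_case=n_case, n_ctrl=n_ctrl
        )
        return cls(table, **kwargs)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_case: int, n_ctrl: int, **kwargs
    ) -> "PooledAssociation":
        """Build from a DataFrame with the count-table columns
        (``chrom, pos, ref, alt, case_depth, case_alt, ctrl_depth,
        ctrl_alt`` and optionally ``site_id``)."""
        if "site_id" in df.columns:
            ids = df["site_id"].astype(str).tolist()
        else:
            ids = [
                f"{c}:{p}:{r}:{a}"
                for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
            ]
        sites = [
            core.SiteCounts(
                site_id=ids[i],
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                depth_case=int(row["case_depth"]),
                alt_case=int(row["case_alt"]),
                depth_ctrl=int(row["ctrl_depth"]),
                alt_ctrl=int(row["ctrl_alt"]),
            )
            for i, (_, row) in enumerate(df.iterrows())
        ]
        table = io_pools.CountTable(
            sites=sites,
            case_spec=core.PoolSpec(n_case),
            ctrl_spec=core.PoolSpec(n_ctrl),
            source="dataframe",
            format="dataframe",
        )
        return cls(table, **kwargs)

    # ---------------------------------------------------------------- fitting
    def fit(self, k: float | str | None = "calibrate") -> "PooledAssociationResults":
        """Filter, (optionally) calibrate and test every site.

        ``k`` applies only to the full variance model: a number fixes the
        contribution variance, ``"calibrate"`` (default) estimates it by
        median matching on the filtered sites, ``None`` or 0 treats the pool
        as equimolar.
        """
        table = self.count_table
        passed, report = filters.maf_filter(table.sites, self.maf_threshold)

        calib = None
        k_value: float | None
        if self.variance_model is core.VarianceModel.FULL:
            if k == "calibrate":
                calib = _calib.estimate_k(
                    passed,
                    table.case_spec,
                    table.ctrl_spec,
                    include_interaction=self.include_interaction,
                    p_for_variance=self.p_for_variance,
                )
                k_value = calib.k_hat
            elif k is None:
                k_value = table.case_spec.k_excess or 0.0
            else:
                k_value = float(k)
        else:
            k_value = None

        results = core.run_site_tests(
            passed,
            table.case_spec,
            table.ctrl_spec,
            model=self.variance_model,
            k=k_value,
            include_interaction=self.include_interaction,
            p_for_variance=self.p_for_variance,
        )
        return PooledAssociationResults(
            model=self,
            table=results,
            k_hat=k_value,
            calibration=calib,
            filter_report=report,
        )


class PooledAssociationResults:
    """Fitted results: per-site tests, calibration and diagnostics."""

    def __init__(self, model, table, k_hat, calibration, filter_report):
        self.model = model
        self.table = table
        self.k_hat = k_hat
        self.calibration = calibration
        self.filter_report = filter_report

    # ---------------------------------------------------------------- diagnostics
    @property
    def n_tested(self) -> int:
        return int(self.table["testable"].sum())

    @property
    def genomic_lambda(self) -> float:
        """Inflation factor of the fitted statistics."""
        return _calib.genomic_lambda(self.table["statistic"].dropna())

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Tested sites with p-value at or below ``alpha``, by rank."""
        out = self.table[self.table["p_value"] <= alpha]
        return out.sort_values("rank")

    def top(self, n: int = 10) -> pd.DataFrame:
        """The ``n`` highest-priority sites."""
        ranked = self.table[self.table["rank"] > 0]
        return ranked.sort_values("rank").head(n)

    def qq_data(self) -> pd.DataFrame:
        """Expected vs observed -log10 p-values for a QQ plot."""
        return io_pools.qq_table(self.table["p_value"])

    def plot_qq(self, ax=None):
        """QQ plot of the fitted p-values (requires matplotlib)."""
        import matplotlib.pyplot as plt

        qq = self.qq_data()
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(qq["expected_neglog10_p"], qq["observed_neglog10_p"], ".", ms=3)
        lim = max(qq["expected_neglog10_p"].max(), qq["observed_neglog10_p"].max())
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel(r"expected $-\log_{10} p$")
        ax.set_ylabel(r"observed $-\log_{10} p$")
        ax.set_title(
            f"{self.model.variance_model.value} model, "
            rf"$\lambda$ = {self.genomic_lambda:.3f}"
        )
        return ax

    # ---------------------------------------------------------------- output
    def save(self, prefix, seed: int | None = None) -> tuple[str, str]:
        """Write ``<prefix>.results.tsv`` and ``<prefix>.qq.tsv``."""
        results_path = f"{prefix}.results.tsv"
        qq_path = f"{prefix}.qq.tsv"
        io_pools.write_results(
            self.table,
            results_path,
            calibration=self.calibration,
            filter_report=self.filter_report,
            seed=seed,
            qq_path=qq_path,
        )
        return results_path, qq_path

    def summary(self, n_top: int = 10) -> str:
        """Human-readable run summary with the top-ranked sites."""
        m = self.model
        ct = m.count_table
        rep = self.filter_report
        lines = [
            "      Pooled case-control association test",
            "=" * 58,
            f"{'Variance model:':<36}{m.variance_model.value}",
            f"{'Case pool (individuals / chrom):':<36}"
            f"{ct.case_spec.n_individuals} / {ct.case_spec.n_chromosomes}",
            f"{'Control pool (individuals / chrom):':<36}"
            f"{ct.ctrl_spec.n_individuals} / {ct.ctrl_spec.n_chromosomes}",
            f"{'Sites (input / passed MAF filter):':<36}"
            f"{rep.n_input} / {rep.n_passed}",
            f"{'MAF threshold:':<36}{m.maf_threshold:g}",
        ]
        if self.k_hat is not None:
            lines.append(f"{'k (contribution variance):':<36}{self.k_hat:.4g}")
        if self.calibration is not None:
            c = self.calibration
            lines += [
                f"{'lambda before calibration:':<36}{c.lambda_before:.4f}",
                f"{'lambda after calibration:':<36}{c.lambda_after:.4f}",
                f"{'calibration iterations:':<36}{c.iterations}"
                + ("  (boundary)" if c.boundary_hit else ""),
            ]
        else:
            lines.append(f"{'genomic inflation lambda:':<36}{self.genomic_lambda:.4f}")
        lines.append("-" * 58)
        cols = ["rank", "site_id", "p_hat_case", "p_hat_ctrl", "statistic", "p_value"]
        top = self.top(n_top)[cols]
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append(top.to_string(index=False))
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<PooledAssociationResults: {self.n_tested} tested sites, "
            f"model={self.model.variance_model.value}, k={self.k_hat}>"
        )
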