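"""Model/Results facade over the valuation pipeline.

:class:`ValueOfLostWelfare` holds the harmonized, fully imputed
country-year table (burden plus economics plus hierarchy assignments);
``fit`` evaluates the valuation chain under one parameter setting and
returns a :class:`VLWResults` with the country-level estimates, regional
aggregates, national summary statistics and a printable summary table.

Typical use::

    model = ValueOfLostWelfare.from_files("daly.csv", "econ.csv", "hierarchy.csv")
    res = model.fit(elasticity=1.0, discount_rate=0.03)
    print(res.summary())
    res.aggregate("super_region")
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import aggregation, imputation, io_harmonize, valuation
from .locations import Hierarchy, read_hierarchy
from .synthetic import WorldBundle


class BenchmarkError(ValueError):
    """The benchmark economy is absent from the economic inputs."""


class ValueOfLostWelfare:
    """Welfare-loss valuation model for one cause-year across countries.

    Parameters
    ----------
    data : DataFrame
        Harmonized country table with hierarchy columns, daly_val/lower/
        upper, and complete gdp_per_capita / population / gdp_total /
        life_expectancy (imputation must already have run).
    hierarchy : Hierarchy
        Canonical location universe.
    benchmark_location : str
        Country whose economy anchors the benefit transfer; its
        per-capita GDP is read from ``data`` so the benchmark stays
        consistent with the input vintage.
    vsl_benchmark : float
        Value of a statistical life in the benchmark economy (currency
        units of the GDP table).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        hierarchy: Hierarchy,
        benchmark_location: str = "United States of America",
        vsl_benchmark: float = 11_800_000.0,
        year: int = 2021,
        reports: dict | None = None,
    ) -> None:
        econ_cols = ["gdp_per_capita", "population", "gdp_total", "life_expectancy"]
        if data[econ_cols].isna().any().any():
            bad = data.loc[data[econ_cols].isna().any(axis=1), "location_id"].tolist()
            raise valuation.DomainError(
                f"model data has missing economic fields for {bad}; impute first"
            )
        self.data = data.sort_values("location_id", ignore_index=True)
        self.hierarchy = hierarchy
        self.benchmark_location = benchmark_location
        self.vsl_benchmark = vsl_benchmark
        self.year = year
        self.reports = reports or {}

        node = hierarchy.resolve(benchmark_location)
        if node is None:
            raise BenchmarkError(f"benchmark {benchmark_location!r} not in the hierarchy")
        row = self.data[self.data["location_id"] == node.location_id]
        if row.empty:
            raise BenchmarkError(
                f"benchmark {benchmark_location!r} has no row in the model data"
            )
        self.gdp_pc_benchmark = float(row["gdp_per_capita"].iloc[0])

    # ------------------------------------------------------------------ #
    @classmethod
    def from_files(
        cls,
        daly_path: str | Path,
        econ_path: str | Path,
        hierarchy_path: str | Path,
        benchmark_location: str = "United States of America",
        vsl_benchmark: float = 11_800_000.0,
        year: int = 2021,
        cause_filter: str = "colorectal",
        aliases: dict[str, str] | None = None,
    ) -> "ValueOfLostWelfare":
        """Read, harmonize and impute the three input tables.

        The economic table may be a multi-year long panel (interpolated
        to *year*, flat carry at the edges) or a single-year table; any
        remaining country-level gaps are filled from regional donors.
        """
        hierarchy = read_hierarchy(hierarchy_path, aliases=aliases)
        daly_records, daly_rejects = io_harmonize.read_gbd_daly(
            daly_path, cause_filter=cause_filter
        )
        imp_report = imputation.ImputationReport()
        try:
            panel = io_harmonize.read_econ_panel(econ_path)
        except io_harmonize.FormatError:
            econ_records = io_harmonize.read_econ(econ_path, year)
        else:
            wide, imp_report = imputation.impute_series_table(panel, year, imp_report)
            econ_records = io_harmonize.econ_records_from_wide(wide, year)

        table, recon = io_harmonize.harmonize(daly_records, econ_records, hierarchy)
        table, imp_report = imputation.impute_missing_countries(table, hierarchy, imp_report)
        reports = {
            "daly_rejections": daly_rejects,
            "reconciliation": recon,
            "imputation": imp_report,
        }
        return cls(
            table,
            hierarchy,
            benchmark_location=benchmark_location,
            vsl_benchmark=vsl_benchmark,
            year=year,
            reports=reports,
        )

    @classmethod
    def from_bundle(
        cls,
        bundle: WorldBundle,
        tmp_dir: str | Path | None = None,
        **kwargs,
    ) -> "ValueOfLostWelfare":
        """Build the model from a synthetic :class:`WorldBundle`.

        Goes through the same file round trip as real inputs so the
        readers are exercised; benchmark defaults to the bundle's own.
        """
        import tempfile

        kwargs.setdefault("benchmark_location", bundle.meta["benchmark_location"])
        kwargs.setdefault("year", bundle.meta.get("target_year", 2021))
        if tmp_dir is None:
            with tempfile.TemporaryDirectory() as td:
                paths = bundle.write(td)
                return cls.from_files(
                    paths["daly"], paths["econ"], paths["hierarchy"], **kwargs
                )
        paths = bundle.write(tmp_dir)
        return cls.from_files(paths["daly"], paths["econ"], paths["hierarchy"], **kwargs)

    # ------------------------------------------------------------------ #
    def make_params(
        self,
        elasticity: float = 1.0,
        discount_rate: float = 0.03,
        discounting_enabled: bool = True,
    ) -> valuation.ValuationParams:
        return valuation.ValuationParams(
            gdp_pc_benchmark=self.gdp_pc_benchmark,
            vsl_benchmark=self.vsl_benchmark,
            benchmark_location=self.benchmark_location,
            elasticity=elasticity,
            discount_rate=discount_rate,
            discounting_enabled=discounting_enabled,
        )

    def fit(
        self,
        elasticity: float = 1.0,
        discount_rate: float = 0.03,
        discounting_enabled: bool = True,
    ) -> "VLWResults":
        """Evaluate the valuation chain for every country."""
        params = self.make_params(elasticity, discount_rate, discounting_enabled)
        valued = valuation.value_table(self.data, params)
        return VLWResults(self, params, valued)

    @property
    def n_countries(self) -> int:
        return len(self.data)


class VLWResults:
    """Fitted valuation: country estimates, aggregates and summaries.

    ``countries`` carries, per country, the transferred VSL, plain and
    annuitized VSLY, the welfare-loss triple (central, lower, upper —
    the burden's 95% uncertainty interval scaled through the valuation),
    its GDP share, the discounted counterparts, and the discounting
    uplift in percent.
    """

    def __init__(self, model: ValueOfLostWelfare, params: valuation.ValuationParams,
                 countries: pd.DataFrame) -> None:
        self.model = model
        self.params = params
        self.countries = countries

    def aggregate(self, level: str, discounted: bool = False) -> pd.DataFrame:
        return aggregation.aggregate(
            self.countries, self.model.hierarchy, level, discounted=discounted
        )

    def aggregates(self, discounted: bool = False) -> pd.DataFrame:
        return aggregation.aggregate_all(
            self.countries, self.model.hierarchy, discounted=discounted
        )

    def national_summary(self) -> dict:
        return aggregation.national_summary(self.countries)

    def country_table(self, precision: int = 2) -> pd.DataFrame:
        return valuation.country_results_frame(self.countries, precision=precision)

    @property
    def global_vlw(self) -> tuple[float, float, float]:
        g = self.aggregate("global").iloc[0]
        return (float(g["vlw_val"]), float(g["vlw_lower"]), float(g["vlw_upper"]))

    @property
    def global_pct_gdp(self) -> tuple[float, float, float]:
        g = self.aggregate("global").iloc[0]
        return (float(g["pct_val"]), float(g["pct_lower"]), float(g["pct_upper"]))

    def summary(self) -> str:
        """Printable overview: parameters, global totals, national spread."""
        ns = self.national_summary()
        gv, gp = self.global_vlw, self.global_pct_gdp
        p = self.params
        lines = [
            "Value of Lost Welfare — valuation results",
            "=" * 57,
            f"Countries: {self.model.n_countries}    Year: {self.model.year}",
            f"Benchmark: {p.benchmark_location} "
            f"(VSL {p.vsl_benchmark / 1e6:.1f}M, GDP pc {p.gdp_pc_benchmark:,.0f})",
            f"Income elasticity: {p.elasticity}    "
            f"Discount rate: {p.discount_rate if p.discounting_enabled else 0.0:.2%}",
            "-" * 57,
            f"Global VLW (millions): {gv[0] / 1e6:,.2f} "
            f"[{gv[1] / 1e6:,.2f} – {gv[2] / 1e6:,.2f}]",
            f"Global VLW/GDP (%):    {gp[0]:.2f} [{gp[1]:.2f} – {gp[2]:.2f}]",
            "-" * 57,
            f"National VLW median (millions): {ns['vlw']['median'] / 1e6:,.2f} "
            f"(IQR {ns['vlw']['iqr'][0] / 1e6:,.2f} – {ns['vlw']['iqr'][1] / 1e6:,.2f})",
            f"National VLW/GDP median (%):    {ns['pct_gdp']['median']:.2f} "
            f"(IQR {ns['pct_gdp']['iqr'][0]:.2f} – {ns['pct_gdp']['iqr'][1]:.2f})",
            f"  range {ns['pct_gdp']['min']:.2f} ({ns['pct_gdp']['min_country']}) "
            f"to {ns['pct_gdp']['max']:.2f} ({ns['pct_gdp']['max_country']})",
            f"Discounted national medians: VLW {ns['vlw_discounted']['median'] / 1e6:,.2f}M, "
            f"VLW/GDP {ns['pct_gdp_discounted']['median']:.2f}%",
            f"Discount uplift range (%): {ns['discount_uplift_pct']['min']:.2f} "
            f"to {ns['discount_uplift_pct']['max']:.2f} "
            f"({ns['discount_uplift_pct']['max_country']})",
        ]
        return "\n".join(lines)

    def plot_regions(self, level: str = "super_region", metric: str = "pct_gdp", ax=None):
        """Horizontal bar chart of regional VLW or VLW/GDP with UI whiskers."""
        import matplotlib.pyplot as plt

        agg = self.aggregate(level).sort_values("pct_val" if metric == "pct_gdp" else "vlw_val")
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.4 * len(agg) + 1.5))
        if metric == "pct_gdp":
            vals, lo, hi = agg["pct_val"], agg["pct_lower"], agg["pct_upper"]
            ax.set_xlabel("VLW as % of GDP")
        else:
            vals, lo, hi = agg["vlw_val"] / 1e6, agg["vlw_lower"] / 1e6, agg["vlw_upper"] / 1e6
            ax.set_xlabel("VLW (millions)")
        ax.barh(agg["region_id"], vals, xerr=[vals - lo, hi - vals], capsize=3)
        ax.set_title(f"Welfare loss by {level.replace('_', ' ')}")
        return ax


__all__ = ["ValueOfLostWelfare", "VLWResults", "BenchmarkError"]
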