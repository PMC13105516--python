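"""Filling missing economic inputs.

Two mechanisms, applied in this order:

1. Per-country time series with missing years are completed by linear
   interpolation between the nearest observed neighbours; years outside
   the observed range carry the nearest observed value flat.
2. Countries missing an indicator for all years receive a donor value:
   the population-weighted mean of observed countries in their
   geographic region, cascading to the super-region and finally to all
   countries when fewer than three donors are available.

Valuation never sees missing fields: imputation runs first and every
filled cell is listed in the imputation report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locations import Hierarchy

INDICATORS = ("gdp_per_capita", "population", "life_expectancy")

MIN_DONORS = 3


class CannotImputeError(ValueError):
    """A series (or donor pool) has no observed values at all."""


@dataclass
class TimeSeries:
    """One indicator's (year, value) track for one location.

    ``mask`` is True where the value was observed; filled entries keep
    mask False so provenance survives the imputation pass.
    """

    location_id: str
    indicator: str
    years: np.ndarray
    values: np.ndarray
    mask: np.ndarray  # True = observed

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.all(np.diff(self.years) > 0):
            raise ValueError(f"{self.location_id}/{self.indicator}: years must be strictly increasing")
        observed = self.values[self.mask]
        if self.indicator in ("gdp_per_capita", "population", "gdp_total") and np.any(observed <= 0):
            raise ValueError(f"{self.location_id}/{self.indicator}: observed values must be positive")

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())


def interpolate_linear(series: TimeSeries) -> TimeSeries:
    """Complete a time series by linear interpolation with flat edge carry.

    Interior gaps are filled on the straight line between the nearest
    observed neighbours; gaps before the first or after the last
    observation carry that observation's value unchanged. Requires at
    least one observed point.
    """
    if series.n_observed == 0:
        raise CannotImputeError(
            f"{series.location_id}/{series.indicator}: no observed points to interpolate from"
        )
    obs_years = series.years[series.mask].astype(float)
    obs_vals = series.values[series.mask]
    # np.interp is exactly the convention: linear interior, clamped edges
    filled = np.interp(series.years.astype(float), obs_years, obs_vals)
    values = np.where(series.mask, series.values, filled)
    return TimeSeries(series.location_id, series.indicator, series.years, values, series.mask)


@dataclass
class ImputationReport:
    """Every imputed cell: location, indicator, method, value."""

    rows: list[dict] = field(default_factory=list)

    def add(self, location_id: str, indicator: str, method: str, value: float,
            year: int | None = None) -> None:
        self.rows.append(
            {"location_id": location_id, "indicator": indicator,
             "year": year, "method": method, "value": value}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["location_id", "indicator", "year", "method", "value"]
        )

    def __len__(self) -> int:
        return len(self.rows)


def _donor_value(
    table: pd.DataFrame, donors: pd.DataFrame, indicator: str
) -> float:
    """Population-weighted donor mean; plain mean for population itself."""
    if indicator == "population":
        return float(donors[indicator].mean())
    weights = donors["population"].to_numpy(float)
    vals = donors[indicator].to_numpy(float)
    if np.isnan(weights).any() or weights.sum() <= 0:
        return float(np.nanmean(vals))
    return float(np.average(vals, weights=weights))


def impute_missing_countries(
    table: pd.DataFrame,
    hierarchy: Hierarchy,
    report: ImputationReport | None = None,
) -> tuple[pd.DataFrame, ImputationReport]:
    """Fill country-level gaps with regional donor means.

    For each country missing an indicator, donors are the countries in
    the same geographic region with that indicator observed; if fewer
    than three, the super-region; if still fewer than three, all
    countries (with a warning). ``gdp_total`` is then closed as
    gdp_per_capita × population wherever missing. Imputing an already
    complete table is a no-op.
    """
    report = report if report is not None else ImputationReport()
    out = table.copy()

    for indicator in INDICATORS:
        missing_idx = out.index[out[indicator].isna()]
        if len(missing_idx) == 0:
            continue
        observed = out[out[indicator].notna()]
        if observed.empty:
            raise CannotImputeError(f"no country observes {indicator}; cannot impute")
        for i in missing_idx:
            row = out.loc[i]
            for level, scope in (
                ("region", observed[observed["region"] == row["region"]]),
                ("super_region", observed[observed["super_region"] == row["super_region"]]),
                ("global", observed),
            ):
                if len(scope) >= MIN_DONORS or (level == "global" and len(scope) > 0):
                    if level == "global":
                        warnings.warn(
                            f"{row['name']}: fewer than {MIN_DONORS} regional donors for "
                            f"{indicator}; falling back to global donor pool",
                            stacklevel=2,
                        )
                    value = _donor_value(out, scope, indicator)
                    out.loc[i, indicator] = value
                    report.add(row["location_id"], indicator, f"{level}-donor", value)
                    break

    gap = out["gdp_total"].isna()
    for i in out.index[gap]:
        value = out.loc[i, "gdp_per_capita"] * out.loc[i, "population"]
        out.loc[i, "gdp_total"] = value
        report.add(out.loc[i, "location_id"], "gdp_total", "product-closure", value)

    return out, report


def impute_series_table(
    long: pd.DataFrame,
    target_year: int,
    report: ImputationReport | None = None,
) -> tuple[pd.DataFrame, ImputationReport]:
    """Interpolate a long (location_id, indicator, year, value) panel and
    extract the target year.

    Returns a wide frame (location_id × indicator) for *target_year*;
    locations with no observed value at all for an indicator come back
    NaN (left to the donor-based pass).
    """
    report = report if report is not None else ImputationReport()
    rows = []
    for (loc, ind), grp in long.groupby(["location_id", "indicator"], sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(int)
        values = grp["value"].to_numpy(float)
        mask = ~np.isnan(values)
        if target_year not in years:
            years = np.append(years, target_year)
            values = np.append(values, np.nan)
            mask = np.append(mask, False)
            order = np.argsort(years)
            years, values, mask = years[order], values[order], mask[order]
        if not mask.any():
            rows.append({"location_id": loc, "indicator": ind, "value": np.nan})
            continue
        ts = interpolate_linear(TimeSeries(loc, ind, years, values, mask))
        at = float(ts.values[ts.years == target_year][0])
        if not bool(mask[ts.years == target_year][0]):
            report.add(loc, ind, "linear-interpolation", at, year=target_year)
        rows.append({"location_id": loc, "indicator": ind, "value": at})
    wide = (
        pd.DataFrame(rows)
        .pivot(index="location_id", columns="indicator", values="value")
        .rename_axis(columns=None)
    )
    return wide, report


__all__ = [
    "TimeSeries",
    "ImputationReport",
    "CannotImputeError",
    "interpolate_linear",
    "impute_missing_countries",
    "impute_series_table",
]
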