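"""Monetizing disease burden with the value-of-a-statistical-life-year
(VSLY) framework.

The chain, per country *i*:

- **Benefit transfer.** A benchmark value of a statistical life (VSL),
  taken from the United States, is transferred across countries by
  income: ``VSL_i = VSL_bench × (gdp_pc_i / gdp_pc_bench)^ε`` where ε is
  the income elasticity of the willingness to pay for mortality-risk
  reduction. No floor or ceiling is applied — economies richer than the
  benchmark receive a larger VSL.
- **Per-life-year value.** ``VSLY_i = VSL_i / (LE_i / 2)``: the VSL is
  spread over half the national life expectancy at birth, a stand-in
  for average remaining life years at the time of health loss.
- **Discounted variant.** With annual discount rate r the half-life
  span is annuitized: ``VSLY_disc = VSL / a(r, LE/2)`` where
  ``a(r, n) = (1 − (1+r)^−n) / r`` is the present value of a unit
  annuity (``a(0, n) = n`` exactly). Since a(r, n) < n for r > 0, the
  discounted per-year value — and hence the welfare loss — exceeds the
  undiscounted one; the uplift grows with life expectancy.
- **Welfare loss.** ``VLW_i = DALY_i × VSLY_i`` applied elementwise to
  the burden estimate and both ends of its 95% uncertainty interval
  (VSLY is treated as deterministic; only the burden uncertainty
  propagates), and ``%GDP_i = 100 × VLW_i / GDP_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_harmonize import CountryEconRecord, DalyRecord


class DomainError(ValueError):
    """An input is outside the formula's domain (e.g. GDP ≤ 0)."""


@dataclass(frozen=True)
class ValuationParams:
    """Parameters of the valuation chain.

    ``gdp_pc_benchmark`` is the benchmark economy's per-capita GDP and
    must come from the same economic table as every other country so the
    transfer ratio is internally consistent; it is therefore required
    rather than defaulted. ``vsl_benchmark`` defaults to the 2021 U.S.
    Department of Transportation figure of $11.8 million.
    """

    gdp_pc_benchmark: float
    vsl_benchmark: float = 11_800_000.0
    benchmark_location: str = "United States of America"
    elasticity: float = 1.0
    discount_rate: float = 0.03
    discounting_enabled: bool = True

    def __post_init__(self) -> None:
        if self.vsl_benchmark <= 0:
            raise DomainError("vsl_benchmark must be positive")
        if self.gdp_pc_benchmark <= 0:
            raise DomainError("gdp_pc_benchmark must be positive")
        if self.elasticity < 0:
            raise DomainError("elasticity must be non-negative")
        if not (0 <= self.discount_rate < 1):
            raise DomainError("discount_rate must lie in [0, 1)")

    def with_(self, **kwargs) -> "ValuationParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CountryValuation:
    """Full valuation output for one country."""

    location_id: str
    vsl: float
    vsly: float
    vsly_discounted: float
    vlw: tuple[float, float, float]            # (val, lower, upper)
    vlw_pct_gdp: tuple[float, float, float]
    vlw_discounted: tuple[float, float, float]
    vlw_pct_gdp_discounted: tuple[float, float, float]
    discount_uplift_pct: float


def compute_vsl(gdp_per_capita: float, params: ValuationParams) -> float:
    """Benefit-transfer VSL: benchmark scaled by the income ratio to power ε."""
    if gdp_per_capita <= 0:
        raise DomainError(f"gdp_per_capita must be positive, got {gdp_per_capita}")
    return params.vsl_benchmark * (gdp_per_capita / params.gdp_pc_benchmark) ** params.elasticity


def compute_vsly(vsl: float, life_expectancy: float) -> float:
    """VSL spread over half the national life expectancy, unrounded."""
    if life_expectancy <= 0:
        raise DomainError(f"life_expectancy must be positive, got {life_expectancy}")
    return vsl / (life_expectancy / 2.0)


def annuity_factor(rate: float, n_years: float) -> float:
    """Present value of a unit-per-year stream over *n_years* at *rate*.

    ``(1 − (1+rate)^−n) / rate``; returns *n_years* exactly at rate 0
    (the continuity limit).
    """
    if n_years <= 0:
        raise DomainError(f"n_years must be positive, got {n_years}")
    if rate < 0:
        raise DomainError(f"rate must be non-negative, got {rate}")
    if rate == 0:
        return float(n_years)
    # expm1/log1p form of (1 − (1+rate)^−n)/rate, stable as rate → 0
    return -math.expm1(-n_years * math.log1p(rate)) / rate


def compute_vsly_discounted(vsl: float, life_expectancy: float, rate: float) -> float:
    """Annuitized VSLY: VSL over the annuity factor of half the life expectancy.

    Equals the plain VSLY exactly at rate 0.
    """
    if life_expectancy <= 0:
        raise DomainError(f"life_expectancy must be positive, got {life_expectancy}")
    return vsl / annuity_factor(rate, life_expectancy / 2.0)


def compute_vlw(daly: DalyRecord, vsly: float) -> tuple[float, float, float]:
    """Welfare-loss triple: the DALY (val, lower, upper) each times VSLY.

    This elementwise product is the uncertainty-propagation rule — the
    GBD interval passes through the (deterministic) valuation untouched
    in relative terms, so the interval ordering is preserved.
    """
    if vsly <= 0:
        raise DomainError(f"vsly must be positive, got {vsly}")
    return (daly.val * vsly, daly.lower * vsly, daly.upper * vsly)


def pct_gdp(vlw: tuple[float, float, float], gdp_total: float) -> tuple[float, float, float]:
    """Welfare loss as a share of GDP, on the 0–100 scale, elementwise."""
    if gdp_total <= 0:
        raise DomainError(f"gdp_total must be positive, got {gdp_total}")
    return tuple(100.0 * x / gdp_total for x in vlw)


def value_country(
    econ: CountryEconRecord,
    daly: DalyRecord,
    params: ValuationParams,
) -> CountryValuation:
    """Run the full chain for one country; deterministic given inputs."""
    for fld in ("gdp_per_capita", "gdp_total", "life_expectancy"):
        if math.isnan(getattr(econ, fld)):
            raise DomainError(
                f"{econ.location_id}: {fld} is missing; run imputation before valuation"
            )
    vsl = compute_vsl(econ.gdp_per_capita, params)
    vsly = compute_vsly(vsl, econ.life_expectancy)
    rate = params.discount_rate if params.discounting_enabled else 0.0
    vsly_disc = compute_vsly_discounted(vsl, econ.life_expectancy, rate)
    vlw = compute_vlw(daly, vsly)
    vlw_disc = compute_vlw(daly, vsly_disc)
    pct = pct_gdp(vlw, econ.gdp_total)
    pct_disc = pct_gdp(vlw_disc, econ.gdp_total)
    uplift = 100.0 * (vlw_disc[0] / vlw[0] - 1.0) if vlw[0] > 0 else 0.0
    return CountryValuation(
        location_id=econ.location_id,
        vsl=vsl,
        vsly=vsly,
        vsly_discounted=vsly_disc,
        vlw=vlw,
        vlw_pct_gdp=pct,
        vlw_discounted=vlw_disc,
        vlw_pct_gdp_discounted=pct_disc,
        discount_uplift_pct=uplift,
    )


def value_table(table: pd.DataFrame, params: ValuationParams) -> pd.DataFrame:
    """Vectorized valuation of a harmonized, imputed country table.

    Expects columns gdp_per_capita, population, gdp_total,
    life_expectancy, daly_val/lower/upper; returns the table extended
    with vsl, vsly, vsly_discounted, vlw_* , pct_*, vlw_disc_*,
    pct_disc_* and discount_uplift_pct columns.
    """
    required = {"gdp_per_capita", "gdp_total", "life_expectancy",
                "daly_val", "daly_lower", "daly_upper"}
    missing = required - set(table.columns)
    if missing:
        raise DomainError(f"valuation table missing columns: {sorted(missing)}")
    if table[list(required)].isna().any().any():
        bad = table.loc[table[list(required)].isna().any(axis=1), "location_id"].tolist()
        raise DomainError(f"missing inputs for {bad}; run imputation before valuation")
    if (table["gdp_per_capita"] <= 0).any() or (table["gdp_total"] <= 0).any() \
            or (table["life_expectancy"] <= 0).any():
        raise DomainError("non-positive economic inputs")

    out = table.copy()
    gdp_pc = out["gdp_per_capita"].to_numpy(float)
    le = out["life_expectancy"].to_numpy(float)
    gdp = out["gdp_total"].to_numpy(float)

    vsl = params.vsl_benchmark * (gdp_pc / params.gdp_pc_benchmark) ** params.elasticity
    vsly = vsl / (le / 2.0)
    rate = params.discount_rate if params.discounting_enabled else 0.0
    n = le / 2.0
    af = n if rate == 0 else -np.expm1(-n * np.log1p(rate)) / rate
    vsly_disc = vsl / af

    out["vsl"] = vsl
    out["vsly"] = vsly
    out["vsly_discounted"] = vsly_disc
    for stat in ("val", "lower", "upper"):
        out[f"vlw_{stat}"] = out[f"daly_{stat}"] * vsly
        out[f"vlw_disc_{stat}"] = out[f"daly_{stat}"] * vsly_disc
        out[f"pct_{stat}"] = 100.0 * out[f"vlw_{stat}"] / gdp
        out[f"pct_disc_{stat}"] = 100.0 * out[f"vlw_disc_{stat}"] / gdp
    with np.errstate(invalid="ignore", divide="ignore"):
        uplift = 100.0 * (out["vlw_disc_val"] / out["vlw_val"] - 1.0)
    out["discount_uplift_pct"] = uplift.where(out["vlw_val"] > 0, 0.0)
    return out


def country_results_frame(valued: pd.DataFrame, precision: int = 2) -> pd.DataFrame:
    """Table-style country results: monetary columns in millions."""
    res = pd.DataFrame({"location_id": valued["location_id"]})
    if "name" in valued.columns:
        res["name"] = valued["name"]
    res["vsl"] = (valued["vsl"] / 1e6).round(precision)
    res["vsly"] = valued["vsly"].round(precision)
    res["vsly_discounted"] = valued["vsly_discounted"].round(precision)
    for stat in ("val", "lower", "upper"):
        res[f"vlw_{stat}"] = (valued[f"vlw_{stat}"] / 1e6).round(precision)
        res[f"pct_{stat}"] = valued[f"pct_{stat}"].round(4)
    res["discount_uplift_pct"] = valued["discount_uplift_pct"].round(precision)
    return res


__all__ = [
    "ValuationParams",
    "CountryValuation",
    "DomainError",
    "compute_vsl",
    "compute_vsly",
    "annuity_factor",
    "compute_vsly_discounted",
    "compute_vlw",
    "pct_gdp",
    "value_country",
    "value_table",
    "country_results_frame",
]
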