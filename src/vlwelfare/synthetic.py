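"""Synthetic world generator.

Emits burden, economic and hierarchy tables in exactly the dialects the
readers consume, so every pipeline stage is testable without downloads.
The generated world mimics the qualitative structure of the real one:
per-capita income is log-normal across countries, life expectancy rises
with log income, and the colorectal-cancer DALY rate rises with the
income-derived SDI quintile (richer, older populations carry more burden
per head). It makes no attempt to match the actual 2021 distribution of
GDP or burden.

Alongside the input files the generator writes a *truth ledger*: every
latent value per country plus an independently computed expected welfare
loss (single closed-form expression, base elasticity, no discounting),
used by tests as ground truth for closure and recovery checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .locations import SDI_QUINTILES

TARGET_YEAR = 2021
PANEL_YEARS = tuple(range(2017, 2022))


class WorldSpecError(ValueError):
    """A generator parameter is outside its valid range."""


@dataclass(frozen=True)
class WorldSpec:
    """Knobs of the synthetic world.

    Scale parameters are medians of log-normal draws (Int$ for income,
    persons for population); ``le_link`` makes life expectancy affine in
    ln(income), clipped to plausible bounds; ``daly_rate_link`` sets the
    all-ages DALY rate per 100 000 at the lowest SDI quintile and its
    proportional increase per quintile step. ``ui_halfwidth`` is the
    relative 95%-interval half width around each burden estimate;
    ``missingness`` is the fraction of economic panel cells hidden;
    ``volatility`` is the s.d. of multiplicative year-over-year noise in
    the economic panel.
    """

    n_countries: int = 204
    seed: int = 0
    gdp_pc_lognormal: tuple[float, float] = (15_000.0, 1.1)
    population_lognormal: tuple[float, float] = (6_000_000.0, 1.9)
    le_link: tuple[float, float, tuple[float, float]] = (40.0, 3.2, (50.0, 88.0))
    daly_rate_link: tuple[float, float] = (120.0, 0.8)
    ui_halfwidth: float = 0.15
    missingness: float = 0.05
    volatility: float = 0.02
    hierarchy_shape: tuple[int, int] = (21, 7)

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise WorldSpecError("n_countries must be >= 1")
        if not (0 < self.ui_halfwidth < 1):
            raise WorldSpecError("ui_halfwidth must lie in (0, 1)")
        if not (0 <= self.missingness < 1):
            raise WorldSpecError("missingness must lie in [0, 1)")
        if self.volatility < 0:
            raise WorldSpecError("volatility must be non-negative")
        for val, nm in ((self.gdp_pc_lognormal, "gdp_pc_lognormal"),
                        (self.population_lognormal, "population_lognormal")):
            if val[0] <= 0 or val[1] <= 0:
                raise WorldSpecError(f"{nm} scale parameters must be positive")
        n_regions, n_super = self.hierarchy_shape
        if n_regions < n_super or n_super < 1:
            raise WorldSpecError("hierarchy_shape must satisfy n_regions >= n_super >= 1")


@dataclass
class WorldBundle:
    """In-memory view of one generated world."""

    spec: WorldSpec
    daly: pd.DataFrame
    econ: pd.DataFrame
    hierarchy: pd.DataFrame
    truth: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "daly": out / "daly.csv",
            "econ": out / "econ.csv",
            "hierarchy": out / "hierarchy.csv",
            "truth": out / "truth.csv",
            "meta": out / "truth_meta.json",
        }
        # default float repr is the shortest round-trip form: re-reading
        # the files reproduces the latent values bit-exactly
        self.daly.to_csv(paths["daly"], index=False)
        self.econ.to_csv(paths["econ"], index=False)
        self.hierarchy.to_csv(paths["hierarchy"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        paths["meta"].write_text(json.dumps(self.meta, indent=2, sort_keys=True) + "\n")
        return paths


def _balanced_hierarchy(n_countries: int, n_regions: int, n_super: int) -> pd.DataFrame:
    """Assign countries round-robin to regions; regions round-robin to super-regions."""
    region_of = [f"Region {k % n_regions + 1:02d}" for k in range(n_countries)]
    super_of_region = {
        f"Region {r + 1:02d}": f"Super-region {r % n_super + 1}" for r in range(n_regions)
    }
    return pd.DataFrame(
        {
            "location_id": [f"C{k + 1:03d}" for k in range(n_countries)],
            "name": [f"Country {k + 1:03d}" for k in range(n_countries)],
            "region": region_of,
            "super_region": [super_of_region[r] for r in region_of],
        }
    )


def _sdi_quintiles(gdp_pc: np.ndarray) -> list[str]:
    """Quintile assignment by per-capita-income rank, lowest fifth = 'low'."""
    order = np.argsort(np.argsort(gdp_pc))  # ranks, 0-based
    n = len(gdp_pc)
    idx = np.minimum((order * 5) // n, 4)
    return [SDI_QUINTILES[i] for i in idx]


def generate_world(spec: WorldSpec) -> WorldBundle:
    """Draw one synthetic world; deterministic given the spec (incl. seed).

    File emission order is canonical (sorted by location_id), so a fixed
    seed yields byte-identical files across runs.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_countries

    hier = _balanced_hierarchy(n, *spec.hierarchy_shape)

    med_g, sig_g = spec.gdp_pc_lognormal
    gdp_pc = np.exp(rng.normal(np.log(med_g), sig_g, size=n))
    med_p, sig_p = spec.population_lognormal
    population = np.exp(rng.normal(np.log(med_p), sig_p, size=n))

    icpt, slope, (lo, hi) = spec.le_link
    life_exp = np.clip(icpt + slope * np.log(gdp_pc), lo, hi)

    sdi = _sdi_quintiles(gdp_pc)
    sdi_index = np.array([SDI_QUINTILES.index(q) for q in sdi], dtype=float)
    base_rate, gradient = spec.daly_rate_link
    daly_rate = base_rate * (1.0 + gradient * sdi_index)  # per 100k
    daly_val = population * daly_rate / 1e5
    daly_lower = daly_val * (1.0 - spec.ui_halfwidth)
    daly_upper = daly_val * (1.0 + spec.ui_halfwidth)

    hier["iso3"] = [f"S{k + 1:02X}".ljust(3, "X") for k in range(n)]
    hier["sdi_quintile"] = sdi
    hier = hier[["location_id", "name", "iso3", "region", "super_region", "sdi_quintile"]]

    daly = pd.DataFrame(
        {
            "measure_name": "DALYs (Disability-Adjusted Life Years)",
            "location_name": hier["name"],
            "sex_name": "Both",
            "age_name": "All ages",
            "cause_name": "Colorectal cancer",
            "metric_name": "Number",
            "year": TARGET_YEAR,
            "val": daly_val,
            "upper": daly_upper,
            "lower": daly_lower,
        }
    )

    # Economic panel 2017–2021: smooth growth with multiplicative noise,
    # anchored at the 2021 latents.
    years = np.array(PANEL_YEARS)
    growth = {"gdp_per_capita": 0.02, "population": 0.01, "life_expectancy": 0.001}
    latent_2021 = {
        "gdp_per_capita": gdp_pc,
        "population": population,
        "life_expectancy": life_exp,
    }
    panel_rows = []
    for ind in ("gdp_per_capita", "population", "life_expectancy"):
        g = growth[ind]
        for j, year in enumerate(years):
            back = TARGET_YEAR - year
            noise = (
                np.exp(rng.normal(0.0, spec.volatility, size=n))
                if (spec.volatility > 0 and back > 0)
                else np.ones(n)
            )
            vals = latent_2021[ind] / (1.0 + g) ** back * noise
            if ind == "life_expectancy":
                vals = np.clip(vals, lo, hi)
            panel_rows.append(
                pd.DataFrame(
                    {"country": hier["name"], "indicator": ind, "year": year, "value": vals}
                )
            )
    econ = pd.concat(panel_rows, ignore_index=True)

    if spec.missingness > 0:
        hide = rng.random(len(econ)) < spec.missingness
        # never blind an entire (country, indicator) series
        keep_one = econ.assign(hide=hide).groupby(["country", "indicator"])["hide"].transform("all")
        hide &= ~keep_one.to_numpy()
        econ.loc[hide, "value"] = np.nan

    econ = econ.sort_values(["country", "indicator", "year"], ignore_index=True)

    # Independent expected valuation (base elasticity 1, undiscounted,
    # benchmark = richest country), one closed-form expression.
    bench_i = int(np.argmax(gdp_pc))
    bench_gdp_pc = float(gdp_pc[bench_i])
    vsl_bench = 11_800_000.0
    expected_vlw = daly_val * (vsl_bench * (gdp_pc / bench_gdp_pc) ** 1.0) / (life_exp / 2.0)

    truth = hier.copy()
    truth["gdp_per_capita"] = gdp_pc
    truth["population"] = population
    truth["gdp_total"] = gdp_pc * population
    truth["life_expectancy"] = life_exp
    truth["daly_val"] = daly_val
    truth["daly_lower"] = daly_lower
    truth["daly_upper"] = daly_upper
    truth["expected_vlw_val"] = expected_vlw

    meta = {
        "seed": spec.seed,
        "n_countries": n,
        "target_year": TARGET_YEAR,
        "benchmark_location": str(hier["name"].iloc[bench_i]),
        "benchmark_location_id": str(hier["location_id"].iloc[bench_i]),
        "benchmark_gdp_per_capita": bench_gdp_pc,
        "total_daly_val": float(daly_val.sum()),
        "total_expected_vlw_val": float(expected_vlw.sum()),
        "n_hidden_econ_cells": int(econ["value"].isna().sum()),
    }
    return WorldBundle(spec=spec, daly=daly, econ=econ, hierarchy=hier, truth=truth, meta=meta)


def make_toy3() -> WorldBundle:
    """Three-country worked fixture with hand-derivable outputs.

    Country A is a quarter of the benchmark income, B *is* the benchmark,
    C is twice it. The companion ``truth`` frame tabulates the expected
    VSL/VSLY/VLW/%GDP chain for every combination of elasticity in
    {0.55, 1.0, 1.5} and discount rate in {0, 0.03}, each as one direct
    arithmetic expression.
    """
    rows = [
        # id, name, gdp_pc, population, life_expectancy, daly triple
        ("A", "Alandia", 16_000.0, 5_000_000.0, 70.0, (1_000.0, 800.0, 1_200.0)),
        ("B", "Benchia", 64_000.0, 100_000_000.0, 80.0, (50_000.0, 40_000.0, 60_000.0)),
        ("C", "Crestia", 128_000.0, 10_000_000.0, 84.0, (2_000.0, 1_600.0, 2_400.0)),
    ]
    hier = pd.DataFrame(
        {
            "location_id": [r[0] for r in rows],
            "name": [r[1] for r in rows],
            "iso3": ["ALA", "BEN", "CRE"],
            "region": ["Toy West", "Toy North", "Toy North"],
            "super_region": ["Toy Hemisphere", "Toy Hemisphere", "Toy Hemisphere"],
            "sdi_quintile": ["middle", "high", "high"],
        }
    )
    daly = pd.DataFrame(
        {
            "measure_name": "DALYs (Disability-Adjusted Life Years)",
            "location_name": [r[1] for r in rows],
            "sex_name": "Both",
            "age_name": "All ages",
            "cause_name": "Colorectal cancer",
            "metric_name": "Number",
            "year": TARGET_YEAR,
            "val": [r[5][0] for r in rows],
            "upper": [r[5][2] for r in rows],
            "lower": [r[5][1] for r in rows],
        }
    )
    econ_rows = []
    for _, name, gdp_pc, pop, le, _daly in rows:
        econ_rows += [
            {"country": name, "indicator": "gdp_per_capita", "year": TARGET_YEAR, "value": gdp_pc},
            {"country": name, "indicator": "population", "year": TARGET_YEAR, "value": pop},
            {"country": name, "indicator": "life_expectancy", "year": TARGET_YEAR, "value": le},
        ]
    econ = pd.DataFrame(econ_rows)

    vsl_bench, bench_gdp_pc = 11_800_000.0, 64_000.0
    truth_rows = []
    for loc, _name, gdp_pc, pop, le, (dv, dl, du) in rows:
        for eps in (0.55, 1.0, 1.5):
            for r in (0.0, 0.03):
                vsl = vsl_bench * (gdp_pc / bench_gdp_pc) ** eps
                n_half = le / 2.0
                af = n_half if r == 0 else (1.0 - (1.0 + r) ** (-n_half)) / r
                vsly = vsl / af
                gdp_total = gdp_pc * pop
                truth_rows.append(
                    {
                        "location_id": loc,
                        "elasticity": eps,
                        "discount_rate": r,
                        "vsl": vsl,
                        "vsly": vsly,
                        "vlw_val": dv * vsly,
                        "vlw_lower": dl * vsly,
                        "vlw_upper": du * vsly,
                        "pct_val": 100.0 * dv * vsly / gdp_total,
                        "pct_lower": 100.0 * dl * vsly / gdp_total,
                        "pct_upper": 100.0 * du * vsly / gdp_total,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    meta = {
        "benchmark_location": "Benchia",
        "benchmark_location_id": "B",
        "benchmark_gdp_per_capita": bench_gdp_pc,
        "target_year": TARGET_YEAR,
        "total_daly_val": float(daly["val"].sum()),
    }
    spec = WorldSpec(n_countries=3, seed=0, missingness=0.0)
    return WorldBundle(spec=spec, daly=daly, econ=econ, hierarchy=hier, truth=truth, meta=meta)


__all__ = ["WorldSpec", "WorldBundle", "WorldSpecError", "generate_world", "make_toy3",
           "TARGET_YEAR", "PANEL_YEARS"]
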