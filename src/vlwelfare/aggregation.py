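"""Rolling country valuations up the location hierarchy.

Regional welfare-loss triples are the elementwise sums of their members';
the regional GDP share is the **ratio of sums** — summed loss over summed
GDP — never the mean of member percentages, so large economies weigh in
proportionally. Every grouping level (21 geographic regions, 7
super-regions, 5 SDI quintiles, global) partitions the same country set,
so total VLW is conserved across levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locations import Hierarchy, LocationError

AGG_LEVELS = ("region", "super_region", "sdi_quintile", "global")

_LEVEL_COLUMN = {
    "region": "region",
    "super_region": "super_region",
    "sdi_quintile": "sdi_quintile",
}


class EmptyInputError(ValueError):
    """Summary statistics need at least one country."""


@dataclass(frozen=True)
class RegionAggregate:
    """Summed welfare loss and ratio-of-sums GDP share for one hierarchy node."""

    region_id: str
    level: str
    member_count: int
    vlw: tuple[float, float, float]
    gdp_total: float
    pct_gdp: tuple[float, float, float]


def aggregate(
    valued: pd.DataFrame,
    hierarchy: Hierarchy,
    level: str,
    discounted: bool = False,
) -> pd.DataFrame:
    """Aggregate a valued country table to *level*.

    Returns one row per node with member_count, the summed VLW triple,
    summed GDP and the ratio-of-sums percentage triple. Nodes with zero
    members are omitted (no 0/0 percentages). Raises
    :class:`~vlwelfare.locations.LocationError` if a country lacks an
    assignment at the requested level.
    """
    if level not in AGG_LEVELS:
        raise LocationError(f"unknown aggregation level {level!r}")
    prefix = "vlw_disc" if discounted else "vlw"
    cols = [f"{prefix}_{s}" for s in ("val", "lower", "upper")]

    df = valued.copy()
    if level == "global":
        df["_key"] = "Global"
    else:
        col = _LEVEL_COLUMN[level]
        if col not in df.columns:
            key = hierarchy.group_key(level)
            df["_key"] = df["location_id"].map(key)
        else:
            df["_key"] = df[col]
        unassigned = df.loc[df["_key"].isna() | (df["_key"] == ""), "location_id"]
        if len(unassigned):
            raise LocationError(
                f"countries without {level} assignment: {sorted(unassigned.tolist())}"
            )

    grouped = df.groupby("_key", sort=True)
    agg = grouped.agg(
        member_count=("location_id", "size"),
        vlw_val=(cols[0], "sum"),
        vlw_lower=(cols[1], "sum"),
        vlw_upper=(cols[2], "sum"),
        gdp_total=("gdp_total", "sum"),
    ).reset_index(names="region_id")
    agg.insert(1, "level", level)
    for stat in ("val", "lower", "upper"):
        agg[f"pct_{stat}"] = 100.0 * agg[f"vlw_{stat}"] / agg["gdp_total"]
    return agg


def aggregate_all(valued: pd.DataFrame, hierarchy: Hierarchy,
                  discounted: bool = False) -> pd.DataFrame:
    """Stack aggregates for every level, global first (Table-1 layout)."""
    frames = [
        aggregate(valued, hierarchy, lvl, discounted=discounted)
        for lvl in ("global", "sdi_quintile", "super_region", "region")
    ]
    return pd.concat(frames, ignore_index=True)


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    """Median and quartiles with linear interpolation of order statistics."""
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def national_summary(valued: pd.DataFrame) -> dict:
    """Across-country median/IQR and extremes of VLW and %GDP.

    Covers both the undiscounted and discounted scenarios, plus the
    range of the discounting uplift. Quartiles interpolate linearly
    between order statistics.
    """
    if len(valued) == 0:
        raise EmptyInputError("national summary needs at least one country")
    names = valued["name"] if "name" in valued.columns else valued["location_id"]

    def block(col: str) -> dict:
        x = valued[col].to_numpy(float)
        med, q1, q3 = _median_iqr(x)
        imin, imax = int(np.argmin(x)), int(np.argmax(x))
        return {
            "median": med, "iqr": (q1, q3),
            "min": float(x[imin]), "min_country": str(names.iloc[imin]),
            "max": float(x[imax]), "max_country": str(names.iloc[imax]),
        }

    uplift = valued["discount_uplift_pct"].to_numpy(float)
    iu_min, iu_max = int(np.argmin(uplift)), int(np.argmax(uplift))
    return {
        "n_countries": int(len(valued)),
        "vlw": block("vlw_val"),
        "pct_gdp": block("pct_val"),
        "vlw_discounted": block("vlw_disc_val"),
        "pct_gdp_discounted": block("pct_disc_val"),
        "discount_uplift_pct": {
            "min": float(uplift[iu_min]), "min_country": str(names.iloc[iu_min]),
            "max": float(uplift[iu_max]), "max_country": str(names.iloc[iu_max]),
        },
    }


def aggregates_to_records(agg: pd.DataFrame) -> list[RegionAggregate]:
    return [
        RegionAggregate(
            region_id=r.region_id,
            level=r.level,
            member_count=int(r.member_count),
            vlw=(r.vlw_val, r.vlw_lower, r.vlw_upper),
            gdp_total=r.gdp_total,
            pct_gdp=(r.pct_val, r.pct_lower, r.pct_upper),
        )
        for r in agg.itertuples(index=False)
    ]


def aggregates_table(agg: pd.DataFrame, precision: int = 2) -> pd.DataFrame:
    """Region table with monetary columns in millions (Table-1 style)."""
    out = agg[["region_id", "level", "member_count"]].copy()
    for stat in ("val", "lower", "upper"):
        out[f"vlw_{stat}"] = (agg[f"vlw_{stat}"] / 1e6).round(precision)
    for stat in ("val", "lower", "upper"):
        out[f"pct_{stat}"] = agg[f"pct_{stat}"].round(precision)
    return out


__all__ = [
    "RegionAggregate",
    "EmptyInputError",
    "AGG_LEVELS",
    "aggregate",
    "aggregate_all",
    "national_summary",
    "aggregates_to_records",
    "aggregates_table",
]
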