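"""Readers for GBD-results-style burden tables and WDI-style economic
tables, plus harmonization of the two against a canonical country list.

GBD results exports vary with query-tool options: columns may be
``location_name`` / ``location_id`` / plain ``location``, etc.; both
variants are accepted. Only all-ages, both-sexes rows of the requested
cause and the "Number" metric are consumed — the analysis operates on
country totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .locations import Hierarchy

ECON_INDICATORS = ("gdp_per_capita", "population", "life_expectancy", "gdp_total")

#: WDI indicator codes and common labels mapped to canonical indicator names.
INDICATOR_ALIASES = {
    "ny.gdp.pcap.pp.kd": "gdp_per_capita",
    "gdp per capita, ppp (constant 2021 international $)": "gdp_per_capita",
    "gdp_per_capita": "gdp_per_capita",
    "gdp_pc": "gdp_per_capita",
    "sp.pop.totl": "population",
    "population, total": "population",
    "population": "population",
    "sp.dyn.le00.in": "life_expectancy",
    "life expectancy at birth, total (years)": "life_expectancy",
    "life_expectancy": "life_expectancy",
    "ny.gdp.mktp.pp.kd": "gdp_total",
    "gdp, ppp (constant 2021 international $)": "gdp_total",
    "gdp_total": "gdp_total",
}

_BOTH_SEXES = {"both", "both sexes"}
_ALL_AGES = {"all ages", "all age", "age-standardized excluded", "all"}


class FormatError(ValueError):
    """A required column is absent or a cell cannot be parsed."""


class EmptySelectionError(ValueError):
    """Filtering left zero rows."""


class DuplicateLocationError(ValueError):
    """Two input rows resolve to the same canonical location."""


@dataclass(frozen=True)
class DalyRecord:
    """One location-year DALY estimate with its 95% uncertainty interval."""

    location_id: str
    year: int
    cause: str
    val: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.val <= self.upper):
            raise ValueError(
                f"DALY interval violated for {self.location_id}: "
                f"lower={self.lower}, val={self.val}, upper={self.upper}"
            )


@dataclass
class CountryEconRecord:
    """One country-year of economic inputs.

    ``provenance`` records per field whether the value was observed,
    derived (gdp_total from the per-capita × population identity) or is
    still missing and awaits imputation.
    """

    location_id: str
    year: int
    gdp_per_capita: float = math.nan
    population: float = math.nan
    gdp_total: float = math.nan
    life_expectancy: float = math.nan
    provenance: dict = field(default_factory=dict)

    LE_BOUNDS = (30.0, 95.0)

    def validate(self) -> None:
        if not math.isnan(self.gdp_per_capita) and self.gdp_per_capita <= 0:
            raise ValueError(f"{self.location_id}: gdp_per_capita must be > 0")
        if not math.isnan(self.population) and self.population <= 0:
            raise ValueError(f"{self.location_id}: population must be > 0")
        le = self.life_expectancy
        if not math.isnan(le) and not (self.LE_BOUNDS[0] <= le <= self.LE_BOUNDS[1]):
            raise ValueError(
                f"{self.location_id}: life_expectancy {le} outside {self.LE_BOUNDS}"
            )
        trio = (self.gdp_per_capita, self.population, self.gdp_total)
        if all(self.provenance.get(f) == "observed" for f in
               ("gdp_per_capita", "population", "gdp_total")) and all(
                   not math.isnan(v) for v in trio):
            rel = abs(self.gdp_total - self.gdp_per_capita * self.population) / self.gdp_total
            if rel > 0.05:
                raise ValueError(
                    f"{self.location_id}: gdp_total inconsistent with "
                    f"gdp_per_capita × population (relative gap {rel:.3f})"
                )

    @property
    def missing_fields(self) -> list[str]:
        return [
            f for f in ("gdp_per_capita", "population", "gdp_total", "life_expectancy")
            if math.isnan(getattr(self, f))
        ]


def _pick_column(df: pd.DataFrame, stem: str) -> str | None:
    """GBD exports name columns ``<stem>``, ``<stem>_name`` or ``<stem>_id``."""
    for cand in (f"{stem}_name", stem, f"{stem}_id"):
        if cand in df.columns:
            return cand
    return None


def read_gbd_daly(
    path: str | Path,
    cause_filter: str = "colorectal",
    metric_filter: str = "Number",
) -> tuple[list[DalyRecord], pd.DataFrame]:
    """Read a GBD-results CSV and return (records, rejection report).

    Keeps rows whose cause contains *cause_filter* (case-insensitive),
    whose metric equals *metric_filter*, and that are both-sexes /
    all-ages totals (sex/age columns, if present, are filtered; their
    absence means the export is already a total). Rows violating
    lower ≤ val ≤ upper are not returned; they appear in the rejection
    report with a reason.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]

    cols = {}
    for stem in ("location", "cause", "metric", "year", "val", "upper", "lower"):
        col = _pick_column(df, stem)
        if col is None:
            raise FormatError(f"missing required column for {stem!r}")
        cols[stem] = col

    mask = df[cols["cause"]].astype(str).str.lower().str.contains(cause_filter.lower())
    mask &= df[cols["metric"]].astype(str).str.lower() == metric_filter.lower()
    sex_col = _pick_column(df, "sex")
    if sex_col is not None and df[sex_col].dtype == object:
        mask &= df[sex_col].astype(str).str.lower().isin(_BOTH_SEXES)
    age_col = _pick_column(df, "age")
    if age_col is not None and df[age_col].dtype == object:
        mask &= df[age_col].astype(str).str.lower().isin(_ALL_AGES)

    sel = df.loc[mask]
    if sel.empty:
        raise EmptySelectionError(
            f"no rows match cause~{cause_filter!r}, metric={metric_filter!r}"
        )

    records: list[DalyRecord] = []
    rejected: list[dict] = []
    for row in sel.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(sel.columns, row))
        try:
            val = float(r[cols["val"]])
            lower = float(r[cols["lower"]])
            upper = float(r[cols["upper"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"unparseable DALY value in row {r}") from exc
        loc = str(r[cols["location"]])
        year = int(r[cols["year"]])
        cause = str(r[cols["cause"]])
        if not (0 <= lower <= val <= upper):
            rejected.append(
                {"location": loc, "year": year, "val": val, "lower": lower,
                 "upper": upper, "reason": "interval ordering violated"}
            )
            continue
        records.append(DalyRecord(loc, year, cause, val, lower, upper))

    report = pd.DataFrame(
        rejected, columns=["location", "year", "val", "lower", "upper", "reason"]
    )
    return records, report


def _econ_is_long(df: pd.DataFrame) -> bool:
    low = {c.lower() for c in df.columns}
    return {"indicator", "value"} <= low and ("year" in low)


def read_econ(
    path: str | Path,
    year: int,
    layout: str = "auto",
) -> list[CountryEconRecord]:
    """Read a WDI-style economic table; one record per country for *year*.

    Long layout has columns (country, indicator, year, value); wide layout
    has (country, indicator, <year>, <year>, ...). ``gdp_total`` is filled
    from gdp_per_capita × population when absent (provenance "derived").
    Countries missing both GDP measures are emitted with NaN fields
    flagged for downstream imputation rather than rejected.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if layout == "auto":
        layout = "long" if _econ_is_long(df) else "wide"

    country_col = next((c for c in ("country", "location", "location_name", "location_id")
                        if c in df.columns), None)
    if country_col is None:
        raise FormatError("missing country/location column in economic table")
    if "indicator" not in df.columns:
        raise FormatError("missing 'indicator' column in economic table")

    if layout == "long":
        sub = df[df["year"].astype(int) == int(year)]
        value_col = "value"
    else:
        ycol = str(year)
        if ycol not in df.columns:
            raise FormatError(f"wide economic table has no column for year {year}")
        sub = df
        value_col = ycol

    out: dict[str, CountryEconRecord] = {}
    for row in sub.itertuples(index=False):
        r = dict(zip(sub.columns, row))
        ind = INDICATOR_ALIASES.get(str(r["indicator"]).strip().lower())
        if ind is None:
            continue
        raw = r[value_col]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() in ("", ".."):
            continue
        try:
            value = float(raw)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"unparseable value {raw!r} for {r[country_col]}/{ind}") from exc
        loc = str(r[country_col])
        rec = out.setdefault(loc, CountryEconRecord(location_id=loc, year=int(year)))
        setattr(rec, ind, value)
        rec.provenance[ind] = "observed"

    for rec in out.values():
        if math.isnan(rec.gdp_total) and not math.isnan(rec.gdp_per_capita) and not math.isnan(rec.population):
            rec.gdp_total = rec.gdp_per_capita * rec.population
            rec.provenance["gdp_total"] = "derived"
        for f in rec.missing_fields:
            rec.provenance.setdefault(f, "missing")
        rec.validate()

    return [out[k] for k in sorted(out)]


def read_econ_panel(path: str | Path) -> pd.DataFrame:
    """Read a long WDI-style table as a normalized multi-year panel.

    Returns columns (location_id, indicator, year, value) with canonical
    indicator names; rows with unrecognized indicators are dropped and
    missing cells kept as NaN (for interpolation downstream).
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if not _econ_is_long(df):
        raise FormatError("economic panel must be long (country, indicator, year, value)")
    country_col = next((c for c in ("country", "location", "location_name", "location_id")
                        if c in df.columns), None)
    if country_col is None:
        raise FormatError("missing country/location column in economic panel")
    panel = pd.DataFrame(
        {
            "location_id": df[country_col].astype(str),
            "indicator": df["indicator"].astype(str).str.strip().str.lower()
            .map(INDICATOR_ALIASES),
            "year": df["year"].astype(int),
            "value": pd.to_numeric(df["value"].replace("..", math.nan), errors="raise"),
        }
    )
    return panel.dropna(subset=["indicator"]).reset_index(drop=True)


def econ_records_from_wide(wide: pd.DataFrame, year: int) -> list[CountryEconRecord]:
    """Build validated records from a (location × indicator) wide frame."""
    records = []
    for loc, row in wide.iterrows():
        rec = CountryEconRecord(location_id=str(loc), year=int(year))
        for ind in ECON_INDICATORS:
            if ind in row.index and not pd.isna(row[ind]):
                setattr(rec, ind, float(row[ind]))
                rec.provenance[ind] = "observed"
        if math.isnan(rec.gdp_total) and not math.isnan(rec.gdp_per_capita) \
                and not math.isnan(rec.population):
            rec.gdp_total = rec.gdp_per_capita * rec.population
            rec.provenance["gdp_total"] = "derived"
        for f in rec.missing_fields:
            rec.provenance.setdefault(f, "missing")
        rec.validate()
        records.append(rec)
    return sorted(records, key=lambda r: r.location_id)


@dataclass
class ReconciliationReport:
    """Bookkeeping from the harmonize join: nothing is dropped silently."""

    daly_only: list[str] = field(default_factory=list)
    econ_only: list[str] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)
    flagged_for_imputation: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["# Harmonization reconciliation report"]
        for label, items in (
            ("Burden source only (no economic data; flagged for imputation)", self.daly_only),
            ("Economic source only (no burden rows; dropped)", self.econ_only),
            ("Unresolved against the canonical location list (dropped)", self.unresolved),
            ("Countries with fields flagged for imputation", self.flagged_for_imputation),
        ):
            lines.append(f"{label}: {len(items)}")
            lines.extend(f"  - {i}" for i in sorted(items))
        return "\n".join(lines) + "\n"


def harmonize(
    daly: list[DalyRecord],
    econ: list[CountryEconRecord],
    hierarchy: Hierarchy,
) -> tuple[pd.DataFrame, ReconciliationReport]:
    """Join burden and economic records on the canonical location list.

    Location strings from both sources are resolved through the
    hierarchy's alias table. The output covers exactly the countries
    with burden data and (possibly imputable) economic data; countries
    whose economic record is absent entirely are kept with NaN economic
    fields and listed in the report as flagged for imputation.
    Raises :class:`DuplicateLocationError` if two raw rows resolve to
    one canonical country.
    """
    report = ReconciliationReport()

    daly_by_id: dict[str, DalyRecord] = {}
    for rec in daly:
        node = hierarchy.resolve(rec.location_id)
        if node is None:
            report.unresolved.append(rec.location_id)
            continue
        if node.location_id in daly_by_id:
            raise DuplicateLocationError(
                f"two burden rows resolve to {node.name!r} after aliasing"
            )
        daly_by_id[node.location_id] = rec

    econ_by_id: dict[str, CountryEconRecord] = {}
    for erec in econ:
        node = hierarchy.resolve(erec.location_id)
        if node is None:
            report.econ_only.append(erec.location_id)  # WDI-only aggregates etc.
            continue
        if node.location_id in econ_by_id:
            raise DuplicateLocationError(
                f"two economic rows resolve to {node.name!r} after aliasing"
            )
        econ_by_id[node.location_id] = erec

    rows = []
    for loc_id, drec in daly_by_id.items():
        node = hierarchy.node(loc_id)
        erec = econ_by_id.get(loc_id)
        if erec is None:
            report.daly_only.append(node.name)
            report.flagged_for_imputation.append(node.name)
            erec = CountryEconRecord(location_id=loc_id, year=drec.year)
        elif erec.missing_fields:
            report.flagged_for_imputation.append(node.name)
        rows.append(
            {
                "location_id": loc_id,
                "name": node.name,
                "region": node.parent_region,
                "super_region": node.parent_super_region,
                "sdi_quintile": node.sdi_quintile,
                "year": drec.year,
                "daly_val": drec.val,
                "daly_lower": drec.lower,
                "daly_upper": drec.upper,
                "gdp_per_capita": erec.gdp_per_capita,
                "population": erec.population,
                "gdp_total": erec.gdp_total,
                "life_expectancy": erec.life_expectancy,
            }
        )

    econ_only_canonical = [
        hierarchy.node(i).name for i in econ_by_id if i not in daly_by_id
    ]
    report.econ_only.extend(econ_only_canonical)

    table = pd.DataFrame(rows).sort_values("location_id", ignore_index=True)
    return table, report


def write_harmonized(table: pd.DataFrame, path: str | Path,
                     precision: int | None = None) -> None:
    """Serialize the harmonized table as text-decimal CSV.

    By default floats are written in shortest round-trip form, so
    re-reading reproduces the values bit-exactly; pass *precision* for
    fixed significant digits instead.
    """
    fmt = None if precision is None else f"%.{precision}g"
    table.to_csv(path, index=False, float_format=fmt)


def read_harmonized(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("location_id", "name", "region", "super_region", "sdi_quintile"):
        df[col] = df[col].astype(str)
    return df


__all__ = [
    "DalyRecord",
    "CountryEconRecord",
    "ReconciliationReport",
    "FormatError",
    "EmptySelectionError",
    "DuplicateLocationError",
    "read_gbd_daly",
    "read_econ",
    "read_econ_panel",
    "econ_records_from_wide",
    "harmonize",
    "write_harmonized",
    "read_harmonized",
]
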