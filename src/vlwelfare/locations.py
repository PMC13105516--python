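"""Location hierarchy for burden aggregation.

Countries nest in 21 geographic regions, which nest in 7 super-regions;
independently each country belongs to one of five sociodemographic-index
(SDI) quintiles. A :class:`LocationNode` is one node of that forest; the
:class:`Hierarchy` wraps the full country list plus name-alias resolution
so that burden and economic tables quoting slightly different country
names join on a single canonical identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SDI_QUINTILES = ("low", "low-middle", "middle", "high-middle", "high")
LEVELS = ("country", "region", "super_region", "sdi_quintile", "global")

#: Common spelling variants between GBD and WDI exports. Keys are lowercase.
DEFAULT_ALIASES = {
    "vietnam": "Viet Nam",
    "viet nam": "Viet Nam",
    "united states": "United States of America",
    "usa": "United States of America",
    "united states of america": "United States of America",
    "russia": "Russian Federation",
    "russian federation": "Russian Federation",
    "iran": "Iran (Islamic Republic of)",
    "south korea": "Republic of Korea",
    "korea, rep.": "Republic of Korea",
    "north korea": "Democratic People's Republic of Korea",
    "tanzania": "United Republic of Tanzania",
    "syria": "Syrian Arab Republic",
    "venezuela": "Venezuela (Bolivarian Republic of)",
    "bolivia": "Bolivia (Plurinational State of)",
    "laos": "Lao People's Democratic Republic",
    "moldova": "Republic of Moldova",
    "brunei": "Brunei Darussalam",
    "cape verde": "Cabo Verde",
    "turkey": "Türkiye",
    "turkiye": "Türkiye",
    "czech republic": "Czechia",
    "gambia, the": "Gambia",
    "the gambia": "Gambia",
    "egypt, arab rep.": "Egypt",
    "congo, dem. rep.": "Democratic Republic of the Congo",
    "dr congo": "Democratic Republic of the Congo",
}


class LocationError(ValueError):
    """Raised for unresolvable, duplicated or unassigned locations."""


@dataclass(frozen=True)
class LocationNode:
    """One node of the location hierarchy.

    Country nodes carry all three parent assignments (region,
    super-region, SDI quintile); higher-level nodes leave the fields
    they do not have empty.
    """

    location_id: str
    name: str
    level: str
    iso3: str | None = None
    parent_region: str | None = None
    parent_super_region: str | None = None
    sdi_quintile: str | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise LocationError(f"unknown hierarchy level {self.level!r}")
        if self.level == "country":
            missing = [
                f
                for f in ("parent_region", "parent_super_region", "sdi_quintile")
                if getattr(self, f) in (None, "")
            ]
            if missing:
                raise LocationError(
                    f"country {self.name!r} lacks hierarchy assignment: {missing}"
                )
            if self.sdi_quintile not in SDI_QUINTILES:
                raise LocationError(
                    f"country {self.name!r} has unknown SDI quintile "
                    f"{self.sdi_quintile!r}"
                )


@dataclass
class Hierarchy:
    """Canonical country universe with alias-based name resolution."""

    countries: list[LocationNode]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.location_id for c in self.countries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LocationError(f"duplicate location_id in hierarchy: {dupes}")
        # region -> super-region must be a function (many-to-one, consistent)
        seen: dict[str, str] = {}
        for c in self.countries:
            prior = seen.setdefault(c.parent_region, c.parent_super_region)
            if prior != c.parent_super_region:
                raise LocationError(
                    f"region {c.parent_region!r} mapped to two super-regions "
                    f"({prior!r}, {c.parent_super_region!r})"
                )
        self._by_name = {c.name.lower(): c for c in self.countries}
        self._by_id = {c.location_id: c for c in self.countries}
        self._by_iso3 = {c.iso3: c for c in self.countries if c.iso3}
        self._alias = {**DEFAULT_ALIASES, **{k.lower(): v for k, v in self.aliases.items()}}

    def __len__(self) -> int:
        return len(self.countries)

    def __iter__(self):
        return iter(self.countries)

    def resolve(self, name_or_id: str) -> LocationNode | None:
        """Map a raw location string to its canonical node, or None."""
        key = str(name_or_id).strip()
        if key in self._by_id:
            return self._by_id[key]
        if key in self._by_iso3:
            return self._by_iso3[key]
        low = key.lower()
        if low in self._alias:
            low = self._alias[low].lower()
        return self._by_name.get(low)

    def node(self, location_id: str) -> LocationNode:
        return self._by_id[location_id]

    def group_key(self, level: str) -> pd.Series:
        """Country-indexed Series mapping location_id to its node at *level*."""
        if level not in ("region", "super_region", "sdi_quintile", "global"):
            raise LocationError(f"cannot group at level {level!r}")
        attr = {
            "region": "parent_region",
            "super_region": "parent_super_region",
            "sdi_quintile": "sdi_quintile",
        }
        idx = [c.location_id for c in self.countries]
        if level == "global":
            return pd.Series("Global", index=idx, name="global")
        return pd.Series(
            [getattr(c, attr[level]) for c in self.countries], index=idx, name=level
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location_id": [c.location_id for c in self.countries],
                "name": [c.name for c in self.countries],
                "iso3": [c.iso3 or "" for c in self.countries],
                "region": [c.parent_region for c in self.countries],
                "super_region": [c.parent_super_region for c in self.countries],
                "sdi_quintile": [c.sdi_quintile for c in self.countries],
            }
        ).sort_values("location_id", ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, aliases: dict[str, str] | None = None) -> "Hierarchy":
        required = {"location_id", "name", "region", "super_region", "sdi_quintile"}
        missing = required - set(df.columns)
        if missing:
            raise LocationError(f"hierarchy table missing columns: {sorted(missing)}")
        nodes = [
            LocationNode(
                location_id=str(r.location_id),
                name=str(r.name),
                level="country",
                iso3=(str(r.iso3) or None) if "iso3" in df.columns and pd.notna(r.iso3) else None,
                parent_region=str(r.region),
                parent_super_region=str(r.super_region),
                sdi_quintile=str(r.sdi_quintile),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(nodes, aliases=aliases or {})


def read_hierarchy(path: str | Path, aliases: dict[str, str] | None = None) -> Hierarchy:
    """Read a hierarchy CSV (location_id, name, iso3, region, super_region, sdi_quintile)."""
    return Hierarchy.from_frame(pd.read_csv(path, dtype=str), aliases=aliases)
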