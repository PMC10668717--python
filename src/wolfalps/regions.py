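"""Country partitions and the Alpine-range polygon.

The monitoring standard only needs metric distances and a 10 km grid, so
synthetic study regions live on an abstract planar LAEA-like plane with
coordinates in kilometres. Real data with a declared projected CRS pass
through unchanged (no reprojection is performed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

__all__ = ["CountryLayout", "default_layout"]


@dataclass
class CountryLayout:
    """A partition of a planar study region into countries, plus the
    Alpine-range polygon used to restrict trend reporting.

    Coordinates are kilometres unless ``units`` says otherwise.
    """

    countries: dict[str, BaseGeometry]
    alpine_range: BaseGeometry
    units: str = "km"
    crs: str | None = None  # declared CRS for real data; None = abstract plane
    _region: BaseGeometry | None = field(default=None, repr=False)

    @property
    def region(self) -> BaseGeometry:
        if self._region is None:
            self._region = unary_union(list(self.countries.values()))
        return self._region

    def country_of(self, x: float, y: float) -> str | None:
        """Country whose polygon covers the point (ties broken by name order)."""
        from shapely.geometry import Point

        p = Point(x, y)
        for name in sorted(self.countries):
            if self.countries[name].covers(p):
                return name
        return None

    def countries_intersecting(self, geom: BaseGeometry) -> set[str]:
        """Countries whose polygon genuinely overlaps a geometry (shared
        boundaries alone do not count)."""
        out = set()
        for name, poly in self.countries.items():
            inter = poly.intersection(geom)
            if not inter.is_empty and inter.area > 0:
                out.add(name)
        return out

    def validate(self) -> None:
        """Check the country polygons partition the region without overlap."""
        names = sorted(self.countries)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                inter = self.countries[a].intersection(self.countries[b])
                if inter.area > 1e-9:
                    raise ValueError(f"country polygons overlap: {a} ∩ {b}")

    # -- GeoJSON round trip ------------------------------------------------
    def to_geojson(self) -> dict:
        features = [
            {
                "type": "Feature",
                "properties": {"country": name},
                "geometry": mapping(poly),
            }
            for name, poly in sorted(self.countries.items())
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {"role": "alpine_range"},
                "geometry": mapping(self.alpine_range),
            }
        )
        return {
            "type": "FeatureCollection",
            "properties": {"units": self.units, "crs": self.crs},
            "features": features,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, indent=1)

    @classmethod
    def from_geojson(cls, obj: dict) -> "CountryLayout":
        countries: dict[str, BaseGeometry] = {}
        alpine = None
        for feat in obj["features"]:
            props = feat.get("properties") or {}
            geom = shape(feat["geometry"])
            if props.get("role") == "alpine_range":
                alpine = geom
            elif "country" in props:
                countries[props["country"]] = geom
        if alpine is None:
            alpine = unary_union(list(countries.values()))
        meta = obj.get("properties") or {}
        return cls(
            countries=countries,
            alpine_range=alpine,
            units=meta.get("units", "km"),
            crs=meta.get("crs"),
        )

    @classmethod
    def load(cls, path) -> "CountryLayout":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


def default_layout(
    width_km: float = 600.0, height_km: float = 400.0, margin_km: float = 40.0
) -> CountryLayout:
    """Four-country quadrant layout on a rectangular study region.

    Emulates an alpine arc shared by neighbouring countries: two internal
    borders cross the region so territories near them become transboundary.
    The Alpine range is the region minus a peripheral margin, so occurrence
    beyond the range can exist without entering the trend.
    """
    from shapely.geometry import box

    w2, h2 = width_km / 2.0, height_km / 2.0
    countries = {
        "IT": box(0, 0, w2, h2),
        "FR": box(0, h2, w2, height_km),
        "CH": box(w2, h2, width_km, height_km),
        "SI": box(w2, 0, width_km, h2),
    }
    alpine = box(margin_km, margin_km, width_km - margin_km, height_km - margin_km)
    return CountryLayout(countries=countries, alpine_range=alpine)
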