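"""Occurrence mapping on a 10 × 10 km reference grid.

Wolf occurrence is reported as the set of 10 × 10 km grid cells (EEA-style
reference grid, planar LAEA-like coordinates) where species presence was
confirmed within a monitoring year: at least one C1 sign, or two mutually
independent C2 signs. C3 signs never confirm a cell. The area of occurrence
is 100 km² per confirmed cell, restricted to the Alpine-range polygon when a
trend over the population's range is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.geometry.base import BaseGeometry

__all__ = [
    "CELL_SIZE_M",
    "GridCellId",
    "OccurrenceMap",
    "cell_of",
    "confirm_cells",
    "area_of_occurrence",
    "c2_signs_independent",
    "occurrence_table",
    "occurrence_geojson",
]

#: Side length of a reference-grid cell, in metres.
CELL_SIZE_M = 10_000.0


@dataclass(frozen=True, order=True)
class GridCellId:
    """A 10 km reference-grid cell, identified by floor-division indices.

    The cell covers the half-open square
    ``[10 km·e, 10 km·(e+1)) × [10 km·n, 10 km·(n+1))``.
    """

    easting_index: int
    northing_index: int

    def __str__(self) -> str:
        return f"10kmE{self.easting_index}N{self.northing_index}"

    @property
    def polygon(self) -> Polygon:
        """Cell square in metres."""
        e, n = self.easting_index, self.northing_index
        return box(e * CELL_SIZE_M, n * CELL_SIZE_M, (e + 1) * CELL_SIZE_M, (n + 1) * CELL_SIZE_M)

    @property
    def center_m(self) -> tuple[float, float]:
        return (
            (self.easting_index + 0.5) * CELL_SIZE_M,
            (self.northing_index + 0.5) * CELL_SIZE_M,
        )


def cell_of(x_m: float, y_m: float) -> GridCellId:
    """Grid cell containing a point given in metres.

    Boundary points belong to the cell whose lower-left corner they touch
    (half-open convention), so (10 000, 0) is in E1N0, not E0N0.
    """
    return GridCellId(int(np.floor(x_m / CELL_SIZE_M)), int(np.floor(y_m / CELL_SIZE_M)))


@dataclass
class OccurrenceMap:
    """Confirmed occurrence cells for one monitoring year."""

    monitoring_year: str
    confirmed_cells: set[GridCellId] = field(default_factory=set)
    supporting_evidence: dict[GridCellId, list[str]] = field(default_factory=dict)
    #: per-cell C1/C2 tallies, kept for reporting (includes unconfirmed cells)
    counts: dict[GridCellId, tuple[int, int]] = field(default_factory=dict)


def c2_signs_independent(
    date_a, xy_a, track_a, date_b, xy_b, track_b, *, min_dist_km: float = 1.0
) -> bool:
    """Decide whether two C2 signs are mutually independent.

    Two C2 signs support a cell only if they plausibly reflect separate
    detection events: they must fall on different calendar dates, or lie
    more than ``min_dist_km`` apart without sharing a track identifier.
    """
    if date_a != date_b:
        return True
    dist = float(np.hypot(xy_a[0] - xy_b[0], xy_a[1] - xy_b[1]))
    same_track = (
        track_a is not None
        and track_b is not None
        and not pd.isna(track_a)
        and not pd.isna(track_b)
        and track_a == track_b
    )
    return dist > min_dist_km and not same_track


def confirm_cells(
    classified: pd.DataFrame,
    year: str,
    *,
    coord_units: str = "km",
    min_dist_km: float = 1.0,
) -> OccurrenceMap:
    """Confirm occurrence cells for one monitoring year.

    A cell is confirmed by ≥1 C1 sign or ≥2 mutually independent C2 signs
    located in it during the monitoring year. Sign location is the recorded
    point (a track is represented by its point record).

    Parameters
    ----------
    classified
        Output of :func:`wolfalps.classification.classify_signs`.
    coord_units
        Units of the x/y columns ("km" or "m").
    """
    omap = OccurrenceMap(monitoring_year=year)
    if classified.empty:
        return omap
    scale = 1000.0 if coord_units == "km" else 1.0
    sub = classified[
        (classified["monitoring_year"] == year)
        & classified["category"].isin(["C1", "C2"])
    ]
    if sub.empty:
        return omap

    dates = pd.to_datetime(sub["date"]).dt.date
    cells = [
        cell_of(float(x) * scale, float(y) * scale)
        for x, y in zip(sub["x"], sub["y"])
    ]
    track_ids = sub["track_id"] if "track_id" in sub.columns else pd.Series(pd.NA, index=sub.index)

    by_cell: dict[GridCellId, list[int]] = {}
    for pos, cell in zip(sub.index, cells):
        by_cell.setdefault(cell, []).append(pos)

    for cell in sorted(by_cell):
        idxs = by_cell[cell]
        cats = sub.loc[idxs, "category"]
        c1 = [i for i in idxs if cats[i] == "C1"]
        c2 = [i for i in idxs if cats[i] == "C2"]
        omap.counts[cell] = (len(c1), len(c2))
        confirmed = False
        evidence: list[str] = []
        if c1:
            confirmed = True
            evidence = [str(sub.at[i, "sign_id"]) for i in c1]
        elif len(c2) >= 2:
            # any mutually independent pair suffices
            for a in range(len(c2)):
                for b in range(a + 1, len(c2)):
                    ia, ib = c2[a], c2[b]
                    if c2_signs_independent(
                        dates[ia],
                        (float(sub.at[ia, "x"]) * scale / 1000.0, float(sub.at[ia, "y"]) * scale / 1000.0),
                        track_ids[ia],
                        dates[ib],
                        (float(sub.at[ib, "x"]) * scale / 1000.0, float(sub.at[ib, "y"]) * scale / 1000.0),
                        track_ids[ib],
                        min_dist_km=min_dist_km,
                    ):
                        confirmed = True
                        break
                if confirmed:
                    break
            if confirmed:
                evidence = [str(sub.at[i, "sign_id"]) for i in c2]
        if confirmed:
            omap.confirmed_cells.add(cell)
            omap.supporting_evidence[cell] = evidence
    return omap


def area_of_occurrence(
    omap: OccurrenceMap,
    alpine_polygon: BaseGeometry | None = None,
    *,
    polygon_units: str = "km",
) -> float:
    """Area of occurrence in km²: 100 km² per confirmed in-range cell.

    A cell is in range when its *center* lies inside the Alpine polygon
    (a deterministic rule that avoids partial-intersection bookkeeping).
    With no polygon, every confirmed cell counts.
    """
    if alpine_polygon is None:
        return 100.0 * len(omap.confirmed_cells)
    if alpine_polygon.is_empty:
        raise ValueError("alpine polygon is empty")
    scale = 1000.0 if polygon_units == "km" else 1.0
    n = sum(
        1
        for cell in omap.confirmed_cells
        if alpine_polygon.covers(Point(cell.center_m[0] / scale, cell.center_m[1] / scale))
    )
    return 100.0 * n


def occurrence_table(omap: OccurrenceMap) -> pd.DataFrame:
    """Tabular export: one row per cell with any C1/C2 sign."""
    rows = []
    for cell in sorted(omap.counts):
        n_c1, n_c2 = omap.counts[cell]
        rows.append(
            {
                "cell_id": str(cell),
                "monitoring_year": omap.monitoring_year,
                "n_C1": n_c1,
                "n_C2": n_c2,
                "confirmed": cell in omap.confirmed_cells,
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "monitoring_year", "n_C1", "n_C2", "confirmed"])


def occurrence_geojson(omap: OccurrenceMap, *, coord_units: str = "km") -> dict:
    """Confirmed cells as a GeoJSON FeatureCollection of squares."""
    div = 1000.0 if coord_units == "km" else 1.0
    features = []
    for cell in sorted(omap.confirmed_cells):
        poly = cell.polygon
        coords = [[(x / div, y / div) for x, y in poly.exterior.coords]]
        features.append(
            {
                "type": "Feature",
                "properties": {"cell_id": str(cell), "monitoring_year": omap.monitoring_year},
                "geometry": {"type": "Polygon", "coordinates": coords},
            }
        )
    return {"type": "FeatureCollection", "features": features}
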