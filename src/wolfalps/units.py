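"""Resolution of wolf reproductive units (packs and pairs).

The population index of the monitoring standard is the number of
reproductive units — packs and pairs — not the number of individuals.
This module turns classified C1/C2 signs of one monitoring year into
resolved units:

1. :func:`cluster_signs` groups signs into candidate territories (shared
   genotypes first, then spatial proximity);
2. :func:`split_adjacent_packs` separates neighbouring packs that proximity
   merged, but only when the agreed distinguishing evidence exists
   (pedigree separation, simultaneous reproduction, telemetry);
3. :func:`classify_unit` applies the pack/pair decision rules;
4. :func:`resolve_transboundary` merges units reported on both sides of a
   national border so each is counted exactly once, labelling them TR
   (genetic match across the border) or LTR (likely transboundary from the
   spatio-temporal sign distribution);
5. :func:`summarize` produces per-country and population totals.

A territory is represented by a circle of 200 km² centred on the centroid
of the minimum convex polygon over the unit's C1–C2 sign locations.
Dispersers and solitary individuals never enter the unit counts; they are
retained separately (they still contribute to the occurrence map).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point
from shapely.geometry.base import BaseGeometry

from .grid import c2_signs_independent
from .regions import CountryLayout

__all__ = [
    "TERRITORY_AREA_KM2",
    "Territory",
    "ReproductiveUnit",
    "PopulationSummary",
    "IntegrityError",
    "cluster_signs",
    "classify_unit",
    "split_adjacent_packs",
    "resolve_transboundary",
    "resolve_units",
    "summarize",
]

#: Conventional territory representation area (km²).
TERRITORY_AREA_KM2 = 200.0


class IntegrityError(ValueError):
    """Raised when genotype bookkeeping is internally inconsistent."""


def _representation_radius(area_km2: float = TERRITORY_AREA_KM2) -> float:
    return math.sqrt(area_km2 / math.pi)


@dataclass
class Territory:
    """A candidate territory: a cluster of C1–C2 signs of one year."""

    territory_id: str
    monitoring_year: str
    signs: pd.DataFrame
    area_km2: float = TERRITORY_AREA_KM2

    @property
    def member_sign_ids(self) -> list[str]:
        return [str(s) for s in self.signs["sign_id"]]

    @property
    def genotype_labels(self) -> set[str]:
        col = self.signs.get("genotype_label")
        if col is None:
            return set()
        return set(col.dropna().astype(str))

    @property
    def pedigree_labels(self) -> set[str]:
        col = self.signs.get("pedigree_label")
        if col is None:
            return set()
        return set(col.dropna().astype(str))

    @property
    def mcp(self) -> BaseGeometry:
        """Minimum convex polygon over the sign points (may be degenerate)."""
        pts = MultiPoint([(float(x), float(y)) for x, y in zip(self.signs["x"], self.signs["y"])])
        return pts.convex_hull

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.mcp.centroid
        return (c.x, c.y)

    @property
    def radius_km(self) -> float:
        return _representation_radius(self.area_km2)

    @property
    def representation_circle(self) -> BaseGeometry:
        cx, cy = self.centroid
        return Point(cx, cy).buffer(self.radius_km, quad_segs=64)


@dataclass
class ReproductiveUnit:
    """A resolved pack or pair, counted once at the population level."""

    unit_id: str
    year: str
    status: str  # "pack" | "pair"
    territory: Territory | None = None
    countries: set[str] = field(default_factory=set)
    transboundary_status: str = "national"  # "national" | "TR" | "LTR"
    evidence_basis: str = ""
    country: str | None = None  # primary country (centroid) for national units
    country_pair: tuple[str, str] | None = None  # for TR/LTR units

    @property
    def genotype_labels(self) -> set[str]:
        return self.territory.genotype_labels if self.territory is not None else set()


# ---------------------------------------------------------------------------
# clustering


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_signs(
    classified: pd.DataFrame,
    year: str,
    *,
    linkage_km: float = 15.0,
    area_km2: float = TERRITORY_AREA_KM2,
) -> list[Territory]:
    """Cluster the C1–C2 signs of one monitoring year into territories.

    Signs sharing a genotype label are always linked (genetics overrides
    distance); remaining links join signs within ``linkage_km``; connected
    components become candidate territories. Singleton components without
    hard evidence or a genotype are dropped (a lone unconfirmed-quality
    sign cannot support a territory).
    """
    sub = classified[
        (classified["monitoring_year"] == year)
        & classified["category"].isin(["C1", "C2"])
    ].reset_index(drop=True)
    if sub.empty:
        return []

    n = len(sub)
    uf = _UnionFind(n)

    if "genotype_label" in sub.columns:
        by_geno: dict[str, list[int]] = {}
        for i, g in enumerate(sub["genotype_label"]):
            if pd.notna(g):
                by_geno.setdefault(str(g), []).append(i)
        for idxs in by_geno.values():
            for j in idxs[1:]:
                uf.union(idxs[0], j)

    xy = sub[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    for i, j in sorted(tree.query_pairs(linkage_km)):
        uf.union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)

    territories: list[Territory] = []
    for root in sorted(comps):
        idxs = comps[root]
        block = sub.iloc[idxs]
        if len(idxs) == 1:
            row = block.iloc[0]
            has_geno = "genotype_label" in block.columns and pd.notna(row.get("genotype_label"))
            if row["category"] != "C1" and not has_geno:
                continue
        tid = f"{year}-T{len(territories):03d}"
        territories.append(Territory(tid, year, block.reset_index(drop=True), area_km2=area_km2))
    return territories


# ---------------------------------------------------------------------------
# pack / pair rules


def _is_true(v) -> bool:
    return bool(v) if (v is not None and not pd.isna(v)) else False


def _reproduction_evidence(signs: pd.DataFrame) -> str | None:
    """C1 or C2 evidence that the unit reproduced this monitoring year."""
    c1 = signs[signs["category"] == "C1"]
    if "age_class" in signs.columns:
        pup_dna = c1[c1["age_class"].astype("object") == "pup"]
        if len(pup_dna):
            return "C1 pup evidence"
    if "pups_present" in signs.columns:
        if any(_is_true(v) for v in c1.get("pups_present", pd.Series(dtype=object))):
            return "C1 pup evidence"
    c2 = signs[signs["category"] == "C2"]
    howls = c2[c2["evidence_type"] == "howl"]
    if "pups_heard" in signs.columns and len(howls):
        if any(_is_true(v) for v in howls["pups_heard"]):
            return "C2 howl with pups"
    return None


def _independent_group_tracks(signs: pd.DataFrame, min_group: int = 3) -> bool:
    """≥2 mutually independent C2 tracks each showing ≥``min_group`` animals."""
    if "n_individuals" not in signs.columns:
        return False
    c2t = signs[
        (signs["category"] == "C2")
        & (signs["evidence_type"] == "track")
        & signs["n_individuals"].map(lambda v: not pd.isna(v) and float(v) >= min_group)
    ]
    if len(c2t) < 2:
        return False
    dates = pd.to_datetime(c2t["date"]).dt.date.tolist()
    xs = c2t["x"].astype(float).tolist()
    ys = c2t["y"].astype(float).tolist()
    tracks = c2t["track_id"].tolist() if "track_id" in c2t.columns else [None] * len(c2t)
    for a in range(len(c2t)):
        for b in range(a + 1, len(c2t)):
            if c2_signs_independent(
                dates[a], (xs[a], ys[a]), tracks[a], dates[b], (xs[b], ys[b]), tracks[b]
            ):
                return True
    return False


def _c1_individual_count(signs: pd.DataFrame) -> int:
    """Number of individuals confirmed by C1 (genotypes, or animals counted
    on good photo/video)."""
    c1 = signs[signs["category"] == "C1"]
    n_geno = 0
    if "genotype_label" in c1.columns:
        n_geno = c1["genotype_label"].dropna().nunique()
    n_photo = 0
    if "n_individuals" in c1.columns:
        counts = c1["n_individuals"].dropna()
        if len(counts):
            n_photo = int(counts.astype(float).max())
    return max(n_geno, n_photo)


def _pair_bond_evidence(signs: pd.DataFrame) -> bool:
    """C1 evidence that exactly one male and one female travel together:
    a good photo/video of the two, or genetic proof of the couple on one
    track or joint sampling event (same date, same place)."""
    c1 = signs[signs["category"] == "C1"]
    if "n_individuals" in c1.columns:
        media = c1[c1["evidence_type"].isin(["photo_video", "telemetry"])]
        if any(not pd.isna(v) and float(v) == 2 for v in media.get("n_individuals", [])):
            return True
    if "genotype_label" not in c1.columns:
        return False
    geno = c1[c1["genotype_label"].notna()]
    if geno["genotype_label"].nunique() < 2:
        return False
    # couple genotyped on the same track
    if "track_id" in geno.columns:
        on_track = geno[geno["track_id"].notna()]
        per_track = on_track.groupby("track_id")["genotype_label"].nunique()
        if (per_track >= 2).any():
            return True
    # joint sampling event: both genotypes within 2 km on the same day
    dates = pd.to_datetime(geno["date"]).dt.date
    for d in sorted(set(dates)):
        day = geno[(dates == d).to_numpy()]
        if day["genotype_label"].nunique() >= 2:
            xy = day[["x", "y"]].to_numpy(dtype=float)
            dist = np.hypot(
                xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1]
            )
            gl = day["genotype_label"].to_numpy()
            close = (dist <= 2.0) & (gl[:, None] != gl[None, :])
            if close.any():
                return True
    return False


def classify_unit(territory: Territory) -> tuple[str, str]:
    """Apply the pack/pair decision rules to a candidate territory.

    Returns ``(status, evidence_basis)`` with status one of ``"pack"``,
    ``"pair"``, ``"none"``.

    A *pack* requires reproduction confirmed by one C1 or C2, or at least
    two independent C2 tracks of ≥3 animals traveling together, or ≥3
    individuals confirmed by C1. A *pair* requires C1 proof of exactly one
    male and one female bonding (photo/video of the two, or genetic proof
    of the couple). Reproduction evidence dominates, so a territory meeting
    both rules is a pack. Anything else is a disperser or solitary animal
    and is excluded from unit counts.
    """
    signs = territory.signs
    repro = _reproduction_evidence(signs)
    if repro is not None:
        return "pack", repro
    n_c1 = _c1_individual_count(signs)
    if n_c1 >= 3:
        return "pack", "≥3 individuals by C1"
    if _independent_group_tracks(signs):
        return "pack", "2 independent C2 tracks of ≥3"
    # pair: exactly one male + one female among adult genotypes
    sexes: dict[str, str] = {}
    if "genotype_label" in signs.columns:
        c1 = signs[(signs["category"] == "C1") & signs["genotype_label"].notna()]
        for _, row in c1.iterrows():
            age = row.get("age_class")
            if not pd.isna(age) and str(age) == "pup":
                continue
            sex = row.get("genotype_sex")
            sexes[str(row["genotype_label"])] = (
                str(sex) if (sex is not None and not pd.isna(sex)) else "?"
            )
    if len(sexes) == 2 and sorted(sexes.values()) == ["F", "M"] and _pair_bond_evidence(signs):
        return "pair", "C1 male+female bonding"
    return "none", "no confirming evidence"


# ---------------------------------------------------------------------------
# adjacent-pack splitting


def split_adjacent_packs(
    territories: list[Territory], *, min_support: int = 1
) -> list[Territory]:
    """Separate neighbouring units that spatial linkage merged.

    Two adjacent packs count as two units only when they can be clearly
    distinguished: genetic pedigree identification with space separation,
    simultaneous proof of reproduction in each, or telemetry separation.
    A merged cluster containing several pedigree labels is partitioned by
    pedigree (non-genotyped signs join the nearest pedigree subgroup);
    subgroups lacking any distinguishing evidence stay merged.
    """
    out: list[Territory] = []
    counter = 0
    for terr in territories:
        pedigrees = sorted(terr.pedigree_labels)
        if len(pedigrees) <= 1:
            out.append(terr)
            continue
        signs = terr.signs
        ped = signs.get("pedigree_label")
        groups: dict[str, list[int]] = {p: [] for p in pedigrees}
        centroids: dict[str, np.ndarray] = {}
        for p in pedigrees:
            mask = (ped.astype("object") == p).fillna(False).to_numpy()
            groups[p] = list(np.flatnonzero(mask))
            centroids[p] = signs.iloc[groups[p]][["x", "y"]].to_numpy(dtype=float).mean(axis=0)
        unassigned = [i for i in range(len(signs)) if pd.isna(ped.iloc[i])]
        for i in unassigned:
            xy = signs.iloc[i][["x", "y"]].to_numpy(dtype=float)
            best = min(pedigrees, key=lambda p: float(np.hypot(*(centroids[p] - xy))))
            groups[best].append(i)

        # distinguishing evidence: each subgroup needs its own pedigree
        # genotypes (given) plus enough support; otherwise merge into the
        # nearest distinguished subgroup.
        sub_terrs: list[pd.DataFrame] = []
        for p in pedigrees:
            block = signs.iloc[sorted(groups[p])].reset_index(drop=True)
            if len(block) >= min_support:
                sub_terrs.append(block)
        if len(sub_terrs) <= 1:
            out.append(terr)
            continue
        for block in sub_terrs:
            tid = f"{terr.territory_id}.{counter}"
            counter += 1
            out.append(Territory(tid, terr.monitoring_year, block, area_km2=terr.area_km2))
    return out


# ---------------------------------------------------------------------------
# transboundary resolution


def _unit_countries(unit: ReproductiveUnit, layout: CountryLayout | None) -> set[str]:
    countries = set(unit.countries)
    if unit.territory is not None:
        if "country" in unit.territory.signs.columns:
            countries |= set(unit.territory.signs["country"].dropna().astype(str))
        if layout is not None:
            countries |= layout.countries_intersecting(unit.territory.representation_circle)
    return countries


def _sign_countries(unit: ReproductiveUnit) -> set[str]:
    if unit.territory is None:
        return set(unit.countries)
    col = unit.territory.signs.get("country")
    return set(col.dropna().astype(str)) if col is not None else set()


def _genetic_countries(unit: ReproductiveUnit) -> set[str]:
    """Countries where this unit's members were genetically documented."""
    if unit.territory is None:
        return set()
    signs = unit.territory.signs
    if "genotype_label" not in signs.columns or "country" not in signs.columns:
        return set()
    geno = signs[signs["genotype_label"].notna()]
    return set(geno["country"].dropna().astype(str))


def _merge_units(a: ReproductiveUnit, b: ReproductiveUnit) -> ReproductiveUnit:
    if a.territory is not None and b.territory is not None:
        signs = pd.concat([a.territory.signs, b.territory.signs], ignore_index=True)
        signs = signs.drop_duplicates(subset="sign_id", ignore_index=True)
        terr = Territory(a.territory.territory_id, a.territory.monitoring_year, signs,
                         area_km2=a.territory.area_km2)
    else:
        terr = a.territory or b.territory
    status = "pack" if "pack" in (a.status, b.status) else a.status
    return ReproductiveUnit(
        unit_id=min(a.unit_id, b.unit_id),
        year=a.year,
        status=status,
        territory=terr,
        countries=a.countries | b.countries,
        evidence_basis=a.evidence_basis or b.evidence_basis,
    )


def resolve_transboundary(
    units: list[ReproductiveUnit],
    layout: CountryLayout | None = None,
    *,
    border_window_km: float = 10.0,
) -> list[ReproductiveUnit]:
    """Resolve cross-border units so each is counted exactly once.

    Units of the same year sharing a genotype label (the same animals
    reported in two national datasets) are merged. A merged or single unit
    is labelled ``TR`` when its members were genetically documented in two
    countries; ``LTR`` when its representation circle crosses a border and
    its signs occur within ``border_window_km`` of that border on both
    sides, without cross-border genetic confirmation; ``national``
    otherwise. Idempotent: resolving a resolved list changes nothing.
    """
    units = sorted(units, key=lambda u: u.unit_id)

    # integrity: a genotype may not be claimed from more than two countries
    claims: dict[str, set[str]] = {}
    for u in units:
        for g in sorted(u.genotype_labels):
            claims.setdefault(g, set()).update(_genetic_countries(u) or _sign_countries(u))
    for g, cs in claims.items():
        if len(cs) > 2:
            raise IntegrityError(
                f"genotype {g} claimed from {len(cs)} countries: {sorted(cs)}"
            )

    # merge duplicate reports by shared genotype (within a year)
    merged: list[ReproductiveUnit] = []
    for unit in units:
        target = None
        for m in merged:
            if m.year == unit.year and (m.genotype_labels & unit.genotype_labels):
                target = m
                break
        if target is None:
            merged.append(unit)
        else:
            merged[merged.index(target)] = _merge_units(target, unit)

    out: list[ReproductiveUnit] = []
    for unit in merged:
        countries = _unit_countries(unit, layout)
        genetic = _genetic_countries(unit)
        sign_countries = _sign_countries(unit)
        status = "national"
        pair: tuple[str, str] | None = None
        if len(genetic) >= 2:
            status = "TR"
            pair = tuple(sorted(genetic)[:2])  # type: ignore[assignment]
        elif layout is not None and unit.territory is not None:
            circle = unit.territory.representation_circle
            crossed = sorted(layout.countries_intersecting(circle))
            if len(crossed) >= 2 and len(sign_countries) >= 2:
                both = sorted(sign_countries & set(crossed))
                if len(both) >= 2:
                    a, b = both[0], both[1]
                    border = layout.countries[a].boundary.intersection(
                        layout.countries[b].boundary
                    )
                    if not border.is_empty:
                        near = _signs_near_border_both_sides(
                            unit, a, b, border, border_window_km
                        )
                        if near:
                            status = "LTR"
                            pair = (a, b)
        elif layout is None and len(sign_countries) >= 2:
            # no geometry available: fall back to the sign distribution
            status = "LTR"
            pair = tuple(sorted(sign_countries)[:2])  # type: ignore[assignment]

        country = unit.country
        if country is None:
            if unit.territory is not None and layout is not None:
                cx, cy = unit.territory.centroid
                country = layout.country_of(cx, cy)
            elif len(countries) == 1:
                country = next(iter(countries))
        out.append(
            ReproductiveUnit(
                unit_id=unit.unit_id,
                year=unit.year,
                status=unit.status,
                territory=unit.territory,
                countries=countries,
                transboundary_status=status,
                evidence_basis=unit.evidence_basis,
                country=country,
                country_pair=pair or unit.country_pair,
            )
        )
    return out


def _signs_near_border_both_sides(
    unit: ReproductiveUnit, a: str, b: str, border, window_km: float
) -> bool:
    signs = unit.territory.signs
    near = {a: False, b: False}
    for _, row in signs.iterrows():
        c = row.get("country")
        if c not in near or near[c]:
            continue
        if border.distance(Point(float(row["x"]), float(row["y"]))) <= window_km:
            near[c] = True
    return near[a] and near[b]


# ---------------------------------------------------------------------------
# summaries


@dataclass
class PopulationSummary:
    """Per-country and total reproductive-unit counts for one year."""

    year: str
    national: dict[str, dict[str, int]]  # country -> {"packs": n, "pairs": n}
    transboundary: dict[str, dict[str, int]]  # "A–B" -> {"packs": n, "pairs": n}
    total_packs: int
    total_pairs: int
    total_units: int
    pair_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for country in sorted(self.national):
            d = self.national[country]
            rows.append({"year": self.year, "scope": country, "packs": d["packs"], "pairs": d["pairs"]})
        for pair in sorted(self.transboundary):
            d = self.transboundary[pair]
            rows.append({"year": self.year, "scope": pair, "packs": d["packs"], "pairs": d["pairs"]})
        rows.append(
            {"year": self.year, "scope": "TOTAL", "packs": self.total_packs, "pairs": self.total_pairs}
        )
        return pd.DataFrame(rows, columns=["year", "scope", "packs", "pairs"])


def summarize(units: list[ReproductiveUnit], year: str) -> PopulationSummary:
    """Aggregate resolved units into a population summary.

    Each transboundary (TR/LTR) unit is listed under its country pair and
    added exactly once to the totals; national units are listed under their
    country. The pair fraction is pairs / all units.
    """
    national: dict[str, dict[str, int]] = {}
    transboundary: dict[str, dict[str, int]] = {}
    total_packs = total_pairs = 0
    for unit in units:
        if unit.year != year:
            continue
        if unit.status not in ("pack", "pair"):
            continue
        key_field = "packs" if unit.status == "pack" else "pairs"
        if unit.transboundary_status in ("TR", "LTR"):
            if unit.country_pair is not None:
                label = "–".join(sorted(unit.country_pair))
            else:
                label = "–".join(sorted(unit.countries)[:2])
            transboundary.setdefault(label, {"packs": 0, "pairs": 0})[key_field] += 1
        else:
            country = unit.country or (sorted(unit.countries)[0] if unit.countries else "?")
            national.setdefault(country, {"packs": 0, "pairs": 0})[key_field] += 1
        if unit.status == "pack":
            total_packs += 1
        else:
            total_pairs += 1
    total_units = total_packs + total_pairs
    pair_fraction = total_pairs / total_units if total_units else 0.0
    return PopulationSummary(
        year=year,
        national=national,
        transboundary=transboundary,
        total_packs=total_packs,
        total_pairs=total_pairs,
        total_units=total_units,
        pair_fraction=pair_fraction,
    )


def resolve_units(
    classified: pd.DataFrame,
    year: str,
    layout: CountryLayout | None = None,
    *,
    linkage_km: float = 15.0,
    area_km2: float = TERRITORY_AREA_KM2,
) -> tuple[list[ReproductiveUnit], list[Territory]]:
    """Full unit-resolution chain for one monitoring year.

    Returns ``(resolved units, non-unit territories)`` — the latter are
    disperser/solitary clusters kept for occurrence but never counted.
    """
    territories = cluster_signs(classified, year, linkage_km=linkage_km, area_km2=area_km2)
    territories = split_adjacent_packs(territories)
    units: list[ReproductiveUnit] = []
    others: list[Territory] = []
    for terr in territories:
        status, basis = classify_unit(terr)
        if status == "none":
            others.append(terr)
            continue
        units.append(
            ReproductiveUnit(
                unit_id=terr.territory_id,
                year=year,
                status=status,
                territory=terr,
                evidence_basis=basis,
            )
        )
    resolved = resolve_transboundary(units, layout)
    return resolved, others
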