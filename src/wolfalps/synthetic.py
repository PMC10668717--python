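"""Synthetic multi-country wolf recolonization datasets with ground truth.

Emulates the data-generating process the monitoring standard assumes: a
small founding nucleus of territorial reproductive units (packs and pairs)
grows roughly exponentially, new pairs settle at dispersal-kernel distances
from existing territories (occasionally far away, acting as stepping
stones for later colonization), pairs convert to packs on first
reproduction, and every unit sheds signs of presence — DNA samples,
photos, tracks, scats, howls, depredations — with imperfect detection and
genotyping. Dispersing individuals leave signs outside territories, and
unverifiable noise signs (attribute-poor by construction, so they can
never reach C1) are scattered over the study region.

Everything is deterministic given the configuration seed, and the true
unit behind every sign is emitted in a separate linkage table so the whole
downstream pipeline can be scored against ground truth.

Coordinates are planar kilometres on an abstract LAEA-like plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification import monitoring_year_label
from .regions import CountryLayout, default_layout

__all__ = [
    "SimulationConfig",
    "TrueUnit",
    "CapacityError",
    "simulate_population",
    "generate_signs",
    "truth_to_frame",
    "score_recovery",
]


class CapacityError(RuntimeError):
    """The study region cannot hold the requested number of territories."""


#: expected signs per unit-year, by evidence class
DEFAULT_DETECTION_RATES = {
    "dna_sample": 6.0,
    "photo_video": 2.5,
    "track": 3.0,
    "scat": 2.0,
    "howl": 1.5,
    "kill": 1.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic recolonization process.

    ``growth_rate`` is the expected yearly multiplier of the unit count;
    it is realised as a branching process in which each unit survives with
    probability ``survival`` and founds one new pair with probability
    ``growth_rate − survival``. ``pair_fraction`` is the target share of
    pairs among units; the first-year reproduction probability is solved
    from it (see :meth:`first_year_repro_prob`).
    """

    seed: int = 0
    n_years: int = 10
    initial_units: int = 4
    growth_rate: float = 1.22
    pair_fraction: float = 0.15
    territory_area_km2: float = 200.0
    dispersal_scale_km: float = 40.0
    long_range_fraction: float = 0.05
    survival: float = 0.95
    repro_prob: float = 0.9  # pair → pack conversion after the first year
    pack_repro_prob: float = 0.9  # yearly reproduction of established packs
    detection_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_RATES)
    )
    genotyping_success: float = 0.9
    noise_sign_rate: float = 0.2  # signs per 100 km² per year
    disperser_rate: float = 0.3  # dispersers per unit per year
    start_year: int = 2005
    layout: CountryLayout = field(default_factory=default_layout)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pair_fraction <= 1.0:
            raise ValueError("pair_fraction must be in [0, 1]")
        if not 0.0 <= self.genotyping_success <= 1.0:
            raise ValueError("genotyping_success must be in [0, 1]")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if any(v < 0 for v in self.detection_rates.values()) or self.noise_sign_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.founding_prob <= 1.0:
            raise ValueError(
                "growth_rate − survival must be a probability; got "
                f"{self.founding_prob:.3f}"
            )

    @property
    def founding_prob(self) -> float:
        return self.growth_rate - self.survival

    @property
    def territory_radius_km(self) -> float:
        return math.sqrt(self.territory_area_km2 / math.pi)

    @property
    def min_spacing_km(self) -> float:
        """Minimum distance between territory centers (non-overlap)."""
        return 2.0 * self.territory_radius_km

    def first_year_repro_prob(self) -> float:
        """Probability that a newly founded pair reproduces already in its
        founding year, solved so the stationary pair share equals
        ``pair_fraction`` under the configured demography."""
        p, s, lam, q = self.founding_prob, self.survival, self.growth_rate, self.repro_prob
        if p <= 0:
            return 0.0
        rho = 1.0 - self.pair_fraction * (lam - s * (1.0 - q)) / p
        return float(min(1.0, max(0.0, rho)))


@dataclass
class TrueUnit:
    """Ground-truth state of one reproductive unit in one monitoring year."""

    unit_id: str
    year: str
    status: str  # "pack" | "pair"
    center: tuple[float, float]
    member_genotypes: tuple[str, ...]  # adults + this year's pups, sorted
    member_info: dict[str, tuple[str, str]]  # genotype -> (sex, age_class)
    countries_overlapped: frozenset[str]
    reproduced_this_year: bool


@dataclass
class _LiveUnit:
    unit_id: str
    center: tuple[float, float]
    adults: dict[str, str]  # genotype -> sex
    founded_year: int
    is_pack: bool = False


def _uniform_in_disk(rng: np.random.Generator, center, radius: float):
    r = radius * math.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return (center[0] + r * math.cos(theta), center[1] + r * math.sin(theta))


def _point_in_region(layout: CountryLayout, p) -> bool:
    from shapely.geometry import Point

    return layout.region.covers(Point(p[0], p[1]))


def _place_center(
    rng: np.random.Generator,
    layout: CountryLayout,
    existing: list[tuple[float, float]],
    config: SimulationConfig,
    origin: tuple[float, float] | None,
    max_tries: int = 100,
) -> tuple[float, float] | None:
    minx, miny, maxx, maxy = layout.region.bounds
    for _ in range(max_tries):
        if origin is None or rng.uniform() < config.long_range_fraction:
            cand = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        else:
            dist = rng.exponential(config.dispersal_scale_km) + config.min_spacing_km
            theta = rng.uniform(0.0, 2.0 * math.pi)
            cand = (origin[0] + dist * math.cos(theta), origin[1] + dist * math.sin(theta))
        if not _point_in_region(layout, cand):
            continue
        if all(
            math.hypot(cand[0] - e[0], cand[1] - e[1]) >= config.min_spacing_km
            for e in existing
        ):
            return cand
    return None


def simulate_population(config: SimulationConfig) -> list[list[TrueUnit]]:
    """Run the branching recolonization process.

    Returns one list of :class:`TrueUnit` per monitoring year. Each unit
    persists with probability ``survival`` and founds one new pair with
    probability ``growth_rate − survival``, so the expected yearly
    multiplier of the unit count is ``growth_rate``. New pairs settle at
    dispersal-kernel distances from a random existing unit, with a small
    long-range uniform component creating stepping stones; territory
    centers keep a minimum spacing so territories do not overlap.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    geno_counter = 0
    unit_counter = 0

    def new_genotype(sex: str) -> str:
        nonlocal geno_counter
        geno_counter += 1
        return f"G{geno_counter:05d}{sex}"

    def new_unit(center, year_idx: int) -> _LiveUnit:
        nonlocal unit_counter
        unit_counter += 1
        adults = {new_genotype("M"): "M", new_genotype("F"): "F"}
        return _LiveUnit(f"U{unit_counter:04d}", center, adults, year_idx)

    # founding nucleus in the south-west corner of the region
    minx, miny, maxx, maxy = layout.region.bounds
    source = (minx + 0.2 * (maxx - minx), miny + 0.25 * (maxy - miny))
    live: list[_LiveUnit] = []
    centers: list[tuple[float, float]] = []
    for _ in range(config.initial_units):
        c = _place_center(rng, layout, centers, config, origin=source, max_tries=500)
        if c is None:
            raise CapacityError(
                f"region too small to place {config.initial_units} territories "
                f"with spacing {config.min_spacing_km:.1f} km"
            )
        centers.append(c)
        live.append(new_unit(c, 0))

    rho = config.first_year_repro_prob()
    from shapely.geometry import Point

    yearly: list[list[TrueUnit]] = []
    for t in range(config.n_years):
        label = monitoring_year_label(config.start_year + t)
        rows: list[TrueUnit] = []
        for u in live:
            # reproduction this monitoring year
            if u.is_pack:
                reproduced = rng.uniform() < config.pack_repro_prob
            else:
                p_rep = rho if u.founded_year == t else config.repro_prob
                reproduced = rng.uniform() < p_rep
            pups: dict[str, str] = {}
            if reproduced:
                u.is_pack = True
                n_pups = 2 + rng.poisson(1.5)
                for _ in range(n_pups):
                    sex = "M" if rng.uniform() < 0.5 else "F"
                    pups[new_genotype(sex)] = sex
            members = dict(u.adults)
            info = {g: (s, "adult") for g, s in u.adults.items()}
            for g, s in pups.items():
                members[g] = s
                info[g] = (s, "pup")
            circle = Point(u.center).buffer(config.territory_radius_km, quad_segs=32)
            countries = frozenset(layout.countries_intersecting(circle))
            rows.append(
                TrueUnit(
                    unit_id=u.unit_id,
                    year=label,
                    status="pack" if u.is_pack else "pair",
                    center=u.center,
                    member_genotypes=tuple(sorted(members)),
                    member_info=info,
                    countries_overlapped=countries,
                    reproduced_this_year=reproduced,
                )
            )
            # one pup per litter may be retained as a future adult
            if pups and len(u.adults) < 5:
                keep = sorted(pups)[0]
                u.adults[keep] = pups[keep]
        yearly.append(rows)

        if t == config.n_years - 1:
            break

        # transition to next year: survival then founding
        survivors = [u for u in live if rng.uniform() < config.survival]
        founders = [u for u in live if rng.uniform() < config.founding_prob]
        centers = [u.center for u in survivors]
        new_units: list[_LiveUnit] = []
        for parent in founders:
            c = _place_center(rng, layout, centers, config, origin=parent.center)
            if c is None:
                continue  # region saturated around this parent
            centers.append(c)
            new_units.append(new_unit(c, t + 1))
        live = survivors + new_units
    return yearly


def truth_to_frame(yearly: list[list[TrueUnit]]) -> pd.DataFrame:
    """Flatten ground truth into one row per unit-year."""
    rows = []
    for year_units in yearly:
        for u in year_units:
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "year": u.year,
                    "status": u.status,
                    "center_x": u.center[0],
                    "center_y": u.center[1],
                    "n_members": len(u.member_genotypes),
                    "member_genotypes": ";".join(u.member_genotypes),
                    "countries": ";".join(sorted(u.countries_overlapped)),
                    "reproduced": u.reproduced_this_year,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "unit_id", "year", "status", "center_x", "center_y",
            "n_members", "member_genotypes", "countries", "reproduced",
        ],
    )


# ---------------------------------------------------------------------------
# sign generation


def _random_date(rng: np.random.Generator, year_label: str) -> str:
    from .classification import parse_monitoring_year

    start = pd.Timestamp(year=parse_monitoring_year(year_label), month=5, day=1)
    return (start + pd.Timedelta(days=int(rng.integers(0, 365)))).date().isoformat()


def generate_signs(
    yearly: list[list[TrueUnit]], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the observable sign table from ground truth.

    Per unit-year, counts of each evidence class are Poisson at the
    configured detection rates and placed uniformly in the territory
    circle; DNA samples carry genotype labels with probability
    ``genotyping_success`` (pedigree label = the social unit, as resolved
    by the genetics laboratory). Dispersers leave tracks and occasional
    DNA outside territories; noise signs are attribute-poor so they can
    never be classified C1. Returns ``(signs, links)`` where ``links``
    maps each sign to its true source (``unit:<id>``, ``disperser:<id>``
    or ``noise``) — ground truth lives only in the second table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    layout = config.layout
    radius = config.territory_radius_km
    rates = {**DEFAULT_DETECTION_RATES, **config.detection_rates}
    minx, miny, maxx, maxy = layout.region.bounds
    region_area = layout.region.area

    signs: list[dict] = []
    links: list[dict] = []
    sign_counter = 0
    track_counter = 0
    disp_counter = 0

    def add_sign(year, source, xy, etype, **attrs):
        nonlocal sign_counter
        sign_counter += 1
        sid = f"S{sign_counter:06d}"
        country = layout.country_of(xy[0], xy[1])
        signs.append(
            {
                "sign_id": sid,
                "date": attrs.pop("date", None) or _random_date(rng, year),
                "x": round(xy[0], 4),
                "y": round(xy[1], 4),
                "country": country,
                "evidence_type": etype,
                **attrs,
            }
        )
        links.append({"sign_id": sid, "source": source, "year": year})
        return sid

    def point_in_territory(center):
        for _ in range(50):
            p = _uniform_in_disk(rng, center, radius)
            if _point_in_region(layout, p):
                return p
        return center

    def genotype_attrs(unit: TrueUnit, member: str | None = None) -> dict:
        if member is None:
            member = str(rng.choice(sorted(unit.member_genotypes)))
        sex, age = unit.member_info[member]
        if rng.uniform() < config.genotyping_success:
            return {
                "genotype_label": member,
                "genotype_sex": sex,
                "age_class": age,
                "pedigree_label": unit.unit_id,
            }
        return {}

    for year_units in yearly:
        if not year_units:
            continue
        year = year_units[0].year
        occupied = [u.center for u in year_units]
        for unit in year_units:
            source = f"unit:{unit.unit_id}"
            group_size = len(unit.member_genotypes)
            # --- DNA samples
            for _ in range(rng.poisson(rates.get("dna_sample", 0.0))):
                add_sign(
                    year, source, point_in_territory(unit.center), "dna_sample",
                    dna_confirmed_wolf=True, technically_documented=True,
                    **genotype_attrs(unit),
                )
            # --- photo / video
            for _ in range(rng.poisson(rates.get("photo_video", 0.0))):
                good = rng.uniform() < 0.85
                if unit.status == "pair":
                    n_ind = 2 if rng.uniform() < 0.8 else 1
                else:
                    n_ind = int(min(group_size, 2 + rng.poisson(1.5)))
                attrs = {
                    "photo_quality": "good" if good else "bad",
                    "n_individuals": n_ind,
                    "technically_documented": True,
                }
                if good and unit.reproduced_this_year and rng.uniform() < 0.5:
                    attrs["pups_present"] = True
                add_sign(year, source, point_in_territory(unit.center), "photo_video", **attrs)
            # --- tracks (with occasional DNA collected on the track)
            for _ in range(rng.poisson(rates.get("track", 0.0))):
                track_counter += 1
                tid = f"TRK{track_counter:05d}"
                length = float(np.round(np.exp(rng.normal(math.log(300.0), 0.8)), 1))
                n_ind = 2 if unit.status == "pair" else int(min(group_size, 1 + rng.poisson(2.0)))
                p = point_in_territory(unit.center)
                date = _random_date(rng, year)
                add_sign(
                    year, source, p, "track",
                    date=date, track_id=tid,
                    track_length_m=length,
                    typical_pattern=rng.uniform() < 0.9,
                    n_individuals=n_ind,
                    on_snow=rng.uniform() < 0.5,
                    technically_documented=True,
                )
                # couple or member DNA found along the track
                dna_on_track = 0.5 if unit.status == "pair" else 0.25
                if rng.uniform() < dna_on_track:
                    members = sorted(unit.member_genotypes)
                    picks = members if unit.status == "pair" else [str(rng.choice(members))]
                    for m in picks:
                        add_sign(
                            year, source, p, "dna_sample",
                            date=date, track_id=tid,
                            dna_confirmed_wolf=True, technically_documented=True,
                            **genotype_attrs(unit, m),
                        )
            # --- scats without DNA
            for _ in range(rng.poisson(rates.get("scat", 0.0))):
                add_sign(
                    year, source, point_in_territory(unit.center), "scat",
                    expert_checked=rng.uniform() < 0.7,
                    technically_documented=True,
                )
            # --- howls
            howl_rate = rates.get("howl", 0.0) * (1.0 if unit.reproduced_this_year else 0.2)
            for _ in range(rng.poisson(howl_rate)):
                add_sign(
                    year, source, point_in_territory(unit.center), "howl",
                    pups_heard=unit.reproduced_this_year,
                    expert_checked=rng.uniform() < 0.9,
                    technically_documented=True,
                )
            # --- depredations
            for _ in range(rng.poisson(rates.get("kill", 0.0))):
                add_sign(
                    year, source, point_in_territory(unit.center), "kill",
                    typical_bites=rng.uniform() < 0.8,
                    technically_documented=True,
                )

        # --- dispersers: solitary animals outside territories
        for _ in range(rng.poisson(config.disperser_rate * len(year_units))):
            disp_counter += 1
            did = f"D{disp_counter:04d}"
            sex = "M" if rng.uniform() < 0.6 else "F"
            for _ in range(200):
                p = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
                if _point_in_region(layout, p) and all(
                    math.hypot(p[0] - c[0], p[1] - c[1]) > radius for c in occupied
                ):
                    break
            source = f"disperser:{did}"
            n_signs = 1 + rng.poisson(0.8)
            for k in range(n_signs):
                q = (p[0] + rng.normal(0, 3.0), p[1] + rng.normal(0, 3.0))
                if not _point_in_region(layout, q):
                    q = p
                if rng.uniform() < 0.5:
                    geno = {}
                    if rng.uniform() < config.genotyping_success:
                        geno = {
                            "genotype_label": did,
                            "genotype_sex": sex,
                            "age_class": "adult",
                            "pedigree_label": did,
                        }
                    add_sign(year, source, q, "dna_sample",
                             dna_confirmed_wolf=True, technically_documented=True, **geno)
                else:
                    track_counter += 1
                    add_sign(
                        year, source, q, "track",
                        track_id=f"TRK{track_counter:05d}",
                        track_length_m=float(np.round(np.exp(rng.normal(math.log(250.0), 0.8)), 1)),
                        typical_pattern=rng.uniform() < 0.85,
                        n_individuals=1,
                        on_snow=rng.uniform() < 0.5,
                        technically_documented=True,
                    )

        # --- noise: unverifiable signs, attribute-poor by construction
        n_noise = rng.poisson(config.noise_sign_rate * region_area / 100.0)
        for _ in range(n_noise):
            for _ in range(50):
                p = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
                if _point_in_region(layout, p):
                    break
            kind = str(rng.choice(["sighting", "scat", "track", "howl"]))
            attrs: dict = {"technically_documented": rng.uniform() > 0.3}
            if kind == "track":
                attrs.update(
                    track_length_m=float(np.round(rng.uniform(5.0, 90.0), 1)),
                    typical_pattern=rng.uniform() < 0.5,
                    on_snow=True,
                    n_individuals=1,
                )
            elif kind == "scat":
                attrs.update(expert_checked=False)
            elif kind == "howl":
                attrs.update(pups_heard=False, expert_checked=False)
            add_sign(year, "noise", p, kind, **attrs)

    from .classification import ATTRIBUTE_COLUMNS

    base_cols = ["sign_id", "date", "x", "y", "country", "evidence_type"]
    signs_df = pd.DataFrame(signs)
    if signs_df.empty:
        signs_df = pd.DataFrame(columns=base_cols + list(ATTRIBUTE_COLUMNS))
    for col in ATTRIBUTE_COLUMNS:
        if col not in signs_df.columns:
            signs_df[col] = pd.NA
    signs_df = signs_df[base_cols + list(ATTRIBUTE_COLUMNS)]
    links_df = pd.DataFrame(links, columns=["sign_id", "source", "year"])
    return signs_df, links_df


# ---------------------------------------------------------------------------
# ground-truth scoring


def score_recovery(
    resolved_by_year: dict[str, list],
    links: pd.DataFrame,
    yearly: list[list[TrueUnit]],
) -> dict:
    """Score pipeline output against ground truth.

    A true unit-year is *recovered with correct status* when some resolved
    unit of that year draws the majority of its signs from that unit and
    carries the same pack/pair status. Also checks that no genotype label
    is assigned to two resolved units within a year.
    """
    link_map = dict(zip(links["sign_id"].astype(str), links["source"]))
    n_true = 0
    n_recovered = 0
    n_correct_status = 0
    double_assignments = 0
    for year_units in yearly:
        if not year_units:
            continue
        year = year_units[0].year
        truth = {u.unit_id: u.status for u in year_units}
        n_true += len(truth)
        resolved = resolved_by_year.get(year, [])
        claimed: dict[str, str] = {}
        matched: dict[str, str] = {}
        for ru in resolved:
            for g in sorted(ru.genotype_labels):
                if g in claimed and claimed[g] != ru.unit_id:
                    double_assignments += 1
                claimed[g] = ru.unit_id
            if ru.territory is None:
                continue
            sources = [
                link_map.get(str(s), "?") for s in ru.territory.signs["sign_id"]
            ]
            counts = pd.Series(sources).value_counts()
            top = counts.index[0]
            if counts.iloc[0] * 2 >= len(sources) and top.startswith("unit:"):
                uid = top.split(":", 1)[1]
                if uid in truth and uid not in matched:
                    matched[uid] = ru.status
        n_recovered += len(matched)
        n_correct_status += sum(1 for uid, st in matched.items() if truth[uid] == st)
    return {
        "n_true_unit_years": n_true,
        "n_recovered": n_recovered,
        "n_correct_status": n_correct_status,
        "recovery_rate": n_recovered / n_true if n_true else float("nan"),
        "correct_status_rate": n_correct_status / n_true if n_true else float("nan"),
        "genotype_double_assignments": double_assignments,
    }
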