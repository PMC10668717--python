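"""Validation of wolf signs of presence (SCALP-style C1/C2/C3 categories).

Every field observation — a DNA sample, a photographed animal, a snow track,
a depredated sheep, a howling session — is screened for genuineness and then
assigned one of three validation categories:

* **C1** — hard evidence: the species identity is certain (captured or dead
  animals, DNA-confirmed samples, good-quality photo/video, telemetry).
* **C2** — confirmed observation: an experienced person verified a sign that
  is consistent with a wolf (tracks ≥ 100 m with typical pattern, scats
  checked by an expert, kills with typical bites corroborated by other C2
  data, howls with pups verified by an expert).
* **C3** — unconfirmed observation: everything that could be a wolf but
  cannot be verified (short tracks, unchecked scats, single howls,
  unsupported sightings, bad-quality images).

Records lacking minimal technical documentation, or for which intentional
deception cannot be ruled out, are discarded before classification.

The monitoring year is the biological wolf year, running from 1 May of
calendar year Y through 30 April of Y+1, labelled ``"Y–Y+1"``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "EVIDENCE_TYPES",
    "SignRecord",
    "ClassifiedSign",
    "ClassificationError",
    "screen_genuineness",
    "classify_sign",
    "classify_signs",
    "assign_monitoring_year",
    "monitoring_year_label",
    "parse_monitoring_year",
]

#: Recognised evidence types for a sign of presence.
EVIDENCE_TYPES = frozenset(
    {
        "live_capture",
        "dead_animal",
        "dna_sample",
        "photo_video",
        "telemetry",
        "track",
        "scat",
        "kill",
        "howl",
        "sighting",
    }
)

#: Attribute columns carried by the signs table; missing ones default to NA.
ATTRIBUTE_COLUMNS = (
    "track_length_m",
    "typical_pattern",
    "expert_checked",
    "dna_confirmed_wolf",
    "genotype_label",
    "genotype_sex",
    "age_class",
    "pedigree_label",
    "photo_quality",
    "pups_heard",
    "pups_present",
    "n_individuals",
    "combined_with_c2",
    "technically_documented",
    "on_snow",
    "on_c2_track",
    "track_id",
    "typical_bites",
    "suspected_deception",
)

# en dash, as used in monitoring-year labels such as "2020–2021"
_DASH = "–"


class ClassificationError(ValueError):
    """Raised for records that cannot be classified (unknown evidence type)."""


@dataclass
class SignRecord:
    """One field observation of wolf presence.

    Coordinates are planar (declared CRS or abstract plane); ``attributes``
    is a typed bag — keys irrelevant to ``evidence_type`` may be absent.
    """

    sign_id: str
    date: _dt.date
    x: float
    y: float
    country: str
    evidence_type: str
    attributes: dict[str, Any] = field(default_factory=dict)

    def get(self, key: str, default: Any = None) -> Any:
        return self.attributes.get(key, default)


@dataclass
class ClassifiedSign:
    sign: SignRecord
    category: str  # "C1" | "C2" | "C3" | "discarded"
    monitoring_year: str


def monitoring_year_label(start_year: int) -> str:
    """Label of the monitoring year starting 1 May of ``start_year``."""
    return f"{start_year}{_DASH}{start_year + 1}"


def parse_monitoring_year(label: str) -> int:
    """Starting calendar year of a monitoring-year label.

    Accepts an en dash or a plain hyphen as separator.
    """
    head = label.replace("-", _DASH).split(_DASH)[0]
    return int(head)


def assign_monitoring_year(date: _dt.date | str | pd.Timestamp) -> str:
    """Map a calendar date to its monitoring-year label.

    The wolf biological year runs from reproduction to the next reproduction:
    dates from 1 May of year Y through 30 April of Y+1 belong to "Y–Y+1".
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    elif isinstance(date, pd.Timestamp):
        date = date.date()
    start = date.year if date.month >= 5 else date.year - 1
    return monitoring_year_label(start)


def _truthy(value: Any) -> bool:
    """Interpret an attribute that may be NA/None/str as a boolean flag."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    if value is pd.NA or value is pd.NaT:
        return False
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes", "t"}
    return bool(value)


def screen_genuineness(record: SignRecord | dict[str, Any]) -> bool:
    """Return ``True`` if a record is retained for classification.

    A sign is discarded when it lacks the minimum technical description
    (``technically_documented`` false) or when intentional deception cannot
    be ruled out (``suspected_deception`` true). ``technically_documented``
    defaults to true when absent: the flag records an explicit screening
    failure, not the presence of paperwork.
    """
    get = record.get if isinstance(record, SignRecord) else lambda k, d=None: record.get(k, d)
    documented = get("technically_documented", True)
    if documented is not None and not pd.isna(documented) and not _truthy(documented):
        return False
    if _truthy(get("suspected_deception", False)):
        return False
    return True


def classify_sign(record: SignRecord | dict[str, Any]) -> str:
    """Assign a validation category (C1/C2/C3) to one kept record.

    Implements the agreed decision table. DNA confirmation promotes any
    evidence type to C1 (a scat, hair or urine sample whose DNA analysis
    confirms the species is hard evidence regardless of how it looks).
    Table-level context (kills corroborated by nearby C2 data, tracks
    indirectly certified by DNA collected on them) is resolved by
    :func:`classify_signs`; at record level the corresponding pre-computed
    flags ``combined_with_c2`` and ``on_c2_track`` are honoured.
    """
    if isinstance(record, SignRecord):
        etype = record.evidence_type
        get = record.get
    else:
        etype = record.get("evidence_type")
        get = lambda k, d=None: record.get(k, d)  # noqa: E731

    if etype not in EVIDENCE_TYPES:
        raise ClassificationError(f"unknown evidence_type: {etype!r}")

    # DNA evidence confirms the biological sample whatever its type.
    if _truthy(get("dna_confirmed_wolf")):
        return "C1"

    if etype in ("live_capture", "dead_animal", "telemetry"):
        return "C1"
    if etype == "dna_sample":
        # a sample whose analysis did not (or could not) confirm the species
        return "C3"
    if etype == "photo_video":
        quality = get("photo_quality", "bad")
        return "C1" if str(quality).lower() == "good" else "C3"
    if etype == "track":
        length = get("track_length_m")
        ok = (
            _truthy(get("typical_pattern"))
            and length is not None
            and not pd.isna(length)
            and float(length) >= 100.0
        )
        return "C2" if ok else "C3"
    if etype == "scat":
        if _truthy(get("expert_checked")) or _truthy(get("on_c2_track")):
            return "C2"
        return "C3"
    if etype == "kill":
        if _truthy(get("typical_bites")) and _truthy(get("combined_with_c2")):
            return "C2"
        return "C3"
    if etype == "howl":
        if _truthy(get("pups_heard")) and _truthy(get("expert_checked")):
            return "C2"
        return "C3"
    # sighting: never verifiable on its own
    return "C3"


def _ensure_attribute_columns(signs: pd.DataFrame) -> pd.DataFrame:
    signs = signs.copy()
    for col in ATTRIBUTE_COLUMNS:
        if col not in signs.columns:
            signs[col] = pd.NA
    return signs


def classify_signs(
    signs: pd.DataFrame,
    *,
    kill_link_km: float = 10.0,
    kill_link_days: int = 14,
    coord_units: str = "km",
) -> pd.DataFrame:
    """Screen, classify and year-stamp a table of signs.

    Adds ``category`` (C1/C2/C3/discarded) and ``monitoring_year`` columns.
    Two table-level passes refine the per-record decision:

    1. *Kill corroboration* — a kill with typical bites becomes C2 only if
       another C2 sign lies within ``kill_link_km`` and ``kill_link_days``
       (the linkage rule; an explicit ``combined_with_c2`` flag short-cuts it).
    2. *Indirect DNA certification* — a C2/C3 track is upgraded to C1 when a
       DNA-confirmed sample was collected on that same track
       (shared ``track_id``).

    Parameters
    ----------
    signs
        Table with columns ``sign_id, date, x, y, country, evidence_type``
        plus any attribute columns; missing attributes are treated as absent.
    coord_units
        "km" or "m"; used only for the kill-linkage distance.
    """
    if signs.empty:
        out = signs.copy()
        out["category"] = pd.Series(dtype="object")
        out["monitoring_year"] = pd.Series(dtype="object")
        return out

    signs = _ensure_attribute_columns(signs)
    dates = pd.to_datetime(signs["date"])
    monitoring_year = dates.map(assign_monitoring_year)

    kept = signs.apply(lambda row: screen_genuineness(row.to_dict()), axis=1)
    category = pd.Series("discarded", index=signs.index, dtype="object")

    if kept.any():
        base = signs.loc[kept].apply(lambda row: classify_sign(row.to_dict()), axis=1)
        category.loc[kept] = base

    scale = 1.0 if coord_units == "km" else 1000.0

    # pass 1: kills corroborated by independent C2 data nearby in space/time
    kill_mask = kept & (signs["evidence_type"] == "kill") & (category == "C3")
    if kill_mask.any():
        c2_mask = category == "C2"
        c2_xy = signs.loc[c2_mask, ["x", "y"]].to_numpy(dtype=float)
        c2_dates = dates.loc[c2_mask].to_numpy()
        for idx in signs.index[kill_mask]:
            if not _truthy(signs.at[idx, "typical_bites"]):
                continue
            if len(c2_xy) == 0:
                continue
            dxy = c2_xy - np.array([signs.at[idx, "x"], signs.at[idx, "y"]], dtype=float)
            dist_km = np.hypot(dxy[:, 0], dxy[:, 1]) / scale
            dt_days = np.abs((c2_dates - dates.loc[idx].to_datetime64()) / np.timedelta64(1, "D"))
            if np.any((dist_km <= kill_link_km) & (dt_days <= kill_link_days)):
                category.at[idx] = "C2"

    # pass 2: tracks indirectly certified by DNA collected on the track
    dna_tracks = set(
        signs.loc[
            kept
            & signs["dna_confirmed_wolf"].map(_truthy)
            & signs["track_id"].notna(),
            "track_id",
        ]
    )
    if dna_tracks:
        upgrade = (
            kept
            & (signs["evidence_type"] == "track")
            & signs["track_id"].isin(dna_tracks)
        )
        category.loc[upgrade] = "C1"

    out = signs.copy()
    out["category"] = category
    out["monitoring_year"] = monitoring_year
    return out


def classified_to_records(classified: pd.DataFrame) -> Iterable[ClassifiedSign]:
    """Yield :class:`ClassifiedSign` objects from a classified table."""
    for _, row in classified.iterrows():
        attrs = {
            k: row[k]
            for k in ATTRIBUTE_COLUMNS
            if k in row.index and not pd.isna(row[k])
        }
        rec = SignRecord(
            sign_id=str(row["sign_id"]),
            date=pd.to_datetime(row["date"]).date(),
            x=float(row["x"]),
            y=float(row["y"]),
            country=str(row["country"]),
            evidence_type=str(row["evidence_type"]),
            attributes=attrs,
        )
        yield ClassifiedSign(rec, str(row["category"]), str(row["monitoring_year"]))
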