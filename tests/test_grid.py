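"""Occurrence-grid rules: cell indexing, confirmation, area, monotonicity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from conftest import make_sign, signs_frame
from wolfalps.classification import classify_signs
from wolfalps.grid import (
    GridCellId,
    OccurrenceMap,
    area_of_occurrence,
    c2_signs_independent,
    cell_of,
    confirm_cells,
    occurrence_table,
)


@pytest.mark.parametrize(
    "x,y,e,n",
    [
        (0.0, 0.0, 0, 0),
        (9_999.99, 0.0, 0, 0),
        (10_000.0, 0.0, 1, 0),
        (432_500.0, 2_431_200.0, 43, 243),  # floor division on each axis
        (-1.0, -1.0, -1, -1),
    ],
)
def test_cell_of(x, y, e, n):
    """Half-open 10 km squares: boundary points belong to the cell whose
    lower-left corner they touch."""
    cell = cell_of(x, y)
    assert (cell.easting_index, cell.northing_index) == (e, n)
    assert str(cell) == f"10kmE{e}N{n}"


@settings(max_examples=200, derandomize=True)
@given(x=st.floats(-1e6, 1e6), y=st.floats(-1e6, 1e6))
def test_cell_contains_point(x, y):
    cell = cell_of(x, y)
    assert cell.easting_index * 10_000 <= x < (cell.easting_index + 1) * 10_000
    assert cell.northing_index * 10_000 <= y < (cell.northing_index + 1) * 10_000


def _classified(rows):
    return classify_signs(signs_frame(rows))


def test_one_c1_confirms():
    rows = [make_sign(sign_id="A", evidence_type="dna_sample", dna_confirmed_wolf=True,
                      x=5.0, y=5.0, date="2016-01-10")]
    omap = confirm_cells(_classified(rows), "2015–2016")
    assert omap.confirmed_cells == {GridCellId(0, 0)}
    assert omap.supporting_evidence[GridCellId(0, 0)] == ["A"]


def test_one_c2_does_not_confirm():
    rows = [make_sign(sign_id="A", evidence_type="scat", expert_checked=True,
                      x=5.0, y=5.0, date="2016-01-10")]
    omap = confirm_cells(_classified(rows), "2015–2016")
    assert omap.confirmed_cells == set()
    assert omap.counts[GridCellId(0, 0)] == (0, 1)


def test_two_independent_c2_confirm_same_day_same_track_does_not():
    """Two C2 signs from the same track event on the same day are one
    observation; on different days they are independent and confirm."""
    base = dict(evidence_type="track", typical_pattern=True, track_length_m=200.0,
                x=5.0, y=5.0, track_id="TRK9")
    same_event = [
        make_sign(sign_id="A", date="2016-01-10", **base),
        make_sign(sign_id="B", date="2016-01-10", **{**base, "x": 5.2}),
    ]
    omap = confirm_cells(_classified(same_event), "2015–2016")
    assert omap.confirmed_cells == set()

    different_days = [
        make_sign(sign_id="A", date="2016-01-10", **base),
        make_sign(sign_id="B", date="2016-01-12", **{**base, "x": 5.2}),
    ]
    omap2 = confirm_cells(_classified(different_days), "2015–2016")
    assert omap2.confirmed_cells == {GridCellId(0, 0)}


def test_same_day_far_apart_different_tracks_independent():
    assert c2_signs_independent(
        pd.Timestamp("2016-01-10").date(), (0.0, 0.0), "T1",
        pd.Timestamp("2016-01-10").date(), (3.0, 0.0), "T2",
    )
    assert not c2_signs_independent(
        pd.Timestamp("2016-01-10").date(), (0.0, 0.0), None,
        pd.Timestamp("2016-01-10").date(), (0.5, 0.0), None,
    )


def test_c3_never_contributes():
    rows = [make_sign(sign_id=f"S{i}", evidence_type="sighting", x=5.0, y=5.0,
                      date="2016-01-10") for i in range(5)]
    omap = confirm_cells(_classified(rows), "2015–2016")
    assert omap.confirmed_cells == set()


@pytest.mark.parametrize("n_cells,expected", [(910, 91_000.0), (411, 41_100.0), (0, 0.0)])
def test_area_is_100_km2_per_cell(n_cells, expected):
    """Area of occurrence = 100 km² × confirmed in-range cells."""
    omap = OccurrenceMap("2020–2021", {GridCellId(i % 50, i // 50) for i in range(n_cells)})
    big = box(-1e6, -1e6, 1e6, 1e6)
    assert area_of_occurrence(omap, big, polygon_units="m") == expected
    assert area_of_occurrence(omap) == expected


def test_area_restricted_to_alpine_range():
    omap = OccurrenceMap("2020–2021", {GridCellId(0, 0), GridCellId(10, 0)})
    inner = box(0, 0, 50_000, 50_000)  # covers first cell's center only
    assert area_of_occurrence(omap, inner, polygon_units="m") == 100.0


def test_empty_polygon_errors():
    from shapely.geometry import Polygon

    omap = OccurrenceMap("2020–2021", {GridCellId(0, 0)})
    with pytest.raises(ValueError):
        area_of_occurrence(omap, Polygon())


def test_area_always_multiple_of_100(reference_run):
    classified = reference_run["classified"]
    year = sorted(set(classified["monitoring_year"]))[0]
    omap = confirm_cells(classified, year)
    area = area_of_occurrence(omap)
    assert area % 100.0 == 0.0


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.data())
def test_monotonicity_under_sign_addition(data):
    """Adding signs never unconfirms a cell; removing a C3 sign never
    changes the map."""
    n = data.draw(st.integers(1, 8))
    rows = []
    for i in range(n):
        etype = data.draw(st.sampled_from(["dna_sample", "scat", "track", "sighting"]))
        attrs = {}
        if etype == "dna_sample":
            attrs["dna_confirmed_wolf"] = data.draw(st.booleans())
        if etype == "scat":
            attrs["expert_checked"] = data.draw(st.booleans())
        if etype == "track":
            attrs["typical_pattern"] = True
            attrs["track_length_m"] = data.draw(st.sampled_from([50.0, 200.0]))
        rows.append(
            make_sign(sign_id=f"S{i}", evidence_type=etype,
                      x=data.draw(st.floats(0.0, 30.0)), y=data.draw(st.floats(0.0, 30.0)),
                      date=f"2016-01-{data.draw(st.integers(1, 28)):02d}", **attrs)
        )
    year = "2015–2016"
    before = confirm_cells(_classified(rows), year).confirmed_cells
    extra = make_sign(sign_id="EXTRA", evidence_type="scat", expert_checked=True,
                      x=3.0, y=3.0, date="2016-02-01")
    after = confirm_cells(_classified(rows + [extra]), year).confirmed_cells
    assert before <= after

    classified = _classified(rows)
    no_c3 = classified[classified["category"] != "C3"]
    assert confirm_cells(no_c3, year).confirmed_cells == before


def test_occurrence_table_shape(reference_run):
    classified = reference_run["classified"]
    year = sorted(set(classified["monitoring_year"]))[-1]
    tab = occurrence_table(confirm_cells(classified, year))
    assert list(tab.columns) == ["cell_id", "monitoring_year", "n_C1", "n_C2", "confirmed"]
    assert (tab["n_C1"] + tab["n_C2"] > 0).all()
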