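"""Pack/pair resolution: clustering, unit rules, adjacent-pack splitting,
transboundary deduplication, population summaries."""

import math
import random

import pytest

from conftest import make_sign, signs_frame
from wolfalps.classification import classify_signs
from wolfalps.regions import default_layout
from wolfalps.synthetic import score_recovery
from wolfalps.units import (
    IntegrityError,
    ReproductiveUnit,
    Territory,
    classify_unit,
    cluster_signs,
    resolve_transboundary,
    resolve_units,
    split_adjacent_packs,
    summarize,
)

YEAR = "2015–2016"


def _classified(rows):
    return classify_signs(signs_frame(rows))


def _territory(rows, tid="T1"):
    return Territory(tid, YEAR, _classified(rows))


def dna(sign_id, x, y, genotype, sex="M", date="2016-01-10", **kw):
    return make_sign(sign_id=sign_id, evidence_type="dna_sample", x=x, y=y, date=date,
                     dna_confirmed_wolf=True, genotype_label=genotype, genotype_sex=sex,
                     age_class=kw.pop("age_class", "adult"), **kw)


# ---------------------------------------------------------------------------
# clustering


def test_shared_genotype_links_across_distance():
    """Genetics overrides distance: identical genotype 60 km apart is one
    territory."""
    rows = [dna("A", 0.0, 0.0, "G1"), dna("B", 60.0, 0.0, "G1")]
    terrs = cluster_signs(_classified(rows), YEAR)
    assert len(terrs) == 1 and terrs[0].genotype_labels == {"G1"}


def test_distant_clusters_split():
    rows = [dna("A", 0.0, 0.0, "G1"), dna("B", 40.0, 0.0, "G2")]
    assert len(cluster_signs(_classified(rows), YEAR)) == 2


def test_nearby_signs_link_at_threshold():
    rows = [dna("A", 0.0, 0.0, "G1"), dna("B", 14.0, 0.0, "G2")]
    assert len(cluster_signs(_classified(rows), YEAR)) == 1


def test_empty_input():
    assert cluster_signs(_classified([make_sign(sign_id="X")]).iloc[0:0], YEAR) == []


def test_lone_unconfirmed_sign_dropped():
    rows = [make_sign(sign_id="A", evidence_type="scat", expert_checked=True)]
    assert cluster_signs(_classified(rows), YEAR) == []


# ---------------------------------------------------------------------------
# pack / pair rules


def test_howl_with_pups_makes_pack():
    rows = [
        make_sign(sign_id="H", evidence_type="howl", pups_heard=True, expert_checked=True),
        dna("D", 100.5, 100.5, "G1"),
    ]
    status, basis = classify_unit(_territory(rows))
    assert status == "pack" and "howl" in basis


def test_pup_dna_makes_pack():
    rows = [dna("D1", 100.0, 100.0, "G1"), dna("D2", 100.5, 100.5, "G2", age_class="pup")]
    assert classify_unit(_territory(rows))[0] == "pack"


def test_three_c1_individuals_make_pack():
    rows = [dna(f"D{i}", 100.0 + i, 100.0, f"G{i}") for i in range(3)]
    assert classify_unit(_territory(rows))[0] == "pack"


def test_two_independent_group_tracks_make_pack():
    base = dict(evidence_type="track", typical_pattern=True, track_length_m=400.0,
                n_individuals=4)
    rows = [
        make_sign(sign_id="T1", date="2016-01-10", x=100.0, y=100.0, track_id="A", **base),
        make_sign(sign_id="T2", date="2016-01-20", x=101.0, y=100.0, track_id="B", **base),
    ]
    assert classify_unit(_territory(rows))[0] == "pack"


def test_male_female_couple_is_pair():
    """C1 genetic proof of one male + one female on the same track, no
    pups: a pair."""
    rows = [
        dna("D1", 100.0, 100.0, "GM", sex="M", track_id="TRK1"),
        dna("D2", 100.0, 100.0, "GF", sex="F", track_id="TRK1"),
    ]
    status, basis = classify_unit(_territory(rows))
    assert status == "pair"


def test_pair_by_good_photo_of_two():
    rows = [
        dna("D1", 100.0, 100.0, "GM", sex="M"),
        dna("D2", 108.0, 100.0, "GF", sex="F"),
        make_sign(sign_id="P", evidence_type="photo_video", photo_quality="good",
                  n_individuals=2),
    ]
    assert classify_unit(_territory(rows))[0] == "pair"


def test_two_same_sex_genotypes_not_a_pair():
    rows = [
        dna("D1", 100.0, 100.0, "G1", sex="M", track_id="TRK1"),
        dna("D2", 100.0, 100.0, "G2", sex="M", track_id="TRK1"),
    ]
    assert classify_unit(_territory(rows))[0] == "none"


def test_reproduction_dominates_pair_evidence():
    rows = [
        dna("D1", 100.0, 100.0, "GM", sex="M", track_id="TRK1"),
        dna("D2", 100.0, 100.0, "GF", sex="F", track_id="TRK1"),
        make_sign(sign_id="H", evidence_type="howl", pups_heard=True, expert_checked=True),
    ]
    assert classify_unit(_territory(rows))[0] == "pack"


def test_only_c3_sightings_is_no_unit():
    rows = [make_sign(sign_id=f"S{i}", evidence_type="sighting") for i in range(4)]
    assert classify_unit(_territory(rows))[0] == "none"


# ---------------------------------------------------------------------------
# adjacent packs


def _adjacent_cluster(with_pedigrees=True, with_repro=True):
    """Two pack nuclei 12 km apart, merged by the 15 km linkage."""
    rows = []
    for k, x0 in enumerate([100.0, 112.0]):
        ped = {"pedigree_label": f"P{k}"} if with_pedigrees else {}
        rows += [
            dna(f"D{k}a", x0, 100.0, f"G{k}a", **ped),
            dna(f"D{k}b", x0 + 1.0, 100.0, f"G{k}b", sex="F", **ped),
        ]
        if with_repro:
            rows.append(
                make_sign(sign_id=f"H{k}", evidence_type="howl", pups_heard=True,
                          expert_checked=True, x=x0, y=101.0, date="2016-02-15")
            )
    return rows


def test_adjacent_packs_with_pedigrees_split():
    terrs = cluster_signs(_classified(_adjacent_cluster()), YEAR)
    assert len(terrs) == 1  # merged by proximity
    split = split_adjacent_packs(terrs)
    assert len(split) == 2
    assert {frozenset(t.pedigree_labels) for t in split} == {
        frozenset({"P0"}), frozenset({"P1"})
    }
    # howls (non-genotyped) joined their nearest nucleus
    assert all(len(t.signs) == 3 for t in split)


def test_adjacent_clusters_without_distinguishing_evidence_stay_one():
    terrs = cluster_signs(_classified(_adjacent_cluster(with_pedigrees=False)), YEAR)
    split = split_adjacent_packs(terrs)
    assert len(split) == 1


# ---------------------------------------------------------------------------
# transboundary resolution


def _unit_from_rows(rows, uid):
    terr = Territory(uid, YEAR, _classified(rows))
    status, basis = classify_unit(terr)
    return ReproductiveUnit(uid, YEAR, status, territory=terr, evidence_basis=basis)


def test_cross_border_genetic_match_merged_to_one_TR():
    """The same genotypes reported from Italy and France: one TR unit."""
    layout = default_layout()  # IT below y=200, FR above, border at y=200 for x<300
    italian = [
        dna("I1", 100.0, 195.0, "GM", country="IT", track_id="TRK1"),
        dna("I2", 100.0, 195.0, "GF", sex="F", country="IT", track_id="TRK1"),
    ]
    french = [
        dna("F1", 101.0, 205.0, "GM", country="FR"),
        dna("F2", 102.0, 206.0, "GF", sex="F", country="FR"),
    ]
    units = [_unit_from_rows(italian, "IT-01"), _unit_from_rows(french, "FR-01")]
    resolved = resolve_transboundary(units, layout)
    assert len(resolved) == 1
    assert resolved[0].transboundary_status == "TR"
    assert resolved[0].country_pair == ("FR", "IT")


def test_duplicate_national_records_deduplicated():
    """Counting drops by one when two national datasets report one pack."""
    layout = default_layout()
    rows_it = [dna(f"I{i}", 100.0, 195.0, f"G{i}", country="IT") for i in range(3)]
    rows_fr = [dna(f"F{i}", 101.0, 204.0, f"G{i}", country="FR") for i in range(3)]
    units = [_unit_from_rows(rows_it, "IT-01"), _unit_from_rows(rows_fr, "FR-01")]
    assert len(resolve_transboundary(units, layout)) == len(units) - 1


def test_interior_unit_stays_national():
    rows = [dna("D1", 100.0, 100.0, "GM", track_id="T1"),
            dna("D2", 100.0, 100.0, "GF", sex="F", track_id="T1")]
    resolved = resolve_transboundary([_unit_from_rows(rows, "U1")], default_layout())
    assert resolved[0].transboundary_status == "national"
    assert resolved[0].country == "IT"


def test_circle_crossing_border_without_genetics_is_LTR():
    rows = [
        make_sign(sign_id="T1", evidence_type="track", typical_pattern=True,
                  track_length_m=300.0, n_individuals=4, x=100.0, y=197.0,
                  country="IT", date="2016-01-05"),
        make_sign(sign_id="T2", evidence_type="track", typical_pattern=True,
                  track_length_m=300.0, n_individuals=4, x=100.0, y=203.0,
                  country="FR", date="2016-02-05"),
    ]
    resolved = resolve_transboundary([_unit_from_rows(rows, "U1")], default_layout())
    assert resolved[0].transboundary_status == "LTR"
    assert resolved[0].country_pair == ("FR", "IT")


def test_genotype_in_three_countries_is_integrity_error():
    rows = [
        dna("A", 299.0, 195.0, "GX", country="IT"),
        dna("B", 299.0, 205.0, "GX", country="FR"),
        dna("C", 305.0, 205.0, "GX", country="CH"),
    ]
    with pytest.raises(IntegrityError):
        resolve_transboundary([_unit_from_rows(rows, "U1")], default_layout())


def test_resolution_idempotent_and_order_invariant(reference_run):
    classified = reference_run["classified"]
    layout = reference_run["config"].layout
    year = sorted(set(classified["monitoring_year"]))[-1]
    units, _ = resolve_units(classified, year, layout)
    again = resolve_transboundary(units, layout)
    assert len(again) == len(units)
    assert {u.unit_id for u in again} == {u.unit_id for u in units}

    shuffled = list(units)
    random.Random(7).shuffle(shuffled)
    re2 = resolve_transboundary(shuffled, layout)
    s1, s2 = summarize(units, year), summarize(re2, year)
    assert (s1.total_packs, s1.total_pairs) == (s2.total_packs, s2.total_pairs)


def test_no_genotype_in_two_units_after_resolution(reference_run):
    classified = reference_run["classified"]
    layout = reference_run["config"].layout
    for year in sorted(set(classified["monitoring_year"])):
        units, _ = resolve_units(classified, year, layout)
        seen = {}
        for u in units:
            for g in u.genotype_labels:
                assert g not in seen, f"genotype {g} in two units in {year}"
                seen[g] = u.unit_id


# ---------------------------------------------------------------------------
# summaries


def make_resolved(uid, status, country=None, pair=None):
    tb = "national" if pair is None else "TR"
    return ReproductiveUnit(uid, YEAR, status, countries={country} if country else set(pair),
                            transboundary_status=tb, country=country, country_pair=pair)


def fixture_2015_16():
    units = []
    k = 0
    for country, packs, pairs in [("IT", 27, 8), ("FR", 31, 3), ("CH", 1, 1), ("SI", 2, 0)]:
        for _ in range(packs):
            units.append(make_resolved(f"U{k}", "pack", country)); k += 1
        for _ in range(pairs):
            units.append(make_resolved(f"U{k}", "pair", country)); k += 1
    units.append(make_resolved(f"U{k}", "pack", pair=("CH", "IT"))); k += 1
    for _ in range(3):
        units.append(make_resolved(f"U{k}", "pack", pair=("FR", "IT"))); k += 1
    return units


def test_population_summary_totals():
    s = summarize(fixture_2015_16(), YEAR)
    assert (s.total_packs, s.total_pairs, s.total_units) == (65, 12, 77)
    assert round(100 * s.pair_fraction, 1) == 15.6
    assert s.national["IT"] == {"packs": 27, "pairs": 8}
    assert s.transboundary["FR–IT"] == {"packs": 3, "pairs": 0}


def test_zero_pairs_fraction():
    units = [make_resolved("U1", "pack", "IT")]
    assert summarize(units, YEAR).pair_fraction == 0.0


def test_summary_empty():
    s = summarize([], YEAR)
    assert s.total_units == 0 and s.pair_fraction == 0.0


# ---------------------------------------------------------------------------
# recovery on the shared reference dataset


def test_reference_recovery(reference_run):
    classified = reference_run["classified"]
    layout = reference_run["config"].layout
    resolved = {
        y: resolve_units(classified, y, layout)[0]
        for y in sorted(set(classified["monitoring_year"]))
    }
    score = score_recovery(resolved, reference_run["links"], reference_run["truth"])
    assert score["correct_status_rate"] >= 0.9
    assert score["genotype_double_assignments"] == 0


def test_territory_representation_circle():
    rows = [dna("D1", 100.0, 100.0, "G1"), dna("D2", 110.0, 100.0, "G2")]
    terr = _territory(rows)
    assert terr.centroid == pytest.approx((105.0, 100.0))
    assert terr.radius_km == pytest.approx(math.sqrt(200.0 / math.pi))
    assert terr.representation_circle.area == pytest.approx(200.0, rel=1e-3)
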