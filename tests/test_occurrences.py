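"""Ingestion, georeferencing, synonymy and the curation cascade."""

import numpy as np
import pandas as pd
import pytest
import shapely
from hypothesis import given, settings, strategies as st

from faunatrends.occurrences import (
    Gazetteer,
    apply_synonyms,
    curate,
    frame_to_records,
    normalize_locality,
    read_occurrences,
    records_to_frame,
    resolve_georeferences,
    _covers,
)
from conftest import HAND_TALLY_REMAINING, HAND_TALLY_REMOVALS, make_records


# ---------------------------------------------------------------------- I/O

def write_csv(tmp_path, text, name="occ.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_extracts_years_from_full_dates(tmp_path):
    p = write_csv(
        tmp_path,
        "scientificName,eventDate,decimalLatitude,decimalLongitude\n"
        "Buccinum undatum,1905-06-15,54.1,7.9\n"
        "Asterias rubens,1950-01-02,54.2,8.0\n"
        "Carcinus maenas,2001-11-30,54.3,8.1\n",
    )
    df = read_occurrences(p)
    assert len(df) == 3
    assert df["year"].tolist() == [1905.0, 1950.0, 2001.0]


def test_read_year_range_takes_first_year(tmp_path):
    p = write_csv(tmp_path, "scientificName,eventDate\nBuccinum undatum,1902-1912\n")
    assert read_occurrences(p)["year"].iloc[0] == 1902.0


def test_read_missing_coordinate_is_retained_as_missing(tmp_path):
    p = write_csv(
        tmp_path,
        "scientificName,eventDate,decimalLatitude,decimalLongitude\n"
        "Buccinum undatum,1905,,\n",
    )
    df = read_occurrences(p)
    assert len(df) == 1
    assert df["lat"].isna().all() and df["lon"].isna().all()


def test_read_unparseable_fields_never_fail_the_row(tmp_path):
    p = write_csv(
        tmp_path,
        "scientificName,eventDate,decimalLatitude,decimalLongitude\n"
        "Buccinum undatum,no date recorded,not-a-number,8.0\n",
    )
    df = read_occurrences(p)
    assert len(df) == 1
    assert df["year"].isna().all()
    # a half-missing coordinate pair is unusable and becomes fully missing
    assert df["lat"].isna().all() and df["lon"].isna().all()


def test_read_requires_species_column_and_rows(tmp_path):
    p = write_csv(tmp_path, "eventDate,decimalLatitude\n1905,54.0\n")
    with pytest.raises(ValueError, match="species column"):
        read_occurrences(p)
    p2 = write_csv(tmp_path, "scientificName,eventDate\n", name="empty.csv")
    with pytest.raises(ValueError, match="no records"):
        read_occurrences(p2)


def test_record_roundtrip_through_dataclass():
    df = make_records([("Buccinum undatum", "Gastropoda", "Mollusca", 1900, 5.0, 5.0)])
    recs = frame_to_records(df)
    assert recs[0].species == "Buccinum undatum"
    back = records_to_frame(recs)
    assert back["species"].tolist() == df["species"].tolist()
    assert back["year"].tolist() == df["year"].tolist()


# ------------------------------------------------------------ georeferencing

def test_gazetteer_normalization_and_resolution():
    gaz = Gazetteer({"Helgoland": (54.18, 7.88)})
    df = make_records(
        [
            ("Buccinum undatum", "Gastropoda", "Mollusca", 1900, None, None, "Helgoland "),
            ("Buccinum undatum", "Gastropoda", "Mollusca", 1900, None, None, "Atlantis"),
            ("Buccinum undatum", "Gastropoda", "Mollusca", 1900, 50.0, 1.0, "helgoland"),
        ]
    )
    out, n_res, n_unres = resolve_georeferences(df, gaz)
    assert len(out) == len(df)  # never changes the record count
    assert (n_res, n_unres) == (1, 1)
    assert out.loc[0, "lat"] == 54.18 and out.loc[0, "lon"] == 7.88
    assert out.loc[1, "lat"] != out.loc[1, "lat"]  # still NaN
    # already-georeferenced record untouched even though its locality matches
    assert out.loc[2, "lat"] == 50.0


def test_normalize_locality_idempotent():
    for s in ["  Doggerbank ", "NORTH  sea", "Kieler\tBucht"]:
        once = normalize_locality(s)
        assert normalize_locality(once) == once


# ----------------------------------------------------------------- synonymy

def _substitute_to_fixpoint(name, table):
    # independent oracle: repeated single-step substitution
    for _ in range(len(table) + 1):
        if name not in table:
            return name
        name = table[name]
    raise AssertionError("cycle")


def test_synonym_chain_resolves_to_terminal_name():
    table = {"a": "b", "b": "c", "Gibbula cineraria": "Steromphala cineraria"}
    df = make_records(
        [(s, "Gastropoda", "Mollusca", 1900, 5.0, 5.0) for s in ["a", "b", "Gibbula cineraria", "x"]]
    )
    out = apply_synonyms(df, table)
    expected = [_substitute_to_fixpoint(s, table) for s in ["a", "b", "Gibbula cineraria", "x"]]
    assert out["species"].tolist() == expected == ["c", "c", "Steromphala cineraria", "x"]


def test_synonym_cycle_is_a_hard_error():
    df = make_records([("a", "Gastropoda", "Mollusca", 1900, 5.0, 5.0)])
    with pytest.raises(ValueError, match="cycle"):
        apply_synonyms(df, {"a": "b", "b": "a"})


@settings(derandomize=True, max_examples=50)
@given(
    st.dictionaries(
        st.sampled_from(list("abcdefgh")), st.sampled_from(list("abcdefgh")), max_size=6
    )
)
def test_synonym_application_is_idempotent(table):
    names = sorted(set(table) | set(table.values()) | {"zz"})
    df = make_records([(s, "Gastropoda", "Mollusca", 1900, 5.0, 5.0) for s in names])
    try:
        once = apply_synonyms(df, table)
    except ValueError:
        return  # cyclic table: rejection is the contract
    twice = apply_synonyms(once, table)
    assert once["species"].tolist() == twice["species"].tolist()


# ----------------------------------------------------------------- curation

def test_curation_cascade_matches_hand_tally(hand_tally_setup):
    curated, report = curate(**hand_tally_setup)
    assert [r for _, r, _ in report.stages] == HAND_TALLY_REMOVALS
    assert [n for _, _, n in report.stages] == HAND_TALLY_REMAINING
    assert len(curated) == 27
    # bookkeeping identity: removals + survivors == input
    assert sum(r for _, r, _ in report.stages) + len(curated) == report.input_size


def test_curation_is_deterministic_and_order_stable(hand_tally_setup):
    a, _ = curate(**hand_tally_setup)
    b, _ = curate(**hand_tally_setup)
    assert a.to_csv(index=False) == b.to_csv(index=False)


def test_curation_boundary_point_is_inside(study_box):
    df = make_records(
        [
            ("Buccinum undatum", "Gastropoda", "Mollusca", 1900, 10.0, 10.0),
            ("Buccinum undatum", "Gastropoda", "Mollusca", 1900, 5.0, 5.0),
        ]
    )
    curated, report = curate(df, study_box)
    assert len(curated) == 2  # boundary-inclusive containment


def test_curation_empty_output_is_hard_error(study_box):
    df = make_records([("Buccinum undatum", "Gastropoda", "Mollusca", None, 5.0, 5.0)])
    with pytest.raises(ValueError, match="no records survive"):
        curate(df, study_box)


# ------------------------------------------------- point-in-polygon oracle

def _ray_cast(poly_xy, x, y):
    inside = False
    n = len(poly_xy)
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xin = (x2 - x1) * (y - y1) / (y2 - y1) + x1
            if x < xin:
                inside = not inside
    return inside


def test_point_in_polygon_agrees_with_ray_casting(rng):
    # convex pentagon; random points almost surely avoid the boundary
    verts = [(2.0, 0.0), (5.0, 1.0), (6.0, 4.0), (3.0, 6.0), (0.5, 3.0)]
    poly = shapely.Polygon(verts)
    x = rng.uniform(-1, 7, size=1000)
    y = rng.uniform(-1, 7, size=1000)
    ours = _covers(poly, x, y)
    oracle = np.array([_ray_cast(verts, xi, yi) for xi, yi in zip(x, y)])
    assert (ours == oracle).all()
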