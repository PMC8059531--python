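"""Shared fixtures: small occurrence frames with hand-tallied expectations."""

import numpy as np
import pandas as pd
import pytest
import shapely

from faunatrends.occurrences import COLUMNS


def make_records(rows):
    """Build a canonical occurrence frame from (species, class, phylum, year,
    lat, lon) tuples, optionally extended with locality."""
    recs = []
    for i, row in enumerate(rows):
        species, cls, phylum, year, lat, lon = row[:6]
        locality = row[6] if len(row) > 6 else None
        recs.append(
            {
                "record_id": str(i),
                "species": species,
                "genus": species.split()[0] if species else "",
                "class": cls,
                "phylum": phylum,
                "year": year,
                "lat": lat,
                "lon": lon,
                "locality": locality,
                "institution": "TST",
                "catalogue_no": f"TST{i:04d}",
            }
        )
    df = pd.DataFrame(recs, columns=COLUMNS)
    for c in ("year", "lat", "lon"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


@pytest.fixture
def study_box():
    return shapely.box(0.0, 0.0, 10.0, 10.0)


@pytest.fixture
def excluded_box():
    return shapely.box(8.0, 8.0, 10.0, 10.0)


# Hand-tallied 50-record curation fixture.  Stage-by-stage manual tally:
#   input 50
#   (1) 5 records without coordinates            -> 45 remain
#   (2) 4 records at lon 15 (outside study box)  -> 41
#   (3) 3 records without a year                 -> 38
#   (4) 2 records of a non-whitelisted class     -> 36
#   (5) 3 lots not determined to species level   -> 33
#   (6) 2 infaunal + 1 small-bodied species      -> 30
#   (7) 3 records inside the excluded box        -> 27
HAND_TALLY_REMOVALS = [5, 4, 3, 2, 3, 3, 3]
HAND_TALLY_REMAINING = [45, 41, 38, 36, 33, 30, 27]


@pytest.fixture
def hand_tally_records():
    rows = []
    # stage 1: no coordinates
    rows += [("Buccinum undatum", "Gastropoda", "Mollusca", 1900, None, None)] * 5
    # stage 2: outside the study box
    rows += [("Buccinum undatum", "Gastropoda", "Mollusca", 1900, 5.0, 15.0)] * 4
    # stage 3: no year
    rows += [("Buccinum undatum", "Gastropoda", "Mollusca", None, 5.0, 5.0)] * 3
    # stage 4: class not whitelisted
    rows += [("Asterias rubens", "Asteroidea", "Echinodermata", 1950, 5.0, 5.0)] * 2
    # stage 5: not species level
    rows += [
        ("Mytilus", "Bivalvia_wl", "Mollusca", 1950, 5.0, 5.0),
        ("Buccinum sp.", "Gastropoda", "Mollusca", 1950, 5.0, 5.0),
        ("Abra indet.", "Bivalvia_wl", "Mollusca", 1950, 5.0, 5.0),
    ]
    # stage 6: infauna (2) and small size (1)
    rows += [("Mya arenaria", "Bivalvia_wl", "Mollusca", 1950, 5.0, 5.0)] * 2
    rows += [("Parvus minutus", "Gastropoda", "Mollusca", 1950, 5.0, 5.0)]
    # stage 7: inside the excluded box
    rows += [("Buccinum undatum", "Gastropoda", "Mollusca", 1950, 9.0, 9.0)] * 3
    # survivors
    rows += [
        ("Buccinum undatum", "Gastropoda", "Mollusca", 1890 + i, 5.0, 5.0)
        for i in range(27)
    ]
    assert len(rows) == 50
    return make_records(rows)


@pytest.fixture
def hand_tally_setup(hand_tally_records, study_box, excluded_box):
    traits = pd.DataFrame(
        {
            "species": ["Mya arenaria", "Parvus minutus", "Buccinum undatum"],
            "is_infauna": [True, False, False],
            "mean_size_cm": [5.0, 0.8, 8.0],
        }
    ).set_index("species")
    whitelist = {"Gastropoda", "Malacostraca", "Bivalvia_wl"}
    return dict(
        df=hand_tally_records,
        study_polygon=study_box,
        excluded_polygons=[excluded_box],
        taxon_whitelist=whitelist,
        trait_table=traits,
        min_size_cm=1.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
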