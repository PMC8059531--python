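"""Lot-level occurrence records: ingestion, georeferencing, synonymy, curation.

The unit of observation throughout this package is the *lot*: all specimens of
one species from one sampling event, catalogued together.  Record counts are
therefore deposition-event counts, never individual counts.

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns in :data:`COLUMNS`; :func:`frame_to_records` / :func:`records_to_frame`
convert to and from the row-level :class:`OccurrenceRecord` dataclass.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "COLUMNS",
    "DARWIN_CORE_DIALECT",
    "OccurrenceRecord",
    "Gazetteer",
    "CurationReport",
    "read_occurrences",
    "write_occurrences",
    "records_to_frame",
    "frame_to_records",
    "normalize_locality",
    "resolve_georeferences",
    "apply_synonyms",
    "load_polygon",
    "load_gazetteer",
    "load_traits",
    "curate",
]

#: Canonical column order of the occurrence frame.
COLUMNS = [
    "record_id",
    "species",
    "genus",
    "class",
    "phylum",
    "year",
    "lat",
    "lon",
    "locality",
    "institution",
    "catalogue_no",
]

#: Default mapping from record roles to Darwin-Core-style column headers.
DARWIN_CORE_DIALECT = {
    "species": "scientificName",
    "class": "class",
    "phylum": "phylum",
    "year": "eventDate",
    "lat": "decimalLatitude",
    "lon": "decimalLongitude",
    "locality": "locality",
    "institution": "institutionCode",
    "catalogue_no": "catalogNumber",
}

# Earliest plausible collection year for these collections; later years are
# treated as transcription errors and left missing.
YEAR_MIN = 1750
YEAR_MAX = 2100

_YEAR_RE = re.compile(r"(1[7-9]\d\d|20\d\d|2100)")

# Epithets that mark a lot as not determined to species level.
_NON_SPECIFIC_EPITHETS = {"sp.", "spec.", "indet."}


@dataclass
class OccurrenceRecord:
    """One collection lot (all specimens of one species from one event)."""

    record_id: str
    species: str
    genus: str | None = None
    class_: str | None = None
    phylum: str | None = None
    year: int | None = None
    lat: float | None = None
    lon: float | None = None
    locality: str | None = None
    institution: str | None = None
    catalogue_no: str | None = None


def records_to_frame(records: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    rows = [
        (
            r.record_id,
            r.species,
            r.genus,
            r.class_,
            r.phylum,
            r.year,
            r.lat,
            r.lon,
            r.locality,
            r.institution,
            r.catalogue_no,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["year"] = pd.to_numeric(df["year"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    return df


def frame_to_records(df: pd.DataFrame) -> list[OccurrenceRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        out.append(
            OccurrenceRecord(
                record_id=str(d["record_id"]),
                species=d["species"],
                genus=d.get("genus"),
                class_=d.get("class"),
                phylum=d.get("phylum"),
                year=None if pd.isna(d["year"]) else int(d["year"]),
                lat=None if pd.isna(d["lat"]) else float(d["lat"]),
                lon=None if pd.isna(d["lon"]) else float(d["lon"]),
                locality=d.get("locality"),
                institution=d.get("institution"),
                catalogue_no=d.get("catalogue_no"),
            )
        )
    return out


def _extract_year(value: object) -> float:
    """First 4-digit substring in [1750, 2100]; NaN if none.

    Event dates may be full ISO dates or free text; year ranges like
    "1902-1912" yield the first year.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value)
    m = _YEAR_RE.search(s)
    if not m:
        return np.nan
    y = int(m.group(0))
    if YEAR_MIN <= y <= YEAR_MAX:
        return float(y)
    return np.nan


def read_occurrences(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read delimited occurrence text into the canonical frame.

    Parameters
    ----------
    path
        UTF-8 CSV/TSV file with a header row.
    dialect
        Mapping from record roles (``species``, ``year``, ``lat`` ...) to
        column names in the file; defaults to Darwin-Core-style headers.
        The ``year`` role may point at an event-date column — the calendar
        year is extracted from it.
    sep
        Field separator; inferred from the file extension when ``None``
        (``.tsv`` → tab, otherwise comma).

    Unparseable coordinates and years become missing values and never fail
    the row; row order is preserved.  A file without a species column, or
    with no data rows, is a hard error.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    d = dict(DARWIN_CORE_DIALECT)
    if dialect:
        d.update(dialect)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if d["species"] not in raw.columns:
        raise ValueError(
            f"species column {d['species']!r} not present in {path.name} "
            f"(columns: {list(raw.columns)})"
        )
    if len(raw) == 0:
        raise ValueError(f"{path.name} contains a header but no records")

    def col(role: str) -> pd.Series:
        name = d.get(role)
        if name is not None and name in raw.columns:
            s = raw[name]
            return s.mask(s == "")
        return pd.Series([np.nan] * len(raw), index=raw.index)

    species = col("species").fillna("")
    genus = species.str.split().str[0].where(species != "", None)
    df = pd.DataFrame(
        {
            "record_id": [str(i) for i in range(len(raw))],
            "species": species,
            "genus": genus,
            "class": col("class"),
            "phylum": col("phylum"),
            "year": col("year").map(_extract_year),
            "lat": pd.to_numeric(col("lat"), errors="coerce"),
            "lon": pd.to_numeric(col("lon"), errors="coerce"),
            "locality": col("locality"),
            "institution": col("institution"),
            "catalogue_no": col("catalogue_no"),
        }
    )
    cat = df["catalogue_no"]
    has_cat = cat.notna()
    df.loc[has_cat, "record_id"] = cat[has_cat].astype(str)
    # out-of-range coordinates are unusable, treat as missing
    bad_lat = df["lat"].abs() > 90
    bad_lon = df["lon"].abs() > 180
    df.loc[bad_lat, "lat"] = np.nan
    df.loc[bad_lon, "lon"] = np.nan
    incomplete = df["lat"].isna() != df["lon"].isna()
    df.loc[incomplete, ["lat", "lon"]] = np.nan
    return df


def write_occurrences(df: pd.DataFrame, path: str | Path, curated: bool | None = None) -> None:
    """Write the canonical frame as CSV, optionally with a curation_pass flag."""
    out = df.copy()
    if curated is not None:
        out["curation_pass"] = bool(curated)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Georeferencing via the in-dataset gazetteer
# ---------------------------------------------------------------------------

_WS_RE = re.compile(r"\s+")


def normalize_locality(text: str) -> str:
    """Case-fold, trim and collapse whitespace (idempotent)."""
    return _WS_RE.sub(" ", str(text).strip()).casefold()


class Gazetteer:
    """Normalized locality string → (lat, lon) lookup."""

    def __init__(self, mapping: Mapping[str, tuple[float, float]]):
        self._map: dict[str, tuple[float, float]] = {}
        for key, (lat, lon) in mapping.items():
            lat, lon = float(lat), float(lon)
            if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                raise ValueError(f"invalid coordinates for locality {key!r}: {(lat, lon)}")
            self._map[normalize_locality(key)] = (lat, lon)

    def get(self, locality: str) -> tuple[float, float] | None:
        return self._map.get(normalize_locality(locality))

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, locality: str) -> bool:
        return normalize_locality(locality) in self._map


def load_gazetteer(path: str | Path) -> Gazetteer:
    """Read a gazetteer CSV with columns locality, lat, lon."""
    df = pd.read_csv(path)
    return Gazetteer({r.locality: (r.lat, r.lon) for r in df.itertuples(index=False)})


def resolve_georeferences(
    df: pd.DataFrame, gazetteer: Gazetteer
) -> tuple[pd.DataFrame, int, int]:
    """Fill coordinates from the gazetteer for records that lack them.

    Only records without coordinates but with locality text are candidates;
    records that already carry coordinates are never overwritten.  Returns
    the updated frame plus (n_resolved, n_unresolved) over the candidates.
    """
    df = df.copy()
    candidates = df["lat"].isna() & df["locality"].notna() & (df["locality"] != "")
    n_resolved = 0
    for idx in df.index[candidates]:
        hit = gazetteer.get(df.at[idx, "locality"])
        if hit is not None:
            df.at[idx, "lat"], df.at[idx, "lon"] = hit
            n_resolved += 1
    return df, n_resolved, int(candidates.sum()) - n_resolved


# ---------------------------------------------------------------------------
# Taxonomic synonymy (offline stand-in for a live registry lookup)
# ---------------------------------------------------------------------------

def _resolve_synonym(name: str, table: Mapping[str, str]) -> str:
    seen = [name]
    current = name
    while current in table:
        current = table[current]
        if current in seen:
            cycle = seen[seen.index(current):] + [current]
            raise ValueError("synonym cycle: " + " -> ".join(cycle))
        seen.append(current)
    return current


def apply_synonyms(df: pd.DataFrame, synonym_table: Mapping[str, str]) -> pd.DataFrame:
    """Replace every species name by its terminal accepted name.

    Chains (a→b, b→c) are followed to their fixpoint, so the operation is
    idempotent.  A cycle in the table is a hard error naming the cycle.
    """
    resolved = {name: _resolve_synonym(name, synonym_table) for name in set(synonym_table)}
    df = df.copy()
    df["species"] = df["species"].map(lambda s: resolved.get(s, s))
    df["genus"] = df["species"].str.split().str[0]
    return df


# ---------------------------------------------------------------------------
# Spatial inputs
# ---------------------------------------------------------------------------

def load_polygon(source: str | Path | dict | BaseGeometry) -> BaseGeometry:
    """Load a (Multi)Polygon from GeoJSON (file path, dict, or geometry)."""
    if isinstance(source, BaseGeometry):
        return source
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = json.load(fh)
    if source.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in source["features"]]
        return shapely.union_all(geoms)
    if source.get("type") == "Feature":
        return shape(source["geometry"])
    return shape(source)


def load_traits(path: str | Path) -> pd.DataFrame:
    """Read a trait table CSV: species, is_infauna, mean_size_cm."""
    df = pd.read_csv(path)
    if df["species"].duplicated().any():
        dupes = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in trait table: {dupes}")
    df["is_infauna"] = df["is_infauna"].astype(bool)
    return df.set_index("species")


def _covers(geom: BaseGeometry, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Boundary-inclusive point-in-polygon test (vectorised)."""
    pts = shapely.points(np.asarray(lon, dtype=float), np.asarray(lat, dtype=float))
    return shapely.covers(geom, pts)


def _is_species_level(name: str) -> bool:
    tokens = str(name).split()
    if len(tokens) < 2:
        return False
    return tokens[1].casefold() not in _NON_SPECIFIC_EPITHETS


# ---------------------------------------------------------------------------
# The curation cascade
# ---------------------------------------------------------------------------

@dataclass
class CurationReport:
    """Per-stage bookkeeping of the curation cascade."""

    input_size: int
    stages: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_removed: int, n_remaining: int) -> None:
        self.stages.append((name, int(n_removed), int(n_remaining)))

    @property
    def final_size(self) -> int:
        return self.stages[-1][2] if self.stages else self.input_size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_removed", "n_remaining"])

    def log_lines(self) -> list[str]:
        lines = [f"curation input: {self.input_size} records"]
        for name, removed, remaining in self.stages:
            lines.append(f"  {name}: removed {removed}, {remaining} remaining")
        return lines


CURATION_STAGES = [
    "no_coordinates",
    "outside_study_region",
    "missing_year",
    "taxon_not_whitelisted",
    "not_species_level",
    "trait_excluded",
    "inside_excluded_region",
]


def curate(
    df: pd.DataFrame,
    study_polygon: BaseGeometry,
    excluded_polygons: Sequence[BaseGeometry] = (),
    taxon_whitelist: set[str] | None = None,
    trait_table: pd.DataFrame | None = None,
    min_size_cm: float = 1.0,
) -> tuple[pd.DataFrame, CurationReport]:
    """Apply the fixed curation cascade and account for every removal.

    Stages, in order: (1) drop records with no coordinates; (2) drop records
    outside the study polygon (boundary counts as inside); (3) drop records
    without a collection year; (4) drop records whose class and phylum are
    both absent from the whitelist; (5) drop lots not determined to species
    level; (6) drop infaunal species and species with mean size at or below
    ``min_size_cm``; (7) drop records inside any excluded region.

    Filters whose auxiliary input is not supplied (whitelist, traits,
    exclusion polygons) are recorded as removing zero records, so the report
    always lists the same stages.  An empty result is a hard error.
    """
    report = CurationReport(input_size=len(df))
    cur = df

    def drop(stage: str, mask_drop: pd.Series | np.ndarray) -> None:
        nonlocal cur
        mask_drop = np.asarray(mask_drop, dtype=bool)
        cur = cur.loc[~mask_drop]
        report.add(stage, int(mask_drop.sum()), len(cur))

    drop("no_coordinates", cur["lat"].isna() | cur["lon"].isna())

    if len(cur):
        inside = _covers(study_polygon, cur["lon"].to_numpy(), cur["lat"].to_numpy())
    else:
        inside = np.zeros(0, dtype=bool)
    drop("outside_study_region", ~inside)

    drop("missing_year", cur["year"].isna())

    if taxon_whitelist is not None:
        ok = cur["class"].isin(taxon_whitelist) | cur["phylum"].isin(taxon_whitelist)
        drop("taxon_not_whitelisted", ~ok)
    else:
        drop("taxon_not_whitelisted", np.zeros(len(cur), dtype=bool))

    drop("not_species_level", ~cur["species"].map(_is_species_level))

    if trait_table is not None and len(cur):
        infauna = cur["species"].map(
            lambda s: bool(trait_table["is_infauna"].get(s, False))
        )
        size = cur["species"].map(lambda s: trait_table["mean_size_cm"].get(s, np.nan))
        too_small = pd.to_numeric(size, errors="coerce") <= min_size_cm
        drop("trait_excluded", infauna | too_small.fillna(False))
    else:
        drop("trait_excluded", np.zeros(len(cur), dtype=bool))

    if excluded_polygons and len(cur):
        lon = cur["lon"].to_numpy()
        lat = cur["lat"].to_numpy()
        in_any = np.zeros(len(cur), dtype=bool)
        for poly in excluded_polygons:
            in_any |= _covers(poly, lon, lat)
        drop("inside_excluded_region", in_any)
    else:
        drop("inside_excluded_region", np.zeros(len(cur), dtype=bool))

    if len(cur) == 0:
        raise ValueError("no records survive curation")
    return cur.reset_index(drop=True), report
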