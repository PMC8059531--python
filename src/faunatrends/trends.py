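"""Relative observation trends: per-species annual record proportions
regressed on year, against two taxonomic ranks and two dataset variants.

A species' records in each year are set in relation to all records of its
class (and, separately, its phylum) that year, which buffers the raw counts
against year-to-year swings in collecting effort.  Years with fewer than
``min_rank_records`` records of the higher taxon are dropped, and species
with fewer than ``min_species_records`` records overall are not fitted.  In
qualifying years where the higher taxon was collected but the species was
not, the species' proportion is zero — omitting those years would bias the
slope toward zero for species that appear or disappear.

A trend call requires significance against class and/or phylum with a
consistent sign, in both the full dataset and the dataset without the
exclusion region (the heavily resampled Dogger Bank in the original study);
species whose class and phylum trends disagree in sign are excluded as
discordant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry.base import BaseGeometry

from .occurrences import _covers

__all__ = [
    "ProportionSeries",
    "TrendFit",
    "TrendCall",
    "annual_proportions",
    "ols_trend",
    "classify_trend",
    "run_trend_analysis",
    "RANKS",
    "VARIANTS",
]

RANKS = ("class", "phylum")
VARIANTS = ("full", "excl_region")


@dataclass
class ProportionSeries:
    """Annual record proportions of one species relative to one rank."""

    species: str
    rank: str
    data: pd.DataFrame  # columns: year, n_species_records, n_rank_records, proportion

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class TrendFit:
    species: str
    rank: str
    variant: str
    slope: float
    stderr: float
    t_stat: float
    p_value: float
    n_years: int
    degenerate: bool = False  # zero-residual fit with nonzero slope

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05  # informational; callers pass their own alpha


@dataclass
class TrendCall:
    species: str
    direction: str  # increasing | declining | none | discordant_excluded
    fits: dict  # (rank, variant) -> TrendFit | None
    reason: str = ""


def annual_proportions(
    records: pd.DataFrame,
    species: str,
    rank: str,
    min_rank_records: int = 5,
    min_species_records: int = 10,
) -> ProportionSeries:
    """Annual proportion of a species' records within its class or phylum.

    Returns an empty series (no fit possible) when the species has fewer
    than ``min_species_records`` lots overall.  Years where the rank total
    falls below ``min_rank_records`` are dropped; qualifying years without
    the species contribute proportion zero.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    sp_mask = records["species"] == species
    if not sp_mask.any():
        raise ValueError(f"species {species!r} not present in records")
    taxa = records.loc[sp_mask, rank].dropna().unique()
    if len(taxa) != 1:
        raise ValueError(
            f"{rank} membership of {species!r} is unknown or ambiguous: {list(taxa)}"
        )
    taxon = taxa[0]
    empty = pd.DataFrame(
        columns=["year", "n_species_records", "n_rank_records", "proportion"]
    )
    if int(sp_mask.sum()) < min_species_records:
        return ProportionSeries(species, rank, empty)

    rank_counts = (
        records.loc[records[rank] == taxon]
        .groupby(records["year"].astype(int))
        .size()
        .rename("n_rank_records")
    )
    rank_counts = rank_counts[rank_counts >= min_rank_records]
    sp_counts = (
        records.loc[sp_mask]
        .groupby(records.loc[sp_mask, "year"].astype(int))
        .size()
        .rename("n_species_records")
    )
    data = rank_counts.to_frame().join(sp_counts, how="left").fillna(0).reset_index()
    data["n_species_records"] = data["n_species_records"].astype(int)
    data["proportion"] = data["n_species_records"] / data["n_rank_records"]
    data = data[["year", "n_species_records", "n_rank_records", "proportion"]]
    return ProportionSeries(species, rank, data.sort_values("year").reset_index(drop=True))


def _ols_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, bool]:
    """Slope, stderr, t, p for y ~ x by centred closed-form least squares."""
    n = len(x)
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    if sxx == 0.0:
        raise ValueError("zero variance in year; regression undefined")
    slope = float(np.dot(xc, y) / sxx)
    intercept = float(y.mean())  # in centred coordinates
    resid = y - (intercept + slope * xc)
    sse = float(np.dot(resid, resid))
    dof = n - 2
    if sse <= max(1e-30, 1e-14 * float(np.dot(y, y))):
        # zero-residual fit: constant series -> no evidence (p = 1);
        # perfect nonzero trend -> maximal evidence (p = 0), flagged degenerate
        if slope == 0.0:
            return 0.0, 0.0, 0.0, 1.0, False
        return slope, 0.0, np.inf, 0.0, True
    s2 = sse / dof
    stderr = float(np.sqrt(s2 / sxx))
    t = slope / stderr
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return slope, stderr, t, p, False


def ols_trend(series: ProportionSeries, variant: str = "full") -> TrendFit | None:
    """OLS of proportion on calendar year with a two-sided t-test.

    Returns ``None`` (no fit) with fewer than three usable years.  The year
    covariate is centred before fitting for numerical stability, which
    leaves the slope unchanged.
    """
    data = series.data
    if len(data) < 3:
        return None
    x = data["year"].to_numpy(dtype=float)
    y = data["proportion"].to_numpy(dtype=float)
    slope, stderr, t, p, degen = _ols_closed_form(x, y)
    return TrendFit(
        species=series.species,
        rank=series.rank,
        variant=variant,
        slope=slope,
        stderr=stderr,
        t_stat=t,
        p_value=p,
        n_years=len(data),
        degenerate=degen,
    )


def classify_trend(fits: dict, alpha: float = 0.05) -> TrendCall:
    """Combine the four per-species fits into one call.

    ``fits`` maps (rank, variant) to a :class:`TrendFit` or ``None``.
    Within each variant, the provisional direction is the sign shared by all
    significant fits; significant fits with opposing signs exclude the
    species as discordant.  The final direction requires the same
    provisional direction in both variants, otherwise ``none``.
    """
    species = next(
        (f.species for f in fits.values() if f is not None), "<unknown>"
    )
    provisional: dict[str, str] = {}
    for variant in VARIANTS:
        sig = [
            fits.get((rank, variant))
            for rank in RANKS
            if fits.get((rank, variant)) is not None
            and fits[(rank, variant)].p_value <= alpha
            and fits[(rank, variant)].slope != 0.0
        ]
        signs = {("increasing" if f.slope > 0 else "declining") for f in sig}
        if len(signs) > 1:
            return TrendCall(species, "discordant_excluded", fits,
                             reason=f"opposing significant signs in {variant}")
        provisional[variant] = signs.pop() if signs else "none"
    if (
        provisional["full"] != "none"
        and provisional["full"] == provisional["excl_region"]
    ):
        return TrendCall(species, provisional["full"], fits)
    reason = ""
    if provisional["full"] != provisional["excl_region"]:
        reason = "not recovered in both dataset variants"
    return TrendCall(species, "none", fits, reason=reason)


class _VariantTables:
    """Year-count tables for one dataset variant, for fast per-species fits."""

    def __init__(self, df: pd.DataFrame, min_rank_records: int):
        years = df["year"].astype(int)
        self.species_totals = df.groupby("species").size()
        self.sp_year = df.groupby(["species", years]).size()
        # qualifying years (rank total >= threshold) per taxon, per rank
        self.rank_years: dict[str, dict[str, pd.Series]] = {}
        self.taxon_of: dict[str, dict[str, str]] = {}
        for rank in RANKS:
            totals = df.groupby([df[rank], years]).size()
            self.rank_years[rank] = {
                taxon: sub[sub >= min_rank_records].droplevel(0)
                for taxon, sub in totals.groupby(level=0)
            }
            self.taxon_of[rank] = (
                df[[rank, "species"]].dropna().drop_duplicates("species")
                .set_index("species")[rank].to_dict()
            )

    def fit(
        self, species: str, rank: str, variant: str, min_species_records: int
    ) -> TrendFit | None:
        if species not in self.species_totals.index:
            return None
        if int(self.species_totals[species]) < min_species_records:
            return None
        taxon = self.taxon_of[rank].get(species)
        if taxon is None:
            return None
        rank_totals = self.rank_years[rank].get(taxon)
        if rank_totals is None or len(rank_totals) < 3:
            return None
        sp_counts = self.sp_year.loc[species].reindex(rank_totals.index).fillna(0)
        x = rank_totals.index.to_numpy(dtype=float)
        y = (sp_counts.to_numpy(dtype=float) / rank_totals.to_numpy(dtype=float))
        slope, stderr, t, p, degen = _ols_closed_form(x, y)
        return TrendFit(species, rank, variant, slope, stderr, t, p, len(x), degen)


def run_trend_analysis(
    records: pd.DataFrame,
    excluded_region_polygon: BaseGeometry | None = None,
    alpha: float = 0.05,
    min_rank_records: int = 5,
    min_species_records: int = 10,
) -> tuple[list[TrendCall], pd.DataFrame]:
    """Fit and classify relative record trends for every species.

    Builds the full dataset and the variant without the exclusion region,
    fits class and phylum proportions per species in each, and classifies.
    Returns the calls plus a flat table of all fits and final directions.
    """
    variants: dict[str, pd.DataFrame] = {"full": records}
    if excluded_region_polygon is not None:
        geo_ok = records["lat"].notna() & records["lon"].notna()
        inside = np.zeros(len(records), dtype=bool)
        if geo_ok.any():
            inside[geo_ok.to_numpy()] = _covers(
                excluded_region_polygon,
                records.loc[geo_ok, "lon"].to_numpy(),
                records.loc[geo_ok, "lat"].to_numpy(),
            )
        kept = records.loc[~inside]
        if len(kept) == 0:
            raise ValueError("exclusion polygon removes every record")
        variants["excl_region"] = kept
    else:
        variants["excl_region"] = records

    # Precomputed per-variant tables; equivalent to calling annual_proportions
    # + ols_trend per species but ~100x faster on large simulated datasets
    # (the equivalence is asserted in the test suite).
    tables = {name: _VariantTables(df, min_rank_records) for name, df in variants.items()}

    all_species = sorted(records["species"].unique())
    calls: list[TrendCall] = []
    rows = []
    for sp in all_species:
        fits: dict[tuple[str, str], TrendFit | None] = {}
        for variant in VARIANTS:
            for rank in RANKS:
                fits[(rank, variant)] = tables[variant].fit(
                    sp, rank, variant, min_species_records
                )
        if all(f is None for f in fits.values()):
            call = TrendCall(sp, "none", fits, reason="no_fit")
        else:
            call = classify_trend(fits, alpha=alpha)
        calls.append(call)
        row: dict[str, object] = {"species": sp, "direction": call.direction,
                                  "reason": call.reason}
        for (rank, variant), fit in fits.items():
            prefix = f"{rank}_{variant}"
            row[f"{prefix}_slope"] = fit.slope if fit else np.nan
            row[f"{prefix}_p"] = fit.p_value if fit else np.nan
            row[f"{prefix}_n_years"] = fit.n_years if fit else 0
        rows.append(row)
    return calls, pd.DataFrame(rows)
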