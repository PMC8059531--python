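"""Time-split detectors: the post-cutoff first-record screen and the
binomial decline test, plus a gridded spatio-temporal artefact check.

Both detectors split the curated lot table at a cutoff year chosen to mark
the end of the first systematic multi-year survey era (1912 for the North
and Baltic Sea collections).  A year equal to the cutoff belongs to the
historical period; "after" always means strictly greater.

* Potential neozoa: species whose first record falls after the cutoff, once
  species that are plausibly just rare (fewer than ``min_records`` lots, a
  single collection year, or collected only during the most intensive survey
  window) are set aside.
* Potential decline: for each species, the lower tail of
  Binomial(n_total, p0) at the observed number of post-cutoff lots, where p0
  is the overall post-cutoff share of all lots.  The p-value is computed by
  exact summation of the probability mass function — no normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Baseline",
    "SpeciesWindowSummary",
    "split_counts",
    "baseline_proportion",
    "binomial_lower_tail",
    "decline_test",
    "neozoa_screen",
    "artefact_coverage",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = [
    "species",
    "n_total",
    "n_after",
    "first_year",
    "last_year",
    "n_distinct_years",
    "p_decline",
    "label",
]


@dataclass(frozen=True)
class Baseline:
    """Overall post-cutoff share of lots — the decline test's null probability."""

    p0: float
    n_records_total: int


@dataclass
class SpeciesWindowSummary:
    species: str
    n_total: int
    n_after: int
    first_year: int
    last_year: int
    n_distinct_years: int
    p_decline: float | None = None
    label: str = "unclassified"


def split_counts(records: pd.DataFrame, cutoff_year: int) -> pd.DataFrame:
    """Per-species lot counts before/after the cutoff (year > cutoff = after)."""
    if records["year"].isna().any():
        raise ValueError("all records must carry a collection year")
    df = records[["species", "year"]].copy()
    df["year"] = df["year"].astype(int)
    grouped = df.groupby("species")["year"]
    out = pd.DataFrame(
        {
            "n_total": grouped.size(),
            "n_after": grouped.apply(lambda y: int((y > cutoff_year).sum())),
            "first_year": grouped.min(),
            "last_year": grouped.max(),
            "n_distinct_years": grouped.nunique(),
        }
    ).reset_index()
    out["p_decline"] = np.nan
    out["label"] = "unclassified"
    return out[SUMMARY_COLUMNS]


def baseline_proportion(records: pd.DataFrame, cutoff_year: int) -> Baseline:
    """Exact overall proportion of lots collected after the cutoff."""
    years = records["year"]
    if years.isna().any():
        raise ValueError("all records must carry a collection year")
    n = len(years)
    n_after = int((years > cutoff_year).sum())
    if n_after == 0 or n_after == n:
        raise ValueError(
            f"all {n} records fall on one side of cutoff {cutoff_year}; "
            "the decline test is undefined"
        )
    return Baseline(p0=n_after / n, n_records_total=n)


def binomial_lower_tail(k: np.ndarray | int, n: np.ndarray | int, p: float) -> np.ndarray:
    """P(X <= k) for X ~ Binomial(n, p), by exact pmf summation.

    Vectorised over parallel arrays ``k`` and ``n``; builds the pmf table up
    to max(n) and sums the masked rows.  Intended for the lot-count scale
    (n up to a few thousand).
    """
    k = np.atleast_1d(np.asarray(k, dtype=int))
    n = np.atleast_1d(np.asarray(n, dtype=int))
    if np.any(k < 0) or np.any(k > n) or np.any(n < 0):
        raise ValueError("require 0 <= k <= n")
    j = np.arange(int(n.max()) + 1)
    pmf = stats.binom.pmf(j[None, :], n[:, None], p)
    mask = j[None, :] <= k[:, None]
    return np.minimum((pmf * mask).sum(axis=1), 1.0)


def decline_test(
    summaries: pd.DataFrame,
    baseline: Baseline,
    alpha: float = 0.05,
    correction: str = "none",
    min_records: int = 0,
) -> pd.DataFrame:
    """Flag species collected significantly less often than expected after
    the cutoff.

    ``p_decline`` is the exact binomial lower-tail probability of observing
    at most ``n_after`` post-cutoff lots out of ``n_total`` when each lot is
    independently post-cutoff with probability ``baseline.p0``.  A species is
    a ``declining_candidate`` when the (optionally Benjamini–Hochberg
    corrected) p-value is at most ``alpha``.  ``min_records`` optionally
    restricts the test to species with at least that many lots (off by
    default — the original procedure applied no floor).
    """
    if correction not in {"none", "benjamini_hochberg"}:
        raise ValueError(f"unknown correction {correction!r}")
    out = summaries.copy()
    eligible = out["n_total"] >= max(min_records, 1)
    k = out.loc[eligible, "n_after"].to_numpy()
    n = out.loc[eligible, "n_total"].to_numpy()
    p = binomial_lower_tail(k, n, baseline.p0)
    out.loc[eligible, "p_decline"] = p
    if correction == "benjamini_hochberg":
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        out.loc[eligible, "p_adjusted"] = p_adj
        significant = pd.Series(p_adj <= alpha, index=out.index[eligible])
    else:
        significant = pd.Series(p <= alpha, index=out.index[eligible])
    sig_idx = significant.index[significant]
    # the rare-species exclusion applies to the first-record screen only;
    # the decline test has no record floor by default, so it may reclassify
    # those species — but never a neozoa candidate (a post-cutoff-only
    # species has n_after = n_total and cannot have a small lower tail)
    keep = out.loc[sig_idx, "label"].isin(["unclassified", "rare_excluded"])
    out.loc[sig_idx[keep], "label"] = "declining_candidate"
    return out


def neozoa_screen(
    records: pd.DataFrame,
    cutoff_year: int,
    min_records: int = 10,
    intensive_window: tuple[int, int] = (1977, 1990),
) -> pd.DataFrame:
    """Screen for species first deposited after the cutoff year.

    Species with fewer than ``min_records`` lots, a single distinct
    collection year, or collected only within the closed intensive survey
    window are labelled ``rare_excluded`` — their late appearance is more
    plausibly an effort artefact than establishment.  Of the remainder,
    species whose first record postdates the cutoff are
    ``neozoa_candidate``; all others stay ``unclassified``.
    """
    summaries = split_counts(records, cutoff_year)
    lo, hi = intensive_window
    years = records[["species", "year"]].copy()
    years["year"] = years["year"].astype(int)
    in_window = (
        years.assign(inside=years["year"].between(lo, hi))
        .groupby("species")["inside"]
        .all()
    )
    only_window = summaries["species"].map(in_window)
    rare = (
        (summaries["n_total"] < min_records)
        | (summaries["n_distinct_years"] == 1)
        | only_window
    )
    summaries.loc[rare, "label"] = "rare_excluded"
    candidate = ~rare & (summaries["first_year"] > cutoff_year)
    summaries.loc[candidate, "label"] = "neozoa_candidate"
    return summaries


def artefact_coverage(
    records: pd.DataFrame,
    species: str,
    cutoff_year: int,
    cell_deg: float = 0.5,
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """Quantified spatio-temporal artefact check for one species.

    The study area is gridded into ``cell_deg`` × ``cell_deg`` lon/lat
    cells.  ``coverage`` is the fraction of the species' post-cutoff records
    falling in cells that hold at least one pre-cutoff record of *any*
    species; a species whose post-cutoff records mostly come from
    historically unsampled cells (coverage below ``threshold``) is flagged
    as a possible artefact of shifting collecting effort rather than a real
    faunal change.

    A species with no georeferenced post-cutoff records has nothing to
    question: coverage 1.0, not flagged.
    """
    if species not in set(records["species"]):
        raise ValueError(f"species {species!r} not present in records")
    geo = records.dropna(subset=["lat", "lon", "year"])
    cells_x = np.floor(geo["lon"].to_numpy() / cell_deg).astype(int)
    cells_y = np.floor(geo["lat"].to_numpy() / cell_deg).astype(int)
    cell_ids = pd.Series(list(zip(cells_x, cells_y)), index=geo.index)
    pre_cells = set(cell_ids[geo["year"] <= cutoff_year])
    post_mask = (geo["species"] == species) & (geo["year"] > cutoff_year)
    post_cells = cell_ids[post_mask]
    if len(post_cells) == 0:
        return 1.0, False
    coverage = float(np.mean([c in pre_cells for c in post_cells]))
    return coverage, bool(coverage < threshold)
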