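"""Relative record trends: proportions, OLS fits, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from faunatrends.trends import (
    ProportionSeries,
    TrendFit,
    annual_proportions,
    classify_trend,
    ols_trend,
    run_trend_analysis,
)
from conftest import make_records


def ols_matrix_oracle(x, y):
    """From-scratch least squares on the design matrix [1, x]."""
    X = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(x) - 2
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), dof)
    return float(beta[1]), se, float(t), float(p)


def series_from(years, props, species="Aa bb", rank="class"):
    data = pd.DataFrame(
        {
            "year": years,
            "n_species_records": 0,
            "n_rank_records": 1,
            "proportion": props,
        }
    )
    return ProportionSeries(species, rank, data)


def trend_records(class_counts, species_counts, start=1950, cls="Gastropoda"):
    """One focal species plus filler of the same class, by year."""
    rows = []
    for i, (nc, ns) in enumerate(zip(class_counts, species_counts)):
        y = start + i
        rows += [("Aa bb", cls, "Mollusca", y, 5.0, 5.0)] * ns
        rows += [("Filler sp1", cls, "Mollusca", y, 5.0, 5.0)] * (nc - ns)
    return make_records(rows)


# ------------------------------------------------------- annual proportions

def test_annual_proportions_worked_example():
    df = trend_records([10, 10, 10], [1, 2, 3])
    s = annual_proportions(df, "Aa bb", "class", min_species_records=1)
    assert s.data["proportion"].tolist() == pytest.approx([0.1, 0.2, 0.3])


def test_annual_proportions_drops_thin_rank_years():
    df = trend_records([10, 4, 10], [1, 1, 3])
    s = annual_proportions(df, "Aa bb", "class", min_species_records=1)
    assert s.data["year"].tolist() == [1950, 1952]


def test_annual_proportions_species_below_floor_gives_empty_series():
    df = trend_records([10, 10, 10], [2, 3, 3])
    s = annual_proportions(df, "Aa bb", "class", min_species_records=10)
    assert len(s) == 0
    assert ols_trend(s) is None


def test_annual_proportions_zero_fills_qualifying_years():
    df = trend_records([10, 10, 10], [5, 0, 5])
    s = annual_proportions(df, "Aa bb", "class", min_species_records=1)
    assert s.data["proportion"].tolist() == pytest.approx([0.5, 0.0, 0.5])


def test_proportions_sum_to_one_within_rank_year():
    rng = np.random.default_rng(4)
    rows = []
    for sp in [f"Genus{i} sp{i}" for i in range(6)]:
        for y in rng.choice(np.arange(1950, 1960), size=30):
            rows.append((sp, "Gastropoda", "Mollusca", int(y), 5.0, 5.0))
    df = make_records(rows)
    series = [
        annual_proportions(df, sp, "class", min_species_records=1)
        for sp in df["species"].unique()
    ]
    merged = pd.concat(
        [s.data.assign(species=s.species) for s in series], ignore_index=True
    )
    sums = merged.groupby("year")["proportion"].sum()
    assert np.allclose(sums.to_numpy(), 1.0)


def test_annual_proportions_unknown_rank_membership_errors():
    df = trend_records([10, 10, 10], [4, 4, 4])
    df.loc[df["species"] == "Aa bb", "class"] = None
    with pytest.raises(ValueError, match="unknown or ambiguous"):
        annual_proportions(df, "Aa bb", "class", min_species_records=1)


# ------------------------------------------------------------------ ols fit

def test_ols_worked_series_slope():
    s = series_from([2000, 2001, 2002, 2003, 2004], [0.1, 0.2, 0.15, 0.3, 0.25])
    fit = ols_trend(s)
    assert fit.slope == pytest.approx(0.04, abs=1e-12)  # Sxy/Sxx = 0.4/10


def test_ols_constant_series_is_null():
    fit = ols_trend(series_from([2000, 2001, 2002], [0.2, 0.2, 0.2]))
    assert fit.slope == 0.0 and fit.p_value == 1.0 and not fit.degenerate


def test_ols_perfect_trend_is_degenerate_maximal_evidence():
    fit = ols_trend(series_from([2000, 2001, 2002, 2003], [0.1, 0.2, 0.3, 0.4]))
    assert fit.slope == pytest.approx(0.1, abs=1e-12)
    assert fit.p_value == 0.0 and fit.degenerate


def test_ols_matches_matrix_oracle_on_random_series(rng):
    for _ in range(100):
        n = int(rng.integers(3, 40))
        years = np.sort(rng.choice(np.arange(1900, 2016), size=n, replace=False))
        props = rng.uniform(0, 1, size=n)
        fit = ols_trend(series_from(years.astype(float), props))
        slope, se, t, p = ols_matrix_oracle(years.astype(float), props)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.stderr == pytest.approx(se, rel=1e-10)
        assert fit.t_stat == pytest.approx(t, rel=1e-10)
        assert fit.p_value == pytest.approx(p, abs=1e-10)


# ----------------------------------------------------------- classification

def fit_with(rank, variant, slope, p):
    return TrendFit("Aa bb", rank, variant, slope, 0.01, slope / 0.01, p, 10)


def test_classify_requires_both_variants_and_consistent_sign():
    fits = {
        ("class", "full"): fit_with("class", "full", +0.01, 0.01),
        ("phylum", "full"): fit_with("phylum", "full", +0.005, 0.5),
        ("class", "excl_region"): fit_with("class", "excl_region", +0.01, 0.02),
        ("phylum", "excl_region"): fit_with("phylum", "excl_region", 0.001, 0.9),
    }
    assert classify_trend(fits, alpha=0.05).direction == "increasing"

    # significant but opposing signs within a variant: discordant
    fits_d = dict(fits)
    fits_d[("phylum", "full")] = fit_with("phylum", "full", -0.01, 0.001)
    assert classify_trend(fits_d, alpha=0.05).direction == "discordant_excluded"

    # significant in the full dataset only: sensitivity rule says none
    fits_s = dict(fits)
    fits_s[("class", "excl_region")] = fit_with("class", "excl_region", +0.01, 0.4)
    assert classify_trend(fits_s, alpha=0.05).direction == "none"


# -------------------------------------------------------------- full driver

def test_run_trend_analysis_without_exclusion_overlap_is_variant_invariant():
    import shapely

    df = trend_records([20] * 12, [1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6])
    far_box = shapely.box(100, 40, 101, 41)  # no records inside
    calls, table = run_trend_analysis(df, far_box, alpha=0.05)
    for _, row in table.iterrows():
        assert row["class_full_slope"] == pytest.approx(row["class_excl_region_slope"], abs=1e-15)
    directions = {c.species: c.direction for c in calls}
    assert directions["Aa bb"] == "increasing"


def test_species_endemic_to_excluded_region_gets_no_call():
    import shapely

    rows = []
    for i in range(12):
        rows.append(("Endemic species", "Gastropoda", "Mollusca", 1950 + i, 0.5, 0.5))
        rows += [("Filler sp1", "Gastropoda", "Mollusca", 1950 + i, 5.0, 5.0)] * 9
    df = make_records(rows)
    box = shapely.box(0, 0, 1, 1)
    calls, _ = run_trend_analysis(df, box, alpha=0.05)
    call = {c.species: c for c in calls}["Endemic species"]
    assert call.direction == "none"
    assert call.fits[("class", "excl_region")] is None


def test_fast_path_equals_per_species_operations(rng):
    # the vectorised driver must reproduce annual_proportions + ols_trend
    rows = []
    for i in range(8):
        sp = f"Genus{i} sp{i}"
        years = rng.choice(np.arange(1940, 2010), size=int(rng.integers(8, 60)))
        for y in years:
            rows.append((sp, "Gastropoda" if i % 2 else "Bivalvia", "Mollusca",
                         int(y), 5.0, 5.0))
    df = make_records(rows)
    _, table = run_trend_analysis(df, None, alpha=0.05)
    for _, row in table.iterrows():
        for rank in ("class", "phylum"):
            series = annual_proportions(df, row["species"], rank)
            fit = ols_trend(series)
            if fit is None:
                assert np.isnan(row[f"{rank}_full_slope"])
            else:
                assert row[f"{rank}_full_slope"] == pytest.approx(fit.slope, abs=1e-12)
                assert row[f"{rank}_full_p"] == pytest.approx(fit.p_value, abs=1e-12)


def test_planted_increasing_species_is_recovered():
    from faunatrends.synthetic import (
        Pulse,
        ScenarioConfig,
        SpeciesSpec,
        simulate_collections,
    )

    hits = 0
    for seed in range(5):
        species = [
            SpeciesSpec(f"Genus{i:02d} simulatus", "Gastropoda", "Mollusca",
                        "stable", abundance=2.0)
            for i in range(9)
        ] + [
            SpeciesSpec("Genus09 simulatus", "Gastropoda", "Mollusca",
                        "increasing", abundance=1.0, rate=1.02)
        ]
        cfg = ScenarioConfig(
            year_start=1900, year_end=2000, grid_nx=3, grid_ny=3,
            species=species, pulses=[], baseline=0.06, seed=100 + seed,
        )
        records, _ = simulate_collections(cfg)
        calls, _ = run_trend_analysis(records, None, alpha=0.05)
        directions = {c.species: c.direction for c in calls}
        hits += directions["Genus09 simulatus"] == "increasing"
    assert hits >= 4
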