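"""Red-List concordance check: do record counts track abundance categories?

The downstream detectors assume that deposition frequency reflects natural
abundance — common species should have more collection lots than rare ones.
This module tests that assumption by regressing per-species record counts on
an independent ordered abundance classification (in the original study, the
German Red List categories for benthic marine invertebrates) with a Poisson
log-linear model.

For a single categorical factor the Poisson maximum-likelihood fit has a
closed form: the fitted mean of each category equals the category's sample
mean, and the deviance follows from the Poisson log-likelihood with the
convention 0·log 0 = 0.  The model is compared with the intercept-only model
by a likelihood-ratio chi-square test on (#categories − 1) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceTable",
    "GLMFit",
    "poisson_factor_glm",
    "abundance_concordance",
    "load_abundance",
]


@dataclass
class AbundanceTable:
    """Species → ordered abundance category, with the declared category order."""

    categories: Mapping[str, str]
    order: Sequence[str]

    def __post_init__(self) -> None:
        extra = set(self.categories.values()) - set(self.order)
        if extra:
            raise ValueError(f"categories not in declared order: {sorted(extra)}")


def load_abundance(path: str | Path, order: Sequence[str]) -> AbundanceTable:
    """Read a CSV with columns species, category."""
    df = pd.read_csv(path)
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in abundance table")
    return AbundanceTable(dict(zip(df["species"], df["category"])), list(order))


@dataclass
class GLMFit:
    """One-way Poisson log-linear fit of counts on a categorical factor."""

    categories: list[str]
    fitted_means: dict[str, float]
    coefficients: dict[str, float]  # log(mean_g / mean_ref); ref category -> 0
    reference: str
    deviance: float
    null_deviance: float
    lr_stat: float
    df: int
    p_value: float


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    # unit deviance 2*(y log(y/mu) - (y - mu)), with 0 log 0 = 0
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def poisson_factor_glm(
    counts: Sequence[int],
    groups: Sequence[str],
    order: Sequence[str] | None = None,
) -> GLMFit:
    """Fit a Poisson model with a single categorical predictor.

    The fitted mean of category *g* is its sample mean (the exact MLE for
    this layout); the coefficient of *g* is log(mean_g / mean_ref) with the
    reference being the first category in ``order`` (or first appearance).
    A category whose counts are all zero gets a −inf coefficient sentinel
    and a warning; it still enters the likelihood-ratio test.
    """
    y = np.asarray(counts, dtype=float)
    g = pd.Series(list(groups))
    if len(y) != len(g):
        raise ValueError("counts and groups differ in length")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be non-negative integers")
    if order is None:
        order = list(dict.fromkeys(g))
    present = [c for c in order if (g == c).any()]
    if len(present) < 2:
        raise ValueError("need at least two categories with observations")
    if not np.any(y > 0):
        raise ValueError("all counts are zero; model undefined")

    means = {c: float(y[(g == c).to_numpy()].mean()) for c in present}
    ref = present[0]
    coeffs: dict[str, float] = {}
    for c in present:
        if means[c] == 0.0:
            warnings.warn(
                f"category {c!r} has all-zero counts; coefficient is -inf",
                RuntimeWarning,
                stacklevel=2,
            )
            coeffs[c] = -np.inf
        elif means[ref] == 0.0:
            coeffs[c] = np.inf if c != ref else 0.0
        else:
            coeffs[c] = float(np.log(means[c] / means[ref]))

    mu = g.map(means).to_numpy(dtype=float)
    # cells in an all-zero category have y = mu = 0 and contribute 0 deviance
    pos = mu > 0
    dev = _poisson_deviance(y[pos], mu[pos])
    mu0 = np.full_like(y, y.mean())
    null_dev = _poisson_deviance(y, mu0)
    lr = max(null_dev - dev, 0.0)
    df = len(present) - 1
    p = float(stats.chi2.sf(lr, df)) if lr > 0 else 1.0
    return GLMFit(
        categories=present,
        fitted_means=means,
        coefficients=coeffs,
        reference=ref,
        deviance=dev,
        null_deviance=null_dev,
        lr_stat=lr,
        df=df,
        p_value=p,
    )


def abundance_concordance(
    species_counts: Mapping[str, int],
    abundance: AbundanceTable,
) -> tuple[GLMFit, int, pd.DataFrame]:
    """Test record counts against the abundance classification.

    Restricts to species present in both tables, fits
    :func:`poisson_factor_glm` with the declared category order, and returns
    the fit, the number of shared species, and a per-category descriptive
    table (n species, min/median/max record count).
    """
    shared = sorted(set(species_counts) & set(abundance.categories))
    if not shared:
        raise ValueError("no species shared between record counts and abundance table")
    counts = [int(species_counts[s]) for s in shared]
    groups = [abundance.categories[s] for s in shared]
    fit = poisson_factor_glm(counts, groups, order=abundance.order)
    desc = (
        pd.DataFrame({"category": groups, "n_records": counts})
        .groupby("category")["n_records"]
        .agg(n_species="size", min="min", median="median", max="max")
        .reindex([c for c in abundance.order if c in set(groups)])
        .reset_index()
    )
    return fit, len(shared), desc
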