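"""Posterior summaries of the fitted model.

All summaries are deterministic functions of the stored draws: average
rate profiles by age, birth cohort and period; area-level multiplicative
effects exp(phi) with exceedance probabilities P(exp(phi) > 1); joint
space-time surfaces exp(phi + delta); region-to-national cohort rate
ratios; and age-specific rate trajectories against cohort or period.

"Average rates" over a margin are population-weighted by default (weights
n_gait), so the national profile at a level equals total expected deaths
over total person-years there; pass ``weighted=False`` for unweighted
means of the cell rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import MortalityDataset
from .errors import StructureError
from .inference import PosteriorResult, exceedance_probability
from .structure import cohort_index_grid

__all__ = [
    "median_rate_grid",
    "average_rate_profile",
    "region_effect_map",
    "spacetime_surface",
    "cohort_ratio_map",
    "age_profiles_by",
    "summary_bundle",
]

PER = 100_000.0


def median_rate_grid(result: PosteriorResult, dataset: MortalityDataset) -> np.ndarray:
    """Posterior-median rate per cell, shape (G, A, I, T), on the rate scale.

    The median commutes with exp, so this equals exp(median log-rate);
    computed area-by-area to bound memory.
    """
    dims = result.spec.dims
    out = np.empty(dims.shape)
    kgrid = cohort_index_grid(dims)
    b = result.pooled("beta")
    al = result.pooled("alpha")
    ga = result.pooled("gamma")
    ka = result.pooled("kappa")[:, :, kgrid]  # (S, G, I, T)
    ph = result.pooled("phi")
    de = result.pooled("delta")
    base = b[:, :, None, None] + al[:, :, None, :] + ga[:, :, :, None] + ka
    for a in range(dims.A):
        draws = base + (ph[:, a] + 0.0)[:, None, None, None] + de[:, a][:, None, None, :]
        out[:, a] = np.median(draws, axis=0)
    return np.exp(out)


def _axis_groups(dataset: MortalityDataset, axis: str):
    """Iterate (label, mask over the (I, T) grid) for the requested margin."""
    dims = dataset.dims
    if axis == "age":
        for i, lab in enumerate(dataset.age_groups):
            m = np.zeros((dims.I, dims.T), dtype=bool)
            m[i, :] = True
            yield lab, m
    elif axis == "period":
        for t, year in enumerate(dataset.years):
            m = np.zeros((dims.I, dims.T), dtype=bool)
            m[:, t] = True
            yield year, m
    elif axis == "cohort":
        kgrid = cohort_index_grid(dims)
        for k in range(dims.K):
            m = kgrid == k
            if m.any():
                yield k + 1, m
    else:
        raise StructureError(f"unknown axis {axis!r}; use age, cohort or period")


def average_rate_profile(
    result: PosteriorResult,
    dataset: MortalityDataset,
    axis: str,
    gender: int,
    areas: list[int] | None = None,
    weighted: bool = True,
    rate_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Average posterior-median rate per level of age, cohort or period.

    For each level, cells at that level (over the selected areas) are
    averaged, population-weighted by default, and scaled per 100,000.
    """
    rates = rate_grid if rate_grid is not None else median_rate_grid(result, dataset)
    a_idx = np.arange(dataset.dims.A) if areas is None else np.asarray(areas)
    r = rates[gender][a_idx]       # (A', I, T)
    n = dataset.population[gender][a_idx]
    rows = []
    for label, mask in _axis_groups(dataset, axis):
        w = n[:, mask]
        if w.sum() <= 0:
            continue  # level with no person-years: excluded
        vals = r[:, mask]
        avg = float(np.average(vals, weights=w)) if weighted else float(vals.mean())
        rows.append({axis: label, "rate": avg * PER})
    return pd.DataFrame(rows)


def region_effect_map(result: PosteriorResult, area_labels: list[str] | None = None) -> pd.DataFrame:
    """Per-area exp(phi) posterior median and exceedance P(exp(phi) > 1)."""
    if "phi" not in result.spec.effects:
        raise StructureError("model has no spatial effect phi")
    phi = result.pooled("phi")  # (S, A)
    A = phi.shape[1]
    labels = area_labels if area_labels is not None else [str(a + 1) for a in range(A)]
    return pd.DataFrame(
        {
            "area": labels,
            "effect": np.exp(np.median(phi, axis=0)),
            "prob_above_1": [exceedance_probability(np.exp(phi[:, a]), 1.0) for a in range(A)],
        }
    )


def spacetime_surface(result: PosteriorResult, area_labels=None, years=None) -> pd.DataFrame:
    """Posterior median of exp(phi_a + delta_at) per (area, period)."""
    if result.spec.interaction_type == "none":
        raise StructureError("model has no space-time interaction delta")
    phi = result.pooled("phi")      # (S, A)
    delta = result.pooled("delta")  # (S, A, T)
    surf = np.median(np.exp(phi[:, :, None] + delta), axis=0)  # (A, T)
    A, T = surf.shape
    labels = area_labels if area_labels is not None else [str(a + 1) for a in range(A)]
    yrs = years if years is not None else list(range(1, T + 1))
    rows = [
        {"area": labels[a], "year": yrs[t], "effect": surf[a, t]}
        for a in range(A)
        for t in range(T)
    ]
    return pd.DataFrame(rows)


def cohort_ratio_map(
    result: PosteriorResult,
    dataset: MortalityDataset,
    gender: int,
    weighted: bool = True,
) -> pd.DataFrame:
    """Region-specific average cohort rates divided by the national cohort profile."""
    rates = median_rate_grid(result, dataset)
    national = average_rate_profile(
        result, dataset, "cohort", gender, weighted=weighted, rate_grid=rates
    ).set_index("cohort")["rate"]
    rows = []
    for a, area in enumerate(dataset.areas):
        regional = average_rate_profile(
            result, dataset, "cohort", gender, areas=[a], weighted=weighted, rate_grid=rates
        ).set_index("cohort")["rate"]
        for k, r in regional.items():
            nat = national.get(k, np.nan)
            if not np.isfinite(nat) or nat <= 0:
                continue  # national profile unavailable at this cohort
            rows.append({"area": area, "cohort": k, "ratio": r / nat})
    return pd.DataFrame(rows)


def age_profiles_by(
    result: PosteriorResult,
    dataset: MortalityDataset,
    axis: str,
    gender: int,
    areas: list[int] | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-age-group rate trajectories against birth cohort or period.

    Each age group i contributes points at the T cohorts k = M (I - i) + t,
    t = 1..T, or at each period.  Areas are aggregated population-weighted
    unless a subset is given.
    """
    if axis not in ("cohort", "period"):
        raise StructureError(f"axis must be 'cohort' or 'period', got {axis!r}")
    dims = dataset.dims
    rates = median_rate_grid(result, dataset)
    a_idx = np.arange(dims.A) if areas is None else np.asarray(areas)
    kgrid = cohort_index_grid(dims)
    rows = []
    for i, age in enumerate(dataset.age_groups):
        for t, year in enumerate(dataset.years):
            r = rates[gender, a_idx, i, t]
            n = dataset.population[gender, a_idx, i, t]
            val = float(np.average(r, weights=n)) if weighted else float(r.mean())
            rows.append(
                {
                    "age_group": age,
                    "cohort": int(kgrid[i, t]) + 1,
                    "period": year,
                    "rate": val * PER,
                }
            )
    df = pd.DataFrame(rows)
    key = "cohort" if axis == "cohort" else "period"
    return df[["age_group", key, "rate"]]


def summary_bundle(result: PosteriorResult, dataset: MortalityDataset) -> dict[str, pd.DataFrame]:
    """Every reported summary in one dictionary of tables."""
    out: dict[str, pd.DataFrame] = {}
    rates = median_rate_grid(result, dataset)
    for axis in ("age", "cohort", "period"):
        for g, gender in enumerate(dataset.genders):
            out[f"avg_rate_by_{axis}_{gender}"] = average_rate_profile(
                result, dataset, axis, g, rate_grid=rates
            )
    if "phi" in result.spec.effects:
        out["region_effects"] = region_effect_map(result, dataset.areas)
        if result.spec.interaction_type != "none":
            out["spacetime"] = spacetime_surface(result, dataset.areas, dataset.years)
    for g, gender in enumerate(dataset.genders):
        out[f"cohort_ratios_{gender}"] = cohort_ratio_map(result, dataset, g)
        out[f"age_by_cohort_{gender}"] = age_profiles_by(result, dataset, "cohort", g)
        out[f"age_by_period_{gender}"] = age_profiles_by(result, dataset, "period", g)
    return out
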