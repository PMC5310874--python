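"""Crude and directly standardized mortality rates per 100,000 person-years."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import MortalityDataset, StandardPopulation, esp2013_standard
from .errors import AlignmentError, DataValidationError

__all__ = [
    "crude_rate",
    "age_specific_rates",
    "direct_standardized_rate",
    "standardized_rate_series",
    "describe",
]

PER = 100_000.0


def crude_rate(deaths, population):
    """deaths / population scaled to per 100,000 person-years.

    Accepts scalars or arrays; population must be strictly positive.
    """
    deaths = np.asarray(deaths, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(deaths < 0):
        raise DataValidationError("negative death count")
    if np.any(~(population > 0)):
        raise DataValidationError("crude rate needs population > 0")
    out = deaths / population * PER
    return out.item() if out.ndim == 0 else out


def age_specific_rates(dataset: MortalityDataset) -> pd.DataFrame:
    """Crude rate per (gender, age group), aggregating areas and periods."""
    d = dataset.deaths.sum(axis=(1, 3)).astype(float)  # (G, I)
    n = dataset.population.sum(axis=(1, 3))
    rows = []
    for g, gender in enumerate(dataset.genders):
        for i, age in enumerate(dataset.age_groups):
            rows.append(
                {
                    "gender": gender,
                    "age_group": age,
                    "deaths": int(d[g, i]),
                    "population": n[g, i],
                    "rate": crude_rate(d[g, i], n[g, i]),
                }
            )
    return pd.DataFrame(rows)


def direct_standardized_rate(
    age_rates, std: StandardPopulation, age_groups: list[str] | None = None
):
    """Directly standardized rate: weighted mean of age-specific rates.

    ``age_rates`` is a vector of rates per 100,000 aligned with the
    standard's age groups; pass ``age_groups`` to check the alignment by
    label.  Weights are renormalized to sum to one, so the result is a
    convex combination of the age-specific rates.
    """
    r = np.asarray(age_rates, dtype=float)
    if r.shape[-1] != std.weights.size:
        raise AlignmentError(
            f"{r.shape[-1]} age rates vs {std.weights.size} standard weights"
        )
    if age_groups is not None and list(age_groups) != list(std.age_groups):
        raise AlignmentError(
            f"age-group labels differ: {list(age_groups)} vs {list(std.age_groups)}"
        )
    out = r @ std.normalized
    return out.item() if np.ndim(out) == 0 else out


def standardized_rate_series(
    dataset: MortalityDataset, std: StandardPopulation | None = None
) -> pd.DataFrame:
    """Age-standardized rate per (gender, year) using the direct method."""
    std = std if std is not None else esp2013_standard()
    rows = []
    for g, gender in enumerate(dataset.genders):
        for t, year in enumerate(dataset.years):
            d = dataset.deaths[g, :, :, t].sum(axis=0).astype(float)  # per age
            n = dataset.population[g, :, :, t].sum(axis=0)
            asr = direct_standardized_rate(crude_rate(d, n), std, dataset.age_groups)
            rows.append({"gender": gender, "year": year, "asr": asr})
    return pd.DataFrame(rows)


def describe(dataset: MortalityDataset, std: StandardPopulation | None = None) -> pd.DataFrame:
    """Descriptive table: crude age-specific rates plus per-year ASRs."""
    age = age_specific_rates(dataset)
    age.insert(0, "kind", "age_specific")
    asr = standardized_rate_series(dataset, std)
    asr.insert(0, "kind", "standardized")
    return pd.concat([age, asr], ignore_index=True)
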