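"""Direct age standardization, the stratum inclusion filter, and rate
comparison utilities.

The directly standardized rate is the weighted average of age-band
crude rates, with weights taken from a fixed standard population
(here the 2000 U.S. standard million by default) and renormalized over
the bands actually present so partial age windows (25-49, 50-69,
70-84) are handled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import StratumCounts

__all__ = [
    "StandardPopulation",
    "US_STANDARD_2000",
    "us_standard_2000",
    "direct_standardized_rate",
    "inclusion_filter",
    "InclusionResult",
    "percent_difference",
    "rate_table_from_counts",
]

# 2000 U.S. standard million, 5-year age bands 0-4 ... 80-84, 85+
# (Census P25-1130 projected population, scaled to 1,000,000).
US_STANDARD_2000: dict[str, float] = {
    "0-4": 69135, "5-9": 72533, "10-14": 73032, "15-19": 72169,
    "20-24": 66478, "25-29": 64529, "30-34": 71044, "35-39": 80762,
    "40-44": 81851, "45-49": 72118, "50-54": 62716, "55-59": 48454,
    "60-64": 38793, "65-69": 34264, "70-74": 31773, "75-79": 27000,
    "80-84": 17842, "85+": 15508,
}


@dataclass(frozen=True)
class StandardPopulation:
    """Age-band weights of a standard population.

    Weights are normalized to sum to 1 on construction; the
    standardized rate is therefore invariant to uniform rescaling of
    the raw weights.
    """

    weights: pd.Series  # indexed by age-band label

    def __post_init__(self):
        w = pd.Series(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("standard-population weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("standard-population weights sum to zero")
        if w.index.duplicated().any():
            raise ValueError("duplicate age-band labels in standard population")
        object.__setattr__(self, "weights", w / total)

    @classmethod
    def from_csv(cls, path) -> "StandardPopulation":
        df = pd.read_csv(path)
        if not {"age_band", "weight"} <= set(df.columns):
            raise ValueError("standard population CSV needs columns age_band,weight")
        return cls(weights=df.set_index("age_band")["weight"])

    def restrict(self, bands) -> "StandardPopulation":
        """Weights renormalized over a subset of bands (partial age window)."""
        missing = [b for b in bands if b not in self.weights.index]
        if missing:
            raise ValueError(f"age bands not in standard population: {missing}")
        return StandardPopulation(weights=self.weights.loc[list(bands)])


def us_standard_2000() -> StandardPopulation:
    """The 2000 U.S. standard population as band weights."""
    return StandardPopulation(weights=pd.Series(US_STANDARD_2000, dtype=float))


def direct_standardized_rate(counts: StratumCounts, std: StandardPopulation) -> float:
    """Directly standardized rate per 100,000 person-years.

    rate = 100000 * sum_a w_a * cases_a / pop_a, with the standard
    weights renormalized over the bands present in ``counts``.
    """
    bands = list(counts.age_bands)
    have = set(std.weights.index)
    missing = [b for b in bands if b not in have]
    if missing:
        raise ValueError(f"age bands missing from standard population: {missing}")
    pop = np.asarray(counts.population, dtype=float)
    cases = np.asarray(counts.cases, dtype=float)
    zero = [b for b, p in zip(bands, pop) if p <= 0]
    if zero:
        raise ValueError(f"zero or negative population in age bands: {zero}")
    if np.any(cases < 0):
        raise ValueError("negative case counts")
    w = std.restrict(bands).weights.to_numpy()
    return float(1e5 * np.sum(w * cases / pop))


def rate_table_from_counts(counts_df: pd.DataFrame, std: StandardPopulation) -> pd.DataFrame:
    """Standardized rate and cumulative case count per county-stratum.

    ``counts_df`` has columns county,cancer,age_group,sex,age_band,
    cases,population (one row per age band).  Returns a RateTable with
    columns county,cancer,age_group,sex,rate,cases.
    """
    required = {"county", "cancer", "age_group", "sex", "age_band", "cases", "population"}
    missing = required - set(counts_df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    rows = []
    keys = ["county", "cancer", "age_group", "sex"]
    for key, grp in counts_df.groupby(keys, sort=True):
        sc = StratumCounts(
            age_bands=tuple(grp["age_band"]),
            cases=grp["cases"].to_numpy(),
            population=grp["population"].to_numpy(dtype=float),
        )
        rate = direct_standardized_rate(sc, std)
        rows.append((*key, rate, int(grp["cases"].sum())))
    return pd.DataFrame(rows, columns=[*keys, "rate", "cases"])


@dataclass(frozen=True)
class InclusionResult:
    """Outcome of the robustness inclusion filter.

    ``required_counties`` is the smallest integer strictly exceeding
    min_fraction x n_counties_total; a stratum is retained iff its
    number of counties with cumulative cases strictly above
    ``min_cases`` reaches that threshold.
    """

    retained: tuple[tuple, ...]  # (cancer, age_group, sex) keys
    qualifying: pd.DataFrame  # per-stratum qualifying-county counts
    required_counties: int
    min_cases: int
    min_fraction: float


def inclusion_filter(
    rates: pd.DataFrame,
    n_counties_total: int,
    min_fraction: float = 0.6,
    min_cases: int = 5,
) -> InclusionResult:
    """Retain strata where > min_fraction of all counties report
    > min_cases cumulative cases (both inequalities strict)."""
    if n_counties_total <= 0:
        raise ValueError("n_counties_total must be positive")
    required = math.floor(min_fraction * n_counties_total) + 1
    keys = ["cancer", "age_group", "sex"]
    rows = []
    retained = []
    for key, grp in rates.groupby(keys, sort=True):
        n_qual = int((grp["cases"] > min_cases).sum())
        keep = n_qual > min_fraction * n_counties_total
        rows.append((*key, n_qual, keep))
        if keep:
            retained.append(key)
    qualifying = pd.DataFrame(rows, columns=[*keys, "n_qualifying", "retained"])
    return InclusionResult(
        retained=tuple(retained),
        qualifying=qualifying,
        required_counties=required,
        min_cases=min_cases,
        min_fraction=min_fraction,
    )


def percent_difference(rate_a: float, rate_ref: float) -> float:
    """100 x (rate_a - rate_ref) / rate_ref."""
    if rate_ref <= 0:
        raise ValueError("reference rate must be positive")
    return 100.0 * (rate_a - rate_ref) / rate_ref
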