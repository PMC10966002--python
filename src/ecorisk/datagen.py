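"""Synthetic county-level study data with known ground truth.

Everything the analysis pipeline consumes can be generated here: a
counties x exposures table with block correlation structure, a county
outcome with planted standardized effects, Poisson age-band case counts
for direct-standardization checks, and annual piecewise log-linear
incidence series for trend analysis.

Exposures are jointly Gaussian.  Real county-level exposure measures are
mixed-scale, but every variable is z-scored before modelling, so the
correlation structure is the only feature downstream stages see and
Gaussianity is the minimal sufficient model.

A single global seed is expanded into independent per-generator
sub-streams (via numpy SeedSequence spawn keys), so adding a new
generator never perturbs existing draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "TrendSpec",
    "StratumCounts",
    "AnnualSeries",
    "generate_exposures",
    "generate_outcome",
    "generate_counts",
    "generate_trend_series",
    "noise_sd_for_r2",
    "write_fixtures",
]

# Fixed spawn keys: one independent random stream per generator.
_STREAMS = {
    "exposures": 0,
    "outcome": 1,
    "counts": 2,
    "trend": 3,
    "permutation": 4,
    "fixtures": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# exposure tables


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a counties x exposures table.

    ``variable_blocks`` is a list of (block size, within-block
    correlation); variables in different blocks are independent.  The
    implied equicorrelation matrix of each block must be positive
    semi-definite, which for a block of size m requires
    rho >= -1/(m - 1).  Variables are named x01, x02, ... across blocks
    unless ``variable_names`` overrides them.
    """

    n_counties: int = 62
    variable_blocks: tuple[tuple[int, float], ...] = ((31, 0.0),)
    planted_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0
    variable_names: tuple[str, ...] | None = None

    @property
    def n_variables(self) -> int:
        return sum(m for m, _ in self.variable_blocks)

    def names(self) -> list[str]:
        if self.variable_names is not None:
            return list(self.variable_names)
        return [f"x{i + 1:02d}" for i in range(self.n_variables)]

    def validate(self) -> None:
        if self.n_counties <= 0:
            raise ValueError("n_counties must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for bi, (m, rho) in enumerate(self.variable_blocks):
            if m <= 0:
                raise ValueError(f"block {bi}: size must be positive")
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"block {bi}: correlation {rho} outside [-1, 1]")
            if m > 1 and rho < -1.0 / (m - 1):
                raise ValueError(
                    f"block {bi} (size {m}, correlation {rho}): implied "
                    f"correlation matrix is not positive semi-definite "
                    f"(need rho >= {-1.0 / (m - 1):.4f})"
                )
        names = self.names()
        if len(names) != self.n_variables:
            raise ValueError("variable_names length does not match blocks")
        unknown = sorted(set(self.planted_effects) - set(names))
        if unknown:
            raise ValueError(f"planted effect names not among variables: {unknown}")


def generate_exposures(spec: SyntheticSpec) -> pd.DataFrame:
    """Draw the exposure table implied by ``spec``.

    Returns a DataFrame indexed by county id (c01, c02, ...) with one
    column per variable; each block is sampled from an equicorrelated
    multivariate normal with unit marginals.  Deterministic per seed.
    """
    spec.validate()
    rng = _rng(spec.seed, "exposures")
    cols = []
    for m, rho in spec.variable_blocks:
        # equicorrelation: x = sqrt(rho)*shared + sqrt(1-rho)*idiosyncratic
        if rho >= 0:
            shared = rng.standard_normal((spec.n_counties, 1))
            own = rng.standard_normal((spec.n_counties, m))
            block = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        else:
            cov = np.full((m, m), rho)
            np.fill_diagonal(cov, 1.0)
            L = np.linalg.cholesky(cov + 1e-12 * np.eye(m))
            block = rng.standard_normal((spec.n_counties, m)) @ L.T
        cols.append(block)
    X = np.hstack(cols)
    counties = [f"c{i + 1:02d}" for i in range(spec.n_counties)]
    return pd.DataFrame(X, index=pd.Index(counties, name="county"), columns=spec.names())


# ---------------------------------------------------------------------------
# outcomes


@dataclass(frozen=True)
class OutcomeSample:
    """A generated outcome vector plus its realized population R^2.

    ``population_r2`` is Var(signal) / (Var(signal) + noise_sd^2) with
    the signal variance computed from the sample covariance of the
    realized exposures.
    """

    y: pd.Series
    signal_var: float
    noise_sd: float

    @property
    def population_r2(self) -> float:
        denom = self.signal_var + self.noise_sd**2
        return self.signal_var / denom if denom > 0 else 0.0


def generate_outcome(
    X: pd.DataFrame,
    effects: dict[str, float],
    noise_sd: float,
    seed: int,
) -> OutcomeSample:
    """y = sum_i beta_i x_i + eps with eps ~ iid Normal(0, noise_sd^2)."""
    unknown = sorted(set(effects) - set(X.columns))
    if unknown:
        raise ValueError(f"unknown effect names: {unknown}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = _rng(seed, "outcome")
    signal = np.zeros(len(X))
    for name, beta in effects.items():
        signal = signal + beta * X[name].to_numpy()
    eps = rng.standard_normal(len(X)) * noise_sd
    if effects:
        names = list(effects)
        beta = np.array([effects[nm] for nm in names])
        S = np.cov(X[names].to_numpy(), rowvar=False, ddof=1)
        S = np.atleast_2d(S)
        signal_var = float(beta @ S @ beta)
    else:
        signal_var = 0.0
    y = pd.Series(signal + eps, index=X.index, name="y")
    return OutcomeSample(y=y, signal_var=signal_var, noise_sd=float(noise_sd))


def noise_sd_for_r2(signal_var: float, target_r2: float) -> float:
    """Noise SD giving population R^2 = target for a given signal variance."""
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    return float(np.sqrt(signal_var * (1.0 - target_r2) / target_r2))


# ---------------------------------------------------------------------------
# age-band case counts


@dataclass(frozen=True)
class StratumCounts:
    """Per age-band case counts and person-year populations for one
    county-stratum (cancer x age-group x sex)."""

    age_bands: tuple[str, ...]
    cases: np.ndarray  # nonnegative integers
    population: np.ndarray  # person-years, positive
    county: str = "c01"
    cancer: str = "all"
    age_group: str = "all"
    sex: str = "all"

    def __post_init__(self):
        if len(self.age_bands) != len(self.cases) or len(self.cases) != len(self.population):
            raise ValueError("age_bands, cases and population must align")


def generate_counts(
    true_rates: np.ndarray,
    populations: np.ndarray,
    seed: int,
    age_bands: tuple[str, ...] | None = None,
    **labels,
) -> StratumCounts:
    """Poisson case counts with mean rate x population / 100,000 per band."""
    true_rates = np.asarray(true_rates, dtype=float)
    populations = np.asarray(populations, dtype=float)
    if np.any(true_rates < 0):
        raise ValueError("true rates must be nonnegative")
    if np.any(populations < 0):
        raise ValueError("populations must be nonnegative")
    rng = _rng(seed, "counts")
    mean = true_rates * populations / 1e5
    cases = rng.poisson(mean)
    if age_bands is None:
        age_bands = tuple(f"band{i + 1}" for i in range(len(true_rates)))
    return StratumCounts(
        age_bands=tuple(age_bands), cases=cases, population=populations, **labels
    )


# ---------------------------------------------------------------------------
# annual trend series


@dataclass(frozen=True)
class TrendSpec:
    """Piecewise log-linear annual incidence series.

    Each segment has a constant annual percent change (APC, %); the log
    rate is continuous at the break years.  ``segment_apcs`` must have
    one more entry than ``break_years``.
    """

    start_year: int = 2000
    end_year: int = 2018
    baseline_rate: float = 50.0
    segment_apcs: tuple[float, ...] = (0.0,)
    break_years: tuple[int, ...] = ()
    noise_sd_log: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be nonnegative")
        if len(self.segment_apcs) != len(self.break_years) + 1:
            raise ValueError("need exactly one APC per segment (breaks + 1)")
        if not 0 <= len(self.break_years) <= 2:
            raise ValueError("0 to 2 break years supported")
        if any(a <= -100.0 for a in self.segment_apcs):
            raise ValueError("APC must exceed -100%")
        if list(self.break_years) != sorted(set(self.break_years)):
            raise ValueError("break years must be strictly increasing")
        for b in self.break_years:
            if not self.start_year < b < self.end_year:
                raise ValueError(f"break year {b} not strictly inside the series")


@dataclass(frozen=True)
class AnnualSeries:
    """Annual age-standardized incidence rates for one cancer and sex."""

    years: np.ndarray
    rates: np.ndarray
    cancer: str = "all"
    sex: str = "all"

    def __post_init__(self):
        years = np.asarray(self.years)
        rates = np.asarray(self.rates, dtype=float)
        if len(years) != len(rates):
            raise ValueError("years and rates must align")
        if np.any(np.diff(years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(rates <= 0):
            raise ValueError("rates must be positive (log-linear model)")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "rates", rates)

    def __len__(self) -> int:
        return len(self.years)


def generate_trend_series(spec: TrendSpec) -> AnnualSeries:
    """Realize the piecewise log-linear series described by ``spec``.

    log rate(t) accumulates slope ln(1 + APC/100) per year within each
    segment, continuous at the breaks, plus iid Normal(0, noise_sd_log^2)
    noise on the log scale.
    """
    spec.validate()
    years = np.arange(spec.start_year, spec.end_year + 1)
    slopes = [np.log1p(a / 100.0) for a in spec.segment_apcs]
    bounds = [spec.start_year, *spec.break_years, spec.end_year]
    log_rate = np.empty(len(years), dtype=float)
    level = np.log(spec.baseline_rate)
    for seg, slope in enumerate(slopes):
        lo, hi = bounds[seg], bounds[seg + 1]
        mask = (years >= lo) & (years <= hi)
        log_rate[mask] = level + slope * (years[mask] - lo)
        level = level + slope * (hi - lo)
    rng = _rng(spec.seed, "trend")
    log_rate = log_rate + rng.standard_normal(len(years)) * spec.noise_sd_log
    return AnnualSeries(years=years, rates=np.exp(log_rate))


# ---------------------------------------------------------------------------
# fixture bundles


def write_fixtures(
    outdir: str | Path,
    seed: int = 0,
    n_counties: int = 62,
    n_noise_vars: int = 15,
    planted: dict[str, float] | None = None,
    target_r2: float = 0.5,
) -> dict:
    """Materialize a complete miniature study into ``outdir``.

    Writes exposures.csv (wide, county x variables, incl. the three
    forced race & SES columns and latitude terms), rates.csv (county
    standardized rates + cumulative cases for two synthetic strata),
    counts.csv and std_pop.csv (one stratum of age-band counts for the
    standardization path), trend.csv (two annual series), and
    ground_truth.json.  Returns the ground-truth dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if planted is None:
        planted = {"smoking": 0.5, "ozone": 0.5}

    solo_names = ["smoking", "ozone", "phys_inactivity"] + [
        f"noise{i + 1:02d}" for i in range(n_noise_vars)
    ]
    # one correlated pair above the 0.6 conflict threshold, the rest independent
    spec = SyntheticSpec(
        n_counties=n_counties,
        variable_blocks=((2, 0.8),) + tuple((1, 0.0) for _ in solo_names),
        seed=seed,
        variable_names=("pm25_nh4", "pm25_so4", *solo_names),
    )
    X = generate_exposures(spec)

    forced_spec = SyntheticSpec(
        n_counties=n_counties,
        variable_blocks=((3, 0.3), (1, 0.0), (1, 0.0)),
        seed=seed + 1,
        variable_names=("poverty", "uninsured", "pct_white", "latitude", "lat_noise"),
    )
    F = generate_exposures(forced_spec).drop(columns=["lat_noise"])
    F["latitude2"] = F["latitude"] ** 2

    all_X = pd.concat([X, F], axis=1)
    sig_var = float(sum(b**2 for b in planted.values()))
    noise_sd = noise_sd_for_r2(sig_var, target_r2)
    out = generate_outcome(all_X, planted, noise_sd, seed)

    rng = _rng(seed, "fixtures")
    rows = []
    for stratum_i, (cancer, age_group, sex, base, scale) in enumerate(
        [("lung", "25-49", "male", 50.0, 10.0), ("thyroid", "25-49", "female", 30.0, 6.0)]
    ):
        rate = np.clip(base + scale * out.y.to_numpy(), 1.0, None)
        pop = rng.uniform(2e4, 5e5, size=n_counties)
        cases = rng.poisson(rate * pop / 1e5 * 9)  # 9-year cumulative
        for c, r, cs in zip(all_X.index, rate, cases):
            rows.append((c, cancer, age_group, sex, round(float(r), 6), int(cs)))
    rates_df = pd.DataFrame(
        rows, columns=["county", "cancer", "age_group", "sex", "rate", "cases"]
    )

    bands = ("25-29", "30-34", "35-39", "40-44", "45-49")
    band_rates = np.array([20.0, 30.0, 45.0, 60.0, 80.0])
    weights = np.array([0.22, 0.21, 0.20, 0.19, 0.18])
    count_rows = []
    for ci, county in enumerate(all_X.index[:10]):
        pops = rng.uniform(1e4, 8e4, size=len(bands))
        sc = generate_counts(band_rates, pops, seed + 100 + ci, age_bands=bands,
                             county=county, cancer="lung", age_group="25-49", sex="male")
        for b, cs, p in zip(sc.age_bands, sc.cases, sc.population):
            count_rows.append((county, "lung", "25-49", "male", b, int(cs), round(float(p), 2)))
    counts_df = pd.DataFrame(
        count_rows,
        columns=["county", "cancer", "age_group", "sex", "age_band", "cases", "population"],
    )
    std_df = pd.DataFrame({"age_band": bands, "weight": weights})

    trend_rows = []
    for cancer, sex, apcs, breaks in [
        ("thyroid", "female", (3.0,), ()),
        ("colorectal", "male", (3.0, -2.0), (2009,)),
    ]:
        ts = TrendSpec(segment_apcs=apcs, break_years=breaks, noise_sd_log=0.02, seed=seed)
        series = generate_trend_series(ts)
        for yr, r in zip(series.years, series.rates):
            trend_rows.append((int(yr), round(float(r), 6), cancer, sex))
    trend_df = pd.DataFrame(trend_rows, columns=["year", "rate", "cancer", "sex"])

    all_X.round(9).to_csv(outdir / "exposures.csv")
    rates_df.to_csv(outdir / "rates.csv", index=False)
    counts_df.to_csv(outdir / "counts.csv", index=False)
    std_df.to_csv(outdir / "std_pop.csv", index=False)
    trend_df.to_csv(outdir / "trend.csv", index=False)

    truth = {
        "seed": seed,
        "planted_effects": planted,
        "noise_sd": noise_sd,
        "population_r2": out.population_r2,
        "forced": ["poverty", "uninsured", "pct_white"],
        "spatial": ["latitude", "latitude2"],
        "correlated_pair": ["pm25_nh4", "pm25_so4"],
        "trend_truth": {
            "thyroid/female": {"apcs": [3.0], "breaks": []},
            "colorectal/male": {"apcs": [3.0, -2.0], "breaks": [2009]},
        },
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return truth
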