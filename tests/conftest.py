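import numpy as np
import pandas as pd
import pytest

from ecorisk.datagen import SyntheticSpec, generate_exposures, generate_outcome, noise_sd_for_r2


@pytest.fixture(scope="session")
def planted_frame():
    """62 counties, two planted factors (beta = 0.5) among 20 candidates,
    three forced covariates, population R^2 = 0.5."""

    def make(seed):
        spec = SyntheticSpec(
            n_counties=62,
            variable_blocks=((2, 0.8),) + tuple((1, 0.0) for _ in range(18)),
            seed=seed,
        )
        X = generate_exposures(spec)
        forced = generate_exposures(
            SyntheticSpec(n_counties=62, variable_blocks=((3, 0.3),), seed=seed + 10_000,
                          variable_names=("poverty", "uninsured", "pct_white"))
        )
        planted = {"x03": 0.5, "x04": 0.5}
        noise = noise_sd_for_r2(0.5, 0.5)  # population signal variance 0.5
        y = generate_outcome(X, planted, noise, seed=seed).y
        return y, X, forced, tuple(planted)

    return make


@pytest.fixture(scope="session")
def null_frame():
    """Same layout, but the outcome is pure noise."""

    def make(seed):
        spec = SyntheticSpec(
            n_counties=62,
            variable_blocks=((2, 0.8),) + tuple((1, 0.0) for _ in range(18)),
            seed=seed,
        )
        X = generate_exposures(spec)
        forced = generate_exposures(
            SyntheticSpec(n_counties=62, variable_blocks=((3, 0.3),), seed=seed + 10_000,
                          variable_names=("poverty", "uninsured", "pct_white"))
        )
        y = generate_outcome(X, {}, 1.0, seed=seed).y
        return y, X, forced

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rate_table():
    """Rate table for inclusion-filter tests: one stratum with every
    county above the case threshold, one with exactly 37 of 62."""
    rows = []
    for i in range(62):
        rows.append((f"c{i:02d}", "lung", "25-49", "male", 50.0, 10))
        rows.append((f"c{i:02d}", "rare", "25-49", "male", 2.0, 6 if i < 37 else 3))
    return pd.DataFrame(rows, columns=["county", "cancer", "age_group", "sex", "rate", "cases"])
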