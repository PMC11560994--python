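import numpy as np
import pandas as pd
import pytest

from ammistab import (
    MAIZE_ERROR_DF,
    MAIZE_ERROR_MS,
    CellMeansMatrix,
    TrialData,
    fit_ammi,
    generate_met,
    load_maize_trial,
)


@pytest.fixture(scope="session")
def maize():
    """Packaged 69 x 5 maize trial (cell means + published reference values)."""
    return load_maize_trial()


@pytest.fixture(scope="session")
def maize_fit(maize):
    """Full-axis AMMI fit of the maize cell means with the published error stratum."""
    return fit_ammi(
        maize.means, n_axes="all", error_ms=MAIZE_ERROR_MS, error_df=MAIZE_ERROR_DF
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def small_trial():
    """A balanced 6 x 4 x 3 synthetic trial with modest noise."""
    trial, truth = generate_met(
        G=6, E=4, r=3, mu=10.0, alpha_sd=1.0, beta_sd=0.5,
        singular_values=(1.5, 0.7), block_sd=0.2, error_sd=0.3, seed=7,
    )
    return trial, truth


def random_means(rng, G, E, r=1, scale=1.0, loc=10.0) -> CellMeansMatrix:
    vals = loc + scale * rng.standard_normal((G, E))
    return CellMeansMatrix(
        pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(G)],
            columns=[f"e{j}" for j in range(E)],
        ),
        replicate_count=r,
    )


def trial_from_array(y: np.ndarray) -> TrialData:
    """Build a TrialData from a G x E x r array of plot yields."""
    G, E, r = y.shape
    rows = [
        (f"g{i}", f"e{j}", f"b{k}", float(y[i, j, k]))
        for j in range(E)
        for k in range(r)
        for i in range(G)
    ]
    return TrialData(pd.DataFrame(rows, columns=["genotype", "environment", "block", "yield"]))
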