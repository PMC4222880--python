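import numpy as np
import pandas as pd
import pytest

from pelagostat.simulate import default_simulation_spec, simulate_survey


@pytest.fixture(scope="session")
def small_survey():
    """A reduced 3-species, 4-year synthetic survey shared across tests."""
    return simulate_survey(default_simulation_spec(seed=42, n_years=4, n_bands=90))


@pytest.fixture()
def toy_csv(tmp_path):
    """A 4-row, 1-species, 1-year survey file."""
    df = pd.DataFrame(
        {
            "year": [2003] * 4,
            "lon": [4.0, 4.02, 4.0, 4.02],
            "lat": [42.5, 42.5, 42.52, 42.52],
            "anchovy": [1.0, 2.0, 0.0, 3.0],
        }
    )
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
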