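import numpy as np
import pandas as pd
import pytest

from ooclock import SampleTable, BetaMatrix, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale dataset reused by read-only tests."""
    config = SimulationConfig(
        n_probes=400,
        n_cattle_blood=40,
        n_cattle_oocyte=30,
        n_human_blood=0,
        n_blood_up=30,
        n_blood_down=30,
        n_oocyte_up=20,
        n_oocyte_down=20,
        n_shared=10,
        n_divergent=10,
        seed=11,
    )
    return simulate_dataset(config)


@pytest.fixture()
def sample_table():
    def make(n=6, tissue="blood", species="cattle", ages=None, donor=None):
        ages = ages if ages is not None else np.linspace(1.0, 12.0, n)
        lifespan = 38.0 if species == "cattle" else 122.5
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "species": species,
                "tissue": tissue,
                "age_years": ages,
                "max_lifespan_years": lifespan,
            }
        )
        if donor is not None:
            df["donor_id"] = donor
        return SampleTable(df)

    return make


@pytest.fixture()
def beta_matrix():
    def make(values, probes=None, samples=None):
        values = np.asarray(values, float)
        probes = probes or [f"cg{i}" for i in range(values.shape[0])]
        samples = samples or [f"s{i}" for i in range(values.shape[1])]
        return BetaMatrix(pd.DataFrame(values, index=probes, columns=samples))

    return make
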