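import numpy as np
import pandas as pd
import pytest

from dnamet.simulate import CohortSpec, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """3 cohorts, 6 metabolites, 3000 CpGs — shared light fixture."""
    cfg = SimulationConfig(
        cohort_specs=[CohortSpec("A", 200, 45, 12, 25, 3.5, 0.5),
                      CohortSpec("B", 180, 38, 10, 24, 3.0, 0.45),
                      CohortSpec("C", 180, 62, 9, 28, 4.0, 0.55)],
        n_metabolites=6, n_cpgs=3000, causal_cpgs_per_metabolite=100,
        missing_rate=0.002, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_survival():
    """6 subjects with censoring, hand-checkable."""
    return pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                         "event": [1, 0, 1, 1, 0, 1]},
                        index=[f"s{i}" for i in range(6)])
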