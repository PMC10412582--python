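import numpy as np
import pandas as pd
import pytest

from chemoscore.simulate import SimulationConfig, simulate_cohort


def log_matrix(tpm: dict[str, list[float]], samples: list[str]) -> pd.DataFrame:
    """Genes-by-samples matrix of log2(TPM + 0.001) built from TPM rows."""
    df = pd.DataFrame.from_dict(tpm, orient="index", columns=samples, dtype=float)
    return np.log2(df + 0.001)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete simulated cohort shared across tests."""
    config = SimulationConfig(
        n_tumor_types=8,
        samples_per_type=40,
        n_cold_types=2,
        n_tmb_associated_types=3,
        tmb_base_mean=30.0,
        seed=7,
    )
    expression, maf, clinical = simulate_cohort(config)
    return config, expression, maf, clinical
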