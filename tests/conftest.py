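import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bromoscreen import Contrast, RnaSimConfig, ScreenSimConfig, simulate_counts, simulate_screen

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def screen_sim():
    """The planted screen at the study conditions: 100 lines, 20 BRD-preferential."""
    config = ScreenSimConfig(n_lines=100, n_brd_preferential=20, noise_sd=0.05, seed=11)
    viability, truth = simulate_screen(config)
    return viability, truth


@pytest.fixture(scope="session")
def counts_sim():
    """Null RNA-seq simulation (no planted DE) with spike-ins, 3 vs 3."""
    config = RnaSimConfig(n_genes=2000, seed=42)
    return simulate_counts(config)


@pytest.fixture(scope="session")
def de_contrast(counts_sim):
    _, _, sheet = counts_sim
    return Contrast(
        treated=tuple(sheet.loc[sheet.condition == "treated", "sample_id"]),
        control=tuple(sheet.loc[sheet.condition == "DMSO", "sample_id"]),
        label="treated_vs_DMSO",
    )


@pytest.fixture()
def flat_series():
    from bromoscreen import DoseResponseSeries

    doses = np.logspace(-9, -5, 10)
    return DoseResponseSeries("L1", "lin1", "CCS1477", doses, np.ones(10))


@pytest.fixture()
def tiny_counts():
    """4 genes x 4 samples with 10 clean spike-in rows for size-factor tests."""
    rng = np.random.default_rng(0)
    genes = [f"GENE{i}" for i in range(4)]
    spikes = [f"ERCC-{i:05d}" for i in range(1, 11)]
    data = rng.integers(50, 200, size=(14, 4))
    return pd.DataFrame(data, index=genes + spikes, columns=[f"s{i}" for i in range(4)])
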