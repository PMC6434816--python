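import pytest
from hypothesis import HealthCheck, settings

from pearldecon import (
    SimulationConfig,
    contamination_from_rates,
    donor_snv_rates,
    filter_by_genotype_quality,
    simulate_dataset,
)
from pearldecon.synthetic_data import gene_panel_table

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**overrides) -> SimulationConfig:
    """A scaled-down study design: quick to simulate, same structure."""
    defaults = dict(
        seed=11,
        n_sites=90,
        n_private_sites_per_donor=25,
        n_hosts=36,
        mean_depth=100,
        n_genes=30,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """One small stochastic dataset shared by read-only tests."""
    config = small_config()
    return config, simulate_dataset(config)


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    config = small_config(noiseless=True, sequencing_error_rate=0.0)
    return config, simulate_dataset(config)


@pytest.fixture(scope="session")
def adjusted_panel_matrix(small_dataset):
    """Contamination-adjusted panel expression from the small dataset."""
    from pearldecon import adjust_matrix, select_panel

    config, (meta, calls, _depths, tpm, _truth) = small_dataset
    rates = donor_snv_rates(filter_by_genotype_quality(calls), meta)
    estimates = contamination_from_rates(rates)
    adjusted = adjust_matrix(tpm, estimates, meta)
    panel = gene_panel_table(config)
    return meta, panel, select_panel(adjusted, panel)
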