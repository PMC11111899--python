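import pytest

from pvsignal.pipeline import simulate_and_validate
from pvsignal.simulate import SimConfig, generate_gene_fixtures, generate_quarter


@pytest.fixture(scope="session")
def small_quarter():
    """A 2k-case quarter with one strong planted signal and real duplicates."""
    cfg = SimConfig(n_cases=2000, n_drugs=20, n_pts=50, baseline_event_rate=0.02,
                    planted_signals=((0, 0, 10.0),), duplicate_fraction=0.08,
                    missing_demo_fraction=0.1, seed=7)
    return cfg, generate_quarter(cfg)


@pytest.fixture(scope="session")
def validation_report():
    """The 20-seed planted-signal recovery and null false-flag study."""
    return simulate_and_validate(repetitions=20, seed=0)


@pytest.fixture(scope="session")
def gene_fixtures():
    """Gene fixtures at the dimensions of the worked example (76-node PPI)."""
    return generate_gene_fixtures(n_universe=2000, n_drug_targets=232,
                                  n_disease_genes=1049, overlap=76, n_edges=198,
                                  seed=5, n_hubs=11)
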