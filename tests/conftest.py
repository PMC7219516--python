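import pytest

from bcrep import SimConfig, build_lineages, filter_productive, simulate_repertoire


@pytest.fixture(scope="session")
def sim_small():
    """A small 3-donor x 5-subset synthetic repertoire with its ledger."""
    cfg = SimConfig(seed=7, lineages_per_subset=120)
    records, truth = simulate_repertoire(cfg)
    return records, truth


@pytest.fixture(scope="session")
def lineages_small(sim_small):
    records, _ = sim_small
    return build_lineages(filter_productive(records), min_reads=5)
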