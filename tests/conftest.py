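import numpy as np
import pytest

from darktaxa import synthio


@pytest.fixture
def rng():
    return np.random.default_rng(20230518)


@pytest.fixture(scope="session")
def small_scenario():
    return synthio.CommunityScenario(
        n_traps=5,
        n_families=3,
        family_profile=(0.5, 0.3, 0.2),
        species_mean=4.0,
        species_dispersion=5.0,
        turnover=0.8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_scenario):
    return synthio.simulate_community(small_scenario)


@pytest.fixture(scope="session")
def tiny_read_sim():
    """A complete small read-simulation bundle shared across modules."""
    scenario = synthio.CommunityScenario(
        n_traps=2,
        n_families=2,
        family_profile=(0.6, 0.4),
        species_mean=2.0,
        species_dispersion=None,
        turnover=1.0,
        seed=3,
    )
    truth = synthio.simulate_community(scenario)
    spec = synthio.ReadSimSpec(depth_mean=55, error_rate=0.0, seed=4)
    traps = dict(zip(truth.specimens.specimen_id, truth.specimens.trap))
    sheet = synthio.build_demux_sheet(traps, spec)
    barcodes = dict(zip(truth.specimens.specimen_id, truth.specimens.sequence))
    reads, provenance = synthio.simulate_reads(barcodes, sheet, spec)
    return {
        "truth": truth,
        "spec": spec,
        "sheet": sheet,
        "barcodes": barcodes,
        "reads": reads,
        "provenance": provenance,
    }
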