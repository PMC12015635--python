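import pytest

from capsforge.synthetic_data import SimulationConfig, simulate_study, write_simulation


@pytest.fixture(scope="session")
def study():
    """One full study simulation shared across tests (deterministic)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    paths = write_simulation(study.genome, study.matrix, study.truth, out)
    return paths


@pytest.fixture(scope="session")
def small_sim():
    """A tiny, fast simulation: 2 markers, no decoys, few background sites."""
    return simulate_study(
        SimulationConfig(
            seed=3,
            n_sites=30,
            n_caps_markers=2,
            n_duplicate_decoys=0,
            n_linked_pairs=0,
            contig_length=8_000,
        )
    )
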