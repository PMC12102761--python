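import pytest

from mitocodon import (
    RunConfig, SimulationConfig, emit_genbank, get_code, run_pipeline,
    simulate_cds_family,
)

#: Reduced gene panel for fast end-to-end tests: keeps the shortest and
#: longest genes plus a light-strand one so every code path is exercised.
SMALL_GENES = (
    ("ATP6", 227), ("ATP8", 56), ("COX1", 300), ("COX2", 230), ("COX3", 261),
    ("CYTB", 280), ("NAD1", 250), ("NAD2", 240), ("NAD3", 116), ("NAD4", 260),
    ("NAD4L", 98), ("NAD5", 300), ("NAD6", 172),
)


@pytest.fixture(scope="session")
def code2():
    return get_code(2)


@pytest.fixture(scope="session")
def code1():
    return get_code(1)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=42, n_taxa=7, genes=SMALL_GENES)


@pytest.fixture(scope="session")
def sim_blocks(sim_config):
    blocks, truth = simulate_cds_family(sim_config)
    return blocks, truth


@pytest.fixture(scope="session")
def genbank_dir(sim_config, sim_blocks, tmp_path_factory):
    blocks, _ = sim_blocks
    out = tmp_path_factory.mktemp("genbank")
    emit_genbank(sim_config, blocks, out)
    return out


@pytest.fixture(scope="session")
def pipeline_outputs(genbank_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(genbank_dir=str(genbank_dir), out_dir=str(out), quiet=True)
    return config, run_pipeline(config)
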