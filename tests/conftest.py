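import numpy as np
import pytest

from plexscreen.demux import DemuxConfig, demultiplex_plate
from plexscreen.synth import SimConfig, build_design, generate_plate


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(model_names=("JHOS2",), seed=11)


@pytest.fixture(scope="session")
def default_plate(sim_config):
    """One full 96-well plate at the default study conditions (~12k cells)."""
    rng = np.random.default_rng(sim_config.seed)
    design = build_design(sim_config, rng)
    return generate_plate("JHOS2", sim_config, design, rng)


@pytest.fixture(scope="session")
def default_demux(default_plate):
    return demultiplex_plate(default_plate.tag_counts, default_plate.plate_map,
                             DemuxConfig(seed=1))


@pytest.fixture(scope="session")
def demux_vs_truth(default_plate, default_demux):
    """Per-droplet demux call joined to the generator's truth record."""
    return default_demux.assignments.merge(default_plate.truth, on="barcode",
                                           suffixes=("", "_true"))
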