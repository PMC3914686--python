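import logging

import numpy as np
import pytest

from indelpop.discordant_sv import call_svs
from indelpop.sv_filters import DiscordantIndex, apply_cascade
from indelpop.synthetic_data import (SimConfig, generate_truth,
                                     simulate_read_pairs)

logging.getLogger("indelpop").setLevel(logging.ERROR)


def small_sim_config(**overrides):
    base = dict(seed=0, genome_length=600_000, deletion_count=6,
                deletion_size_range=(1000, 20_000), n_genes=40, n_tes=120,
                repeat_hotspot_count=2, hotspot_length=10_000)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


def run_sv_chain(truth, config):
    """simulate -> call -> filter; returns dict of all intermediates."""
    streams, depths, counters = simulate_read_pairs(truth, config)
    candidates, pooled, class_counts = call_svs(streams)
    index = DiscordantIndex(pooled, config.genome_length)
    retained, verdicts = apply_cascade(candidates, depths, index,
                                       config.reference_line)
    return {"streams": streams, "depths": depths, "candidates": candidates,
            "pooled": pooled, "index": index, "retained": retained,
            "verdicts": verdicts, "counters": counters}


@pytest.fixture(scope="session")
def small_chain(small_truth, small_config):
    return run_sv_chain(small_truth, small_config)


@pytest.fixture(scope="session")
def default_chain():
    """The default study configuration, end to end (the heavyweight
    fixture: shared across recovery and enrichment checks)."""
    config = SimConfig()
    truth = generate_truth(config)
    chain = run_sv_chain(truth, config)
    chain["truth"] = truth
    chain["config"] = config
    return chain


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
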