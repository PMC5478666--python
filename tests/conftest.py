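import logging

import pytest

from endomethyl import run_synthetic
from endomethyl.config import SimConfig
from endomethyl.pipeline import PipelineConfig
from endomethyl.synthetic import simulate_study

logging.disable(logging.INFO)


SMALL = SimConfig(n_probes=3000, n_dmr_blocks=10, seed=7)


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic study reused across unit tests."""
    return simulate_study(SMALL)


@pytest.fixture(scope="session")
def small_run():
    """Full pipeline result on the small study (fast permutation depth)."""
    cfg = SimConfig(n_probes=3000, n_dmr_blocks=10, seed=7)
    return run_synthetic(cfg, PipelineConfig(n_permutations=499, seed=7))
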