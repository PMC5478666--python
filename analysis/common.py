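"""Shared paths and the study configuration used by the analysis drivers.

The study conditions mirror the paired endometrial design: 17 subjects
sampled at LH+2 and LH+8, a 20,000-CpG array landscape, ~5% planted
differential CpGs with small, mostly positive beta-shifts, 30 contiguous
differential blocks, and a 7-subject expression sub-cohort.
"""

from pathlib import Path

from endomethyl.config import SimConfig
from endomethyl.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "synthetic_study"

SEED = 2026

SIM_CONFIG = SimConfig(seed=SEED)
PIPE_CONFIG = PipelineConfig(n_permutations=9_999, seed=SEED)


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
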