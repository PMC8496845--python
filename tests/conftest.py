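import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from intronlab import design, simulate


@pytest.fixture(scope="session")
def small_library():
    """50-variant demo library covering all subsets (session-wide fixture)."""
    cfg = design.LibraryConfig(
        n_combinatorial=20,
        n_negative_controls=5,
        n_natural=8,
        n_mutated=8,
        two_intron_pool=3,
    )
    return design.design_library(cfg, seed=20240)


@pytest.fixture(scope="session")
def small_truth(small_library):
    return simulate.default_ground_truth(small_library, seed=77)


@pytest.fixture(scope="session")
def clean_reads(small_library, small_truth):
    """Error-free RNA reads: every read is its isoform's exact sequence."""
    reads, truth_table = simulate.simulate_sample(
        small_library, small_truth, 12_000, seed=99, sample="RNA", error_rate=0.0
    )
    return reads, truth_table


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
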