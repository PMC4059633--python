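import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from itseval.core import PipelineConfig
from itseval.primers import PRIMER_PAIRS
from itseval.simulate import (CommunityConfig, ReadSimConfig,
                              make_fusion_samples, make_reference_set,
                              simulate_reads)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140616)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="session")
def clean_run():
    """A small error-free multiplexed run with known truth.

    5 well-separated taxa, 4 samples x 120 reads, no substitutions,
    chimeras or dimer artifacts, flat high quality.
    """
    refs = make_reference_set(CommunityConfig(
        n_taxa=5, abundance_model=[0.35, 0.25, 0.18, 0.14, 0.08], seed=11))
    fwd, rev = PRIMER_PAIRS["ITS86F/ITS4"]
    samples = make_fusion_samples(4, fwd, rev, seed=12)
    cfg = ReadSimConfig(reads_per_sample=120, n_samples=4, sub_rate=0.0,
                        homopolymer_err_rate=0.0, ambig_rate=0.0,
                        chimera_rate=0.0, dimer_rate=0.0, qual_slope=0.0,
                        qual_jitter=0.0, seed=13)
    reads, truth = simulate_reads(refs, samples, cfg)
    return refs, samples, reads, truth


@pytest.fixture()
def pipeline_cfg():
    return PipelineConfig(rarefy_depth=50, rarefy_iters=200, seed=1)
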