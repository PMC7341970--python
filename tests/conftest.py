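import numpy as np
import pytest

from chromstate.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_atac_fragments,
    simulate_chip_fragments,
)


@pytest.fixture(scope="session")
def default_truth():
    """Default synthetic epigenome (500 genes, 50 responsive), seed 1."""
    cfg = SimulationConfig(seed=1)
    genes, truth = simulate_annotation(cfg)
    return genes, truth


@pytest.fixture(scope="session")
def chip_default(default_truth):
    """Control/knockout H3K4me3 + H3K27me3 fragment sets at default depth."""
    _, truth = default_truth
    return {
        (mark, geno): simulate_chip_fragments(truth, mark, geno, replicate=0)
        for mark in ("H3K4me3", "H3K27me3")
        for geno in ("control", "knockout")
    }


@pytest.fixture(scope="session")
def atac_default(default_truth):
    _, truth = default_truth
    return {
        geno: simulate_atac_fragments(truth, geno, replicate=0)
        for geno in ("control", "knockout")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
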