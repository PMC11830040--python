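import numpy as np
import pytest

from cpgdyad import (
    ConfusionParams,
    DepthModel,
    make_genome,
    simulate_read_calls,
    simulate_truth,
)


@pytest.fixture(scope="session")
def small_genome():
    """A 50 kb single-chromosome genome with planted CpGs and GC islands."""
    return make_genome(
        length_bp=50_000, cpg_density=0.01, seed=11,
        high_gc_segments=2, high_gc_length=1_000,
    )


@pytest.fixture(scope="session")
def noiseless_duplex_calls(small_genome):
    """Duplex-only calls with identity confusion: observed dyads == truth."""
    _, cpgs, _ = small_genome
    truth = simulate_truth(cpgs, mode="dyad_table", seed=12,
                           confusion=ConfusionParams.identity())
    calls = simulate_read_calls(
        truth, DepthModel(mean_depth=4.0, duplex_rate=1.0), seed=13
    )
    return truth, calls


@pytest.fixture
def rng():
    return np.random.default_rng(7)
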