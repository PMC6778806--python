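import numpy as np
import pytest

from haplopsc import SimConfig, simulate_population
from haplopsc._seq import encode


@pytest.fixture(scope="session")
def small_truth():
    """30 genes, no paralogs, equal expression, error-free reads."""
    cfg = SimConfig(n_genes=30, seed=11, error_rate=0.0, expression_logsd=0.0)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def paralog_truth():
    """20 genes in 10 two-member paralog families at 2% divergence."""
    cfg = SimConfig(n_genes=20, seed=7, paralog_fraction=1.0,
                    paralog_divergence=0.02, error_rate=0.0,
                    expression_logsd=0.0)
    return simulate_population(cfg)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(seq: str, positions, rng: np.random.Generator) -> str:
    arr = encode(seq).copy()
    for p in positions:
        arr[p] = (arr[p] + rng.integers(1, 4)) % 4
    return "".join("ACGT"[i] for i in arr)
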