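import numpy as np
import pandas as pd
import pytest

from pgrn.synth import SimConfig, simulate_all


@pytest.fixture(scope="session")
def std_cfg() -> SimConfig:
    """The standard synthetic study configuration."""
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def std_sim(std_cfg):
    """One full simulated study shared across tests (read-only)."""
    return simulate_all(std_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_intervals(
    rng: np.random.Generator, n: int, chrom_len: int = 2000, chroms=("c1",), max_len: int = 120
) -> pd.DataFrame:
    """Small random interval set for brute-force oracle comparisons."""
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, chrom_len - max_len, size=n)
    length = rng.integers(1, max_len, size=n)
    return pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})
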