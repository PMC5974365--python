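import numpy as np
import pandas as pd
import pytest

from epidiff.simulate import (
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """One-contig 300 kb dataset: fast, used by structural tests."""
    cfg = SimulationConfig(n_contigs=1, contig_length=300_000,
                           block_length=50_000, n_dmr=20, n_ltr=10)
    return simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def medium_dataset():
    """Two-contig 2 Mb dataset for the pattern-reproduction checks."""
    cfg = SimulationConfig(n_contigs=2, contig_length=1_000_000)
    return simulate_dataset(cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_cx_frame(rng, n=50, contig="ctg1"):
    """Random but valid cytosine-report rows for I/O round trips."""
    pos = np.sort(rng.choice(np.arange(1, 10 * n), size=n, replace=False))
    ctx = rng.choice(["CG", "CHG", "CHH"], size=n)
    tri = np.where(ctx == "CG", "CGA", np.where(ctx == "CHG", "CAG", "CTT"))
    return pd.DataFrame({
        "contig": contig,
        "position": pos,
        "strand": rng.choice(["+", "-"], size=n),
        "meth": rng.integers(0, 30, size=n),
        "unmeth": rng.integers(0, 30, size=n),
        "context": ctx,
        "tri": tri,
    })
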