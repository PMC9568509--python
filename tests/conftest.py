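import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from treecap import ExpressionDataset, SimulationConfig, normalize_log, simulate_branching


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sim_dataset():
    """A small clean branching dataset with ground truth (session-cached)."""
    return simulate_branching(SimulationConfig(n_cells=400, seed=7))


@pytest.fixture()
def tiny_ds():
    """Hand-sized dataset: 5 cells x 4 genes with log counts."""
    counts = np.array(
        [
            [10, 0, 3, 1],
            [0, 5, 2, 0],
            [4, 4, 4, 4],
            [1, 0, 0, 9],
            [2, 3, 1, 2],
        ],
        dtype=float,
    )
    ds = ExpressionDataset(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(5)],
        gene_names=[f"g{j}" for j in range(4)],
    )
    return normalize_log(ds, target_sum=10.0)


def make_gradient_dataset(n=30, n_genes=6, seed=0):
    """Noiseless 1-D expression gradient: cell i at position i/(n-1)."""
    pos = np.linspace(0.0, 1.0, n)
    rng = np.random.default_rng(seed)
    slopes = rng.uniform(1.0, 3.0, size=n_genes) * np.where(rng.uniform(size=n_genes) < 0.5, -1, 1)
    intercepts = rng.uniform(2.0, 4.0, size=n_genes)
    log_counts = intercepts[None, :] + pos[:, None] * slopes[None, :]
    return ExpressionDataset(
        counts=np.expm1(log_counts),
        cell_ids=[f"c{i}" for i in range(n)],
        gene_names=[f"g{j}" for j in range(n_genes)],
        log_counts=log_counts,
        sim_time=pos,
    )
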