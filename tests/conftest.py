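import numpy as np
import pandas as pd
import pytest

from migenet.containers import OmicsMatrix
from migenet.network import build_bipartite
from migenet.synthetic import SynthConfig, generate_matched_dataset


def make_matrix(values, side, prefix="f", samples=None):
    values = np.asarray(values, dtype=float)
    ids = [f"{prefix}{i}" for i in range(values.shape[0])]
    if samples is None:
        samples = [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=ids, columns=samples), side)


def k22(extra_microbes=0, extra_genes=0):
    """K_{2,2} plus optional isolated nodes."""
    microbes = [f"m{i}" for i in range(2 + extra_microbes)]
    genes = [f"g{i}" for i in range(2 + extra_genes)]
    edges = [(m, g, 1.0) for m in microbes[:2] for g in genes[:2]]
    return build_bipartite(edges, microbes, genes)


def random_bipartite(rng, max_side=6, p=0.4):
    """Random bipartite network with <= 12 nodes for oracle comparisons."""
    nm = int(rng.integers(1, max_side + 1))
    ng = int(rng.integers(1, max_side + 1))
    microbes = [f"m{i}" for i in range(nm)]
    genes = [f"g{i}" for i in range(ng)]
    edges = [(m, g, 1.0) for m in microbes for g in genes if rng.random() < p]
    return build_bipartite(edges, microbes, genes)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-scale matched dataset used across integration tests."""
    config = SynthConfig(n_genes=120, n_microbes=25, n_samples_early=40,
                         n_samples_late=40, n_couplings=40,
                         coupling_strength=0.8, rewire_fraction=1.0, seed=7)
    return generate_matched_dataset(config)
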