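import numpy as np
import pandas as pd
import pytest

from oitnet.synthetic_data import (
    build_ground_truth,
    cma_config,
    pna_config,
    simulate_study,
)


@pytest.fixture(scope="session")
def cma_truth():
    return build_ground_truth(cma_config())


@pytest.fixture(scope="session")
def pna_truth():
    return build_ground_truth(pna_config())


@pytest.fixture(scope="session")
def small_cma_study(cma_truth):
    """Default-size CMA-flavoured study (~90 animals over 3 experiments)."""
    return simulate_study(cma_truth, n_per_arm=6, seed=42)


def make_random_bn(rng: np.random.Generator, max_nodes: int = 8, max_levels: int = 3):
    """Random discrete Bayesian network with Dirichlet CPTs.

    Nodes are ordered v0..v{n-1}; each node receives up to 3 parents from
    its predecessors, guaranteeing acyclicity.
    """
    from oitnet.bayesnet import BayesNet, ExpertDAG

    n_nodes = int(rng.integers(3, max_nodes + 1))
    names = [f"v{i}" for i in range(n_nodes)]
    levels = {
        name: tuple(f"s{j}" for j in range(rng.integers(2, max_levels + 1)))
        for name in names
    }
    edges = []
    for i in range(1, n_nodes):
        n_par = int(rng.integers(0, min(i, 3) + 1))
        for p in rng.choice(i, size=n_par, replace=False):
            edges.append((names[p], names[i]))
    dag = ExpertDAG(levels=levels, edges=tuple(edges))
    cpts = {}
    for name in names:
        shape = tuple(len(levels[p]) for p in dag.parents(name)) + (len(levels[name]),)
        cpts[name] = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1]).reshape(shape)
    return BayesNet(dag=dag, cpts=cpts)


def planted_two_block_table(
    seed: int,
    n_samples: int = 200,
    per_block: int = 8,
    loading: float = 0.8,
    noise: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Feature table with two independent latent blocks (planted partition)."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, 2))
    cols = {
        f"b{b}_f{i:02d}": loading * z[:, b] + rng.normal(0, noise, n_samples)
        for b in range(2)
        for i in range(per_block)
    }
    table = pd.DataFrame(cols)
    labels = {c: 0 if c.startswith("b0") else 1 for c in table.columns}
    return table, labels
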