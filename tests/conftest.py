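import numpy as np
import pandas as pd
import pytest

from allogrades import parse_newick
from allogrades.synthdata import simulate_bm, simulate_tree


@pytest.fixture(scope="session")
def three_taxon():
    """((A:1,B:1):1,C:2); — the canonical worked example."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree20():
    return simulate_tree(20, seed=42)


@pytest.fixture(scope="session")
def tree64():
    return simulate_tree(64, seed=7)


@pytest.fixture(scope="session")
def bm_trait64(tree64):
    vals = simulate_bm(tree64, sigma2=0.004, root_state=1.0, seed=11)
    return pd.Series(vals, index=tree64.tip_labels)


def dense_asr_oracle(tree, y):
    """Conditional-mean ancestral-state oracle: ML root by dense GLS,
    node estimates from the node-tip shared-path covariance."""
    from numpy.linalg import inv

    from allogrades import bm_covariance

    V = bm_covariance(tree)
    Vi = inv(V)
    one = np.ones(tree.n_tips)
    yv = y.loc[tree.tip_labels].to_numpy()
    mu = one @ Vi @ yv / (one @ Vi @ one)

    def mrca_depth(u, v):
        anc = {u}
        while u != 0:
            u = tree.parent[u]
            anc.add(u)
        while v not in anc:
            v = tree.parent[v]
        return tree.depth[v]

    out = {}
    for u in range(tree.n_nodes):
        if not tree.children[u]:
            continue
        c = np.array([mrca_depth(u, t) for t in tree.tip_ids])
        out[u] = mu + c @ Vi @ (yv - mu)
    return out


def brute_force_bm_cov(tree):
    """Path-enumeration oracle: V[i,j] = summed lengths of shared
    root-to-tip branches."""
    paths = []
    for u in tree.tip_ids:
        edges = {}
        v = u
        while v != 0:
            edges[v] = tree.length[v]
            v = tree.parent[v]
        paths.append(edges)
    n = len(paths)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = set(paths[i]) & set(paths[j])
            V[i, j] = sum(paths[i][e] for e in shared)
    return V
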