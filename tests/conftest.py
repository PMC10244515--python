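import itertools

import numpy as np
import pytest

from connricci import FCMatrix, FCN


def make_fcn(n, edges, density=0.1, subject_id="s"):
    return FCN(roi_ids=tuple(f"r{i}" for i in range(n)),
               edges=tuple(sorted(tuple(sorted(e)) for e in edges)),
               density=density, subject_id=subject_id)


def random_connected_fcn(n, p, rng):
    """Random G(n, p) conditioned on connectivity (rejection + spanning path)."""
    while True:
        mask = rng.random((n, n)) < p
        edges = {(i, j) for i in range(n) for j in range(i + 1, n)
                 if mask[i, j]}
        # ensure connectivity by adding a random spanning path
        perm = rng.permutation(n)
        edges |= {tuple(sorted((int(perm[k]), int(perm[k + 1]))))
                  for k in range(n - 1)}
        return make_fcn(n, edges)


def random_fc_matrix(n, rng, subject_id="s", group="young"):
    """A valid random correlation matrix (sample correlation of iid noise)."""
    x = rng.normal(size=(4 * n, n))
    c = np.corrcoef(x, rowvar=False)
    return FCMatrix(subject_id=subject_id, group=group, values=c,
                    roi_ids=tuple(f"r{i}" for i in range(n)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def k3():
    return make_fcn(3, [(0, 1), (0, 2), (1, 2)], density=1.0)


@pytest.fixture
def c4():
    return make_fcn(4, [(0, 1), (1, 2), (2, 3), (0, 3)])


def connected_graphs_up_to(n_max):
    """All connected graphs on up to n_max labeled vertices, one per
    isomorphism class (from the networkx graph atlas)."""
    import networkx as nx

    out = []
    for g in nx.graph_atlas_g():
        if 2 <= g.number_of_nodes() <= n_max and nx.is_connected(g):
            out.append(g)
    return out
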