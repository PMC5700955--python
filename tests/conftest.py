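import numpy as np
import pytest
import scipy.sparse as sp

from cytohsne import ExpressionMatrix, HsneParams, TransitionMatrix


@pytest.fixture
def chain3():
    """Symmetric 3-node chain a-b-c with landmarks {a, c}.

    Transitions: a->b with prob 1, b->{a, c} with prob 1/2 each, c->b with
    prob 1.  Absorbing-chain closed form: influence of b splits (1/2, 1/2);
    AoI-overlap similarity s(a, c) = 1 * 0.5 * 0.5 = 0.25 and weights
    (1.5, 1.5) for unit parent weights.
    """
    probs = sp.csr_matrix(
        np.array(
            [
                [0.0, 1.0, 0.0],
                [0.5, 0.0, 0.5],
                [0.0, 1.0, 0.0],
            ]
        )
    )
    return TransitionMatrix(probs=probs, n=3)


@pytest.fixture
def small_params():
    return HsneParams(n_walks_selection=200, walk_length=5, n_walks_influence=200, k=10, perplexity=5.0, seed=42)


@pytest.fixture
def blob_matrix():
    """1,000 points from one 5-D Gaussian blob, marked as transformed."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=(1000, 5))
    return ExpressionMatrix(
        values=x,
        cell_ids=[f"c{i}" for i in range(1000)],
        marker_names=[f"m{j}" for j in range(5)],
        transformed=True,
    )


def random_row_stochastic(n: int, out_degree: int, seed: int) -> TransitionMatrix:
    """Random sparse row-stochastic graph (strongly connected via a cycle)."""
    rng = np.random.default_rng(seed)
    rows, cols, vals = [], [], []
    for i in range(n):
        targets = rng.choice(n - 1, size=min(out_degree, n - 1), replace=False)
        targets = np.where(targets >= i, targets + 1, targets)  # no self-loops
        targets[0] = (i + 1) % n  # embed a cycle so the chain is irreducible
        targets = np.unique(targets)
        w = rng.random(targets.size) + 0.05
        rows.extend([i] * targets.size)
        cols.extend(targets.tolist())
        vals.extend((w / w.sum()).tolist())
    probs = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return TransitionMatrix(probs=probs, n=n)
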