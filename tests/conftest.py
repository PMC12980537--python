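import numpy as np
import pytest

from carebalance.panel_io import SpatialWeights


def binary_weights(labels, edges):
    """Symmetric binary SpatialWeights from an undirected edge list."""
    n = len(labels)
    pos = {l: i for i, l in enumerate(labels)}
    W = np.zeros((n, n))
    for a, b in edges:
        i, j = pos[a], pos[b]
        W[i, j] = W[j, i] = 1.0
    return SpatialWeights(labels=list(labels), matrix=W)


@pytest.fixture
def cycle4():
    """4-cycle A-B-C-D-A."""
    return binary_weights("ABCD", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])


@pytest.fixture
def path4():
    """Path A-B-C-D."""
    return binary_weights("ABCD", [("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def path5():
    return binary_weights("ABCDE", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


def naive_morans_i(x, W, standardize=False):
    """Independent O(n^2) double-loop Moran's I (test oracle)."""
    x = np.asarray(x, dtype=float)
    Wm = np.array(W.matrix, dtype=float)
    if standardize:
        rs = Wm.sum(axis=1, keepdims=True)
        Wm = np.divide(Wm, rs, out=np.zeros_like(Wm), where=rs > 0)
    n = x.size
    xbar = x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += Wm[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += Wm[i, j]
    denom = sum((xi - xbar) ** 2 for xi in x)
    return n / s0 * num / denom
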