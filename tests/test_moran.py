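"""Global/local Moran and Gi*: closed forms, oracle equivalence, inference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carebalance.moran import (
    getis_ord_gstar,
    global_morans_i,
    local_moran,
    moran_permutation_test,
    moran_z_test,
)
from carebalance.panel_io import SpatialWeights

from conftest import binary_weights, naive_morans_i


def oracle_z(x, W, mode):
    """Independent implementation of the Cliff-Ord moments (test oracle).

    Explicit-loop S0/S1/S2 and the textbook normality/randomization variance
    expressions, written separately from the package code path.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    s0 = s1 = 0.0
    for i in range(n):
        for j in range(n):
            s0 += W[i, j]
            s1 += 0.5 * (W[i, j] + W[j, i]) ** 2
    s2 = 0.0
    for i in range(n):
        s2 += (sum(W[i, :]) + sum(W[:, i])) ** 2
    EI = -1.0 / (n - 1)
    if mode == "normality":
        VI = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - EI**2
    else:
        d = x - x.mean()
        b2 = (d**4).mean() / (d**2).mean() ** 2
        A = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
        B = b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0)
        VI = (A - B) / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - EI**2
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - x.mean()) * (x[j] - x.mean())
    I = n / s0 * num / ((x - x.mean()) ** 2).sum()
    return (I - EI) / math.sqrt(VI)


class TestGlobalMoran:
    def test_checkerboard_on_cycle_is_minus_one(self, cycle4):
        assert global_morans_i([1, -1, 1, -1], cycle4, standardize=False) == pytest.approx(-1.0)

    def test_path_block_pattern_matches_double_loop(self, path4):
        # x = (1,1,-1,-1) on A-B-C-D: brute-force double sum gives 1/3 (raw W)
        x = [1.0, 1.0, -1.0, -1.0]
        assert global_morans_i(x, path4, standardize=False) == pytest.approx(1 / 3)
        assert global_morans_i(x, path4, standardize=True) == pytest.approx(0.5)

    def test_single_pair_two_term_sum(self):
        # only w_01 = w_10 = 1; x=(3,1,4,2): I = (4/2)*2*d0*d1/sum d^2 = -0.6
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        sw = SpatialWeights(labels=list("ABCD"), matrix=W)
        assert global_morans_i([3, 1, 4, 2], sw, standardize=False) == pytest.approx(-0.6)

    def test_constant_attribute_rejected(self, cycle4):
        with pytest.raises(ValueError, match="zero variance"):
            global_morans_i([2, 2, 2, 2], cycle4)

    def test_label_alignment_via_series(self, path4):
        shuffled = pd.Series({"D": -1.0, "B": 1.0, "A": 1.0, "C": -1.0})
        assert global_morans_i(shuffled, path4, standardize=False) == pytest.approx(1 / 3)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(4, 6), st.integers(0, 10_000))
    def test_oracle_equivalence_small_graphs(self, n, seed):
        """Vectorized I equals the naive O(n^2) loop on random graphs, n <= 6."""
        rng = np.random.default_rng(seed)
        W = np.triu(rng.random((n, n)) < 0.6, k=1).astype(float)
        W = W + W.T
        if W.sum() == 0:
            W[0, 1] = W[1, 0] = 1.0
        sw = SpatialWeights(labels=[str(i) for i in range(n)], matrix=W)
        x = rng.normal(size=n)
        for std in (False, True):
            assert global_morans_i(x, sw, standardize=std) == pytest.approx(
                naive_morans_i(x, sw, standardize=std), abs=1e-12
            )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
        st.floats(-10, 10),
        st.floats(0.01, 100),
    )
    def test_affine_and_weight_scaling_invariance(self, a, b, c):
        path5 = binary_weights(
            "ABCDE", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")]
        )
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        base = global_morans_i(x, path5)
        assert global_morans_i(a * x + b, path5) == pytest.approx(base, abs=1e-9)
        scaled = SpatialWeights(labels=path5.labels, matrix=c * path5.matrix)
        assert global_morans_i(x, scaled, standardize=False) == pytest.approx(
            global_morans_i(x, path5, standardize=False), abs=1e-9
        )


class TestZTest:
    def test_expected_value_eleven_districts(self):
        W = np.ones((11, 11)) - np.eye(11)
        sw = SpatialWeights(labels=[str(i) for i in range(11)], matrix=W)
        res = moran_z_test(np.arange(11.0), sw)
        assert res.EI == pytest.approx(-0.1)

    def test_upper_tail_p_convention(self, path5):
        """p_norm is the upper-tail probability of z, so z = 0 gives p = 0.5."""
        from carebalance.moran import _normal_p

        assert _normal_p(0.0, "greater") == pytest.approx(0.5)
        res = moran_z_test(np.array([2.0, 7.0, 1.0, 5.0, 3.0]), path5)
        from scipy.stats import norm

        assert res.p_norm == pytest.approx(norm.sf(res.z))

    @pytest.mark.parametrize("mode", ["normality", "randomization"])
    def test_z_matches_independent_moment_oracle(self, mode, path5):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        for std in (False, True):
            Wm = path5.row_standardized().matrix if std else path5.matrix
            res = moran_z_test(x, path5, variance_mode=mode, standardize=std)
            assert res.z == pytest.approx(oracle_z(x, Wm, mode), abs=1e-12)

    def test_z_identity_holds(self, path5):
        res = moran_z_test(np.array([2.0, 7.0, 1.0, 5.0, 3.0]), path5)
        assert res.z == pytest.approx((res.I - res.EI) / np.sqrt(res.VI))


class TestPermutationTest:
    def test_same_seed_reproduces_p(self, path5):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        p1 = moran_permutation_test(x, path5, n_perm=199, seed=42).p_perm
        p2 = moran_permutation_test(x, path5, n_perm=199, seed=42).p_perm
        assert p1 == p2

    def test_clustered_blocks_highly_significant(self):
        # two connected constant blocks joined by one edge
        n = 10
        edges = [(str(i), str(i + 1)) for i in range(n - 1)]
        W = binary_weights([str(i) for i in range(n)], edges)
        x = np.array([0.0] * 5 + [1.0] * 5) + np.linspace(0, 1e-6, n)
        res = moran_permutation_test(x, W, n_perm=999, seed=1)
        assert res.p_perm <= 0.01

    def test_permutation_rule_and_bounds(self, path5):
        res = moran_permutation_test(
            np.array([3.0, 1.0, 4.0, 1.0, 5.0]), path5, n_perm=199, seed=0
        )
        assert 0 < res.p_perm <= 1
        assert res.p_perm * (res.n_perm + 1) == int(res.p_perm * (res.n_perm + 1))

    def test_rejects_fewer_than_99_permutations(self, path5):
        with pytest.raises(ValueError, match="99"):
            moran_permutation_test(np.arange(5.0), path5, n_perm=50)


class TestLocalMoran:
    def test_sum_identity_with_global(self, path5):
        x = np.array([2.0, 9.0, 4.0, 7.0, 1.0])
        lisa = local_moran(x, path5, n_perm=99, seed=0)
        I = global_morans_i(x, path5, standardize=True)
        assert lisa["Ii"].sum() == pytest.approx(5 * I, abs=1e-10)

    def test_all_positive_field_is_all_hh(self):
        W = binary_weights("ABCDE", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "A")])
        # deviations all on the same side for half the ring -> check HH where
        # both own value and neighborhood average sit above the mean
        x = np.array([10.0, 11.0, 12.0, 11.5, 10.5])
        lisa = local_moran(x, W, n_perm=99, seed=0)
        above = x > x.mean()
        lag_above = (W.row_standardized().matrix @ (x - x.mean())) > 0
        both = above & lag_above
        assert (lisa.loc[both, "quadrant"] == "HH").all()

    def test_designed_cluster_core_is_hot(self):
        # 4x4 grid with one high-value corner block
        import networkx as nx

        G = nx.grid_2d_graph(4, 4)
        nodes = sorted(G.nodes)
        pos = {nd: i for i, nd in enumerate(nodes)}
        W = np.zeros((16, 16))
        for a, b in G.edges:
            W[pos[a], pos[b]] = W[pos[b], pos[a]] = 1.0
        sw = SpatialWeights(labels=[str(i) for i in range(16)], matrix=W)
        x = np.zeros(16)
        block = [pos[nd] for nd in nodes if nd[0] <= 1 and nd[1] <= 1]
        x[block] = 10.0
        corner = pos[(0, 0)]  # its whole neighborhood lies inside the block
        x[corner] = 10.5
        x += np.linspace(0, 0.01, 16)
        lisa = local_moran(x, sw, n_perm=999, seed=3, alpha=0.05)
        assert int(np.argmax(x)) == corner
        assert lisa.loc[corner, "cluster"] == "hot"


class TestGetisOrdGstar:
    def test_uniform_attribute_gives_zeros(self, cycle4):
        z = getis_ord_gstar([3.0, 3.0, 3.0, 3.0], cycle4)
        np.testing.assert_array_equal(z.to_numpy(), 0.0)

    def test_hub_of_high_valued_leaves_is_maximum(self):
        """A hub whose whole neighborhood is high-valued (embedded in a larger
        low-valued graph) gets the top Gi* score: the statistic responds to
        the local weighted sum, not just the own value."""
        labels = list("ABCDEFGH")
        edges = [("A", "B"), ("A", "C"), ("A", "D"),  # hub A with leaves
                 ("D", "E"), ("E", "F"), ("F", "G"), ("G", "H")]  # low tail
        W = binary_weights(labels, edges)
        x = pd.Series(
            [5.0, 5.0, 5.0, 5.0, 0.0, 0.0, 0.0, 0.0], index=labels
        )
        z = getis_ord_gstar(x, W)
        assert z.idxmax() == "A"
        assert z["A"] > 0 > z["G"]

    def test_matches_textbook_formula_on_random_fixture(self):
        rng = np.random.default_rng(8)
        n = 8
        A = np.triu(rng.random((n, n)) < 0.5, k=1).astype(float)
        A = A + A.T
        A[0, 1] = A[1, 0] = 1.0
        sw = SpatialWeights(labels=[str(i) for i in range(n)], matrix=A)
        x = rng.random(n)
        z = getis_ord_gstar(x, sw).to_numpy()
        # independent loop evaluation of the Gi* z-score, self included
        Wstar = A.copy()
        np.fill_diagonal(Wstar, 1.0)
        xbar = x.mean()
        S = math.sqrt((x**2).mean() - xbar**2)
        for i in range(n):
            wi = Wstar[i].sum()
            s1i = (Wstar[i] ** 2).sum()
            num = float(Wstar[i] @ x) - xbar * wi
            den = S * math.sqrt((n * s1i - wi**2) / (n - 1))
            assert z[i] == pytest.approx(num / den, abs=1e-12)
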