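"""Entropy weights, TOPSIS node weights, subgroups, and coverage."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hnicn import fixtures, lass
from hnicn.corpus_io import CollabNetwork, CorpusError


def frame(values, index=None, columns=None):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values,
                        index=index or [f"N{i}" for i in range(values.shape[0])],
                        columns=columns or [f"c{j}" for j in range(values.shape[1])])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


class TestNormalizeMentions:
    def test_column_endpoints_map_to_interval_ends(self):
        mm = lass.normalize_mentions(frame([[0], [5], [10]]))
        assert mm.normalized.iloc[:, 0].tolist() == [1.0, 1.5, 2.0]

    def test_constant_column_maps_to_midpoint(self):
        mm = lass.normalize_mentions(frame([[4], [4], [4]]))
        assert (mm.normalized.values == 1.5).all()

    def test_single_row_rejected(self):
        with pytest.raises(CorpusError):
            lass.normalize_mentions(frame([[1, 2]]))

    def test_global_scope_uses_matrix_extrema(self):
        mm = lass.normalize_mentions(frame([[0, 2], [4, 8]]), scope="global")
        # global min 0, max 8: value 2 -> 1.25, 4 -> 1.5
        assert np.allclose(mm.normalized.values, [[1.0, 1.25], [1.5, 2.0]])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(arrays(float, (6, 3), elements=st.floats(0, 1000)))
    def test_column_range_property(self, values):
        mm = lass.normalize_mentions(frame(values))
        data = mm.normalized.values
        assert (data >= 1.0).all() and (data <= 2.0).all()
        for j in range(data.shape[1]):
            col = data[:, j]
            if values[:, j].min() == values[:, j].max():
                assert (col == 1.5).all()
            else:
                assert col.min() == pytest.approx(1.0)
                assert col.max() == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# entropy weight method
# ---------------------------------------------------------------------------


class TestEntropyWeights:
    def test_uniform_column_has_unit_entropy_zero_utility(self):
        mm = lass.normalize_mentions(frame([[3, 0], [3, 5], [3, 9]]))
        iw = lass.entropy_index_weights(mm)
        assert iw.inf_entropy.iloc[0] == pytest.approx(1.0)
        assert iw.inf_utility.iloc[0] == pytest.approx(0.0)

    def test_proportions_and_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        mm = lass.normalize_mentions(frame(rng.integers(0, 50, (8, 4))))
        iw = lass.entropy_index_weights(mm)
        assert iw.p.sum(axis=0).values == pytest.approx(np.ones(4))
        assert iw.weight_index.sum() == pytest.approx(1.0)
        assert ((iw.inf_entropy >= 0) & (iw.inf_entropy <= 1)).all()
        assert (iw.inf_utility == 1 - iw.inf_entropy).all()

    def test_concentrated_column_attains_low_entropy(self):
        # one dominant row: entropy well below the uniform maximum
        mm = lass.normalize_mentions(frame([[0], [0], [0], [1000]]))
        iw = lass.entropy_index_weights(mm)
        assert iw.inf_entropy.iloc[0] < 1.0

    def test_published_utility_column_normalizes_to_published_weights(self):
        tbl = fixtures.index_weight_table()
        weights = tbl["inf_utility"] / tbl["inf_utility"].sum()
        # published weights came from unrounded utilities: +-0.001
        assert weights.values == pytest.approx(tbl["weight_index"].values, abs=1e-3)

    def test_published_utility_equals_one_minus_entropy(self):
        tbl = fixtures.index_weight_table()
        assert ((1 - tbl["inf_entropy"]).round(4) == tbl["inf_utility"]).all()


# ---------------------------------------------------------------------------
# TOPSIS
# ---------------------------------------------------------------------------


def topsis_oracle(data, weights):
    """Step-by-step independent evaluation: rescale each column by its
    extrema, weight it, take per-column ideal/anti-ideal, Euclidean
    distances, then closeness. Pure-python loops, no shared code path."""
    n, m = len(data), len(data[0])
    z = [[0.0] * m for _ in range(n)]
    for j in range(m):
        col = [data[i][j] for i in range(n)]
        lo, hi = min(col), max(col)
        for i in range(n):
            scaled = 0.0 if hi == lo else (data[i][j] - lo) / (hi - lo)
            z[i][j] = scaled * weights[j]
    z_plus = [max(z[i][j] for i in range(n)) for j in range(m)]
    z_minus = [min(z[i][j] for i in range(n)) for j in range(m)]
    close = []
    for i in range(n):
        dp = math.sqrt(sum((z[i][j] - z_plus[j]) ** 2 for j in range(m)))
        dm = math.sqrt(sum((z[i][j] - z_minus[j]) ** 2 for j in range(m)))
        close.append(0.5 if dp + dm == 0 else dm / (dp + dm))
    return close


class TestTopsis:
    def test_closeness_from_published_distances(self):
        assert lass.closeness_from_distances(0.159, 0.384) == pytest.approx(0.707, abs=5e-4)

    def test_ideal_and_anti_ideal_limits(self):
        assert lass.closeness_from_distances(0.3, 0.0) == 0.0
        assert lass.closeness_from_distances(0.0, 0.3) == 1.0
        assert lass.closeness_from_distances(0.0, 0.0) == 0.5

    def test_published_closeness_normalizes_to_published_node_weights(self):
        tbl = fixtures.node_weight_table()
        weights = lass.normalize_closeness(tbl["closeness"])
        assert weights["A1"] == pytest.approx(0.188, abs=1e-3)  # NHC
        assert weights["A2"] == pytest.approx(0.153, abs=1e-3)  # MCA
        assert weights["A15"] == pytest.approx(0.043, abs=1e-3)  # PBC
        assert weights.values == pytest.approx(tbl["weight_node"].values, abs=1e-3)

    def test_agrees_with_step_by_step_oracle_on_random_matrices(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            raw = frame(rng.integers(0, 40, (5, 3)))
            mm = lass.normalize_mentions(raw)
            iw = lass.entropy_index_weights(mm)
            nw = lass.topsis_node_weights(mm, iw)
            expected = topsis_oracle(mm.normalized.values.tolist(),
                                     iw.weight_index.values.tolist())
            assert nw.closeness.values == pytest.approx(expected, abs=1e-12)

    def test_node_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        mm = lass.normalize_mentions(frame(rng.integers(0, 30, (7, 4))))
        nw = lass.topsis_node_weights(mm, lass.entropy_index_weights(mm))
        assert nw.weight_node.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((nw.closeness >= 0) & (nw.closeness <= 1)).all()

    def test_identical_rows_share_closeness(self):
        mm = lass.normalize_mentions(frame([[2, 3], [2, 3], [2, 3]]))
        nw = lass.topsis_node_weights(mm, lass.entropy_index_weights(mm))
        assert nw.closeness.nunique() == 1


# ---------------------------------------------------------------------------
# subgroups and coverage
# ---------------------------------------------------------------------------


def star_network(leaves=5):
    codes = ["HUB"] + [f"L{i}" for i in range(leaves)]
    return CollabNetwork(codes, {("HUB", leaf): 2 for leaf in codes[1:]})


class TestSubgroups:
    def test_star_subgroup_sizes(self):
        subs = lass.build_subgroups(star_network(5))
        assert subs["HUB"].amount == 6
        for leaf in [c for c in subs if c != "HUB"]:
            assert subs[leaf].amount == 2
            assert subs[leaf].members == {"HUB"}

    def test_isolated_node_is_singleton(self):
        net = CollabNetwork(["A", "B", "C"], {("A", "B"): 1})
        subs = lass.build_subgroups(net)
        assert subs["C"].amount == 1 and subs["C"].members == frozenset()

    def test_membership_matches_adjacency_scan(self):
        rng = np.random.default_rng(11)
        codes = [f"N{i}" for i in range(7)]
        mult = {}
        for i in codes:
            for j in codes:
                if i != j and rng.random() < 0.3:
                    mult[(i, j)] = int(rng.integers(1, 4))
        net = CollabNetwork(codes, mult)
        subs = lass.build_subgroups(net)
        for center in codes:
            expected = {
                j for j in codes
                if j != center and mult.get((center, j), 0) + mult.get((j, center), 0) >= 1
            }
            assert subs[center].members == expected
            for m in expected:
                assert subs[center].member_link_count[m] == (
                    mult.get((center, m), 0) + mult.get((m, center), 0)
                )


class TestCoverage:
    def test_isolated_center_gets_floor_value(self):
        sub = lass.Subgroup("X", frozenset(), {})
        weights = pd.Series({"X": 1.0})
        assert lass.collaboration_coverage(sub, weights) == 1.0

    def test_single_member_hand_evaluation(self):
        sub = lass.Subgroup("X", frozenset({"Y"}), {"Y": 3})
        weights = pd.Series({"X": 0.8, "Y": 0.2})
        # 10 * (0.2 * 3) / 1
        assert lass.collaboration_coverage(sub, weights, 10) == pytest.approx(6.0)

    def test_two_member_hand_evaluation(self):
        sub = lass.Subgroup("X", frozenset({"Y", "Z"}), {"Y": 2, "Z": 1})
        weights = pd.Series({"X": 0.6, "Y": 0.1, "Z": 0.3})
        # 10 * (0.1*2 + 0.3*1) / 2
        assert lass.collaboration_coverage(sub, weights, 10) == pytest.approx(2.5)

    def test_scales_linearly_in_adj_par(self):
        sub = lass.Subgroup("X", frozenset({"Y"}), {"Y": 5})
        weights = pd.Series({"Y": 0.25})
        base = lass.collaboration_coverage(sub, weights, 1)
        for k in (2, 10, 100):
            assert lass.collaboration_coverage(sub, weights, k) == pytest.approx(k * base)

    def test_nonpositive_adj_par_rejected(self):
        sub = lass.Subgroup("X", frozenset({"Y"}), {"Y": 1})
        with pytest.raises(CorpusError):
            lass.collaboration_coverage(sub, pd.Series({"Y": 0.5}), 0)

    def test_coverage_table_covers_all_nodes(self):
        net = star_network(4)
        weights = pd.Series(0.2, index=net.nodes)
        nw = type("NW", (), {"weight_node": weights})()
        cov = lass.coverage_table(net, nw, 10)
        assert set(cov.index) == set(net.nodes)
        assert (cov > 0).all()
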