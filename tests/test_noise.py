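"""Noise strength, network layers, and the cross-layer comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import ctnet
from ctnet.noise import NoiseTable, RegulatoryNetwork

from conftest import make_expression


def network_from_edges(edges, nodes=None):
    df = pd.DataFrame(edges, columns=["source", "target", "sign"])
    if nodes is None:
        nodes = sorted(set(df["source"]) | set(df["target"]))
    return RegulatoryNetwork(nodes, df)


class TestNoiseStrength:
    def test_constant_expression_is_noise_free(self):
        X = pd.DataFrame({"g": [2.0, 2.0, 2.0]}, index=["a", "b", "c"])
        nt = ctnet.noise_strength(make_expression(X))
        assert nt.eta.loc["g", 0] == 0.0

    def test_hand_computed_variance_over_mean(self):
        """Values [1, 3]: mean 2, sample variance 2, eta = 1."""
        X = pd.DataFrame({"g": [1.0, 3.0]}, index=["a", "b"])
        nt = ctnet.noise_strength(make_expression(X))
        assert nt.eta.loc["g", 0] == pytest.approx(1.0)

    def test_scale_covariance(self, rng):
        vals = rng.uniform(0.5, 3, 30)
        X1 = pd.DataFrame({"g": vals}, index=[f"c{i}" for i in range(30)])
        X2 = X1 * 3.0
        e1 = ctnet.noise_strength(make_expression(X1)).eta.loc["g", 0]
        e2 = ctnet.noise_strength(make_expression(X2)).eta.loc["g", 0]
        assert e2 == pytest.approx(3.0 * e1)

    def test_zero_mean_flagged(self):
        X = pd.DataFrame({"g": [0.0, 0.0, 0.0]}, index=["a", "b", "c"])
        nt = ctnet.noise_strength(make_expression(X))
        assert np.isnan(nt.eta.loc["g", 0])

    def test_z_rows_standardised(self, default_expr):
        nt = ctnet.noise_strength(default_expr)
        np.testing.assert_allclose(nt.z.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(nt.z.std(axis=1, ddof=1), 1.0, atol=1e-10)


class TestClassifyLayers:
    def test_rule_examples(self):
        net = network_from_edges(
            [
                ("hub", "a", 1),
                ("hub", "b", 1),  # hub: no regulators -> upstream
                ("a", "mid", 1),
                ("b", "mid", 1),
                ("mid", "a", 1),
                ("mid", "b", 1),  # mid: r = 2/2 = 1 -> midstream
                ("a", "low", 1),
                ("b", "low", 1),
                ("mid", "low", 1),
                ("low", "a", 1),  # low: r = 1/3 -> downstream
            ]
        )
        layers = ctnet.classify_layers(net)
        assert layers["hub"] == "upstream"
        assert layers["mid"] == "midstream"
        assert layers["low"] == "downstream"

    def test_boundary_ratios_are_midstream(self):
        # r exactly 4 and exactly 0.5 both stay midstream
        edges = [("u", "x", 1)] + [("x", f"t{i}", 1) for i in range(4)]
        edges += [("u", "y", 1), ("t0", "y", 1), ("y", "t1", 1)]
        layers = ctnet.classify_layers(network_from_edges(edges))
        assert layers["x"] == "midstream"  # out 4 / in 1
        assert layers["y"] == "midstream"  # out 1 / in 2

    def test_inhibitory_edges_ignored(self):
        net = network_from_edges([("a", "b", -1), ("b", "a", 1)])
        layers = ctnet.classify_layers(net)
        assert layers["b"] == "upstream"  # only inhibitory input
        assert layers["a"] == "downstream"  # one activating regulator, no targets

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_direct_counting_oracle(self, seed):
        """Independent re-implementation by raw edge counting on random graphs."""
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(12)]
        edges = []
        for _ in range(30):
            s, t = rng.choice(12, 2, replace=False)
            edges.append((nodes[s], nodes[t], int(rng.choice([1, -1]))))
        edges = list(dict.fromkeys(edges))
        net = network_from_edges(edges, nodes=nodes)
        layers = ctnet.classify_layers(net)
        for n in nodes:
            out_a = sum(1 for s, t, g in edges if s == n and g == 1)
            in_a = sum(1 for s, t, g in edges if t == n and g == 1)
            if in_a == 0 or out_a / in_a > 4:
                want = "upstream"
            elif out_a / in_a < 0.5:
                want = "downstream"
            else:
                want = "midstream"
            assert layers[n] == want, n


def noise_table_from_groups(up_vals, down_vals, n_mid=0, mid_vals=None):
    genes = (
        [f"u{i}" for i in range(len(up_vals))]
        + [f"m{i}" for i in range(n_mid)]
        + [f"d{i}" for i in range(len(down_vals))]
    )
    vals = list(up_vals) + list(mid_vals or [1.0] * n_mid) + list(down_vals)
    eta = pd.DataFrame({0.0: vals, 6.0: vals}, index=genes)
    edges = []
    for i in range(len(up_vals)):
        for j in range(len(down_vals)):
            edges.append((f"u{i}", f"d{j}", 1))
    net = network_from_edges(edges, nodes=genes)
    return NoiseTable(eta, eta), net


class TestLayerNoiseTest:
    def test_complete_separation_matches_exact_tail(self, rng):
        """Every downstream value above every upstream value: U = 100 and the
        one-sided p equals the exact permutation tail 1 / C(20, 10)."""
        up = rng.uniform(0.1, 0.5, 10)
        down = rng.uniform(1.0, 2.0, 10)
        nt, net = noise_table_from_groups(up, down)
        rep = ctnet.layer_noise_test(nt, net)
        assert rep["U"] == 100.0
        assert rep["p"] == pytest.approx(1.0 / comb(20, 10, exact=True))

    def test_one_sided_duality(self, rng):
        up = rng.uniform(0.5, 1.5, 15)
        down = rng.uniform(0.5, 1.5, 15)
        nt, net = noise_table_from_groups(up, down)
        p_fwd = ctnet.layer_noise_test(nt, net, "downstream", "upstream")["p"]
        p_rev = ctnet.layer_noise_test(nt, net, "upstream", "downstream")["p"]
        assert p_fwd + p_rev >= 1.0
        assert p_fwd + p_rev <= 1.1  # equality up to the point mass at the observed U

    def test_empty_layer_rejected(self, rng):
        nt, net = noise_table_from_groups(rng.uniform(size=5), [])
        with pytest.raises(ValueError, match=">= 2 genes"):
            ctnet.layer_noise_test(nt, net)


class TestClusterNoiseHeatmap:
    def test_identical_rows_merge_first_at_zero(self):
        z = pd.DataFrame(
            [[1.0, 0.0, -1.0], [1.0, 0.0, -1.0], [5.0, 5.0, 5.0]],
            index=["a", "b", "c"],
        )
        nt = NoiseTable(z, z)
        out = ctnet.cluster_noise_heatmap(nt)
        link = out["linkage"]
        assert link[0, 2] == 0.0  # first merge at height zero
        assert {out["genes"][int(link[0, 0])], out["genes"][int(link[0, 1])]} == {"a", "b"}

    def test_three_rows_match_hand_average_linkage(self):
        """Distances d(a,b)=1, d(a,c)=5, d(b,c)=4: a+b merge at 1, then c at 4.5."""
        z = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]], index=["a", "b", "c"]
        )
        out = ctnet.cluster_noise_heatmap(NoiseTable(z, z))
        link = out["linkage"]
        assert link[0, 2] == pytest.approx(1.0)
        assert link[1, 2] == pytest.approx((5.0 + 4.0) / 2)

    def test_row_permutation_gives_identical_result(self, default_expr):
        nt = ctnet.noise_strength(default_expr)
        out1 = ctnet.cluster_noise_heatmap(nt)
        perm = NoiseTable(nt.eta.iloc[::-1], nt.z.iloc[::-1])
        out2 = ctnet.cluster_noise_heatmap(perm)
        assert out1["leaf_order"] == out2["leaf_order"]
        np.testing.assert_allclose(out1["linkage"], out2["linkage"])

    def test_undefined_rows_excluded(self):
        z = pd.DataFrame(
            [[1.0, 0.0], [np.nan, 1.0], [0.0, 1.0]], index=["a", "b", "c"]
        )
        out = ctnet.cluster_noise_heatmap(NoiseTable(z, z))
        assert out["excluded"] == ["b"]
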