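"""Spearman networks, TOM, module detection, and hinge genes."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import ctnet
from ctnet.coexpression import spearman_pair, tom

from conftest import make_expression


class TestSpearman:
    def test_perfect_monotone_pair(self):
        rho, p = spearman_pair([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], [2, 4, 8, 16, 32, 64, 100, 200, 300, 400])
        assert rho == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        """x = 1..5 vs y = [5,6,7,8,7]: average ranks of y are (1,2,3.5,5,3.5),
        so rho = Pearson([1..5], ranks) = 8 / sqrt(10 * 9.5)."""
        rho, _ = spearman_pair([1, 2, 3, 4, 5], [5, 6, 7, 8, 7])
        assert rho == pytest.approx(8.0 / np.sqrt(10 * 9.5), abs=1e-12)

    def test_exact_small_n_p_for_perfect_correlation(self):
        """Only 2 of n! rank permutations reach |rho| = 1, so p = 2/n!."""
        x = [1, 2, 3, 4, 5, 6]
        rho, p = spearman_pair(x, [10, 20, 30, 40, 50, 60])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2.0 / math.factorial(6))

    def test_networks_symmetric_with_q_dominating_p(self, default_networks):
        for t in default_networks.time_points[:2]:
            net = default_networks[t]
            np.testing.assert_allclose(net.rho.to_numpy(), net.rho.to_numpy().T)
            np.testing.assert_allclose(np.diag(net.rho.to_numpy()), 1.0)
            assert (net.rho.abs().to_numpy() <= 1 + 1e-12).all()
            iu = np.triu_indices(len(net.rho), k=1)
            assert (net.q.to_numpy()[iu] >= net.p.to_numpy()[iu] - 1e-15).all()

    def test_zero_variance_gene_excluded(self, rng):
        X = pd.DataFrame(
            {"a": rng.normal(1, 0.3, 20), "b": rng.normal(1, 0.3, 20), "c": 1.0},
            index=[f"c{i}" for i in range(20)],
        )
        nets = ctnet.spearman_networks(make_expression(X))
        assert nets[0.0].excluded == ["c"]
        assert list(nets[0.0].rho.columns) == ["a", "b"]

    def test_edge_lists_have_no_self_edges(self, default_networks):
        for t in default_networks.time_points:
            e = default_networks[t].edges("q")
            assert (e["source"] != e["target"]).all()


class TestCountEdges:
    def test_independent_genes_give_few_edges(self, rng):
        X = pd.DataFrame(
            rng.normal(1, 0.3, size=(40, 8)),
            index=[f"c{i}" for i in range(40)],
            columns=[f"g{i}" for i in range(8)],
        )
        counts = ctnet.count_edges(ctnet.spearman_networks(make_expression(X)), "q")
        assert counts.loc[0.0].sum() <= 2

    def test_planted_module_peaks_at_its_time(self, rng):
        """A module correlated only at 24 h dominates that time's edge count."""
        frames, times = [], []
        for t in [0.0, 6.0, 24.0, 48.0]:
            X = rng.normal(1.5, 0.3, size=(120, 12))
            if t == 24.0:
                z = rng.normal(0, 1, 120)
                X[:, :10] += 0.5 * z[:, None]
            frames.append(X)
            times.extend([t] * 120)
        X = pd.DataFrame(
            np.vstack(frames),
            index=[f"c{i}" for i in range(480)],
            columns=[f"g{i}" for i in range(12)],
        )
        counts = ctnet.count_edges(ctnet.spearman_networks(make_expression(X, time_h=times)), "q")
        assert counts["n_pos"].idxmax() == 24.0

    def test_pair_count_bound(self, default_networks):
        counts = ctnet.count_edges(default_networks, "q")
        assert (counts.sum(axis=1) <= 45 * 44 / 2).all()


class TestTom:
    def test_identical_neighbourhoods_full_overlap(self):
        a = np.array(
            [
                [0, 1, 1, 1],
                [1, 0, 1, 1],
                [1, 1, 0, 1],
                [1, 1, 1, 0],
            ],
            dtype=float,
        )
        omega = tom(a)
        assert omega[0, 1] == pytest.approx(1.0)

    def test_three_node_path(self):
        """a-b-c path: omega(a, c) = (1 + 0) / (min(1,1) + 1 - 0) = 0.5."""
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        omega = tom(a)
        assert omega[0, 2] == pytest.approx(0.5)
        assert np.diag(omega).tolist() == [1.0, 1.0, 1.0]

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_triple_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        omega = tom(a)
        k = a.sum(axis=1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n))
                want = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert abs(omega[i, j] - want) < 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            tom(np.array([[0, 1.0], [0.5, 0]]))
        with pytest.raises(ValueError, match="diagonal"):
            tom(np.array([[1.0, 0.5], [0.5, 0.0]]))
        with pytest.raises(ValueError, match="in \\[0, 1\\]"):
            tom(np.array([[0, 1.5], [1.5, 0]]))


def well_separated_truth(seed=0):
    """Two strongly-correlated planted modules with nothing between them."""
    return ctnet.make_truth(
        module_loading=0.7,
        include_hinge=False,
        seed=seed,
    )


class TestDetectModules:
    def test_planted_modules_recovered_with_ari_one(self):
        truth = well_separated_truth(seed=2)
        expr = ctnet.normalize(ctnet.generate_ct_table(truth))
        nets = ctnet.spearman_networks(expr)
        mods = ctnet.detect_modules(nets, 24.0, 2)
        truth_modules = {g.name: g.module_id for g in truth.genes if g.module_id}
        got, want = [], []
        for gene, m in truth_modules.items():
            assert gene in mods.modules.index, f"{gene} not assigned"
            got.append(mods.modules[gene])
            want.append(m)
        assert adjusted_rand_score(want, got) == 1.0

    def test_single_clique_single_module(self, rng):
        z = rng.normal(0, 1, 120)
        X = pd.DataFrame(
            {f"g{i}": 1.5 + 0.8 * z + rng.normal(0, 0.3, 120) for i in range(6)},
            index=[f"c{i}" for i in range(120)],
        )
        nets = ctnet.spearman_networks(make_expression(X))
        mods = ctnet.detect_modules(nets, 0.0, 1)
        assert (mods.modules == 1).all()
        assert len(mods.modules) == 6

    def test_gene_order_invariance_up_to_label_swap(self):
        truth = well_separated_truth(seed=3)
        expr = ctnet.normalize(ctnet.generate_ct_table(truth))
        nets = ctnet.spearman_networks(expr)
        mods1 = ctnet.detect_modules(nets, 24.0, 2)
        rev = ctnet.ExpressionMatrix(
            expr.expr.iloc[:, ::-1], expr.detected.iloc[:, ::-1], expr.cell_meta
        )
        mods2 = ctnet.detect_modules(ctnet.spearman_networks(rev), 24.0, 2)
        common = mods1.modules.index.intersection(mods2.modules.index)
        assert adjusted_rand_score(
            mods1.modules[common].to_list(), mods2.modules[common].to_list()
        ) == 1.0


class TestModuleTrajectories:
    def test_single_gene_module_equals_gene_stats(self, default_expr, default_networks):
        mods = ctnet.ModuleAssignment(
            pd.Series({"TF01": 1}), [], 24.0, 1
        )
        out = ctnet.module_trajectories(default_expr, mods)
        eta = ctnet.noise_strength(default_expr).eta
        meta = default_expr.cell_meta
        for t in default_expr.time_points:
            manual = default_expr.expr.loc[meta["time_h"] == t, "TF01"].mean()
            assert out["mean_expression"].loc[1, t] == pytest.approx(manual)
            assert out["mean_noise"].loc[1, t] == pytest.approx(eta.loc["TF01", t])

    def test_rising_module_expression_fold(self, default_truth, default_expr, default_networks):
        """Module 1 genes switch on and ramp up: mean expression grows >= 2-fold."""
        mods = ctnet.detect_modules(default_networks, 24.0, 2)
        m1 = [g for g in default_truth.module_genes(1) if g in mods.modules.index]
        label = mods.modules[m1].mode()[0]
        traj = ctnet.module_trajectories(default_expr, mods)["mean_expression"].loc[label]
        assert traj.iloc[-1] / traj.iloc[0] >= 2.0


class TestHingeGenes:
    def test_no_negative_edges_empty_ranking(self, rng):
        X = pd.DataFrame(
            rng.normal(1.5, 0.3, size=(50, 6)),
            index=[f"c{i}" for i in range(50)],
            columns=[f"g{i}" for i in range(6)],
        )
        nets = ctnet.spearman_networks(make_expression(X))
        mods = ctnet.ModuleAssignment(
            pd.Series({f"g{i}": 1 + i % 2 for i in range(6)}), [], 0.0, 2
        )
        assert len(ctnet.hinge_genes(nets, mods, 0.0)) == 0

    def test_planted_hinge_ranked_first(self, default_truth, default_expr, default_networks):
        mods = ctnet.detect_modules(default_networks, 24.0, 2)
        ranked = ctnet.hinge_genes(default_networks, mods, 24.0)
        assert len(ranked) > 0
        assert ranked["gene"].iloc[0] == "HINGE1"
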