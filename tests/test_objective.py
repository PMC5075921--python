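import numpy as np
import pytest

import fuzzysig as fs
from fuzzysig.objective import DatasetSimulator, caps_for_nodes
from fuzzysig.prior import Edge, PriorNetwork

from conftest import dtw_path_oracle


class TestMSELoss:
    def test_identical_is_zero(self):
        y = np.random.default_rng(0).uniform(0, 1, (4, 3))
        assert fs.mse_loss(y, y) == 0.0

    def test_mean_over_all_cells(self):
        assert fs.mse_loss([[0, 1]], [[1, 0]]) == pytest.approx(1.0)
        assert fs.mse_loss([[0.5]], [[0.0]]) == pytest.approx(0.25)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fs.mse_loss([[0, 1]], [[0, 1, 0]])


class TestDTWAlign:
    def test_identical_sequences_diagonal_path(self):
        y = [0.1, 0.5, 0.9]
        path, loss = fs.dtw_align(y, y)
        assert loss == 0.0
        np.testing.assert_array_equal(path.a, [0, 1, 2])
        np.testing.assert_array_equal(path.b, [0, 1, 2])

    def test_stretched_step_function_aligns_exactly(self):
        _, loss = fs.dtw_align([0, 1], [0, 0, 1, 1])
        assert loss == 0.0

    def test_path_satisfies_warping_constraints(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.uniform(0, 1, rng.integers(1, 6))
            z = rng.uniform(0, 1, rng.integers(1, 6))
            path, _ = fs.dtw_align(y, z)
            assert path.a[0] == path.b[0] == 0
            assert path.a[-1] == len(y) - 1 and path.b[-1] == len(z) - 1
            da, db = np.diff(path.a), np.diff(path.b)
            assert np.all((da >= 0) & (da <= 1))
            assert np.all((db >= 0) & (db <= 1))
            assert np.all(da + db >= 1)  # each step advances at least one index

    def test_matches_exhaustive_path_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            y = rng.uniform(0, 1, rng.integers(1, 6))
            z = rng.uniform(0, 1, rng.integers(1, 6))
            _, loss = fs.dtw_align(y, z)
            assert loss == pytest.approx(dtw_path_oracle(y, z), abs=1e-12)
            assert fs.dtw_loss(y, z) == pytest.approx(loss, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            y = rng.uniform(0, 1, 4)
            z = rng.uniform(0, 1, 5)
            assert fs.dtw_align(y, z)[1] == pytest.approx(fs.dtw_align(z, y)[1])

    def test_bounded_by_diagonal_alignment(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            y = rng.uniform(0, 1, 5)
            z = rng.uniform(0, 1, 5)
            diag = float(np.mean((y - z) ** 2))
            assert fs.dtw_align(y, z)[1] <= diag + 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            fs.dtw_align([], [1.0])


def _ts_dataset(series_per_node, conditions=None):
    """series_per_node: dict node -> 1D sequence (single series)."""
    nodes = list(series_per_node)
    arr = np.column_stack([np.asarray(series_per_node[n], float) for n in nodes])
    cond = conditions or [fs.Condition.make()]
    return fs.PerturbationDataset.time_series(nodes, cond, [arr])


class TestTimeseriesLoss:
    def test_single_node_equals_dtw(self):
        y = [0.0, 1.0, 0.0]
        z = np.array([[0.0], [0.5], [1.0], [0.5], [0.0], [0.0], [0.1], [0.2], [0.0]])
        ds = _ts_dataset({"A": y})
        expected = fs.dtw_align(y, z[:, 0])[1]
        assert fs.timeseries_loss(ds, [z]) == pytest.approx(expected)

    def test_two_nodes_sum_independent_losses(self):
        rng = np.random.default_rng(1)
        yA, yB = rng.uniform(0, 1, 4), rng.uniform(0, 1, 4)
        zA, zB = rng.uniform(0, 1, 12), rng.uniform(0, 1, 12)
        ds = _ts_dataset({"A": yA, "B": yB})
        total = fs.timeseries_loss(ds, [np.column_stack([zA, zB])])
        assert total == pytest.approx(dtw_path_oracle(yA, zA) + dtw_path_oracle(yB, zB))

    def test_consistent_stretch_gives_zero(self):
        y = [0.0, 1.0]
        z = np.repeat([0.0, 1.0], 3)[:, None]
        ds = _ts_dataset({"A": y})
        assert fs.timeseries_loss(ds, [z]) == 0.0

    def test_shape_mismatch_rejected(self):
        ds = _ts_dataset({"A": [0.0, 1.0], "B": [1.0, 0.0]})
        with pytest.raises(ValueError):
            fs.timeseries_loss(ds, [np.zeros((6, 1))])


def _prior(edges, nodes, **kw):
    return PriorNetwork(nodes=nodes,
                        edges=[Edge(s, t, sg, c) for s, t, sg, c in edges], **kw)


class TestPriorPenalty:
    def test_exact_binary_support_is_zero(self):
        nodes = ["A", "B", "C"]
        prior = _prior([("A", "B", 1, 1.0), ("B", "C", -1, 1.0)], nodes)
        B = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        assert fs.prior_penalty(B, prior) == 0.0

    def test_excluded_prior_edge_costs_its_confidence(self):
        prior = _prior([("A", "B", 1, 0.8)], ["A", "B"])
        assert fs.prior_penalty(np.zeros((2, 2)), prior) == pytest.approx(0.8)

    def test_non_prior_edge_costs_one(self):
        prior = _prior([], ["A", "B"])
        B = np.array([[0, 1], [0, 0]])
        assert fs.prior_penalty(B, prior) == pytest.approx(1.0)

    def test_reduces_to_qualitative_disagreement_count(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(5)]
        for _ in range(20):
            W = (rng.random((5, 5)) < 0.3).astype(float)
            np.fill_diagonal(W, 0)
            B = (rng.random((5, 5)) < 0.3).astype(int)
            np.fill_diagonal(B, 0)
            edges = [(nodes[i], nodes[j], 1, 1.0)
                     for i, j in zip(*np.nonzero(W))]
            prior = _prior(edges, nodes)
            disagreements = int(np.sum(B != W.astype(int)))
            assert fs.prior_penalty(B, prior) == pytest.approx(disagreements)


class TestIndegreePenalty:
    @pytest.mark.parametrize("indeg, cap, expected", [(2, 3, 0), (5, 3, 2), (0, 0, 0)])
    def test_hinge(self, indeg, cap, expected):
        B = np.zeros((6, 6), dtype=int)
        B[:indeg, 5] = 1
        assert fs.indegree_penalty(B, [None] * 5 + [cap]) == expected

    def test_uncapped_nodes_free(self):
        B = np.ones((3, 3)) - np.eye(3)
        assert fs.indegree_penalty(B, [None, None, None]) == 0.0


class TestObjective:
    def test_zero_weights_give_pure_loss(self, chain3, chain3_panel):
        prior = _prior([], list(chain3.nodes), roles=dict(chain3.roles))
        total, parts = fs.objective(chain3, chain3_panel, prior,
                                    fs.ObjectiveConfig(gamma=0.0, lam=0.0))
        assert total == pytest.approx(parts["loss"])
        assert parts["loss"] == pytest.approx(0.0, abs=1e-12)

    def test_decomposition_is_exact(self, chain3, chain3_panel):
        prior = _prior([("S", "A", 1, 0.8), ("B", "A", 1, 0.3)],
                       list(chain3.nodes), roles=dict(chain3.roles),
                       d_max_default=0)
        cfg = fs.ObjectiveConfig(gamma=0.5, lam=0.25)
        total, parts = fs.objective(chain3, chain3_panel, prior, cfg)
        sim = DatasetSimulator(chain3_panel, chain3.nodes)
        loss = sim.loss(chain3)
        pp = fs.prior_penalty(chain3.B, prior, chain3.nodes)
        ip = fs.indegree_penalty(chain3.B, caps_for_nodes(prior, chain3.nodes))
        # S->A matches (cost 1-0.8), B->A missing from model (0.3), A->B not
        # in prior (1.0); caps of 0 penalize both single-parent nodes.
        assert pp == pytest.approx(0.2 + 0.3 + 1.0)
        assert ip == pytest.approx(2.0)
        assert total == pytest.approx(loss + 0.5 * pp + 0.25 * ip, abs=1e-14)

    def test_monotone_in_gamma_and_lambda(self, chain3, chain3_panel):
        prior = _prior([("B", "A", 1, 0.9)], list(chain3.nodes),
                       roles=dict(chain3.roles), d_max_default=0)
        totals = [
            fs.objective(chain3, chain3_panel, prior,
                         fs.ObjectiveConfig(gamma=g, lam=l))[0]
            for (g, l) in [(0.0, 0.0), (0.5, 0.0), (1.0, 0.0),
                           (1.0, 0.5), (1.0, 1.0)]
        ]
        assert totals == sorted(totals)

    def test_perfect_fit_matching_binary_prior(self, chain3, chain3_panel):
        prior = _prior([("S", "A", 1, 1.0), ("A", "B", 1, 1.0)],
                       list(chain3.nodes), roles=dict(chain3.roles),
                       d_max_default=2)
        total, _ = fs.objective(chain3, chain3_panel, prior,
                                fs.ObjectiveConfig(gamma=0.5, lam=0.5))
        assert total == pytest.approx(0.0, abs=1e-12)


class TestPerNodeErrorTable:
    def test_lse_and_mse_columns(self, chain3_panel):
        Z = np.asarray(chain3_panel.values).copy()
        Z[:, 0] += 0.1  # node A off by 0.1 in all 5 conditions
        Z = np.clip(Z, 0, 1)
        table = fs.per_node_error_table(chain3_panel, Z)
        resid = Z - chain3_panel.values
        assert table.loc["A", "LSE"] == pytest.approx(np.sum(resid[:, 0] ** 2))
        assert table.loc["A", "MSE"] == pytest.approx(table.loc["A", "LSE"] / 5)
        assert table.loc["total", "LSE"] == pytest.approx(
            table.loc[["A", "B"], "LSE"].sum())
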