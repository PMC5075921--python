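import numpy as np
import pandas as pd
import pytest

import fuzzysig as fs
from fuzzysig.prior import Edge, PriorNetwork


class TestStructuralDistance:
    def test_identical_networks_distance_zero(self, toy9_model):
        assert fs.structural_distance(toy9_model, toy9_model) == 0

    def test_counts_additions_plus_deletions(self):
        truth = {("a", "b"), ("b", "c"), ("c", "d")}
        learned = {("a", "b"), ("d", "a")}  # 1 spurious, misses 2 true edges
        assert fs.structural_distance(learned, truth) == 3

    def test_edgeless_vs_ten_edge_truth(self, toy9_model):
        assert fs.structural_distance(set(), toy9_model) == 10

    def test_metric_properties_on_random_edge_sets(self):
        rng = np.random.default_rng(0)
        pairs = [(f"n{i}", f"n{j}") for i in range(5) for j in range(5) if i != j]
        for _ in range(30):
            sets = [
                {pairs[k] for k in rng.choice(len(pairs), rng.integers(0, 8),
                                              replace=False)}
                for _ in range(3)
            ]
            a, b, c = sets
            assert fs.structural_distance(a, b) == fs.structural_distance(b, a)
            assert fs.structural_distance(a, a) == 0
            assert (fs.structural_distance(a, c)
                    <= fs.structural_distance(a, b) + fs.structural_distance(b, c))


class TestRandomPriorLike:
    def test_generated_networks_satisfy_all_three_rules(self, toy9_model):
        prior = fs.perturb_prior(toy9_model, 1.0, 0.5, seed=1)
        stim = set(prior.stimulated)
        for seed in range(10):
            rand = fs.random_prior_like(prior, seed=seed)
            assert len(rand.edges) == len(prior.edges)
            assert set(rand.nodes) == set(prior.nodes)
            incident = {n: 0 for n in rand.nodes}
            for e in rand.edges:
                incident[e.source] += 1
                incident[e.target] += 1
                assert e.target not in stim
            assert all(v >= 1 for v in incident.values())
            for s in stim:
                assert any(e.source == s for e in rand.edges)
            # confidences are resampled from the original prior's scores
            original = {round(e.confidence, 12) for e in prior.edges}
            assert {round(e.confidence, 12) for e in rand.edges} <= original

    def test_infeasible_constraints_rejected(self):
        prior = PriorNetwork(
            nodes=["S", "A", "B"], roles={"S": "stimulated"},
            edges=[Edge("S", "A", 1, 0.5)])
        # one edge cannot make all three nodes incident
        with pytest.raises(ValueError):
            fs.random_prior_like(prior, seed=0, retry_cap=200)


class TestRandomPriorNull:
    def test_separation_case_yields_small_empirical_p(self):
        truth = fs.LogicModel.from_edges(
            ["S", "A", "B", "C"],
            [("S", "A", 1, 1), ("A", "B", 1, 1), ("B", "C", 1, 1)],
            fs.HillParams(),
            {"S": "stimulated", "A": "measured", "B": "measured", "C": "measured"})
        conds = [{"S": v} for v in (0.0, 0.25, 0.5, 0.75, 1.0)]
        ds, _ = fs.make_steady_state_panel(truth, conds, seed=0)
        prior = PriorNetwork(
            nodes=list(truth.nodes), roles=dict(truth.roles),
            edges=[Edge("S", "A", 1, 0.9), Edge("A", "B", 1, 0.9),
                   Edge("B", "C", 1, 0.9)],
            d_max_default=2)
        ga = fs.GAConfig(population_size=40, generations=25, n_restarts=2, seed=0)
        res = fs.random_prior_null(prior, ds, fs.ObjectiveConfig(0.5, 0.5),
                                   ga, n_random=20, seed=0)
        assert res.loss_true == pytest.approx(0.0, abs=1e-9)
        assert res.empirical_p < 0.1
        assert res.z_score > 0
        assert len(res.random_losses) == 20

    def test_requires_a_stimulated_node(self, chain3_panel):
        prior = PriorNetwork(nodes=["S", "A", "B"], roles={},
                             edges=[Edge("S", "A", 1, 0.5)])
        with pytest.raises(ValueError):
            fs.random_prior_null(prior, chain3_panel)


def _fate_model():
    """u is an unmeasured free input; x a measured input; y = u AND x."""
    return fs.LogicModel.from_edges(
        ["u", "x", "y"], [("u", "y", 1, 1), ("x", "y", 1, 1)],
        fs.HillParams(), {"x": "measured", "y": "measured"})


class TestPredictCellFates:
    def test_fate_wired_to_constant_true_node_is_always_on(self):
        model = _fate_model()
        phospho = pd.DataFrame({"x": [1.0], "y": [1.0]}, index=[0.0])
        pred = fs.predict_cell_fates(model, [("x", "Apoptosis", 1)], phospho,
                                     n_runs=200, seed=0)
        assert pred.loc[0.0, "Apoptosis"] == 1.0

    def test_fate_from_free_node_near_half(self):
        model = _fate_model()
        phospho = pd.DataFrame({"x": [1.0], "y": [1.0]}, index=[0.0])
        pred = fs.predict_cell_fates(model, [("u", "Fate", 1)], phospho,
                                     n_runs=2000, seed=1)
        assert pred.loc[0.0, "Fate"] == pytest.approx(0.5, abs=0.05)

    def test_single_run_fixed_seed_deterministic(self):
        model = _fate_model()
        phospho = pd.DataFrame({"x": [0.0], "y": [0.0]}, index=[0.0])
        p1 = fs.predict_cell_fates(model, [("u", "Fate", 1)], phospho,
                                   n_runs=1, seed=3)
        p2 = fs.predict_cell_fates(model, [("u", "Fate", 1)], phospho,
                                   n_runs=1, seed=3)
        pd.testing.assert_frame_equal(p1, p2)
        assert p1.loc[0.0, "Fate"] in (0.0, 1.0)

    def test_inhibitory_fate_edge_inverts(self):
        model = _fate_model()
        phospho = pd.DataFrame({"x": [1.0], "y": [1.0]}, index=[0.0])
        pred = fs.predict_cell_fates(model, [("x", "Death", -1)], phospho,
                                     n_runs=100, seed=0)
        assert pred.loc[0.0, "Death"] == 0.0

    def test_binarization_threshold(self):
        model = _fate_model()
        phospho = pd.DataFrame({"x": [0.49, 0.51], "y": [0.0, 0.0]},
                               index=[0.0, 1.0])
        pred = fs.predict_cell_fates(model, [("x", "Fate", 1)], phospho,
                                     n_runs=50, seed=0)
        assert pred.loc[0.0, "Fate"] == 0.0
        assert pred.loc[1.0, "Fate"] == 1.0

    def test_fate_node_inside_model_rejected(self):
        model = _fate_model()
        phospho = pd.DataFrame({"x": [1.0]}, index=[0.0])
        with pytest.raises(ValueError):
            fs.predict_cell_fates(model, [("x", "y", 1)], phospho, n_runs=10)

    def test_no_fate_edges_rejected(self):
        model = _fate_model()
        phospho = pd.DataFrame({"x": [1.0]}, index=[0.0])
        with pytest.raises(ValueError):
            fs.predict_cell_fates(model, [], phospho, n_runs=10)


class TestFateCorrelation:
    def test_identical_series_correlate_perfectly(self):
        pred = pd.DataFrame({"Apoptosis": [0.1, 0.4, 0.8, 0.9]})
        assert fs.fate_correlation(pred, pred)["Apoptosis"] == pytest.approx(1.0)

    def test_affine_transform_invariance(self):
        pred = pd.DataFrame({"F": [0.1, 0.4, 0.8, 0.9]})
        obs = pd.DataFrame({"F": 0.5 * pred["F"] + 0.2})
        assert fs.fate_correlation(pred, obs)["F"] == pytest.approx(1.0)

    def test_anticorrelated_series(self):
        pred = pd.DataFrame({"F": [0.0, 0.5, 1.0]})
        obs = pd.DataFrame({"F": [1.0, 0.5, 0.0]})
        assert fs.fate_correlation(pred, obs)["F"] == pytest.approx(-1.0)

    def test_drop_points_alignment(self):
        pred = pd.DataFrame({"F": [0.1, 9.0, 9.0, 9.0, 0.4, 0.8]})
        obs = pd.DataFrame({"F": [0.1, 0.4, 0.8]})
        r = fs.fate_correlation(pred, obs, drop_points={1, 2, 3})["F"]
        assert r == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        pred = pd.DataFrame({"F": [0.1, 0.2]})
        obs = pd.DataFrame({"F": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            fs.fate_correlation(pred, obs)


class TestPriorRatioExperiment:
    def test_table_is_tidy_and_reproducible(self, toy9_model):
        trajs = fs.boolean_trajectories(toy9_model, 2, 10, seed=0)
        ds = fs.timeseries_dataset_from_trajectories(toy9_model, trajs, seed=0)
        grid = fs.ExperimentGrid(prior_ratios=(1.0,), noise_ratios=(0.0,),
                                 n_repeats=2, seed=5)
        ga = fs.GAConfig(population_size=12, generations=5, n_restarts=1, seed=0)
        t1 = fs.run_prior_ratio_experiment(toy9_model, ds, grid, ga_config=ga)
        t2 = fs.run_prior_ratio_experiment(toy9_model, ds, grid, ga_config=ga)
        pd.testing.assert_frame_equal(t1, t2)
        assert list(t1.columns) == ["prior_ratio", "noise_ratio", "repeat",
                                    "sd", "total", "loss"]
        assert len(t1) == 2
        assert (t1["sd"] >= 0).all()
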