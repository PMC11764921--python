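import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from sirenet import SignedNetwork
from sirenet.procomren import (
    ConditionObservation,
    ProbabilisticLogicModel,
    WeightedNetwork,
    condition_means,
    dbn_update,
    fit_weights,
    normalize_to_unit_interval,
    steady_state,
)

CHAIN = SignedNetwork.from_edges([("A", "B", 1), ("B", "C", 1)])
CHAIN_W = WeightedNetwork(CHAIN, {("A", "B", 1): 1.0, ("B", "C", 1): 1.0})

FANIN = SignedNetwork.from_edges([("A", "C", 1), ("B", "C", 1), ("D", "C", -1)])


def fanin_weighted(ka=0.3, kd=0.5):
    return WeightedNetwork(
        FANIN,
        {("A", "C", 1): ka, ("B", "C", 1): 1.0 - ka, ("D", "C", -1): kd},
    )


class TestWeightedNetworkInvariants:
    def test_activating_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="activating"):
            WeightedNetwork(
                FANIN,
                {("A", "C", 1): 0.3, ("B", "C", 1): 0.3, ("D", "C", -1): 0.5},
            )

    def test_inhibiting_sum_bounded_by_one(self):
        net = SignedNetwork.from_edges([("A", "C", -1), ("B", "C", -1)])
        with pytest.raises(ValueError, match="inhibiting"):
            WeightedNetwork(net, {("A", "C", -1): 0.7, ("B", "C", -1): 0.7})

    def test_weights_must_cover_edges(self):
        with pytest.raises(ValueError, match="cover"):
            WeightedNetwork(CHAIN, {("A", "B", 1): 1.0})

    def test_weight_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            WeightedNetwork(
                CHAIN, {("A", "B", 1): 1.0, ("B", "C", 1): 1.5}
            )


class TestDbnUpdate:
    def test_single_activator_passes_value(self):
        net = SignedNetwork.from_edges([("P", "X", 1)])
        w = WeightedNetwork(net, {("P", "X", 1): 1.0})
        assert dbn_update({"P": 0.5, "X": 0.0}, "X", w) == pytest.approx(0.5)

    def test_full_inhibition_zeroes_target(self):
        net = SignedNetwork.from_edges([("P", "X", 1), ("Q", "X", -1)])
        w = WeightedNetwork(net, {("P", "X", 1): 1.0, ("Q", "X", -1): 1.0})
        assert dbn_update({"P": 1.0, "Q": 1.0, "X": 0.0}, "X", w) == 0.0

    def test_mixed_fan_in_arithmetic(self):
        # activation 0.3*1 + 0.7*0 = 0.3; inhibition 0.5*0.5 = 0.25
        net = SignedNetwork.from_edges(
            [("P", "X", 1), ("Q", "X", 1), ("R", "X", -1)]
        )
        w = WeightedNetwork(
            net, {("P", "X", 1): 0.3, ("Q", "X", 1): 0.7, ("R", "X", -1): 0.5}
        )
        values = {"P": 1.0, "Q": 0.0, "R": 0.5, "X": 0.0}
        assert dbn_update(values, "X", w) == pytest.approx(0.3 * (1 - 0.25))

    def test_no_parents_keeps_value(self):
        assert dbn_update({"A": 0.7, "B": 0.0, "C": 0.0}, "A", CHAIN_W) == 0.7

    def test_closure_property(self):
        """Valid weights and [0,1] states can never leave [0,1]."""
        rng = np.random.default_rng(0)
        net = SignedNetwork.from_edges(
            [("P", "X", 1), ("Q", "X", 1), ("R", "X", -1), ("S", "X", -1)]
        )
        for _ in range(2000):
            a = rng.dirichlet([1.0, 1.0])
            inh = rng.uniform(0, 1, 2)
            inh *= rng.uniform(0, 1) / max(inh.sum(), 1e-12)
            w = WeightedNetwork(
                net,
                {
                    ("P", "X", 1): a[0],
                    ("Q", "X", 1): a[1],
                    ("R", "X", -1): inh[0],
                    ("S", "X", -1): inh[1],
                },
            )
            values = dict(zip("PQRSX", rng.uniform(0, 1, 5)))
            assert 0.0 <= dbn_update(values, "X", w) <= 1.0


class TestSteadyState:
    def test_activating_chain_propagates_clamp(self):
        res = steady_state(CHAIN_W, {"A": 0.8})
        assert res.converged
        assert res.values["B"] == pytest.approx(0.8)
        assert res.values["C"] == pytest.approx(0.8)

    def test_inhibitor_only_node_uses_basal_activation(self):
        net = SignedNetwork.from_edges([("A", "B", -1)])
        w = WeightedNetwork(net, {("A", "B", -1): 0.4})
        res = steady_state(w, {"A": 1.0})
        assert res.values["B"] == pytest.approx(0.6)

    def test_symmetric_positive_cycle_holds_init(self):
        net = SignedNetwork.from_edges([("A", "B", 1), ("B", "A", 1)])
        w = WeightedNetwork(net, {("A", "B", 1): 1.0, ("B", "A", 1): 1.0})
        res = steady_state(w, {}, init=0.5)
        assert res.converged
        assert res.values == {"A": 0.5, "B": 0.5}

    def test_acyclic_converges_within_longest_path(self):
        res = steady_state(CHAIN_W, {"A": 0.3}, init=0.0)
        assert res.converged
        assert res.n_iter <= 3  # longest path length 2, plus the check pass

    def test_unknown_clamp_rejected(self):
        with pytest.raises(KeyError):
            steady_state(CHAIN_W, {"Z": 0.5})


class TestFitWeights:
    def _fanin_observations(self, truth, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        conds = [
            ("CTL", {"A": 0.2, "B": 0.9, "D": 0.1}),
            ("CASE", {"A": 0.9, "B": 0.3, "D": 0.8}),
        ]
        obs = []
        for label, clamps in conds:
            ss = steady_state(truth, clamps)
            target = float(
                np.clip(ss.values["C"] + rng.normal(0.0, noise_sd), 0.0, 1.0)
            )
            obs.append(ConditionObservation(label, {"C": target}, clamps))
        return obs

    def test_noise_free_self_consistency(self):
        truth = fanin_weighted()
        res = fit_weights(FANIN, self._fanin_observations(truth), n_restarts=5, seed=1)
        assert res.mse <= 1e-6

    def test_parameter_recovery_low_noise(self):
        truth = fanin_weighted(ka=0.3, kd=0.5)
        obs = self._fanin_observations(truth, noise_sd=0.01, seed=42)
        res = fit_weights(FANIN, obs, n_restarts=20, seed=42)
        for edge, k in truth.weights.items():
            assert res.network.weights[edge] == pytest.approx(k, abs=0.05)

    def test_single_edge_forced_weight_one(self):
        net = SignedNetwork.from_edges([("A", "B", 1)])
        obs = [ConditionObservation("C1", {"B": 0.8}, {"A": 0.8})]
        res = fit_weights(net, obs, n_restarts=1, seed=0)
        assert res.network.weights[("A", "B", 1)] == 1.0
        assert res.mse == pytest.approx(0.0, abs=1e-12)

    def test_best_of_restarts_nonincreasing_with_nested_seeds(self):
        truth = fanin_weighted(ka=0.8, kd=0.9)
        obs = self._fanin_observations(truth, noise_sd=0.02, seed=3)
        mses = [
            fit_weights(FANIN, obs, n_restarts=n, seed=11).mse for n in (1, 3, 8)
        ]
        assert mses[0] >= mses[1] >= mses[2]

    def test_no_measured_nodes_rejected(self):
        with pytest.raises(ValueError):
            fit_weights(FANIN, [], n_restarts=1, seed=0)
        with pytest.raises(KeyError):
            fit_weights(
                FANIN, [ConditionObservation("C1", {"Z": 0.5}, {})], n_restarts=1, seed=0
            )

    def test_estimator_interface(self):
        truth = fanin_weighted()
        model = ProbabilisticLogicModel(n_restarts=5, seed=1)
        model.fit(FANIN, self._fanin_observations(truth))
        assert model.mse_ <= 1e-6
        pred = model.predict({"A": 0.2, "B": 0.9, "D": 0.1})
        assert 0.0 <= pred["C"] <= 1.0
        assert model.get_params()["n_restarts"] == 5


class TestTargetNormalization:
    def _adata(self, ctl_vals, case_vals, gene="G1"):
        x = np.array(ctl_vals + case_vals, dtype=float)[:, None]
        obs = pd.DataFrame(
            {
                "condition": ["CTL"] * len(ctl_vals) + ["CASE"] * len(case_vals),
                "cell_type": "T",
            },
            index=[f"c{i}" for i in range(len(x))],
        )
        return AnnData(X=x, obs=obs, var=pd.DataFrame(index=[gene]))

    def test_minmax_maps_conditions_to_unit_interval(self):
        out = normalize_to_unit_interval(self._adata([2.0, 2.0], [4.0, 4.0]), "T")
        assert out["CTL"]["G1"] == 0.0 and out["CASE"]["G1"] == 1.0

    def test_equal_means_map_to_half(self):
        out = normalize_to_unit_interval(self._adata([3.0, 3.0], [3.0, 3.0]), "T")
        assert out["CTL"]["G1"] == 0.5 and out["CASE"]["G1"] == 0.5

    def test_absent_gene_omitted(self):
        out = normalize_to_unit_interval(
            self._adata([1.0], [2.0]), "T", genes=["G1", "MISSING"]
        )
        assert "MISSING" not in out["CTL"]

    def test_condition_means_recovers_group_averages(self):
        out = condition_means(self._adata([0.2, 0.4], [0.8, 0.6]), "T")
        assert out["CTL"]["G1"] == pytest.approx(0.3)
        assert out["CASE"]["G1"] == pytest.approx(0.7)
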