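import numpy as np
import pandas as pd
import pytest

from qlqsar.ql_descriptors import DescriptorMatrix, QLDescriptor
from qlqsar.nn_qsar import (
    DegenerateDataError,
    NetworkSpec,
    PruneRule,
    SensitivityReport,
    TrainProtocol,
    TrainedNetwork,
    default_protocol,
    predict,
    prune,
    run_iterative,
    sensitivity,
    split_dataset,
    train_network,
    train_population,
)
from qlqsar.synthetic_data import gen_planted_matrix


def matrix_from_arrays(X, y, codes=None):
    codes = codes or [f"D{j:03d}" for j in range(X.shape[1])]
    ids = [f"S{i:03d}" for i in range(X.shape[0])]
    return DescriptorMatrix(
        pd.DataFrame(np.asarray(X, dtype=int), index=ids, columns=codes),
        pd.Series(np.asarray(y, dtype=float), index=ids, name="activity"),
        [QLDescriptor((c, c)) for c in codes],
    )


@pytest.fixture()
def planted13():
    return gen_planted_matrix(13, 6, 1, [30.0], 0.0, seed=7).matrix


class TestSplitDataset:
    def test_thirteen_compounds_split_eight_five(self, planted13):
        train, test = split_dataset(planted13, 0.6, seed=1)
        assert len(train) == 8 and len(test) == 5
        assert not set(train) & set(test)
        assert sorted(train + test) == sorted(planted13.compound_ids)

    def test_same_seed_reproduces_partition(self, planted13):
        assert split_dataset(planted13, 0.6, 42) == split_dataset(planted13, 0.6, 42)

    def test_too_few_compounds_rejected(self):
        m = matrix_from_arrays(np.eye(4), [1, 2, 3, 4])
        with pytest.raises(ValueError, match="at least 5"):
            split_dataset(m, 0.6, 0)

    def test_test_membership_frequency_is_binomial(self, planted13):
        # each compound should land in the 5-compound test set ~5/13 of the time
        counts = {cid: 0 for cid in planted13.compound_ids}
        n_rep = 1000
        for seed in range(n_rep):
            _, test = split_dataset(planted13, 0.6, seed)
            for cid in test:
                counts[cid] += 1
        p = 5 / 13
        sigma = (n_rep * p * (1 - p)) ** 0.5  # ~15.3
        for cid, n in counts.items():
            assert abs(n - n_rep * p) < 4 * sigma, (cid, n)


class TestTrainNetwork:
    def test_perfectly_separable_single_input(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=16)
        m = matrix_from_arrays(x[:, None], 20.0 + 40.0 * x)
        spec = NetworkSpec(n_inputs=1, n_hidden=1, hidden_activation="identity",
                           output_activation="identity", max_optimizer_steps=500)
        part = split_dataset(m, 0.6, 3)
        net = train_network(spec, m, part, seed=3)
        assert net.combined_r >= 0.999

    def test_all_zero_inputs_rejected(self):
        m = matrix_from_arrays(np.zeros((8, 3)), np.arange(8.0))
        spec = NetworkSpec(n_inputs=3, n_hidden=2)
        with pytest.raises(DegenerateDataError):
            train_network(spec, m, split_dataset(m, 0.6, 0), 0)

    def test_noiseless_planted_matches_least_squares(self):
        # one planted column, zero noise: the bottleneck net and OLS agree
        ds = gen_planted_matrix(30, 5, 1, [30.0], 0.0, seed=11)
        m = ds.matrix
        spec = NetworkSpec(n_inputs=5, n_hidden=1, hidden_activation="identity",
                           output_activation="identity", max_optimizer_steps=2000)
        part = split_dataset(m, 0.6, 5)
        net = train_network(spec, m, part, seed=5)
        X = np.column_stack([np.ones(len(m.y)), m.X.values])
        beta, *_ = np.linalg.lstsq(X, m.y.values, rcond=None)
        ols_pred = X @ beta
        net_pred = np.array([predict(net, row) for row in m.X.values])
        r = np.corrcoef(net_pred, ols_pred)[0, 1]
        assert r >= 0.999

    def test_zero_variance_test_activities_flagged_nan(self):
        y = np.array([10.0, 10, 10, 10, 10, 10, 50, 60])
        X = np.eye(8)[:, :4]
        m = matrix_from_arrays(X, y)
        # craft a partition whose test half has constant activity
        part = (["S005", "S006", "S007", "S000"], ["S001", "S002", "S003", "S004"])
        net = train_network(NetworkSpec(4, 2), m, part, 0)
        assert np.isnan(net.test_r)


class TestTrainPopulation:
    def test_single_network_protocol(self, planted13):
        proto = TrainProtocol(networks_per_iteration=1, rng_seed=0)
        pop = train_population(proto, planted13)
        assert len(pop) == 1

    def test_same_seed_identical_ranking_and_weights(self, planted13):
        proto = TrainProtocol(networks_per_iteration=12, rng_seed=9)
        a = train_population(proto, planted13)
        b = train_population(proto, planted13)
        assert [n.seed for n in a] == [n.seed for n in b]
        for x, y in zip(a, b):
            assert np.array_equal(x.weights, y.weights)

    def test_planted_signal_top_network_generalizes(self):
        ds = gen_planted_matrix(40, 8, 2, [30.0, 20.0], 0.05, seed=3)
        proto = TrainProtocol(networks_per_iteration=100, rng_seed=3)
        pop = train_population(proto, ds.matrix)
        assert pop[0].test_r >= 0.9


class TestSensitivity:
    def _linear_net(self, codes, w1_rows, w2, b2, matrix):
        m = len(w2)
        k = len(codes)
        weights = np.concatenate([
            np.asarray(w1_rows, dtype=float).ravel(), np.zeros(m),
            np.asarray(w2, dtype=float), [b2],
        ])
        spec = NetworkSpec(n_inputs=k, n_hidden=m, hidden_activation="identity",
                           output_activation="identity")
        train_ids = matrix.compound_ids[:8]
        test_ids = matrix.compound_ids[8:]
        return TrainedNetwork(spec, weights, codes, train_ids, test_ids,
                              1.0, 1.0, 1.0, 0.0, 1.0, True, 0)

    def test_disconnected_input_has_unit_sensitivity(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, size=(12, 2))
        m = matrix_from_arrays(X, 50 + 30 * X[:, 0], codes=["a", "b"])
        # weight from input "b" to the hidden layer is exactly zero
        net = self._linear_net(["a", "b"], [[30.0, 0.0]], [1.0], 50.0, m)
        rep = sensitivity(net, m)
        assert rep.sens["b"] == 1.0

    def test_constant_column_has_unit_sensitivity(self):
        # ablation by the training mean leaves a constant column unchanged
        X = np.column_stack([np.ones(12), np.random.default_rng(1).integers(0, 2, 12)])
        m = matrix_from_arrays(X, 50 + 20 * X[:, 1], codes=["const", "sig"])
        net = self._linear_net(["const", "sig"], [[5.0, 20.0]], [1.0], 45.0, m)
        rep = sensitivity(net, m)
        assert rep.sens["const"] == 1.0
        assert rep.sens["sig"] > 1.0

    def test_single_regressor_matches_analytic_ablation(self):
        # y = 50 + w x fitted exactly; ablating x predicts the train mean
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, size=12).astype(float)
        y = 50 + 30 * x
        m = matrix_from_arrays(x[:, None], y, codes=["x"])
        net = self._linear_net(["x"], [[30.0]], [1.0], 50.0, m)
        rep = sensitivity(net, m)
        xbar = x[:8].mean()
        mse_full = 0.0
        # full model is exact, so Sens is the +inf sentinel
        assert rep.sens["x"] == float("inf")
        # with an imperfect model the ratio equals the analytic value
        net2 = self._linear_net(["x"], [[29.0]], [1.0], 50.0, m)
        rep2 = sensitivity(net2, m)
        pred_full = 50 + 29 * x
        pred_abl = 50 + 29 * xbar * np.ones_like(x)
        expected = np.mean((pred_abl - y) ** 2) / np.mean((pred_full - y) ** 2)
        assert rep2.sens["x"] == pytest.approx(expected, rel=1e-12)


class TestPrune:
    def _report(self, sens):
        ranking = sorted(sens, key=lambda c: (-sens[c], c))
        return SensitivityReport(sens=sens, ranking=ranking)

    def test_keep_top_24_of_60(self):
        ds = gen_planted_matrix(20, 60, 0, [], 5.0, seed=2)
        rep = self._report({c: float(j) for j, c in enumerate(ds.matrix.X.columns)})
        out = prune(ds.matrix, rep, PruneRule(keep_top=24))
        assert out.n_descriptors == 24

    def test_ties_break_by_canonical_code(self):
        ds = gen_planted_matrix(10, 6, 0, [], 5.0, seed=2)
        rep = self._report({c: 1.0 for c in ds.matrix.X.columns})
        out = prune(ds.matrix, rep, PruneRule(keep_top=3))
        assert list(out.X.columns) == sorted(ds.matrix.X.columns)[:3]

    def test_threshold_rule_keeps_above_one(self):
        ds = gen_planted_matrix(10, 8, 0, [], 5.0, seed=5)
        codes = list(ds.matrix.X.columns)
        sens = {c: (2.0 if j < 4 else 0.5) for j, c in enumerate(codes)}
        out = prune(ds.matrix, self._report(sens), PruneRule(min_sens=1.0))
        assert set(out.X.columns) == set(codes[:4])

    def test_rule_leaving_fewer_than_two_warns_and_keeps_top2(self):
        ds = gen_planted_matrix(10, 5, 0, [], 5.0, seed=5)
        sens = {c: 0.1 for c in ds.matrix.X.columns}
        with pytest.warns(UserWarning, match="keeping top 2"):
            out = prune(ds.matrix, self._report(sens), PruneRule(min_sens=1.0))
        assert out.n_descriptors == 2


class TestRunIterative:
    def test_single_iteration_no_pruning(self):
        ds = gen_planted_matrix(16, 10, 2, [25.0, 15.0], 2.0, seed=6)
        proto = TrainProtocol(networks_per_iteration=10, n_iterations=1, rng_seed=6)
        res = run_iterative(proto, ds.matrix)
        assert len(res.history) == 1
        assert res.final_matrix.n_descriptors == 10

    def test_input_counts_strictly_decrease(self):
        ds = gen_planted_matrix(16, 30, 2, [25.0, 15.0], 2.0, seed=6)
        proto = TrainProtocol(networks_per_iteration=15, n_iterations=3, rng_seed=6)
        res = run_iterative(proto, ds.matrix)
        counts = [r.n_inputs for r in res.history]
        assert all(a > b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 13

    def test_seeded_determinism_bit_identical(self):
        ds = gen_planted_matrix(16, 12, 2, [25.0, 15.0], 2.0, seed=2)
        proto = TrainProtocol(networks_per_iteration=8, n_iterations=2, rng_seed=5)
        a = run_iterative(proto, ds.matrix)
        b = run_iterative(proto, ds.matrix)
        assert [r.n_inputs for r in a.history] == [r.n_inputs for r in b.history]
        assert np.array_equal(a.final_network.weights, b.final_network.weights)
        assert a.final_sensitivity.ranking == b.final_sensitivity.ranking


class TestPredict:
    def test_zero_weight_network_outputs_bias(self):
        m = matrix_from_arrays(np.eye(8)[:, :3], np.arange(8.0))
        spec = NetworkSpec(3, 2, "identity", "identity")
        net = TrainedNetwork(spec, np.zeros(spec.n_params), list(m.X.columns),
                             m.compound_ids[:5], m.compound_ids[5:],
                             0, 0, 0, 0.0, 1.0, True, 0)
        # all weights and biases zero -> output is the output bias (0)
        assert predict(net, [1, 1, 0]) == 0.0

    def test_identity_1_1_1_network_is_affine(self):
        m = matrix_from_arrays(np.eye(8)[:, :1], np.arange(8.0))
        spec = NetworkSpec(1, 1, "identity", "identity")
        # w1=2, b1=0.5, w2=3, b2=-1 -> y = 3*(2x + 0.5) - 1 = 6x + 0.5
        net = TrainedNetwork(spec, np.array([2.0, 0.5, 3.0, -1.0]),
                             ["x"], m.compound_ids[:5], m.compound_ids[5:],
                             0, 0, 0, 0.0, 1.0, True, 0)
        assert predict(net, [1.0]) == pytest.approx(6.5)
        assert predict(net, [0.0]) == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self):
        spec = NetworkSpec(2, 1)
        net = TrainedNetwork(spec, np.zeros(spec.n_params), ["a", "b"],
                             [], [], 0, 0, 0, 0.0, 1.0, True, 0)
        with pytest.raises(ValueError, match="expected 2 inputs"):
            predict(net, [1.0])


class TestProtocolValidation:
    @pytest.mark.parametrize("kw", [
        dict(split_fraction=0.0),
        dict(networks_per_iteration=0),
        dict(n_iterations=0),
        dict(population_schedule=(10, 10)),  # length != n_iterations (3)
        dict(early_stopping="sometimes"),
    ])
    def test_invalid_protocols_rejected(self, kw):
        with pytest.raises(ValueError):
            TrainProtocol(**kw)

    def test_default_protocol_totals_about_500_networks(self):
        proto = default_protocol(1)
        assert sum(proto.networks_for(i) for i in (1, 2, 3)) == 500
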