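import numpy as np
import pytest

from rbgnn import constants, gnn
from rbgnn.chemgraph import MolecularGraph, parse_smiles
from rbgnn.errors import ConfigError, ContractError


# -- independent numpy oracles (no shared code with the implementation) --

def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def gru_oracle(x, h, w):
    """Single GRU step for one node, gate-by-gate scalar math."""
    r = sigmoid(x @ w["Wxr"] + w["bxr"] + h @ w["Whr"] + w["bhr"])
    z = sigmoid(x @ w["Wxz"] + w["bxz"] + h @ w["Whz"] + w["bhz"])
    n = np.tanh(x @ w["Wxn"] + w["bxn"] + r * (h @ w["Whn"] + w["bhn"]))
    return (1.0 - z) * n + z * h


def lstm_oracle(sequence, w, width):
    h, c = np.zeros(width), np.zeros(width)
    for x in sequence:
        i = sigmoid(x @ w["Wxi"] + h @ w["Whi"] + w["bi"])
        f = sigmoid(x @ w["Wxf"] + h @ w["Whf"] + w["bf"])
        g = np.tanh(x @ w["Wxg"] + h @ w["Whg"] + w["bg"])
        o = sigmoid(x @ w["Wxo"] + h @ w["Who"] + w["bo"])
        c = f * c + i * g
        h = o * np.tanh(c)
    return h


def random_gru_weights(rng, d):
    w = {}
    for gate in "rzn":
        w[f"Wx{gate}"] = rng.normal(size=(2 * d, d))
        w[f"Wh{gate}"] = rng.normal(size=(d, d))
        w[f"bx{gate}"] = rng.normal(size=d)
        w[f"bh{gate}"] = rng.normal(size=d)
    return w


def random_lstm_weights(rng, width):
    w = {}
    for gate in "ifgo":
        w[f"Wx{gate}"] = rng.normal(size=(width, width))
        w[f"Wh{gate}"] = rng.normal(size=(width, width))
        w[f"b{gate}"] = rng.normal(size=width)
    return w


def permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    return MolecularGraph(
        n=g.n, adjacency=g.adjacency[np.ix_(perm, perm)],
        atom_features=g.atom_features[perm], smiles_canonical=g.smiles_canonical)


# -- message / aggregate -------------------------------------------------

class TestMessage:
    def test_zero_vector_maps_to_zero(self, rng):
        W = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(
            gnn.message(np.zeros(4), W, "relu"), np.zeros(4))

    def test_identity_configuration(self):
        x = np.array([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(
            gnn.message(x, np.eye(3), "identity"), x)

    def test_hand_computed_relu_case(self):
        W = np.array([[1.0, 1.0], [0.0, 2.0]])
        h = np.array([1.0, -1.0])
        # W @ h = (0, -2); relu -> (0, 0)
        np.testing.assert_array_equal(gnn.message(h, W, "relu"), [0.0, 0.0])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ContractError):
            gnn.message(np.ones(3), np.eye(4))

    def test_unknown_activation_raises(self):
        with pytest.raises(ConfigError):
            gnn.message(np.ones(2), np.eye(2), "softplus")


class TestAggregate:
    def test_empty_neighborhood_sums_to_zero(self):
        np.testing.assert_array_equal(
            gnn.aggregate(np.empty((0, 3))), np.zeros(3))

    def test_duplicate_messages_double(self):
        m = np.array([1.5, -2.0])
        np.testing.assert_array_equal(gnn.aggregate(np.stack([m, m])), 2 * m)

    def test_componentwise_sum(self):
        msgs = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        np.testing.assert_array_equal(gnn.aggregate(msgs), [3.0, 3.0])


# -- update (GRU) --------------------------------------------------------

class TestUpdate:
    def test_matches_hand_rolled_gru_oracle(self, rng):
        d = 2
        w = random_gru_weights(rng, d)
        h_prev, h_n = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        x = np.concatenate([h_prev, h_n])
        expected = gru_oracle(x, h_prev, w)
        np.testing.assert_allclose(
            gnn.update(h_prev, h_n, 0.0, w), expected, atol=1e-12)

    def test_epsilon_minus_one_zeroes_self_half_of_input(self, rng):
        d = 3
        w = random_gru_weights(rng, d)
        h_prev, h_n = rng.normal(size=d), rng.normal(size=d)
        x = np.concatenate([np.zeros(d), h_n])
        expected = gru_oracle(x, h_prev, w)
        np.testing.assert_allclose(
            gnn.update(h_prev, h_n, -1.0, w), expected, atol=1e-12)

    def test_epsilon_scales_self_input(self, rng):
        d = 2
        w = random_gru_weights(rng, d)
        h_prev, h_n = rng.normal(size=d), rng.normal(size=d)
        x = np.concatenate([1.5 * h_prev, h_n])
        np.testing.assert_allclose(
            gnn.update(h_prev, h_n, 0.5, w), gru_oracle(x, h_prev, w),
            atol=1e-12)

    def test_length_mismatch_raises(self, rng):
        w = random_gru_weights(rng, 2)
        with pytest.raises(ContractError):
            gnn.update(np.ones(2), np.ones(3), 0.0, w)


# -- readout -------------------------------------------------------------

class TestReadout:
    def test_single_node_unit_weight(self, rng):
        h = rng.normal(size=3)
        z = gnn.readout_weight_sum_and_max(h.reshape(1, -1), np.ones(1))
        np.testing.assert_allclose(z, np.concatenate([h, h]))

    def test_hand_computed_two_rows(self):
        H = np.array([[1.0, 2.0], [3.0, 0.0]])
        z = gnn.readout_weight_sum_and_max(H, np.ones(2))
        np.testing.assert_array_equal(z, [4.0, 2.0, 3.0, 2.0])

    def test_invariant_to_row_permutation(self, rng):
        H = rng.normal(size=(5, 4))
        w = rng.uniform(0.1, 1.0, size=5)
        perm = rng.permutation(5)
        np.testing.assert_allclose(
            gnn.readout_weight_sum_and_max(H, w),
            gnn.readout_weight_sum_and_max(H[perm], w[perm]), atol=1e-12)

    def test_disconnected_doubling_doubles_sum_half_only(self, rng):
        H = rng.normal(size=(4, 3))
        w = rng.uniform(0.1, 1.0, size=4)
        z = gnn.readout_weight_sum_and_max(H, w)
        z2 = gnn.readout_weight_sum_and_max(
            np.vstack([H, H]), np.concatenate([w, w]))
        np.testing.assert_allclose(z2[:3], 2 * z[:3], atol=1e-12)
        np.testing.assert_allclose(z2[3:], z[3:], atol=1e-12)


# -- fingerprint (LSTM) --------------------------------------------------

class TestFingerprint:
    def test_single_step_matches_oracle(self, rng):
        width = 4
        w = random_lstm_weights(rng, width)
        z1 = rng.normal(size=width)
        np.testing.assert_allclose(
            gnn.fingerprint([z1], w), lstm_oracle([z1], w, width), atol=1e-12)

    def test_two_step_sequence_matches_oracle(self, rng):
        width = 4
        w = random_lstm_weights(rng, width)
        zs = [rng.normal(size=width) for _ in range(2)]
        np.testing.assert_allclose(
            gnn.fingerprint(zs, w), lstm_oracle(zs, w, width), atol=1e-12)

    def test_empty_sequence_raises(self, rng):
        with pytest.raises(ContractError):
            gnn.fingerprint([], random_lstm_weights(rng, 2))


# -- full layer vs brute-force per-node oracle ---------------------------

def test_one_layer_matches_per_node_brute_force(fixture_smiles, tiny_params):
    """message -> sum over neighbours -> GRU, looped node by node."""
    params = tiny_params
    d = params.d
    rng = np.random.default_rng(0)
    small = [s for s in fixture_smiles if parse_smiles(s).n <= 5]
    assert len(small) >= 10
    for s in small:
        g = parse_smiles(s)
        H = rng.normal(size=(g.n, d))
        for t in range(params.T):
            w = params.weights
            gru = {k.split("_", 1)[1]: w[k]
                   for k in w if k.startswith(f"gru{t}_")}
            eps = float(w[f"eps{t}"][0, 0])
            expected = np.empty_like(H)
            for v in range(g.n):
                h_n = np.zeros(d)
                for u in range(g.n):
                    if g.adjacency[v, u]:
                        h_n += np.maximum(H[u] @ w[f"msg_W{t}"], 0.0)
                x = np.concatenate([(1 + eps) * H[v], h_n])
                expected[v] = gru_oracle(x, H[v], gru)
            got = gnn.layer(H, g.adjacency, params, t)
            np.testing.assert_allclose(got, expected, atol=1e-9)
            H = got


# -- forward -------------------------------------------------------------

class TestForward:
    def test_probability_in_unit_interval(self, fixture_smiles, tiny_params):
        for s in fixture_smiles[:10]:
            assert 0.0 <= gnn.forward(parse_smiles(s), tiny_params) <= 1.0

    def test_equivalent_smiles_identical_probability(self, tiny_params):
        p1 = gnn.forward(parse_smiles("CCO"), tiny_params)
        p2 = gnn.forward(parse_smiles("OCC"), tiny_params)
        assert abs(p1 - p2) < 1e-5

    def test_permutation_invariance(self, fixture_smiles, tiny_params):
        rng = np.random.default_rng(7)
        molecules = [s for s in fixture_smiles if parse_smiles(s).n >= 3][:20]
        assert len(molecules) == 20
        for s in molecules:
            g = parse_smiles(s)
            p0 = gnn.forward(g, tiny_params)
            for _ in range(5):
                perm = rng.permutation(g.n)
                assert abs(gnn.forward(permute_graph(g, perm), tiny_params)
                           - p0) < 1e-5

    def test_zero_head_gives_half(self, tiny_params):
        params = tiny_params.copy()
        params.weights["head_w"][:] = 0.0
        params.weights["head_b"][:] = 0.0
        for s in ("C", "c1ccccc1", "ClCCCl"):
            assert gnn.forward(parse_smiles(s), params) == 0.5

    def test_zero_head_weights_with_bias_degenerates_to_logistic(
            self, tiny_params):
        params = tiny_params.copy()
        params.weights["head_w"][:] = 0.0
        params.weights["head_b"][:] = 0.7
        expected = 1.0 / (1.0 + np.exp(-0.7))
        assert gnn.forward(parse_smiles("CCO"), params) == pytest.approx(
            expected, abs=1e-15)

    def test_feature_width_mismatch_raises(self, tiny_params):
        g = parse_smiles("CC")
        bad = MolecularGraph(n=g.n, adjacency=g.adjacency,
                             atom_features=g.atom_features[:, :10],
                             smiles_canonical=g.smiles_canonical)
        with pytest.raises(ContractError):
            gnn.forward(bad, tiny_params)


# -- params / checkpoints ------------------------------------------------

class TestParams:
    def test_initialization_reproducible(self):
        a = gnn.init_params(T=2, d=4, seed=9)
        b = gnn.init_params(T=2, d=4, seed=9)
        for k in a.weights:
            np.testing.assert_array_equal(a.weights[k], b.weights[k])

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            gnn.init_params(T=0)
        with pytest.raises(ConfigError):
            gnn.init_params(activation="nope")

    def test_checkpoint_roundtrip(self, tmp_path, tiny_params):
        path = tmp_path / "model.json"
        gnn.save_checkpoint(tiny_params, path)
        loaded = gnn.load_checkpoint(path)
        assert loaded.T == tiny_params.T and loaded.d == tiny_params.d
        g = parse_smiles("CC(=O)O")
        assert gnn.forward(g, loaded) == gnn.forward(g, tiny_params)

    def test_checkpoint_layout_version_verified(self, tmp_path, tiny_params):
        import json
        path = tmp_path / "model.json"
        gnn.save_checkpoint(tiny_params, path)
        payload = json.loads(path.read_text())
        payload["config"]["feature_layout_version"] = "canonical-v0"
        path.write_text(json.dumps(payload))
        with pytest.raises(ConfigError):
            gnn.load_checkpoint(path)
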