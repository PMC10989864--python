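"""Message-passing network for ready-biodegradability classification.

The architecture follows the Graph Isomorphism Network family with
recurrent updates:

* message:    m_u = sigma(W h_u), a linear perceptron per layer;
* aggregate:  h_N(v) = sum of messages over the neighbours of v;
* update:     h_v  = GRU([(1 + eps) * h_v_prev || h_N(v)], state = h_v_prev);
* readout:    z_t  = [ sum_v w_v h_v  ||  max_v h_v ]  per layer
              (w_v a learned sigmoid scalar gate of h_v);
* fingerprint: z_G = final hidden state of an LSTM over (z_1 ... z_T);
* head:       p    = logistic(a . z_G + b), the RB probability.

All layer readouts feed the LSTM so that every depth of structural
context contributes to the fingerprint, not just the deepest one.

Everything is deterministic given the initialization seed, and the
whole composition is invariant under relabelling of the atoms because
sum and max pooling are order-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import constants
from .autodiff import Tensor
from .chemgraph import MolecularGraph
from .errors import ConfigError, ContractError

GRU_GATES = ("r", "z", "n")
LSTM_GATES = ("i", "f", "g", "o")


@dataclass
class ModelParams:
    """Architecture configuration plus every learnable weight.

    Weight matrices are stored in right-multiply orientation (rows of
    node features times the matrix). ``epsilon`` per layer is stored as
    a (1, 1) array named ``eps{t}``.
    """

    T: int
    d: int
    d0: int
    activation: str
    seed: int
    epsilon_learnable: bool
    feature_layout_version: str
    weights: dict[str, np.ndarray] = field(repr=False)

    def trainable_keys(self) -> list[str]:
        keys = list(self.weights)
        if not self.epsilon_learnable:
            keys = [k for k in keys if not k.startswith("eps")]
        return keys

    def copy(self) -> "ModelParams":
        return ModelParams(
            T=self.T, d=self.d, d0=self.d0, activation=self.activation,
            seed=self.seed, epsilon_learnable=self.epsilon_learnable,
            feature_layout_version=self.feature_layout_version,
            weights={k: v.copy() for k, v in self.weights.items()},
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


def init_params(T: int = 3, d: int = 64, d0: int = constants.ATOM_FEATURE_DIM,
                activation: str = "relu", seed: int = 0,
                epsilon_learnable: bool = True) -> ModelParams:
    """Seeded, bit-reproducible parameter initialization."""
    if T < 1 or d < 1:
        raise ConfigError("T and d must be >= 1")
    if activation not in ad.ACTIVATIONS:
        raise ConfigError(f"unknown activation {activation!r}")
    rng = np.random.default_rng(seed)
    w: dict[str, np.ndarray] = {
        "in_W": _glorot(rng, d0, d),
        "in_b": np.zeros((1, d)),
    }
    for t in range(T):
        w[f"msg_W{t}"] = _glorot(rng, d, d)
        w[f"eps{t}"] = np.zeros((1, 1))
        for gate in GRU_GATES:
            w[f"gru{t}_Wx{gate}"] = _glorot(rng, 2 * d, d)
            w[f"gru{t}_Wh{gate}"] = _glorot(rng, d, d)
            w[f"gru{t}_bx{gate}"] = np.zeros((1, d))
            w[f"gru{t}_bh{gate}"] = np.zeros((1, d))
        w[f"gate{t}_w"] = _glorot(rng, d, 1)
        w[f"gate{t}_b"] = np.zeros((1, 1))
    for gate in LSTM_GATES:
        w[f"lstm_Wx{gate}"] = _glorot(rng, 2 * d, 2 * d)
        w[f"lstm_Wh{gate}"] = _glorot(rng, 2 * d, 2 * d)
        w[f"lstm_b{gate}"] = np.zeros((1, 2 * d))
    w["head_w"] = _glorot(rng, 2 * d, 1)
    w["head_b"] = np.zeros((1, 1))
    return ModelParams(
        T=T, d=d, d0=d0, activation=activation, seed=seed,
        epsilon_learnable=epsilon_learnable,
        feature_layout_version=constants.FEATURE_LAYOUT_VERSION, weights=w,
    )


# ---------------------------------------------------------------------
# Tensor-graph building blocks (shared by inference and training)
# ---------------------------------------------------------------------

def _gru_step(x: Tensor, h: Tensor, p: dict[str, Tensor], t: int) -> Tensor:
    r = ad.sigmoid(x @ p[f"gru{t}_Wxr"] + p[f"gru{t}_bxr"]
                   + h @ p[f"gru{t}_Whr"] + p[f"gru{t}_bhr"])
    z = ad.sigmoid(x @ p[f"gru{t}_Wxz"] + p[f"gru{t}_bxz"]
                   + h @ p[f"gru{t}_Whz"] + p[f"gru{t}_bhz"])
    n = ad.tanh(x @ p[f"gru{t}_Wxn"] + p[f"gru{t}_bxn"]
                + r * (h @ p[f"gru{t}_Whn"] + p[f"gru{t}_bhn"]))
    return (1.0 - z) * n + z * h


def _lstm_run(zs: list[Tensor], p: dict[str, Tensor], width: int) -> Tensor:
    h = Tensor(np.zeros((1, width)))
    c = Tensor(np.zeros((1, width)))
    for x in zs:
        i = ad.sigmoid(x @ p["lstm_Wxi"] + h @ p["lstm_Whi"] + p["lstm_bi"])
        f = ad.sigmoid(x @ p["lstm_Wxf"] + h @ p["lstm_Whf"] + p["lstm_bf"])
        g = ad.tanh(x @ p["lstm_Wxg"] + h @ p["lstm_Whg"] + p["lstm_bg"])
        o = ad.sigmoid(x @ p["lstm_Wxo"] + h @ p["lstm_Who"] + p["lstm_bo"])
        c = f * c + i * g
        h = o * ad.tanh(c)
    return h


def _readout_t(H: Tensor, weights: Tensor) -> Tensor:
    return ad.concat([ad.sum_rows(weights * H), ad.max_rows(H)], axis=1)


def forward_tensor(graph: MolecularGraph, params: ModelParams,
                   tensors: dict[str, Tensor] | None = None) -> Tensor:
    """Build the full computation graph; returns the (1, 1) probability.

    ``tensors`` lets the trainer pass persistent leaf tensors so that
    gradients accumulate on them across a minibatch.
    """
    if graph.atom_features.shape[1] != params.d0:
        raise ContractError(
            f"graph feature width {graph.atom_features.shape[1]} != model d0 "
            f"{params.d0}")
    p = tensors if tensors is not None else {
        k: Tensor(v) for k, v in params.weights.items()}
    act = ad.ACTIVATIONS[params.activation]
    X = Tensor(graph.atom_features)
    A = Tensor(graph.adjacency)
    H = X @ p["in_W"] + p["in_b"]
    zs = []
    for t in range(params.T):
        M = act(H @ p[f"msg_W{t}"])
        HN = A @ M
        x = ad.concat([(1.0 + p[f"eps{t}"]) * H, HN], axis=1)
        H = _gru_step(x, H, p, t)
        gate = ad.sigmoid(H @ p[f"gate{t}_w"] + p[f"gate{t}_b"])
        zs.append(_readout_t(H, gate))
    zG = _lstm_run(zs, p, 2 * params.d)
    return ad.sigmoid(zG @ p["head_w"] + p["head_b"])


# ---------------------------------------------------------------------
# Public functional operations (NumPy in / NumPy out)
# ---------------------------------------------------------------------

def message(h_prev: np.ndarray, W: np.ndarray,
            activation: str = "relu") -> np.ndarray:
    """m = activation(W . h_prev) for one node vector or a stack of rows.

    ``W`` is in mathematical orientation (output x input).
    """
    h_prev = np.asarray(h_prev, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    vector = h_prev.ndim == 1
    rows = h_prev.reshape(1, -1) if vector else h_prev
    if W.shape[1] != rows.shape[1]:
        raise ContractError(
            f"message: W columns {W.shape[1]} != feature width {rows.shape[1]}")
    if activation not in ad.ACTIVATIONS:
        raise ConfigError(f"unknown activation {activation!r}")
    out = ad.ACTIVATIONS[activation](Tensor(rows @ W.T)).value
    return out[0] if vector else out


def aggregate(messages: np.ndarray) -> np.ndarray:
    """Sum neighbour messages; an empty (0, d) stack sums to zeros."""
    messages = np.asarray(messages, dtype=np.float64)
    if messages.ndim != 2:
        raise ContractError("aggregate expects a (k, d) message stack")
    return messages.sum(axis=0)


def update(h_prev: np.ndarray, h_N: np.ndarray, epsilon: float,
           gru_weights: dict[str, np.ndarray]) -> np.ndarray:
    """One GRU update step for a single node.

    ``gru_weights`` uses the layer-local key names ``Wx{r,z,n}``,
    ``Wh{r,z,n}``, ``bx{r,z,n}``, ``bh{r,z,n}``.
    """
    h_prev = np.asarray(h_prev, dtype=np.float64).reshape(1, -1)
    h_N = np.asarray(h_N, dtype=np.float64).reshape(1, -1)
    if h_prev.shape != h_N.shape:
        raise ContractError("update: h_prev and h_N must have equal length")
    p = {f"gru0_{k}": Tensor(v) for k, v in gru_weights.items()}
    x = np.concatenate([(1.0 + epsilon) * h_prev, h_N], axis=1)
    return _gru_step(Tensor(x), Tensor(h_prev), p, 0).value[0]


def readout_weight_sum_and_max(H: np.ndarray,
                               weights: np.ndarray) -> np.ndarray:
    """z = [sum_v w_v h_v || max_v h_v], a length-2d vector."""
    H = np.asarray(H, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64).reshape(-1, 1)
    if H.ndim != 2 or weights.shape[0] != H.shape[0]:
        raise ContractError("readout: weights must supply one scalar per node")
    return _readout_t(Tensor(H), Tensor(weights)).value[0]


def fingerprint(layer_readouts: list[np.ndarray],
                lstm_weights: dict[str, np.ndarray]) -> np.ndarray:
    """Final LSTM hidden state over the ordered per-layer readouts."""
    if len(layer_readouts) == 0:
        raise ContractError("fingerprint: empty readout sequence")
    zs = [Tensor(np.asarray(z, dtype=np.float64).reshape(1, -1))
          for z in layer_readouts]
    p = {f"lstm_{k}": Tensor(v) for k, v in lstm_weights.items()}
    width = zs[0].shape[1]
    return _lstm_run(zs, p, width).value[0]


def layer(H: np.ndarray, adjacency: np.ndarray, params: ModelParams,
          t: int) -> np.ndarray:
    """One full message-passing layer: message -> sum -> GRU update.

    ``H`` is the (n, d) node representation entering layer ``t``;
    returns the updated (n, d) representations.
    """
    H = np.asarray(H, dtype=np.float64)
    if H.ndim != 2 or H.shape[1] != params.d:
        raise ContractError(f"layer: H must be (n, {params.d})")
    if not 0 <= t < params.T:
        raise ContractError(f"layer index {t} outside 0..{params.T - 1}")
    p = {k: Tensor(v) for k, v in params.weights.items()}
    act = ad.ACTIVATIONS[params.activation]
    Ht = Tensor(H)
    M = act(Ht @ p[f"msg_W{t}"])
    HN = Tensor(adjacency) @ M
    x = ad.concat([(1.0 + p[f"eps{t}"]) * Ht, HN], axis=1)
    return _gru_step(x, Ht, p, t).value


def forward(graph: MolecularGraph, params: ModelParams) -> float:
    """Probability that the molecule is readily biodegradable."""
    return float(forward_tensor(graph, params).value[0, 0])


# ---------------------------------------------------------------------
# Checkpoint I/O (JSON: config + weights)
# ---------------------------------------------------------------------

def save_checkpoint(params: ModelParams, path) -> None:
    payload = {
        "config": {
            "T": params.T, "d": params.d, "d0": params.d0,
            "activation": params.activation, "seed": params.seed,
            "epsilon_learnable": params.epsilon_learnable,
            "feature_layout_version": params.feature_layout_version,
        },
        "weights": {k: v.tolist() for k, v in params.weights.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> ModelParams:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = payload["config"]
    if cfg["feature_layout_version"] != constants.FEATURE_LAYOUT_VERSION:
        raise ConfigError(
            f"checkpoint feature layout {cfg['feature_layout_version']!r} does "
            f"not match installed layout {constants.FEATURE_LAYOUT_VERSION!r}")
    return ModelParams(
        T=cfg["T"], d=cfg["d"], d0=cfg["d0"], activation=cfg["activation"],
        seed=cfg["seed"], epsilon_learnable=cfg["epsilon_learnable"],
        feature_layout_version=cfg["feature_layout_version"],
        weights={k: np.asarray(v, dtype=np.float64)
                 for k, v in payload["weights"].items()},
    )
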