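"""Graph convolutional classifier over the seven-feature lesion graph.

Each lesion becomes one seven-node graph sample: node *u* carries the
z-scored value of feature *u* and all samples share the frozen
correlation topology.  Classification is graph-level — a message-passing
stack produces node embeddings, a mean-pool readout collapses them to one
vector, and a skip-connected feed-forward head predicts benign vs
malignant.

One message-passing layer computes, per node,

    m_u = act( W_n x_u + W_nb * sum_{v in N(u)} w_uv x_v + b )

with the signed Pearson edge weight ``w_uv`` scaling each neighbour
contribution, then merges ``m_u`` with the previous embedding through a
combination cell (a pointwise ConvLSTM-style gate by default; GRU-style
and concat+dense variants are provided), and finally L2-normalizes each
node embedding.  A graph-attention (GAT) baseline with multi-head softmax
attention is included for comparison.

Optimisation uses a Nadam-style adaptive-moment rule with Nesterov
momentum on the first moment.  Everything is pure NumPy via the
:mod:`lesiongraph._autodiff` tape, and fully deterministic given the
configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._autodiff import Tensor, concat, softmax_cross_entropy
from .dataset_io import FEATURE_NAMES
from .graph import CorrelationGraph

COMBINATIONS = ("convlstm1d", "gru", "concat_dense")
ACTIVATIONS = ("elu", "relu", "gelu", "tanh")


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters of the GCN classifier.

    Defaults are the ablation-selected configuration: three message-passing
    layers with hidden widths [64, 64] (the last width repeats for any
    additional layer), ConvLSTM-style combination, ELU activation, Nadam
    optimiser at learning rate 0.01, dropout 0.3, batch size 64, 200
    epochs, nine GELU feed-forward blocks, mean-pool readout.
    """

    n_gcn_layers: int = 3
    hidden_units: tuple = (64, 64)
    activation: str = "elu"
    combination: str = "convlstm1d"
    dropout: float = 0.3
    optimizer: str = "nadam"
    learning_rate: float = 0.01
    batch_size: int = 64
    epochs: int = 200
    ffn_blocks: int = 9
    ffn_activation: str = "gelu"
    readout: str = "mean"
    seed: int = 0

    def __post_init__(self):
        if self.combination not in COMBINATIONS:
            raise ValueError(f"combination must be one of {COMBINATIONS}")
        if self.activation not in ACTIVATIONS or self.ffn_activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.readout != "mean":
            raise ValueError("only mean-pool readout is supported")
        self.hidden_units = tuple(int(h) for h in self.hidden_units)

    @property
    def layer_widths(self) -> list:
        h = list(self.hidden_units)
        while len(h) < self.n_gcn_layers:
            h.append(h[-1])
        return h[: self.n_gcn_layers]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class GraphSample:
    """One lesion on the shared topology: a scalar per feature-node."""

    node_values: np.ndarray  # (n_nodes,), z-scored feature values
    label: int
    topology: CorrelationGraph  # shared across the dataset


@dataclass
class PredictionOutput:
    """Class probabilities (benign, malignant) for one sample."""

    probabilities: np.ndarray  # (2,), sums to 1

    @property
    def predicted_label(self) -> int:
        return int(np.argmax(self.probabilities))


@dataclass
class TrainStats:
    """Per-feature z-score statistics, computed on the training split only."""

    mean: np.ndarray
    std: np.ndarray
    names: list


def compute_train_stats(table: pd.DataFrame, feature_names=None) -> TrainStats:
    names = list(feature_names) if feature_names is not None else FEATURE_NAMES
    X = table[names].to_numpy(dtype=float)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return TrainStats(mean=X.mean(axis=0), std=std, names=names)


def build_graph_samples(
    table: pd.DataFrame, graph: CorrelationGraph, train_stats: TrainStats
) -> list[GraphSample]:
    """One GraphSample per table row, z-scored with the training statistics."""
    if list(graph.nodes) != list(train_stats.names):
        raise ValueError("graph nodes and training statistics name different features")
    missing = [n for n in graph.nodes if n not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks graph node columns: {missing}")
    X = table[list(graph.nodes)].to_numpy(dtype=float)
    Z = (X - train_stats.mean) / train_stats.std
    labels = table["label"].to_numpy()
    return [GraphSample(Z[i], int(labels[i]), graph) for i in range(len(table))]


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _act(x: Tensor, name: str) -> Tensor:
    return getattr(x, name)()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def _ones(*shape) -> Tensor:
    return Tensor(np.ones(shape), requires_grad=True)


class Dense:
    def __init__(self, rng, d_in, d_out):
        self.W = _glorot(rng, d_in, d_out)
        self.b = _zeros(d_out)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class LayerNorm:
    """Per-sample normalization over the last axis with learned scale/shift."""

    def __init__(self, dim, eps: float = 1e-5):
        self.gamma = _ones(dim)
        self.beta = _zeros(dim)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred / (var + self.eps).pow(0.5) * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class MessagePassing:
    """Edge-weighted aggregation: act(W_n x + W_nb (A x) + b)."""

    def __init__(self, rng, d_in, d_out, activation="elu"):
        self.W_self = _glorot(rng, d_in, d_out)
        self.W_nbr = _glorot(rng, d_in, d_out)
        self.b = _zeros(d_out)
        self.activation = activation

    def __call__(self, x: Tensor, adjacency: Tensor) -> Tensor:
        if np.isnan(x.data).any():
            raise ValueError("NaN in node embeddings")
        pre = x @ self.W_self + (adjacency @ x) @ self.W_nbr + self.b
        return _act(pre, self.activation)

    def parameters(self):
        return [self.W_self, self.W_nbr, self.b]


class ConvLSTM1DCell:
    """Pointwise ConvLSTM-style gate merging message (input) and prior embedding.

    The convolution kernel over the node axis has width one — weights are
    shared across nodes, which keeps the layer permutation-equivariant as
    a graph operator must be.  The prior embedding acts as both hidden and
    (projected) cell state.
    """

    def __init__(self, rng, d_prev, d_msg):
        self.W_x = [_glorot(rng, d_msg, d_msg) for _ in range(4)]  # i, f, o, g
        self.W_h = [_glorot(rng, d_prev, d_msg) for _ in range(4)]
        self.b = [_zeros(d_msg) for _ in range(4)]
        self.W_cell = _glorot(rng, d_prev, d_msg)  # prior embedding -> cell state

    def __call__(self, prev: Tensor, msg: Tensor) -> Tensor:
        i = (msg @ self.W_x[0] + prev @ self.W_h[0] + self.b[0]).sigmoid()
        f = (msg @ self.W_x[1] + prev @ self.W_h[1] + self.b[1]).sigmoid()
        o = (msg @ self.W_x[2] + prev @ self.W_h[2] + self.b[2]).sigmoid()
        g = (msg @ self.W_x[3] + prev @ self.W_h[3] + self.b[3]).tanh()
        c = f * (prev @ self.W_cell) + i * g
        return o * c.tanh()

    def parameters(self):
        return self.W_x + self.W_h + self.b + [self.W_cell]


class GRUCell:
    """GRU-style update: message as input, projected prior embedding as state."""

    def __init__(self, rng, d_prev, d_msg):
        self.W_proj = _glorot(rng, d_prev, d_msg)
        self.W_z = _glorot(rng, d_msg, d_msg)
        self.U_z = _glorot(rng, d_msg, d_msg)
        self.b_z = _zeros(d_msg)
        self.W_r = _glorot(rng, d_msg, d_msg)
        self.U_r = _glorot(rng, d_msg, d_msg)
        self.b_r = _zeros(d_msg)
        self.W_h = _glorot(rng, d_msg, d_msg)
        self.U_h = _glorot(rng, d_msg, d_msg)
        self.b_h = _zeros(d_msg)

    def __call__(self, prev: Tensor, msg: Tensor) -> Tensor:
        h = prev @ self.W_proj
        z = (msg @ self.W_z + h @ self.U_z + self.b_z).sigmoid()
        r = (msg @ self.W_r + h @ self.U_r + self.b_r).sigmoid()
        h_tilde = (msg @ self.W_h + (r * h) @ self.U_h + self.b_h).tanh()
        return (1.0 - z) * h + z * h_tilde

    def parameters(self):
        return [
            self.W_proj, self.W_z, self.U_z, self.b_z,
            self.W_r, self.U_r, self.b_r, self.W_h, self.U_h, self.b_h,
        ]


class ConcatDenseCell:
    """Dense layer over [prior embedding, message]."""

    def __init__(self, rng, d_prev, d_msg, activation="elu"):
        self.dense = Dense(rng, d_prev + d_msg, d_msg)
        self.activation = activation

    def __call__(self, prev: Tensor, msg: Tensor) -> Tensor:
        return _act(self.dense(concat([prev, msg], axis=-1)), self.activation)

    def parameters(self):
        return self.dense.parameters()


_CELLS = {"convlstm1d": ConvLSTM1DCell, "gru": GRUCell, "concat_dense": ConcatDenseCell}


class GCNLayer:
    """Message passing -> combination cell -> per-node L2 normalization."""

    def __init__(self, rng, d_in, d_out, activation="elu", combination="convlstm1d"):
        self.message = MessagePassing(rng, d_in, d_out, activation)
        cell_cls = _CELLS[combination]
        if combination == "concat_dense":
            self.cell = cell_cls(rng, d_in, d_out, activation)
        else:
            self.cell = cell_cls(rng, d_in, d_out)

    def __call__(self, x: Tensor, adjacency: Tensor) -> Tensor:
        msg = self.message(x, adjacency)
        return self.cell(x, msg).l2_normalize(axis=-1)

    def parameters(self):
        return self.message.parameters() + self.cell.parameters()


class FFNBlock:
    """normalization -> dropout -> dense(activation), with an additive skip."""

    def __init__(self, rng, dim, dropout=0.3, activation="gelu"):
        self.norm = LayerNorm(dim)
        self.dense = Dense(rng, dim, dim)
        self.dropout = dropout
        self.activation = activation

    def __call__(self, x: Tensor, train: bool, rng) -> Tensor:
        y = self.norm(x)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = rng.random(y.data.shape) < keep
            y = y * Tensor(mask / keep)
        y = _act(self.dense(y), self.activation)
        return x + y

    def parameters(self):
        return self.norm.parameters() + self.dense.parameters()


class FFNHead:
    """Input normalization, stacked skip blocks, and the softmax classifier."""

    def __init__(self, rng, dim, n_blocks=9, dropout=0.3, activation="gelu", n_classes=2):
        self.in_norm = LayerNorm(dim)
        self.blocks = [FFNBlock(rng, dim, dropout, activation) for _ in range(n_blocks)]
        self.out = Dense(rng, dim, n_classes)

    def __call__(self, x: Tensor, train: bool, rng) -> Tensor:
        y = self.in_norm(x)
        for block in self.blocks:
            y = block(y, train, rng)
        return self.out(y)  # logits

    def parameters(self):
        ps = self.in_norm.parameters() + self.out.parameters()
        for b in self.blocks:
            ps += b.parameters()
        return ps


class GCNModel:
    """The full graph classifier: GCN stack -> mean pool -> FFN head."""

    def __init__(self, config: ModelConfig, adjacency: np.ndarray):
        adjacency = np.asarray(adjacency, dtype=float)
        if adjacency.shape[0] != adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        self.config = config
        self.adjacency = Tensor(adjacency)
        self.n_nodes = adjacency.shape[0]
        rng = np.random.default_rng(config.seed)
        widths = config.layer_widths
        self.layers = []
        d_in = 1
        for w in widths:
            self.layers.append(
                GCNLayer(rng, d_in, w, config.activation, config.combination)
            )
            d_in = w
        self.head = FFNHead(
            rng, d_in, config.ffn_blocks, config.dropout, config.ffn_activation
        )

    def forward(self, X: np.ndarray, train: bool = False, rng=None) -> Tensor:
        """Logits for a batch of node-value vectors X of shape (n, n_nodes)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_nodes:
            raise ValueError(
                f"expected node-value batch of shape (n, {self.n_nodes}), got {X.shape}"
            )
        h = Tensor(X[:, :, None])  # (n, nodes, 1)
        for layer in self.layers:
            h = layer(h, self.adjacency)
        pooled = h.mean(axis=1)  # graph-level readout
        return self.head(pooled, train, rng)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.forward(X, train=False).data
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def parameters(self):
        ps = []
        for layer in self.layers:
            ps += layer.parameters()
        ps += self.head.parameters()
        return ps

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


# ---------------------------------------------------------------------------
# GAT baseline
# ---------------------------------------------------------------------------

class GATLayer:
    """Multi-head softmax attention over graph neighbourhoods.

    Attention coefficients are normalized over each node's neighbourhood
    (isolated nodes fall back to a self-loop); head outputs are
    concatenated and passed through ELU.
    """

    def __init__(self, rng, d_in, d_out, n_heads=8, adjacency_mask=None):
        if d_out % n_heads:
            raise ValueError("d_out must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_out // n_heads
        self.W = _glorot(rng, d_in, d_out)
        self.a_src = Tensor(
            rng.uniform(-0.1, 0.1, size=(self.n_heads, self.d_head, 1)), requires_grad=True
        )
        self.a_dst = Tensor(
            rng.uniform(-0.1, 0.1, size=(self.n_heads, self.d_head, 1)), requires_grad=True
        )
        self.mask = adjacency_mask  # (nodes, nodes) bool

    def attention(self, x: Tensor) -> Tensor:
        """Attention coefficients, shape (batch, heads, nodes, nodes)."""
        return self._forward(x, return_attention=True)

    def __call__(self, x: Tensor) -> Tensor:
        return self._forward(x, return_attention=False)

    def _forward(self, x: Tensor, return_attention: bool):
        if np.isnan(x.data).any():
            raise ValueError("NaN in node embeddings")
        n_batch, n_nodes, _ = x.data.shape
        h = x @ self.W  # (B, N, H*dh)
        h = h.reshape(n_batch, n_nodes, self.n_heads, self.d_head).transpose((0, 2, 1, 3))
        s_src = h @ self.a_src  # (B, H, N, 1)
        s_dst = h @ self.a_dst
        e = (s_src + s_dst.transpose((0, 1, 3, 2))).leaky_relu(0.2)  # (B, H, N, N)
        mask = self.mask
        if mask is None:
            mask = np.ones((n_nodes, n_nodes), dtype=bool)
        bias = np.where(mask, 0.0, -1e9)
        alpha = (e + Tensor(bias)).softmax(axis=-1)
        if return_attention:
            return alpha
        out = alpha @ h  # (B, H, N, dh)
        out = out.transpose((0, 2, 1, 3)).reshape(
            n_batch, n_nodes, self.n_heads * self.d_head
        )
        return out.elu()

    def parameters(self):
        return [self.W, self.a_src, self.a_dst]


def attention_mask(adjacency: np.ndarray) -> np.ndarray:
    """Neighbourhood mask for attention; isolated nodes get a self-loop."""
    A = np.asarray(adjacency) != 0
    isolated = ~A.any(axis=1)
    mask = A.copy()
    mask[isolated, isolated] = True
    return mask


class GATModel:
    """Two ELU dense layers + two 8-head attention layers + softmax head."""

    def __init__(self, adjacency: np.ndarray, hidden: int = 128, n_heads: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.adjacency = np.asarray(adjacency, dtype=float)
        self.n_nodes = self.adjacency.shape[0]
        mask = attention_mask(self.adjacency)
        self.dense1 = Dense(rng, 1, hidden)
        self.dense2 = Dense(rng, hidden, hidden)
        self.gat1 = GATLayer(rng, hidden, hidden, n_heads, mask)
        self.gat2 = GATLayer(rng, hidden, hidden, n_heads, mask)
        self.out = Dense(rng, hidden, 2)

    def forward(self, X: np.ndarray, train: bool = False, rng=None) -> Tensor:
        h = Tensor(np.asarray(X, dtype=float)[:, :, None])
        h = self.dense1(h).elu()
        h = self.dense2(h).elu()
        h = self.gat1(h)
        h = self.gat2(h)
        return self.out(h.mean(axis=1))

    predict_proba = GCNModel.predict_proba

    def parameters(self):
        ps = self.dense1.parameters() + self.dense2.parameters() + self.out.parameters()
        ps += self.gat1.parameters() + self.gat2.parameters()
        return ps


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class Nadam:
    """Adam with Nesterov momentum on the first moment (Nadam-style)."""

    def __init__(self, params, lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            m_hat = b1 * m / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)


@dataclass
class TrainedModel:
    model: GCNModel
    history: TrainHistory

    def predict(self, samples) -> list[PredictionOutput]:
        return predict(self.model, samples)


def _stack(samples) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.node_values for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    return X, y


def _check_topology(samples):
    first = samples[0].topology
    for s in samples[1:]:
        if s.topology is not first and (
            s.topology.nodes != first.nodes or s.topology.edges != first.edges
        ):
            raise ValueError("samples do not share one graph topology")
    return first


def _eval(model, X, y):
    probs = model.predict_proba(X)
    loss = float(-np.log(probs[np.arange(len(y)), y] + 1e-12).mean())
    acc = float((probs.argmax(axis=1) == y).mean())
    return loss, acc


def train_model(samples, config: ModelConfig, val_samples=None) -> TrainedModel:
    """Train the GCN on graph samples; deterministic given ``config.seed``."""
    if not samples:
        raise ValueError("no training samples")
    topology = _check_topology(samples)
    X, y = _stack(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    model = GCNModel(config, topology.adjacency())
    opt = Nadam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = TrainHistory()
    Xv = yv = None
    if val_samples:
        Xv, yv = _stack(val_samples)
    n = len(X)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(X[idx], train=True, rng=rng)
            loss = softmax_cross_entropy(logits, y[idx])
            loss.backward()
            opt.step()
        tl, ta = _eval(model, X, y)
        history.train_loss.append(tl)
        history.train_accuracy.append(ta)
        if Xv is not None:
            vl, va = _eval(model, Xv, yv)
            history.val_loss.append(vl)
            history.val_accuracy.append(va)
    return TrainedModel(model=model, history=history)


def predict(model, samples) -> list[PredictionOutput]:
    """Class probabilities for graph samples under a trained model."""
    if isinstance(model, TrainedModel):
        model = model.model
    topology = _check_topology(samples)
    if len(topology.nodes) != model.n_nodes:
        raise ValueError("sample topology does not match the model's node count")
    X, _ = _stack(samples)
    probs = model.predict_proba(X)
    return [PredictionOutput(p) for p in probs]
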