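"""Graph-temporal forecasting network.

The forward pass composes, per batch of aligned segments:

1. two stacked graph-convolution layers over the patient relation graph,
2. a convolution along the sample (spatial) axis,
3. temporal attention producing a distribution over the T window steps,
4. a GRU over the attention-reweighted sequence,
5. temporal + spatial MLP heads fused with a linear residual map of the
   raw input window.

Everything runs on the bundled NumPy autodiff engine; a forward pass in
eval mode is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .srgraph import SRGraph

__all__ = [
    "HETERConfig",
    "HETERParams",
    "ForwardTrace",
    "gcn_layer",
    "graph_module",
    "conv_component",
    "temporal_attention",
    "gru_forward",
    "output_head",
    "heter_forward",
]


@dataclass(frozen=True)
class HETERConfig:
    """Hyperparameters of the network. ``window``/``horizon_steps`` must
    match the aligned tensors; ``k`` is carried for bookkeeping only."""

    window: int = 8
    horizon_steps: int = 1
    k: int = 25
    gcn_hidden: int = 64
    conv_channels: int = 32
    conv_kernel: int = 3
    att_hidden: int = 16
    gru_hidden: int = 64
    mlp_hidden: int = 32
    smlp_hidden: int = 16
    dropout_g: float = 0.2
    dropout_co: float = 0.2
    dropout_o: float = 0.2
    candidate_activation: str = "sigmoid"  # printed form; "tanh" is the conventional GRU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.horizon_steps < 1:
            raise ValueError("horizon_steps must be >= 1")
        for name in ("gcn_hidden", "conv_channels", "conv_kernel", "att_hidden",
                     "gru_hidden", "mlp_hidden", "smlp_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("dropout_g", "dropout_co", "dropout_o"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.candidate_activation not in ("sigmoid", "tanh"):
            raise ValueError("candidate_activation must be 'sigmoid' or 'tanh'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "HETERConfig":
        return cls(**data)


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class HETERParams:
    """All learnable tensors, keyed by name."""

    tensors: dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def initialize(cls, config: HETERConfig, n_nodes: int) -> "HETERParams":
        rng = np.random.default_rng(config.seed)
        T, s, H = config.window, config.horizon_steps, config.gru_hidden
        G, C, kk = config.gcn_hidden, config.conv_channels, config.conv_kernel
        A, M, SM = config.att_hidden, config.mlp_hidden, config.smlp_hidden
        spec: dict[str, tuple[tuple[int, ...], int, int]] = {
            # name: (shape, fan_in, fan_out)
            "W_g1": ((T, G), T, G),
            "b_g": ((G,), T, G),
            "W_g2": ((G, T), G, T),
            "W_co": ((kk, C), kk, C),
            "W_ta2": ((C, A), C, A),
            "b_ta2": ((A,), C, A),
            "W_ta1": ((A, 1), A, 1),
            "b_ta1": ((1,), A, 1),
            "W_r": ((H + C, H), H + C, H),
            "b_r": ((H,), H + C, H),
            "W_u": ((H + C, H), H + C, H),
            "b_u": ((H,), H + C, H),
            "W_c": ((H + C, H), H + C, H),
            "b_c": ((H,), H + C, H),
            "W_t1": ((H, M), H, M),
            "b_t1": ((M,), H, M),
            "W_t2": ((M, s), M, s),
            "b_t2": ((s,), M, s),
            "W_s1": ((n_nodes, SM), n_nodes, SM),
            "b_s1": ((SM,), n_nodes, SM),
            "W_s2": ((SM, n_nodes), SM, n_nodes),
            "b_s2": ((n_nodes,), SM, n_nodes),
            "W_o": ((T, s), T, s),
            "b_o": ((s,), T, s),
        }
        tensors = {}
        for name, (shape, fi, fo) in spec.items():
            if name.startswith("b"):
                data = np.zeros(shape)
            elif name == "W_s2":
                # zero-init the head's last layer: training starts from the
                # pure linear-residual model and learns corrections on top
                data = np.zeros(shape)
            elif name == "W_o":
                # identity-init the linear skip: map every horizon step to
                # the window's last observation (a last-value start point)
                data = np.zeros(shape)
                data[-1, :] = 1.0
            else:
                data = _xavier(rng, fi, fo, shape)
            tensors[name] = Tensor(data, requires_grad=True)
        return cls(tensors=tensors)

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def items(self):
        return self.tensors.items()

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.grad = None

    def detach(self) -> None:
        """Drop any recorded graph edges on the parameter leaves."""
        for t in self.tensors.values():
            t._parents = ()
            t._backward = None

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.tensors.values())

    def save(self, path, config: HETERConfig) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {k: t.data for k, t in self.tensors.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> tuple["HETERParams", HETERConfig]:
        with np.load(path) as data:
            config = HETERConfig.from_dict(
                json.loads(bytes(data["__config__"].tobytes()).decode())
            )
            tensors = {
                k: Tensor(data[k].copy(), requires_grad=True)
                for k in data.files
                if k != "__config__"
            }
        return cls(tensors=tensors), config


@dataclass
class ForwardTrace:
    """Intermediate activations of one forward pass (eval-mode debugging)."""

    r_g1: np.ndarray
    r_g2: np.ndarray
    r_co: np.ndarray
    s_ta: np.ndarray
    h_t: np.ndarray
    r_o: np.ndarray
    o: np.ndarray


def _dropout(x: Tensor, p: float, training: bool, rng: np.random.Generator | None) -> Tensor:
    if not training or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout requires an rng")
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def gcn_layer(P, X, W, b=None) -> Tensor:
    """One graph convolution: ``P @ X @ W (+ b)``.

    ``P`` is the (N, N) normalized propagation matrix, ``X`` node features
    of shape (..., N, F).
    """
    P, X, W = ad.as_tensor(P), ad.as_tensor(X), ad.as_tensor(W)
    if P.shape[-1] != X.shape[-2]:
        raise ValueError(
            f"propagation matrix size {P.shape} incompatible with features {X.shape}"
        )
    out = P @ X @ W
    if b is not None:
        out = out + ad.as_tensor(b)
    return out


def graph_module(
    X: Tensor,
    graph: SRGraph,
    params: HETERParams,
    config: HETERConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """Two stacked GCN layers; returns (first, second) representations."""
    if graph.n_nodes != X.shape[-2]:
        raise ValueError(
            f"graph has {graph.n_nodes} nodes but input has {X.shape[-2]} samples"
        )
    P = Tensor(graph.propagation)
    r_g1 = gcn_layer(P, X, params["W_g1"], params["b_g"])
    hidden = _dropout(ad.relu(r_g1), config.dropout_g, training, rng)
    r_g2 = gcn_layer(P, hidden, params["W_g2"])  # second layer: no bias
    return r_g1, r_g2


def conv_component(
    r_g2: Tensor,
    params: HETERParams,
    config: HETERConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Convolution along the sample axis with same-length padding.

    Input (batch, N, T) -> output (batch, N, T, C); the kernel W_co has
    shape (kernel, channels) and is shared across time steps.
    """
    batch, n, t = r_g2.shape
    kk = config.conv_kernel
    if kk > n:
        raise ValueError(f"conv kernel {kk} larger than sample extent {n}")
    pad_left = (kk - 1) // 2
    pad_right = kk - 1 - pad_left
    pieces = []
    if pad_left:
        pieces.append(Tensor(np.zeros((batch, pad_left, t))))
    pieces.append(r_g2)
    if pad_right:
        pieces.append(Tensor(np.zeros((batch, pad_right, t))))
    padded = ad.concat(pieces, axis=1) if len(pieces) > 1 else r_g2
    shifted = ad.stack_last([padded[:, dk : dk + n, :] for dk in range(kk)])
    conv = shifted @ params["W_co"]  # (batch, N, T, kernel) @ (kernel, C)
    return _dropout(ad.relu(conv), config.dropout_co, training, rng)


def temporal_attention(r_co: Tensor, params: HETERParams) -> Tensor:
    """Attention scores over the window's time steps.

    Input (batch, N, T, C) -> scores (batch, N, T), softmax along T, so
    every (batch, sample) row is a probability distribution.
    """
    hidden = ad.relu(r_co @ params["W_ta2"] + params["b_ta2"])
    logits = hidden @ params["W_ta1"] + params["b_ta1"]  # (batch, N, T, 1)
    batch, n, t = logits.shape[0], logits.shape[1], logits.shape[2]
    return ad.softmax(logits.reshape(batch, n, t), axis=-1)


def gru_cell(
    x: Tensor,
    h: Tensor,
    params: HETERParams,
    candidate_activation: str = "sigmoid",
) -> Tensor:
    """One GRU step. Candidate activation defaults to sigmoid (the printed
    form of this architecture); pass ``"tanh"`` for the conventional cell."""
    act = ad.sigmoid if candidate_activation == "sigmoid" else ad.tanh
    hx = ad.concat([h, x], axis=-1)
    r = ad.sigmoid(hx @ params["W_r"] + params["b_r"])
    u = ad.sigmoid(hx @ params["W_u"] + params["b_u"])
    rhx = ad.concat([r * h, x], axis=-1)
    c = act(rhx @ params["W_c"] + params["b_c"])
    return (1.0 - u) * h + u * c


def gru_forward(
    sequence: Tensor,
    params: HETERParams,
    config: HETERConfig,
    h0: Tensor | None = None,
) -> Tensor:
    """Run the GRU along the time axis of (batch, N, T, C); returns h_T of
    shape (batch, N, gru_hidden)."""
    batch, n, t, _ = sequence.shape
    h = h0 if h0 is not None else Tensor(np.zeros((batch, n, config.gru_hidden)))
    for step in range(t):
        x = sequence[:, :, step, :]
        h = gru_cell(x, h, params, config.candidate_activation)
    return h


def output_head(
    h_t: Tensor,
    X: Tensor,
    params: HETERParams,
    config: HETERConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """Temporal MLP -> spatial MLP, fused with the linear residual map.

    Returns (r_o, output); output = r_o + X @ W_o + b_o, shape (batch, N, s).
    """
    dropped = _dropout(h_t, config.dropout_o, training, rng)
    tm = ad.relu(dropped @ params["W_t1"] + params["b_t1"]) @ params["W_t2"] + params["b_t2"]
    # spatial MLP mixes information across the sample axis
    zt = tm.swapaxes(-1, -2)  # (batch, s, N)
    sm = ad.relu(zt @ params["W_s1"] + params["b_s1"]) @ params["W_s2"] + params["b_s2"]
    r_o = sm.swapaxes(-1, -2)  # (batch, N, s)
    linear = X @ params["W_o"] + params["b_o"]
    return r_o, r_o + linear


def heter_forward(
    X,
    graph: SRGraph,
    params: HETERParams,
    config: HETERConfig,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
    return_trace: bool = False,
):
    """Full forward pass over a batch of aligned segments.

    ``X`` has shape (batch, N, T); output has shape (batch, N, s) in
    normalized units. Dropout is active only when ``mode == "train"``.
    """
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    training = mode == "train"
    X = ad.as_tensor(X)
    if X.ndim != 3:
        raise ValueError("X must have shape (batch, N, T)")
    if X.shape[2] != config.window:
        raise ValueError(f"input window {X.shape[2]} != configured {config.window}")

    r_g1, r_g2 = graph_module(X, graph, params, config, training, rng)
    r_co = conv_component(r_g2, params, config, training, rng)
    s_ta = temporal_attention(r_co, params)
    batch, n, t = s_ta.shape
    reweighted = r_co * s_ta.reshape(batch, n, t, 1)
    h_t = gru_forward(reweighted, params, config)
    r_o, out = output_head(h_t, X, params, config, training, rng)

    if return_trace:
        trace = ForwardTrace(
            r_g1=r_g1.data, r_g2=r_g2.data, r_co=r_co.data, s_ta=s_ta.data,
            h_t=h_t.data, r_o=r_o.data, o=out.data,
        )
        return out, trace
    return out
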