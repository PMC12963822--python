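"""Three-layer graph attention network with typed-edge embeddings.

Architecture (defaults follow the published dimensioning):

* layer 1 — 2 attention heads, input dim 2 (expression Z, m5C Z), 16
  output dims per head, concatenated to 32;
* layer 2 — 2 heads, 32 in, 16 per head, concatenated to 32;
* layer 3 — 1 head compressing 32 dims to a single importance logit.

A 32-dimensional edge-type embedding feeds every layer's attention
logit; batch normalization follows layers 1 and 2; activations are ELU;
dropout 0.3 is applied after each normalized layer. For an edge j -> i
with type t the unnormalized attention logit of one head is

    e_ij = LeakyReLU( a_dst . W h_i  +  a_src . W h_j  +  P . g(t) )

where ``g`` is the layer's edge-type embedding table and ``P`` its
projection vector; ``alpha_ij`` is the softmax of ``e_ij`` over the
in-neighborhood of i, which always includes a structural self-loop with
a reserved edge type so even isolated genes have a defined neighborhood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .ppi_graph import PPINetwork


@dataclass(frozen=True)
class GATConfig:
    """Architecture hyperparameters."""

    in_dim: int = 2
    layer1_heads: int = 2
    layer1_out: int = 16
    layer2_heads: int = 2
    layer2_out: int = 16
    layer3_heads: int = 1
    layer3_out: int = 1
    edge_embed_dim: int = 32
    dropout: float = 0.3
    leaky_relu_slope: float = 0.2
    attention_dropout: bool = False
    n_edge_types: int = 1
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.layer3_heads != 1:
            raise ValueError("the output layer uses a single attention head")
        if min(self.in_dim, self.layer1_out, self.layer2_out,
               self.edge_embed_dim, self.n_edge_types) < 1:
            raise ValueError("all dimensions must be positive")

    def layer_dims(self) -> list[tuple[int, int, int]]:
        """Per layer: (heads, input dim, output dim per head).

        Input dims of layers 2 and 3 are forced by head concatenation.
        """
        return [
            (self.layer1_heads, self.in_dim, self.layer1_out),
            (self.layer2_heads, self.layer1_heads * self.layer1_out, self.layer2_out),
            (self.layer3_heads, self.layer2_heads * self.layer2_out, self.layer3_out),
        ]


@dataclass
class GATParameters:
    """All learned weights plus batch-norm running statistics."""

    config: GATConfig
    tensors: dict[str, Tensor]
    running: dict[str, np.ndarray]
    seed: int = 0

    def trainable(self) -> list[Tensor]:
        return [self.tensors[k] for k in sorted(self.tensors)]

    def copy(self) -> "GATParameters":
        return GATParameters(
            config=self.config,
            tensors={k: Tensor(v.data.copy(), requires_grad=True)
                     for k, v in self.tensors.items()},
            running={k: v.copy() for k, v in self.running.items()},
            seed=self.seed,
        )

    def validate_shapes(self) -> None:
        expected = _expected_shapes(self.config)
        got = {k: v.data.shape for k, v in self.tensors.items()}
        got.update({k: v.shape for k, v in self.running.items()})
        if got != expected:
            missing = set(expected) - set(got)
            extra = set(got) - set(expected)
            wrong = {k: (got[k], expected[k]) for k in set(got) & set(expected)
                     if got[k] != expected[k]}
            raise ValueError(
                f"parameter shapes inconsistent with config: missing={missing} "
                f"extra={extra} wrong={wrong}"
            )
        for k, v in self.tensors.items():
            if not np.all(np.isfinite(v.data)):
                raise ValueError(f"non-finite values in parameter {k}")


def _expected_shapes(cfg: GATConfig) -> dict[str, tuple[int, ...]]:
    shapes: dict[str, tuple[int, ...]] = {}
    n_types = cfg.n_edge_types + 1  # + reserved self-loop type
    for layer, (heads, d_in, d_out) in enumerate(cfg.layer_dims(), start=1):
        shapes[f"embed{layer}"] = (n_types, cfg.edge_embed_dim)
        shapes[f"b{layer}"] = (heads * d_out,)
        for h in range(heads):
            shapes[f"W{layer}_{h}"] = (d_in, d_out)
            shapes[f"a_src{layer}_{h}"] = (d_out,)
            shapes[f"a_dst{layer}_{h}"] = (d_out,)
            shapes[f"P{layer}_{h}"] = (cfg.edge_embed_dim,)
    for layer in (1, 2):
        heads, _, d_out = cfg.layer_dims()[layer - 1]
        dim = heads * d_out
        shapes[f"bn{layer}_gamma"] = (dim,)
        shapes[f"bn{layer}_beta"] = (dim,)
        shapes[f"bn{layer}_mean"] = (dim,)
        shapes[f"bn{layer}_var"] = (dim,)
    return shapes


def init_parameters(config: GATConfig, seed: int | None = None) -> GATParameters:
    """Glorot-uniform transforms and attention vectors, zero biases and
    edge projections, small-uniform edge embeddings. Same seed, same bytes."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    tensors: dict[str, Tensor] = {}
    running: dict[str, np.ndarray] = {}
    n_types = config.n_edge_types + 1

    def glorot(*shape):
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        fan_out = shape[-1] if len(shape) > 1 else 1
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)

    for layer, (heads, d_in, d_out) in enumerate(config.layer_dims(), start=1):
        tensors[f"embed{layer}"] = Tensor(
            rng.uniform(-0.1, 0.1, size=(n_types, config.edge_embed_dim)),
            requires_grad=True,
        )
        tensors[f"b{layer}"] = Tensor(np.zeros(heads * d_out), requires_grad=True)
        for h in range(heads):
            tensors[f"W{layer}_{h}"] = glorot(d_in, d_out)
            tensors[f"a_src{layer}_{h}"] = glorot(d_out)
            tensors[f"a_dst{layer}_{h}"] = glorot(d_out)
            tensors[f"P{layer}_{h}"] = Tensor(
                np.zeros(config.edge_embed_dim), requires_grad=True
            )
    for layer in (1, 2):
        heads, _, d_out = config.layer_dims()[layer - 1]
        dim = heads * d_out
        tensors[f"bn{layer}_gamma"] = Tensor(np.ones(dim), requires_grad=True)
        tensors[f"bn{layer}_beta"] = Tensor(np.zeros(dim), requires_grad=True)
        running[f"bn{layer}_mean"] = np.zeros(dim)
        running[f"bn{layer}_var"] = np.ones(dim)
    params = GATParameters(config=config, tensors=tensors, running=running,
                           seed=seed)
    params.validate_shapes()
    return params


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def _self_loop_edges(net: PPINetwork, n_edge_types: int):
    """Directed edges augmented with one self-loop per node (reserved type)."""
    n = net.n_nodes
    esrc = np.concatenate([net.edge_src, np.arange(n)])
    edst = np.concatenate([net.edge_dst, np.arange(n)])
    etype = np.concatenate([net.edge_type, np.full(n, n_edge_types)])
    if net.edge_type.size and net.edge_type.max() >= n_edge_types:
        raise ValueError(
            f"network uses edge type {int(net.edge_type.max())} but the model "
            f"was configured for {n_edge_types} types"
        )
    return esrc, edst, etype


def _head_attention(h, W, a_src, a_dst, embeds, P, esrc, edst, n, slope):
    """One head's (alpha, transformed features); alpha sums to 1 per node."""
    H = ad.matmul(h, W)
    logit = ad.add(
        ad.add(
            ad.asum(ad.mul(ad.gather_rows(H, edst), a_dst), axis=1),
            ad.asum(ad.mul(ad.gather_rows(H, esrc), a_src), axis=1),
        ),
        ad.asum(ad.mul(embeds, P), axis=1),
    )
    e = ad.leaky_relu(logit, slope)
    alpha = ad.segment_softmax(e, edst, n)
    return alpha, H


def forward_logits(
    net: PPINetwork,
    node_features: np.ndarray,
    params: GATParameters,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Full-graph forward pass returning one importance logit per node.

    ``mode="train"`` uses batch statistics (updating the running ones)
    and applies dropout from ``rng``; ``mode="eval"`` is deterministic,
    using running statistics with dropout as identity.
    """
    cfg = params.config
    if mode not in {"train", "eval"}:
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    X = np.asarray(node_features, dtype=float)
    if X.shape != (net.n_nodes, cfg.in_dim):
        raise ValueError(
            f"node features must be ({net.n_nodes}, {cfg.in_dim}), got {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite node features")
    if mode == "train" and rng is None:
        raise ValueError("train mode needs an rng for dropout")

    esrc, edst, etype = _self_loop_edges(net, cfg.n_edge_types)
    n = net.n_nodes
    t = params.tensors
    h = Tensor(X)

    for layer, (heads, _, d_out) in enumerate(cfg.layer_dims(), start=1):
        embeds = ad.gather_rows(t[f"embed{layer}"], etype)
        head_outputs = []
        for head in range(heads):
            alpha, H = _head_attention(
                h, t[f"W{layer}_{head}"], t[f"a_src{layer}_{head}"],
                t[f"a_dst{layer}_{head}"], embeds, t[f"P{layer}_{head}"],
                esrc, edst, n, cfg.leaky_relu_slope,
            )
            if cfg.attention_dropout and mode == "train":
                keep = (rng.random(alpha.shape) >= cfg.dropout) / (1 - cfg.dropout)
                alpha = ad.mul(alpha, keep)
            msg = ad.mul(ad.reshape(alpha, (-1, 1)), ad.gather_rows(H, esrc))
            head_outputs.append(ad.scatter_sum(msg, edst, n))
        out = head_outputs[0] if heads == 1 else ad.concat(head_outputs, axis=1)
        out = ad.add(out, t[f"b{layer}"])
        if layer in (1, 2):
            out = _batch_norm(out, params, layer, mode)
            out = ad.elu(out)
            if cfg.dropout > 0 and mode == "train":
                keep = (rng.random(out.shape) >= cfg.dropout) / (1 - cfg.dropout)
                out = ad.mul(out, keep)
        h = out
    return ad.reshape(h, (n,))


def forward(
    net: PPINetwork,
    node_features: np.ndarray,
    params: GATParameters,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-node importance scores in (0, 1) (sigmoid of the logits)."""
    logits = forward_logits(net, node_features, params, mode=mode, rng=rng)
    return 1.0 / (1.0 + np.exp(-logits.data))


def _batch_norm(x: Tensor, params: GATParameters, layer: int, mode: str) -> Tensor:
    cfg = params.config
    gamma = params.tensors[f"bn{layer}_gamma"]
    beta = params.tensors[f"bn{layer}_beta"]
    if mode == "train":
        mu = ad.mean(x, axis=0, keepdims=True)
        centered = ad.sub(x, mu)
        var = ad.mean(ad.mul(centered, centered), axis=0, keepdims=True)
        xhat = ad.div(centered, ad.sqrt(ad.add(var, cfg.bn_eps)))
        n = x.shape[0]
        unbias = n / max(n - 1, 1)
        m = cfg.bn_momentum
        params.running[f"bn{layer}_mean"] *= 1 - m
        params.running[f"bn{layer}_mean"] += m * mu.data.ravel()
        params.running[f"bn{layer}_var"] *= 1 - m
        params.running[f"bn{layer}_var"] += m * unbias * var.data.ravel()
    else:
        mu = params.running[f"bn{layer}_mean"]
        sd = np.sqrt(params.running[f"bn{layer}_var"] + cfg.bn_eps)
        xhat = ad.div(ad.sub(x, mu), sd)
    return ad.add(ad.mul(xhat, gamma), beta)


def attention_coefficients(
    layer: int,
    head: int,
    node_features: np.ndarray,
    net: PPINetwork,
    params: GATParameters,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Attention weights of one layer/head given that layer's input features.

    Returns (alpha, edge_src, edge_dst) over the self-loop-augmented edge
    set; for every node the weights over its in-edges sum to 1.
    """
    cfg = params.config
    heads, d_in, _ = cfg.layer_dims()[layer - 1]
    if not 0 <= head < heads:
        raise ValueError(f"layer {layer} has {heads} heads, asked for {head}")
    X = np.asarray(node_features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite node features")
    if X.shape[1] != d_in:
        raise ValueError(f"layer {layer} expects {d_in}-dim inputs, got {X.shape[1]}")
    esrc, edst, etype = _self_loop_edges(net, cfg.n_edge_types)
    t = params.tensors
    embeds = ad.gather_rows(t[f"embed{layer}"], etype)
    alpha, _ = _head_attention(
        Tensor(X), t[f"W{layer}_{head}"], t[f"a_src{layer}_{head}"],
        t[f"a_dst{layer}_{head}"], embeds, t[f"P{layer}_{head}"],
        esrc, edst, net.n_nodes, cfg.leaky_relu_slope,
    )
    return alpha.data, esrc, edst


# ---------------------------------------------------------------------------
# Checkpointing (JSON: config block + parameter arrays + training seed)
# ---------------------------------------------------------------------------

def save_checkpoint(params: GATParameters, path: str | Path) -> None:
    payload = {
        "config": asdict(params.config),
        "seed": params.seed,
        "tensors": {k: v.data.tolist() for k, v in params.tensors.items()},
        "running": {k: v.tolist() for k, v in params.running.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> GATParameters:
    payload = json.loads(Path(path).read_text())
    config = GATConfig(**payload["config"])
    params = GATParameters(
        config=config,
        tensors={k: Tensor(np.array(v, dtype=float), requires_grad=True)
                 for k, v in payload["tensors"].items()},
        running={k: np.array(v, dtype=float)
                 for k, v in payload["running"].items()},
        seed=int(payload["seed"]),
    )
    params.validate_shapes()
    return params
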