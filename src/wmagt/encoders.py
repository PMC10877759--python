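"""Node encoders: weighted multi-aggregate graph convolution + graph transformer.

Each similarity graph is encoded twice from the same projected inputs and
the two paths are blended with a fixed mixing weight lambda:

* a mixed-aggregation path ``beta * ReLU(Pool(XW, A)) + alpha * ReLU(S XW)``
  where ``S = D^{-1/2}(A+I)D^{-1/2}`` is the normalized propagation of a
  standard GCN and ``Pool`` is a pairwise-interaction pooling
  ``Z = (A XW)^2 - (A^2 ⊙ XW^2)`` — per node and channel the sum of
  products of all ordered pairs of distinct neighbour features, computed
  via the square-of-sums minus sum-of-squares identity.  alpha and beta
  are learnable scalars so the model weighs the two aggregations itself.
* a graph-transformer path: masked multi-head scaled dot-product
  self-attention over each node's extended k-NN neighbourhood, summed (in
  parallel) with a position-wise feed-forward block, heads concatenated
  and projected back to the embedding dimension.

Initial node features are the rows of the dense similarity matrix
projected linearly to the embedding dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import (Tensor, as_tensor, concat, glorot, masked_softmax,
                        relu)
from .graph_data import SimilarityGraph

__all__ = [
    "EncoderConfig",
    "NodeEmbeddings",
    "init_encoder_params",
    "encoder_param_list",
    "gcn_layer",
    "pairwise_pool",
    "mixed_aggregate",
    "attention_weights",
    "transformer_layer",
    "weighted_projection",
    "encode_nodes",
]


@dataclass
class EncoderConfig:
    """Encoder hyperparameters.

    lambda_mix blends the transformer path (weight lambda) with the
    mixed-aggregation path (weight 1 - lambda); alpha/beta start at 0.5
    and are trained.
    """

    embed_dim: int = 64
    num_heads: int = 4
    lambda_mix: float = 0.8
    dropout: float = 0.3
    alpha_init: float = 0.5
    beta_init: float = 0.5
    attention_scope: str = "knn"        # "knn" | "full"
    transformer_block: str = "parallel"  # "parallel" | "sequential"

    def __post_init__(self):
        if self.embed_dim % self.num_heads != 0:
            raise ValueError("embed_dim must be divisible by num_heads")
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must be in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.attention_scope not in ("knn", "full"):
            raise ValueError("attention_scope must be 'knn' or 'full'")
        if self.transformer_block not in ("parallel", "sequential"):
            raise ValueError("transformer_block must be 'parallel' or 'sequential'")


@dataclass
class NodeEmbeddings:
    """Per-node embedding matrix aligned with `node_ids`."""

    vectors: np.ndarray
    node_ids: list[str]

    def __post_init__(self):
        if not np.isfinite(self.vectors).all():
            raise ValueError("node embeddings contain non-finite values")


# -- parameters -------------------------------------------------------------

def init_encoder_params(rng: np.random.Generator, n_nodes: int,
                        config: EncoderConfig) -> dict:
    d = config.embed_dim
    d_head = d // config.num_heads
    return {
        "w_in": glorot(rng, (n_nodes, d)),
        "heads": [glorot(rng, (d, d_head)) for _ in range(config.num_heads)],
        "w_out": glorot(rng, (d, d)),
        "b_out": Tensor(np.zeros(d), requires_grad=True),
        "ff_w1": glorot(rng, (d, d)),
        "ff_b1": Tensor(np.zeros(d), requires_grad=True),
        "ff_w2": glorot(rng, (d, d)),
        "ff_b2": Tensor(np.zeros(d), requires_grad=True),
        "w_agg": glorot(rng, (d, d)),
        "alpha": Tensor(config.alpha_init, requires_grad=True),
        "beta": Tensor(config.beta_init, requires_grad=True),
    }


def encoder_param_list(params: dict) -> list[Tensor]:
    out: list[Tensor] = []
    for v in params.values():
        out.extend(v if isinstance(v, list) else [v])
    return out


# -- building blocks --------------------------------------------------------

def gcn_layer(features, normalized_adj, weight) -> Tensor:
    """One graph-convolution update: ReLU(S X W)."""
    features = as_tensor(features)
    normalized_adj = as_tensor(normalized_adj)
    weight = as_tensor(weight)
    if features.shape[1] != weight.shape[0]:
        raise ValueError(
            f"feature dim {features.shape[1]} does not match weight rows "
            f"{weight.shape[0]}"
        )
    return relu(normalized_adj @ features @ weight)


def pairwise_pool(features_projected, adjacency) -> Tensor:
    """Pairwise-interaction pooling Z = (A XW)^2 - (A^2 ⊙ XW^2).

    Per node i and channel c this equals the sum over ordered pairs of
    distinct neighbours j != k of A_ij A_ik x_jc x_kc: the square of the
    weighted neighbour sum minus the weighted sum of squares.
    """
    xw = as_tensor(features_projected)
    A = as_tensor(adjacency)
    if A.shape[0] != A.shape[1] or A.shape[1] != xw.shape[0]:
        raise ValueError(f"adjacency {A.shape} does not match features {xw.shape}")
    return (A @ xw) ** 2 - (A**2) @ (xw**2)


def mixed_aggregate(features, adjacency, normalized_adj, weight,
                    alpha_agg, beta_agg) -> Tensor:
    """beta * ReLU(Pool(XW, A)) + alpha * ReLU(S XW)."""
    features = as_tensor(features)
    weight = as_tensor(weight)
    xw = features @ weight
    pool_branch = relu(pairwise_pool(xw, adjacency))
    gcn_branch = relu(as_tensor(normalized_adj) @ xw)
    return as_tensor(beta_agg) * pool_branch + as_tensor(alpha_agg) * gcn_branch


def attention_weights(embeddings, weight, mask, scale: float | None = None) -> Tensor:
    """Masked scaled dot-product attention weights.

    Scores e_ij = (W h_i) . (W h_j) / sqrt(d_head) are softmax-normalized
    over each node's allowed targets (`mask`); rows are probability
    vectors over the mask and exactly 0 outside it.
    """
    h = as_tensor(embeddings)
    w = as_tensor(weight)
    proj = h @ w
    if scale is None:
        scale = 1.0 / np.sqrt(proj.shape[1])
    scores = (proj @ proj.T) * scale
    return masked_softmax(scores, mask)


def transformer_layer(embeddings, params: dict, mask, config: EncoderConfig) -> Tensor:
    """Multi-head masked self-attention + feed-forward node update.

    With ``transformer_block='parallel'`` the attention block and the
    feed-forward block are applied to the same input and summed; the
    'sequential' variant is the conventional residual Transformer block.
    """
    h = as_tensor(embeddings)

    def attn_block(x: Tensor) -> Tensor:
        heads = []
        for w_h in params["heads"]:
            proj = x @ w_h  # scores and values share the head projection
            scale = 1.0 / np.sqrt(proj.shape[1])
            attn = masked_softmax((proj @ proj.T) * scale, mask)
            heads.append(attn @ proj)
        stacked = concat(heads, axis=1)
        return stacked @ params["w_out"] + params["b_out"]

    def ff_block(x: Tensor) -> Tensor:
        hidden = relu(x @ params["ff_w1"] + params["ff_b1"])
        return hidden @ params["ff_w2"] + params["ff_b2"]

    if config.transformer_block == "parallel":
        return attn_block(h) + ff_block(h)
    y = h + attn_block(h)
    return y + ff_block(y)


def weighted_projection(features, weight, norm_matrix=None, bias=None) -> Tensor:
    """norm . (X W) + bias, with bias broadcast per feature channel."""
    features = as_tensor(features)
    weight = as_tensor(weight)
    if features.shape[1] != weight.shape[0]:
        raise ValueError(
            f"feature dim {features.shape[1]} does not match weight rows "
            f"{weight.shape[0]}"
        )
    out = features @ weight
    if norm_matrix is not None:
        out = as_tensor(norm_matrix) @ out
    if bias is not None:
        out = out + as_tensor(bias)
    return out


# -- full encoder -----------------------------------------------------------

def encode_nodes(graph: SimilarityGraph, normalized_adj: np.ndarray,
                 params: dict, config: EncoderConfig,
                 training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Encode one similarity graph into embed_dim-dimensional node states.

    Output = lambda * transformer path + (1 - lambda) * mixed-aggregation
    path; dropout is applied only when `training` is true (requires `rng`).
    """
    x0 = Tensor(graph.values) @ params["w_in"]
    if config.attention_scope == "knn":
        mask = graph.neighbor_mask()
        np.fill_diagonal(mask, True)  # self always attends to itself
    else:
        mask = np.ones((graph.n_nodes, graph.n_nodes), dtype=bool)

    lam = config.lambda_mix
    parts: list[Tensor] = []
    if lam > 0.0:
        parts.append(as_tensor(lam) * transformer_layer(x0, params, mask, config))
    if lam < 1.0:
        mixed = mixed_aggregate(x0, graph.sparse_adjacency, normalized_adj,
                                params["w_agg"], params["alpha"], params["beta"])
        parts.append(as_tensor(1.0 - lam) * mixed)
    out = parts[0] if len(parts) == 1 else parts[0] + parts[1]

    if training and config.dropout > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = (rng.random(out.shape) >= config.dropout) / (1.0 - config.dropout)
        out = out * Tensor(keep)
    return out
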