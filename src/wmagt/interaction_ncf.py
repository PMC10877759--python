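"""Neural collaborative filtering: interaction/neighbour embeddings + decoder.

For a (drug, disease) pair the decoder input concatenates

* the interaction embedding: projected drug and disease embeddings
  multiplied element-wise and L2-normalized per pair (printed twice in the
  pair vector, matching the published concatenation; a flag collapses the
  duplication),
* a drug neighbour embedding: similarity-weighted mean of the drug's
  extended k-NN neighbours' embeddings projected to the neighbour
  dimension (32), and the analogous disease neighbour embedding.

The concatenated vector is scored by an MLP with ReLU hidden layers
(64, 32) and a sigmoid output.  The 'w/o NCF' ablation omits both the
neighbour-embedding and the interaction-embedding (element-wise product)
steps and feeds the pair's two raw encoder representations, concatenated,
straight to a decoder of matching input width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import (Tensor, as_tensor, clamp, concat, glorot, relu,
                        sigmoid, take_rows, tsum)
from .encoders import (EncoderConfig, NodeEmbeddings, encode_nodes,
                       encoder_param_list, init_encoder_params,
                       weighted_projection)
from .graph_data import HeteroBundle, SimilarityGraph

__all__ = [
    "DecoderConfig",
    "ModelConfig",
    "PairBatch",
    "PairVector",
    "project_pair",
    "interaction_embedding",
    "neighbor_embedding",
    "build_pair_vector",
    "decode",
    "init_decoder_params",
    "WMAGTModel",
    "predict_matrix",
]

_NORM_EPS = 1e-12


@dataclass
class DecoderConfig:
    hidden_dims: tuple[int, ...] = (64, 32)

    def __post_init__(self):
        if any(d <= 0 for d in self.hidden_dims):
            raise ValueError("decoder hidden dims must be positive")


@dataclass
class ModelConfig:
    """Full model configuration (encoder + NCF + decoder + ablations)."""

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    interaction_dim: int = 64
    neighbor_dim: int = 32
    duplicate_interaction: bool = True
    use_transformer: bool = True   # False = 'w/o Transformer' ablation
    use_ncf: bool = True           # False = 'w/o NCF' ablation


@dataclass
class PairBatch:
    """Aligned (drug index, disease index, label) triples."""

    drug_indices: np.ndarray
    disease_indices: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.drug_indices = np.asarray(self.drug_indices, dtype=np.intp)
        self.disease_indices = np.asarray(self.disease_indices, dtype=np.intp)
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if not (len(self.drug_indices) == len(self.disease_indices)
                == len(self.labels)):
            raise ValueError("pair batch fields must have equal lengths")

    def __len__(self):
        return len(self.labels)


@dataclass
class PairVector:
    """The assembled NCF input for one pair (kept for introspection)."""

    interaction: np.ndarray
    drug_neighbor: np.ndarray
    disease_neighbor: np.ndarray
    concatenated: np.ndarray


# -- NCF building blocks ----------------------------------------------------

def project_pair(drug_embeddings, disease_embeddings, proj_drug, proj_disease):
    """Linear maps of both embedding matrices into a common interaction space."""
    y1 = as_tensor(drug_embeddings) @ as_tensor(proj_drug)
    y2 = as_tensor(disease_embeddings) @ as_tensor(proj_disease)
    if y1.shape[1] != y2.shape[1]:
        raise ValueError(
            f"projected dims differ: {y1.shape[1]} vs {y2.shape[1]}"
        )
    return y1, y2


def _l2_normalize_rows(x: Tensor) -> Tensor:
    sumsq = tsum(x**2, axis=1, keepdims=True)
    denom = clamp(sumsq, lo=_NORM_EPS**2) ** 0.5
    return x / denom


def interaction_embedding(projected_drug, projected_disease):
    """Element-wise product of the pair, L2-normalized per row.

    Accepts single vectors or aligned batches; an all-zero product returns
    the zero vector (guarded normalization).
    """
    single = (not isinstance(projected_drug, Tensor)
              and np.asarray(projected_drug).ndim == 1)
    d = as_tensor(np.atleast_2d(projected_drug)
                  if not isinstance(projected_drug, Tensor) else projected_drug)
    e = as_tensor(np.atleast_2d(projected_disease)
                  if not isinstance(projected_disease, Tensor) else projected_disease)
    if d.shape != e.shape:
        raise ValueError(f"pair shapes differ: {d.shape} vs {e.shape}")
    out = _l2_normalize_rows(d * e)
    if single:
        return out.data[0]
    return out


def neighbor_weight_matrix(graph: SimilarityGraph) -> np.ndarray:
    """Row-stochastic weights for the similarity-weighted neighbour mean."""
    W = graph.sparse_adjacency.copy()
    return W / W.sum(axis=1, keepdims=True)


def neighbor_embedding(node_index: int, embeddings, graph: SimilarityGraph,
                       neighbor_proj, bias=None) -> np.ndarray:
    """Similarity-weighted mean over the node's extended k-NN set, projected.

    Single-node convenience form; the model computes all nodes at once with
    `neighbor_weight_matrix`.
    """
    vectors = embeddings.vectors if isinstance(embeddings, NodeEmbeddings) \
        else np.asarray(embeddings)
    weights = neighbor_weight_matrix(graph)[node_index]
    agg = weights @ vectors
    out = weighted_projection(Tensor(agg[None, :]), neighbor_proj, None, bias)
    return out.data[0]


def build_pair_vector(interaction, drug_neighbor, disease_neighbor,
                      duplicate_interaction: bool = True):
    """Concatenate (interaction [, interaction], drug_nb, disease_nb).

    The interaction block appears twice by default, matching the published
    pair-vector layout.
    """
    if isinstance(interaction, Tensor):
        blocks = [interaction]
        if duplicate_interaction:
            blocks.append(interaction)
        blocks += [as_tensor(drug_neighbor), as_tensor(disease_neighbor)]
        return concat(blocks, axis=1)
    interaction = np.asarray(interaction, dtype=np.float64)
    parts = [interaction, interaction] if duplicate_interaction else [interaction]
    parts += [np.asarray(drug_neighbor, dtype=np.float64),
              np.asarray(disease_neighbor, dtype=np.float64)]
    cat = np.concatenate(parts)
    return PairVector(interaction=interaction,
                      drug_neighbor=np.asarray(drug_neighbor, dtype=np.float64),
                      disease_neighbor=np.asarray(disease_neighbor, dtype=np.float64),
                      concatenated=cat)


def init_decoder_params(rng: np.random.Generator, input_dim: int,
                        config: DecoderConfig,
                        prior: float | None = None) -> list[tuple[Tensor, Tensor]]:
    """MLP parameters; the output bias starts at logit(prior) if given.

    Prior-probability initialization of the final bias is the standard
    companion of the focal loss under heavy class imbalance: the model
    starts at the base rate instead of 0.5, so early epochs are not spent
    relearning the marginal.
    """
    dims = [input_dim, *config.hidden_dims, 1]
    layers = []
    for a, b in zip(dims[:-1], dims[1:]):
        layers.append((glorot(rng, (a, b)), Tensor(np.zeros(b), requires_grad=True)))
    if prior is not None:
        prior = min(max(prior, 1e-6), 1 - 1e-6)
        layers[-1][1].data[:] = np.log(prior / (1.0 - prior))
    return layers


def decode(pair_vectors, decoder_params) -> Tensor:
    """MLP with ReLU hidden layers and a sigmoid output in (0, 1)."""
    x = as_tensor(pair_vectors)
    if x.ndim == 1:
        x = as_tensor(x.data[None, :])
    if x.shape[1] != decoder_params[0][0].shape[0]:
        raise ValueError(
            f"pair vector length {x.shape[1]} does not match decoder input "
            f"{decoder_params[0][0].shape[0]}"
        )
    for w, b in decoder_params[:-1]:
        x = relu(x @ w + b)
    w, b = decoder_params[-1]
    return sigmoid(x @ w + b)


# -- full model -------------------------------------------------------------

class WMAGTModel:
    """Encoders + NCF + decoder over one heterogeneous bundle.

    All parameters live in plain autodiff tensors; `param_list` feeds the
    optimizer.  Prediction (no dropout) is fully deterministic.
    """

    def __init__(self, bundle: HeteroBundle, config: ModelConfig,
                 rng: np.random.Generator):
        self.bundle = bundle
        self.config = config
        enc_cfg = config.encoder
        if not config.use_transformer:
            enc_cfg = EncoderConfig(**{**enc_cfg.__dict__, "lambda_mix": 0.0})
        self.encoder_config = enc_cfg

        n = bundle.association.n_drugs
        m = bundle.association.n_diseases
        d = enc_cfg.embed_dim
        self.drug_enc = init_encoder_params(rng, n, enc_cfg)
        self.disease_enc = init_encoder_params(rng, m, enc_cfg)
        self._nb_w_drug = neighbor_weight_matrix(bundle.drug_graph)
        self._nb_w_disease = neighbor_weight_matrix(bundle.disease_graph)

        if config.use_ncf:
            self.proj_drug = glorot(rng, (d, config.interaction_dim))
            self.proj_disease = glorot(rng, (d, config.interaction_dim))
            self.nb_proj_drug = glorot(rng, (d, config.neighbor_dim))
            self.nb_bias_drug = Tensor(np.zeros(config.neighbor_dim),
                                       requires_grad=True)
            self.nb_proj_disease = glorot(rng, (d, config.neighbor_dim))
            self.nb_bias_disease = Tensor(np.zeros(config.neighbor_dim),
                                          requires_grad=True)
            n_int = 2 if config.duplicate_interaction else 1
            dec_in = n_int * config.interaction_dim + 2 * config.neighbor_dim
        else:
            dec_in = 2 * d
        base_rate = bundle.association.values.mean()
        self.decoder = init_decoder_params(rng, dec_in, config.decoder,
                                           prior=float(base_rate))

    def param_list(self) -> list[Tensor]:
        params = encoder_param_list(self.drug_enc)
        params += encoder_param_list(self.disease_enc)
        if self.config.use_ncf:
            params += [self.proj_drug, self.proj_disease,
                       self.nb_proj_drug, self.nb_bias_drug,
                       self.nb_proj_disease, self.nb_bias_disease]
        for w, b in self.decoder:
            params += [w, b]
        return params

    # -- forward ------------------------------------------------------------
    def encode(self, training: bool = False,
               rng: np.random.Generator | None = None) -> tuple[Tensor, Tensor]:
        drug = encode_nodes(self.bundle.drug_graph,
                            self.bundle.normalized_drug_adj,
                            self.drug_enc, self.encoder_config,
                            training=training, rng=rng)
        disease = encode_nodes(self.bundle.disease_graph,
                               self.bundle.normalized_disease_adj,
                               self.disease_enc, self.encoder_config,
                               training=training, rng=rng)
        return drug, disease

    def forward_pairs(self, drug_idx, disease_idx, training: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Scores for aligned index lists; returns a (batch, 1) tensor."""
        drug_emb, disease_emb = self.encode(training=training, rng=rng)
        if not self.config.use_ncf:
            d_rows = take_rows(drug_emb, drug_idx)
            e_rows = take_rows(disease_emb, disease_idx)
            return decode(concat([d_rows, e_rows], axis=1), self.decoder)
        y1, y2 = project_pair(drug_emb, disease_emb,
                              self.proj_drug, self.proj_disease)
        inter = interaction_embedding(take_rows(y1, drug_idx),
                                      take_rows(y2, disease_idx))
        nb_drug_all = weighted_projection(
            Tensor(self._nb_w_drug) @ drug_emb,
            self.nb_proj_drug, None, self.nb_bias_drug)
        nb_dis_all = weighted_projection(
            Tensor(self._nb_w_disease) @ disease_emb,
            self.nb_proj_disease, None, self.nb_bias_disease)
        pair_vec = build_pair_vector(
            inter,
            take_rows(nb_drug_all, drug_idx),
            take_rows(nb_dis_all, disease_idx),
            duplicate_interaction=self.config.duplicate_interaction,
        )
        return decode(pair_vec, self.decoder)

    def predict_matrix(self) -> np.ndarray:
        """Deterministic n x m score matrix over all pairs (eval mode)."""
        n = self.bundle.association.n_drugs
        m = self.bundle.association.n_diseases
        drug_idx = np.repeat(np.arange(n), m)
        disease_idx = np.tile(np.arange(m), n)
        scores = self.forward_pairs(drug_idx, disease_idx, training=False)
        return scores.data.reshape(n, m)


def predict_matrix(model: WMAGTModel, bundle: HeteroBundle | None = None) -> np.ndarray:
    """Score every (drug, disease) pair of the bundle with the model."""
    if bundle is not None and bundle is not model.bundle:
        model = _rebind(model, bundle)
    return model.predict_matrix()


def _rebind(model: WMAGTModel, bundle: HeteroBundle) -> WMAGTModel:
    # Same side networks are required: only labels may differ between bundles.
    clone = object.__new__(WMAGTModel)
    clone.__dict__ = {**model.__dict__, "bundle": bundle}
    return clone
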