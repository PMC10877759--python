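"""Heterogeneous information graph assembly for drug-disease link prediction.

The prediction task is framed on three networks: a binary drug-disease
association network (an n x m matrix A), a drug-drug similarity network
(n x n, values in [0, 1]) and a disease-disease similarity network
(m x m).  Dense similarity matrices are sparsified to each node's extended
k-nearest-neighbour set (the node itself plus its k most similar
neighbours) and the resulting weighted adjacencies are symmetrically
normalized with self-loops, D^{-1/2} (A + I) D^{-1/2}, for spectral
propagation in the encoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AssociationMatrix",
    "SimilarityGraph",
    "HeteroBundle",
    "load_association_matrix",
    "load_similarity_matrix",
    "knn_sparsify",
    "normalize_adjacency",
    "build_hetero_bundle",
    "write_dense_matrix",
    "write_triples",
]

_SYM_TOL = 1e-8


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class AssociationMatrix:
    """Binary drug-disease association matrix with identifier lists."""

    values: np.ndarray
    drug_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        bad = (self.values != 0) & (self.values != 1)
        if bad.any():
            r, d = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"non-binary entry at ({self.drug_ids[r]}, {self.disease_ids[d]}): "
                f"{self.values[r, d]!r}"
            )
        self.values = self.values.astype(np.int8)
        if self.values.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise ValueError(
                f"association shape {self.values.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.disease_ids)} diseases"
            )
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.disease_ids, "disease")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())


@dataclass
class SimilarityGraph:
    """Symmetric similarity matrix plus its extended k-NN sparsification.

    ``knn_sets[i]`` is the extended neighbour set of node i: the node itself
    and its k most similar other nodes (ties broken by lower index).
    ``sparse_adjacency`` keeps the original similarity weight on edge (i, j)
    whenever j is in the set of i or i is in the set of j (union
    symmetrization), with diagonal 1 for the self-member.
    """

    values: np.ndarray
    node_ids: list[str]
    k: int
    knn_sets: list[np.ndarray] = field(default_factory=list)
    sparse_adjacency: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def neighbor_mask(self) -> np.ndarray:
        """Boolean n x n mask of the symmetrized extended k-NN edge set."""
        return self.sparse_adjacency > 0


@dataclass
class HeteroBundle:
    """The assembled heterogeneous graph: associations + both side networks."""

    association: AssociationMatrix
    drug_graph: SimilarityGraph
    disease_graph: SimilarityGraph
    normalized_drug_adj: np.ndarray
    normalized_disease_adj: np.ndarray

    def with_association(self, association: AssociationMatrix) -> "HeteroBundle":
        """Same side networks, different labels (used for fold masking)."""
        return HeteroBundle(
            association=association,
            drug_graph=self.drug_graph,
            disease_graph=self.disease_graph,
            normalized_drug_adj=self.normalized_drug_adj,
            normalized_disease_adj=self.normalized_disease_adj,
        )


# -- IO ---------------------------------------------------------------------

def load_association_matrix(path, fmt: str = "dense") -> AssociationMatrix:
    """Load an association matrix from a labeled dense table or sparse triples.

    Parameters
    ----------
    path : file path
    fmt : "dense" (TSV/CSV, first row = disease ids, first column = drug ids)
        or "triples" (3 columns: drug_id, disease_id, value; missing pairs
        are 0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if fmt in ("dense", "dense-table"):
        df = pd.read_csv(path, sep=sep, index_col=0)
        return AssociationMatrix(
            values=df.to_numpy(),
            drug_ids=[str(i) for i in df.index],
            disease_ids=[str(c) for c in df.columns],
        )
    if fmt in ("triples", "sparse-triples"):
        df = pd.read_csv(path, sep=sep, header=None,
                         names=["drug_id", "disease_id", "value"])
        drug_ids = sorted(df["drug_id"].astype(str).unique())
        disease_ids = sorted(df["disease_id"].astype(str).unique())
        ri = {d: i for i, d in enumerate(drug_ids)}
        ci = {d: i for i, d in enumerate(disease_ids)}
        values = np.zeros((len(drug_ids), len(disease_ids)))
        for _, row in df.iterrows():
            values[ri[str(row["drug_id"])], ci[str(row["disease_id"])]] = row["value"]
        return AssociationMatrix(values, drug_ids, disease_ids)
    raise ValueError(f"unknown format {fmt!r}; expected 'dense' or 'triples'")


def load_similarity_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Load a labeled square similarity matrix; returns (values, node_ids)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"similarity matrix {path} row/column ids differ")
    return df.to_numpy(dtype=np.float64), [str(i) for i in df.index]


def write_dense_matrix(path, values, row_ids, col_ids) -> None:
    """Write a labeled dense matrix as TSV at 6 significant digits."""
    df = pd.DataFrame(np.asarray(values), index=row_ids, columns=col_ids)
    df.to_csv(path, sep="\t", float_format="%.6g")


def write_triples(path, association: AssociationMatrix) -> None:
    rows, cols = np.nonzero(association.values)
    with open(path, "w") as fh:
        for r, c in zip(rows, cols):
            fh.write(f"{association.drug_ids[r]}\t{association.disease_ids[c]}\t1\n")


# -- graph construction -----------------------------------------------------

def knn_sparsify(similarity: np.ndarray, node_ids: list[str], k: int) -> SimilarityGraph:
    """Sparsify a dense similarity matrix to extended k-NN neighbourhoods.

    Each node keeps itself plus its ``min(k, n-1)`` most similar other nodes;
    similarity ties are broken by lower node index.  The edge set is the
    symmetrized union and every kept edge carries the original weight.
    """
    S = np.asarray(similarity, dtype=np.float64)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError(f"similarity matrix must be square, got {S.shape}")
    if not np.allclose(S, S.T, atol=_SYM_TOL):
        raise ValueError("similarity matrix is not symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=_SYM_TOL):
        raise ValueError("similarity matrix diagonal must be 1")
    if k < 0:
        raise ValueError("k must be non-negative")
    k_eff = min(k, n - 1)

    knn_sets: list[np.ndarray] = []
    keep = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = np.lexsort((np.arange(n), -S[i]))  # descending sim, then index
        order = order[order != i][:k_eff]
        members = np.sort(np.concatenate(([i], order)))
        knn_sets.append(members.astype(np.intp))
        keep[i, members] = True
    keep |= keep.T  # union symmetrization
    sparse = np.where(keep, S, 0.0)
    return SimilarityGraph(values=S, node_ids=list(node_ids), k=k,
                           knn_sets=knn_sets, sparse_adjacency=sparse)


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^{-1/2} (A + I) D^{-1/2}."""
    A = np.asarray(adjacency, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    if (A < 0).any():
        raise ValueError("adjacency must be non-negative")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


def build_hetero_bundle(
    association: AssociationMatrix,
    drug_similarity: np.ndarray,
    disease_similarity: np.ndarray,
    k: int = 15,
    binarize: bool = False,
) -> HeteroBundle:
    """Assemble the heterogeneous graph from its three matrices.

    ``binarize`` replaces kept k-NN edge weights with 1 before
    normalization (the weighted form is the default).
    """
    drug_similarity = np.asarray(drug_similarity, dtype=np.float64)
    disease_similarity = np.asarray(disease_similarity, dtype=np.float64)
    n, m = association.values.shape
    if drug_similarity.shape != (n, n):
        raise ValueError(
            f"drug similarity is {drug_similarity.shape}, expected ({n}, {n}) "
            "to match the association rows"
        )
    if disease_similarity.shape != (m, m):
        raise ValueError(
            f"disease similarity is {disease_similarity.shape}, expected "
            f"({m}, {m}) to match the association columns"
        )
    drug_graph = knn_sparsify(drug_similarity, association.drug_ids, k)
    disease_graph = knn_sparsify(disease_similarity, association.disease_ids, k)

    def _norm(graph: SimilarityGraph) -> np.ndarray:
        W = graph.sparse_adjacency.copy()
        np.fill_diagonal(W, 0.0)  # normalize_adjacency adds the self-loop
        if binarize:
            W = (W > 0).astype(np.float64)
        return normalize_adjacency(W)

    return HeteroBundle(
        association=association,
        drug_graph=drug_graph,
        disease_graph=disease_graph,
        normalized_drug_adj=_norm(drug_graph),
        normalized_disease_adj=_norm(disease_graph),
    )
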