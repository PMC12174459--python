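"""Patient-similarity networks from cosine similarity.

Each omics view induces a weighted graph whose nodes are samples and whose
edge weights are cosine similarities between the samples' (normalized)
feature vectors.  Because the method's attention layers only need a
neighborhood structure, the dense similarity matrix is sparsified to a target
mean degree: the global threshold tau is the k-th largest off-diagonal pair
similarity with k = round(avg_degree * n / 2), and every pair with
similarity >= tau keeps its edge.  Self-loops of weight 1 are always present
so each node attends at least to itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .io import OmicsView

__all__ = ["PatientGraph", "cosine_similarity_matrix", "sparsify",
           "build_graph", "write_edge_list", "attach_new_samples"]


@dataclass
class PatientGraph:
    """Symmetric nonnegative adjacency over samples for one view.

    Off-diagonal entries are either 0 (no edge) or the cosine similarity of
    the two samples; the diagonal is 1.  ``tau`` is the sparsification
    threshold actually used (needed to attach new samples inductively).
    """

    sample_ids: list[str]
    adjacency: np.ndarray
    view_name: str
    tau: float = -np.inf

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=np.float64)
        if A.shape != (len(self.sample_ids),) * 2:
            raise ValueError("adjacency shape does not match sample count")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if not np.allclose(np.diag(A), 1.0):
            raise ValueError("diagonal self-loops must equal 1")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return len(self.sample_ids)

    @property
    def neighbor_mask(self) -> np.ndarray:
        """Boolean neighborhoods (entries > 0); includes the self-loop."""
        return self.adjacency > 0


def cosine_similarity_matrix(view: OmicsView | np.ndarray) -> np.ndarray:
    """S_ij = <x_i, x_j> / (|x_i| |x_j|); zero rows get similarity 0."""
    X = view.values if isinstance(view, OmicsView) else np.asarray(view, float)
    S = _sk_cosine(X)
    S = (S + S.T) / 2.0  # exact symmetry against rounding
    nonzero = np.linalg.norm(X, axis=1) > 0
    np.fill_diagonal(S, np.where(nonzero, 1.0, 0.0))
    return S


def sparsify(S: np.ndarray, avg_degree: float, sample_ids=None,
             view_name: str = "") -> PatientGraph:
    """Keep the strongest pairs so the mean off-diagonal degree ~ avg_degree.

    k = round(avg_degree * n / 2) clipped to [1, n(n-1)/2]; tau is the k-th
    largest off-diagonal pair similarity and every pair with S_ij >= tau is
    kept (ties at tau are all retained).  The diagonal is set to 1.
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    if n < 2:
        raise ValueError("sparsify needs at least 2 nodes")
    if not np.allclose(S, S.T):
        raise ValueError("similarity matrix must be symmetric")
    iu = np.triu_indices(n, k=1)
    pair_vals = S[iu]
    k = int(round(avg_degree * n / 2.0))
    k = min(max(k, 1), pair_vals.size)
    tau = float(np.sort(pair_vals)[::-1][k - 1])
    A = np.where(S >= tau, S, 0.0)
    np.fill_diagonal(A, 1.0)
    ids = list(sample_ids) if sample_ids is not None else \
        [str(i) for i in range(n)]
    return PatientGraph(ids, A, view_name, tau=tau)


def build_graph(view: OmicsView, avg_degree: float = 10.0) -> PatientGraph:
    S = cosine_similarity_matrix(view)
    return sparsify(S, avg_degree, sample_ids=view.sample_ids,
                    view_name=view.view_name)


def write_edge_list(graph: PatientGraph, path) -> None:
    """Dump kept edges (i, j, weight) as a 3-column TSV, i < j plus loops."""
    with open(path, "w") as fh:
        fh.write("sample_i\tsample_j\tweight\n")
        A = graph.adjacency
        for i in range(graph.n_nodes):
            fh.write(f"{graph.sample_ids[i]}\t{graph.sample_ids[i]}\t1\n")
            for j in range(i + 1, graph.n_nodes):
                if A[i, j] > 0:
                    fh.write(f"{graph.sample_ids[i]}\t{graph.sample_ids[j]}"
                             f"\t{A[i, j]:.10g}\n")


def attach_new_samples(train_graph: PatientGraph, train_values: np.ndarray,
                       new_values: np.ndarray,
                       new_ids: list[str]) -> PatientGraph:
    """Inductive attachment: connect new samples to *training* nodes only.

    New samples get edges to every training node whose cosine similarity
    reaches the graph's fitted threshold tau; the training block is reused
    unchanged, no retraining or full-graph reconstruction is needed.
    New-new pairs are never connected (their labels are unknown and the
    trained attention never saw such edges).
    """
    nt = train_graph.n_nodes
    nn_ = new_values.shape[0]
    X = np.vstack([train_values, new_values])
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = X / norms
    cross = U[nt:] @ U[:nt].T  # new x train similarities
    A = np.zeros((nt + nn_, nt + nn_))
    A[:nt, :nt] = train_graph.adjacency
    keep = cross >= train_graph.tau
    A[nt:, :nt] = np.where(keep, cross, 0.0)
    A[:nt, nt:] = A[nt:, :nt].T
    np.fill_diagonal(A, 1.0)
    return PatientGraph(train_graph.sample_ids + list(new_ids), A,
                        train_graph.view_name, tau=train_graph.tau)
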