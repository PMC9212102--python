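"""Per-subject weighted graph encoding of a connectivity matrix.

Each brain region is a node whose feature vector is its row of the Fisher-z
connectivity matrix (its connectivity profile to all regions). Edges come
from a K-nearest-neighbor rule on Euclidean distance between node features,
symmetrized by union, with a Gaussian kernel weight by default. Graph
convolution consumes the renormalized adjacency
W_hat = D~^{-1/2} (W + I) D~^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .connectome import ConnectivityMatrix


@dataclass
class SubjectGraph:
    """G = (V, E, W) for one subject plus the normalized operator."""

    subject_id: str
    features: np.ndarray  # (a, a) node features = z-matrix rows
    adjacency: np.ndarray  # (a, a) symmetric, nonnegative, zero diagonal
    normalized: np.ndarray  # D~^{-1/2} (W+I) D~^{-1/2}
    label: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]


def knn_adjacency(
    X: np.ndarray, k: int = 10, weighting: str = "gaussian"
) -> np.ndarray:
    """Weighted KNN adjacency from Euclidean distances between feature rows.

    Each node connects to its k nearest neighbors (ties broken toward the
    lower region index); the directed neighbor lists are symmetrized by
    union, W_ij = max(w_ij, w_ji). Gaussian weights use
    w_ij = exp(-d_ij^2 / (2 sigma^2)) with sigma the mean of all selected
    (pre-symmetrization) distances; binary weights are 1.
    """
    X = np.asarray(X, dtype=float)
    a = X.shape[0]
    if not 1 <= k <= a - 1:
        raise ValueError(f"k={k} out of range [1, {a - 1}]")
    if weighting not in ("gaussian", "binary"):
        raise ValueError(f"unknown weighting {weighting!r}")
    d = squareform(pdist(X))
    np.fill_diagonal(d, np.inf)
    # stable argsort on distances -> ties resolved toward lower index
    order = np.argsort(d, axis=1, kind="stable")
    neighbors = order[:, :k]
    rows = np.repeat(np.arange(a), k)
    cols = neighbors.ravel()
    sel = np.zeros((a, a), dtype=bool)
    sel[rows, cols] = True
    if weighting == "binary":
        w_dir = sel.astype(float)
    else:
        sigma = d[rows, cols].mean()
        w_dir = np.where(sel, np.exp(-(d**2) / (2.0 * sigma**2)), 0.0)
    W = np.maximum(w_dir, w_dir.T)
    np.fill_diagonal(W, 0.0)
    return W


def normalize_adjacency(W: np.ndarray) -> np.ndarray:
    """Renormalization trick: D~^{-1/2} (W + I) D~^{-1/2}; spectrum in [-1, 1]."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if np.max(np.abs(W - W.T)) > 1e-10:
        raise ValueError("adjacency must be symmetric")
    if np.any(W < 0):
        raise ValueError("adjacency weights must be nonnegative")
    Wt = W + np.eye(W.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(Wt.sum(axis=1))
    return Wt * np.outer(d_inv_sqrt, d_inv_sqrt)


def build_graph(
    matrix: ConnectivityMatrix,
    k: int = 10,
    weighting: str = "gaussian",
    label: str | None = None,
) -> SubjectGraph:
    X = matrix.values
    W = knn_adjacency(X, k=k, weighting=weighting)
    return SubjectGraph(
        subject_id=matrix.subject_id,
        features=X,
        adjacency=W,
        normalized=normalize_adjacency(W),
        label=label,
    )


def build_cohort_graphs(
    matrices: list[ConnectivityMatrix],
    k: int = 10,
    weighting: str = "gaussian",
    labels: list[str] | None = None,
) -> list[SubjectGraph]:
    """One SubjectGraph per matrix; all subjects must share region labels."""
    if not matrices:
        raise ValueError("no matrices given")
    ref = matrices[0].region_labels
    for m in matrices[1:]:
        if m.region_labels != ref:
            raise ValueError(
                f"subject {m.subject_id}: region labels differ from cohort"
            )
    if labels is None:
        labels = [None] * len(matrices)
    return [
        build_graph(m, k=k, weighting=weighting, label=lab)
        for m, lab in zip(matrices, labels)
    ]


def dump_edge_list(graph: SubjectGraph, path) -> None:
    """Inspection dump: TSV of (i, j, weight) for the upper triangle."""
    iu = np.triu_indices(graph.n_nodes, k=1)
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in zip(*iu):
            w = graph.adjacency[i, j]
            if w > 0:
                fh.write(f"{i}\t{j}\t{w:.10g}\n")
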