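"""Nodal network topology of salient regions and clinical correlations.

Thresholded weighted networks keep only the strongest positive Fisher-z
edges (path-length semantics require nonnegative weights). Path-based
centralities use edge length = 1/weight, so stronger connections are
shorter:

* degree — sum of incident edge weights (strength; neighbor count when
  binary),
* nodal efficiency — mean inverse shortest-path length to every other node
  (unreachable nodes contribute 0),
* betweenness — number of shortest paths between other node pairs passing
  through the node (fractional on ties, each unordered pair counted once).

Group differences use a label-permutation test on the difference of group
means; symptom scores from heterogeneous clinical scales are standardized to
Percent of Maximum Possible (POMP) before Pearson correlation, with BH-FDR
over the regions x metrics (x symptom dimension) family.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .harmonize import AnalysisError, bh_fdr

METRICS = ("degree", "efficiency", "betweenness")


class DegenerateNetworkError(ValueError):
    """The thresholded network has no positive edges."""


def threshold_network(z_matrix: np.ndarray, sparsity: float = 0.20) -> np.ndarray:
    """Keep the top ``sparsity`` fraction of positive edges by weight.

    The target count is round(sparsity * a(a-1)/2); negative edges are never
    retained, and if fewer positive edges exist than the target, all positive
    edges are kept. Output is symmetric with zero diagonal.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    z = np.asarray(z_matrix, dtype=float)
    a = z.shape[0]
    iu = np.triu_indices(a, k=1)
    vals = z[iu]
    pos = np.flatnonzero(vals > 0)
    if pos.size == 0:
        raise DegenerateNetworkError("no positive edges to retain")
    target = int(round(sparsity * vals.size))
    keep = pos[np.argsort(-vals[pos], kind="stable")[:target]]
    out = np.zeros_like(z)
    out[iu[0][keep], iu[1][keep]] = vals[keep]
    return out + out.T


def _length_matrix(W: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def _shortest_paths(W: np.ndarray) -> np.ndarray:
    L = _length_matrix(W)
    finite = np.where(np.isfinite(L), L, 0.0)
    mask = np.isfinite(L) & (L > 0)
    return shortest_path(np.where(mask, finite, 0.0), method="D", directed=False)


def nodal_degree(W: np.ndarray, node: int | None = None):
    """Weighted degree (strength): sum of incident edge weights."""
    W = np.asarray(W, dtype=float)
    deg = W.sum(axis=1)
    return deg if node is None else float(deg[node])


def nodal_efficiency(W: np.ndarray, node: int | None = None):
    """E(i) = mean over j != i of 1/d_ij with d from 1/weight edge lengths."""
    W = np.asarray(W, dtype=float)
    d = _shortest_paths(W)
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    eff = inv.sum(axis=1) / (W.shape[0] - 1)
    return eff if node is None else float(eff[node])


def nodal_betweenness(W: np.ndarray, node: int | None = None):
    """Shortest-path betweenness under 1/weight edge lengths.

    Unordered source-target pairs are counted once (so the middle node of a
    3-node path scores 1); shortest-path ties contribute fractionally.
    """
    W = np.asarray(W, dtype=float)
    a = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(a))
    ii, jj = np.nonzero(np.triu(W, k=1))
    G.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / W[i, j]) for i, j in zip(ii, jj)), weight="length"
    )
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    vals = np.array([bc[i] for i in range(a)])
    return vals if node is None else float(vals[node])


def nodal_metrics(W: np.ndarray) -> dict[str, np.ndarray]:
    """All three centralities for every node of one thresholded network."""
    return {
        "degree": nodal_degree(W),
        "efficiency": nodal_efficiency(W),
        "betweenness": nodal_betweenness(W),
    }


def cohort_nodal_metrics(
    z_matrices: list[np.ndarray],
    subject_ids: list[str],
    sparsity: float = 0.20,
    regions: list[int] | None = None,
    region_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Long-format NodalMetricTable for selected regions of every subject."""
    rows = []
    for sid, z in zip(subject_ids, z_matrices):
        W = threshold_network(np.asarray(z), sparsity=sparsity)
        m = nodal_metrics(W)
        sel = regions if regions is not None else range(W.shape[0])
        for r in sel:
            name = region_labels[r] if region_labels else f"region_{r:03d}"
            for metric in METRICS:
                rows.append(
                    {
                        "subject_id": sid,
                        "region_index": r,
                        "region": name,
                        "metric": metric,
                        "value": m[metric][r],
                        "sparsity": sparsity,
                    }
                )
    return pd.DataFrame(rows)


def permutation_group_test(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    q: float = 0.05,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Two-tailed permutation test on the difference of group means.

    ``values`` is (n_subjects,) or (n_subjects, n_tests); the statistic is
    mean(group1) - mean(group0) per column, the null is built by permuting
    labels (the same permutations across columns), and
    p = (1 + #{|perm| >= |obs|}) / (n_perm + 1). BH-FDR flags are computed
    across all columns.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse p-value grid", UserWarning, stacklevel=2
        )
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise AnalysisError(f"need exactly 2 groups, got {groups.size}")
    g1 = labels == groups[1]
    n1, n0 = int(g1.sum()), int((~g1).sum())
    if min(n0, n1) < 2:
        raise AnalysisError("each group needs >= 2 subjects")
    obs = X[g1].mean(axis=0) - X[~g1].mean(axis=0)

    rng = np.random.default_rng([23, seed])
    n = X.shape[0]
    count = np.zeros(X.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pg1 = perm[:n1]
        pg0 = perm[n1:]
        stat = X[pg1].mean(axis=0) - X[pg0].mean(axis=0)
        count += np.abs(stat) >= np.abs(obs) - 1e-12
    p = (1.0 + count) / (n_perm + 1.0)
    df = pd.DataFrame(
        {
            "name": names if names is not None else np.arange(X.shape[1]),
            "diff": obs,
            "p": p,
            "fdr_significant": bh_fdr(p, q),
        }
    )
    df.attrs["groups"] = (str(groups[0]), str(groups[1]))
    return df


def pomp(raw, scale_min: float, scale_max: float):
    """Percent of Maximum Possible: 100 * (raw - min) / (max - min)."""
    if scale_max <= scale_min:
        raise ValueError("scale_max must exceed scale_min")
    raw = np.asarray(raw, dtype=float)
    if np.any((raw < scale_min) | (raw > scale_max)):
        raise ValueError("raw score outside declared scale bounds")
    out = 100.0 * (raw - scale_min) / (scale_max - scale_min)
    return float(out) if out.ndim == 0 else out


def correlate_symptoms(
    metric_values: np.ndarray,
    pomp_scores: np.ndarray,
    q: float = 0.05,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each metric column with POMP symptom scores.

    Only complete cases (finite score and metric) enter; fewer than 4 pairs
    is an error. BH-FDR across the columns supplied (the caller builds the
    regions x metrics x symptom-dimension family).
    """
    X = np.asarray(metric_values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    s = np.asarray(pomp_scores, dtype=float)
    rs, ps = [], []
    for col in range(X.shape[1]):
        ok = np.isfinite(s) & np.isfinite(X[:, col])
        if ok.sum() < 4:
            raise AnalysisError(
                f"column {col}: only {int(ok.sum())} complete pairs (< 4)"
            )
        if np.std(X[ok, col]) == 0 or np.std(s[ok]) == 0:
            rs.append(0.0)
            ps.append(1.0)
            continue
        r, p = stats.pearsonr(X[ok, col], s[ok])
        rs.append(float(r))
        ps.append(float(p))
    ps = np.array(ps)
    return pd.DataFrame(
        {
            "name": names if names is not None else np.arange(X.shape[1]),
            "r": rs,
            "p": ps,
            "fdr_significant": bh_fdr(ps, q),
        }
    )
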