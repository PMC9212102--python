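"""Functional-connectivity estimation from ROI time series.

Connectivity between two brain regions is the Pearson correlation of their
BOLD time series; the Fisher r-to-z transform (atanh) stabilizes variance.
Matrices are symmetric with a zero diagonal: self-connectivity carries no
information as a node feature and a zero diagonal keeps KNN distances finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# r is clipped before atanh; perfect correlations would map to +/-inf
R_CLIP = 1.0 - 1e-7


class DegenerateRegionError(ValueError):
    """A region's time series has zero variance."""


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region connectivity for one subject.

    ``values`` holds Pearson r (``is_z=False``) or Fisher-z (``is_z=True``);
    the diagonal is 0 by convention.
    """

    subject_id: str
    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)
    is_z: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if v.shape[0] < 2:
            raise ValueError("need at least 2 regions")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite values")
        if np.max(np.abs(v - v.T)) > 1e-10:
            raise ValueError("connectivity matrix is not symmetric within 1e-10")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v
        if not self.region_labels:
            self.region_labels = [f"region_{i:03d}" for i in range(v.shape[0])]
        if len(self.region_labels) != v.shape[0]:
            raise ValueError("region label count does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def pearson_connectivity(
    ts: np.ndarray, subject_id: str = "", region_labels: list[str] | None = None
) -> ConnectivityMatrix:
    """Pearson correlation between all pairs of regional time series.

    Parameters
    ----------
    ts : array, shape (n_timepoints, n_regions)
        One column per region.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("need a 2-D time-series array with >= 3 timepoints")
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateRegionError(
            f"region(s) {bad.tolist()} have zero-variance time series"
        )
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        subject_id=subject_id, values=r, region_labels=region_labels or [], is_z=False
    )


def fisher_z(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Apply the Fisher r-to-z transform elementwise (off-diagonal).

    r is clipped to +/-(1 - 1e-7) so perfect correlations stay finite.
    Applying the transform to an already-transformed matrix is an error.
    """
    if matrix.is_z:
        raise ValueError("matrix already holds Fisher-z values")
    z = np.arctanh(np.clip(matrix.values, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    return replace(matrix, values=z, is_z=True)


def vectorize_upper(matrix: np.ndarray | ConnectivityMatrix) -> np.ndarray:
    """Row-major strict upper triangle as a 1-D edge vector of length a(a-1)/2.

    This edge ordering is the package-wide convention shared by the ComBat
    and SVM feature tables.
    """
    v = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("expected a square matrix")
    if np.max(np.abs(v - v.T)) > 1e-8:
        raise ValueError("expected a symmetric matrix")
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu].copy()


def devectorize_upper(vector: np.ndarray, n_regions: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: symmetric matrix, zero diagonal."""
    vector = np.asarray(vector, dtype=float)
    expected = n_regions * (n_regions - 1) // 2
    if vector.ndim != 1 or vector.size != expected:
        raise ValueError(
            f"edge vector of length {vector.size} does not match "
            f"{n_regions} regions (expected {expected})"
        )
    m = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=1)
    m[iu] = vector
    return m + m.T


def edge_names(region_labels: list[str]) -> list[str]:
    """Edge names ``edge_<i>_<j>`` in the canonical upper-triangle order."""
    a = len(region_labels)
    iu = np.triu_indices(a, k=1)
    return [f"edge_{i}_{j}" for i, j in zip(*iu)]


def edge_incidence(n_regions: int) -> np.ndarray:
    """(i, j) region indices per edge, canonical order; shape (n_edges, 2)."""
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)


def write_matrix(matrix: ConnectivityMatrix, path) -> None:
    """Write as TSV with a header row of region labels (full precision)."""
    df = pd.DataFrame(
        matrix.values, columns=matrix.region_labels, index=matrix.region_labels
    )
    df.to_csv(path, sep="\t", float_format="%.17g", index=False)


def read_matrix(path, subject_id: str = "", is_z: bool = True) -> ConnectivityMatrix:
    """Read a TSV connectivity matrix written by :func:`write_matrix`."""
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"cannot parse connectivity matrix {path}: {exc}") from exc
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise ValueError(f"non-numeric columns in {path}: {list(bad)}")
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path}: matrix is {values.shape[0]}x{values.shape[1]}, expected square"
        )
    nan = np.argwhere(~np.isfinite(values))
    if nan.size:
        i, j = nan[0]
        raise ValueError(f"{path}: non-finite value at row {i + 1}, column {j + 1}")
    return ConnectivityMatrix(
        subject_id=subject_id,
        values=values,
        region_labels=list(df.columns),
        is_z=is_z,
    )


def stack_edges(matrices: list[ConnectivityMatrix]) -> pd.DataFrame:
    """Cohort edge table: rows = subjects, columns = canonical edge names."""
    if not matrices:
        raise ValueError("no matrices given")
    labels = matrices[0].region_labels
    for m in matrices[1:]:
        if m.region_labels != labels:
            raise ValueError(
                f"region labels of subject {m.subject_id} differ from cohort"
            )
    rows = np.stack([vectorize_upper(m) for m in matrices])
    return pd.DataFrame(
        rows, index=[m.subject_id for m in matrices], columns=edge_names(labels)
    )
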