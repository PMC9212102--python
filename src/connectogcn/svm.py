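"""Linear maximum-margin baseline on upper-triangle edge features.

The regularization constant C is chosen by an inner stratified 10-fold grid
search over {1e-3 ... 1e3} maximizing balanced accuracy, then the model is
refit on the full training set at the chosen C. Edge weights of the fitted
hyperplane are aggregated per brain region (mean over the region's incident
edges) to rank the regions driving the decision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .connectome import edge_incidence

DEFAULT_C_GRID: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)


class NestedLinearSVM(ClassifierMixin, BaseEstimator):
    """Linear SVM with nested cross-validated C selection.

    ``fit`` runs the inner grid search (``inner_folds`` stratified folds,
    balanced accuracy) and refits at the winning C; ``best_C_`` and the
    hyperplane ``coef_`` are exposed for region-weight aggregation.
    """

    def __init__(
        self,
        C_grid: tuple[float, ...] = DEFAULT_C_GRID,
        inner_folds: int = 10,
        seed: int = 0,
    ):
        self.C_grid = C_grid
        self.inner_folds = inner_folds
        self.seed = seed

    def fit(self, X, y):
        if not self.C_grid or any(c <= 0 for c in self.C_grid):
            raise ValueError("C_grid must be nonempty with all C > 0")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training needs at least 2 classes")
        if not np.all(np.isfinite(X)):
            raise ValueError("edge features must be finite")
        inner = StratifiedKFold(
            n_splits=self.inner_folds, shuffle=True, random_state=self.seed
        )
        search = GridSearchCV(
            SVC(kernel="linear"),
            param_grid={"C": list(self.C_grid)},
            scoring="balanced_accuracy",
            cv=inner,
            refit=True,
        )
        search.fit(X, y)
        self.search_ = search
        self.best_C_ = float(search.best_params_["C"])
        self.model_ = search.best_estimator_
        self.classes_ = self.model_.classes_
        self.coef_ = self.model_.coef_.ravel()
        self.intercept_ = float(self.model_.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError("NestedLinearSVM is not fitted")

    def decision_function(self, X):
        self._check_fitted()
        return self.model_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X):
        self._check_fitted()
        return self.model_.predict(np.asarray(X, dtype=float))


def region_weights(
    edge_weights: np.ndarray,
    n_regions: int,
    mode: str = "abs_mean",
    top_k: int = 10,
    region_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate an edge-level weight vector to per-region scores.

    Each region's score is the mean over its ``n_regions - 1`` incident
    edges, of the absolute weights (``abs_mean``, saliency by contribution
    magnitude) or the signed weights (``signed_mean``). ``edge_weights`` may
    be a single hyperplane or a (n_folds, n_edges) stack, in which case
    fold-level region scores are averaged.

    Returns a DataFrame sorted by descending score with a ``rank`` column;
    ``top_k`` only annotates which rows form the reported top list.
    """
    if mode not in ("abs_mean", "signed_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    w = np.atleast_2d(np.asarray(edge_weights, dtype=float))
    n_edges = n_regions * (n_regions - 1) // 2
    if w.shape[1] != n_edges:
        raise ValueError(
            f"weight vector length {w.shape[1]} does not match "
            f"{n_regions} regions ({n_edges} edges)"
        )
    if mode == "abs_mean":
        w = np.abs(w)
    inc = edge_incidence(n_regions)
    scores = np.zeros((w.shape[0], n_regions))
    for r in range(n_regions):
        mask = (inc[:, 0] == r) | (inc[:, 1] == r)
        scores[:, r] = w[:, mask].mean(axis=1)
    mean_scores = scores.mean(axis=0)
    order = np.lexsort((np.arange(n_regions), -mean_scores))
    if region_labels is None:
        region_labels = [f"region_{i:03d}" for i in range(n_regions)]
    return pd.DataFrame(
        {
            "region": [region_labels[i] for i in order],
            "region_index": order,
            "score": mean_scores[order],
            "rank": np.arange(1, n_regions + 1),
            "in_top_k": np.arange(n_regions) < top_k,
        }
    )
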