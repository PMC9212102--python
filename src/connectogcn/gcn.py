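"""Graph convolutional network classifier with exact CAM node saliency.

Architecture: a stack of graph convolutions H^(l+1) = ReLU(W_hat H^(l) Theta^(l))
over the per-subject KNN graph, global average pooling (GAP) over nodes, and
a single linear classification head. Keeping exactly one linear layer after
GAP makes class activation mapping (CAM) an exact decomposition of the
logit: with M_c(v) = sum_k w^c_k H^(L)_{v,k},

    mean_v M_c(v) = logit_c - b_c

so per-node activations attribute the class score to brain regions without
gradient approximation.

The network is implemented directly in NumPy (forward pass, manual
backpropagation, Adam) in single precision with seeded initialization and
shuffling, so training is bit-reproducible on a fixed platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import train_test_split

from .connectome import ConnectivityMatrix
from .graphs import SubjectGraph, build_graph, knn_adjacency, normalize_adjacency

DTYPE = np.float32


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _as_graph_arrays(
    X, k: int, weighting: str
) -> tuple[np.ndarray, np.ndarray]:
    """Coerce input to stacked (A_hat, features) arrays of shape (n, a, ·)."""
    if isinstance(X, np.ndarray) and X.ndim == 3:
        feats = X.astype(DTYPE)
        adj = np.stack(
            [normalize_adjacency(knn_adjacency(x, k=k, weighting=weighting)) for x in X]
        ).astype(DTYPE)
        return adj, feats
    graphs = list(X)
    if graphs and isinstance(graphs[0], ConnectivityMatrix):
        graphs = [build_graph(m, k=k, weighting=weighting) for m in graphs]
    if not (graphs and isinstance(graphs[0], SubjectGraph)):
        raise TypeError(
            "X must be a (n, a, a) array, a list of ConnectivityMatrix, "
            "or a list of SubjectGraph"
        )
    adj = np.stack([g.normalized for g in graphs]).astype(DTYPE)
    feats = np.stack([g.features for g in graphs]).astype(DTYPE)
    return adj, feats


class GCNClassifier(ClassifierMixin, BaseEstimator):
    """Graph-level classifier: conv stack -> GAP -> linear head.

    Parameters
    ----------
    hidden : tuple of int
        Widths of the graph-convolution layers.
    k, weighting : KNN graph construction (used when ``fit`` receives raw
        connectivity matrices rather than prebuilt graphs).
    class_weight : "balanced" weights the cross-entropy by inverse class
        frequency (default, the cohort is imbalanced); None disables.
    patience : early-stopping patience, in epochs, on the loss of an inner
        stratified validation split (``val_fraction`` of the training data);
        the returned model is the best-validation-loss snapshot.
    """

    def __init__(
        self,
        hidden: tuple[int, ...] = (64, 64, 128),
        lr: float = 1e-3,
        weight_decay: float = 5e-4,
        max_epochs: int = 200,
        patience: int = 20,
        val_fraction: float = 0.1,
        batch_size: int = 32,
        class_weight: str | None = "balanced",
        dropout: float = 0.0,
        k: int = 10,
        weighting: str = "gaussian",
        seed: int = 0,
    ):
        self.hidden = hidden
        self.lr = lr
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.dropout = dropout
        self.k = k
        self.weighting = weighting
        self.seed = seed

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        if not self.hidden or any(h < 1 for h in self.hidden):
            raise ValueError("hidden must contain positive layer widths")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training needs at least 2 classes")
        adj, feats = _as_graph_arrays(X, self.k, self.weighting)
        n, a, b = feats.shape

        rng = np.random.default_rng([19, self.seed])
        widths = [b, *self.hidden]
        params = [
            _glorot(rng, widths[i], widths[i + 1]) for i in range(len(self.hidden))
        ]
        head_w = _glorot(rng, self.hidden[-1], self.classes_.size).T
        head_b = np.zeros(self.classes_.size, dtype=DTYPE)

        if self.class_weight == "balanced":
            counts = np.bincount(y_idx, minlength=self.classes_.size)
            cw = n / (self.classes_.size * counts)
        elif self.class_weight is None:
            cw = np.ones(self.classes_.size)
        else:
            raise ValueError(f"unknown class_weight {self.class_weight!r}")
        cw = cw.astype(DTYPE)

        # inner validation split for early stopping (never sees test data)
        use_val = (
            self.patience is not None
            and self.val_fraction > 0
            and np.all(np.bincount(y_idx) >= 2)
            and n * self.val_fraction >= 2
        )
        if use_val:
            tr, va = train_test_split(
                np.arange(n),
                test_size=self.val_fraction,
                stratify=y_idx,
                random_state=int(rng.integers(2**31 - 1)),
            )
        else:
            tr, va = np.arange(n), np.empty(0, dtype=int)

        state = _AdamState([*params, head_w, head_b], lr=self.lr)
        best = {"loss": np.inf, "params": None, "epoch": -1}
        history: list[dict] = []
        wait = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(tr)
            ep_loss = 0.0
            ep_wsum = 0.0
            for start in range(0, order.size, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss, grads = self._loss_and_grads(
                    adj[idx], feats[idx], y_idx[idx], params, head_w, head_b, cw, rng
                )
                state.step([*params, head_w, head_b], grads, self.weight_decay)
                wsum = float(cw[y_idx[idx]].sum())
                ep_loss += loss * wsum
                ep_wsum += wsum
            entry = {"epoch": epoch, "train_loss": ep_loss / max(ep_wsum, 1e-12)}
            if use_val:
                val_loss = self._eval_loss(
                    adj[va], feats[va], y_idx[va], params, head_w, head_b, cw
                )
                entry["val_loss"] = val_loss
                if val_loss < best["loss"] - 1e-7:
                    best.update(
                        loss=val_loss,
                        params=[p.copy() for p in [*params, head_w, head_b]],
                        epoch=epoch,
                    )
                    wait = 0
                else:
                    wait += 1
            history.append(entry)
            if use_val and wait >= self.patience:
                break
        if use_val and best["params"] is not None:
            *params, head_w, head_b = best["params"]

        # canonical zero-sum gauge: softmax is invariant to a common shift of
        # the class weights/biases, so remove it; CAM then measures purely
        # discriminative evidence instead of class-shared activation.
        head_w = head_w - head_w.mean(axis=0)
        head_b = head_b - head_b.mean()

        self.weights_ = params
        self.head_weight_ = head_w
        self.head_bias_ = head_b
        self.history_ = history
        self.n_features_in_ = b
        self.n_nodes_ = a
        return self

    # ------------------------------------------------------- forward passes

    def _forward(
        self,
        adj: np.ndarray,
        feats: np.ndarray,
        params,
        train_rng: np.random.Generator | None = None,
    ):
        """Batched forward; returns (logits, H_L, caches for backprop)."""
        H = feats
        caches = []
        for theta in params:
            HW = H @ theta
            Z = adj @ HW
            mask = None
            Hn = np.maximum(Z, 0.0)
            if train_rng is not None and self.dropout > 0:
                mask = (
                    train_rng.random(Hn.shape) >= self.dropout
                ).astype(DTYPE) / DTYPE(1.0 - self.dropout)
                Hn = Hn * mask
            caches.append((H, Z, mask))
            H = Hn
        pooled = H.mean(axis=1)
        return pooled, H, caches

    def _loss_and_grads(self, adj, feats, y_idx, params, head_w, head_b, cw, rng):
        pooled, H_L, caches = self._forward(
            adj, feats, params, train_rng=rng if self.dropout > 0 else None
        )
        logits = pooled @ head_w.T + head_b
        probs = _softmax(logits.astype(np.float64))
        w = cw[y_idx]
        wsum = w.sum()
        ce = -np.log(np.maximum(probs[np.arange(y_idx.size), y_idx], 1e-12))
        loss = float((w * ce).sum() / wsum)

        dlogits = probs.copy()
        dlogits[np.arange(y_idx.size), y_idx] -= 1.0
        dlogits = (dlogits * (w / wsum)[:, None]).astype(DTYPE)
        d_head_w = dlogits.T @ pooled
        d_head_b = dlogits.sum(axis=0)
        dpooled = dlogits @ head_w
        a = adj.shape[1]
        dH = np.broadcast_to(dpooled[:, None, :] / DTYPE(a), H_L.shape).copy()
        grads = [None] * len(params)
        for li in range(len(params) - 1, -1, -1):
            H_in, Z, mask = caches[li]
            if mask is not None:
                dH = dH * mask
            dZ = dH * (Z > 0)
            AdZ = adj @ dZ  # adj symmetric
            grads[li] = np.einsum("bij,bik->jk", H_in, AdZ)
            if li > 0:
                dH = AdZ @ params[li].T
        return loss, [*grads, d_head_w, d_head_b]

    def _eval_loss(self, adj, feats, y_idx, params, head_w, head_b, cw):
        pooled, _, _ = self._forward(adj, feats, params)
        logits = pooled @ head_w.T + head_b
        probs = _softmax(logits.astype(np.float64))
        w = cw[y_idx]
        ce = -np.log(np.maximum(probs[np.arange(y_idx.size), y_idx], 1e-12))
        return float((w * ce).sum() / w.sum())

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise NotFittedError("GCNClassifier is not fitted")

    def _forward64(self, X):
        """Inference pass in double precision (weights stay float32-valued)."""
        adj, feats = _as_graph_arrays(X, self.k, self.weighting)
        params = [p.astype(np.float64) for p in self.weights_]
        pooled, H_L, _ = self._forward(
            adj.astype(np.float64), feats.astype(np.float64), params
        )
        logits = pooled @ self.head_weight_.astype(np.float64).T + self.head_bias_
        return logits, H_L

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        return self._forward64(X)[0]

    def predict_proba(self, X) -> np.ndarray:
        return _softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        return self.classes_[np.argmax(logits, axis=1)]

    def node_feature_maps(self, X) -> np.ndarray:
        """Final-layer node feature maps H^(L), shape (n, a, hidden[-1])."""
        self._check_fitted()
        return self._forward64(X)[1]

    def cam_scores(self, X, target_class=None) -> np.ndarray:
        """Exact CAM node activations M_c(v) for ``target_class`` (n, a).

        ``mean over nodes of M_c(v) == logit_c - b_c`` holds to float
        precision. Defaults to the "patient" class if present, else the last
        class.
        """
        self._check_fitted()
        if self.head_weight_.shape[1] != self.hidden[-1]:
            raise ValueError("CAM requires the single linear head after GAP")
        if target_class is None:
            target_class = (
                "patient" if "patient" in self.classes_ else self.classes_[-1]
            )
        (ci,) = np.flatnonzero(self.classes_ == target_class)
        H_L = self.node_feature_maps(X)
        return H_L @ self.head_weight_[ci]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(DTYPE)


class _AdamState:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, weight_decay=0.0):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g + DTYPE(weight_decay) * p
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= DTYPE(lr_t) * m / (np.sqrt(v) + self.eps)


def gcn_forward(
    model: GCNClassifier, graph: SubjectGraph
) -> tuple[np.ndarray, np.ndarray]:
    """Single-graph forward pass: (class logits, final node feature maps)."""
    model._check_fitted()
    if graph.features.shape[1] != model.n_features_in_:
        raise ValueError(
            f"graph width {graph.features.shape[1]} != model input width "
            f"{model.n_features_in_}"
        )
    logits, H_L = model._forward64([graph])
    return logits[0], H_L[0]


# ------------------------------------------------------------------ saliency


@dataclass
class SaliencyMap:
    """Mean CAM activation per region with a descending top-k ranking."""

    mean_activation: np.ndarray
    per_subject: np.ndarray
    ranking: np.ndarray  # region indices, descending by the ranking key
    top_k: int
    region_labels: list[str]
    mode: str = "abs"

    @property
    def top_regions(self) -> np.ndarray:
        return self.ranking[: self.top_k]

    def to_frame(self) -> pd.DataFrame:
        order = self.ranking
        return pd.DataFrame(
            {
                "region": [self.region_labels[i] for i in order],
                "region_index": order,
                "mean_activation": self.mean_activation[order],
                "rank": np.arange(1, order.size + 1),
            }
        )


def aggregate_saliency(
    per_subject_scores: np.ndarray,
    top_k: int = 10,
    region_labels: list[str] | None = None,
    mode: str = "abs",
) -> SaliencyMap:
    """Average node activations across subjects and rank regions.

    With ``mode="abs"`` (default) regions are ranked by the magnitude of the
    mean activation, so evidence of either sign — hyper- as well as
    hypoconnectivity pushes the logit in opposite directions — counts toward
    saliency; ``mode="signed"`` ranks by the raw mean. Ties are broken
    toward the lower region index.
    """
    if mode not in ("abs", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    scores = np.atleast_2d(np.asarray(per_subject_scores, dtype=float))
    if scores.size == 0:
        raise ValueError("no saliency scores given")
    mean = scores.mean(axis=0)
    a = mean.size
    key = np.abs(mean) if mode == "abs" else mean
    ranking = np.lexsort((np.arange(a), -key))
    if region_labels is None:
        region_labels = [f"region_{i:03d}" for i in range(a)]
    return SaliencyMap(
        mean_activation=mean,
        per_subject=scores,
        ranking=ranking,
        top_k=min(top_k, a),
        region_labels=list(region_labels),
        mode=mode,
    )
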