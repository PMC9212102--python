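"""Cross-validation schemes and performance metrics.

Two evaluation regimes: pooled stratified k-fold (class proportions
preserved per fold) and leave-one-site-out (LOSO), where each acquisition
site is held out in turn — sites contributing a single class are never used
as test sets (they stay in training) and are listed as skipped. Performance
is reported as balanced accuracy, sensitivity, specificity (percent) and
rank-based AUC, with 95% CIs: normal approximation across fold estimates for
k-fold, subject-level bootstrap of the pooled test predictions for LOSO.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

POSITIVE = "patient"


class SplitError(ValueError):
    """The requested cross-validation split cannot be constructed."""


@dataclass
class CVScheme:
    """kind: 'stratified_kfold' or 'loso'."""

    kind: str = "stratified_kfold"
    n_folds: int = 10
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("stratified_kfold", "loso"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "stratified_kfold" and self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def stratified_kfold_split(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold id per subject; exhaustive, disjoint, class-balanced folds."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise SplitError(
            f"smallest class has {counts.min()} subjects, cannot make {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(labels.size, dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros(labels.size), labels)):
        folds[test] = f
    return folds


def loso_split(site_ids, labels) -> tuple[list[dict], list[str]]:
    """One loop per site that contains both classes.

    Returns (loops, skipped_sites); each loop dict has ``site``,
    ``train_idx``, ``test_idx``. Single-class sites are train-only.
    """
    site_ids = np.asarray(site_ids)
    labels = np.asarray(labels)
    loops, skipped = [], []
    for site in sorted(np.unique(site_ids).tolist()):
        mask = site_ids == site
        if np.unique(labels[mask]).size < 2:
            skipped.append(site)
            continue
        loops.append(
            {
                "site": site,
                "train_idx": np.flatnonzero(~mask),
                "test_idx": np.flatnonzero(mask),
            }
        )
    if not loops:
        raise SplitError("no site contains both classes")
    return loops, skipped


def confusion_metrics(
    predictions, labels, positive: str = POSITIVE
) -> tuple[float, float, float]:
    """(balanced accuracy, sensitivity, specificity), all in percent."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    pos = labels == positive
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError(f"both classes required to compute sensitivity/specificity")
    sens = 100.0 * np.mean(predictions[pos] == positive)
    spec = 100.0 * np.mean(predictions[~pos] != positive)
    return (sens + spec) / 2.0, sens, spec


def auc(scores, labels, positive: str = POSITIVE) -> float:
    """Rank-based (Mann-Whitney, midrank ties) area under the ROC curve."""
    labels = np.asarray(labels)
    return float(roc_auc_score((labels == positive).astype(int), scores))


def confidence_interval(
    estimates, level: float = 0.95
) -> tuple[float, float, float]:
    """Normal-approximation CI from the spread of per-fold estimates."""
    est = np.asarray(estimates, dtype=float)
    mean = est.mean()
    if est.size < 2:
        return mean, mean, mean
    half = 1.959963984540054 * est.std(ddof=1) / np.sqrt(est.size)
    return mean, mean - half, mean + half


def _bootstrap_ci(
    pred, scores, labels, seed: int, n_boot: int = 1000, positive: str = POSITIVE
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap over pooled test subjects (LOSO CIs)."""
    rng = np.random.default_rng([29, seed])
    n = labels.size
    stats: dict[str, list[float]] = {m: [] for m in ("bacc", "sens", "spec", "auc")}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.unique(labels[idx]).size < 2:
            continue
        b, se, sp = confusion_metrics(pred[idx], labels[idx], positive)
        stats["bacc"].append(b)
        stats["sens"].append(se)
        stats["spec"].append(sp)
        stats["auc"].append(auc(scores[idx], labels[idx], positive))
    return {
        m: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for m, v in stats.items()
    }


@dataclass
class CVReport:
    """Per-fold and pooled classification performance."""

    rows: pd.DataFrame
    summary: dict
    model_kind: str = "gcn"
    harmonization: str = "after"
    ci_method: str = "normal_across_folds"
    skipped_sites: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6f")

    def to_json(self, path) -> None:
        payload = {
            "model_kind": self.model_kind,
            "harmonization": self.harmonization,
            "ci_method": self.ci_method,
            "skipped_sites": self.skipped_sites,
            "summary": self.summary,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _take(X, idx):
    if isinstance(X, np.ndarray):
        return X[idx]
    return [X[i] for i in idx]


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        try:
            proba = model.predict_proba(X)
        except AttributeError:  # wrapper whose inner model lacks probabilities
            proba = None
        if proba is not None:
            ci = int(np.flatnonzero(model.classes_ == POSITIVE)[0])
            return proba[:, ci]
    s = np.asarray(model.decision_function(X))
    if s.ndim == 2:
        ci = int(np.flatnonzero(model.classes_ == POSITIVE)[0])
        return s[:, ci]
    if model.classes_[1] != POSITIVE:
        s = -s
    return s


def cross_validate(
    make_model,
    X,
    y,
    scheme: CVScheme,
    site_ids=None,
    model_kind: str = "gcn",
    harmonization: str = "after",
) -> CVReport:
    """Run a CV scheme end to end and collect a CVReport.

    ``make_model(fold_seed)`` must return an unfitted estimator; each fold
    gets a seed derived deterministically from the scheme seed so the whole
    report is reproducible bit-for-bit.
    """
    y = np.asarray(y)
    rows = []
    pooled_pred, pooled_scores, pooled_labels = [], [], []
    skipped: list[str] = []

    if scheme.kind == "stratified_kfold":
        fold_iter = []
        for rep in range(scheme.n_repeats):
            folds = stratified_kfold_split(y, scheme.n_folds, scheme.seed + rep)
            for f in range(scheme.n_folds):
                test = np.flatnonzero(folds == f)
                train = np.flatnonzero(folds != f)
                fold_iter.append((f"rep{rep}_fold{f}", train, test))
    else:
        if site_ids is None:
            raise SplitError("LOSO requires site_ids")
        loops, skipped = loso_split(site_ids, y)
        fold_iter = [(d["site"], d["train_idx"], d["test_idx"]) for d in loops]

    for i, (name, train, test) in enumerate(fold_iter):
        model = make_model(scheme.seed * 1000 + i)
        model.fit(_take(X, train), y[train])
        pred = model.predict(_take(X, test))
        scores = _scores(model, _take(X, test))
        bacc, sens, spec = confusion_metrics(pred, y[test])
        rows.append(
            {
                "fold": name,
                "n_test": test.size,
                "balanced_accuracy": bacc,
                "sensitivity": sens,
                "specificity": spec,
                "auc": auc(scores, y[test]),
            }
        )
        pooled_pred.append(pred)
        pooled_scores.append(scores)
        pooled_labels.append(y[test])

    df = pd.DataFrame(rows)
    summary: dict = {}
    if scheme.kind == "stratified_kfold":
        ci_method = "normal_across_folds"
        for metric, col in (
            ("balanced_accuracy", "balanced_accuracy"),
            ("sensitivity", "sensitivity"),
            ("specificity", "specificity"),
            ("auc", "auc"),
        ):
            mean, lo, hi = confidence_interval(df[col].to_numpy())
            summary[metric] = {"mean": mean, "ci_lo": lo, "ci_hi": hi}
    else:
        ci_method = "bootstrap_pooled_subjects"
        pred = np.concatenate(pooled_pred)
        scores = np.concatenate(pooled_scores)
        labels = np.concatenate(pooled_labels)
        bacc, sens, spec = confusion_metrics(pred, labels)
        cis = _bootstrap_ci(pred, scores, labels, seed=scheme.seed)
        for metric, value in (
            ("balanced_accuracy", bacc),
            ("sensitivity", sens),
            ("specificity", spec),
            ("auc", auc(scores, labels)),
        ):
            key = {"balanced_accuracy": "bacc"}.get(metric, metric[:4])
            key = {"bacc": "bacc", "sens": "sens", "spec": "spec", "auc": "auc"}[key]
            summary[metric] = {
                "mean": value,
                "ci_lo": cis[key][0],
                "ci_hi": cis[key][1],
            }
    return CVReport(
        rows=df,
        summary=summary,
        model_kind=model_kind,
        harmonization=harmonization,
        ci_method=ci_method,
        skipped_sites=skipped,
    )
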