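"""Clustering, supervised backends, and agreement metrics.

Unsupervised route: k-means with silhouette-based selection of k over a
2..20 sweep, prediction by nearest centroid.  Supervised route: a
pluggable backend exposing fit/predict_proba (the default trains a small
network on the 6-D features; a frozen-base CNN fine-tune satisfies the
same contract when an accelerator is available).  Metrics: confusion
matrix, macro/weighted F1, Cohen's kappa, Fowlkes-Mallows index and
per-class confidence distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.neural_network import MLPClassifier

DEFAULT_K_RANGE = (2, 20)


# ---------------------------------------------------------------- clustering

@dataclass
class ClusterModel:
    centroids: np.ndarray  # k x d
    chosen_k: int
    training_silhouette: float
    feature_means: np.ndarray
    feature_stds: np.ndarray

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = (np.asarray(features, dtype=float) - self.feature_means) / self.feature_stds
        d = np.linalg.norm(X[:, None, :] - self.centroids[None, :, :], axis=2)
        return d.argmin(axis=1)


def select_k(
    features: np.ndarray,
    k_min: int = DEFAULT_K_RANGE[0],
    k_max: int = DEFAULT_K_RANGE[1],
    seed: int = 0,
    return_score: bool = False,
):
    """Silhouette sweep over k in [k_min, k_max]; ties go to smaller k.

    Features are standardized internally, matching ``fit_kmeans``.
    """
    X = np.asarray(features, dtype=float)
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd < 1e-12, 1.0, sd)
    n_unique = len(np.unique(X, axis=0))
    if n_unique <= k_min:
        warnings.warn("too few distinct points for the sweep; returning k_min")
        return (k_min, float("nan")) if return_score else k_min
    best_k, best_s = k_min, -np.inf
    for k in range(k_min, min(k_max, n_unique - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed, tol=1e-4, max_iter=300)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(X, labels)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if return_score:
        return best_k, best_s
    return best_k


def fit_kmeans(features: np.ndarray, k: int, seed: int = 0) -> ClusterModel:
    """Lloyd iterations with k-means++ seeding and 10 restarts; features
    are standardized internally and the parameters kept on the model."""
    X = np.asarray(features, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xs = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed, tol=1e-4, max_iter=300)
    labels = km.fit_predict(Xs)
    sil = silhouette_score(Xs, labels) if len(np.unique(labels)) > 1 else float("nan")
    return ClusterModel(
        centroids=km.cluster_centers_,
        chosen_k=k,
        training_silhouette=float(sil),
        feature_means=mu,
        feature_stds=sd,
    )


def predict_clusters(model: ClusterModel, features: np.ndarray) -> np.ndarray:
    return model.predict(features)


# ------------------------------------------------------------- supervised

class FeatureBackend:
    """Desk-scale supervised backend over the 6-D feature vectors.

    Satisfies the classifier contract (fit / predict_proba); a
    frozen-base CNN fine-tune is a drop-in replacement when image-level
    training is wanted and hardware permits.
    """

    name = "feature-mlp"

    def __init__(self, hidden: int = 64, iterations: int = 200, seed: int = 0):
        self.iterations = iterations
        self._clf = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            max_iter=iterations,
            random_state=seed,
            solver="adam",
        )
        self.classes_: np.ndarray | None = None
        self.loss_curve_: list[float] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeatureBackend":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate class set")
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) < 1e-12, 1.0, X.std(axis=0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings at small n
            self._clf.fit((X - self._mu) / self._sd, y)
        self.classes_ = self._clf.classes_
        self.loss_curve_ = list(self._clf.loss_curve_)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict_proba((X - self._mu) / self._sd)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict((X - self._mu) / self._sd)


def train_supervised(
    X: np.ndarray,
    y: np.ndarray,
    backend: FeatureBackend | None = None,
) -> FeatureBackend:
    """Fit the (pluggable) supervised backend on labeled feature rows."""
    backend = backend or FeatureBackend()
    return backend.fit(np.asarray(X, dtype=float), np.asarray(y))


# ---------------------------------------------------------------- metrics

def confusion(true, pred, labels: list | None = None) -> pd.DataFrame:
    """Confusion matrix as a labeled DataFrame (rows true, cols pred)."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    if len(true) != len(pred):
        raise ValueError("length mismatch")
    if labels is None:
        labels = sorted(set(true) | set(pred))
    idx = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true, pred):
        m[idx[t], idx[p]] += 1
    return pd.DataFrame(m, index=labels, columns=labels)


def f1_scores(matrix: pd.DataFrame | np.ndarray) -> dict[str, float]:
    """Per-class F1 plus macro and (support-)weighted averages, from a
    confusion matrix."""
    m = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    labels = list(matrix.index) if isinstance(matrix, pd.DataFrame) else list(range(m.shape[0]))
    tp = np.diag(m).astype(float)
    support = m.sum(axis=1).astype(float)
    pred_tot = m.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        rec = np.where(support > 0, tp / support, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    out = {f"f1_{lab}": float(v) for lab, v in zip(labels, f1)}
    out["f1_macro"] = float(f1.mean())
    w = support / max(support.sum(), 1.0)
    out["f1_weighted"] = float((f1 * w).sum())
    return out


def f1_macro(matrix) -> float:
    return f1_scores(matrix)["f1_macro"]


def cohens_kappa(a, b) -> float:
    """Chance-corrected agreement between two labelings (not permutation
    aware: labels must mean the same thing in both)."""
    m = confusion(a, b).to_numpy().astype(float)
    n = m.sum()
    if n == 0:
        raise ValueError("empty labelings")
    po = np.diag(m).sum() / n
    pe = float((m.sum(axis=1) / n) @ (m.sum(axis=0) / n))
    if np.isclose(pe, 1.0):
        return 1.0 if np.isclose(po, 1.0) else 0.0
    return float((po - pe) / (1.0 - pe))


def fowlkes_mallows(a, b) -> float:
    """FMI between two partitions via the pair-counting contingency
    table: geometric mean of pairwise precision and recall."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    c = confusion(a, b).to_numpy().astype(float)
    tk = (c**2).sum() - len(a)  # 2 * pairs co-clustered in both
    pk = (c.sum(axis=1) ** 2).sum() - len(a)
    qk = (c.sum(axis=0) ** 2).sum() - len(a)
    if pk == 0 or qk == 0:
        return 0.0
    return float(tk / np.sqrt(pk * qk))


def confidence_distribution(
    proba: np.ndarray,
    classes: np.ndarray,
    quantiles: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Distribution of max-probability confidence per *predicted* class."""
    proba = np.asarray(proba, dtype=float)
    pred = np.asarray(classes)[proba.argmax(axis=1)]
    conf = proba.max(axis=1)
    rows = []
    for lab in classes:
        sel = conf[pred == lab]
        row = {"class": lab, "n": int(sel.size)}
        for q in quantiles:
            row[f"q{int(q * 100):02d}"] = float(np.quantile(sel, q)) if sel.size else float("nan")
        row["frac_above_0.6"] = float((sel > 0.6).mean()) if sel.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def map_clusters_to_classes(cluster_labels: np.ndarray, class_labels: np.ndarray) -> dict:
    """Majority-vote mapping cluster id -> class label on paired data."""
    cluster_labels = np.asarray(cluster_labels)
    class_labels = np.asarray(class_labels)
    mapping = {}
    for c in np.unique(cluster_labels):
        vals, counts = np.unique(class_labels[cluster_labels == c], return_counts=True)
        mapping[c] = vals[counts.argmax()]
    return mapping


@dataclass
class EvalReport:
    confusion: pd.DataFrame
    f1: dict[str, float]
    kappa: float
    fmi: float
    confidence: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": {str(i): {str(c): int(v) for c, v in row.items()} for i, row in self.confusion.iterrows()},
            "kappa": self.kappa,
            "fmi": self.fmi,
            **self.f1,
        }
        if self.confidence is not None:
            d["confidence"] = self.confidence.to_dict(orient="records")
        return d


def evaluate(true, pred, proba: np.ndarray | None = None, classes=None) -> EvalReport:
    cm = confusion(true, pred)
    conf = None
    if proba is not None and classes is not None:
        conf = confidence_distribution(proba, np.asarray(classes))
    return EvalReport(
        confusion=cm,
        f1=f1_scores(cm),
        kappa=cohens_kappa(true, pred),
        fmi=fowlkes_mallows(true, pred),
        confidence=conf,
    )
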