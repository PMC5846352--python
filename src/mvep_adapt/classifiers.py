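"""The two self-labelers: a posterior-calibrated SVM and fuzzy C-means.

Both expose the same contract — given feature vectors they return an
assigned label and a confidence in [0, 1] for that label — so the
calibration stage can treat them uniformly.  The SVM side wraps
scikit-learn's RBF SVC with Platt-type probability calibration at default
hyperparameters (no tuning).  The fuzzy C-means side is implemented from
scratch: two clusters, Euclidean distances, fuzzifier m, with the classic
alternating membership/center updates, and its clusters are mapped onto
task labels by matching cluster centers to the supervised class means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "SVMModel",
    "FCMModel",
    "ClassCenters",
    "train_svm",
    "predict_posterior",
    "compute_class_centers",
    "fit_fcm",
    "match_clusters",
    "fcm_label",
]


@dataclass
class SVMModel:
    """Trained binary RBF SVM with posterior output."""

    clf: SVC
    classes_: np.ndarray
    n_train: int

    def posterior(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(np.atleast_2d(X))


def train_svm(X: np.ndarray, y: np.ndarray, seed: int = 0) -> SVMModel:
    """Fit the RBF SVM with library-default hyperparameters.

    ``probability=True`` enables Platt-style posterior calibration; the
    seed fixes its internal cross-validation so training is deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("need at least 2 samples per class")
    with warnings.catch_warnings():
        # probability=True is the documented Platt-calibration path in this
        # sklearn release; silence its pending-deprecation notice.
        warnings.simplefilter("ignore", FutureWarning)
        clf = SVC(kernel="rbf", probability=True, random_state=seed)
        clf.fit(X, y)
    return SVMModel(clf=clf, classes_=clf.classes_, n_train=len(y))


def predict_posterior(model: SVMModel, X: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Assigned label (argmax posterior) and its probability, per sample.

    The returned probability is the posterior of the assigned label, hence
    always >= 0.5 for a binary problem.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.clf.n_features_in_:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training "
            f"dimension {model.clf.n_features_in_}"
        )
    proba = model.posterior(X)
    idx = np.argmax(proba, axis=1)
    return model.classes_[idx], proba[np.arange(len(idx)), idx]


@dataclass
class ClassCenters:
    """Per-class arithmetic means of training features (C1 = target class)."""

    c1: np.ndarray
    c2: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.vstack([self.c1, self.c2])


def compute_class_centers(X: np.ndarray, y: np.ndarray,
                          positive_label=1) -> ClassCenters:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos = X[y == positive_label]
    neg = X[y != positive_label]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute centers")
    return ClassCenters(c1=pos.mean(axis=0), c2=neg.mean(axis=0))


@dataclass
class FCMModel:
    centers: np.ndarray       # 2 x d  (U1, U2)
    memberships: np.ndarray   # n x 2, rows sum to 1
    m: float
    objective: float
    objective_history: list[float]
    n_iterations: int


def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """u_ic = 1 / sum_j (d_ic / d_ij)^(2/(m-1)); d = 0 gives a hard 1."""
    d = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
    u = np.zeros((len(X), len(centers)))
    zero = d <= 1e-300
    any_zero = zero.any(axis=1)
    if np.any(any_zero):
        rows = np.where(any_zero)[0]
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    rest = ~any_zero
    if np.any(rest):
        ratio = (d[rest][:, :, None] / d[rest][:, None, :]) ** (2.0 / (m - 1.0))
        u[rest] = 1.0 / ratio.sum(axis=2)
    return u


def _objective(X: np.ndarray, centers: np.ndarray, u: np.ndarray,
               m: float) -> float:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float((u ** m * d2).sum())


def fit_fcm(X: np.ndarray, m: float = 2.0,
            init_centers: ClassCenters | np.ndarray | None = None,
            tol: float = 1e-6, max_iter: int = 300,
            seed: int | None = None) -> FCMModel:
    """Two-cluster fuzzy C-means by alternating updates.

    Initialization defaults to the supervised class centers when provided
    (deterministic); otherwise two distinct points are drawn at random
    (seeded).  Iteration stops when the center shift falls below ``tol``
    or after ``max_iter`` rounds.  The objective sum u^m d^2 is recorded
    per iteration and is non-increasing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    if len(X) < 2 or len(np.unique(X, axis=0)) < 2:
        raise ValueError("need at least 2 distinct points to form 2 clusters")
    if init_centers is None:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(X), size=2, replace=False)
        centers = X[idx].astype(float).copy()
        if np.allclose(centers[0], centers[1]):
            uniq = np.unique(X, axis=0)
            centers = uniq[:2].astype(float).copy()
    elif isinstance(init_centers, ClassCenters):
        centers = init_centers.as_array().astype(float).copy()
    else:
        centers = np.asarray(init_centers, dtype=float).copy()

    history: list[float] = []
    u = _memberships(X, centers, m)
    for it in range(1, max_iter + 1):
        um = u ** m
        denom = um.sum(axis=0)
        if np.any(denom <= 0):
            raise ValueError("degenerate cluster: empty membership mass")
        new_centers = (um.T @ X) / denom[:, None]
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        u = _memberships(X, centers, m)
        history.append(_objective(X, centers, u, m))
        if shift < tol:
            break
    return FCMModel(centers=centers, memberships=u, m=m,
                    objective=history[-1], objective_history=history,
                    n_iterations=len(history))


def match_clusters(fcm: FCMModel, centers: ClassCenters,
                   labels: tuple = (1, 0)) -> dict[int, object]:
    """Map fCM clusters onto task labels by center proximity.

    Of the two possible assignments of cluster centers (U1, U2) to class
    centers (C1, C2), the one minimizing the total Euclidean distance is
    chosen; this reduces to nearest-center assignment whenever that is
    consistent, and resolves the case where both clusters are nearest the
    same class center.  ``labels`` are the task labels of (C1, C2).
    """
    u1, u2 = fcm.centers
    c = centers.as_array()
    direct = np.linalg.norm(u1 - c[0]) + np.linalg.norm(u2 - c[1])
    swapped = np.linalg.norm(u1 - c[1]) + np.linalg.norm(u2 - c[0])
    if direct <= swapped:
        return {0: labels[0], 1: labels[1]}
    return {0: labels[1], 1: labels[0]}


def fcm_label(fcm: FCMModel, mapping: dict[int, object]
              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample assigned task label and its confidence (max membership)."""
    cluster = np.argmax(fcm.memberships, axis=1)
    conf = fcm.memberships[np.arange(len(cluster)), cluster]
    labels = np.array([mapping[c] for c in cluster])
    return labels, conf
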