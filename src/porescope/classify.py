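"""Discrimination engines: kernel-density classification and Rotation-Forest
grids with cross-validated F-measure scoring.

Two engines mirror the two analysis stages: (i) a non-parametric
density classifier on a low-dimensional feature pair — e.g. pulse
height I_p and apex bluntness beta_apex — evaluated by stratified 5-fold
cross validation, and (ii) Rotation-Forest ensembles with exchangeable
base learners scored over a (feature vector x classifier) grid by
10-fold cross-validated F-measure,

    F_Meas = 2 P_pre P_rec / (P_pre + P_rec),
    P_pre = TP/(TP+FP),  P_rec = TP/(TP+FN).

The Rotation Forest follows its published construction: per tree, the
features are partitioned into K random disjoint subsets; for each
subset an axis-decorrelating principal-axes transform (all components
kept) is fit on a bootstrap sample of a random subset of classes, and
the blocks are assembled into the tree's orthonormal rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression, RidgeClassifier, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier, ExtraTreeClassifier

__all__ = [
    "Metrics",
    "KDEClassifier",
    "RotationForestClassifier",
    "GridResult",
    "compute_metrics",
    "cross_validate",
    "run_grid",
    "base_learner",
    "default_roster",
    "expand_roster",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metrics:
    """Confusion counts and the derived precision/recall/F-measure."""

    tp: int
    fp: int
    fn: int
    tn: int
    p_pre: float
    p_rec: float
    f_meas: float
    degenerate: bool = False     # flagged when TP+FP or TP+FN was zero

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else float("nan")


def compute_metrics(tp: int, fp: int, fn: int, tn: int = 0) -> Metrics:
    """Precision, recall and F-measure from confusion counts.

    Degenerate denominators (TP+FP = 0 or TP+FN = 0) are flagged rather
    than silently zeroed; F is reported as 0 with the flag set.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    p_pre = tp / (tp + fp) if tp + fp else 0.0
    p_rec = tp / (tp + fn) if tp + fn else 0.0
    if p_pre + p_rec > 0:
        f = 2.0 * p_pre * p_rec / (p_pre + p_rec)
    else:
        f = 0.0
        degenerate = degenerate or tp == 0
    return Metrics(tp, fp, fn, tn, p_pre, p_rec, f, degenerate)


# ---------------------------------------------------------------------------
# kernel-density classifier
# ---------------------------------------------------------------------------

class KDEClassifier(BaseEstimator, ClassifierMixin):
    """Non-parametric density classifier with product Gaussian kernels.

    Features are standardized globally; each class gets a per-dimension
    Silverman bandwidth.  Prediction is the argmax of class density
    times prior (equal priors by default).
    """

    def __init__(self, priors: dict | None = None):
        self.priors = priors

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        for d, s in enumerate(self.std_):
            if s == 0:
                raise ValueError(f"degenerate (zero-variance) feature at column {d}")
        Z = (X - self.mean_) / self.std_
        d = Z.shape[1]
        self.train_ = {}
        self.bandwidths_ = {}
        for c in self.classes_:
            Zc = Z[y == c]
            n = len(Zc)
            sigma = Zc.std(axis=0, ddof=1) if n > 1 else np.ones(d)
            sigma = np.where(sigma > 0, sigma, 1.0)
            h = sigma * (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0))
            self.train_[c] = Zc
            self.bandwidths_[c] = h
        return self

    def _log_density(self, Z: np.ndarray) -> np.ndarray:
        out = np.empty((len(Z), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            Zc = self.train_[c]
            h = self.bandwidths_[c]
            u = (Z[:, None, :] - Zc[None, :, :]) / h
            logk = -0.5 * np.sum(u * u, axis=2) - np.sum(np.log(h)) \
                - 0.5 * Z.shape[1] * math.log(2 * math.pi)
            mx = logk.max(axis=1)
            out[:, j] = mx + np.log(np.mean(np.exp(logk - mx[:, None]), axis=1))
        return out

    def predict_proba(self, X):
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.std_
        logd = self._log_density(Z)
        priors = np.array([
            (self.priors or {}).get(c, 1.0 / len(self.classes_))
            for c in self.classes_
        ])
        logp = logd + np.log(priors)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def kde_fit_predict(X_train, y_train, X_test, priors: dict | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Fit the density classifier and predict test labels.

    Returns ``(labels, posteriors)``; deterministic given its inputs.
    """
    clf = KDEClassifier(priors=priors).fit(X_train, y_train)
    return clf.predict(X_test), clf.predict_proba(X_test)


# ---------------------------------------------------------------------------
# Rotation Forest
# ---------------------------------------------------------------------------

class RotationForestClassifier(BaseEstimator, ClassifierMixin):
    """Rotation Forest meta-classifier over an arbitrary base learner.

    Per tree, features are split into ``n_subsets`` random disjoint
    groups; each group's rotation block is the principal-axes transform
    fit on a bootstrap sample (75%) of a random non-empty subset of
    classes, all components kept, so every block is orthonormal.
    Prediction is the majority vote over trees (ties broken toward the
    first class label).
    """

    def __init__(self, base_estimator=None, n_trees: int = 10,
                 n_subsets: int | None = None, random_state: int | None = 0):
        self.base_estimator = base_estimator
        self.n_trees = n_trees
        self.n_subsets = n_subsets        # None: min(3, n_features)
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, d = X.shape
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_subsets is None:
            self.n_subsets_ = min(3, d)
        else:
            self.n_subsets_ = self.n_subsets
        if not (1 <= self.n_subsets_ <= d):
            raise ValueError(f"n_subsets must lie in [1, {d}] for {d} features")
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        base = self.base_estimator if self.base_estimator is not None \
            else DecisionTreeClassifier(random_state=0)
        self.rotations_ = []
        self.estimators_ = []
        for _ in range(self.n_trees):
            perm = rng.permutation(d)
            groups = np.array_split(perm, self.n_subsets_)
            rotation = np.zeros((d, d))
            for g in groups:
                chosen = self.classes_[rng.random(len(self.classes_)) < 0.5]
                if chosen.size == 0:
                    chosen = self.classes_[[rng.integers(len(self.classes_))]]
                rows = np.flatnonzero(np.isin(y, chosen))
                boot = rng.choice(rows, size=max(len(g) + 1, int(0.75 * len(rows))),
                                  replace=True)
                sub = X[np.ix_(boot, g)]
                block = _principal_axes(sub)
                rotation[np.ix_(g, g)] = block
            Xr = X @ rotation
            est = clone(base)
            if "random_state" in est.get_params():
                est.set_params(random_state=int(rng.integers(2 ** 31 - 1)))
            est.fit(Xr, y)
            self.rotations_.append(rotation)
            self.estimators_.append(est)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        votes = np.zeros((len(X), len(self.classes_)), dtype=int)
        lookup = {c: j for j, c in enumerate(self.classes_)}
        for rotation, est in zip(self.rotations_, self.estimators_):
            pred = est.predict(X @ rotation)
            for i, p in enumerate(pred):
                votes[i, lookup[p]] += 1
        return self.classes_[np.argmax(votes, axis=1)]


def _principal_axes(sub: np.ndarray) -> np.ndarray:
    """Orthonormal principal-axes transform of a data block; constant
    (zero-variance) blocks fall back to the identity."""
    centered = sub - sub.mean(axis=0)
    if np.allclose(centered, 0):
        return np.eye(sub.shape[1])
    pca = PCA(n_components=sub.shape[1], svd_solver="full")
    try:
        pca.fit(sub)
    except Exception:
        return np.eye(sub.shape[1])
    return pca.components_.T


# ---------------------------------------------------------------------------
# classifier roster
# ---------------------------------------------------------------------------

_BASE_LEARNERS = {
    "tree": lambda: DecisionTreeClassifier(random_state=0),
    "extra_tree": lambda: ExtraTreeClassifier(random_state=0),
    "knn1": lambda: KNeighborsClassifier(n_neighbors=1),
    "knn5": lambda: KNeighborsClassifier(n_neighbors=5),
    "gaussian_nb": GaussianNB,
    "lda": LinearDiscriminantAnalysis,
    "logistic": lambda: LogisticRegression(max_iter=2000),
    "ridge": RidgeClassifier,
    "linear_svm": lambda: LinearSVC(max_iter=5000),
    "sgd": lambda: SGDClassifier(random_state=0),
}


def base_learner(classifier_id: str):
    """Instantiate a roster entry.

    Ids take the form ``rotation_forest(<base>)`` for the meta-classifier
    or a bare base-learner name; ``@k`` alias suffixes (used for
    grid-shape parity) are ignored when resolving the learner.
    """
    cid = classifier_id.split("@")[0]
    if cid.startswith("rotation_forest(") and cid.endswith(")"):
        inner = cid[len("rotation_forest("):-1]
        if inner not in _BASE_LEARNERS:
            raise KeyError(f"unknown base learner: {inner!r}")
        return RotationForestClassifier(base_estimator=_BASE_LEARNERS[inner]())
    if cid == "kde":
        return KDEClassifier()
    if cid in _BASE_LEARNERS:
        return _BASE_LEARNERS[cid]()
    raise KeyError(f"unknown classifier id: {classifier_id!r}")


def default_roster() -> list[str]:
    """Rotation-Forest ensembles over the standard base-learner families."""
    return [f"rotation_forest({name})" for name in _BASE_LEARNERS]


def expand_roster(n: int, roster: list[str] | None = None) -> list[str]:
    """Cycle a roster with ``@k`` aliases up to ``n`` ids (grid-shape parity
    with rosters of arbitrary printed size, e.g. 67)."""
    roster = roster or default_roster()
    out = []
    k = 0
    while len(out) < n:
        for cid in roster:
            if len(out) == n:
                break
            out.append(cid if k == 0 else f"{cid}@{k}")
        k += 1
    return out


# ---------------------------------------------------------------------------
# cross validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_metrics: list[Metrics]
    pooled: Metrics
    positive_class: str
    seed: int

    @property
    def accuracy(self) -> float:
        return self.pooled.accuracy


def cross_validate(X, y, classifier, k_folds: int = 10, seed: int = 0,
                   positive_class=None) -> CVResult:
    """Stratified k-fold cross validation with pooled confusion counts.

    Folds are near-equal (sizes differ by at most one per class); the
    aggregate metrics come from pooling the per-fold confusion counts,
    not from averaging per-fold scores.  The positive class defaults to
    the first label alphabetically.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if counts.min() < k_folds:
        small = classes[np.argmin(counts)]
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than {k_folds} folds"
        )
    pos = positive_class if positive_class is not None else sorted(map(str, classes))[0]
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_metrics = []
    totals = np.zeros(4, dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        est = clone(classifier)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        truth = y[test_idx]
        tp = int(np.sum((pred == pos) & (truth == pos)))
        fp = int(np.sum((pred == pos) & (truth != pos)))
        fn = int(np.sum((pred != pos) & (truth == pos)))
        tn = int(np.sum((pred != pos) & (truth != pos)))
        fold_metrics.append(compute_metrics(tp, fp, fn, tn))
        totals += (tp, fp, fn, tn)
    pooled = compute_metrics(*totals)
    return CVResult(fold_metrics, pooled, str(pos), seed)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass
class GridResult:
    """F-measure scores over every (feature vector x classifier) cell."""

    f_meas: np.ndarray            # (n_specs, n_classifiers), NaN on failure
    accuracy: np.ndarray
    p_pre: np.ndarray
    p_rec: np.ndarray
    spec_names: list[str]
    classifier_ids: list[str]
    fold_scores: dict = field(default_factory=dict)
    seed: int = 0
    k_folds: int = 10
    catalog_hash: str = ""
    failures: dict = field(default_factory=dict)

    @property
    def f_max(self) -> float:
        return float(np.nanmax(self.f_meas))

    @property
    def best_cell(self) -> tuple[str, str]:
        i, j = np.unravel_index(np.nanargmax(self.f_meas), self.f_meas.shape)
        return self.spec_names[i], self.classifier_ids[j]

    @property
    def best_accuracy(self) -> float:
        return float(np.nanmax(self.accuracy))

    def best_cell_metrics(self) -> dict:
        """Pooled precision/recall/F of the highest-F cell."""
        i, j = np.unravel_index(np.nanargmax(self.f_meas), self.f_meas.shape)
        return {"P_pre": float(self.p_pre[i, j]), "P_rec": float(self.p_rec[i, j]),
                "F_Meas": float(self.f_meas[i, j]),
                "accuracy": float(self.accuracy[i, j])}

    def to_report(self) -> dict:
        return {
            "f_max": self.f_max,
            "best_cell": list(self.best_cell),
            "best_accuracy": self.best_accuracy,
            "k_folds": self.k_folds,
            "seed": self.seed,
            "catalog_hash": self.catalog_hash,
            "spec_names": self.spec_names,
            "classifier_ids": self.classifier_ids,
            "f_meas": [[None if np.isnan(v) else float(v) for v in row]
                       for row in self.f_meas],
            "accuracy": [[None if np.isnan(v) else float(v) for v in row]
                         for row in self.accuracy],
            "failures": {k: str(v) for k, v in self.failures.items()},
        }


def run_grid(vectors_by_spec: dict[str, np.ndarray], y,
             classifier_ids: list[str], k_folds: int = 10, seed: int = 0,
             catalog_hash: str = "") -> GridResult:
    """Cross-validate every (feature vector, classifier) combination.

    ``vectors_by_spec`` maps spec names to (n_pulses, length) arrays.
    Per-cell failures are recorded as NaN with the error retained, not
    raised.
    """
    if not vectors_by_spec or not classifier_ids:
        raise ValueError("catalog and roster must be non-empty")
    y = np.asarray(y)
    spec_names = list(vectors_by_spec)
    shape = (len(spec_names), len(classifier_ids))
    f_meas = np.full(shape, np.nan)
    accuracy = np.full(shape, np.nan)
    p_pre = np.full(shape, np.nan)
    p_rec = np.full(shape, np.nan)
    fold_scores = {}
    failures = {}
    for i, name in enumerate(spec_names):
        X = np.asarray(vectors_by_spec[name], dtype=float)
        for j, cid in enumerate(classifier_ids):
            try:
                result = cross_validate(X, y, base_learner(cid), k_folds, seed)
            except Exception as exc:   # noqa: BLE001 - recorded, not fatal
                failures[f"{name}|{cid}"] = exc
                continue
            f_meas[i, j] = result.pooled.f_meas
            accuracy[i, j] = result.accuracy
            p_pre[i, j] = result.pooled.p_pre
            p_rec[i, j] = result.pooled.p_rec
            fold_scores[f"{name}|{cid}"] = [m.f_meas for m in result.fold_metrics]
    return GridResult(f_meas, accuracy, p_pre, p_rec, spec_names, classifier_ids,
                      fold_scores, seed, k_folds, catalog_hash, failures)
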