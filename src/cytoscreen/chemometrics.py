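"""Statistical classification of pre-processed spectra.

Feature reduction is either principal component analysis (3 components) or
marginal-relevance (MR) wavelength selection: the MR score of a wavelength
is the ratio of the between-class to the within-class sum of squares, each
wavelength considered independently.  Eleven classifier configurations are
evaluated under stratified 10-fold cross-validation, with all reducers
fitted on the training split only:

=========  =============================
reducer    classifiers
=========  =============================
PCA (3)    LDA, QDA, kNN
MR (10)    LDA, QDA, kNN, RF, SVM
none       RF, SVM, PLS
=========  =============================

Hyperparameters are fixed, not tuned: kNN k=5; RF 500 trees with
mtry = floor(sqrt(p)); SVM Gaussian kernel with a quantile ("sigest"-style)
bandwidth estimate; PLS with 15 latent variables, classifying by regressing
a +/-1 class code and thresholding at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = [
    "MRScores",
    "PipelineSpec",
    "CVReport",
    "ALLOWED_PIPELINES",
    "all_pipelines",
    "marginal_relevance",
    "select_mr_channels",
    "stratified_folds",
    "crossvalidate",
    "classification_metrics",
]


@dataclass
class MRScores:
    """Per-channel between/within sum-of-squares ratios."""

    score: np.ndarray
    channels: np.ndarray | None = None  # wavenumber per channel, if known

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float).reshape(-1)


#: the classifier configurations evaluated, as (reducer, classifier) pairs
ALLOWED_PIPELINES: tuple[tuple[str, str], ...] = (
    ("pca", "lda"), ("pca", "qda"), ("pca", "knn"),
    ("mr", "lda"), ("mr", "qda"), ("mr", "knn"), ("mr", "rf"), ("mr", "svm"),
    ("none", "rf"), ("none", "svm"), ("none", "pls"),
)


@dataclass(frozen=True)
class PipelineSpec:
    """One of the eleven reducer/classifier combinations."""

    reducer: str  # "none" | "pca" | "mr"
    classifier: str  # "lda" | "qda" | "knn" | "rf" | "svm" | "pls"
    n_components: int = 3  # PCA components
    n_regions: int = 10  # MR regions (one selected wavelength each)

    def __post_init__(self) -> None:
        if (self.reducer, self.classifier) not in ALLOWED_PIPELINES:
            raise ValueError(
                f"({self.reducer!r}, {self.classifier!r}) is not one of the "
                f"{len(ALLOWED_PIPELINES)} evaluated configurations"
            )

    @property
    def name(self) -> str:
        return f"{self.reducer}+{self.classifier}" if self.reducer != "none" else self.classifier


def all_pipelines() -> list[PipelineSpec]:
    return [PipelineSpec(r, c) for r, c in ALLOWED_PIPELINES]


@dataclass
class CVReport:
    """Cross-validation outcome for a set of pipeline configurations."""

    folds: np.ndarray  # fold id per sample
    seed: int
    positive: str
    classes: tuple[str, str]
    predictions: dict[str, np.ndarray] = field(default_factory=dict)  # name -> predicted label per sample
    confusion: dict[str, np.ndarray] = field(default_factory=dict)  # name -> 2x2 pooled counts
    fold_accuracy: dict[str, np.ndarray] = field(default_factory=dict)  # name -> per-fold accuracies
    fold_errors: dict[str, list[str]] = field(default_factory=dict)  # name -> warnings

    def metrics(self, name: str) -> tuple[float, float, float]:
        return classification_metrics(self.confusion[name], positive_index=0)

    def metrics_table(self) -> "object":
        import pandas as pd

        rows = []
        for name in self.confusion:
            acc, sens, spec = self.metrics(name)
            rows.append({"pipeline": name, "accuracy": acc,
                         "sensitivity": sens, "specificity": spec})
        return pd.DataFrame(rows).set_index("pipeline")


# ---------------------------------------------------------------------------
# Marginal relevance


def marginal_relevance(X: np.ndarray, y: np.ndarray) -> MRScores:
    """MR score per channel: between-class SS over within-class SS.

    For channel j with grand mean ``x̄_j``, class means ``x̄_kj`` and class
    sizes ``n_k``: ``B_j = Σ_k n_k (x̄_kj − x̄_j)²`` and
    ``W_j = Σ_k Σ_{i∈k} (x_ij − x̄_kj)²``; the score is ``B_j / W_j`` (+inf
    when only the within term vanishes, 0 when both do).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("marginal relevance needs >= 2 classes")
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise ValueError(f"every class needs >= 2 samples; {small} too small")
    grand = X.mean(axis=0)
    B = np.zeros(X.shape[1])
    W = np.zeros(X.shape[1])
    for k, n_k in zip(classes, counts):
        Xk = X[y == k]
        mk = Xk.mean(axis=0)
        B += n_k * (mk - grand) ** 2
        W += ((Xk - mk) ** 2).sum(axis=0)
    score = np.empty(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        score = B / W
    score[(W == 0) & (B > 0)] = np.inf
    score[(W == 0) & (B == 0)] = 0.0
    return MRScores(score=score)


def select_mr_channels(scores: MRScores, n_regions: int = 10) -> np.ndarray:
    """Best-scoring channel from each of ``n_regions`` contiguous equal-width
    blocks of the channel axis (ties to the lowest index).

    Neighbouring wavelengths carry near-identical MR scores, so a plain
    global top-10 would pick one band ten times over; regional maxima spread
    the selection across the spectrum.
    """
    s = scores.score
    if len(s) < n_regions:
        raise ValueError(f"need >= {n_regions} channels, have {len(s)}")
    blocks = np.array_split(np.arange(len(s)), n_regions)
    return np.array([int(b[int(np.argmax(s[b]))]) for b in blocks], dtype=int)


# ---------------------------------------------------------------------------
# Cross-validation harness


def stratified_folds(y: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Class-stratified fold assignment: a seeded permutation within each
    class, dealt round-robin into ``k`` folds (per-fold class counts differ
    by at most one)."""
    y = np.asarray(y)
    folds = np.empty(len(y), dtype=int)
    rng = np.random.default_rng(seed)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has {len(idx)} samples, fewer than k={k}")
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    """RBF bandwidth from the 0.1/0.9-quantile midrange of pairwise squared
    distances on a subsample (the usual "sigest" empirical estimate)."""
    n = len(X)
    take = min(n, 100)
    idx = rng.choice(n, size=take, replace=False)
    S = X[idx]
    d2 = ((S[:, None, :] - S[None, :, :]) ** 2).sum(axis=-1)
    vals = d2[np.triu_indices(take, k=1)]
    vals = vals[vals > 0]
    if len(vals) == 0:
        return 1.0
    q10, q90 = np.quantile(vals, [0.1, 0.9])
    scale = 0.5 * (q10 + q90)
    return float(1.0 / scale) if scale > 0 else 1.0


class _PLSClassifier:
    """PLS-DA: regress a +/-1 class code on the features, threshold at 0."""

    def __init__(self, n_components: int = 15) -> None:
        self.n_components = n_components

    def fit(self, X: np.ndarray, y_pm1: np.ndarray) -> "_PLSClassifier":
        ncomp = min(self.n_components, X.shape[1], len(X) - 1)
        self._pls = PLSRegression(n_components=ncomp)
        self._pls.fit(X, y_pm1.astype(float))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._pls.predict(X).ravel()

    def predict_pm1(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


def _make_classifier(spec: PipelineSpec, X_train: np.ndarray, seed: int,
                     rng: np.random.Generator):
    if spec.classifier == "lda":
        return LinearDiscriminantAnalysis()
    if spec.classifier == "qda":
        return QuadraticDiscriminantAnalysis()
    if spec.classifier == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if spec.classifier == "rf":
        return RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed, n_jobs=1
        )
    if spec.classifier == "svm":
        gamma = _median_heuristic_gamma(X_train, rng)
        return SVC(kernel="rbf", gamma=gamma, C=1.0)
    if spec.classifier == "pls":
        return _PLSClassifier(n_components=15)
    raise ValueError(spec.classifier)


def crossvalidate(
    X: np.ndarray,
    y: np.ndarray,
    specs: list[PipelineSpec] | None = None,
    k: int = 10,
    seed: int = 0,
    positive: str | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation of the given pipeline configurations.

    Reducers (PCA mean-centred with 3 components; MR scores and channel
    selection) are fitted on each fold's training rows only and applied to
    its test rows, so no information leaks across the split.  The same fold
    assignment is shared by every configuration.  A fold where QDA meets a
    degenerate within-class covariance is recorded and excluded for that
    configuration, never silently.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(str)
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    classes = tuple(sorted(np.unique(y)))
    if len(classes) != 2:
        raise ValueError(f"binary classification only; got classes {classes}")
    if specs is None:
        specs = all_pipelines()
    if positive is None:
        # high-grade class by convention, else the alphabetically-first label
        positive = next((c for c in classes if "high" in c.lower()), classes[0])
    negative = classes[0] if classes[1] == positive else classes[1]

    folds = stratified_folds(y, k=k, seed=seed)
    report = CVReport(folds=folds, seed=seed, positive=positive,
                      classes=(positive, negative))
    rng = np.random.default_rng(seed + 1)

    for spec in specs:
        preds = np.empty(len(y), dtype=object)
        errors: list[str] = []
        fold_acc = []
        valid = np.zeros(len(y), dtype=bool)
        for f in range(k):
            test = folds == f
            train = ~test
            Xtr, Xte = X[train], X[test]
            ytr = y[train]
            if spec.reducer == "pca":
                pca = PCA(n_components=spec.n_components, svd_solver="full")
                Xtr = pca.fit_transform(Xtr)
                Xte = pca.transform(X[test])
            elif spec.reducer == "mr":
                chans = select_mr_channels(marginal_relevance(Xtr, ytr), spec.n_regions)
                Xtr, Xte = Xtr[:, chans], Xte[:, chans]
            clf = _make_classifier(spec, Xtr, seed=seed + 7919 * f, rng=rng)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if isinstance(clf, _PLSClassifier):
                        code = np.where(ytr == positive, 1, -1)
                        clf.fit(Xtr, code)
                        yhat = np.where(clf.predict_pm1(Xte) == 1, positive, negative)
                    else:
                        clf.fit(Xtr, ytr)
                        yhat = clf.predict(Xte)
            except np.linalg.LinAlgError as exc:
                errors.append(f"fold {f}: {spec.name}: {exc}")
                continue
            preds[test] = yhat
            valid |= test
            fold_acc.append(float(np.mean(yhat == y[test])))

        mask = valid
        tp = int(np.sum((preds[mask] == positive) & (y[mask] == positive)))
        fn = int(np.sum((preds[mask] != positive) & (y[mask] == positive)))
        fp = int(np.sum((preds[mask] == positive) & (y[mask] != positive)))
        tn = int(np.sum((preds[mask] != positive) & (y[mask] != positive)))
        report.predictions[spec.name] = preds
        report.confusion[spec.name] = np.array([[tp, fn], [fp, tn]])
        report.fold_accuracy[spec.name] = np.array(fold_acc)
        report.fold_errors[spec.name] = errors
    return report


def classification_metrics(
    confusion: np.ndarray, positive_index: int = 0
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from a 2x2 confusion matrix.

    The matrix is ``[[TP, FN], [FP, TN]]`` with the positive class in row and
    column ``positive_index`` 0; pass ``positive_index=1`` to swap the roles.
    """
    C = np.asarray(confusion, dtype=float).reshape(2, 2)
    if np.any(C < 0) or C.sum() == 0:
        raise ValueError("confusion counts must be non-negative with a positive total")
    if positive_index == 1:
        C = C[::-1, ::-1]
    tp, fn = C[0]
    fp, tn = C[1]
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("a class margin is empty; sensitivity/specificity undefined")
    accuracy = (tp + tn) / C.sum()
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return float(accuracy), float(sensitivity), float(specificity)
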