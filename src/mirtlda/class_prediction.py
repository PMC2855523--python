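"""Two-class prediction with nested leave-one-out cross-validation.

Every training fold repeats the entire model-building process — marker
selection at a stringent significance level (random-variance t by
default) and classifier fitting — so the left-out sample never informs
its own prediction.  Classifiers follow their classical definitions:

* compound covariate predictor (CCP): per-sample score is the
  t-statistic-weighted sum of the selected features; the decision
  threshold is the midpoint of the two class-mean scores;
* diagonal linear discriminant analysis (DLDA): Gaussian discriminant
  with a shared diagonal (pooled per-feature) covariance;
* k-nearest neighbours (k = 1 or 3): Euclidean distance, majority vote,
  ties broken by the nearest neighbour's label;
* nearest centroid: Euclidean distance to the class-mean profile;
* linear-kernel SVM (unit cost, deterministic solver settings);
* Bayesian compound covariate: CCP scores with Gaussian class-conditional
  densities (per-class score variances) and equal priors.

Significance of a cross-validated error rate is assessed by label
permutation: the whole nested LOOCV is repeated on permuted labels and
the p-value is the add-one proportion of permutations doing at least as
well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .class_comparison import RvmHyperparameters, fit_rvm, pooled_t_stats, rvm_t_stats
from .errors import ValidationError

CLASSIFIER_METHODS = (
    "compound_covariate",
    "dlda",
    "knn1",
    "knn3",
    "nearest_centroid",
    "svm_linear",
    "bayesian_cc",
)


@dataclass
class ClassifierSpec:
    method: str = "compound_covariate"
    selection_alpha: float = 0.001
    selection_stat: str = "rvm"  # or "t"

    def __post_init__(self) -> None:
        if self.method not in CLASSIFIER_METHODS:
            raise ValidationError(f"unknown classifier method {self.method!r}")
        if self.selection_stat not in ("rvm", "t"):
            raise ValidationError("selection_stat must be 'rvm' or 't'")


@dataclass
class CvReport:
    """Cross-validation outcome in the shape of a published performance
    table: per-class sensitivity/specificity/PPV/NPV plus the error rate."""

    method: str
    classes: list[str]
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    ppv: dict[str, float]
    npv: dict[str, float]
    error_rate: float
    predictions: list[str]
    true_labels: list[str]
    per_fold_features: list[list] = field(default_factory=list)
    perm_p: float | None = None
    n_permutations: int = 0
    degenerate_folds: int = 0


def select_features(
    X: np.ndarray,
    labels,
    alpha: float = 0.001,
    stat: str = "rvm",
    hyper: RvmHyperparameters | None = None,
):
    """Indices of features differentially expressed between the two
    training classes at level ``alpha``, ordered by p-value.  Also
    returns the per-feature t statistics (used as CCP weights).  An empty
    selection is allowed."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValidationError("feature selection needs exactly 2 classes")
    idx1 = np.flatnonzero(labels == classes[0])
    idx2 = np.flatnonzero(labels == classes[1])
    if stat == "rvm":
        if hyper is None:
            _, _, df, sp2, *_ = pooled_t_stats(X, idx1, idx2)
            hyper = fit_rvm(sp2, df)
        t, p, _ = rvm_t_stats(X, idx1, idx2, hyper)
    else:
        t, p, *_ = pooled_t_stats(X, idx1, idx2)
    chosen = np.flatnonzero(p < alpha)
    chosen = chosen[np.argsort(p[chosen], kind="stable")]
    return chosen, t, p


class _FittedModel:
    """Deterministic two-class model over a fixed feature subset."""

    def __init__(self, spec: ClassifierSpec, features: np.ndarray, classes):
        self.spec = spec
        self.features = features
        self.classes = list(classes)
        self.majority: str | None = None

    def fit(self, X_train: np.ndarray, labels, t_weights=None):
        labels = np.asarray(labels)
        counts = [np.sum(labels == c) for c in self.classes]
        self.majority = self.classes[int(np.argmax(counts))]
        if self.features.size == 0:
            return self
        Xf = X_train[:, self.features]
        m = self.spec.method
        self._mu = np.stack(
            [Xf[labels == c].mean(axis=0) for c in self.classes]
        )
        if m in ("compound_covariate", "bayesian_cc"):
            self._w = t_weights[self.features]
            scores = Xf @ self._w
            s1 = scores[labels == self.classes[0]]
            s2 = scores[labels == self.classes[1]]
            self._score_means = (s1.mean(), s2.mean())
            self._threshold = 0.5 * (s1.mean() + s2.mean())
            if m == "bayesian_cc":
                # per-class score spread; floor avoids zero-width Gaussians
                self._score_sds = (
                    max(s1.std(ddof=1) if s1.size > 1 else 0.0, 1e-12),
                    max(s2.std(ddof=1) if s2.size > 1 else 0.0, 1e-12),
                )
        elif m == "dlda":
            n1 = np.sum(labels == self.classes[0])
            n2 = np.sum(labels == self.classes[1])
            dev = np.concatenate(
                [
                    Xf[labels == self.classes[0]] - self._mu[0],
                    Xf[labels == self.classes[1]] - self._mu[1],
                ]
            )
            df = max(n1 + n2 - 2, 1)
            self._pooled_var = np.maximum((dev**2).sum(axis=0) / df, 1e-12)
        elif m in ("knn1", "knn3"):
            self._train_X = Xf
            self._train_labels = labels
        elif m == "svm_linear":
            self._svm = SVC(kernel="linear", C=1.0, tol=1e-6)
            self._svm.fit(Xf, labels)
        return self

    def predict(self, x: np.ndarray) -> str:
        if self.features.size == 0:
            return self.majority
        xf = np.atleast_2d(x)[:, self.features]
        m = self.spec.method
        if m == "compound_covariate":
            score = float((xf @ self._w)[0])
            m1, m2 = self._score_means
            return (
                self.classes[0]
                if abs(score - m1) < abs(score - m2)
                else self.classes[1]
            )
        if m == "bayesian_cc":
            score = float((xf @ self._w)[0])
            from scipy.stats import norm

            m1, m2 = self._score_means
            s1, s2 = self._score_sds
            logp1 = norm.logpdf(score, m1, s1)
            logp2 = norm.logpdf(score, m2, s2)
            return self.classes[0] if logp1 >= logp2 else self.classes[1]
        if m == "dlda":
            d = ((xf - self._mu[:, None, :]) ** 2 / self._pooled_var).sum(axis=2)
            return self.classes[int(np.argmin(d[:, 0]))]
        if m == "nearest_centroid":
            d = np.linalg.norm(self._mu - xf, axis=1)
            return self.classes[int(np.argmin(d))]
        if m in ("knn1", "knn3"):
            k = 1 if m == "knn1" else 3
            d = np.linalg.norm(self._train_X - xf, axis=1)
            order = np.argsort(d, kind="stable")[:k]
            votes = self._train_labels[order]
            c0 = np.sum(votes == self.classes[0])
            if c0 > k / 2:
                return self.classes[0]
            if c0 < k / 2:
                return self.classes[1]
            return str(votes[0])  # tie -> nearest neighbour's label
        if m == "svm_linear":
            return str(self._svm.predict(xf)[0])
        raise ValidationError(f"unknown method {m!r}")


def train(
    spec: ClassifierSpec, X_train: np.ndarray, labels, features=None, t_weights=None
) -> _FittedModel:
    """Fit a classifier on the training matrix (samples x all features)
    restricted to ``features``.  ``t_weights`` are the per-feature
    training t statistics (needed by the compound-covariate scores)."""
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValidationError("single-class training set")
    if features is None:
        features = np.arange(X_train.shape[1])
    model = _FittedModel(spec, np.asarray(features, dtype=int), classes)
    return model.fit(X_train, labels, t_weights)


def loocv(
    X: np.ndarray,
    labels,
    spec: ClassifierSpec,
    seed: int | None = None,
) -> CvReport:
    """Nested leave-one-out cross-validation with per-fold feature
    reselection.  ``X`` is samples x features; deterministic."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValidationError("two-class prediction only")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValidationError(f"class {c!r} needs >= 2 samples")
    n = X.shape[0]
    predictions: list[str] = []
    fold_features: list[list] = []
    degenerate = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xf = X[keep].T  # features x samples for the selection stats
        feats, t_stats, _ = select_features(
            Xf, labels[keep], alpha=spec.selection_alpha, stat=spec.selection_stat
        )
        if feats.size == 0:
            degenerate += 1
        model = train(spec, X[keep], labels[keep], feats, t_stats)
        predictions.append(model.predict(X[i]))
        fold_features.append(feats.tolist())
    return _report_from_predictions(
        spec.method, classes, predictions, labels.tolist(), fold_features, degenerate
    )


def _report_from_predictions(
    method, classes, predictions, true_labels, fold_features, degenerate
) -> CvReport:
    predictions = list(predictions)
    true_labels = list(true_labels)
    sens, spec_, ppv, npv = {}, {}, {}, {}
    for c in classes:
        tp = sum(p == c and t == c for p, t in zip(predictions, true_labels))
        fn = sum(p != c and t == c for p, t in zip(predictions, true_labels))
        fp = sum(p == c and t != c for p, t in zip(predictions, true_labels))
        tn = sum(p != c and t != c for p, t in zip(predictions, true_labels))
        sens[c] = tp / (tp + fn) if tp + fn else np.nan
        spec_[c] = tn / (tn + fp) if tn + fp else np.nan
        ppv[c] = tp / (tp + fp) if tp + fp else np.nan
        npv[c] = tn / (tn + fn) if tn + fn else np.nan
    errors = sum(p != t for p, t in zip(predictions, true_labels))
    return CvReport(
        method=method,
        classes=list(classes),
        sensitivity=sens,
        specificity=spec_,
        ppv=ppv,
        npv=npv,
        error_rate=errors / len(true_labels),
        predictions=predictions,
        true_labels=true_labels,
        per_fold_features=fold_features,
        degenerate_folds=degenerate,
    )


def permutation_significance(
    X: np.ndarray,
    labels,
    spec: ClassifierSpec,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, CvReport]:
    """Label-permutation significance of the cross-validated error rate.

    p = (1 + #{permutations with CV error <= observed}) / (1 + B);
    the whole nested LOOCV (including reselection) runs per permutation.
    Returns (p, observed report).
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    labels = np.asarray(labels)
    report = loocv(X, labels, spec, seed=seed)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        # permutations can concentrate a class; skip invalid splits as failures
        counts = [np.sum(perm == c) for c in report.classes]
        if min(counts) < 2:
            continue
        rep_b = loocv(X, perm, spec)
        hits += rep_b.error_rate <= report.error_rate + 1e-12
    p = (1.0 + hits) / (1.0 + n_permutations)
    report.perm_p = p
    report.n_permutations = n_permutations
    return p, report
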