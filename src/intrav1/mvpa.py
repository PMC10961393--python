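"""Linear-SVM multivariate pattern analysis of connectivity features.

Two test families: inter-subject *specific* classification with
leave-one-subject-out (LOSO) cross-validation, and within-sample *abstract*
cross-classification where the classifier is trained on one condition pair
(say EG vs EL) and tested on the other (UG vs UL), in both directions, with
the two accuracies averaged.  Feature selection (a per-edge two-sample
t-test at p < 0.01) is always refit inside each training set.  Significance
comes from permutation tests that shuffle training labels only; p-values of
paired tests are combined with Fisher's formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from sklearn.svm import SVC

DEFAULT_ALPHA = 0.01
DEFAULT_C = 1.0
DEFAULT_N_PERM = 1000


@dataclass
class ClassifierModel:
    retained: np.ndarray  # indices into the full edge space
    w: np.ndarray
    b: float
    classes: tuple[str, str]  # decision w.x + b > 0 predicts classes[1]
    C: float = DEFAULT_C

    def predict(self, X: np.ndarray) -> np.ndarray:
        score = X[:, self.retained] @ self.w + self.b
        return np.where(score > 0, self.classes[1], self.classes[0])


@dataclass
class ClassifierResult:
    accuracy: float
    fold_accuracies: np.ndarray | None = None
    direction_accuracies: tuple[float, float] | None = None
    n_permutations: int = 0
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None
    combined_p: float | None = None


@dataclass(frozen=True)
class ConditionPair:
    """One binary contrast: per-subject feature vectors for two conditions.

    ``X[s, k]`` is subject ``s``'s feature vector for condition
    ``conditions[k]``; ``labels[k]`` is the class name used by the
    classifier (e.g. 'Global'/'Local' for a Level contrast).
    """

    subjects: tuple[str, ...]
    conditions: tuple[str, str]
    labels: tuple[str, str]
    X: np.ndarray  # n_subjects x 2 x n_edges

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(samples, labels, subject index) with samples = 2 x n_subjects."""
        n, _, e = self.X.shape
        X = self.X.reshape(n * 2, e)
        y = np.tile(np.asarray(self.labels, dtype=object), n)
        groups = np.repeat(np.arange(n), 2)
        return X, y, groups


def ttest_select(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = True,
) -> np.ndarray:
    """Indices of features whose two-tailed two-sample t-test has p < alpha.

    Features that are constant across all samples have an undefined t and
    are excluded (p treated as 1).  If nothing survives, the single
    smallest-p feature is kept so downstream fits stay defined.
    """
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("feature selection needs exactly two classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 samples")
    if equal_var:
        # inlined Student t-test (hot path inside permutation loops)
        n1, n2 = len(a), len(b)
        v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        df = n1 + n2 - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(
                pooled * (1.0 / n1 + 1.0 / n2)
            )
        p = 2.0 * special.stdtr(df, -np.abs(t))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    retained = np.flatnonzero(p < alpha)
    if retained.size == 0:
        warnings.warn("no feature passed selection; keeping the best one",
                      stacklevel=2)
        retained = np.array([int(np.argmin(p))])
    return retained


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    retained: np.ndarray,
    C: float = DEFAULT_C,
) -> ClassifierModel:
    """Soft-margin linear SVM on the retained features (deterministic)."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 1:
        raise ValueError("training needs samples from two classes")
    if counts.min() < 2 and len(y) < 4:
        raise ValueError("degenerate single-sample class")
    clf = SVC(kernel="linear", C=C)
    clf.fit(X[:, retained], list(y))
    return ClassifierModel(
        retained=np.asarray(retained),
        w=clf.coef_[0].copy(),
        b=float(clf.intercept_[0]),
        classes=tuple(clf.classes_),
        C=C,
    )


def _fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    alpha: float,
    C: float,
) -> float:
    retained = ttest_select(X_train, y_train, alpha=alpha)
    model = train_svm(X_train, y_train, retained, C=C)
    return float(np.mean(model.predict(X_test) == y_test))


def loso_classify(
    pair: ConditionPair,
    alpha: float = DEFAULT_ALPHA,
    C: float = DEFAULT_C,
) -> ClassifierResult:
    """Leave-one-subject-out specific classification.

    Each fold selects features and trains on the remaining 2(n-1) samples
    and tests on the held-out subject's two samples.
    """
    if pair.n_subjects < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    X, y, groups = pair.flat()
    folds = []
    for s in range(pair.n_subjects):
        test = groups == s
        folds.append(_fit_predict(X[~test], y[~test], X[test], y[test], alpha, C))
    folds = np.asarray(folds)
    return ClassifierResult(accuracy=float(folds.mean()), fold_accuracies=folds)


def cross_classify(
    pair_a: ConditionPair,
    pair_b: ConditionPair,
    alpha: float = DEFAULT_ALPHA,
    C: float = DEFAULT_C,
) -> ClassifierResult:
    """Two-direction cross-classification (no cross-validation needed).

    Direction 1 selects and trains on pair A and tests on pair B; direction
    2 swaps the roles; the two accuracies are averaged.
    """
    if pair_a.subjects != pair_b.subjects:
        raise ValueError("the two pairs must hold the same subjects")
    Xa, ya, _ = pair_a.flat()
    Xb, yb, _ = pair_b.flat()
    acc_ab = _fit_predict(Xa, ya, Xb, yb, alpha, C)
    acc_ba = _fit_predict(Xb, yb, Xa, ya, alpha, C)
    return ClassifierResult(
        accuracy=(acc_ab + acc_ba) / 2.0,
        direction_accuracies=(acc_ab, acc_ba),
    )


def _permutation_p(observed: float, null: np.ndarray) -> float:
    return float((1 + np.sum(null >= observed - 1e-12)) / (1 + null.size))


def _flip_pair_labels(
    y: np.ndarray, rng: np.random.Generator, groups: np.ndarray
) -> np.ndarray:
    """Randomly exchange the two condition labels within each subject.

    Respects the paired design (each subject contributes one sample per
    condition), which keeps permuted datasets exchangeable with the
    observed one under the null and hence the permutation p calibrated.
    """
    out = y.copy()
    for g in np.unique(groups):
        if rng.random() < 0.5:
            idx = np.flatnonzero(groups == g)
            out[idx] = out[idx][::-1]
    return out


def permutation_test(
    pair_a: ConditionPair,
    pair_b: ConditionPair | None = None,
    mode: str = "cross",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    C: float = DEFAULT_C,
) -> ClassifierResult:
    """Observed accuracy plus a training-label-randomization null.

    ``mode='cross'`` randomizes only the training labels, in both
    directions, and recomputes the averaged accuracy; ``mode='loso'``
    randomizes the labels within each fold's training set.  Randomization
    exchanges the two condition labels within subjects (see
    ``_flip_pair_labels``), preserving the paired design.  The p-value uses
    the add-one estimator (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    if mode == "cross":
        if pair_b is None:
            raise ValueError("cross mode needs two pairs")
        observed = cross_classify(pair_a, pair_b, alpha=alpha, C=C)
        Xa, ya, ga = pair_a.flat()
        Xb, yb, gb = pair_b.flat()
        null = np.empty(n_perm)
        null_dir = np.empty((n_perm, 2))
        for k in range(n_perm):
            pa = _flip_pair_labels(ya, rng, ga)
            pb = _flip_pair_labels(yb, rng, gb)
            acc1 = _fit_predict(Xa, pa, Xb, yb, alpha, C)
            acc2 = _fit_predict(Xb, pb, Xa, ya, alpha, C)
            null_dir[k] = (acc1, acc2)
            null[k] = (acc1 + acc2) / 2.0
        # the two classifier instances also get their own permutation
        # p-values, combined with Fisher's formula
        p_dirs = [
            _permutation_p(observed.direction_accuracies[d], null_dir[:, d])
            for d in (0, 1)
        ]
        combined = fisher_combine(p_dirs)
    elif mode == "loso":
        observed = loso_classify(pair_a, alpha=alpha, C=C)
        X, y, groups = pair_a.flat()
        null = np.empty(n_perm)
        for k in range(n_perm):
            folds = []
            for s in range(pair_a.n_subjects):
                test = groups == s
                y_tr = _flip_pair_labels(y[~test], rng, groups[~test])
                folds.append(
                    _fit_predict(X[~test], y_tr, X[test], y[test], alpha, C)
                )
            null[k] = float(np.mean(folds))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ClassifierResult(
        accuracy=observed.accuracy,
        fold_accuracies=observed.fold_accuracies,
        direction_accuracies=observed.direction_accuracies,
        n_permutations=n_perm,
        null_accuracies=null,
        p_value=_permutation_p(observed.accuracy, null),
        combined_p=combined if mode == "cross" else None,
    )


def fisher_combine(p_values: list[float], floor: float | None = None) -> float:
    """Fisher's combination: X = -2 sum(ln p) ~ chi-square with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-value clipped before Fisher combination",
                      stacklevel=2)
        p = np.maximum(p, floor if floor is not None else 1e-12)
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * p.size))
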