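"""Supervised NMF: per-class subcommunity extraction plus a linear classifier.

For a labelled count table the types are fitted *separately within each
class* and concatenated, T = (T^(1), ..., T^(g)), so the combined feature
matrix contains each class's own subcommunity signatures.  Every sample is
then projected onto T by non-negative identity-link Poisson regression,
the resulting weight columns are normalized to sum 1 (removing sequencing
depth), and a logistic regression on the normalized weights performs the
classification.  Per-class observation weights (e.g. up-weighting a
minority class) affect only the classifier, never the fitted T and W.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier

from .containers import ClassPartition, CountMatrix, TypeMatrix, WeightMatrix
from .nmf import PoissonNMF
from .regression import transform_samples

__all__ = [
    "SupervisedNMF",
    "SupervisedNMFResults",
    "CrossValidationResult",
    "fit_supervised",
    "crossvalidate",
]

# near-zero ridge: plain logistic regression diverges on separable weight
# matrices, which the method routinely produces
_L2_PENALTY = 1e-8
_MAX_ITER = 1000


def _make_classifier(g: int):
    base = LogisticRegression(C=1.0 / _L2_PENALTY, max_iter=_MAX_ITER)
    return base if g == 2 else OneVsRestClassifier(base)


class SupervisedNMF:
    """Supervised NMF model for a labelled count table.

    Parameters
    ----------
    X : CountMatrix
    part : ClassPartition
        One label per sample; at least two classes.
    k_by_class : mapping class id -> number of types for that class.
    class_weights : mapping class id -> observation weight, optional
        Applied to the logistic classifier (and to weighted CV error),
        not to the factorization.
    epsilon : float
        Re-entry test size for the per-sample weight regressions.
    """

    def __init__(self, X, part, k_by_class, class_weights=None, epsilon: float = 1e-7):
        if not isinstance(X, CountMatrix):
            X = CountMatrix(np.asarray(X))
        if not isinstance(part, ClassPartition):
            part = ClassPartition(np.asarray(part))
        if part.n_samples != X.n_samples:
            raise ValueError(
                f"{part.n_samples} labels for {X.n_samples} samples"
            )
        if part.g < 2:
            raise ValueError("supervised NMF needs at least two classes")
        k_by_class = {str(c): int(k) for c, k in dict(k_by_class).items()}
        if set(k_by_class) != set(part.class_ids):
            raise ValueError(
                f"k_by_class keys {sorted(k_by_class)} != classes {part.class_ids}"
            )
        for c, k in k_by_class.items():
            n_c = part.indices_of(c).size
            if k < 1:
                raise ValueError(f"class {c!r}: k must be >= 1")
            if n_c < k:
                raise ValueError(
                    f"class {c!r} has {n_c} samples but {k} types requested"
                )
        self.X = X
        self.part = part
        self.k_by_class = k_by_class
        self.class_weights = (
            {str(c): float(w) for c, w in dict(class_weights).items()}
            if class_weights else {}
        )
        self.epsilon = float(epsilon)

    @classmethod
    def from_dataframe(cls, counts_df, labels, k_by_class, **kwargs):
        X = CountMatrix.from_dataframe(counts_df)
        labels = np.asarray([labels[s] for s in X.sample_ids]) \
            if hasattr(labels, "__getitem__") and not isinstance(labels, (list, np.ndarray)) \
            else np.asarray(labels)
        return cls(X, ClassPartition(labels), k_by_class, **kwargs)

    def _sample_weights(self) -> np.ndarray:
        return np.asarray(
            [self.class_weights.get(lab, 1.0) for lab in self.part.labels]
        )

    def fit(self, seed: int = 0, n_starts: int = 1, max_iter: int = 2000,
            tol: float = 1e-6) -> "SupervisedNMFResults":
        rng = np.random.default_rng(seed)
        blocks, tags, type_ids = [], [], []
        for c in self.part.class_ids:
            idx = self.part.indices_of(c)
            sub = self.X.select_samples(idx)
            model = PoissonNMF(sub, self.k_by_class[c])
            s = int(rng.integers(2**31 - 1))
            res = (model.fit(seed=s, max_iter=max_iter, tol=tol) if n_starts == 1
                   else model.fit_multistart(n_starts=n_starts, seed=s,
                                             max_iter=max_iter, tol=tol))
            blocks.append(res.T.values)
            tags.extend([c] * self.k_by_class[c])
            type_ids.extend(f"{c}:type{i + 1}" for i in range(self.k_by_class[c]))
        T_combined = TypeMatrix(
            np.hstack(blocks), feature_ids=self.X.feature_ids, type_ids=type_ids
        )
        W_raw, deviances = transform_samples(T_combined, self.X, epsilon=self.epsilon)
        W_norm = W_raw.normalize()
        clf = _make_classifier(self.part.g)
        try:
            clf.fit(W_norm.values.T, self.part.labels,
                    sample_weight=self._sample_weights())
        except TypeError:
            # one-vs-rest wrapper without weight routing (g > 2)
            if self.class_weights:
                warnings.warn(
                    "class weights are not routed to the one-vs-rest "
                    "classifier; fitting unweighted", RuntimeWarning,
                )
            clf.fit(W_norm.values.T, self.part.labels)
        return SupervisedNMFResults(
            model=self, T_combined=T_combined, type_classes=list(tags),
            W_raw=W_raw, W_norm=W_norm, deviances=deviances,
            classifier=clf, seed=int(seed),
        )


@dataclass
class SupervisedNMFResults:
    """Fitted supervised NMF: combined types, training weights, classifier."""

    model: SupervisedNMF
    T_combined: TypeMatrix
    type_classes: list
    W_raw: WeightMatrix
    W_norm: WeightMatrix
    deviances: np.ndarray
    classifier: object
    seed: int

    @property
    def k(self) -> int:
        return self.T_combined.k

    def predict(self, X_new):
        """Classify new samples against the frozen combined types.

        Returns (labels, normalized WeightMatrix); the weights are kept
        for inspection and plotting.
        """
        if not isinstance(X_new, CountMatrix):
            X_new = CountMatrix(np.asarray(X_new))
        W_raw, _ = transform_samples(self.T_combined, X_new, epsilon=self.model.epsilon)
        W_norm = W_raw.normalize()
        labels = np.asarray(self.classifier.predict(W_norm.values.T))
        return labels, W_norm

    def training_error(self, weighted: bool = True) -> float:
        pred = np.asarray(self.classifier.predict(self.W_norm.values.T))
        wrong = (pred != self.model.part.labels).astype(float)
        w = self.model._sample_weights() if weighted else np.ones_like(wrong)
        return float(np.sum(w * wrong) / np.sum(w))

    def summary(self) -> str:
        part = self.model.part
        lines = [
            "Supervised Poisson NMF",
            "=" * 44,
            f"samples:            {part.n_samples}",
            f"classes:            {', '.join(part.class_ids)}",
            "types per class:    " + ", ".join(
                f"{c}={self.model.k_by_class[c]}" for c in part.class_ids
            ),
            f"combined types (k): {self.k}",
            f"training error:     {self.training_error():.4f}",
            f"seed:               {self.seed}",
        ]
        return "\n".join(lines)


def fit_supervised(X, part, k_by_class, seed: int = 0, class_weights=None,
                   epsilon: float = 1e-7, **fit_kwargs) -> SupervisedNMFResults:
    """Functional entry point for ``SupervisedNMF(...).fit(...)``."""
    return SupervisedNMF(
        X, part, k_by_class, class_weights=class_weights, epsilon=epsilon
    ).fit(seed=seed, **fit_kwargs)


@dataclass
class CrossValidationResult:
    fold_test_errors: np.ndarray
    fold_train_errors: np.ndarray
    fold_indices: list
    mean_error: float
    se_error: float

    def summary(self) -> str:
        per_fold = ", ".join(f"{e:.3f}" for e in self.fold_test_errors)
        return (
            f"{len(self.fold_test_errors)}-fold CV test error: "
            f"{self.mean_error:.4f} (SE {self.se_error:.4f})\n"
            f"per fold: [{per_fold}]"
        )


def _fold_assignments(n: int, part: ClassPartition, n_folds: int, scheme: str,
                      rng: np.random.Generator) -> list:
    if scheme == "sequential":
        # contiguous blocks in sample order (time-series splits)
        return [np.sort(a) for a in np.array_split(np.arange(n), n_folds)]
    if scheme != "random":
        raise ValueError(f"unknown fold_scheme {scheme!r}")
    # stratified random folds so every fold sees every class where possible
    folds = [[] for _ in range(n_folds)]
    for c in part.class_ids:
        idx = rng.permutation(part.indices_of(c))
        for pos, i in enumerate(idx):
            folds[pos % n_folds].append(int(i))
    return [np.sort(np.asarray(f, dtype=int)) for f in folds]


def crossvalidate(X, part, k_by_class, n_folds: int, seed: int = 0,
                  fold_scheme: str = "random", class_weights=None,
                  epsilon: float = 1e-7, **fit_kwargs) -> CrossValidationResult:
    """Cross-validated supervised NMF error.

    Types are refitted on the training folds of every split; the held-out
    fold is classified against them.  ``fold_scheme='random'`` draws
    stratified random folds, ``'sequential'`` uses contiguous blocks in
    sample order (for time-indexed series).  With ``class_weights`` the
    reported errors are observation-weighted.
    """
    if not isinstance(X, CountMatrix):
        X = CountMatrix(np.asarray(X))
    if not isinstance(part, ClassPartition):
        part = ClassPartition(np.asarray(part))
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    folds = _fold_assignments(X.n_samples, part, n_folds, fold_scheme, rng)
    cw = dict(class_weights) if class_weights else {}
    test_errors, train_errors, used_folds = [], [], []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(X.n_samples), test_idx)
        train_labels = part.labels[train_idx]
        missing = [c for c in part.class_ids if c not in set(train_labels)]
        feasible = all(
            np.sum(train_labels == c) >= k_by_class[c] for c in part.class_ids
            if c not in missing
        )
        if missing or not feasible or test_idx.size == 0:
            warnings.warn(
                f"fold {f}: class(es) missing or too small in training data; "
                "skipping classifier metrics", RuntimeWarning,
            )
            continue
        fit = SupervisedNMF(
            X.select_samples(train_idx), part.select(train_idx), k_by_class,
            class_weights=cw, epsilon=epsilon,
        ).fit(seed=int(rng.integers(2**31 - 1)), **fit_kwargs)
        pred, _ = fit.predict(X.select_samples(test_idx))
        truth = part.labels[test_idx]
        w = np.asarray([cw.get(lab, 1.0) for lab in truth])
        test_errors.append(float(np.sum(w * (pred != truth)) / np.sum(w)))
        train_errors.append(fit.training_error())
        used_folds.append(test_idx)
    test_errors = np.asarray(test_errors)
    train_errors = np.asarray(train_errors)
    mean = float(test_errors.mean()) if test_errors.size else np.nan
    se = (float(test_errors.std(ddof=1) / np.sqrt(test_errors.size))
          if test_errors.size > 1 else np.nan)
    return CrossValidationResult(
        fold_test_errors=test_errors, fold_train_errors=train_errors,
        fold_indices=used_folds, mean_error=mean, se_error=se,
    )
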