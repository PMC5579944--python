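"""Choosing the number of types per class by cross-validated rank-sum tests.

The number of types k for a class should describe that class well without
also describing the other classes.  For each candidate k, types are
fitted on training folds of the class's own samples; the per-sample
Poisson deviances of the held-out own-class fold and of a paired fold
from the other class(es) are then compared with a Wilcoxon rank-sum test.
A positive standardized statistic Z means the other class fits worse,
i.e. the types are specific to their own class.  The fold statistics are
combined as

    Z_all = (sum of fold Z values) / sqrt(r)

whose standard error is estimated by the *sample* standard deviation of
the fold Z values (not the null value 1: the aim is separation, not a
hypothesis test).  The chosen k is the smallest candidate whose Z_all is
within one such standard deviation of the largest Z_all.

For classes where this curve is not clear-cut, the number of types can be
refined by minimizing cross-validated classification error while holding
the easy classes' k fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import ClassPartition, CountMatrix
from .nmf import PoissonNMF
from .regression import poisson_deviance, fit_weights
from .supervised import crossvalidate

__all__ = ["SelectionReport", "wilcoxon_z", "select_num_types", "refine_by_cv_error"]


def wilcoxon_z(dev_own, dev_other) -> float:
    """Standardized Wilcoxon rank-sum statistic on two deviance samples.

    Pooled deviances are midranked; the rank sum of ``dev_other`` is
    centred by its null mean m(n+m+1)/2 and scaled by the tie-corrected
    null standard deviation.  Z > 0 when the other class's deviances tend
    to be larger (the types describe their own class better).  Returns 0
    when every pooled value is tied.
    """
    own = np.asarray(dev_own, dtype=float).ravel()
    other = np.asarray(dev_other, dtype=float).ravel()
    if own.size == 0 or other.size == 0:
        raise ValueError("both deviance samples must be non-empty")
    n, m = own.size, other.size
    pooled = np.concatenate([own, other])
    ranks = rankdata(pooled)  # midranks for ties (+inf ties rank together)
    w = ranks[n:].sum()
    N = n + m
    mean = m * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 0.0
    return float((w - mean) / np.sqrt(var))


@dataclass
class SelectionReport:
    """Per-k fold Z values, combined Z_all with its SD, and the chosen k."""

    k_grid: list
    z_by_fold: dict
    z_all: dict
    sd_z_all: dict
    chosen_k: int
    r: int

    def summary(self) -> str:
        lines = [
            f"type-number selection ({self.r}-fold CV)",
            "   k      Z_all      sd(Z)",
        ]
        for k in self.k_grid:
            if k in self.z_all:
                mark = " <-- chosen" if k == self.chosen_k else ""
                lines.append(
                    f"  {k:2d}  {self.z_all[k]:9.3f}  {self.sd_z_all[k]:9.3f}{mark}"
                )
            else:
                lines.append(f"  {k:2d}      (infeasible)")
        return "\n".join(lines)


def _folds(n: int, r: int, rng: np.random.Generator) -> list:
    return [np.sort(a) for a in np.array_split(rng.permutation(n), r)]


def _deviances_on(T_vals: np.ndarray, X_cols: np.ndarray, epsilon: float) -> np.ndarray:
    out = np.empty(X_cols.shape[1])
    for j in range(X_cols.shape[1]):
        x = X_cols[:, j]
        res = fit_weights(T_vals, x, epsilon=epsilon)
        out[j] = poisson_deviance(x, T_vals @ res.weights)
    return out


def select_num_types(X_own, X_others, k_grid=None, r: int = 10, seed: int = 0,
                     epsilon: float = 1e-7, max_iter: int = 2000,
                     tol: float = 1e-6) -> SelectionReport:
    """Select the number of types for one class against the other class(es).

    Parameters
    ----------
    X_own : CountMatrix
        Samples of the class whose k is being chosen.
    X_others : CountMatrix or sequence of CountMatrix
        Samples of the remaining class(es); each is split into r folds
        with the same seed and paired fold-for-fold with the own-class
        folds (multi-class deviances are pooled).
    k_grid : candidate numbers of types (default 1..10).
    r : number of cross-validation folds.
    """
    if not isinstance(X_own, CountMatrix):
        X_own = CountMatrix(np.asarray(X_own))
    if isinstance(X_others, CountMatrix) or (
        not isinstance(X_others, (list, tuple))
    ):
        X_others = [X_others]
    X_others = [
        x if isinstance(x, CountMatrix) else CountMatrix(np.asarray(x))
        for x in X_others
    ]
    if k_grid is None:
        k_grid = list(range(1, 11))
    k_grid = sorted(int(k) for k in k_grid)
    if X_own.n_samples < r:
        raise ValueError(f"own class has {X_own.n_samples} samples for {r} folds")

    rng = np.random.default_rng(seed)
    own_folds = _folds(X_own.n_samples, r, np.random.default_rng(seed))
    other_folds = [_folds(x.n_samples, r, np.random.default_rng(seed)) for x in X_others]

    z_by_fold: dict[int, np.ndarray] = {}
    z_all: dict[int, float] = {}
    sd_z_all: dict[int, float] = {}
    for k in k_grid:
        zs = []
        missing = 0
        for f in range(r):
            test_idx = own_folds[f]
            train_idx = np.setdiff1d(np.arange(X_own.n_samples), test_idx)
            if k > min(X_own.n_features, train_idx.size):
                missing += 1
                zs.append(np.nan)
                continue
            fit = PoissonNMF(X_own.select_samples(train_idx), k).fit(
                seed=int(rng.integers(2**31 - 1)), max_iter=max_iter, tol=tol
            )
            Tv = fit.T.values
            dev_own = _deviances_on(Tv, X_own.values[:, test_idx], epsilon)
            dev_other = np.concatenate([
                _deviances_on(Tv, x.values[:, folds[f]], epsilon)
                for x, folds in zip(X_others, other_folds)
            ])
            zs.append(wilcoxon_z(dev_own, dev_other))
        zs = np.asarray(zs)
        if missing > 0.2 * r:
            warnings.warn(f"k={k}: >20% folds infeasible; excluded", RuntimeWarning)
            continue
        valid = zs[~np.isnan(zs)]
        z_by_fold[k] = zs
        z_all[k] = float(valid.sum() / np.sqrt(valid.size))
        sd_z_all[k] = float(valid.std(ddof=1)) if valid.size > 1 else 0.0

    z_all = {k: v for k, v in z_all.items() if np.isfinite(v)}
    if not z_all:
        raise ValueError("no feasible k in the grid")
    ks = sorted(z_all)
    best_k = max(ks, key=lambda k: z_all[k])
    threshold = z_all[best_k] - sd_z_all[best_k]
    chosen = min(k for k in ks if z_all[k] >= threshold)
    return SelectionReport(
        k_grid=k_grid, z_by_fold=z_by_fold, z_all=z_all,
        sd_z_all=sd_z_all, chosen_k=int(chosen), r=r,
    )


def refine_by_cv_error(X, part, fixed_k, k_grid_hard, r: int = 10, seed: int = 0,
                       fold_scheme: str = "random", class_weights=None,
                       epsilon: float = 1e-7) -> int:
    """Refine the hard class's k by minimizing cross-validated error.

    ``fixed_k`` maps the easy class(es) to their chosen numbers of types;
    the single remaining class is swept over ``k_grid_hard``.  Ties (and
    flat error curves) are broken toward the smaller k.
    """
    if not isinstance(part, ClassPartition):
        part = ClassPartition(np.asarray(part))
    fixed_k = {str(c): int(k) for c, k in dict(fixed_k).items()}
    if not fixed_k:
        raise ValueError("at least one class must be fixed")
    hard = [c for c in part.class_ids if c not in fixed_k]
    if len(hard) != 1:
        raise ValueError(
            f"exactly one class may be unfixed; unfixed: {hard}"
        )
    hard = hard[0]
    best_k, best_err = None, np.inf
    for k in sorted(int(k) for k in k_grid_hard):
        k_by_class = dict(fixed_k)
        k_by_class[hard] = k
        cv = crossvalidate(
            X, part, k_by_class, n_folds=r, seed=seed, fold_scheme=fold_scheme,
            class_weights=class_weights, epsilon=epsilon,
        )
        if cv.mean_error < best_err - 1e-12:
            best_k, best_err = k, cv.mean_error
    return int(best_k)
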