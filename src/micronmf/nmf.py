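"""Poisson-likelihood non-negative matrix factorization.

A count table X (p OTUs/genes x n samples) is approximated by the product
T W of a p x k type matrix and a k x n weight matrix, both non-negative.
Each entry X_ij is modelled as an independent Poisson draw with mean
(TW)_ij, so the objective maximized is the Poisson log-likelihood

    L(T, W) = sum_ij [ X_ij log(TW)_ij - (TW)_ij ].

The columns of T are constrained to sum to 1, making each column a
composition over OTUs (a *subcommunity*); the per-sample sequencing depth
is absorbed by W, whose raw columns sum to the corresponding column sums
of X.

Fitting uses the multiplicative updates for the (generalized) KL
divergence, which coincides with the negative Poisson log-likelihood up to
a constant; every sweep ends by renormalizing T's columns to unit sum,
absorbing the scale into W, and rescaling each W column to the sample
depth (the per-column likelihood-optimal scale under unit-sum T), so the
likelihood trace is non-decreasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import CountMatrix, TypeMatrix, WeightMatrix

__all__ = ["PoissonNMF", "PoissonNMFResults", "poisson_loglik", "fit_nmf", "loglik_curve"]

# floor applied to (TW)_ij inside logarithms only; no pseudocounts touch X
_LOG_FLOOR = 1e-12


def poisson_loglik(X, T, W) -> float:
    """Poisson log-likelihood of counts X under mean T @ W.

    Accepts `CountMatrix`/`TypeMatrix`/`WeightMatrix` containers or bare
    arrays.  A term with X_ij = 0 contributes -(TW)_ij even when
    (TW)_ij = 0; a zero mean against a positive count yields -inf.
    """
    Xv = X.values if isinstance(X, CountMatrix) else np.asarray(X, dtype=float)
    Tv = T.values if isinstance(T, TypeMatrix) else np.asarray(T, dtype=float)
    Wv = W.values if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
    if isinstance(W, WeightMatrix) and W.normalized:
        raise ValueError("poisson_loglik expects a raw-scale weight matrix")
    if np.any(Xv < 0) or np.any(Tv < 0) or np.any(Wv < 0):
        raise ValueError("negative entries are not allowed")
    if Tv.shape[0] != Xv.shape[0] or Tv.shape[1] != Wv.shape[0] or Wv.shape[1] != Xv.shape[1]:
        raise ValueError(
            f"dimension mismatch: X {Xv.shape}, T {Tv.shape}, W {Wv.shape}"
        )
    M = Tv @ Wv
    pos = Xv > 0
    if np.any(M[pos] == 0):
        return -np.inf
    out = -M.sum()
    out += float(np.sum(Xv[pos] * np.log(M[pos])))
    return out


def _sweep(X: np.ndarray, T: np.ndarray, W: np.ndarray, depths: np.ndarray):
    """One multiplicative KL update of W then T, with renormalization."""
    # W update (T columns sum to 1, so the denominator T^t 1 is 1)
    M = np.maximum(T @ W, _LOG_FLOOR)
    W = W * (T.T @ (X / M))
    # T update
    M = np.maximum(T @ W, _LOG_FLOOR)
    T = T * ((X / M) @ W.T) / np.maximum(W.sum(axis=1), _LOG_FLOOR)
    # renormalize type columns to unit sum, absorbing scale into W
    scale = T.sum(axis=0)
    scale = np.maximum(scale, _LOG_FLOOR)
    T = T / scale
    W = W * scale[:, None]
    # per-column likelihood-optimal rescale: columns of W sum to depths
    wsum = np.maximum(W.sum(axis=0), _LOG_FLOOR)
    W = W * (depths / wsum)
    return T, W


@dataclass
class PoissonNMFResults:
    """Fitted factorization: T, raw-scale W, and the likelihood trace."""

    model: "PoissonNMF"
    T: TypeMatrix
    W: WeightMatrix
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    seed: int
    converged: bool

    @property
    def k(self) -> int:
        return self.T.k

    def normalized_weights(self) -> WeightMatrix:
        return self.W.normalize()

    def summary(self) -> str:
        lines = [
            "Poisson NMF fit",
            "=" * 40,
            f"features (p):      {self.model.X.n_features}",
            f"samples (n):       {self.model.X.n_samples}",
            f"types (k):         {self.k}",
            f"log-likelihood:    {self.loglik:.4f}",
            f"iterations:        {self.n_iter}" + ("" if self.converged else " (max reached)"),
            f"seed:              {self.seed}",
        ]
        return "\n".join(lines)


class PoissonNMF:
    """Unsupervised Poisson NMF model for a count table.

    Parameters
    ----------
    X : CountMatrix or array-like
        p x n non-negative integer counts.
    k : int
        Number of types (subcommunities), 1 <= k <= min(p, n).

    Examples
    --------
    >>> res = PoissonNMF(counts, k=3).fit(seed=0)
    >>> res.T.to_dataframe()         # subcommunity compositions
    >>> res.normalized_weights()     # per-sample mixing proportions
    """

    def __init__(self, X, k: int):
        if not isinstance(X, CountMatrix):
            X = CountMatrix(np.asarray(X))
        k = int(k)
        if not 1 <= k <= min(X.n_features, X.n_samples):
            raise ValueError(
                f"k={k} out of range [1, {min(X.n_features, X.n_samples)}]"
            )
        self.X = X
        self.k = k

    @classmethod
    def from_dataframe(cls, df, k: int) -> "PoissonNMF":
        return cls(CountMatrix.from_dataframe(df), k)

    def _init_factors(self, rng: np.random.Generator):
        p, n = self.X.values.shape
        # uniform (0, 1] entries, scaled so the initial TW total matches X's
        T = 1.0 - rng.uniform(size=(p, self.k))
        W = 1.0 - rng.uniform(size=(self.k, n))
        T = T / T.sum(axis=0)
        W = W * (self.X.depths / W.sum(axis=0))
        return T, W

    def fit(self, seed: int = 0, max_iter: int = 2000, tol: float = 1e-6) -> PoissonNMFResults:
        """Run multiplicative updates from a seeded random start.

        Convergence is declared when the relative log-likelihood
        improvement over one sweep drops below ``tol``.
        """
        X = self.X.values
        depths = self.X.depths
        rng = np.random.default_rng(seed)
        T, W = self._init_factors(rng)
        trace = [poisson_loglik(X, T, W)]
        converged = False
        for it in range(1, max_iter + 1):
            T, W = _sweep(X, T, W, depths)
            ll = poisson_loglik(X, T, W)
            trace.append(ll)
            prev = trace[-2]
            denom = max(abs(prev), 1.0)
            if abs(ll - prev) / denom < tol:
                converged = True
                break
        T_mat = TypeMatrix(
            T / T.sum(axis=0), feature_ids=self.X.feature_ids,
            type_ids=[f"type{i + 1}" for i in range(self.k)],
        )
        W_mat = WeightMatrix(
            W, normalized=False, type_ids=T_mat.type_ids, sample_ids=self.X.sample_ids
        )
        return PoissonNMFResults(
            model=self, T=T_mat, W=W_mat, loglik=trace[-1],
            loglik_trace=np.asarray(trace), n_iter=len(trace) - 1,
            seed=int(seed), converged=converged,
        )

    def fit_multistart(self, n_starts: int = 10, seed: int = 0, **kwargs) -> PoissonNMFResults:
        """Best-of-``n_starts`` restarts (NMF solutions are not unique)."""
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_starts):
            res = self.fit(seed=int(rng.integers(2**31 - 1)), **kwargs)
            if best is None or res.loglik > best.loglik:
                best = res
        return best


def fit_nmf(X, k: int, seed: int = 0, max_iter: int = 2000, tol: float = 1e-6) -> PoissonNMFResults:
    """Functional entry point: ``PoissonNMF(X, k).fit(...)``."""
    return PoissonNMF(X, k).fit(seed=seed, max_iter=max_iter, tol=tol)


def loglik_curve(X, k_grid, seed: int = 0, n_starts: int = 10, **kwargs) -> dict[int, float]:
    """Best log-likelihood over restarts for each k in ``k_grid``.

    The curve is used to locate the elbow beyond which additional types
    buy little likelihood.  The mapping should be non-decreasing in k
    (larger models nest smaller ones); if restarts are too few for that to
    hold empirically a warning is raised.
    """
    k_grid = [int(k) for k in k_grid]
    if sorted(k_grid) != k_grid:
        raise ValueError("k_grid must be sorted ascending")
    rng = np.random.default_rng(seed)
    out: dict[int, float] = {}
    for k in k_grid:
        model = PoissonNMF(X, k)
        res = model.fit_multistart(n_starts=n_starts, seed=int(rng.integers(2**31 - 1)), **kwargs)
        out[k] = res.loglik
    vals = [out[k] for k in k_grid]
    if any(b < a - 1e-9 * max(1.0, abs(a)) for a, b in zip(vals, vals[1:])):
        warnings.warn(
            "log-likelihood curve is not non-decreasing in k; "
            "increase n_starts for a reliable elbow", RuntimeWarning,
        )
    return out
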