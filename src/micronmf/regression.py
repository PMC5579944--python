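"""Non-negative identity-link Poisson regression of samples on a type matrix.

For a fixed type matrix T (columns summing to 1) and one sample's count
vector x, the mixing weights w >= 0 maximize the Poisson log-likelihood of
x under mean T w, with identity link and no intercept.  The constrained
optimum is found by a backwards-forwards procedure:

1. fit the unconstrained identity-link Poisson regression, initialized
   from the linear least-squares coefficients;
2. eliminate all variables with negative coefficients and refit, until
   every remaining coefficient is positive;
3. record the log-likelihood of the reduced model;
4. test each eliminated variable for re-entry by evaluating the
   likelihood at (w (1 - eps), eps), rescaled so the coefficient sum
   equals the sample depth (with unit-sum T columns the mean total must
   match the count total under the Poisson model);
5. re-admit and refit whenever the likelihood increases; stop when no
   eliminated variable is re-admissible.

Because each re-admission strictly increases the likelihood and there are
finitely many active sets, the loop terminates at a local constrained
maximum whose zero-weight variables all have non-positive likelihood
gradient (the epsilon move is a discrete directional-derivative test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CountMatrix, TypeMatrix, WeightMatrix

__all__ = [
    "NNPRResult",
    "ConvergenceError",
    "fit_weights",
    "poisson_deviance",
    "transform_samples",
]

_LOG_FLOOR = 1e-12
_MU_FLOOR = 1e-10


class ConvergenceError(RuntimeError):
    pass


def _loglik(x: np.ndarray, mu: np.ndarray) -> float:
    """Poisson log-likelihood with the (TW) floor inside the log only."""
    pos = x > 0
    return float(np.sum(x[pos] * np.log(np.maximum(mu[pos], _LOG_FLOOR))) - mu.sum())


def _multiplicative_refine(Ta: np.ndarray, x: np.ndarray, w: np.ndarray,
                           max_iter: int = 2000, tol: float = 1e-12) -> np.ndarray:
    """Polish a non-negative iterate with monotone multiplicative updates.

    The objective is concave in w, so on the non-negative orthant these
    updates converge to the constrained optimum; they are immune to the
    boundary stalling that Newton steps suffer when a fitted mean is
    pinned at zero.
    """
    col = Ta.sum(axis=0)
    w = np.maximum(w, _MU_FLOOR)
    ll = _loglik(x, Ta @ w)
    for _ in range(max_iter):
        mu = np.maximum(Ta @ w, _MU_FLOOR)
        w = w * (Ta.T @ (x / mu)) / np.maximum(col, _MU_FLOOR)
        ll_new = _loglik(x, Ta @ w)
        if ll_new - ll < tol * max(1.0, abs(ll_new)):
            break
        ll = ll_new
    return w


def _fit_unconstrained(Ta: np.ndarray, x: np.ndarray,
                       max_iter: int = 200, tol: float = 1e-9) -> np.ndarray:
    """Identity-link, intercept-free Poisson fit by Fisher scoring.

    Initialized from linear least squares; Newton steps are halved until
    all fitted means are non-negative and the likelihood does not
    decrease.  Coefficients are unconstrained in sign (negative ones are
    handled by the outer elimination loop), but the mean vector is kept
    in the valid region throughout.  If scoring stalls against the
    mean-validity boundary with an all-non-negative iterate, the fit is
    finished by monotone multiplicative updates (the objective is
    concave, so both paths share the same optimum); a stalled iterate
    with negative coefficients is returned as-is — the outer loop only
    needs its sign pattern to eliminate variables.
    """
    p, k = Ta.shape
    w, *_ = np.linalg.lstsq(Ta, x, rcond=None)
    mu = Ta @ w
    if np.any(mu < 0):
        # blend toward a safe interior point until the mean is valid
        w_safe = np.full(k, x.sum() / k)
        for _ in range(60):
            w = 0.5 * w + 0.5 * w_safe
            mu = Ta @ w
            if np.all(mu >= 0):
                break
        else:
            w = w_safe
            mu = Ta @ w
    ll = _loglik(x, mu)
    converged = False
    for _ in range(max_iter):
        mu_f = np.maximum(mu, _MU_FLOOR)
        score = Ta.T @ (x / mu_f - 1.0)
        info = Ta.T @ (Ta / mu_f[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        t = 1.0
        improved = False
        for _ in range(60):
            w_new = w + t * step
            mu_new = Ta @ w_new
            if np.all(mu_new >= 0):
                ll_new = _loglik(x, mu_new)
                if ll_new >= ll:
                    improved = True
                    break
            t *= 0.5
        if not improved:
            converged = True
            break
        delta = ll_new - ll
        w, mu, ll = w_new, mu_new, ll_new
        if delta < tol * max(1.0, abs(ll)):
            converged = True
            break
    if not np.all(np.isfinite(w)):
        raise ConvergenceError(
            f"inner Poisson fit diverged (k={k}, depth={x.sum():.0f})"
        )
    if not converged and np.all(w >= 0):
        w = _multiplicative_refine(Ta, x, w)
    return w


@dataclass
class NNPRResult:
    """Fitted non-negative weights for one sample.

    ``weights`` has length k with zeros for eliminated types; its sum
    equals the sample depth when every T column sums to 1.
    """

    weights: np.ndarray
    active_set: np.ndarray
    loglik: float
    n_outer_iter: int
    loglik_trace: np.ndarray = field(default=None)


def fit_weights(T, x, epsilon: float = 1e-7) -> NNPRResult:
    """Backwards-forwards non-negative Poisson regression of ``x`` on ``T``.

    Parameters
    ----------
    T : TypeMatrix or array of shape (p, k)
    x : count vector of length p with at least one positive entry
    epsilon : float
        Size of the trial coefficient in the re-entry test (step 4).
    """
    Tv = T.values if isinstance(T, TypeMatrix) else np.asarray(T, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != Tv.shape[0]:
        raise ValueError(f"length mismatch: x has {x.shape[0]}, T has {Tv.shape[0]} rows")
    if np.any(x < 0):
        raise ValueError("negative counts")
    depth = x.sum()
    if depth == 0:
        raise ValueError("sample is all zeros; weights are undefined")
    k = Tv.shape[1]

    active = list(range(k))
    trace = []
    n_outer = 0
    while True:
        n_outer += 1
        # steps 1-2: unconstrained fit, batch-drop negative coefficients
        while True:
            w_a = _fit_unconstrained(Tv[:, active], x)
            neg = [active[i] for i in range(len(active)) if w_a[i] < 0]
            if not neg:
                break
            keep = [a for a in active if a not in neg]
            if not keep:
                # T+ can only be empty for a zero sample; keep the best single type
                keep = [active[int(np.argmax(w_a))]]
            active = keep
        # likelihood-optimal rescale: coefficient sum equals sample depth
        total = w_a.sum()
        if not np.isfinite(total) or total <= _LOG_FLOOR:
            # active types share no support with the sample: the constrained
            # MLE is w = 0 (deviance is +inf); an epsilon re-entry test can
            # still move the whole depth onto an overlapping type below
            w_a = np.zeros_like(w_a)
        else:
            w_a = w_a * (depth / total)
        ll = _loglik(x, Tv[:, active] @ w_a)
        if trace and ll <= trace[-1] + 1e-12:
            # a re-admission must strictly improve the refit likelihood;
            # flat progress means we are at the constrained optimum already
            break
        trace.append(ll)
        if n_outer > 2 ** min(k, 16):
            raise ConvergenceError(
                f"backwards-forwards loop exceeded {2 ** min(k, 16)} cycles (k={k})"
            )
        # steps 4-5: epsilon re-entry test, eliminated variables in column order
        removed = sorted(set(range(k)) - set(active))
        readmitted = None
        for v in removed:
            w_trial = np.append(w_a * (1.0 - epsilon), epsilon)
            w_trial *= depth / w_trial.sum()
            mu_trial = Tv[:, active + [v]] @ w_trial
            if _loglik(x, mu_trial) > ll:
                readmitted = v
                break
        if readmitted is None:
            break
        active = sorted(active + [readmitted])

    weights = np.zeros(k)
    weights[active] = w_a
    return NNPRResult(
        weights=weights,
        active_set=np.asarray(active, dtype=int),
        loglik=ll,
        n_outer_iter=n_outer,
        loglik_trace=np.asarray(trace),
    )


def poisson_deviance(x, mu) -> float:
    """Poisson deviance 2 sum[ x log(x/mu) - (x - mu) ], with 0 log 0 = 0.

    The deviance is twice the log-likelihood gap to the saturated model
    (mean = data); smaller means better fit.  A zero mean against a
    positive count gives +inf (flagged, not raised).
    """
    x = np.asarray(x, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    if x.shape != mu.shape:
        raise ValueError("x and mu must have the same length")
    if np.any(mu < 0):
        raise ValueError("negative means")
    if np.any((mu == 0) & (x > 0)):
        return np.inf
    pos = x > 0
    terms = mu - x
    dev = 2.0 * (float(np.sum(x[pos] * np.log(x[pos] / mu[pos]))) + terms.sum())
    return dev


def transform_samples(T, X, epsilon: float = 1e-7):
    """Project every sample of ``X`` onto the fixed types ``T``.

    Each column of X is regressed on T independently (`fit_weights`),
    giving the raw-scale weight matrix; each sample's Poisson deviance
    against its fitted mean T w is returned alongside.

    Returns
    -------
    (WeightMatrix, ndarray of per-sample deviances)
    """
    if not isinstance(X, CountMatrix):
        X = CountMatrix(np.asarray(X))
    if isinstance(T, TypeMatrix):
        if T.feature_ids != X.feature_ids:
            if set(T.feature_ids) == set(X.feature_ids):
                order = [X.feature_ids.index(f) for f in T.feature_ids]
                X = CountMatrix(X.values[order], T.feature_ids, X.sample_ids)
            else:
                missing = sorted(set(T.feature_ids) ^ set(X.feature_ids))
                raise ValueError(f"feature IDs do not match; offending: {missing[:10]}")
        Tv = T.values
        type_ids = T.type_ids
    else:
        Tv = np.asarray(T, dtype=float)
        type_ids = None
        if Tv.shape[0] != X.n_features:
            raise ValueError("feature dimension mismatch between T and X")
    k, n = Tv.shape[1], X.n_samples
    W = np.empty((k, n))
    dev = np.empty(n)
    for j in range(n):
        res = fit_weights(Tv, X.values[:, j], epsilon=epsilon)
        W[:, j] = res.weights
        dev[j] = poisson_deviance(X.values[:, j], Tv @ res.weights)
    W_mat = WeightMatrix(W, normalized=False, type_ids=type_ids, sample_ids=X.sample_ids)
    return W_mat, dev
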