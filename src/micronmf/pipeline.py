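"""End-to-end two-class simulation experiment.

Reproduces the evaluation protocol used throughout the simulation study:
simulate counts for two classes from known type matrices, select the
number of types per class on the training half by the cross-validated
rank-sum procedure, fit the supervised model with the chosen numbers,
and measure the misclassification error on the held-out test half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ClassPartition, CountMatrix
from .selection import select_num_types
from .simulate import NoiseSpec, mislabel, simulate_from_types, simulate_zero_inflated
from .supervised import SupervisedNMF

__all__ = [
    "TwoClassResult",
    "two_class_experiment",
    "holling_recovery_losses",
]


@dataclass
class TwoClassResult:
    chosen_k: dict
    test_error: float
    train_error: float
    n_train_per_class: int
    n_test_per_class: int

    def summary(self) -> str:
        ks = ", ".join(f"{c}={k}" for c, k in self.chosen_k.items())
        return (
            f"chosen types: {ks}; "
            f"train error {self.train_error:.4f}, test error {self.test_error:.4f}"
        )


def two_class_experiment(T_by_class, depth: float = 5000.0,
                         n_per_class: int = 200, snr: float = np.inf,
                         k_grid=None, r: int = 10, seed: int = 0,
                         zero_inflated: bool = False, alpha: float = 0.005,
                         mislabel_fraction: float = 0.0,
                         epsilon: float = 1e-7) -> TwoClassResult:
    """Simulate, select k per class, fit supervised NMF, score test error.

    ``T_by_class`` maps class id -> true TypeMatrix.  For each class,
    ``n_per_class`` samples are generated (the first half is training
    data, the second half test data) at the given sequencing depth and
    SNR.  ``zero_inflated=True`` swaps the uniform weight sampler for the
    Dirichlet(alpha) sampler; ``mislabel_fraction`` flips that fraction
    of *training* labels (outlier scenario).
    """
    if k_grid is None:
        k_grid = list(range(1, 6))
    class_ids = list(T_by_class)
    if len(class_ids) != 2:
        raise ValueError("two classes required")
    rng = np.random.default_rng(seed)
    n_half = n_per_class // 2
    train_parts, test_parts = {}, {}
    for c in class_ids:
        T = T_by_class[c]
        col_sums = np.full(n_per_class, float(depth))
        noise = NoiseSpec.from_types(T, snr)
        sim_seed = int(rng.integers(2**31 - 1))
        if zero_inflated:
            X, _ = simulate_zero_inflated(T, col_sums, alpha=alpha,
                                          noise=noise, seed=sim_seed)
        else:
            X, _ = simulate_from_types(T, col_sums, noise=noise, seed=sim_seed)
        train_parts[c] = X.select_samples(np.arange(n_half))
        test_parts[c] = X.select_samples(np.arange(n_half, n_per_class))

    chosen = {}
    for c in class_ids:
        others = [train_parts[o] for o in class_ids if o != c]
        report = select_num_types(
            train_parts[c], others, k_grid=k_grid, r=r,
            seed=int(rng.integers(2**31 - 1)), epsilon=epsilon,
        )
        chosen[c] = report.chosen_k

    X_train = CountMatrix(
        np.hstack([train_parts[c].values for c in class_ids]),
        feature_ids=train_parts[class_ids[0]].feature_ids,
    )
    labels_train = np.concatenate([[c] * n_half for c in class_ids])
    if mislabel_fraction > 0:
        labels_train = mislabel(labels_train, mislabel_fraction,
                                seed=int(rng.integers(2**31 - 1)))
        # keep every class large enough for its chosen type count
        part_try = ClassPartition(labels_train)
        for c in class_ids:
            chosen[c] = min(chosen[c], part_try.indices_of(c).size)
    fit = SupervisedNMF(
        X_train, ClassPartition(labels_train), chosen, epsilon=epsilon
    ).fit(seed=int(rng.integers(2**31 - 1)))

    X_test = CountMatrix(
        np.hstack([test_parts[c].values for c in class_ids]),
        feature_ids=test_parts[class_ids[0]].feature_ids,
    )
    labels_test = np.concatenate([[c] * (n_per_class - n_half) for c in class_ids])
    pred, _ = fit.predict(X_test)
    return TwoClassResult(
        chosen_k=chosen,
        test_error=float(np.mean(pred != labels_test)),
        train_error=fit.training_error(weighted=False),
        n_train_per_class=n_half,
        n_test_per_class=n_per_class - n_half,
    )


def _nmf_candidate_clusters(T_values: np.ndarray) -> list:
    """Threshold-swept candidate clusters from fitted types.

    For each type, every 'top-j most abundant OTUs' set is a candidate
    cluster (sweeping an abundance threshold over the type's sorted
    values produces exactly these nested sets).
    """
    seen, out = set(), []
    p, k = T_values.shape
    for c in range(k):
        order = np.argsort(-T_values[:, c])
        for j in range(1, p + 1):
            s = frozenset(int(i) for i in order[:j])
            if s not in seen:
                seen.add(s)
                out.append(set(s))
    return out


def _cooccurrence_candidate_clusters(table, n_features: int) -> list:
    """Connected components across all significance levels, plus singletons
    (a subcommunity may be best approximated by one isolated node)."""
    import networkx as nx

    seen, out = set(), []
    levels = sorted(set(table.loc[table["qvalue"] < 1, "qvalue"]))
    for level in levels:
        sub = table[table["qvalue"] <= level]
        g = nx.Graph()
        g.add_edges_from(zip(sub["i"], sub["j"]))
        for comp in nx.connected_components(g):
            s = frozenset(int(i) for i in comp)
            if s not in seen:
                seen.add(s)
                out.append(set(s))
    for i in range(n_features):
        s = frozenset([i])
        if s not in seen:
            seen.add(s)
            out.append(set(s))
    return out


def holling_recovery_losses(X, true_clusters, k_types: int = 4, seed: int = 0,
                            n_perm: int = 1000):
    """Subcommunity-recovery losses of NMF types vs co-occurrence network.

    Fits ``k_types`` NMF types to the abundance table, forms candidate
    clusters by sweeping an abundance threshold over each type, and
    minimizes the recovery loss over unions of candidates for every true
    subcommunity.  The co-occurrence baseline forms its candidates from
    the connected components of the permutation-tested correlation
    network across all significance levels.

    Returns (nmf_losses, cooccurrence_losses): one loss per true cluster.
    """
    from .nmf import PoissonNMF
    from .simulate import cooccurrence_network, optimal_loss

    res = PoissonNMF(X, k_types).fit(seed=seed)
    nmf_candidates = _nmf_candidate_clusters(res.T.values)
    table = cooccurrence_network(X, n_perm=n_perm, seed=seed + 1)
    net_candidates = _cooccurrence_candidate_clusters(table, X.n_features)
    nmf_losses, net_losses = [], []
    for cluster in true_clusters:
        loss_nmf, _ = optimal_loss(set(cluster), nmf_candidates)
        loss_net, _ = optimal_loss(set(cluster), net_candidates)
        nmf_losses.append(loss_nmf)
        net_losses.append(loss_net)
    return nmf_losses, net_losses
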