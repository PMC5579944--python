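"""Synthetic data generators and the ecological benchmark suite.

Covers five study designs used to evaluate the NMF toolkit:

* the NMF-generative sampler: Poisson counts around a mean T W, with
  optional Gaussian perturbation of the mean calibrated to a
  signal-to-noise ratio (SNR) against the per-row spread of T;
* a zero-inflated variant drawing the weights from a symmetric
  Dirichlet with very small concentration;
* outlier generation by mislabelling a fraction of training samples;
* two-class multinomial mixtures of a pair of base compositions with a
  controllable effect size (a clustering benchmark);
* a Holling type II community-dynamics simulator over an interaction
  network with ground-truth subcommunities, together with the
  subcommunity-recovery loss and a permutation-tested co-occurrence
  network baseline.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, rankdata

from .containers import ClassPartition, CountMatrix, TypeMatrix, WeightMatrix

__all__ = [
    "NoiseSpec",
    "MixtureSpec",
    "HollingSystem",
    "random_sparse_types",
    "related_class_types",
    "simulate_from_types",
    "simulate_zero_inflated",
    "mislabel",
    "simulate_mixture_classes",
    "default_edge_plan",
    "build_holling_network",
    "simulate_holling",
    "subcommunity_loss",
    "optimal_loss",
    "cooccurrence_network",
    "network_components",
]


# --------------------------------------------------------------------------
# NMF-generative samplers
# --------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """Gaussian perturbation of the Poisson mean, calibrated by SNR.

    ``sd_vector`` holds one standard deviation per feature row: the
    sample SD of that row of T across types, divided by the SNR
    (4, 2 or 1).  SNR = inf means no perturbation.
    """

    snr: float
    sd_vector: np.ndarray

    def __post_init__(self):
        self.sd_vector = np.asarray(self.sd_vector, dtype=float)
        if np.isinf(self.snr) and np.any(self.sd_vector != 0):
            raise ValueError("snr=inf requires an all-zero sd_vector")

    @classmethod
    def from_types(cls, T, snr: float) -> "NoiseSpec":
        Tv = T.values if isinstance(T, TypeMatrix) else np.asarray(T, dtype=float)
        if np.isinf(snr):
            return cls(snr=np.inf, sd_vector=np.zeros(Tv.shape[0]))
        if snr <= 0:
            raise ValueError("snr must be positive")
        sd = Tv.std(axis=1, ddof=1) if Tv.shape[1] > 1 else np.zeros(Tv.shape[0])
        return cls(snr=float(snr), sd_vector=sd / float(snr))


def random_sparse_types(p: int, k: int, fraction_nonzero: float = 0.2,
                        seed: int = 0) -> TypeMatrix:
    """Sparse synthetic type matrix: each column a composition supported on
    a random ~``fraction_nonzero`` subset of the p features.

    Mimics the sparsity of types fitted to real metagenomes, where each
    subcommunity concentrates its mass on a small group of OTUs/genes.
    """
    rng = np.random.default_rng(seed)
    n_active = max(2, int(round(fraction_nonzero * p)))
    T = np.zeros((p, k))
    for c in range(k):
        support = rng.choice(p, size=n_active, replace=False)
        T[support, c] = rng.gamma(shape=1.0, size=n_active)
    T /= T.sum(axis=0)
    return TypeMatrix(T, type_ids=[f"type{i + 1}" for i in range(k)])


def related_class_types(p: int, ks, seed: int = 0, sigma_pool: float = 1.5,
                        anchor_weight: float = 0.65,
                        sigma_jitter: float = 0.1) -> list:
    """Per-class type matrices sharing a latent subcommunity pool.

    Emulates the structure of types fitted separately to two classes of
    real metagenomes (e.g. healthy vs diseased gut): the classes share
    most of their community building blocks, and each class's types are
    variations within that shared space rather than disjoint profiles.

    A pool of ``max(ks)`` heavy-tailed latent profiles (log-normal
    ``sigma_pool`` across features) is drawn once.  Each class anchors
    its k types on a random subset of pool profiles: a type mixes
    ``anchor_weight`` of its anchor with a Dirichlet-weighted blend of
    the whole pool, then receives a small class/type-specific log-normal
    distortion (``sigma_jitter``).  Within-class types are therefore
    well separated (distinct anchors) while between-class differences
    are modest — the regime in which the number of types is genuinely
    informative (a single fitted type does not already separate the
    classes totally).

    Returns one TypeMatrix per entry of ``ks``.
    """
    rng = np.random.default_rng(seed)
    ks = [int(k) for k in ks]
    L = max(ks)
    pool = np.exp(rng.normal(0.0, sigma_pool, size=(p, L)))
    pool /= pool.sum(axis=0)
    out = []
    for k in ks:
        anchors = rng.permutation(L)[:k]
        T = np.zeros((p, k))
        for c, a in enumerate(anchors):
            alpha = (1.0 - anchor_weight) * rng.dirichlet(np.ones(L))
            alpha[a] += anchor_weight
            base = pool @ alpha
            T[:, c] = base * np.exp(rng.normal(0.0, sigma_jitter, size=p))
        T /= T.sum(axis=0)
        out.append(TypeMatrix(T, type_ids=[f"type{i + 1}" for i in range(k)]))
    return out


def _poisson_counts(T, W, noise, rng):
    Tv = T.values if isinstance(T, TypeMatrix) else np.asarray(T, dtype=float)
    M = Tv @ W
    if noise is not None and not np.isinf(noise.snr):
        M = M + rng.normal(0.0, noise.sd_vector[:, None], size=M.shape)
        M = np.maximum(M, 0.0)  # a Poisson mean cannot be negative
    X = rng.poisson(M).astype(float)
    # a zero-depth sample carries no information; give it one pseudo-read
    zero_cols = np.flatnonzero(X.sum(axis=0) == 0)
    for j in zero_cols:
        X[int(np.argmax(M[:, j])), j] = 1
    return X


def simulate_from_types(T, col_sums, noise: NoiseSpec | None = None, seed: int = 0):
    """Counts from the NMF generative model with uniform random weights.

    W entries are drawn U(0, 1) and each column scaled to the requested
    total (sequencing depth); the Poisson mean is T W plus optional
    Gaussian noise (clamped at 0).  Returns (CountMatrix, true raw W).
    """
    Tv = T.values if isinstance(T, TypeMatrix) else np.asarray(T, dtype=float)
    col_sums = np.asarray(col_sums, dtype=float).ravel()
    if np.any(col_sums <= 0):
        raise ValueError("column sums must be positive")
    rng = np.random.default_rng(seed)
    k, n = Tv.shape[1], col_sums.size
    W = rng.uniform(size=(k, n))
    W *= col_sums / W.sum(axis=0)
    X = _poisson_counts(T, W, noise, rng)
    return CountMatrix(X), WeightMatrix(W)


def simulate_zero_inflated(T, col_sums, alpha: float = 0.005,
                           noise: NoiseSpec | None = None, seed: int = 0):
    """As `simulate_from_types` but with Dirichlet(alpha, ..., alpha) weights.

    A tiny concentration (default 0.005) puts nearly all of each
    sample's depth on very few types, inflating the fraction of zero
    counts towards what real metagenomes show.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    Tv = T.values if isinstance(T, TypeMatrix) else np.asarray(T, dtype=float)
    col_sums = np.asarray(col_sums, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    k, n = Tv.shape[1], col_sums.size
    W = np.empty((k, n))
    for j in range(n):
        # gamma draws at tiny shape underflow to exact zeros, which is the
        # intended sparsity; only an all-zero draw is redrawn
        g = rng.gamma(alpha, size=k)
        while g.sum() == 0:
            g = rng.gamma(alpha, size=k)
        W[:, j] = g / g.sum() * col_sums[j]
    X = _poisson_counts(T, W, noise, rng)
    return CountMatrix(X), WeightMatrix(W)


def mislabel(labels, fraction: float, seed: int = 0) -> np.ndarray:
    """Flip a uniformly random subset of binary labels (outlier generation).

    Exactly ``round(fraction * n)`` labels are flipped, drawn without
    replacement.  Only two-class label vectors are supported.
    """
    labels = np.asarray(labels)
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"mislabel requires binary labels; got {classes}")
    rng = np.random.default_rng(seed)
    n_flip = int(round(fraction * labels.size))
    idx = rng.choice(labels.size, size=n_flip, replace=False)
    out = labels.copy()
    a, b = classes
    out[idx] = np.where(labels[idx] == a, b, a)
    return out


@dataclass
class MixtureSpec:
    """Two-class effect-size mixture of two base compositions.

    Class A mixes the bases in the ratio 1 : s_e, class B in s_e : 1;
    s_e = 1 makes the classes identical.
    """

    p_base1: np.ndarray
    p_base2: np.ndarray
    effect_size: float
    depth: int = 10000
    n_per_class: int = 200

    def __post_init__(self):
        self.p_base1 = np.asarray(self.p_base1, dtype=float).ravel()
        self.p_base2 = np.asarray(self.p_base2, dtype=float).ravel()
        for name, p in (("p_base1", self.p_base1), ("p_base2", self.p_base2)):
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} must be a probability vector")
        if self.p_base1.size != self.p_base2.size:
            raise ValueError("base vectors must have equal length")
        if self.effect_size < 1:
            raise ValueError("effect size must be >= 1")


def simulate_mixture_classes(spec: MixtureSpec, seed: int = 0):
    """Multinomial samples for the two mixture classes.

    Returns (CountMatrix, ClassPartition) with ``n_per_class`` samples
    per class, each of total depth ``spec.depth``.
    """
    rng = np.random.default_rng(seed)
    s = spec.effect_size
    prob_a = (spec.p_base1 + s * spec.p_base2) / (1.0 + s)
    prob_b = (s * spec.p_base1 + spec.p_base2) / (1.0 + s)
    cols, labels = [], []
    for label, prob in (("A", prob_a), ("B", prob_b)):
        draws = rng.multinomial(spec.depth, prob, size=spec.n_per_class)
        cols.append(draws.T)
        labels.extend([label] * spec.n_per_class)
    X = np.hstack(cols).astype(float)
    return CountMatrix(X), ClassPartition(np.asarray(labels))


# --------------------------------------------------------------------------
# Holling type II community dynamics
# --------------------------------------------------------------------------

_B_RANGES = {
    "black": (0.0, 0.008),
    "blue": (-0.002, 0.008),
    "red": (-0.08, 0.0),
}


@dataclass
class HollingSystem:
    """Interaction network and parameters for the Holling type II model.

    Per-sample dynamics for OTU abundances M follow

        dM_i/dt = M_i ( r_i (1 - c_i M_i)
                        + sum_{j != i} b_ij a_ij M_j / (1 + a_ij TH_ij M_j) )

    with intrinsic growth r_i, intraspecific regulation c_i (1/c_i is the
    carrying capacity in isolation), attack rate a_ij, handling time
    TH_ij and interaction coefficient b_ij.  The saturating interaction
    caps the influence of any one OTU at b_ij / TH_ij, which is what lets
    overlapping subcommunities mix approximately additively.
    """

    n_otus: int
    edges: list                       # (i, j, color) undirected pairs
    b: np.ndarray                     # (n, n) interaction coefficients
    a: np.ndarray                     # (n, n) attack rates
    th: np.ndarray                    # (n, n) handling times
    clusters: list                    # ground-truth subcommunity index sets
    dt: float = 0.001
    n_steps: int = 1_000_000


def default_edge_plan(cluster_blocks, within_links: int = 2, n_blue: int = 6,
                      n_red: int = 3, n_otus: int | None = None,
                      seed: int = 0) -> list:
    """Sparse edge plan: circulant black wiring inside each cluster plus a
    few facilitative (blue) and inhibitory (red) between-cluster edges.

    ``cluster_blocks`` are (start, stop) index ranges that may overlap
    (overlapping indices belong to both subcommunities).  Each cluster
    member links to its ``within_links`` nearest followers around the
    cluster ring, giving mean degree ~2*within_links.  Sparse wiring
    keeps the summed saturating interactions (each capped near b/TH)
    small enough that the Euler-discretized dynamics relax to stable
    equilibria instead of oscillating; dense wiring pushes the per-step
    relaxation factor past the stability limit.
    """
    rng = np.random.default_rng(seed)
    plan = {}
    members = [set(range(a, b)) for a, b in cluster_blocks]
    for block in members:
        ring = sorted(block)
        size = len(ring)
        for idx, i in enumerate(ring):
            for d in range(1, within_links + 1):
                j = ring[(idx + d) % size]
                if i != j:
                    plan[(min(i, j), max(i, j))] = "black"
    if n_otus is None:
        n_otus = (max(max(b) for b in members) + 1) if members else 0
    covered = set().union(*members) if members else set()
    candidates = [
        (i, j) for i in range(n_otus) for j in range(i + 1, n_otus)
        if (i, j) not in plan and (i in covered or j in covered)
    ]
    rng.shuffle(candidates)
    for pair in candidates[:n_blue]:
        plan[pair] = "blue"
    for pair in candidates[n_blue:n_blue + n_red]:
        plan[pair] = "red"
    return [(i, j, color) for (i, j), color in sorted(plan.items())]


def build_holling_network(cluster_blocks, isolated: int = 4, edge_plan=None,
                          seed: int = 0) -> HollingSystem:
    """Draw interaction parameters for a clustered Holling network.

    ``b_ij`` is uniform on the edge-color range (both directions drawn
    independently); handling times follow 1/TH ~ 1e5 * Beta(5, 1);
    attack rates default to 1.  Ground-truth subcommunities are the
    cluster blocks; ``isolated`` extra OTUs interact with nobody.
    """
    rng = np.random.default_rng(seed)
    members = [set(range(a, b)) for a, b in cluster_blocks]
    n_otus = ((max(max(b) for b in members) + 1) if members else 0) + isolated
    if edge_plan is None:
        edge_plan = default_edge_plan(
            cluster_blocks, n_otus=n_otus - isolated, seed=seed
        )
    seen = {}
    for i, j, color in edge_plan:
        key = (min(i, j), max(i, j))
        if key in seen and seen[key] != color:
            raise ValueError(f"pair {key} assigned both {seen[key]} and {color}")
        seen[key] = color
    b = np.zeros((n_otus, n_otus))
    a = np.zeros((n_otus, n_otus))
    th = np.zeros((n_otus, n_otus))
    for (i, j), color in seen.items():
        lo, hi = _B_RANGES[color]
        for (s, t) in ((i, j), (j, i)):
            b[s, t] = rng.uniform(lo, hi)
            a[s, t] = 1.0
            th[s, t] = 1.0 / (1e5 * rng.beta(5, 1))
    edges = [(i, j, color) for (i, j), color in sorted(seen.items())]
    return HollingSystem(
        n_otus=n_otus, edges=edges, b=b, a=a, th=th,
        clusters=[sorted(m) for m in members],
    )


def simulate_holling(system: HollingSystem, n_samples: int, seed: int = 0,
                     n_steps: int | None = None, dt: float | None = None,
                     m0_range: tuple = (0.1, 10.0), max_redraws: int = 20,
                     growth=None, self_limit=None, m0=None):
    """Integrate the Holling dynamics to generate abundance samples.

    Each sample draws its own environment: r_i ~ U(0, 1) and
    1/c_i - 1 ~ 99 * Beta(1, 2); initial abundances are U(0.1, 10).
    ``growth`` / ``self_limit`` / ``m0`` (length n_otus) override the
    random draws with fixed per-OTU values shared by all samples.
    Explicit Euler integration runs ``n_steps`` steps of size ``dt``
    (defaults from the system); abundances are floored at 0 if a step
    undershoots.  Diverging samples (any abundance above 1e12) are
    flagged and redrawn.

    Returns (CountMatrix of rounded final abundances, (r, c) arrays of
    shape (n_otus, n_samples)).
    """
    rng = np.random.default_rng(seed)
    n_steps = int(n_steps if n_steps is not None else system.n_steps)
    dt = float(dt if dt is not None else system.dt)
    if dt <= 0 or n_steps < 1:
        raise ValueError("dt must be positive and n_steps >= 1")
    n = system.n_otus

    # directed edge arrays + incidence for a vectorized interaction term
    dst, src = np.nonzero(system.b)
    b_e = system.b[dst, src]
    ath_e = system.a[dst, src] * system.th[dst, src]
    a_e = system.a[dst, src]
    inc = np.zeros((n, dst.size))
    inc[dst, np.arange(dst.size)] = 1.0

    def integrate(R, C, M0):
        M = M0.copy()
        for _ in range(n_steps):
            Mj = M[src, :]
            interact = inc @ (b_e[:, None] * a_e[:, None] * Mj
                              / (1.0 + ath_e[:, None] * Mj))
            M = M + dt * M * (R * (1.0 - C * M) + interact)
            np.maximum(M, 0.0, out=M)
            if np.any(M > 1e12):
                return M, False
        return M, True

    def draw(count):
        if growth is None:
            R = rng.uniform(0.0, 1.0, size=(n, count))
        else:
            R = np.tile(np.asarray(growth, dtype=float)[:, None], (1, count))
        if self_limit is None:
            C = 1.0 / (1.0 + 99.0 * rng.beta(1.0, 2.0, size=(n, count)))
        else:
            C = np.tile(np.asarray(self_limit, dtype=float)[:, None], (1, count))
        if m0 is None:
            M0 = rng.uniform(*m0_range, size=(n, count))
        else:
            M0 = np.tile(np.asarray(m0, dtype=float)[:, None], (1, count))
        return R, C, M0

    R, C, M0 = draw(n_samples)
    M, ok = integrate(R, C, M0)
    redraws = 0
    while not ok or np.any(M.sum(axis=0) < 0.5):
        bad = np.flatnonzero((M > 1e12).any(axis=0) | (M.sum(axis=0) < 0.5))
        redraws += 1
        if redraws > max_redraws:
            raise RuntimeError("too many diverging/empty samples; check parameters")
        warnings.warn(
            f"redrawing {bad.size} diverging or empty sample(s)", RuntimeWarning
        )
        Rb, Cb, Mb = draw(bad.size)
        Mnew, ok = integrate(Rb, Cb, Mb)
        M[:, bad] = Mnew
        R[:, bad], C[:, bad] = Rb, Cb
        ok = ok and not np.any(M.sum(axis=0) < 0.5)
    X = np.round(M)
    return CountMatrix(X), (R, C)


# --------------------------------------------------------------------------
# Subcommunity-recovery loss
# --------------------------------------------------------------------------

def subcommunity_loss(true_set, union_clusters) -> int:
    """Loss of approximating a true subcommunity by a union of clusters.

    One point for each member missing from the union, one for each
    non-member included, and one for every cluster beyond the first.
    """
    true = set(true_set)
    union = set().union(*[set(c) for c in union_clusters]) if union_clusters else set()
    extra_clusters = max(len(union_clusters) - 1, 0)
    return len(true - union) + len(union - true) + extra_clusters


def _bits(s, index):
    out = 0
    for e in s:
        out |= 1 << index[e]
    return out


def optimal_loss(true_set, candidate_clusters, beam_width: int = 100):
    """Minimum subcommunity loss over unions of candidate clusters.

    Exhaustive over all subsets when there are at most 20 candidates;
    otherwise a beam search (default width 100) with a warning.  Returns
    (loss, chosen list of clusters).
    """
    candidates = [frozenset(c) for c in candidate_clusters]
    universe = sorted(set(true_set).union(*candidates) if candidates else set(true_set))
    index = {e: i for i, e in enumerate(universe)}
    true_bits = _bits(true_set, index)
    n_true = len(set(true_set))
    cand_bits = [_bits(c, index) for c in candidates]

    def loss_of(union_bits: int, count: int) -> int:
        return (
            bin(true_bits & ~union_bits).count("1")
            + bin(union_bits & ~true_bits).count("1")
            + max(count - 1, 0)
        )

    f = len(candidates)
    if f == 0:
        return n_true, []
    if f <= 20:
        best_loss, best_mask = n_true, 0
        unions = [0] * (1 << f)
        for mask in range(1, 1 << f):
            lsb = mask & -mask
            unions[mask] = unions[mask ^ lsb] | cand_bits[lsb.bit_length() - 1]
            loss = loss_of(unions[mask], mask.bit_count())
            if loss < best_loss:
                best_loss, best_mask = loss, mask
        chosen = [set(candidates[i]) for i in range(f) if best_mask >> i & 1]
        return best_loss, chosen
    warnings.warn(
        f"{f} candidate clusters: falling back to beam search "
        f"(width {beam_width}); result may be suboptimal", RuntimeWarning,
    )
    # beam over partial unions, candidates in decreasing-overlap order
    order = sorted(
        range(f),
        key=lambda i: -(bin(cand_bits[i] & true_bits).count("1")
                        - bin(cand_bits[i] & ~true_bits).count("1")),
    )
    beam = {(0, 0): 0}  # (union_bits, count) -> mask placeholder
    best_loss, best_masks = n_true, []
    chosen_sets = {(0, 0): []}
    for i in order:
        new_beam = dict(beam)
        new_sets = dict(chosen_sets)
        for (ub, cnt), _ in beam.items():
            nub = ub | cand_bits[i]
            key = (nub, cnt + 1)
            if key not in new_beam:
                new_beam[key] = 0
                new_sets[key] = chosen_sets[(ub, cnt)] + [i]
        scored = sorted(new_beam, key=lambda key: loss_of(*key))[:beam_width]
        beam = {key: 0 for key in scored}
        chosen_sets = {key: new_sets[key] for key in scored}
    best_key = min(beam, key=lambda key: loss_of(*key))
    best_loss = loss_of(*best_key)
    chosen = [set(candidates[i]) for i in chosen_sets[best_key]]
    return best_loss, chosen


# --------------------------------------------------------------------------
# Co-occurrence network baseline
# --------------------------------------------------------------------------

def cooccurrence_network(X, n_perm: int = 1000, fdr_level: float = 0.05,
                         seed: int = 0, method: str = "spearman") -> pd.DataFrame:
    """Permutation-tested pairwise correlation network over features.

    For every feature pair the observed correlation is compared against a
    null built by permuting one member ``n_perm`` times; the two-sided
    empirical p-value (#{|null| >= |obs|} + 1) / (n_perm + 1) is corrected
    across all pairs by Benjamini-Hochberg.  Constant features yield
    p = 1 for all their pairs.

    Returns a DataFrame with columns feature_i, feature_j, corr, pvalue,
    qvalue, significant (at ``fdr_level``).
    """
    if not isinstance(X, CountMatrix):
        X = CountMatrix(np.asarray(X))
    vals = X.values
    p, n = vals.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if method == "spearman":
        data = np.apply_along_axis(rankdata, 1, vals)
    elif method == "pearson":
        data = vals.astype(float)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    sd = data.std(axis=1)
    constant = sd == 0
    Z = np.zeros_like(data)
    ok = ~constant
    Z[ok] = (data[ok] - data[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    corr = (Z @ Z.T) / n

    rng = np.random.default_rng(seed)
    rows = []
    for j in range(1, p):
        if constant[j]:
            null_corr = None
        else:
            perms = np.stack([rng.permutation(Z[j]) for _ in range(n_perm)])
            null_corr = (perms @ Z[:j].T) / n  # (n_perm, j)
        for i in range(j):
            if constant[i] or constant[j]:
                rows.append((i, j, np.nan, 1.0))
                continue
            obs = corr[i, j]
            exceed = int(np.sum(np.abs(null_corr[:, i]) >= abs(obs)))
            rows.append((i, j, obs, (exceed + 1) / (n_perm + 1)))
    table = pd.DataFrame(rows, columns=["i", "j", "corr", "pvalue"])
    table["qvalue"] = false_discovery_control(table["pvalue"].to_numpy(), method="bh")
    table["significant"] = table["qvalue"] <= fdr_level
    table.insert(0, "feature_i", [X.feature_ids[i] for i in table["i"]])
    table.insert(1, "feature_j", [X.feature_ids[j] for j in table["j"]])
    return table


def network_components(table: pd.DataFrame, level: float, n_features: int | None = None):
    """Connected components of the co-occurrence network at a q-value level.

    Returns a list of index sets (singletons excluded).
    """
    import networkx as nx

    g = nx.Graph()
    sub = table[table["qvalue"] <= level]
    g.add_edges_from(zip(sub["i"], sub["j"]))
    return [set(c) for c in nx.connected_components(g) if len(c) > 1]
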