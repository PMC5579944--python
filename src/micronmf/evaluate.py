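"""Evaluation utilities: weight-space distances, PAM mis-clustering, and
the static convex projection of samples onto type positions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .containers import WeightMatrix

__all__ = [
    "weight_distance",
    "pam",
    "pam_misclustering",
    "ProjectionLayout",
    "regular_polygon_positions",
    "project_layout",
]


def weight_distance(W_norm) -> np.ndarray:
    """Pairwise Euclidean distances between normalized weight columns."""
    if isinstance(W_norm, WeightMatrix):
        if not W_norm.normalized:
            raise ValueError("weight_distance expects a normalized weight matrix")
        vals = W_norm.values
    else:
        vals = np.asarray(W_norm, dtype=float)
    return squareform(pdist(vals.T))


def pam(dist: np.ndarray, k_clusters: int, seed: int = 0,
        max_swaps: int = 200) -> np.ndarray:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Classic build phase (greedy cost reduction) followed by swap phase
    (best single medoid/non-medoid exchange until no improvement).
    Tie-breaks are by lowest index, so the result is deterministic; the
    seed argument is kept for interface symmetry with the stochastic
    parts of the package.

    Returns the cluster index of every point.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not 1 <= k_clusters <= n:
        raise ValueError("k_clusters out of range")
    # build
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k_clusters:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    # swap
    def cost(meds):
        return dist[:, meds].min(axis=1).sum()

    best = cost(medoids)
    for _ in range(max_swaps):
        improved = False
        for mi in range(k_clusters):
            for cand in range(n):
                if cand in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = cand
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best, improved = trial, c, True
        if not improved:
            break
    return np.argmin(dist[:, medoids], axis=1)


def pam_misclustering(dist, true_labels, k_clusters: int = 2, seed: int = 0) -> float:
    """PAM clustering error against known class labels.

    The error is the misassignment fraction minimized over cluster-to-
    class matchings (Hungarian assignment), so it is invariant to
    relabelling the clusters.
    """
    true_labels = np.asarray(true_labels)
    classes = sorted(set(true_labels.tolist()))
    assign = pam(np.asarray(dist, dtype=float), k_clusters, seed=seed)
    # contingency: rows clusters, cols classes
    table = np.zeros((k_clusters, len(classes)))
    for cl, lab in zip(assign, true_labels):
        table[cl, classes.index(lab)] += 1
    row, col = linear_sum_assignment(-table)
    matched = table[row, col].sum()
    return float(1.0 - matched / true_labels.size)


@dataclass
class ProjectionLayout:
    """Planar layout: k type positions and n sample points, each sample a
    convex combination of the type positions by its normalized weights."""

    type_positions: np.ndarray  # (k, 2)
    sample_coords: np.ndarray   # (n, 2)
    type_ids: list = None
    sample_ids: list = None

    def to_dataframe(self):
        import pandas as pd

        samples = pd.DataFrame(
            self.sample_coords, columns=["x", "y"],
            index=self.sample_ids or range(self.sample_coords.shape[0]),
        )
        samples["kind"] = "sample"
        types = pd.DataFrame(
            self.type_positions, columns=["x", "y"],
            index=self.type_ids or range(self.type_positions.shape[0]),
        )
        types["kind"] = "type"
        return pd.concat([types, samples])

    def plot(self, ax=None, labels=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if labels is None:
            ax.scatter(*self.sample_coords.T, s=12, alpha=0.7)
        else:
            labels = np.asarray(labels)
            for lab in sorted(set(labels.tolist())):
                m = labels == lab
                ax.scatter(*self.sample_coords[m].T, s=12, alpha=0.7, label=str(lab))
            ax.legend()
        ax.scatter(*self.type_positions.T, marker="x", s=80, c="black")
        ax.set_aspect("equal")
        return ax


def regular_polygon_positions(k: int, radius: float = 1.0) -> np.ndarray:
    """Vertices of a regular k-gon (default type positions)."""
    angles = 2 * np.pi * np.arange(k) / k + np.pi / 2
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def project_layout(W_norm, type_positions=None) -> ProjectionLayout:
    """Convex projection of normalized weights onto given type positions.

    Each sample point is sum_i w_ij * position_i, so it lies inside the
    convex hull of the type positions; the whole layout is determined by
    where the types are placed.
    """
    if isinstance(W_norm, WeightMatrix):
        if not W_norm.normalized:
            raise ValueError("project_layout expects a normalized weight matrix")
        vals, type_ids, sample_ids = W_norm.values, W_norm.type_ids, W_norm.sample_ids
    else:
        vals = np.asarray(W_norm, dtype=float)
        type_ids = sample_ids = None
    k = vals.shape[0]
    if type_positions is None:
        type_positions = regular_polygon_positions(k)
    type_positions = np.asarray(type_positions, dtype=float)
    if type_positions.shape != (k, 2):
        raise ValueError(f"type_positions must have shape ({k}, 2)")
    coords = vals.T @ type_positions
    return ProjectionLayout(
        type_positions=type_positions, sample_coords=coords,
        type_ids=type_ids, sample_ids=sample_ids,
    )
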