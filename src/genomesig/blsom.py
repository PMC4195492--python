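"""Batch-learning self-organizing map (BLSOM) for oligonucleotide signatures.

A SOM maps high-dimensional composition vectors onto a 2-D lattice of weight
(prototype) vectors.  The batch-learning variant used for genome informatics
differs from Kohonen's online SOM in two ways that make the result
reproducible and independent of the order of the input data:

* the initial weights are laid out along the first two principal components
  of the data rather than drawn at random, and
* each epoch assigns *all* vectors to their best-matching weights and then
  replaces every weight by the mean of the vectors assigned within a
  shrinking neighborhood — a pure batch update with no per-sample learning
  rate.

Order independence here is bit-exact: vectors are brought into a canonical
(lexicographic) order before any accumulation, so the same multiset of input
vectors always produces the same floating-point result.

The lattice is rectangular with a Chebyshev (square) neighborhood.  The map
size defaults to one lattice point per ~10 input vectors, and the aspect
ratio follows the ratio of the first two principal standard deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SOMGrid:
    """Rectangular lattice of weight vectors plus training metadata.

    ``weights`` has shape (W, H, D); the linear index of lattice point
    (i, j) is ``i * H + j``, which is also the tie-breaking order for
    best-match assignment.
    """

    width: int
    height: int
    weights: np.ndarray
    training_log: list[dict] = field(default_factory=list)

    @property
    def n_lattice(self) -> int:
        return self.width * self.height

    @property
    def dim(self) -> int:
        return self.weights.shape[2]

    def flat_weights(self) -> np.ndarray:
        """Weights as an (W*H, D) array in linear-index order."""
        return self.weights.reshape(self.n_lattice, self.dim)


@dataclass
class LatticeAssignment:
    """Fragment-to-lattice mapping with a per-lattice species census."""

    coords: np.ndarray           # (n, 2) lattice coordinates per vector
    labels: list[str]            # species label per vector
    width: int
    height: int
    census: dict[tuple[int, int], dict[str, int]]

    @property
    def n_assigned(self) -> int:
        return len(self.labels)

    def pure_flags(self) -> dict[tuple[int, int], bool]:
        """True for lattice points whose fragments all share one species."""
        return {ij: len(c) == 1 for ij, c in self.census.items()}


def _canonical_order(vectors: np.ndarray) -> np.ndarray:
    """Permutation sorting rows lexicographically (ties by value are harmless:
    identical rows contribute identical summands)."""
    return np.lexsort(vectors.T[::-1])


def _principal_axes(vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, top-2 principal directions and their standard deviations.

    Deterministic eigendecomposition of the covariance matrix; each
    component's sign is fixed so its largest-magnitude loading is positive.
    """
    mean = vectors.mean(axis=0)
    centered = vectors - mean
    cov = centered.T @ centered / (len(vectors) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError(
            "degenerate covariance: data has fewer than two directions of variance"
        )
    pcs = evecs[:, :2].T.copy()
    for pc in pcs:
        if pc[np.argmax(np.abs(pc))] < 0:
            pc *= -1
    sigmas = np.sqrt(evals[:2])
    return mean, pcs, sigmas


def pca_initialize(
    vectors: np.ndarray,
    occupancy_target: float = 10.0,
    span: float = 2.0,
) -> SOMGrid:
    """Initialize a SOM lattice along the first two principal components.

    The lattice has roughly ``len(vectors) / occupancy_target`` points, with
    aspect ratio W/H equal to the ratio of the first two principal standard
    deviations (W >= H >= 2).  Weights form a regular grid spanning
    ``span`` standard deviations along each component, clipped at zero
    because composition frequencies are non-negative.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    n, d = vectors.shape
    if n < 10:
        raise ValueError(f"need at least 10 vectors to size a map, got {n}")
    if d < 2:
        raise ValueError("vectors must have dimension >= 2")
    vectors = vectors[_canonical_order(vectors)]
    mean, pcs, sigmas = _principal_axes(vectors)

    n_lattice = max(n / occupancy_target, 8.0)
    ratio = max(float(sigmas[0] / sigmas[1]), 1.0)
    ratio = min(ratio, n_lattice / 4.0)  # keep H >= 2
    height = max(2, round(math.sqrt(n_lattice / ratio)))
    width = max(height, round(n_lattice / height))

    ti = np.linspace(-1.0, 1.0, width) if width > 1 else np.zeros(1)
    tj = np.linspace(-1.0, 1.0, height) if height > 1 else np.zeros(1)
    weights = (
        mean[None, None, :]
        + span * sigmas[0] * ti[:, None, None] * pcs[0][None, None, :]
        + span * sigmas[1] * tj[None, :, None] * pcs[1][None, None, :]
    )
    np.clip(weights, 0.0, None, out=weights)
    return SOMGrid(width=width, height=height, weights=weights)


def _best_match(flat_weights: np.ndarray, vectors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear index of the nearest weight per vector (ties -> smallest index)
    and the squared distance to it."""
    # ||v - w||^2 = ||v||^2 - 2 v.w + ||w||^2 ; argmin over w
    cross = vectors @ flat_weights.T
    w_norm = np.einsum("ij,ij->i", flat_weights, flat_weights)
    scores = w_norm[None, :] - 2.0 * cross
    bmu = np.argmin(scores, axis=1)  # argmin returns the first (smallest) index
    v_norm = np.einsum("ij,ij->i", vectors, vectors)
    d2 = np.maximum(scores[np.arange(len(vectors)), bmu] + v_norm, 0.0)
    return bmu, d2


def _box_sum(grid: np.ndarray, radius: int) -> np.ndarray:
    """Sum over a (2r+1)x(2r+1) Chebyshev box at every lattice point,
    truncated at the lattice edges.  ``grid`` has shape (W, H, ...)."""
    w, h = grid.shape[:2]
    c = grid.cumsum(axis=0).cumsum(axis=1)
    pad_shape = (w + 1, h + 1) + grid.shape[2:]
    c_pad = np.zeros(pad_shape, dtype=grid.dtype)
    c_pad[1:, 1:] = c
    i = np.arange(w)
    j = np.arange(h)
    i0 = np.clip(i - radius, 0, w)
    i1 = np.clip(i + radius + 1, 0, w)
    j0 = np.clip(j - radius, 0, h)
    j1 = np.clip(j + radius + 1, 0, h)
    return (
        c_pad[np.ix_(i1, j1)]
        - c_pad[np.ix_(i0, j1)]
        - c_pad[np.ix_(i1, j0)]
        + c_pad[np.ix_(i0, j0)]
    )


def batch_train(
    grid: SOMGrid,
    vectors: np.ndarray,
    epochs: int = 100,
    r0: float | None = None,
) -> SOMGrid:
    """Train the map with order-independent batch updates.

    Per epoch t: (1) every vector is assigned to its best-matching weight
    (Euclidean distance, ties broken toward the smallest linear index);
    (2) every weight is replaced by the mean of the vectors assigned within
    Chebyshev radius ``r(t) = max(1, round(r0 * (1 - t/epochs)))`` of it,
    keeping its previous value where that neighborhood is empty.

    The neighborhood radius decays linearly from ``r0`` (default
    ``max(W, H) / 4``).  The result is bit-identical under any permutation
    of the input vectors.
    """
    if grid.weights.size == 0:
        raise ValueError("grid has no weights")
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[1] != grid.dim:
        raise ValueError("vector dimension does not match grid weights")
    vectors = vectors[_canonical_order(vectors)]
    w, h, d = grid.weights.shape
    if r0 is None:
        r0 = max(w, h) / 4.0
    weights = grid.weights.copy()
    for t in range(epochs):
        flat = weights.reshape(w * h, d)
        bmu, d2 = _best_match(flat, vectors)
        sums = np.zeros((w * h, d))
        np.add.at(sums, bmu, vectors)
        counts = np.bincount(bmu, minlength=w * h).astype(np.float64)
        radius = max(1, round(r0 * (1.0 - t / epochs)))
        nbh_sums = _box_sum(sums.reshape(w, h, d), radius)
        nbh_counts = _box_sum(counts.reshape(w, h), radius)
        occupied = nbh_counts > 0
        new_weights = weights.copy()
        new_weights[occupied] = nbh_sums[occupied] / nbh_counts[occupied][:, None]
        weights = new_weights
        grid.training_log.append(
            {"epoch": t, "radius": radius, "mean_qe": float(np.sqrt(d2).mean())}
        )
    return SOMGrid(width=w, height=h, weights=weights, training_log=grid.training_log)


def assign(grid: SOMGrid, vectors: np.ndarray, labels: list[str]) -> LatticeAssignment:
    """Assign vectors to their nearest weights and tabulate the census."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[1] != grid.dim:
        raise ValueError("vector dimension does not match grid weights")
    if len(labels) != len(vectors):
        raise ValueError("one label per vector required")
    bmu, _ = _best_match(grid.flat_weights(), vectors)
    coords = np.stack([bmu // grid.height, bmu % grid.height], axis=1)
    census: dict[tuple[int, int], dict[str, int]] = {}
    for (i, j), label in zip(coords, labels):
        cell = census.setdefault((int(i), int(j)), {})
        cell[label] = cell.get(label, 0) + 1
    return LatticeAssignment(
        coords=coords, labels=list(labels), width=grid.width, height=grid.height,
        census=census,
    )


def purity(
    assignment: LatticeAssignment, grouping: dict[str, str] | None = None
) -> float:
    """Fraction of fragments sitting on single-species lattice points.

    ``grouping`` optionally merges labels before purity is computed (e.g.
    two congeneric species counted as one category); merging can only raise
    purity.
    """
    if assignment.n_assigned == 0:
        raise ValueError("empty assignment")
    grouping = grouping or {}
    on_pure = 0
    for cell in assignment.census.values():
        merged: dict[str, int] = {}
        for label, count in cell.items():
            g = grouping.get(label, label)
            merged[g] = merged.get(g, 0) + count
        if len(merged) == 1:
            on_pure += sum(cell.values())
    return on_pure / assignment.n_assigned
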