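"""Rigid-body superposition and RMSD.

Pairwise least-squares superposition (Kabsch) is delegated to
``scipy.spatial.transform.Rotation.align_vectors``.  Multiple structures are
superposed by deterministic iterative consensus fitting: every chain is fitted
onto the running mean coordinate set until the mean stops moving.  The
reported alignment RMSD is the mean over all structure pairs of the RMSD over
core columns in the resulting common frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .model_io import GAP, MultipleAlignment

#: convergence tolerance for consensus fitting (Angstrom)
CONSENSUS_TOL = 1e-6
#: maximum consensus-fit iterations
CONSENSUS_MAX_ITER = 100


@dataclass
class Superposition:
    """A proper rigid transform ``x -> x @ R.T + t`` plus the fit RMSD (A)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation is improper (det < 0)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(np.eye(3), np.zeros(3), 0.0)


def superpose_pair(X: np.ndarray, Y: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of point set ``Y`` onto ``X``.

    Returns the transform minimizing the RMSD between ``X`` and the moved
    ``Y`` (at least 3 points each, equal counts).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"point sets differ in shape: {X.shape} vs {Y.shape}")
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("point sets must have shape (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points to superpose, got {n}")
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(X - cx, Y - cy)
    R = rot.as_matrix()
    t = cx - R @ cy
    return Superposition(R, t, float(rssd) / np.sqrt(n))


def consensus_fit(coord_sets):
    """Superpose several equal-length point sets onto their consensus.

    Iteratively fits every set onto the running mean until the mean moves less
    than :data:`CONSENSUS_TOL` (or :data:`CONSENSUS_MAX_ITER` iterations).
    Deterministic given input order; the common frame is anchored at the first
    set's initial placement.

    Returns ``(superpositions, consensus)``.
    """
    coord_sets = [np.asarray(c, dtype=float) for c in coord_sets]
    if len(coord_sets) < 2:
        raise ValueError("need at least 2 coordinate sets")
    m = coord_sets[0].shape[0]
    if any(c.shape != (m, 3) for c in coord_sets):
        raise ValueError("all coordinate sets must share shape (m, 3)")
    mean = coord_sets[0].copy()
    sups = None
    for _ in range(CONSENSUS_MAX_ITER):
        sups = [superpose_pair(mean, c) for c in coord_sets]
        moved = np.mean([s.apply(c) for s, c in zip(sups, coord_sets)], axis=0)
        if np.abs(moved - mean).max() < CONSENSUS_TOL:
            mean = moved
            break
        mean = moved
    # refresh per-set RMSD against the final consensus
    out = []
    for s, c in zip(sups, coord_sets):
        d = s.apply(c) - mean
        out.append(
            Superposition(s.rotation, s.translation, float(np.sqrt((d**2).sum(axis=1).mean())))
        )
    return out, mean


def average_pairwise_rmsd_coords(coord_sets, superpositions) -> float:
    """Mean over all set pairs of the RMSD in the common superposed frame."""
    moved = [s.apply(c) for s, c in zip(superpositions, coord_sets)]
    k = len(moved)
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            d = moved[i] - moved[j]
            vals.append(np.sqrt((d**2).sum(axis=1).mean()))
    return float(np.mean(vals))


def fit_rmsd(coord_sets) -> float:
    """Consensus-fit several point sets and return the average pairwise RMSD."""
    sups, _ = consensus_fit(coord_sets)
    return average_pairwise_rmsd_coords(coord_sets, sups)


def _column_coords(a: MultipleAlignment, columns) -> list:
    """Per-structure coordinate arrays over the given (core) columns."""
    columns = np.asarray(columns, dtype=int)
    out = []
    for i, s in enumerate(a.structures):
        idx = a.rows[i, columns]
        if np.any(idx == GAP):
            raise ValueError("selected columns must all be core columns")
        out.append(s.coords[idx])
    return out


def superpose_multiple(a: MultipleAlignment, columns) -> list:
    """Superpose every structure of an alignment over a core-column subset.

    Needs at least 3 selected columns, all core.  Returns one
    :class:`Superposition` per structure; the ``rmsd`` field is each
    structure's RMSD against the consensus over the fitting columns.
    """
    columns = np.asarray(columns, dtype=int)
    if len(columns) < 3:
        raise ValueError(
            f"need at least 3 core columns to superpose, got {len(columns)}"
        )
    sups, _ = consensus_fit(_column_coords(a, columns))
    return sups


def column_pair_distances(a: MultipleAlignment, superpositions, column: int):
    """C-alpha distances between all structure pairs present in one column.

    Distances are measured in the common superposed frame; columns with fewer
    than two residues yield an empty list.  Pair order is (i, j) with i < j
    over the present structures.
    """
    present = a.column_residues(column)
    pts = [
        superpositions[i].apply(a.structures[i].coords[r]) for i, r in present
    ]
    dists = []
    for x in range(len(pts)):
        for y in range(x + 1, len(pts)):
            dists.append(float(np.linalg.norm(pts[x] - pts[y])))
    return dists


def average_pairwise_core_rmsd(
    a: MultipleAlignment, superpositions, columns=None
) -> float:
    """Mean over structure pairs of the core-column RMSD in the common frame."""
    if columns is None:
        columns = a.core_columns
    columns = np.asarray(columns, dtype=int)
    if len(columns) < 3:
        raise ValueError("need at least 3 core columns for an RMSD")
    coords = _column_coords(a, columns)
    return average_pairwise_rmsd_coords(coords, superpositions)
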