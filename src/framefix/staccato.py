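"""Staccato-style conservation scores and alignment evaluation metrics.

Implements the weighted sum-of-pairs sequence conservation score (Seq), the
distance-based structural conservation score (Str), their convex combination
(Cons), sequence weights derived from pairwise percent identity, the partial
alignment factor and partial core length, and percent-correct against a
reference alignment.  All scores live on a 0-9 scale where LOWER is better.

Definitions, with A the set of scored columns (core columns unless computing
the partial Seq variant), N structures, and w_i sequence weights:

    Seq' = sum_{c in A} sum_{i<j} w_i w_j S(c_i, c_j) / (W * |A|)
    Seq  = 9 * (1 - (Seq' + 4) / 9.75),            clamped into [0, 9]
    Str  = mean_{c in A} mean_{i<j} T(d_ij(c))
    Cons = omega * Seq + (1 - omega) * Str

where S is BLOSUM62 off the diagonal and a configurable identical-residue
score on it, and T is the per-pair structural term: 9 for distances above the
cap (22.62 A by default) and a pluggable monotone branch below it (default: a
linear ramp reaching 9 exactly at the cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

from . import geometry
from .model_io import GAP, MultipleAlignment, ScoreReport

STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

#: Sum of the 20 standard BLOSUM62 diagonal entries (= 116).
BLOSUM62_DIAGONAL_SUM = float(sum(_BLOSUM62[a, a] for a in STANDARD_AA))
#: Mean of the 20 standard BLOSUM62 diagonal entries (= 5.8).
BLOSUM62_DIAGONAL_MEAN = BLOSUM62_DIAGONAL_SUM / 20.0


def linear_ramp(d: float, params: "StaccatoParams") -> float:
    """Default sub-cap structural branch: 0 at d=0, rising to 9 at the cap."""
    return 9.0 * d / params.cap_distance


@dataclass
class StaccatoParams:
    """Constants of the conservation scores.

    Attributes
    ----------
    f : float
        Structural scale constant carried in the score's published form; the
        default sub-cap branch does not use it but alternative branch
        functions may.
    omega : float
        Weight of the sequence component in Cons (0.5 weights sequence and
        structure equally).
    cap_distance : float
        Distance (A) above which the per-pair structural term is pinned at 9.
    seq_scale, seq_shift, seq_norm : float
        The 9 / 4 / 9.75 constants of the Seq transform.
    identical_residue_score : float
        Substitution value for identical residue pairs.  Default: the mean
        BLOSUM62 diagonal (5.8), which anchors the zero of Seq near the
        normalization constant 9.75 = 4 + 5.75; the literal diagonal sum
        (116) is available via :data:`BLOSUM62_DIAGONAL_SUM`.
    matrix :
        Substitution matrix (biopython Array); defaults to BLOSUM62.
    str_branch : callable
        Sub-cap branch ``T(d, params)``; defaults to :func:`linear_ramp`.
    """

    f: float = 0.07
    omega: float = 0.5
    cap_distance: float = 22.62
    seq_scale: float = 9.0
    seq_shift: float = 4.0
    seq_norm: float = 9.75
    identical_residue_score: float = BLOSUM62_DIAGONAL_MEAN
    matrix: object = None
    str_branch: object = None

    def __post_init__(self):
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if self.f <= 0 or self.cap_distance <= 0:
            raise ValueError("f and cap_distance must be positive")
        if self.matrix is None:
            self.matrix = _BLOSUM62
        if self.str_branch is None:
            self.str_branch = linear_ramp


@dataclass
class SequenceWeights:
    """Per-structure weights w_i with normalizer W = sum_{i<j} w_i w_j."""

    w: np.ndarray
    W: float
    d: np.ndarray  # pairwise identity distances, d(i,j) = 1 - PID/100


def pair_substitution_score(r1: str, r2: str, params: StaccatoParams | None = None) -> float:
    """Substitution score of a residue pair: matrix value off the diagonal,
    ``identical_residue_score`` for identical residues.  Unknown codes are
    treated as 'X'."""
    params = params or StaccatoParams()
    r1 = r1.upper()
    r2 = r2.upper()
    alphabet = params.matrix.alphabet
    if r1 not in alphabet:
        r1 = "X"
    if r2 not in alphabet:
        r2 = "X"
    if r1 == r2:
        return float(params.identical_residue_score)
    return float(params.matrix[r1, r2])


def percent_identity(a: MultipleAlignment, i: int, j: int) -> float:
    """100 x identical residue pairs / columns where both rows have residues
    (0 when the rows share no column)."""
    ri = a.rows[i]
    rj = a.rows[j]
    both = (ri != GAP) & (rj != GAP)
    n = int(both.sum())
    if n == 0:
        return 0.0
    si = a.structures[i]
    sj = a.structures[j]
    same = sum(
        1
        for c in np.flatnonzero(both)
        if si.names[ri[c]].upper() == sj.names[rj[c]].upper()
    )
    return 100.0 * same / n


def sequence_weights(a: MultipleAlignment) -> SequenceWeights:
    """Identity-distance sequence weights.

    w_i = sum_{j != i} d(i, j) / (N - 1) with d = 1 - PID/100.  When every
    pair of sequences is identical (W = 0) the degenerate fallback assigns
    w_i = 1 and W = C(k, 2), i.e. uniform weighting.
    """
    k = a.n_structures
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = 1.0 - percent_identity(a, i, j) / 100.0
    w = d.sum(axis=1) / (k - 1)
    W = sum(w[i] * w[j] for i, j in combinations(range(k), 2))
    if W == 0.0:
        w = np.ones(k)
        W = k * (k - 1) / 2.0
    return SequenceWeights(w=w, W=float(W), d=d)


def str_pair_term(d: float, params: StaccatoParams | None = None) -> float:
    """Per-pair structural term: 9 above the cap distance, monotone branch below."""
    params = params or StaccatoParams()
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if d > params.cap_distance:
        return 9.0
    return float(params.str_branch(d, params))


# -- row-level scoring helpers (shared with region-candidate scoring) -------


def _seq_prime_rows(structures, rows, columns, weights, params, partial):
    """Weighted sum-of-pairs average Seq' over the given columns.

    With ``partial`` any pair involving a gap contributes 0; otherwise all
    selected columns must be gap-free.
    """
    columns = np.asarray(columns, dtype=int)
    if len(columns) == 0:
        raise ValueError("cannot score an empty column subset")
    k = len(structures)
    w = weights.w
    total = 0.0
    for c in columns:
        col = rows[:, c]
        for i in range(k):
            for j in range(i + 1, k):
                if col[i] == GAP or col[j] == GAP:
                    if not partial:
                        raise ValueError(
                            f"column {c} has gaps; core scoring needs core columns"
                        )
                    continue  # gap pairs contribute 0
                s = pair_substitution_score(
                    structures[i].names[col[i]], structures[j].names[col[j]], params
                )
                total += w[i] * w[j] * s
    return total / (weights.W * len(columns))


def _seq_from_prime(seq_prime: float, params: StaccatoParams) -> float:
    seq = params.seq_scale * (1.0 - (seq_prime + params.seq_shift) / params.seq_norm)
    return float(min(max(seq, 0.0), params.seq_scale))


def _str_rows(structures, rows, columns, superpositions, params):
    """Mean over columns of the mean per-pair structural term."""
    columns = np.asarray(columns, dtype=int)
    if len(columns) == 0:
        raise ValueError("cannot score an empty column subset")
    col_vals = []
    for c in columns:
        pts = [
            superpositions[i].apply(structures[i].coords[rows[i, c]])
            for i in range(len(structures))
            if rows[i, c] != GAP
        ]
        terms = [
            str_pair_term(float(np.linalg.norm(pts[x] - pts[y])), params)
            for x in range(len(pts))
            for y in range(x + 1, len(pts))
        ]
        if not terms:
            raise ValueError(f"column {c} has fewer than 2 residues")
        col_vals.append(np.mean(terms))
    return float(np.mean(col_vals))


# -- public scores ---------------------------------------------------------


def seq_score(a, columns, weights=None, params=None) -> float:
    """Seq conservation score over a core-column subset (0 best, 9 worst)."""
    params = params or StaccatoParams()
    weights = weights or sequence_weights(a)
    prime = _seq_prime_rows(a.structures, a.rows, columns, weights, params, partial=False)
    return _seq_from_prime(prime, params)


def seq_score_partial(a, weights=None, params=None) -> float:
    """Partial Seq score over ALL columns; gap pairs contribute 0."""
    params = params or StaccatoParams()
    weights = weights or sequence_weights(a)
    prime = _seq_prime_rows(
        a.structures, a.rows, np.arange(a.n_columns), weights, params, partial=True
    )
    return _seq_from_prime(prime, params)


def str_score(a, columns, superpositions, params=None) -> float:
    """Str conservation score over a core-column subset in a common frame."""
    params = params or StaccatoParams()
    return _str_rows(a.structures, a.rows, columns, superpositions, params)


def cons_score(seq: float, str_: float, params: StaccatoParams | None = None) -> float:
    """Combined conservation score: omega * Seq + (1 - omega) * Str."""
    params = params or StaccatoParams()
    return params.omega * seq + (1.0 - params.omega) * str_


def cons_for_columns(a, columns, weights, superpositions, params=None):
    """(Seq, Str, Cons) over a core-column subset; used for single columns,
    anchor-block runs and region candidates alike."""
    params = params or StaccatoParams()
    s = seq_score(a, columns, weights, params)
    t = str_score(a, columns, superpositions, params)
    return s, t, cons_score(s, t, params)


def partial_core_length(a: MultipleAlignment):
    """Partial alignment factor p and partial core length l * p.

    p averages, over all n columns, the fraction of structure pairs in which
    both members contribute a residue (out of C(k, 2) possible pairs).
    """
    k = a.n_structures
    pairs_total = k * (k - 1) / 2.0
    present = a.rows != GAP
    m = present.sum(axis=0)
    realized = m * (m - 1) / 2.0
    p = float((realized / pairs_total).mean())
    return p, float(realized.sum() / pairs_total)


def _aligned_pairs(a: MultipleAlignment) -> set:
    pairs = set()
    k = a.n_structures
    for c in range(a.n_columns):
        col = a.rows[:, c]
        present = [i for i in range(k) if col[i] != GAP]
        for x in range(len(present)):
            for y in range(x + 1, len(present)):
                i, j = present[x], present[y]
                pairs.add((i, j, int(col[i]), int(col[j])))
    return pairs


def percent_correct(test: MultipleAlignment, ref: MultipleAlignment) -> float:
    """Reference-pair recall: 100 x |aligned residue pairs shared with the
    reference| / |aligned residue pairs in the reference|."""
    if [s.id for s in test.structures] != [s.id for s in ref.structures]:
        raise ValueError("test and reference alignments must share structures")
    ref_pairs = _aligned_pairs(ref)
    if not ref_pairs:
        raise ValueError("reference alignment aligns no residue pairs")
    test_pairs = _aligned_pairs(test)
    return 100.0 * len(ref_pairs & test_pairs) / len(ref_pairs)


def score_alignment(
    a: MultipleAlignment,
    ref: MultipleAlignment | None = None,
    params: StaccatoParams | None = None,
    superpositions=None,
) -> ScoreReport:
    """Assemble the full evaluation row for an alignment.

    Seq/Str/Cons and RMSD are computed over core columns only (at least 3
    required); the partial factor, partial length and partial Seq cover all
    columns; percent-correct is included when a reference is given.
    """
    params = params or StaccatoParams()
    core = a.core_columns
    if len(core) < 3:
        raise ValueError(
            f"alignment has {len(core)} core columns; need at least 3 to score"
        )
    if superpositions is None:
        superpositions = geometry.superpose_multiple(a, core)
    weights = sequence_weights(a)
    seq, strv, cons = cons_for_columns(a, core, weights, superpositions, params)
    rmsd = geometry.average_pairwise_core_rmsd(a, superpositions, core)
    p, plen = partial_core_length(a)
    return ScoreReport(
        core_length=int(len(core)),
        rmsd_core=rmsd,
        seq_core=seq,
        str_core=strv,
        cons_core=cons,
        partial_length=plen,
        partial_factor_p=p,
        seq_partial=seq_score_partial(a, weights, params),
        percent_correct=None if ref is None else percent_correct(a, ref),
    )
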