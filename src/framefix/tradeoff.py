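"""Length-vs-quality comparison tools for multiple structure alignments.

Conservation scores of the Staccato family are not length-invariant: they
favor shorter, tighter alignments.  Two procedures make alignments of
different core lengths comparable:

* :func:`truncate_to_core_length` builds a fair baseline by greedily dropping
  the worst-scoring core columns of an alignment until it matches a target
  core length (dropped residues are kept as single-residue non-core columns,
  so no residue is lost).
* :func:`separator_rank` ranks (Cons, core length) points by the y-intercept
  of a fixed-slope line through each point — the slope taken from a linear
  separator of same-family versus different-family domain pairs in the
  (core length, Cons) plane — lower intercept first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry, staccato
from .model_io import GAP, MultipleAlignment


@dataclass
class SeparatorParams:
    """Fixed-slope separator in the (core length, Cons) plane.

    ``slope`` is score units per core column; ``intercept`` is informational
    (the separator line itself), unused by the ranking.
    """

    slope: float = 0.126
    intercept: float = -0.213

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("separator slope must be positive")


def truncate_to_core_length(
    a: MultipleAlignment,
    target: int,
    params: staccato.StaccatoParams | None = None,
) -> MultipleAlignment:
    """Drop worst-Cons core columns until the core length matches ``target``.

    Single-column Cons uses the full alignment's sequence weights and the
    prevailing core superposition, without refitting between removals; ties
    break to the leftmost column.  Removed residues become single-residue
    non-core columns in place of the removed column, preserving the residue
    multiset of every chain.
    """
    params = params or staccato.StaccatoParams()
    core = a.core_columns
    if target > len(core):
        raise ValueError(
            f"target core length {target} exceeds current core length {len(core)}"
        )
    if target == len(core):
        return a
    sups = geometry.superpose_multiple(a, core)
    weights = staccato.sequence_weights(a)
    cons = {}
    for c in core:
        _, _, cons[int(c)] = staccato.cons_for_columns(
            a, [int(c)], weights, sups, params
        )
    removed = set()
    remaining = [int(c) for c in core]
    while len(remaining) > target:
        worst = max(remaining, key=lambda c: (cons[c], -c))
        remaining.remove(worst)
        removed.add(worst)
    k = a.n_structures
    cols = []
    for c in range(a.n_columns):
        if c in removed:
            for i in range(k):
                col = [GAP] * k
                col[i] = int(a.rows[i, c])
                cols.append(col)
        else:
            cols.append(list(a.rows[:, c]))
    return MultipleAlignment(
        structures=a.structures, rows=np.array(cols, dtype=int).T
    )


def separator_rank(candidates, params: SeparatorParams | None = None):
    """Rank (cons, core_length) candidates by separator y-intercept.

    For each candidate the intercept ``b = cons - slope * core_length`` is
    computed; candidates are returned best (lowest b) first as a list of
    ``(original_index, cons, core_length, b)`` tuples.  The ordering is
    stable for exact intercept ties.
    """
    params = params or SeparatorParams()
    if not candidates:
        raise ValueError("need at least one candidate to rank")
    scored = [
        (i, float(cons), float(length), float(cons) - params.slope * float(length))
        for i, (cons, length) in enumerate(candidates)
    ]
    return sorted(scored, key=lambda t: (t[3], t[0]))
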