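"""Shared fixtures and fixture builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import framefix as ff
from framefix.model_io import GAP, MultipleAlignment, Structure


def make_structure(seq: str, coords=None, id: str = "s", seed: int = 0) -> Structure:
    """Structure from a 1-letter sequence; random well-spread coords unless given."""
    if coords is None:
        rng = np.random.default_rng(seed)
        coords = np.cumsum(rng.normal(0, 2.0, (len(seq), 3)), axis=0)
        coords[:, 0] += 3.8 * np.arange(len(seq))
    return Structure(
        id=id,
        names=list(seq),
        coords=np.asarray(coords, dtype=float),
        labels=[str(i + 1) for i in range(len(seq))],
    )


def alignment_from_strings(rows, coords=None, ids=None) -> MultipleAlignment:
    """Build an alignment from gapped row strings.

    ``coords`` maps row index -> (n_residues, 3) array; rows without coords
    get deterministic pseudo-random ones.
    """
    coords = coords or {}
    structures = []
    for i, row in enumerate(rows):
        seq = row.replace("-", "")
        structures.append(
            make_structure(
                seq,
                coords.get(i),
                id=(ids[i] if ids else f"s{i}"),
                seed=100 + i,
            )
        )
    mat = np.full((len(rows), len(rows[0])), GAP, dtype=int)
    for i, row in enumerate(rows):
        r = 0
        for c, ch in enumerate(row):
            if ch != "-":
                mat[i, c] = r
                r += 1
    return MultipleAlignment(structures=structures, rows=mat)


def random_alignment(rng, k=None, n=None, min_core=3):
    """Random small valid alignment (k <= 4, n <= 10) for oracle checks."""
    k = k or int(rng.integers(2, 5))
    n = n or int(rng.integers(max(4, min_core + 1), 11))
    rows = np.full((k, n), GAP, dtype=int)
    for i in range(k):
        extra = int(rng.integers(0, n - min_core + 1))
        cols = list(range(min_core)) + sorted(
            rng.choice(np.arange(min_core, n), size=extra, replace=False).tolist()
        )
        rows[i, cols] = np.arange(len(cols))
    # drop all-gap columns
    keep = ~np.all(rows == GAP, axis=0)
    rows = rows[:, keep]
    structures = []
    for i in range(k):
        m = int((rows[i] != GAP).sum())
        seq = "".join(rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=m))
        structures.append(make_structure(seq, id=f"r{i}", seed=int(rng.integers(1e6))))
    return MultipleAlignment(structures=structures, rows=rows)


@pytest.fixture(scope="session")
def suite_cases():
    """The standard 20-family register-error suite (generated once)."""
    return ff.make_suite(20, 0, verify=False)


@pytest.fixture(scope="session")
def suite_results(suite_cases):
    """Refinement of every corrupted family, with percent-correct before/after."""
    out = []
    for case in suite_cases:
        res = ff.refine_alignment(case.corrupted)
        pc0 = ff.percent_correct(case.corrupted, case.family.true_alignment)
        pc1 = ff.percent_correct(res.alignment, case.family.true_alignment)
        out.append((case, res, pc0, pc1))
    return out


@pytest.fixture()
def register_case():
    """One small register-error family (k=2) with its corrupted alignment."""
    return ff.register_error_family(ff.standard_specs(1, 0)[0], verify=False)
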