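"""Register-error repair of block-anchored multiple structure alignments.

Geometric multiple structure aligners assemble tightly superposed anchor
blocks and then extend greedily between them on RMSD alone, which can pick an
arbitrary register among near-tied geometric alternatives and discard obvious
sequence similarity.  This module repairs such alignments region by region:

1. :func:`infer_blocks` partitions the alignment columns into anchor blocks
   (runs of tightly superposed core columns) and the inter-block/terminal
   regions between them.
2. For each region, two candidate sub-alignments are built: a pure sequence
   alignment of the region's subsequences (:func:`align_region_sequence`,
   built-in progressive aligner or an external tool), and a greedy structural
   extension inward from the flanking blocks under an RMSD acceptance
   threshold (:func:`align_region_structure`).
3. :func:`score_candidates` computes the combined conservation score (Cons)
   of each candidate — sequence weights taken from the full alignment, the
   structural component in the full alignment's superposed frame — and the
   lower (better) candidate wins; exact ties keep the structural candidate.
4. :func:`splice` substitutes the winner into the alignment without touching
   anchor blocks or losing residues.

:func:`refine_alignment` runs the whole pipeline in one left-to-right pass.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import geometry, staccato
from .model_io import GAP, MultipleAlignment

EXTERNAL_ALIGNERS = ("mafft", "clustalw", "muscle", "probcons")

#: score assigned to a candidate with no core columns (worst possible)
ZERO_CORE_SCORE = 9.0


@dataclass
class RefineParams:
    """Tunable constants of the repair pipeline.

    ``extension_rmsd_threshold`` (5 A) bounds the refit RMSD under which the
    greedy structural extension keeps appending columns.  ``block_window``
    records the 5-9 residue fragment size of the upstream block-based aligner
    and motivates ``block_min_length``; ``block_rmsd_threshold`` (2.5 A) is
    this package's own tightness bound for anchor inference.
    """

    extension_rmsd_threshold: float = 5.0
    block_min_length: int = 5
    block_window: tuple = (5, 9)
    block_rmsd_threshold: float = 2.5
    aligner: str = "builtin"
    tie_break: str = "structural"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if self.extension_rmsd_threshold <= 0 or self.block_rmsd_threshold <= 0:
            raise ValueError("RMSD thresholds must be positive")
        if self.block_min_length < 2:
            raise ValueError("block_min_length must be at least 2")
        if self.aligner not in ("builtin",) + EXTERNAL_ALIGNERS:
            raise ValueError(f"unknown aligner {self.aligner!r}")
        if self.tie_break not in ("structural", "sequence"):
            raise ValueError("tie_break must be 'structural' or 'sequence'")


@dataclass
class Block:
    """A half-open column interval [start, end) of anchored core columns."""

    start: int
    end: int

    def __len__(self):
        return self.end - self.start

    @property
    def columns(self):
        return np.arange(self.start, self.end)


@dataclass
class Region:
    """Columns between two anchor blocks (or a terminus) plus, per structure,
    the half-open residue-index range those columns own."""

    col_start: int
    col_end: int
    res_ranges: list  # [(lo, hi)] per structure
    left_block: Block | None = None
    right_block: Block | None = None

    @property
    def n_residues(self) -> int:
        return sum(hi - lo for lo, hi in self.res_ranges)


@dataclass
class BlockAnnotation:
    """Anchor blocks and complementary regions tiling an alignment."""

    blocks: list
    regions: list


def _blocks_to_regions(a: MultipleAlignment, blocks) -> list:
    """Fill the gaps between ordered blocks (and the termini) with regions."""
    regions = []
    bounds = [0] + [c for b in blocks for c in (b.start, b.end)] + [a.n_columns]
    for idx in range(0, len(bounds), 2):
        cs, ce = bounds[idx], bounds[idx + 1]
        left = blocks[idx // 2 - 1] if idx > 0 else None
        right = blocks[idx // 2] if idx // 2 < len(blocks) else None
        ranges = []
        for i in range(a.n_structures):
            lo = int(a.rows[i, left.end - 1]) + 1 if left is not None else 0
            hi = int(a.rows[i, right.start]) if right is not None else len(a.structures[i])
            ranges.append((lo, hi))
        if ce > cs or any(hi > lo for lo, hi in ranges):
            regions.append(
                Region(col_start=cs, col_end=ce, res_ranges=ranges,
                       left_block=left, right_block=right)
            )
    return regions


def infer_blocks(
    a: MultipleAlignment, superpositions=None, params: RefineParams | None = None
) -> BlockAnnotation:
    """Partition alignment columns into anchor blocks and regions.

    Within every maximal run of consecutive core columns long enough to hold
    a block, columns whose RMS pair distance stays within
    ``block_rmsd_threshold`` are marked tight — first in the global core
    frame (``superpositions``, computed over all core columns when not
    supplied), then confirmed under a run-local refit on the tight subset —
    and maximal tight sub-runs of at least ``block_min_length`` columns
    become anchors.  Everything else (including alignments that produce no
    block at all) is left to regions.  The global frame is used for the
    initial mask because a run-local fit over a run that mixes a long tight
    stretch with a misregistered loop splits the difference and can hide the
    misregistration.
    """
    params = params or RefineParams()
    if superpositions is None and len(a.core_columns) >= 3:
        superpositions = geometry.superpose_multiple(a, a.core_columns)
    mask = a.core_mask
    blocks = []
    c = 0
    n = a.n_columns
    while c < n:
        if not mask[c]:
            c += 1
            continue
        start = c
        while c < n and mask[c]:
            c += 1
        run = np.arange(start, c)
        if len(run) < max(params.block_min_length, 3):
            continue
        tight = _tight_columns(a, run, params, superpositions)
        # maximal tight sub-runs of sufficient length become anchors
        i = 0
        while i < len(run):
            if not tight[i]:
                i += 1
                continue
            j = i
            while j < len(run) and tight[j]:
                j += 1
            if j - i >= params.block_min_length:
                blocks.append(Block(int(run[i]), int(run[j - 1]) + 1))
            i = j
    return BlockAnnotation(blocks=blocks, regions=_blocks_to_regions(a, blocks))


def _tight_columns(a, run, params, global_sups=None):
    """Boolean tightness per column of a core run: initial mask in the global
    core frame (or a run-local fit when unavailable), refreshed once under a
    run-local refit on the tight subset."""
    coords = geometry._column_coords(a, run)
    if global_sups is not None:
        sups = global_sups
    else:
        sups, _ = geometry.consensus_fit(coords)
    tight = _column_rms_ok(coords, sups, params.block_rmsd_threshold)
    if tight.all() or tight.sum() < 3:
        return tight
    # confirm under a refit on the tight subset; the refit can only demote
    # columns, never re-admit ones the global frame already rejected
    refit_sets = [c[tight] for c in coords]
    sups, _ = geometry.consensus_fit(refit_sets)
    return tight & _column_rms_ok(coords, sups, params.block_rmsd_threshold)


def _column_rms_ok(coords, sups, threshold):
    moved = [s.apply(c) for s, c in zip(sups, coords)]
    k = len(moved)
    sq = np.zeros(moved[0].shape[0])
    npairs = 0
    for i in range(k):
        for j in range(i + 1, k):
            sq += ((moved[i] - moved[j]) ** 2).sum(axis=1)
            npairs += 1
    return np.sqrt(sq / npairs) <= threshold + 1e-9


# -- sequence candidate ----------------------------------------------------


def _match_score(res: str, column, matrix) -> float:
    """Residue-vs-profile-column score: mean substitution score against the
    column's residues (gaps contribute 0 to the sum, divisor = column size)."""
    total = 0.0
    for e in column:
        if e != "-":
            a, b = res.upper(), e.upper()
            if a not in matrix.alphabet:
                a = "X"
            if b not in matrix.alphabet:
                b = "X"
            total += float(matrix[a, b])
    return total / len(column)


def _align_seq_to_profile(seq, profile, gap_open, gap_extend, matrix):
    """Affine-gap global alignment (Gotoh) of a sequence against a profile.

    The first gap position costs ``gap_open``, each further position
    ``gap_extend``.  Deterministic tie-break: match > gap-in-profile >
    gap-in-sequence, resolved during traceback.  Returns the new profile
    (list of columns; the sequence appended as the last row).
    """
    n = len(seq)
    m = len(profile)
    nrows = len(profile[0]) if profile else 0
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in profile (consume seq residue)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in sequence (consume profile col)
    # backpointers: state entered from (0=M, 1=Ix, 2=Iy, -1=start)
    bM = np.full((n + 1, m + 1), -1, dtype=int)
    bX = np.full((n + 1, m + 1), -1, dtype=int)
    bY = np.full((n + 1, m + 1), -1, dtype=int)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + gap_extend * (i - 1)
        bX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + gap_extend * (j - 1)
        bY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _match_score(seq[i - 1], profile[j - 1], matrix)
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            bM[i, j] = int(np.argmax(prev))
            M[i, j] = prev[bM[i, j]] + s
            if M[i - 1, j] + gap_open >= Ix[i - 1, j] + gap_extend:
                Ix[i, j] = M[i - 1, j] + gap_open
                bX[i, j] = 0
            else:
                Ix[i, j] = Ix[i - 1, j] + gap_extend
                bX[i, j] = 1
            if M[i, j - 1] + gap_open >= Iy[i, j - 1] + gap_extend:
                Iy[i, j] = M[i, j - 1] + gap_open
                bY[i, j] = 0
            else:
                Iy[i, j] = Iy[i, j - 1] + gap_extend
                bY[i, j] = 2
    finals = (M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax(finals))
    i, j = n, m
    cols = []
    while i > 0 or j > 0:
        if state == 0:
            cols.append(profile[j - 1] + [seq[i - 1]])
            state = int(bM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append(["-"] * nrows + [seq[i - 1]])
            state = int(bX[i, j])
            i -= 1
        else:
            cols.append(profile[j - 1] + ["-"])
            state = int(bY[i, j])
            j -= 1
    cols.reverse()
    return cols


def progressive_align(seqs, gap_open=-11.0, gap_extend=-1.0, matrix=None):
    """Deterministic progressive multiple alignment (guide order = input
    order) with affine gap penalties.  Empty sequences come out all-gap.
    Returns the aligned rows as gapped strings."""
    if matrix is None:
        matrix = staccato._BLOSUM62
    order = [i for i, s in enumerate(seqs) if s]
    if not order:
        return ["" for _ in seqs]
    profile = [[c] for c in seqs[order[0]]]
    for idx in order[1:]:
        profile = _align_seq_to_profile(
            seqs[idx], profile, gap_open, gap_extend, matrix
        )
    width = len(profile)
    out = ["-" * width] * len(seqs)
    for rank, idx in enumerate(order):
        out[idx] = "".join(col[rank] for col in profile)
    return out


def _run_external_aligner(aligner: str, seqs, ids) -> list:
    """Run an external multiple sequence aligner through the subprocess
    contract: FASTA in, aligned FASTA out (stdout or declared output file)."""
    if shutil.which(aligner) is None:
        raise RuntimeError(
            f"external aligner {aligner!r} not found on PATH"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out.fasta"
        fin.write_text("".join(f">{i}\n{s}\n" for i, s in zip(ids, seqs)))
        if aligner == "mafft":
            cmd = ["mafft", "--auto", "--quiet", "--amino", str(fin)]
            res = subprocess.run(cmd, capture_output=True, text=True)
            out_text = res.stdout
        elif aligner == "muscle":
            cmd = ["muscle", "-in", str(fin), "-out", str(fout)]
            res = subprocess.run(cmd, capture_output=True, text=True)
            out_text = fout.read_text() if fout.exists() else ""
        elif aligner == "clustalw":
            cmd = ["clustalw", f"-INFILE={fin}", "-OUTPUT=FASTA",
                   f"-OUTFILE={fout}"]
            res = subprocess.run(cmd, capture_output=True, text=True)
            out_text = fout.read_text() if fout.exists() else ""
        else:  # probcons
            cmd = ["probcons", str(fin)]
            res = subprocess.run(cmd, capture_output=True, text=True)
            out_text = res.stdout
        if res.returncode != 0 or not out_text.strip():
            raise RuntimeError(
                f"external aligner {aligner!r} failed "
                f"(exit {res.returncode}): {res.stderr.strip()[:500]}"
            )
    # parse aligned FASTA, restore input order by id
    aligned = {}
    cur = None
    for line in out_text.splitlines():
        if line.startswith(">"):
            cur = line[1:].split()[0]
            aligned[cur] = []
        elif cur is not None:
            aligned[cur].append(line.strip())
    return ["".join(aligned[str(i)]) for i in ids]


def align_region_sequence(
    region: Region, a: MultipleAlignment, params: RefineParams | None = None
) -> np.ndarray:
    """Sequence-based candidate for a region: a multiple alignment of the
    region's subsequences as a (k, m) residue-index matrix (GAP = -1).

    Chains contributing no residues come out all-gap; a region with no
    residues at all yields a zero-width candidate.
    """
    params = params or RefineParams()
    seqs = [
        a.structures[i].sequence[lo:hi]
        for i, (lo, hi) in enumerate(region.res_ranges)
    ]
    if sum(len(s) for s in seqs) == 0:
        return np.zeros((a.n_structures, 0), dtype=int)
    if params.aligner == "builtin":
        rows_txt = progressive_align(
            seqs, params.gap_open, params.gap_extend
        )
    else:
        nonempty = [i for i, s in enumerate(seqs) if s]
        if len(nonempty) < 2:
            rows_txt = progressive_align(seqs)
        else:
            sub = _run_external_aligner(
                params.aligner, [seqs[i] for i in nonempty], nonempty
            )
            width = len(sub[0])
            rows_txt = ["-" * width] * len(seqs)
            for i, row in zip(nonempty, sub):
                rows_txt[i] = row
    width = max((len(r) for r in rows_txt), default=0)
    cand = np.full((a.n_structures, width), GAP, dtype=int)
    for i, row in enumerate(rows_txt):
        lo = region.res_ranges[i][0]
        r = lo
        for c, ch in enumerate(row):
            if ch != "-":
                cand[i, c] = r
                r += 1
        if r != region.res_ranges[i][1]:
            raise RuntimeError(
                f"aligner {params.aligner!r} lost residues for row {i} "
                f"({r - lo} of {region.res_ranges[i][1] - lo})"
            )
    return cand


# -- structural candidate --------------------------------------------------


def align_region_structure(
    region: Region, a: MultipleAlignment, params: RefineParams | None = None
) -> np.ndarray:
    """Greedy structural candidate: extend inward from the flanking blocks.

    Alternating sides (left flank rightward first), each trial column takes
    the next unconsumed residue of every chain and is kept only if the
    consensus refit over flank block + accepted extension stays within
    ``extension_rmsd_threshold`` (average pairwise RMSD).  A side closes on
    its first rejection or when any chain runs out.  Unconsumed residues are
    emitted between the two extensions as single-residue non-core columns.

    With no flanking block on either side the region's current columns are
    returned unchanged (nothing to extend from).
    """
    params = params or RefineParams()
    k = a.n_structures
    if region.left_block is None and region.right_block is None:
        return a.rows[:, region.col_start:region.col_end].copy()

    def fit_cols(block):
        return [tuple(int(r) for r in a.rows[:, c]) for c in block.columns]

    lp = [lo for lo, _ in region.res_ranges]
    rp = [hi for _, hi in region.res_ranges]
    left_fit = fit_cols(region.left_block) if region.left_block else None
    right_fit = fit_cols(region.right_block) if region.right_block else None
    accepted_left, accepted_right = [], []
    left_open = left_fit is not None
    right_open = right_fit is not None
    turn = "L" if left_open else "R"

    def refit_rmsd(cols):
        sets = [
            np.array([a.structures[i].coords[col[i]] for col in cols])
            for i in range(k)
        ]
        return geometry.fit_rmsd(sets)

    while left_open or right_open:
        if turn == "L" and not left_open:
            turn = "R"
            continue
        if turn == "R" and not right_open:
            turn = "L"
            continue
        if any(lp[i] >= rp[i] for i in range(k)):
            # some chain exhausted: no further core extension on either side
            break
        if turn == "L":
            trial = tuple(lp)
            rmsd = refit_rmsd(left_fit + accepted_left + [trial])
            if rmsd <= params.extension_rmsd_threshold + 1e-9:
                accepted_left.append(trial)
                lp = [v + 1 for v in lp]
            else:
                left_open = False
            turn = "R"
        else:
            trial = tuple(v - 1 for v in rp)
            rmsd = refit_rmsd([trial] + accepted_right + right_fit)
            if rmsd <= params.extension_rmsd_threshold + 1e-9:
                accepted_right.insert(0, trial)
                rp = [v - 1 for v in rp]
            else:
                right_open = False
            turn = "L"

    leftover = []
    for i in range(k):
        for r in range(lp[i], rp[i]):
            col = [GAP] * k
            col[i] = r
            leftover.append(tuple(col))
    cols = accepted_left + leftover + accepted_right
    if not cols:
        return np.zeros((k, 0), dtype=int)
    return np.array(cols, dtype=int).T


# -- candidate choice and splicing -----------------------------------------


def _candidate_residue_sets(cand, k):
    return [sorted(int(r) for r in cand[i] if r != GAP) for i in range(k)]


def candidate_cons(cand, a, weights, superpositions, staccato_params=None):
    """Cons of a region candidate over its core columns, in the context of
    the full alignment (its weights and superposed frame).  A candidate with
    no core column scores :data:`ZERO_CORE_SCORE`."""
    staccato_params = staccato_params or staccato.StaccatoParams()
    if cand.shape[1] == 0:
        return ZERO_CORE_SCORE
    core = np.flatnonzero(np.all(cand != GAP, axis=0))
    if len(core) == 0:
        return ZERO_CORE_SCORE
    prime = staccato._seq_prime_rows(
        a.structures, cand, core, weights, staccato_params, partial=False
    )
    seq = staccato._seq_from_prime(prime, staccato_params)
    strv = staccato._str_rows(
        a.structures, cand, core, superpositions, staccato_params
    )
    return staccato.cons_score(seq, strv, staccato_params)


def score_candidates(
    seq_cand,
    str_cand,
    a,
    weights,
    superpositions,
    staccato_params=None,
    refine_params=None,
):
    """Choose between the sequence and structural candidates of a region.

    Both candidates must cover the identical residue sets.  The candidate
    with the lower Cons wins; exact ties go to ``tie_break`` (structural by
    default).  Returns ``(chosen_rows, info_dict)``.
    """
    refine_params = refine_params or RefineParams()
    k = a.n_structures
    if _candidate_residue_sets(seq_cand, k) != _candidate_residue_sets(str_cand, k):
        raise ValueError("candidates cover different residue sets")
    cons_seq = candidate_cons(seq_cand, a, weights, superpositions, staccato_params)
    cons_str = candidate_cons(str_cand, a, weights, superpositions, staccato_params)
    if cons_seq < cons_str:
        chosen, label = seq_cand, "sequence"
    elif cons_str < cons_seq:
        chosen, label = str_cand, "structural"
    else:
        label = refine_params.tie_break
        chosen = str_cand if label == "structural" else seq_cand
    info = {"cons_sequence": cons_seq, "cons_structural": cons_str, "chosen": label}
    return chosen, info


def splice(
    a: MultipleAlignment, col_start: int, col_end: int, candidate
) -> MultipleAlignment:
    """Replace the columns [col_start, col_end) with a candidate sub-alignment.

    The result is validated: columns outside the window are untouched by
    construction and the alignment invariants (row monotonicity, residue
    conservation) must still hold, otherwise the constructor raises.
    """
    candidate = np.asarray(candidate, dtype=int)
    new_rows = np.concatenate(
        [a.rows[:, :col_start], candidate, a.rows[:, col_end:]], axis=1
    )
    return MultipleAlignment(structures=a.structures, rows=new_rows)


@dataclass
class RefineResult:
    alignment: MultipleAlignment
    report: object
    decisions: list
    blocks_out: list = field(default_factory=list)  # block intervals in output


def refine_alignment(
    a: MultipleAlignment,
    refine_params: RefineParams | None = None,
    staccato_params=None,
    ref: MultipleAlignment | None = None,
) -> RefineResult:
    """Run the full repair pipeline on an alignment.

    Superposes the input over its core columns, infers anchor blocks,
    processes every region once left to right (sequence candidate vs greedy
    structural candidate, lower Cons wins), and rescoring the final
    alignment.  The decision log records both candidates' Cons per region.
    """
    refine_params = refine_params or RefineParams()
    staccato_params = staccato_params or staccato.StaccatoParams()
    core = a.core_columns
    if len(core) < 3:
        raise ValueError("refinement needs at least 3 core columns")
    sups = geometry.superpose_multiple(a, core)
    ann = infer_blocks(a, sups, refine_params)
    weights = staccato.sequence_weights(a)
    cur = a
    shift = 0
    decisions = []
    for region in ann.regions:
        seq_cand = align_region_sequence(region, a, refine_params)
        str_cand = align_region_structure(region, a, refine_params)
        chosen, info = score_candidates(
            seq_cand, str_cand, a, weights, sups, staccato_params, refine_params
        )
        cs, ce = region.col_start + shift, region.col_end + shift
        cur = splice(cur, cs, ce, chosen)
        shift += chosen.shape[1] - (region.col_end - region.col_start)
        info.update(
            region_columns=(region.col_start, region.col_end),
            width_in=region.col_end - region.col_start,
            width_out=int(chosen.shape[1]),
        )
        decisions.append(info)
    blocks_out = []
    delta = 0
    ri = 0
    for b in ann.blocks:
        while ri < len(ann.regions) and ann.regions[ri].col_start < b.start:
            delta += decisions[ri]["width_out"] - decisions[ri]["width_in"]
            ri += 1
        blocks_out.append(Block(b.start + delta, b.end + delta))
    report = staccato.score_alignment(cur, ref=ref, params=staccato_params)
    return RefineResult(
        alignment=cur, report=report, decisions=decisions, blocks_out=blocks_out
    )
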