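"""Deterministic generator of toy structure families with known ground truth.

Chains are ideal C-alpha traces (helix: 2.3 A radius, 1.5 A rise, 100 deg per
residue; strand: extended zigzag; loop: an open walk) copied across a family
with Gaussian coordinate noise, per-chain rigid placement, optional loop
deletions, and an optional *planted register error*: one chain's loop is both
shortened at its start and displaced so that the geometrically closest
correspondence is shifted by one or more residues relative to the sequence
truth.  The register is therefore geometrically near-tied (both the true and
the shifted pairing fall inside the greedy 5 A acceptance window) but the
conserved loop sequence — optionally carrying a distinctive motif — makes
the true register unambiguous to a sequence aligner.

Every family records its ground-truth alignment and its anchor annotation,
and :func:`corrupt_alignment` produces the register-shifted alignment a
purely geometric aligner would plausibly emit; tests and benchmarks then ask
whether refinement recovers the truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import refine, staccato
from .model_io import (
    GAP,
    MultipleAlignment,
    Structure,
    write_alignment,
    write_multichain_pdb,
)

AA20 = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class RegisterShift:
    """A planted register error in one loop of one chain.

    ``offset`` residues are deleted at the loop start of ``chain`` and the
    remaining loop residues are displaced ``displacement`` A sideways from
    the trace position one step behind their true correspondent, so geometry
    slightly favors the wrong (shifted) register while the conserved
    sequence (optionally the ``motif`` planted at ``motif_offset`` within the
    loop) favors the true one.
    """

    loop_index: int = 0  # which loop segment, counting loops only
    chain: int = 1
    offset: int = 1
    motif: str | None = "WWH"
    motif_offset: int = 1
    displacement: float = 4.5


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic family (same seed + spec -> identical output)."""

    k: int = 2
    segments: tuple = (("helix", 10), ("loop", 6), ("helix", 10))
    sigma: float = 0.15
    deletions: dict = field(default_factory=dict)  # chain -> tuple of positions
    shift: RegisterShift | None = None
    seed: int = 0
    placement: bool = True

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("a family needs at least 2 chains")
        if self.sigma < 0:
            raise ValueError("coordinate noise sigma must be >= 0")
        for kind, length in self.segments:
            if kind not in ("helix", "strand", "loop"):
                raise ValueError(f"unknown segment type {kind!r}")
            if length <= 0:
                raise ValueError("segment lengths must be positive")
        if 0 in self.deletions:
            raise ValueError("chain 0 is the reference and takes no deletions")


@dataclass
class Family:
    """One generated family: chains, ground truth, anchors, loop windows."""

    spec: SyntheticSpec
    structures: list
    true_alignment: MultipleAlignment
    annotation: refine.BlockAnnotation
    loop_windows: list  # (col_start, col_end) per loop segment


def _ideal_trace(segments):
    """Reference C-alpha coordinates for a segment plan, plus segment and
    loop column ranges."""
    coords = []
    seg_ranges = []
    loop_ranges = []
    z = 0.0
    pos = 0
    for kind, length in segments:
        start = pos
        if kind == "helix":
            for t in range(length):
                ang = np.deg2rad(100.0 * t)
                coords.append([2.3 * np.cos(ang), 2.3 * np.sin(ang), z + 1.5 * t])
            z += 1.5 * length + 2.0
        elif kind == "strand":
            for t in range(length):
                coords.append([0.5 * (-1) ** t, 0.0, z + 3.3 * t])
            z += 3.3 * length + 0.5
        else:  # loop: open walk, ~3.2 A steps, drifting off-axis
            for t in range(length):
                coords.append([1.0 + 0.4 * t, 1.5, z + 3.2 * t])
            z += 3.2 * length + 0.5
        pos += length
        seg_ranges.append((kind, start, pos))
        if kind == "loop":
            loop_ranges.append((start, pos))
    return np.asarray(coords, dtype=float), seg_ranges, loop_ranges


def _random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix(), rng.uniform(-20.0, 20.0, 3)


def generate_family(spec: SyntheticSpec) -> Family:
    """Build a family from a spec: chains, true alignment, anchor annotation.

    Chain 0 is the complete reference; other chains may lose loop residues to
    deletions (and to the planted shift), and every chain receives noise and,
    unless ``placement`` is off, its own random rigid placement.
    """
    rng = np.random.default_rng(spec.seed)
    coords0, seg_ranges, loop_ranges = _ideal_trace(spec.segments)
    n0 = len(coords0)
    loop_positions = {p for lo, hi in loop_ranges for p in range(lo, hi)}
    for chain, dels in spec.deletions.items():
        if chain >= spec.k:
            raise ValueError(f"deletion chain {chain} out of range")
        if any(p not in loop_positions for p in dels):
            raise ValueError("deletions are only permitted inside loop segments")

    # reference sequence: random, but loop residues distinct within each loop
    seq0 = list(rng.choice(list(AA20), size=n0))
    for lo, hi in loop_ranges:
        picks = rng.choice(list(AA20), size=hi - lo, replace=False)
        seq0[lo:hi] = list(picks)
    shift = spec.shift
    if shift is not None:
        if shift.loop_index >= len(loop_ranges):
            raise ValueError("shift.loop_index beyond the last loop segment")
        if not 0 < shift.chain < spec.k:
            raise ValueError("shift.chain must be a non-reference chain")
        lo, hi = loop_ranges[shift.loop_index]
        if shift.offset >= hi - lo:
            raise ValueError("shift offset consumes the whole loop")
        if shift.motif:
            mstart = lo + shift.motif_offset
            if mstart + len(shift.motif) > hi:
                raise ValueError("motif does not fit in the shifted loop")
            seq0[mstart:mstart + len(shift.motif)] = list(shift.motif)

    structures = []
    rows = np.full((spec.k, n0), GAP, dtype=int)
    for c in range(spec.k):
        deleted = set(spec.deletions.get(c, ()))
        if shift is not None and c == shift.chain:
            lo, hi = loop_ranges[shift.loop_index]
            deleted |= set(range(lo, lo + shift.offset))
        kept = [p for p in range(n0) if p not in deleted]
        base = np.empty((len(kept), 3))
        for idx, p in enumerate(kept):
            if (
                shift is not None
                and c == shift.chain
                and loop_ranges[shift.loop_index][0] <= p < loop_ranges[shift.loop_index][1]
            ):
                # displaced sideways off the position one register step back
                base[idx] = coords0[p - shift.offset] + np.array(
                    [0.0, shift.displacement, 0.0]
                )
            else:
                base[idx] = coords0[p]
        base = base + rng.normal(0.0, spec.sigma, base.shape)
        if spec.placement:
            R, t = _random_rigid(rng)
            base = base @ R.T + t
        structures.append(
            Structure(
                id=f"syn{spec.seed}_{chr(ord('A') + c)}",
                names=[seq0[p] for p in kept],
                coords=base,
                labels=[str(p + 1) for p in kept],
            )
        )
        rows[c, kept] = np.arange(len(kept))

    true_alignment = MultipleAlignment(structures=structures, rows=rows)
    blocks = [
        refine.Block(start, end)
        for kind, start, end in seg_ranges
        if kind != "loop"
    ]
    annotation = refine.BlockAnnotation(
        blocks=blocks, regions=refine._blocks_to_regions(true_alignment, blocks)
    )
    return Family(
        spec=spec,
        structures=structures,
        true_alignment=true_alignment,
        annotation=annotation,
        loop_windows=list(loop_ranges),
    )


def corrupt_alignment(
    true_alignment: MultipleAlignment,
    window,
    chain: int,
    offset: int,
    annotation: refine.BlockAnnotation | None = None,
) -> MultipleAlignment:
    """Shift one chain's residues by ``offset`` columns inside a window.

    Models the register error a purely geometric aligner can commit in a
    loop: block columns are untouched and the residue content of every chain
    is preserved.  Errors: a window overlapping an anchor block (when an
    annotation is supplied) or a shift pushing residues out of the window.
    """
    start, end = window
    if not 0 <= start <= end <= true_alignment.n_columns:
        raise ValueError(f"window {window} out of bounds")
    if annotation is not None:
        for b in annotation.blocks:
            if start < b.end and b.start < end:
                raise ValueError(
                    f"shift window {window} crosses anchor block "
                    f"[{b.start}, {b.end})"
                )
    rows = true_alignment.rows.copy()
    if offset == 0:
        return MultipleAlignment(structures=true_alignment.structures, rows=rows)
    sub = rows[chain, start:end]
    positions = np.flatnonzero(sub != GAP)
    targets = positions + offset
    if len(positions) and (targets.min() < 0 or targets.max() >= end - start):
        raise ValueError("register shift pushes residues out of the window")
    new_sub = np.full_like(sub, GAP)
    new_sub[targets] = sub[positions]
    rows[chain, start:end] = new_sub
    return MultipleAlignment(structures=true_alignment.structures, rows=rows)


@dataclass
class FamilyCase:
    """A family plus the register-corrupted alignment the suite refines."""

    family: Family
    corrupted: MultipleAlignment


def register_error_family(spec: SyntheticSpec, verify: bool = True) -> FamilyCase:
    """Generate a family with a planted shift and its corrupted alignment.

    With ``verify`` the construction is checked: the corrupted alignment must
    differ from the truth, and on the shifted region the sequence candidate's
    Cons must be strictly lower than the structural candidate's under default
    parameters (the planted error must be sequence-repairable), else a
    ``RuntimeError`` flags the spec as uninformative.
    """
    if spec.shift is None:
        raise ValueError("spec has no planted register shift")
    family = generate_family(spec)
    lo, hi = family.loop_windows[spec.shift.loop_index]
    corrupted = corrupt_alignment(
        family.true_alignment,
        (lo, hi),
        spec.shift.chain,
        -spec.shift.offset,
        family.annotation,
    )
    if verify:
        pc = staccato.percent_correct(corrupted, family.true_alignment)
        if pc >= 100.0:
            raise RuntimeError("corruption left the alignment unchanged")
        result = refine.refine_alignment(corrupted)
        informative = any(
            d["cons_sequence"] < d["cons_structural"] for d in result.decisions
        )
        if not informative:
            raise RuntimeError(
                "planted shift is not sequence-repairable under default "
                "parameters; adjust the spec"
            )
    return FamilyCase(family=family, corrupted=corrupted)


def standard_specs(n: int = 20, base_seed: int = 0) -> list:
    """The suite of n seeded register-error family specs used by the tests
    and the benchmark script (varying k, loop length, noise, motif use)."""
    specs = []
    for i in range(n):
        k = 2 + (i % 2)
        loop_len = 5 + (i % 4)
        helix_len = 9 + (i % 3)
        sigma = (0.10, 0.15, 0.20)[i % 3]
        motif = "WWH" if i % 5 != 4 else None
        deletions = {}
        if k == 3 and i % 4 == 3:
            # an extra middle-of-loop deletion in the third chain
            lo = helix_len  # loop starts right after the first helix
            deletions = {2: (lo + loop_len // 2,)}
        specs.append(
            SyntheticSpec(
                k=k,
                segments=(
                    ("helix", helix_len),
                    ("loop", loop_len),
                    ("helix", helix_len),
                ),
                sigma=sigma,
                deletions=deletions,
                shift=RegisterShift(
                    loop_index=0,
                    chain=1,
                    offset=1,
                    motif=motif,
                    motif_offset=1,
                    displacement=4.5,
                ),
                seed=base_seed + i,
            )
        )
    return specs


def make_suite(n: int = 20, base_seed: int = 0, verify: bool = True) -> list:
    """Generate the standard suite as :class:`FamilyCase` objects."""
    return [register_error_family(s, verify=verify) for s in standard_specs(n, base_seed)]


def write_fixture_set(directory, n_families: int = 20, base_seed: int = 0) -> dict:
    """Emit the standard suite as PDB + FASTA + annotation files.

    Each family gets its own subdirectory with a multi-chain C-alpha PDB,
    the ground-truth and corrupted aligned FASTA files, the anchor block
    intervals as TSV, and the generating spec as JSON.  Returns a mapping of
    relative file path to SHA-256 checksum (byte-identical across runs with
    the same seeds).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for case in make_suite(n_families, base_seed, verify=False):
        fam = case.family
        sub = directory / f"family_{fam.spec.seed:04d}"
        sub.mkdir(exist_ok=True)
        write_multichain_pdb(fam.structures, sub / "structures.pdb")
        write_alignment(fam.true_alignment, sub / "true.fasta")
        write_alignment(case.corrupted, sub / "corrupted.fasta")
        (sub / "blocks.tsv").write_text(
            "block_start\tblock_end\n"
            + "".join(f"{b.start}\t{b.end}\n" for b in fam.annotation.blocks)
        )
        spec_dict = asdict(fam.spec)
        spec_dict["deletions"] = {
            str(kk): list(v) for kk, v in spec_dict["deletions"].items()
        }
        (sub / "spec.json").write_text(json.dumps(spec_dict, indent=2) + "\n")
        for f in sorted(sub.iterdir()):
            checksums[f"{sub.name}/{f.name}"] = hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
    return checksums
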