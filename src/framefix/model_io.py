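"""Domain model and I/O: C-alpha structures, gapped multiple alignments, score reports.

The in-memory containers used by every other module:

* :class:`Structure` — one protein chain reduced to its C-alpha trace.
* :class:`MultipleAlignment` — a gapped residue-index matrix over k chains;
  every score and every refinement step operates on this object.
* :class:`ScoreReport` — one evaluation row (core length, RMSD, Seq/Str/Cons,
  partial metrics, optional percent-correct against a reference).

Residue positions are 0-based internally; PDB author numbering (including
insertion codes) is preserved only as opaque labels.  Aligned FASTA with gap
character ``-`` is the single alignment interchange format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO

GAP = -1

_AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
_AA3_TO_1 = {v: k for k, v in _AA1_TO_3.items()}


def _one_letter(resname: str) -> str:
    """Map a residue name to a 1-letter code; non-standard residues become 'X'."""
    name = resname.strip().upper()
    if len(name) == 1 and name in _AA1_TO_3:
        return name
    if name in _AA3_TO_1:
        return _AA3_TO_1[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None and info.is_amino_acid():
        code = info.one_letter_code.upper()
        if code.isalpha() and code in _AA1_TO_3:
            return code
    return "X"


@dataclass
class Structure:
    """A protein chain as an ordered C-alpha trace.

    Parameters
    ----------
    id : str
        Label for the chain (e.g. ``"1abc_A"``).
    names : tuple of str
        1-letter amino-acid code per residue, chain order.
    coords : ndarray, shape (n, 3)
        C-alpha coordinates in Angstroms.
    labels : tuple of str
        Original author numbering (with insertion codes) as opaque labels.
    n_missing_ca : int
        Residues dropped at parse time because they lacked a C-alpha atom.
    """

    id: str
    names: tuple
    coords: np.ndarray
    labels: tuple
    n_missing_ca: int = 0

    def __post_init__(self):
        self.names = tuple(self.names)
        self.labels = tuple(self.labels)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 3):
            raise ValueError(
                f"structure {self.id!r}: coords shape {self.coords.shape} does not "
                f"match {len(self.names)} residues"
            )
        if len(self.labels) != len(self.names):
            raise ValueError(f"structure {self.id!r}: labels/names length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"structure {self.id!r}: residue labels are not unique")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def sequence(self) -> str:
        return "".join(self.names)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return (
            self.id == other.id
            and self.names == other.names
            and self.labels == other.labels
            and np.allclose(self.coords, other.coords)
        )


@dataclass
class MultipleAlignment:
    """A gapped multiple alignment of k >= 2 structures.

    ``rows`` is an integer matrix of shape (k, n) whose entry is either a
    0-based residue index into the corresponding structure or :data:`GAP`.
    Reading the non-gap entries of any row left to right yields
    0, 1, 2, ... with no residue skipped or repeated.
    """

    structures: list
    rows: np.ndarray

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=int)
        self.validate()

    def validate(self) -> None:
        k = len(self.structures)
        if k < 2:
            raise ValueError("an alignment needs at least 2 structures")
        if self.rows.ndim != 2 or self.rows.shape[0] != k:
            raise ValueError(
                f"rows shape {self.rows.shape} does not match {k} structures"
            )
        if self.rows.shape[1] == 0:
            raise ValueError("alignment has zero columns")
        for i, s in enumerate(self.structures):
            entries = self.rows[i][self.rows[i] != GAP]
            if not np.array_equal(entries, np.arange(len(s))):
                raise ValueError(
                    f"row {i} ({s.id}): non-gap entries must enumerate residues "
                    f"0..{len(s) - 1} in order"
                )

    # -- basic geometry of the matrix -------------------------------------

    @property
    def n_structures(self) -> int:
        return len(self.structures)

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    @property
    def core_mask(self) -> np.ndarray:
        """Boolean mask over columns where every structure contributes a residue."""
        return np.all(self.rows != GAP, axis=0)

    @property
    def core_columns(self) -> np.ndarray:
        return np.flatnonzero(self.core_mask)

    @property
    def core_length(self) -> int:
        return int(self.core_mask.sum())

    def column_residues(self, c: int):
        """(structure index, residue index) pairs present in column ``c``."""
        col = self.rows[:, c]
        return [(i, int(r)) for i, r in enumerate(col) if r != GAP]

    def row_string(self, i: int) -> str:
        s = self.structures[i]
        return "".join(
            "-" if r == GAP else s.names[r] for r in self.rows[i]
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MultipleAlignment):
            return NotImplemented
        return (
            [s.id for s in self.structures] == [s.id for s in other.structures]
            and [s.sequence for s in self.structures]
            == [s.sequence for s in other.structures]
            and np.array_equal(self.rows, other.rows)
        )


# Column order of the tabular report.
REPORT_COLUMNS = (
    "Core length", "RMSD", "Seq", "Str", "Cons",
    "Partial length", "Partial Seq", "% Correct",
)


@dataclass
class ScoreReport:
    """One evaluation row for a multiple alignment (lower scores are better)."""

    core_length: int
    rmsd_core: float
    seq_core: float
    str_core: float
    cons_core: float
    partial_length: float
    partial_factor_p: float
    seq_partial: float
    percent_correct: float | None = None

    def __post_init__(self):
        if self.partial_length + 1e-9 < self.core_length:
            raise ValueError("partial length cannot be below core length")
        if not 0.0 <= self.partial_factor_p <= 1.0 + 1e-12:
            raise ValueError("partial alignment factor must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "Core length": self.core_length,
            "RMSD": self.rmsd_core,
            "Seq": self.seq_core,
            "Str": self.str_core,
            "Cons": self.cons_core,
            "Partial length": self.partial_length,
            "Partial Seq": self.seq_partial,
            "% Correct": self.percent_correct,
            "partial_factor_p": self.partial_factor_p,
        }
        return d


# -- readers / writers -----------------------------------------------------


def read_structure(path, chain: str, id: str | None = None) -> Structure:
    """Read one chain's C-alpha trace from a PDB file.

    Residues without a C-alpha atom are dropped and counted in
    ``Structure.n_missing_ca``.  Waters are ignored.

    Raises
    ------
    ValueError
        If the chain is absent (the message lists available chains) or the
        chain contains no C-alpha atoms at all.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        available = ", ".join(c.name for c in model) or "(none)"
        raise ValueError(
            f"{path}: chain {chain!r} not found; available chains: {available}"
        )
    names, coords, labels = [], [], []
    dropped = 0
    for res in ch:
        if res.is_water():
            continue
        ca = None
        for atom in res:
            if atom.name == "CA":
                ca = atom
                break
        if ca is None:
            dropped += 1
            continue
        names.append(_one_letter(res.name))
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        labels.append(f"{res.seqid.num}{res.seqid.icode.strip()}")
    if not names:
        raise ValueError(f"{path}: chain {chain!r} has no C-alpha atoms")
    return Structure(
        id=id or f"{Path(path).stem}_{chain}",
        names=names,
        coords=np.asarray(coords, dtype=float),
        labels=labels,
        n_missing_ca=dropped,
    )


def write_structure(structure: Structure, path, chain: str = "A") -> None:
    """Write a C-alpha-only PDB file (ATOM records, one chain)."""
    lines = []
    for i, (name, xyz) in enumerate(zip(structure.names, structure.coords)):
        res3 = _AA1_TO_3.get(name, "UNK")
        x, y, z = xyz
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {res3:3s} {chain}{i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_multichain_pdb(structures, path) -> None:
    """Write several chains (A, B, ...) into a single C-alpha-only PDB file."""
    lines = []
    serial = 1
    for ci, structure in enumerate(structures):
        chain = chr(ord("A") + ci)
        for i, (name, xyz) in enumerate(zip(structure.names, structure.coords)):
            res3 = _AA1_TO_3.get(name, "UNK")
            x, y, z = xyz
            lines.append(
                f"ATOM  {serial:5d}  CA  {res3:3s} {chain}{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append(f"TER   {serial:5d}      {lines[-1][17:26]}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_alignment(path, structures) -> MultipleAlignment:
    """Read an aligned FASTA file into a :class:`MultipleAlignment`.

    Records pair with ``structures`` in order.  The ungapped sequence of each
    record must match the structure's sequence exactly; the first differing
    position is reported otherwise.  Only ``-`` is accepted as gap.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != len(structures):
        raise ValueError(
            f"{path}: {len(records)} records but {len(structures)} structures"
        )
    if not records:
        raise ValueError(f"{path}: empty alignment file")
    n = len(records[0].seq)
    rows = np.full((len(structures), n), GAP, dtype=int)
    for i, (rec, s) in enumerate(zip(records, structures)):
        seq = str(rec.seq)
        if "." in seq:
            raise ValueError(
                f"{path}: record {rec.id}: '.' gaps are not supported, use '-'"
            )
        if len(seq) != n:
            raise ValueError(
                f"{path}: record {rec.id} has length {len(seq)}, expected {n}"
            )
        ungapped = seq.replace("-", "")
        if len(ungapped) != len(s):
            raise ValueError(
                f"{path}: record {rec.id} has {len(ungapped)} residues but "
                f"structure {s.id} has {len(s)}"
            )
        for pos, (a, b) in enumerate(zip(ungapped, s.sequence)):
            if a.upper() != b.upper():
                raise ValueError(
                    f"{path}: record {rec.id} disagrees with structure {s.id} "
                    f"at residue position {pos} ({a!r} vs {b!r})"
                )
        r = 0
        for c, ch in enumerate(seq):
            if ch != "-":
                rows[i, c] = r
                r += 1
    return MultipleAlignment(structures=list(structures), rows=rows)


def write_alignment(a: MultipleAlignment, path) -> None:
    """Write aligned FASTA (one line per sequence; round-trips exactly)."""
    if a.n_columns == 0:
        raise ValueError("refusing to write an alignment with zero columns")
    with open(path, "w") as fh:
        for i, s in enumerate(a.structures):
            fh.write(f">{s.id}\n{a.row_string(i)}\n")


def write_report(report: ScoreReport, path) -> None:
    """Write a score report as TSV plus a JSON sidecar (``<path>.json``)."""
    d = report.to_dict()
    values = []
    for key in REPORT_COLUMNS:
        v = d[key]
        if v is None:
            values.append("NA")
        elif isinstance(v, float):
            values.append(f"{v:.4f}")
        else:
            values.append(str(v))
    path = Path(path)
    path.write_text(
        "\t".join(REPORT_COLUMNS) + "\n" + "\t".join(values) + "\n"
    )
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(d, indent=2, sort_keys=True) + "\n"
    )
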