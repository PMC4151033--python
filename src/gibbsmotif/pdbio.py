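"""Cα-only protein structure model and PDB input/output.

Every downstream computation — seed feasibility, Gibbs scoring, RMSD — works
on a single point per residue, the Cα atom. This module reduces a PDB file to
that representation: an ordered list of residues, each with its one-letter
symbol, original residue number and Cα coordinates, plus the all-pairs
Cα–Cα distance matrix computed once on construction.

PDB parsing is delegated to :mod:`gemmi`; a fixed-column validation pass runs
first so malformed coordinate fields are reported with their line number
(gemmi silently tolerates them).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio.SeqUtils import seq1

__all__ = [
    "Residue",
    "ProteinStructure",
    "PDBParseError",
    "EmptyStructureError",
    "read_calpha_structure",
    "residue_distance",
    "contact_map",
    "write_calpha_pdb",
    "to_fasta",
]

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Nonstandard three-letter codes mapped onto a standard parent residue.
NONSTANDARD_MAP = {"MSE": "M"}


class PDBParseError(ValueError):
    """A PDB record could not be interpreted."""


class EmptyStructureError(ValueError):
    """No Cα atoms were found on the requested chain."""


@dataclass(frozen=True)
class Residue:
    """One amino acid reduced to its Cα atom.

    Parameters
    ----------
    symbol : str
        One-letter code, one of the 20 standard amino acids.
    seq_index : int
        Residue number as given in the source file (used for reporting).
    chain_id : str
        Chain identifier of the source chain.
    coords : numpy.ndarray
        Cα coordinates in Å, shape ``(3,)``.
    """

    symbol: str
    seq_index: int
    chain_id: str
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.symbol not in STANDARD_AA:
            raise ValueError(f"unknown residue symbol {self.symbol!r}")
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


class ProteinStructure:
    """An ordered chain of Cα residues with a cached distance matrix.

    Parameters
    ----------
    id : str
        Label of the structure (e.g. file stem or PDB id).
    residues : sequence of Residue
        Residues in chain order.
    """

    def __init__(self, id: str, residues: list[Residue]):
        self.id = str(id)
        self.residues = list(residues)
        coords = np.array([r.coords for r in self.residues], dtype=float)
        self.coords = coords.reshape(len(self.residues), 3)
        if len(self.residues):
            diff = self.coords[:, None, :] - self.coords[None, :, :]
            self.dist = np.sqrt((diff**2).sum(axis=2))
        else:
            self.dist = np.zeros((0, 0))

    def __len__(self) -> int:
        return len(self.residues)

    def __repr__(self) -> str:
        return f"ProteinStructure({self.id!r}, {len(self)} residues)"

    @property
    def sequence(self) -> str:
        """One-letter sequence of the parsed residues."""
        return "".join(r.symbol for r in self.residues)


def _validate_atom_lines(pdb_text: str) -> None:
    """Raise PDBParseError naming the first line with unreadable coordinates."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM record")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            fld = line[lo:hi]
            try:
                float(fld)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed coordinate field {fld.strip()!r}"
                ) from None


def read_calpha_structure(
    pdb_text: str, chain: str | None = None, id: str = "structure"
) -> ProteinStructure:
    """Parse PDB text into a Cα-only :class:`ProteinStructure`.

    Only the first model is read. If *chain* is None the first chain that
    carries Cα atoms is used. Alternate locations resolve to the
    first-listed conformer; residues without a Cα atom are skipped with a
    warning; MSE is read as methionine and any other nonstandard residue is
    dropped with a warning so the 20-letter alphabet stays valid.

    Raises
    ------
    PDBParseError
        If a coordinate field cannot be read (the message names the line).
    EmptyStructureError
        If no Cα atom is found on the selected chain.
    """
    _validate_atom_lines(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise EmptyStructureError("no models in input")

    model = st[0]
    chains = [c for c in model if chain is None or c.name == chain]
    residues: list[Residue] = []
    for ch in chains:
        for res in ch:
            ca = None
            for atom in res:
                if atom.name == "CA" and atom.element.name == "C":
                    ca = atom  # first-listed altloc wins
                    break
            if ca is None:
                if res.name != "HOH":
                    logger.warning(
                        "%s %s%d: no CA atom, residue skipped", id, res.name, res.seqid.num
                    )
                continue
            symbol = seq1(res.name, custom_map=NONSTANDARD_MAP)
            if symbol not in STANDARD_AA:
                logger.warning(
                    "%s %s%d: nonstandard residue dropped", id, res.name, res.seqid.num
                )
                continue
            residues.append(
                Residue(
                    symbol=symbol,
                    seq_index=res.seqid.num,
                    chain_id=ch.name,
                    coords=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                )
            )
        if residues:
            break  # default: first chain that yields residues
    if not residues:
        raise EmptyStructureError(
            f"no CA atoms found{' on chain ' + chain if chain else ''}"
        )
    return ProteinStructure(id=id, residues=residues)


def residue_distance(s: ProteinStructure, i: int, j: int) -> float:
    """Euclidean Cα–Cα distance in Å between residues *i* and *j*."""
    n = len(s)
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"residue index out of range (n={n}, i={i}, j={j})")
    return float(s.dist[i, j])


def contact_map(s: ProteinStructure, cutoff: float) -> np.ndarray:
    """Binary residue contact map: 1 iff Cα distance < *cutoff* (diagonal 0).

    Contact maps under a 7–12 Å cutoff are the standard 2D signature of a
    fold; they are used here only for inspecting reported alignments.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cm = (s.dist < cutoff).astype(np.int8)
    np.fill_diagonal(cm, 0)
    return cm


def write_calpha_pdb(s: ProteinStructure) -> str:
    """Serialize a Cα-only structure back to PDB ATOM records."""
    lines = []
    for serial, r in enumerate(s.residues, start=1):
        x, y, z = r.coords
        lines.append(
            f"ATOM  {serial:5d}  CA  {_ONE_TO_THREE[r.symbol]} {r.chain_id[:1] or 'A'}"
            f"{r.seq_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def to_fasta(s: ProteinStructure) -> str:
    """One-letter sequence of the structure in FASTA format."""
    seq = s.sequence
    body = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
    return f">{s.id}\n{body}\n"


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
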