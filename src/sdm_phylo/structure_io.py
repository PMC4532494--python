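"""Reading protein domain coordinates into the internal structure model.

A *domain* here is one chain segment of a PDB or mmCIF file reduced to
its Calpha trace: an ordered list of residues, each carrying its author
residue number, one-letter amino-acid code and Calpha coordinate in
Angstrom.  All downstream alignment math indexes residues by their
0-based position in this filtered list, never by author numbering, so
insertion codes and numbering gaps cannot perturb the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from sdm_phylo.errors import DegenerateInputError, InputError, LookupError_

logger = logging.getLogger(__name__)

MIN_RESIDUES = 3


@dataclass(frozen=True)
class Residue:
    number: int
    amino_acid: str  # one-letter code, 'X' if unknown
    ca_xyz: tuple[float, float, float]  # Angstrom


@dataclass
class DomainStructure:
    """Ordered Calpha trace plus sequence for one protein domain."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """N x 3 array of Calpha coordinates in residue order (Angstrom)."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float).reshape(-1, 3)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def __len__(self) -> int:
        return self.length


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _pick_ca(residue: gemmi.Residue) -> Optional[gemmi.Atom]:
    """Highest-occupancy CA atom; ties broken by file order; None if absent."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element == gemmi.Element("Ca"):
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_structure(
    path: str | Path,
    chain: str,
    residue_range: Optional[tuple[int, int]] = None,
    fmt: Optional[str] = None,
) -> DomainStructure:
    """Read the Calpha trace of one chain (optionally a residue interval).

    Parameters
    ----------
    path:
        PDB or mmCIF file.  The format is inferred from the extension
        unless `fmt` ("pdb" or "cif") overrides it.
    chain:
        Chain identifier within the first model.
    residue_range:
        Optional inclusive (start, end) interval of author residue
        numbers.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"structure file not found: {path}")
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            coor = {"pdb": gemmi.CoorFormat.Pdb, "cif": gemmi.CoorFormat.Mmcif}[fmt]
            st = gemmi.read_structure(str(path), format=coor)
    except KeyError:
        raise InputError(f"unknown structure format: {fmt!r} (use 'pdb' or 'cif')")
    except Exception as exc:  # gemmi raises RuntimeError/ValueError on bad files
        raise InputError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise InputError(f"{path} contains no models")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        available = ", ".join(c.name for c in model) or "<none>"
        raise LookupError_(f"chain {chain!r} not in {path} (available: {available})")

    residues: list[Residue] = []
    for res in ch:
        num = res.seqid.num
        if residue_range is not None and not (residue_range[0] <= num <= residue_range[1]):
            continue
        ca = _pick_ca(res)
        if ca is None:
            logger.warning("%s chain %s residue %s %s lacks a CA atom; skipped",
                           path.name, chain, num, res.name)
            continue
        residues.append(Residue(num, _one_letter(res.name), (ca.pos.x, ca.pos.y, ca.pos.z)))

    if len(residues) < MIN_RESIDUES:
        raise DegenerateInputError(
            f"{path} chain {chain} selection has {len(residues)} CA atoms (< {MIN_RESIDUES})"
        )
    dom_id = path.stem if residue_range is None else f"{path.stem}_{residue_range[0]}-{residue_range[1]}"
    return DomainStructure(id=dom_id, residues=residues)


def extract_sequence(structure: DomainStructure) -> str:
    """One-letter sequence of the domain (unknown residues map to 'X')."""
    return structure.sequence


def from_arrays(
    dom_id: str,
    coords: np.ndarray,
    sequence: str,
    numbers: Optional[Sequence[int]] = None,
) -> DomainStructure:
    """Build a DomainStructure from coordinates + sequence (simulator, tests)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] != len(sequence):
        raise InputError("coords must be N x 3 and match the sequence length")
    if numbers is None:
        numbers = range(1, len(sequence) + 1)
    residues = [
        Residue(int(n), aa, (float(x), float(y), float(z)))
        for n, aa, (x, y, z) in zip(numbers, sequence, coords)
    ]
    return DomainStructure(id=dom_id, residues=residues)


def write_pdb(structure: DomainStructure, path: str | Path, chain: str = "A") -> None:
    """Write the Calpha trace as a minimal single-chain PDB file."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    ch = gemmi.Chain(chain)
    three = {v: k for k, v in _AA3TO1.items()}
    for res in structure.residues:
        r = gemmi.Residue()
        r.name = three.get(res.amino_acid, "UNK")
        r.seqid = gemmi.SeqId(res.number, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*res.ca_xyz)
        atom.occ = 1.0
        r.add_atom(atom)
        ch.add_residue(r)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_fasta(entries: dict[str, str], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 60 columns."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    from Bio.SeqIO import parse as seqio_parse

    out: dict[str, str] = {}
    for rec in seqio_parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise InputError(f"no FASTA records in {path}")
    return out


_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
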