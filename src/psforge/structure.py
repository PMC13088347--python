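"""Cα extraction from PDB files and residue contact matrices.

A pair of residues is in contact when their Cα atoms lie within a
distance threshold (default 10 Å, inclusive).  The diagonal is fixed to
1 by convention but is never scored or used in training.  Residues
without a resolved Cα are masked, not zero-filled: their rows and
columns carry no contact information.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import squareform, pdist

from .sequences import AA_INDEX, ProteinSequence

#: residue used as a masked placeholder where the identity is unknown
#: (numbering gaps); its features are never consumed because the residue
#: stays masked everywhere downstream.
GAP_PLACEHOLDER = "G"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine, routinely modelled as Met
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}


class StructureError(ValueError):
    """Missing chain, unusable coordinates, or malformed structure input."""


@dataclass
class StructureModel:
    """Per-residue Cα coordinates aligned to a sequence.

    ``calpha_coords`` has shape (n, 3) with NaN rows for unresolved
    residues; ``resolved_mask`` marks residues with usable coordinates.
    """

    sequence: ProteinSequence
    calpha_coords: np.ndarray
    resolved_mask: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sequence)
        self.calpha_coords = np.asarray(self.calpha_coords, dtype=float).reshape(n, 3)
        self.resolved_mask = np.asarray(self.resolved_mask, dtype=bool).reshape(n)
        if np.any(~np.isfinite(self.calpha_coords[self.resolved_mask])):
            raise StructureError("resolved residues must have finite coordinates")

    @property
    def n(self) -> int:
        return len(self.sequence)


@dataclass
class ResidueContactMatrix:
    """Symmetric binary Cα contact matrix with a per-residue validity mask."""

    entries: np.ndarray
    mask: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.entries.shape[0]
        if self.entries.shape != (n, n) or self.mask.shape != (n,):
            raise StructureError("contact matrix / mask shapes disagree")
        if not np.array_equal(self.entries, self.entries.T):
            raise StructureError("contact matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.entries.shape[0]


def _pick_calpha(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy Cα of a residue; first wins on occupancy ties."""
    best = None
    for atom in residue:
        if atom.name != "CA" or atom.element != gemmi.Element("C"):
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_calpha_coordinates(
    structure_file: str | Path, chain: str
) -> StructureModel:
    """Read one chain's Cα trace from a PDB file.

    Residues appear in author order; numbering gaps and residues lacking
    a Cα record become unresolved (masked) entries.  Alternate locations
    resolve to the highest-occupancy conformer, first on ties.
    """
    path = Path(structure_file)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: structure contains no models")
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        available = [c.name for c in model]
        raise StructureError(
            f"{path}: chain {chain!r} not found (available: {available})"
        )

    letters: list[str] = []
    coords: list[tuple[float, float, float]] = []
    mask: list[bool] = []
    prev_seqid: int | None = None
    for res in ch:
        info = gemmi.find_tabulated_residue(res.name)
        is_aa = (info is not None and info.is_amino_acid()) or res.name in _THREE_TO_ONE
        if not is_aa:
            continue  # waters, ligands, ions
        seqid = res.seqid.num
        if prev_seqid is not None:
            for _ in range(prev_seqid + 1, seqid):  # numbering gap
                letters.append(GAP_PLACEHOLDER)
                coords.append((np.nan,) * 3)
                mask.append(False)
        prev_seqid = seqid
        one = _THREE_TO_ONE.get(res.name, "X")
        atom = _pick_calpha(res)
        if atom is None or one not in AA_INDEX:
            letters.append(one if one in AA_INDEX else GAP_PLACEHOLDER)
            coords.append((np.nan,) * 3)
            mask.append(False)
        else:
            letters.append(one)
            coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
            mask.append(True)

    if not any(mask):
        raise StructureError(f"{path}: chain {chain!r} has no Cα atoms")
    seq = ProteinSequence(id=f"{path.stem}_{chain}", residues="".join(letters))
    return StructureModel(seq, np.array(coords, dtype=float), np.array(mask))


def compute_rcm(
    model: StructureModel, threshold_angstrom: float = 10.0
) -> ResidueContactMatrix:
    """Contact matrix under the inclusive Cα distance rule.

    entries[i, j] = 1 iff both residues are resolved and their Cα
    distance is <= ``threshold_angstrom``; the diagonal is set to 1.
    """
    if threshold_angstrom <= 0:
        raise StructureError(
            f"contact threshold must be positive, got {threshold_angstrom}"
        )
    if not model.resolved_mask.any():
        raise StructureError("no resolved residues to build a contact matrix from")
    n = model.n
    entries = np.zeros((n, n), dtype=np.uint8)
    idx = np.flatnonzero(model.resolved_mask)
    if idx.size >= 2:
        sub = squareform(pdist(model.calpha_coords[idx])) <= threshold_angstrom
        entries[np.ix_(idx, idx)] = sub.astype(np.uint8)
    np.fill_diagonal(entries, 1)
    return ResidueContactMatrix(entries, model.resolved_mask.copy(), threshold_angstrom)


def write_pdb(model: StructureModel, path: str | Path, chain: str = "A") -> None:
    """Minimal Cα-trace PDB export (resolved residues only)."""
    with open(path, "w") as fh:
        serial = 0
        for i, aa in enumerate(model.sequence.residues):
            if not model.resolved_mask[i]:
                continue
            serial += 1
            x, y, z = model.calpha_coords[i]
            fh.write(
                f"ATOM  {serial:5d}  CA  {ONE_TO_THREE[aa]} {chain}{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C\n"
            )
        fh.write("END\n")


def write_rcm_text(rcm: ResidueContactMatrix, path: str | Path) -> None:
    """Dense whitespace text export: header ``n threshold``, mask row, matrix."""
    with open(path, "w") as fh:
        fh.write(f"{rcm.n} {rcm.threshold:g}\n")
        fh.write(" ".join("1" if m else "0" for m in rcm.mask) + "\n")
        for row in rcm.entries:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_rcm_text(path: str | Path) -> ResidueContactMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise StructureError(f"{path}: expected header 'n threshold'")
        n, threshold = int(header[0]), float(header[1])
        mask = np.array(fh.readline().split(), dtype=int).astype(bool)
        entries = np.loadtxt(fh, dtype=np.uint8, ndmin=2)
    if entries.shape != (n, n) or mask.shape != (n,):
        raise StructureError(f"{path}: matrix dimensions disagree with header")
    return ResidueContactMatrix(entries, mask, threshold)
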