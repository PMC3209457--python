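"""Structure I/O: Cα representations of protein chains and residue selections.

The whole package operates on a coarse-grained view of a protein: one site
per residue, located at the Cα atom.  This module reads such a view from PDB
files (via biotite), writes it back, and resolves author residue numbers —
the coordinate system in which binding motifs and mutation sites are usually
communicated (e.g. "residues 71-90", "position 84") — into 0-based indices
used internally.

Conventions
-----------
* Indices are 0-based internally; every user-facing interface speaks author
  residue numbers from the PDB.
* Alternate locations: the first-listed altloc is kept.
* Insertion codes are rejected with an explicit error; renumber upstream.
* Missing residues leave gaps in the numbering; a selection that touches a
  gap raises :class:`~motifdyn.exceptions.SelectionError` instead of
  silently shrinking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .exceptions import SelectionError, StructureError

__all__ = [
    "Structure",
    "Selection",
    "MutationSpec",
    "read_structure",
    "write_structure",
    "resolve_selection",
]

#: One-letter → three-letter amino acid code map (used by MutationSpec).
_AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
_AA_3 = set(_AA_1TO3.values())


@dataclass
class Structure:
    """An ordered set of Cα sites with author residue numbering.

    Parameters
    ----------
    chain_ids : array of str, shape (N,)
    residue_numbers : array of int, shape (N,)
    residue_names : array of str, shape (N,)
        Three-letter residue codes.
    coords : array of float, shape (N, 3)
        Cα positions in Å.
    model_id : int
        Which model of a multi-model file the coordinates came from
        (0-based).
    metadata : dict
        Free-form annotations (synthetic fixtures record their motif and
        suggested mutation site here); not part of structural identity.
    """

    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    coords: np.ndarray
    model_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype="U3")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_numbers)
        if n < 2:
            raise StructureError(f"a structure needs at least 2 sites, got {n}")
        if self.coords.shape != (n, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match {n} sites"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("coordinates must be finite")
        keys = list(zip(self.chain_ids.tolist(), self.residue_numbers.tolist()))
        if len(set(keys)) != n:
            raise StructureError("(chain_id, residue_number) pairs must be unique")
        if keys != sorted(keys):
            raise StructureError("sites must be ordered by chain then residue number")

    @property
    def n_sites(self) -> int:
        return len(self.residue_numbers)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        return Structure(
            chain_ids=self.chain_ids.copy(),
            residue_numbers=self.residue_numbers.copy(),
            residue_names=self.residue_names.copy(),
            coords=np.asarray(coords, dtype=float).copy(),
            model_id=self.model_id,
            metadata=dict(self.metadata),
        )


@dataclass(frozen=True)
class Selection:
    """A set of author residue numbers, optionally restricted to one chain."""

    residue_numbers: frozenset
    chain_id: str | None = None

    def __init__(self, residue_numbers, chain_id: str | None = None):
        nums = frozenset(int(r) for r in residue_numbers)
        if not nums:
            raise SelectionError("selection must be non-empty")
        object.__setattr__(self, "residue_numbers", nums)
        object.__setattr__(self, "chain_id", chain_id)

    @classmethod
    def from_range(cls, start: int, stop: int, chain_id: str | None = None) -> "Selection":
        """Inclusive residue-number range, e.g. ``from_range(71, 90)``."""
        if stop < start:
            raise SelectionError(f"empty range {start}-{stop}")
        return cls(range(start, stop + 1), chain_id)


@dataclass(frozen=True)
class MutationSpec:
    """A point mutation modeled as a rescaling of incident network springs.

    ``spring_scale`` multiplies the force constant of every elastic-network
    contact incident to ``residue_number``.  Values below 1 weaken the local
    packing (the model for hydrophobic→hydrophilic substitutions such as
    Ala→Thr or Phe→Ser); values above 1 stiffen it.
    """

    residue_number: int
    from_aa: str = "UNK"
    to_aa: str = "UNK"
    spring_scale: float = 0.5
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if not self.spring_scale > 0:
            raise ValueError(f"spring_scale must be > 0, got {self.spring_scale}")
        for attr in ("from_aa", "to_aa"):
            code = getattr(self, attr).upper()
            if len(code) == 1:
                code = _AA_1TO3.get(code, code)
            object.__setattr__(self, attr, code)

    @property
    def label(self) -> str:
        return f"{self.from_aa.capitalize()}{self.residue_number}{self.to_aa.capitalize()}"


def read_structure(path, model_index: int = 0) -> Structure:
    """Read the Cα trace of one model from a PDB file.

    Keeps only Cα atoms of canonical amino acids; the first alternate
    location wins; insertion codes are rejected.

    Raises
    ------
    OSError
        Unreadable file.
    IndexError
        ``model_index`` out of range for the file.
    StructureError
        No Cα atoms survive filtering, or insertion codes present.
    """
    if model_index < 0:
        raise IndexError(f"model_index must be >= 0, got {model_index}")
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if model_index >= n_models:
        raise IndexError(
            f"model_index {model_index} out of range: file has {n_models} model(s)"
        )
    atoms = pdb.get_structure(model=model_index + 1, altloc="first")
    mask = (
        (atoms.atom_name == "CA")
        & bst.filter_canonical_amino_acids(atoms)
        & ~atoms.hetero
    )
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise StructureError(f"no Cα atoms of standard residues in {path}")
    if np.any(ca.ins_code != ""):
        bad = sorted(set(ca.res_id[ca.ins_code != ""].tolist()))
        raise StructureError(
            f"insertion codes are not supported (residues {bad}); renumber first"
        )
    # first altloc also implies first occurrence of duplicated CA records
    _, first = np.unique(
        np.char.add(ca.chain_id.astype("U8"), ca.res_id.astype("U16")),
        return_index=True,
    )
    ca = ca[np.sort(first)]
    return Structure(
        chain_ids=ca.chain_id,
        residue_numbers=ca.res_id,
        residue_names=ca.res_name,
        coords=ca.coord,
        model_id=model_index,
    )


def _to_atom_array(s: Structure) -> bst.AtomArray:
    n = s.n_sites
    arr = bst.AtomArray(n)
    arr.chain_id = s.chain_ids
    arr.res_id = s.residue_numbers
    arr.res_name = s.residue_names
    arr.atom_name = np.full(n, "CA", dtype="U6")
    arr.element = np.full(n, "C", dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.coord = s.coords.astype(np.float32)
    return arr


def write_structure(s: Structure, path) -> None:
    """Write a Structure as a PDB file with one CA ATOM record per site.

    Coordinates are rounded to 3 decimals by the PDB fixed-column format, so
    ``read_structure(write_structure(s))`` reproduces ``s`` to 0.001 Å.
    """
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(s))
    pdb.write(str(path))


def write_multi_model(structures: list[Structure], path) -> None:
    """Write several same-topology structures as MODEL/ENDMDL blocks."""
    if not structures:
        raise StructureError("need at least one structure")
    ref = structures[0]
    stack = bst.stack([_to_atom_array(ref.with_coords(s.coords)) for s in structures])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def resolve_selection(s: Structure, sel: Selection) -> np.ndarray:
    """Map a residue-number selection to 0-based site indices.

    Returns a strictly increasing index array with one entry per selected
    residue.  Residue numbers that do not resolve (including numbers that
    fall in gaps of the author numbering) raise
    :class:`~motifdyn.exceptions.SelectionError` naming the missing residues.
    """
    if sel.chain_id is not None:
        chain_mask = s.chain_ids == sel.chain_id
        if not chain_mask.any():
            raise SelectionError(f"chain {sel.chain_id!r} not present in structure")
    else:
        chain_mask = np.ones(s.n_sites, dtype=bool)
    wanted = sel.residue_numbers
    hit = chain_mask & np.isin(s.residue_numbers, sorted(wanted))
    found = set(s.residue_numbers[hit].tolist())
    missing = sorted(wanted - found)
    if missing:
        raise SelectionError(f"residues not found in structure: {missing}")
    # uniqueness within (chain, resnum) plus an unrestricted chain_id could
    # still match one residue number in two chains → over-resolution
    idx = np.flatnonzero(hit)
    if len(idx) != len(wanted):
        raise SelectionError(
            "selection is ambiguous across chains; specify chain_id"
        )
    return idx
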