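"""Structures, PDB I/O and canonical atom-pair indexing.

A docked complex is held as a :class:`TypedStructure`: two rigid partners
(receptor and ligand) with coordinates in Angstrom, residue identity, a
heavy-atom flag per atom, and — once a typing table has been applied —
an integer atom-type label per atom.  Decoys of one complex share the
receptor and differ only in the rigid-body pose of the ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .tables import TypingTable, TypingError

__all__ = [
    "AtomSet",
    "TypedStructure",
    "EmptyPartnerError",
    "parse_pdb",
    "write_pdb",
    "assign_atom_types",
    "canonical_pair_index",
    "n_pair_types",
]


class EmptyPartnerError(ValueError):
    """Raised when a requested partner (receptor or ligand) has no atoms."""


@dataclass
class AtomSet:
    """Flat per-atom arrays for one rigid partner."""

    coords: np.ndarray        # (n, 3) float64, Angstrom
    atom_names: np.ndarray    # (n,) str
    res_names: np.ndarray     # (n,) str
    chain_ids: np.ndarray     # (n,) str
    res_seq: np.ndarray       # (n,) int
    icodes: np.ndarray        # (n,) str (insertion codes, kept in residue id)
    elements: np.ndarray      # (n,) str
    heavy: np.ndarray         # (n,) bool
    types: Optional[np.ndarray] = None  # (n,) int, set by assign_atom_types

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        n = len(self.coords)
        for name in ("atom_names", "res_names", "chain_ids", "res_seq",
                     "icodes", "elements", "heavy"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n atoms {n}")
            setattr(self, name, arr)
        if self.types is not None:
            self.types = np.asarray(self.types, dtype=np.intp)

    def __len__(self) -> int:
        return len(self.coords)

    def residue_keys(self) -> np.ndarray:
        """Per-atom residue identifier strings ``chain:resseq:icode``."""
        return np.array([
            f"{c}:{s}:{i}" for c, s, i in
            zip(self.chain_ids, self.res_seq, self.icodes)
        ])

    def select(self, mask: np.ndarray) -> "AtomSet":
        return AtomSet(
            coords=self.coords[mask],
            atom_names=self.atom_names[mask],
            res_names=self.res_names[mask],
            chain_ids=self.chain_ids[mask],
            res_seq=self.res_seq[mask],
            icodes=self.icodes[mask],
            elements=self.elements[mask],
            heavy=self.heavy[mask],
            types=None if self.types is None else self.types[mask],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomSet":
        """Rigidly moved copy: ``x -> R x + t``."""
        new = self.select(np.ones(len(self), dtype=bool))
        new.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return new


@dataclass
class TypedStructure:
    """Receptor + ligand partner pair, optionally atom-typed."""

    receptor: AtomSet
    ligand: AtomSet
    table: Optional[TypingTable] = None

    def __post_init__(self) -> None:
        if len(self.receptor) == 0 or len(self.ligand) == 0:
            raise EmptyPartnerError("both partners must contain atoms")
        if self.table is not None:
            for part in (self.receptor, self.ligand):
                if part.types is None:
                    raise ValueError("typed structure lacks type labels")
                if part.types.size and part.types.max() >= self.table.n_types:
                    raise ValueError("type index out of table range")

    @property
    def is_typed(self) -> bool:
        return self.table is not None

    def with_ligand(self, ligand: AtomSet) -> "TypedStructure":
        return TypedStructure(receptor=self.receptor, ligand=ligand,
                              table=self.table)

    def transform_ligand(self, rotation: np.ndarray,
                         translation: np.ndarray) -> "TypedStructure":
        """New decoy pose: receptor fixed, ligand rigidly moved."""
        return self.with_ligand(self.ligand.transformed(rotation, translation))


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _atomset_from_array(arr: struc.AtomArray) -> AtomSet:
    elements = np.char.upper(arr.element.astype(str))
    return AtomSet(
        coords=np.asarray(arr.coord, dtype=np.float64),
        atom_names=arr.atom_name.astype(str),
        res_names=arr.res_name.astype(str),
        chain_ids=arr.chain_id.astype(str),
        res_seq=np.asarray(arr.res_id, dtype=int),
        icodes=(arr.ins_code.astype(str)
                if "ins_code" in arr.get_annotation_categories()
                else np.full(arr.array_length(), "", dtype="<U1")),
        elements=elements,
        heavy=~np.isin(elements, ("H", "D")),
    )


def parse_pdb(path, receptor_chains: Sequence[str],
              ligand_chains: Sequence[str]) -> TypedStructure:
    """Read ATOM/HETATM records and split into receptor and ligand partners.

    Alternate locations: only blank or 'A' altloc records are kept.
    Hydrogens are retained and flagged (``heavy=False``).

    Raises
    ------
    EmptyPartnerError
        If either chain set selects no atoms.
    ValueError
        From the underlying reader, on unparsable records.
    """
    pdb_file = pdbio.PDBFile.read(path)
    arr = pdb_file.get_structure(model=1, altloc="first", extra_fields=[])
    receptor_chains = set(receptor_chains)
    ligand_chains = set(ligand_chains)
    rec_mask = np.isin(arr.chain_id, list(receptor_chains))
    lig_mask = np.isin(arr.chain_id, list(ligand_chains))
    if not rec_mask.any():
        raise EmptyPartnerError(
            f"no atoms found for receptor chains {sorted(receptor_chains)}")
    if not lig_mask.any():
        raise EmptyPartnerError(
            f"no atoms found for ligand chains {sorted(ligand_chains)}")
    return TypedStructure(
        receptor=_atomset_from_array(arr[rec_mask]),
        ligand=_atomset_from_array(arr[lig_mask]),
    )


def _array_from_atomset(part: AtomSet) -> struc.AtomArray:
    n = len(part)
    arr = struc.AtomArray(n)
    arr.coord = part.coords.astype(np.float32)
    arr.atom_name = part.atom_names.astype("<U6")
    arr.res_name = part.res_names.astype("<U5")
    arr.chain_id = part.chain_ids.astype("<U4")
    arr.res_id = part.res_seq.astype(int)
    arr.element = part.elements.astype("<U2")
    arr.set_annotation("ins_code", part.icodes.astype("<U1"))
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_pdb(structure: TypedStructure, path) -> None:
    """Write both partners to a PDB file (receptor chains first)."""
    arr = _array_from_atomset(structure.receptor) \
        + _array_from_atomset(structure.ligand)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(path)


# ---------------------------------------------------------------------------
# Typing
# ---------------------------------------------------------------------------

def _type_partner(part: AtomSet, table: TypingTable, unknown: str) -> AtomSet:
    types = np.empty(len(part), dtype=np.intp)
    keep = np.ones(len(part), dtype=bool)
    for i, (res, atom) in enumerate(zip(part.res_names, part.atom_names)):
        try:
            types[i] = table.type_of(res, atom)
        except TypingError:
            if unknown == "drop":
                keep[i] = False
                types[i] = -1
            else:
                raise
    out = part.select(keep)
    out.types = types[keep]
    # heavy flag follows the table where the element column is uninformative
    out.heavy = np.array([table.heavy_flags[t] for t in out.types])
    return out


def assign_atom_types(structure: TypedStructure, table: TypingTable,
                      unknown: str = "raise") -> TypedStructure:
    """Attach per-atom type indices from a typing table.

    Parameters
    ----------
    unknown:
        ``"raise"`` (default) fails on a (residue, atom) pair the table does
        not cover; ``"drop"`` silently removes such atoms.
    """
    if unknown not in ("raise", "drop"):
        raise ValueError("unknown policy must be 'raise' or 'drop'")
    return TypedStructure(
        receptor=_type_partner(structure.receptor, table, unknown),
        ligand=_type_partner(structure.ligand, table, unknown),
        table=table,
    )


# ---------------------------------------------------------------------------
# Canonical pair indexing
# ---------------------------------------------------------------------------

def n_pair_types(n_types: int) -> int:
    """Number of unordered atom-type pairs: lambda*(lambda+1)/2."""
    return n_types * (n_types + 1) // 2


def canonical_pair_index(a, b, n_types: int):
    """Symmetric bijection from unordered type pairs onto ``[0, C(l+1,2))``.

    ``index(a, b) == index(b, a)``; with ``i = min, j = max``::

        index = i*lambda - i*(i-1)/2 + (j - i)

    Accepts scalars or arrays.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if np.any(a < 0) or np.any(b < 0) or np.any(a >= n_types) or np.any(b >= n_types):
        raise IndexError(f"type index out of range [0, {n_types})")
    i = np.minimum(a, b)
    j = np.maximum(a, b)
    idx = i * n_types - (i * (i - 1)) // 2 + (j - i)
    return int(idx) if idx.ndim == 0 else idx
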