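"""Atom typing tables.

A :class:`TypingTable` maps ``(residue_name, atom_name)`` pairs to integer
atom-type indices in ``[0, n_types)``.  Scoring potentials are parameterised
per unordered *pair* of atom types, so the table fixes the dimensionality of
every feature vector and parameter vector downstream.

The shipped default is a 27-type grouped all-atom (GAA-style) table for the
20 standard amino acids.  Atoms are grouped by the chemical character of the
five residue classes (non-polar, polar, aromatic, positively charged,
negatively charged): 23 heavy-atom group types plus 4 grouped hydrogen
types.  The exact grouping is a documented reconstruction in that spirit,
not a verbatim copy of any published supplementary table.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

__all__ = [
    "TypingTable",
    "TypingError",
    "default_gaa_table",
    "pseudo_bead_table",
    "load_typing_table",
    "save_typing_table",
]


class TypingError(KeyError):
    """Raised when a (residue, atom) pair has no entry in the typing table."""


@dataclass(frozen=True)
class TypingTable:
    """Immutable mapping from (residue_name, atom_name) to atom-type index.

    Parameters
    ----------
    name:
        Identifier recorded in feature grids for compatibility checks.
    n_types:
        Number of distinct atom types (lambda).
    entries:
        ``(res_name, atom_name) -> type index`` with index in ``[0, n_types)``.
    heavy_flags:
        Per-type flag; ``True`` marks a heavy-atom (non-hydrogen) type.
    labels:
        Human-readable per-type labels.
    """

    name: str
    n_types: int
    entries: Mapping[Tuple[str, str], int]
    heavy_flags: Tuple[bool, ...]
    labels: Tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_types <= 0:
            raise ValueError("n_types must be positive")
        if len(self.heavy_flags) != self.n_types:
            raise ValueError("heavy_flags length must equal n_types")
        seen = set(self.entries.values())
        if not seen.issubset(range(self.n_types)):
            raise ValueError("entry type index out of range")
        if seen != set(range(self.n_types)):
            missing = sorted(set(range(self.n_types)) - seen)
            raise ValueError(f"types never assigned by any entry: {missing}")
        if not any(self.heavy_flags):
            raise ValueError("at least one type must be heavy")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"type{i}" for i in range(self.n_types))
            )
        if len(self.labels) != self.n_types:
            raise ValueError("labels length must equal n_types")

    def type_of(self, res_name: str, atom_name: str) -> int:
        try:
            return self.entries[(res_name.strip().upper(), atom_name.strip().upper())]
        except KeyError:
            raise TypingError(
                f"no atom type for residue {res_name!r}, atom {atom_name!r} "
                f"in table {self.name!r}"
            ) from None

    @property
    def heavy_type_indices(self) -> Tuple[int, ...]:
        """Sorted indices of heavy-atom types (layout of BSA feature columns)."""
        return tuple(i for i in range(self.n_types) if self.heavy_flags[i])

    @property
    def n_heavy_types(self) -> int:
        return len(self.heavy_type_indices)

    def content_hash(self) -> str:
        """Stable hash of the full table content, stored in feature grids."""
        h = hashlib.sha256()
        h.update(f"{self.name}|{self.n_types}".encode())
        for key in sorted(self.entries):
            h.update(f"{key[0]}:{key[1]}={self.entries[key]};".encode())
        h.update("".join("H" if f else "-" for f in self.heavy_flags).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Default 27-type grouped all-atom table
# ---------------------------------------------------------------------------

_HEAVY_LABELS = (
    "N_bb", "CA_bb", "C_bb", "O_bb",          # 0-3  backbone
    "CH3_np", "CH2_np", "CH_np", "S_np",       # 4-7  non-polar side chains
    "OH_pol", "N_pol", "O_pol", "C_pol",       # 8-11 polar side chains
    "CH2_pol", "CH3_pol",                      # 12-13
    "C_aro", "CH2_aro", "N_aro",               # 14-16 aromatic side chains
    "N_pos", "CH2_pos", "C_pos",               # 17-19 positively charged
    "O_neg", "C_neg", "CH2_neg",               # 20-22 negatively charged
)
_H_LABELS = ("H_bb", "H_np", "H_pol", "H_aro")  # 23-26 grouped hydrogens

_AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Side-chain heavy atoms; backbone atoms are shared across residues.
_SIDE_CHAIN_HEAVY: Dict[str, Dict[str, int]] = {
    "ALA": {"CB": 4},
    "VAL": {"CB": 6, "CG1": 4, "CG2": 4},
    "LEU": {"CB": 5, "CG": 6, "CD1": 4, "CD2": 4},
    "ILE": {"CB": 6, "CG1": 5, "CG2": 4, "CD1": 4},
    "MET": {"CB": 5, "CG": 5, "SD": 7, "CE": 4},
    "PRO": {"CB": 5, "CG": 5, "CD": 5},
    "CYS": {"CB": 5, "SG": 7},
    "GLY": {},
    "SER": {"CB": 12, "OG": 8},
    "THR": {"CB": 12, "OG1": 8, "CG2": 13},
    "ASN": {"CB": 12, "CG": 11, "OD1": 10, "ND2": 9},
    "GLN": {"CB": 12, "CG": 12, "CD": 11, "OE1": 10, "NE2": 9},
    "HIS": {"CB": 15, "CG": 14, "ND1": 16, "CD2": 14, "CE1": 14, "NE2": 16},
    "PHE": {"CB": 15, "CG": 14, "CD1": 14, "CD2": 14, "CE1": 14, "CE2": 14,
            "CZ": 14},
    "TYR": {"CB": 15, "CG": 14, "CD1": 14, "CD2": 14, "CE1": 14, "CE2": 14,
            "CZ": 14, "OH": 8},
    "TRP": {"CB": 15, "CG": 14, "CD1": 14, "CD2": 14, "NE1": 16, "CE2": 14,
            "CE3": 14, "CZ2": 14, "CZ3": 14, "CH2": 14},
    "LYS": {"CB": 18, "CG": 18, "CD": 18, "CE": 18, "NZ": 17},
    "ARG": {"CB": 18, "CG": 18, "CD": 18, "NE": 17, "CZ": 19, "NH1": 17,
            "NH2": 17},
    "ASP": {"CB": 22, "CG": 21, "OD1": 20, "OD2": 20},
    "GLU": {"CB": 22, "CG": 22, "CD": 21, "OE1": 20, "OE2": 20},
}

# Side-chain hydrogens (PDB v3 names): aliphatic -> H_np, on N/O -> H_pol,
# aromatic ring -> H_aro.
_SIDE_CHAIN_H: Dict[str, Dict[str, int]] = {
    "ALA": {"HB1": 24, "HB2": 24, "HB3": 24},
    "VAL": {"HB": 24, "HG11": 24, "HG12": 24, "HG13": 24,
            "HG21": 24, "HG22": 24, "HG23": 24},
    "LEU": {"HB2": 24, "HB3": 24, "HG": 24, "HD11": 24, "HD12": 24,
            "HD13": 24, "HD21": 24, "HD22": 24, "HD23": 24},
    "ILE": {"HB": 24, "HG12": 24, "HG13": 24, "HG21": 24, "HG22": 24,
            "HG23": 24, "HD11": 24, "HD12": 24, "HD13": 24},
    "MET": {"HB2": 24, "HB3": 24, "HG2": 24, "HG3": 24, "HE1": 24,
            "HE2": 24, "HE3": 24},
    "PRO": {"HB2": 24, "HB3": 24, "HG2": 24, "HG3": 24, "HD2": 24, "HD3": 24},
    "CYS": {"HB2": 24, "HB3": 24, "HG": 25},
    "GLY": {},
    "SER": {"HB2": 24, "HB3": 24, "HG": 25},
    "THR": {"HB": 24, "HG1": 25, "HG21": 24, "HG22": 24, "HG23": 24},
    "ASN": {"HB2": 24, "HB3": 24, "HD21": 25, "HD22": 25},
    "GLN": {"HB2": 24, "HB3": 24, "HG2": 24, "HG3": 24, "HE21": 25,
            "HE22": 25},
    "HIS": {"HB2": 24, "HB3": 24, "HD1": 25, "HD2": 26, "HE1": 26, "HE2": 25},
    "PHE": {"HB2": 24, "HB3": 24, "HD1": 26, "HD2": 26, "HE1": 26,
            "HE2": 26, "HZ": 26},
    "TYR": {"HB2": 24, "HB3": 24, "HD1": 26, "HD2": 26, "HE1": 26,
            "HE2": 26, "HH": 25},
    "TRP": {"HB2": 24, "HB3": 24, "HD1": 26, "HE1": 25, "HE3": 26,
            "HZ2": 26, "HZ3": 26, "HH2": 26},
    "LYS": {"HB2": 24, "HB3": 24, "HG2": 24, "HG3": 24, "HD2": 24,
            "HD3": 24, "HE2": 24, "HE3": 24, "HZ1": 25, "HZ2": 25,
            "HZ3": 25},
    "ARG": {"HB2": 24, "HB3": 24, "HG2": 24, "HG3": 24, "HD2": 24,
            "HD3": 24, "HE": 25, "HH11": 25, "HH12": 25, "HH21": 25,
            "HH22": 25},
    "ASP": {"HB2": 24, "HB3": 24, "HD2": 25},
    "GLU": {"HB2": 24, "HB3": 24, "HG2": 24, "HG3": 24, "HE2": 25},
}

_BACKBONE_HEAVY = {"N": 0, "CA": 1, "C": 2, "O": 3, "OXT": 20}
_BACKBONE_H = {"H": 23, "H1": 23, "H2": 23, "H3": 23,
               "HA": 23, "HA2": 23, "HA3": 23}


def default_gaa_table() -> TypingTable:
    """The shipped 27-type grouped all-atom typing table (20 amino acids)."""
    entries: Dict[Tuple[str, str], int] = {}
    for res in _AMINO_ACIDS:
        for atom, t in _BACKBONE_HEAVY.items():
            if res == "PRO" and atom == "H":
                continue
            entries[(res, atom)] = t
        for atom, t in _BACKBONE_H.items():
            entries.setdefault((res, atom), t)
        for atom, t in _SIDE_CHAIN_HEAVY[res].items():
            entries[(res, atom)] = t
        for atom, t in _SIDE_CHAIN_H[res].items():
            entries[(res, atom)] = t
    heavy = tuple([True] * 23 + [False] * 4)
    return TypingTable(
        name="gaa27",
        n_types=27,
        entries=entries,
        heavy_flags=heavy,
        labels=_HEAVY_LABELS + _H_LABELS,
    )


def pseudo_bead_table(n_types: int) -> TypingTable:
    """Typing table for synthetic bead models.

    Bead residues are named ``P00 .. P{n-1}`` and carry a single heavy
    pseudo-atom named ``CA``, so quality measures that select backbone
    atoms apply to fixtures unchanged.
    """
    entries = {(f"P{i:02d}", "CA"): i for i in range(n_types)}
    return TypingTable(
        name=f"bead{n_types}",
        n_types=n_types,
        entries=entries,
        heavy_flags=tuple([True] * n_types),
        labels=tuple(f"bead{i}" for i in range(n_types)),
    )


def save_typing_table(table: TypingTable, path) -> None:
    """Write a table as TSV: residue, atom, type index, label, heavy flag."""
    with open(path, "w") as fh:
        fh.write("#name\t" + table.name + "\n")
        fh.write("#residue_name\tatom_name\ttype_index\ttype_label\theavy\n")
        for (res, atom), idx in sorted(table.entries.items()):
            heavy = int(table.heavy_flags[idx])
            fh.write(f"{res}\t{atom}\t{idx}\t{table.labels[idx]}\t{heavy}\n")


def load_typing_table(path) -> TypingTable:
    """Read a TSV typing table written by :func:`save_typing_table`."""
    name = "table"
    entries: Dict[Tuple[str, str], int] = {}
    labels: Dict[int, str] = {}
    heavy: Dict[int, bool] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#name\t"):
                name = line.split("\t", 1)[1]
                continue
            if line.startswith("#"):
                continue
            res, atom, idx_s, label, heavy_s = line.split("\t")
            idx = int(idx_s)
            entries[(res, atom)] = idx
            labels[idx] = label
            heavy[idx] = bool(int(heavy_s))
    n_types = max(entries.values()) + 1
    return TypingTable(
        name=name,
        n_types=n_types,
        entries=entries,
        heavy_flags=tuple(heavy.get(i, False) for i in range(n_types)),
        labels=tuple(labels.get(i, f"type{i}") for i in range(n_types)),
    )
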