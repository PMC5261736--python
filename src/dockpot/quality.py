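"""Structural quality of decoys: Fnat, Lrmsd, Irmsd, CAPRI stars, weights.

Quality is always measured against the native (bound) complex.  The three
classical measures are:

Fnat
    Fraction of the native interface residue contacts reproduced by the
    decoy.  A contact is any receptor-residue / ligand-residue pair with a
    heavy-atom cross distance below ``contact_cutoff`` (default 5 A).
Lrmsd
    RMSD over ligand heavy atoms after optimally superposing the decoy
    receptor onto the native receptor.
Irmsd
    RMSD over the backbone heavy atoms of the native interface residues
    (any heavy atom within ``interface_cutoff``, default 10 A, of the
    partner), after superposition on those same atoms.

The CAPRI star classes combine Fnat and Irmsd:
3 stars if Irmsd < 1 and Fnat > 0.5; else 2 if Irmsd < 2 and Fnat > 0.3;
else 1 if Irmsd < 4 and Fnat > 0.1; else 0.  All inequalities are strict,
and the upper Fnat bound sometimes quoted for the one-star class is
treated as the hand-off to the higher classes, not as an exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
from scipy.spatial.distance import cdist

from .structure import AtomSet, TypedStructure

__all__ = [
    "QualityRecord",
    "UndefinedQualityError",
    "interface_contacts",
    "compute_fnat",
    "superpose_rmsd",
    "compute_lrmsd",
    "compute_irmsd",
    "capri_classify",
    "assess_decoy",
    "make_quality_weights",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class UndefinedQualityError(ValueError):
    """Native complex defines no interface, so quality is undefined."""


@dataclass
class QualityRecord:
    """Per-decoy quality assessment."""
    fnat: float
    lrmsd: float
    irmsd: float
    stars: int
    weight: float = 0.0
    is_native: bool = False


def interface_contacts(s: TypedStructure,
                       cutoff: float = 5.0) -> Set[Tuple[str, str]]:
    """Unordered (receptor residue, ligand residue) heavy-atom contacts."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec = s.receptor.select(s.receptor.heavy)
    lig = s.ligand.select(s.ligand.heavy)
    if len(rec) == 0 or len(lig) == 0:
        return set()
    d = cdist(rec.coords, lig.coords)
    ri, li = np.nonzero(d < cutoff)
    rkeys = rec.residue_keys()
    lkeys = lig.residue_keys()
    return {(rkeys[i], lkeys[j]) for i, j in zip(ri, li)}


def compute_fnat(decoy: TypedStructure, native: TypedStructure,
                 cutoff: float = 5.0) -> float:
    """Fraction of native interface contacts preserved by the decoy."""
    native_contacts = interface_contacts(native, cutoff)
    if not native_contacts:
        raise UndefinedQualityError("native complex has no interface "
                                    "contacts; Fnat undefined")
    decoy_contacts = interface_contacts(decoy, cutoff)
    return len(decoy_contacts & native_contacts) / len(native_contacts)


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference``.
    """
    mobile = np.asarray(mobile, dtype=np.float64).reshape(-1, 3)
    reference = np.asarray(reference, dtype=np.float64).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise ValueError("atom count mismatch between mobile and reference")
    if len(mobile) < 3:
        raise ValueError("need at least 3 atoms for a superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    m = mobile - mc
    r = reference - rc
    h = m.T @ r
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    moved = m @ rot.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def _pair_check(a: AtomSet, b: AtomSet) -> None:
    if len(a) != len(b) or not np.array_equal(a.atom_names, b.atom_names):
        raise ValueError("decoy and native atom correspondence mismatch")


def compute_lrmsd(decoy: TypedStructure, native: TypedStructure) -> float:
    """Ligand RMSD (heavy atoms) after receptor superposition."""
    _pair_check(decoy.receptor, native.receptor)
    _pair_check(decoy.ligand, native.ligand)
    rot, trans, _ = superpose_rmsd(decoy.receptor.coords,
                                   native.receptor.coords)
    heavy = native.ligand.heavy
    moved = decoy.ligand.coords[heavy] @ rot.T + trans
    ref = native.ligand.coords[heavy]
    return float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))


def _interface_residues(native: TypedStructure, cutoff: float
                        ) -> Tuple[Set[str], Set[str]]:
    rec = native.receptor.select(native.receptor.heavy)
    lig = native.ligand.select(native.ligand.heavy)
    d = cdist(rec.coords, lig.coords)
    ri, li = np.nonzero(d < cutoff)
    return (set(rec.residue_keys()[np.unique(ri)]),
            set(lig.residue_keys()[np.unique(li)]))


def _interface_backbone_mask(part: AtomSet, residues: Set[str],
                             backbone: Sequence[str]) -> np.ndarray:
    keys = part.residue_keys()
    mask = np.isin(keys, list(residues)) & part.heavy \
        & np.isin(part.atom_names, list(backbone))
    return mask


def compute_irmsd(decoy: TypedStructure, native: TypedStructure,
                  interface_cutoff: float = 10.0,
                  backbone: Sequence[str] = BACKBONE_ATOMS) -> float:
    """Interface backbone RMSD after superposition on the same atoms."""
    rec_res, lig_res = _interface_residues(native, interface_cutoff)
    if not rec_res or not lig_res:
        raise UndefinedQualityError(
            "native complex defines no interface residues at "
            f"{interface_cutoff} A")
    rmask = _interface_backbone_mask(native.receptor, rec_res, backbone)
    lmask = _interface_backbone_mask(native.ligand, lig_res, backbone)
    _pair_check(decoy.receptor, native.receptor)
    _pair_check(decoy.ligand, native.ligand)
    native_atoms = np.vstack([native.receptor.coords[rmask],
                              native.ligand.coords[lmask]])
    decoy_atoms = np.vstack([decoy.receptor.coords[rmask],
                             decoy.ligand.coords[lmask]])
    _, _, rmsd = superpose_rmsd(decoy_atoms, native_atoms)
    return rmsd


def capri_classify(fnat: float, irmsd: float) -> int:
    """CAPRI star class from Fnat and Irmsd (0 = incorrect .. 3 = high)."""
    if not 0.0 <= fnat <= 1.0:
        raise ValueError("fnat must lie in [0, 1]")
    if irmsd < 0:
        raise ValueError("irmsd must be non-negative")
    if irmsd < 1.0 and fnat > 0.5:
        return 3
    if irmsd < 2.0 and fnat > 0.3:
        return 2
    if irmsd < 4.0 and fnat > 0.1:
        return 1
    return 0


def assess_decoy(decoy: TypedStructure, native: TypedStructure,
                 contact_cutoff: float = 5.0,
                 interface_cutoff: float = 10.0) -> QualityRecord:
    """Full quality record (Fnat, Lrmsd, Irmsd, stars) for one decoy."""
    fnat = compute_fnat(decoy, native, contact_cutoff)
    lrmsd = compute_lrmsd(decoy, native)
    irmsd = compute_irmsd(decoy, native, interface_cutoff)
    return QualityRecord(fnat=fnat, lrmsd=lrmsd, irmsd=irmsd,
                         stars=capri_classify(fnat, irmsd))


def make_quality_weights(
    records: Sequence[QualityRecord],
    scheme: Union[str, Callable[[QualityRecord], float]] = "stars",
) -> Tuple[np.ndarray, bool]:
    """Per-complex-normalised training weights for one decoy ensemble.

    Raw weights per scheme: ``"stars"`` uses the integer star class,
    ``"fnat"`` the Fnat value, ``"native-only"`` puts weight 1 on inserted
    native poses and 0 elsewhere; a callable receives each record.  Raw
    weights are divided by their sum over the complex.  If every raw
    weight is zero the weights stay zero and the complex is flagged
    unusable for training (``usable=False``).

    Returns ``(weights, usable)``.
    """
    if not records:
        raise ValueError("need at least one decoy")
    if callable(scheme):
        raw = np.array([float(scheme(r)) for r in records])
    elif scheme == "stars":
        raw = np.array([float(r.stars) for r in records])
    elif scheme == "fnat":
        raw = np.array([r.fnat for r in records])
    elif scheme == "native-only":
        raw = np.array([1.0 if r.is_native else 0.0 for r in records])
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    if np.any(raw < 0):
        raise ValueError("raw quality weights must be non-negative")
    total = raw.sum()
    if total == 0:
        return raw, False
    weights = raw / total
    for rec, w in zip(records, weights):
        rec.weight = float(w)
    return weights, True
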