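"""Per-decoy feature vectors and the on-disk feature grid.

Every potential form is linear in its parameters, so the expensive
geometric work — cross-partner distances, surface areas — is done once per
decoy and stored as a feature row.  Re-scoring the whole decoy ensemble
under new parameters is then a single matrix-vector product.

Feature layouts (see :func:`dockpot.potentials.feature_layout`):

* step: ``column = pair_index * n_bins + bin``; counts of cross-partner
  atom pairs whose distance falls in the half-open bin ``[lo, hi)``.
* vdw: per pair index, ``sum max(r, clash_floor)^-8`` then the matching
  ``^-6`` block, over cross pairs with ``r < cutoff``.
* bsa: per heavy atom type, the solvent-accessible surface area lost on
  complexation, summed over atoms of that type on both partners.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .potentials import (BsaForm, LayoutError, PotentialForm, StepForm,
                         VdwForm, feature_layout, form_from_dict,
                         form_to_dict, n_features)
from .structure import TypedStructure, canonical_pair_index, n_pair_types

__all__ = [
    "step_features",
    "vdw_features",
    "sasa",
    "bsa_features",
    "compute_features",
    "FeatureGrid",
    "build_feature_grid",
    "ELEMENT_RADII",
]

# Per-element van der Waals radii (A) for the SASA quadrature.
ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90,
}
_DEFAULT_RADIUS = 1.80


def _require_typed(s: TypedStructure) -> None:
    if not s.is_typed:
        raise ValueError("structure must be atom-typed before featurization")


def _cross_pairs(s: TypedStructure, cutoff: float):
    """(pair_index, distance) for cross-partner atom pairs with r < cutoff."""
    rc, lc = s.receptor.coords, s.ligand.coords
    if len(rc) * len(lc) <= 250_000:
        d = cdist(rc, lc)
        ri, li = np.nonzero(d < cutoff)
        dist = d[ri, li]
    else:
        tree = cKDTree(lc)
        pairs = cKDTree(rc).query_ball_tree(tree, cutoff)
        ri = np.concatenate([[i] * len(js) for i, js in enumerate(pairs)]) \
            if any(pairs) else np.empty(0, dtype=int)
        li = np.concatenate([js for js in pairs if js]) \
            if any(pairs) else np.empty(0, dtype=int)
        ri = ri.astype(int)
        li = np.asarray(li, dtype=int)
        dist = np.linalg.norm(rc[ri] - lc[li], axis=1)
        keep = dist < cutoff
        ri, li, dist = ri[keep], li[keep], dist[keep]
    lam = s.table.n_types
    pidx = canonical_pair_index(s.receptor.types[ri], s.ligand.types[li], lam)
    return np.atleast_1d(pidx), dist


def step_features(s: TypedStructure, edges: Sequence[float]) -> np.ndarray:
    """Contact counts per (atom-type pair, distance bin)."""
    _require_typed(s)
    form = StepForm(edges=tuple(edges))
    lam = s.table.n_types
    out = np.zeros(n_features(form, lam), dtype=np.float64)
    pidx, dist = _cross_pairs(s, form.edges[-1])
    if dist.size == 0:
        return out
    bins = np.searchsorted(form.edges, dist, side="right") - 1
    ok = (bins >= 0) & (bins < form.n_bins) & (dist >= form.edges[0])
    cols = pidx[ok] * form.n_bins + bins[ok]
    np.add.at(out, cols, 1.0)
    return out


def vdw_features(s: TypedStructure, clash_floor: float = 2.0,
                 cutoff: float = 12.0) -> np.ndarray:
    """Summed ``max(r, clash_floor)^-8`` and ``^-6`` per atom-type pair.

    The clash shift replaces distances below the floor by the floor itself,
    damping the contribution of overlapping atoms.
    """
    _require_typed(s)
    form = VdwForm(clash_floor=clash_floor, cutoff=cutoff)
    lam = s.table.n_types
    npairs = n_pair_types(lam)
    out = np.zeros(2 * npairs, dtype=np.float64)
    pidx, dist = _cross_pairs(s, cutoff)
    if dist.size == 0:
        return out
    r = np.maximum(dist, clash_floor)
    np.add.at(out, pidx, r ** -8)
    np.add.at(out, npairs + pidx, r ** -6)
    return out


# ---------------------------------------------------------------------------
# Solvent-accessible surface area
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere points (golden spiral)."""
    k = np.arange(n, dtype=np.float64)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
         n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    Deterministic surface-point quadrature: each atom carries a fixed set
    of ``n_points`` points on its expanded sphere (radius + probe); a point
    counts as accessible if it lies outside every other atom's expanded
    sphere.  Area = accessible fraction x 4 pi (radius + probe)^2.
    """
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    radii = np.asarray(radii, dtype=np.float64).ravel()
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    n = len(coords)
    unit = _sphere_points(n_points)
    expanded = radii + probe
    tree = cKDTree(coords)
    areas = np.empty(n, dtype=np.float64)
    rmax = expanded.max()
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        nbr = [j for j in tree.query_ball_point(coords[i], expanded[i] + rmax)
               if j != i]
        if nbr:
            d2 = cdist(pts, coords[nbr], "sqeuclidean")
            buried = (d2 < (expanded[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return areas


def _atom_radii(part, radii: Optional[np.ndarray]) -> np.ndarray:
    if radii is not None:
        return np.asarray(radii, dtype=np.float64)
    return np.array([ELEMENT_RADII.get(e, _DEFAULT_RADIUS)
                     for e in part.elements])


def bsa_features(s: TypedStructure, probe: float = 1.4, n_points: int = 960,
                 receptor_radii: Optional[np.ndarray] = None,
                 ligand_radii: Optional[np.ndarray] = None) -> np.ndarray:
    """Buried surface area per heavy atom type (both partners counted).

    The reference state for each partner is the partner isolated in its
    docked internal conformation, so for rigid-body decoys the buried area
    depends only on the interface.  Per atom, burial is
    ``sasa(alone in own partner) - sasa(in complex)``; the per-atom value
    is clamped at zero before summation into the per-type columns.
    """
    _require_typed(s)
    if not s.receptor.heavy.any() or not s.ligand.heavy.any():
        raise ValueError("bsa features need heavy atoms on both partners")
    heavy_types = s.table.heavy_type_indices
    col_of = {t: c for c, t in enumerate(heavy_types)}
    out = np.zeros(len(heavy_types), dtype=np.float64)

    rec = s.receptor.select(s.receptor.heavy)
    lig = s.ligand.select(s.ligand.heavy)
    r_rad = _atom_radii(rec, receptor_radii if receptor_radii is None
                        else receptor_radii[s.receptor.heavy])
    l_rad = _atom_radii(lig, ligand_radii if ligand_radii is None
                        else ligand_radii[s.ligand.heavy])

    sasa_rec = sasa(rec.coords, r_rad, probe, n_points)
    sasa_lig = sasa(lig.coords, l_rad, probe, n_points)
    all_coords = np.vstack([rec.coords, lig.coords])
    all_rad = np.concatenate([r_rad, l_rad])
    sasa_cx = sasa(all_coords, all_rad, probe, n_points)

    nr = len(rec)
    buried = np.concatenate([sasa_rec, sasa_lig]) - sasa_cx
    buried = np.maximum(buried, 0.0)
    types = np.concatenate([rec.types, lig.types])
    for t, b in zip(types, buried):
        out[col_of[t]] += b
    return out


def compute_features(s: TypedStructure, form: PotentialForm) -> np.ndarray:
    """Dispatch featurization for one decoy under a potential form."""
    if form.kind == "step":
        return step_features(s, form.edges)
    if form.kind == "vdw":
        return vdw_features(s, form.clash_floor, form.cutoff)
    if form.kind == "bsa":
        return bsa_features(s, form.probe_radius, form.n_points)
    raise ValueError(f"unknown form kind {form.kind!r}")


# ---------------------------------------------------------------------------
# Feature grids
# ---------------------------------------------------------------------------

@dataclass
class FeatureGrid:
    """Stacked feature rows for all decoys of one complex."""

    complex_id: str
    matrix: np.ndarray                 # (n_decoys, n_features)
    form: PotentialForm
    n_types: int
    table_hash: str
    decoy_ids: List[str]
    heavy_type_indices: Optional[tuple] = None
    native_row: Optional[int] = None   # set when a native pose was inserted
    layout: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        expected = n_features(
            self.form, self.n_types,
            None if self.heavy_type_indices is None
            else len(self.heavy_type_indices))
        if self.matrix.shape[1] != expected:
            raise LayoutError(
                f"matrix has {self.matrix.shape[1]} columns, layout "
                f"expects {expected}")
        if len(self.decoy_ids) != self.matrix.shape[0]:
            raise ValueError("decoy_ids length must match matrix rows")
        if not self.layout:
            self.layout = feature_layout(self.form, self.n_types,
                                         self.heavy_type_indices)

    @property
    def n_decoys(self) -> int:
        return self.matrix.shape[0]

    def compatible_with(self, other: "FeatureGrid") -> bool:
        return (form_to_dict(self.form) == form_to_dict(other.form)
                and self.n_types == other.n_types
                and self.table_hash == other.table_hash)

    def append(self, other: "FeatureGrid") -> "FeatureGrid":
        if not self.compatible_with(other):
            raise LayoutError("cannot append rows from an incompatible grid "
                              "(different form, lambda, or typing table)")
        return FeatureGrid(
            complex_id=self.complex_id,
            matrix=np.vstack([self.matrix, other.matrix]),
            form=self.form, n_types=self.n_types,
            table_hash=self.table_hash,
            decoy_ids=list(self.decoy_ids) + list(other.decoy_ids),
            heavy_type_indices=self.heavy_type_indices,
            native_row=self.native_row,
        )

    # ---- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Binary matrix + JSON header; load(save(grid)) is bit-identical."""
        header = {
            "complex_id": self.complex_id,
            "form": form_to_dict(self.form),
            "n_types": self.n_types,
            "table_hash": self.table_hash,
            "decoy_ids": list(self.decoy_ids),
            "heavy_type_indices": (None if self.heavy_type_indices is None
                                   else list(self.heavy_type_indices)),
            "native_row": self.native_row,
        }
        np.savez(path, matrix=self.matrix,
                 header=np.frombuffer(
                     json.dumps(header).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "FeatureGrid":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            matrix = data["matrix"]
        hti = header["heavy_type_indices"]
        return cls(
            complex_id=header["complex_id"],
            matrix=matrix,
            form=form_from_dict(header["form"]),
            n_types=header["n_types"],
            table_hash=header["table_hash"],
            decoy_ids=header["decoy_ids"],
            heavy_type_indices=None if hti is None else tuple(hti),
            native_row=header["native_row"],
        )


def build_feature_grid(decoys: Sequence[TypedStructure], form: PotentialForm,
                       complex_id: str = "complex",
                       decoy_ids: Optional[Sequence[str]] = None) -> FeatureGrid:
    """Featurize a decoy ensemble sharing one typing table."""
    if not decoys:
        raise ValueError("no decoys given")
    table = decoys[0].table
    if table is None:
        raise ValueError("decoys must be atom-typed")
    for d in decoys:
        if d.table is None or d.table.content_hash() != table.content_hash():
            raise LayoutError("all decoys must share the same typing table")
    rows = np.vstack([compute_features(d, form) for d in decoys])
    ids = (list(decoy_ids) if decoy_ids is not None
           else [f"decoy{i:05d}" for i in range(len(decoys))])
    return FeatureGrid(
        complex_id=complex_id, matrix=rows, form=form,
        n_types=table.n_types, table_hash=table.content_hash(),
        decoy_ids=ids,
        heavy_type_indices=(table.heavy_type_indices
                            if form.kind == "bsa" else None),
    )
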