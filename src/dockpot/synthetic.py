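"""Synthetic toy complexes, decoy ensembles and planted ground truth.

Real docking benchmarks consist of hundreds of complexes with tens of
thousands of rigid-body decoys each; this module generates miniature
stand-ins with the same shape so every pipeline stage (parse -> type ->
featurize -> train -> evaluate) can be exercised end to end without
external data.

A toy complex is a pair of clash-free rigid clusters of typed pseudo-atom
beads (one bead per residue, atom name ``CA``, so backbone-based quality
measures apply unchanged).  Decoys are rigid-body ligand perturbations
drawn from magnitude tiers spanning the CAPRI quality classes, from
exact-native down to fully shuffled poses.  A *planted* linear potential
over the bead-pair features defines ground-truth decoy energies, giving
the trainers a recoverable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .features import FeatureGrid, build_feature_grid
from .potentials import ParameterVector, PotentialForm, StepForm
from .quality import assess_decoy, capri_classify
from .structure import AtomSet, TypedStructure
from .tables import TypingTable, pseudo_bead_table

__all__ = [
    "FixtureSpec",
    "GenerationError",
    "make_toy_complex",
    "perturb_ligand",
    "make_decoy_set",
    "planted_potential_energies",
    "default_planted_potential",
    "PlantedBenchmark",
    "make_planted_benchmark",
]

PSEUDO_ATOM_RADIUS = 1.8  # single bead radius (A); makes sphere checks exact

# (max rotation deg, max translation A) per quality tier
DEFAULT_TIERS: Dict[str, Tuple[float, float]] = {
    "high": (3.0, 0.3),
    "medium": (8.0, 1.0),
    "acceptable": (20.0, 2.5),
    "incorrect": (180.0, 30.0),
}
DEFAULT_TIER_FRACTIONS: Dict[str, float] = {
    "high": 0.05, "medium": 0.05, "acceptable": 0.10, "incorrect": 0.80,
}


class GenerationError(RuntimeError):
    """Fixture generation could not satisfy its constraints."""


@dataclass
class FixtureSpec:
    """Study conditions for a synthetic benchmark.

    Defaults give ten 30+30-bead complexes with 500 decoys each over a
    4-type bead alphabet — large enough for rank statistics, small enough
    to featurize in seconds.
    """
    n_complexes: int = 10
    atoms_per_partner: int = 30
    n_types: int = 4
    decoys_per_complex: int = 500
    tiers: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TIERS))
    tier_fractions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TIER_FRACTIONS))
    noise_sigma: float = 0.0          # planted-energy noise (energy units)
    min_contacts: int = 3             # native interface contacts at 5 A
    min_gap: float = 2.0              # clash-free cross-partner distance
    interface_bias: float = 0.55      # P(type 0) for native-interface beads
    max_retries: int = 50
    seed: int = 0

    def table(self) -> TypingTable:
        return pseudo_bead_table(self.n_types)


def _cluster(n: int, rng: np.random.Generator, radius: float,
             min_sep: float = 2.2, max_tries: int = 20000) -> np.ndarray:
    """Random points in a sphere with a minimum pairwise separation."""
    pts: List[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError("could not place cluster atoms")
        p = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(p) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_sep:
            continue
        pts.append(p)
    return np.array(pts)


def _bead_atomset(coords: np.ndarray, types: np.ndarray, chain: str,
                  table: TypingTable) -> AtomSet:
    n = len(coords)
    return AtomSet(
        coords=coords,
        atom_names=np.full(n, "CA"),
        res_names=np.array([f"P{t:02d}" for t in types]),
        chain_ids=np.full(n, chain),
        res_seq=np.arange(1, n + 1),
        icodes=np.full(n, ""),
        elements=np.full(n, "P"),  # maps to the 1.8 A pseudo-atom radius
        heavy=np.ones(n, dtype=bool),
        types=np.asarray(types, dtype=np.intp),
    )


def _biased_types(own: np.ndarray, partner: np.ndarray, spec: FixtureSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Bead types with interface bias and guaranteed full type coverage."""
    n = len(own)
    types = rng.integers(spec.n_types, size=n)
    at_interface = cdist(own, partner).min(axis=1) < 6.0
    sticky = rng.uniform(size=n) < spec.interface_bias
    types[at_interface & sticky] = 0
    # keep every type represented on this partner
    missing = [t for t in range(spec.n_types) if t not in set(types)]
    if missing:
        spare = np.flatnonzero(~at_interface)
        if len(spare) < len(missing):
            spare = np.arange(n)
        for t, i in zip(missing, rng.permutation(spare)):
            types[i] = t
    return types


def make_toy_complex(spec: FixtureSpec,
                     rng: np.random.Generator) -> TypedStructure:
    """Generate one clash-free native complex with a defined interface.

    The two partners are random bead clusters; the ligand cluster is slid
    toward the receptor along the x axis until the minimum cross-partner
    distance falls in ``[min_gap, min_gap + 2]`` and at least
    ``min_contacts`` residue contacts exist at 5 A.

    Native interfaces carry a compositional bias (``interface_bias``):
    beads within 6 A of the partner are drawn as the "sticky" type 0 with
    elevated probability, emulating the enrichment of particular chemical
    groups (e.g. hydrophobics) at real protein-protein interfaces.  This
    transferable signal is what a trained cross-complex potential can
    legitimately learn.
    """
    table = spec.table()
    n = spec.atoms_per_partner
    radius = max(6.0, 1.7 * n ** (1 / 3) * 2.2 / 2)
    for _ in range(spec.max_retries):
        rec = _cluster(n, rng, radius)
        lig = _cluster(n, rng, radius)
        # slide ligand in from +x until the gap closes to the target window
        offset = rec[:, 0].max() - lig[:, 0].min() + 2 * radius
        lig = lig + np.array([offset, 0.0, 0.0])
        step = 0.25
        ok = False
        for _ in range(int(4 * radius / step) + 200):
            gap = cdist(rec, lig).min()
            if gap < spec.min_gap:
                break
            if gap <= spec.min_gap + 2.0:
                ok = True
                break
            lig = lig - np.array([step, 0.0, 0.0])
        if not ok:
            continue
        rec_t = _biased_types(rec, lig, spec, rng)
        lig_t = _biased_types(lig, rec, spec, rng)
        native = TypedStructure(
            receptor=_bead_atomset(rec, rec_t, "A", table),
            ligand=_bead_atomset(lig, lig_t, "B", table),
            table=table,
        )
        d = cdist(rec, lig)
        if int(np.sum(d < 5.0)) >= spec.min_contacts:
            return native
    raise GenerationError("could not generate a native complex with the "
                          "requested interface")


def perturb_ligand(native: TypedStructure, max_rot_deg: float,
                   max_trans: float,
                   rng: np.random.Generator) -> TypedStructure:
    """Rigid ligand perturbation: rotation about the ligand centroid plus
    a random translation.  Magnitude 0 reproduces the native pose exactly."""
    lig = native.ligand
    center = lig.coords.mean(axis=0)
    if max_rot_deg > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(0, max_rot_deg))
        rot = Rotation.from_rotvec(angle * axis).as_matrix()
    else:
        rot = np.eye(3)
    if max_trans > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        trans = rng.uniform(0, max_trans) * direction
    else:
        trans = np.zeros(3)
    new_coords = (lig.coords - center) @ rot.T + center + trans
    moved = lig.select(np.ones(len(lig), dtype=bool))
    moved.coords = new_coords
    return native.with_ligand(moved)


def _recontact(decoy: TypedStructure, min_gap: float,
               rng: np.random.Generator,
               max_gap_excess: float = 2.0) -> TypedStructure:
    """Slide the ligand back onto the receptor surface if it lost contact.

    Rigid-body samplers emit touching poses; a perturbed ligand that ends
    up detached is translated along the centroid-centroid axis until the
    minimum cross-partner distance falls in
    ``[min_gap, min_gap + max_gap_excess]``.
    """
    rec = decoy.receptor.coords
    lig = decoy.ligand.coords
    gap0 = cdist(rec, lig).min()
    hi_target = min_gap + max_gap_excess
    if gap0 <= hi_target:
        return decoy
    target = rng.uniform(min_gap, hi_target)
    u = rec.mean(axis=0) - lig.mean(axis=0)
    u = u / np.linalg.norm(u)
    lo, hi = 0.0, gap0 + 2.0 * np.linalg.norm(rec.mean(axis=0)
                                              - lig.mean(axis=0))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if cdist(rec, lig + mid * u).min() > target:
            lo = mid
        else:
            hi = mid
    moved = decoy.ligand.select(np.ones(len(decoy.ligand), dtype=bool))
    moved.coords = lig + hi * u
    return decoy.with_ligand(moved)


def make_decoy_set(native: TypedStructure, spec: FixtureSpec,
                   rng: np.random.Generator,
                   require_class_coverage: bool = False,
                   ) -> Tuple[List[TypedStructure], List[str]]:
    """Decoy ensemble drawn from the spec's perturbation tiers.

    Every decoy is kept in surface contact (see :func:`_recontact`), as a
    rigid-body sampler would only emit touching poses.

    Returns ``(decoys, tier_labels)``.  With
    ``require_class_coverage=True`` the set is regenerated (bounded
    retries) until every CAPRI class {0, 1, 2, 3} occurs at least once,
    which needs the tier magnitudes to straddle the class boundaries.
    """
    n = spec.decoys_per_complex
    tier_names = list(spec.tiers)
    fractions = np.array([spec.tier_fractions[t] for t in tier_names])
    fractions = fractions / fractions.sum()
    counts = np.floor(fractions * n).astype(int)
    counts[-1] += n - counts.sum()

    for attempt in range(spec.max_retries):
        decoys: List[TypedStructure] = []
        labels: List[str] = []
        for name, count in zip(tier_names, counts):
            rot, trans = spec.tiers[name]
            for _ in range(count):
                d = perturb_ligand(native, rot, trans, rng)
                decoys.append(_recontact(d, spec.min_gap, rng))
                labels.append(name)
        # shuffle so input order carries no quality information (stable
        # rank tie-breaks must not silently favour near-natives)
        perm = rng.permutation(len(decoys))
        decoys = [decoys[i] for i in perm]
        labels = [labels[i] for i in perm]
        if not require_class_coverage:
            return decoys, labels
        stars = {assess_decoy(d, native).stars for d in decoys}
        if stars == {0, 1, 2, 3}:
            return decoys, labels
    raise GenerationError("decoy set never covered all CAPRI classes; "
                          "adjust tier magnitudes")


def planted_potential_energies(grid: FeatureGrid, planted: ParameterVector,
                               noise_sigma: float = 0.0,
                               rng: Optional[np.random.Generator] = None,
                               ) -> np.ndarray:
    """Ground-truth decoy energies under a planted linear potential.

    ``energy = features @ planted + N(0, noise_sigma)``; lower = better.
    """
    energies = grid.matrix @ planted.values
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        energies = energies + rng.normal(0.0, noise_sigma, len(energies))
    return energies


def default_planted_potential(spec: FixtureSpec,
                              form: Optional[PotentialForm] = None,
                              rng: Optional[np.random.Generator] = None,
                              ) -> ParameterVector:
    """A reproducible random step potential used as planted ground truth."""
    from .potentials import n_features
    form = form or StepForm(edges=(0.0, 4.0, 6.0))
    rng = rng or np.random.default_rng(spec.seed + 7)
    table = spec.table()
    values = rng.normal(0.0, 1.0, n_features(form, table.n_types,
                                             table.n_heavy_types))
    return ParameterVector(
        form=form, values=values, n_types=table.n_types,
        table_hash=table.content_hash(),
        heavy_type_indices=(table.heavy_type_indices
                            if form.kind == "bsa" else None),
        meta={"planted": True},
    )


@dataclass
class PlantedBenchmark:
    """Fixture benchmark: complexes, grids, planted energies, good flags."""
    natives: List[TypedStructure]
    decoys: List[List[TypedStructure]]
    grids: List[FeatureGrid]
    energies: List[np.ndarray]       # planted ground-truth energies
    good: List[np.ndarray]           # lowest-energy decile flags
    planted: ParameterVector
    table: TypingTable
    spec: FixtureSpec


def make_planted_benchmark(spec: Optional[FixtureSpec] = None,
                           form: Optional[PotentialForm] = None,
                           good_fraction: float = 0.1,
                           ) -> PlantedBenchmark:
    """Generate a full planted-potential benchmark from one seed.

    Per complex: a native, a decoy ensemble, its feature grid under
    ``form`` (default two-bin step potential), ground-truth energies from
    the planted potential, and a "good decoy" flag marking the lowest
    ``good_fraction`` of energies.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    form = form or StepForm(edges=(0.0, 4.0, 6.0))
    planted = default_planted_potential(spec, form)
    table = spec.table()
    natives, decoy_sets, grids, energies, good = [], [], [], [], []
    for c in range(spec.n_complexes):
        native = make_toy_complex(spec, rng)
        decoys, _ = make_decoy_set(native, spec, rng)
        grid = build_feature_grid(decoys, form, complex_id=f"cx{c:03d}")
        e = planted_potential_energies(grid, planted, spec.noise_sigma, rng)
        k = max(1, int(np.floor(good_fraction * len(e))))
        flags = np.zeros(len(e), dtype=bool)
        flags[np.argsort(e, kind="stable")[:k]] = True
        natives.append(native)
        decoy_sets.append(decoys)
        grids.append(grid)
        energies.append(e)
        good.append(flags)
    return PlantedBenchmark(natives=natives, decoys=decoy_sets, grids=grids,
                            energies=energies, good=good, planted=planted,
                            table=table, spec=spec)
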