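"""Potential forms and trained parameter vectors.

Three functional forms are supported, all linear in their parameters so
that scoring a decoy is a dot product with its precomputed feature row:

``step``
    A contact potential: constant value per (atom-type pair, distance bin).
``vdw``
    A soft Lennard-Jones-like potential per atom-type pair,
    ``E = alpha * sum r^-8 - beta * sum r^-6`` with
    ``alpha = eps * sigma^8`` and ``beta = eps * sigma^6``.
``bsa``
    Linear in the buried solvent-accessible surface area per heavy
    atom type.

By convention lower (more negative) scores mean better poses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np

from .structure import n_pair_types

__all__ = [
    "StepForm",
    "VdwForm",
    "BsaForm",
    "PotentialForm",
    "ParameterVector",
    "LayoutError",
    "n_features",
    "feature_layout",
    "save_parameters",
    "load_parameters",
]


class LayoutError(ValueError):
    """Incompatible feature/parameter layouts (form, typing table, edges)."""


@dataclass(frozen=True)
class StepForm:
    """Distance-bin contact potential; bins are half-open ``[lo, hi)``."""
    edges: Tuple[float, ...] = (0.0, 10.0)
    kind: str = field(default="step", init=False)

    def __post_init__(self) -> None:
        if len(self.edges) < 2:
            raise ValueError("need at least one bin (two edges)")
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", tuple(float(e) for e in self.edges))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


@dataclass(frozen=True)
class VdwForm:
    """r^-8 / r^-6 potential with a short-range clash shift.

    Cross distances below ``clash_floor`` are shifted up to the floor
    (default 2 A) to damp the influence of atom clashes; pairs beyond
    ``cutoff`` are ignored.
    """
    clash_floor: float = 2.0
    cutoff: float = 12.0
    kind: str = field(default="vdw", init=False)

    def __post_init__(self) -> None:
        if self.clash_floor <= 0:
            raise ValueError("clash_floor must be positive")
        if self.cutoff <= self.clash_floor:
            raise ValueError("cutoff must exceed clash_floor")


@dataclass(frozen=True)
class BsaForm:
    """Buried-surface-area potential over heavy atom types."""
    probe_radius: float = 1.4
    n_points: int = 960
    kind: str = field(default="bsa", init=False)

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_points < 8:
            raise ValueError("n_points too small for a usable quadrature")


PotentialForm = Union[StepForm, VdwForm, BsaForm]


def n_features(form: PotentialForm, n_types: int, n_heavy_types: Optional[int] = None) -> int:
    """Feature-vector length for a form under a typing table of size lambda."""
    npairs = n_pair_types(n_types)
    if form.kind == "step":
        return form.n_bins * npairs
    if form.kind == "vdw":
        return 2 * npairs
    if form.kind == "bsa":
        if n_heavy_types is None:
            raise ValueError("bsa layout needs the number of heavy types")
        return n_heavy_types
    raise ValueError(f"unknown form kind {form.kind!r}")


def feature_layout(form: PotentialForm, n_types: int,
                   heavy_type_indices: Optional[Tuple[int, ...]] = None) -> List[str]:
    """Human-readable description of each feature column.

    step: column ``pair*nbins + bin`` -> ``pair{p}:bin{b}[lo,hi)``;
    vdw: first the r^-8 block, then the r^-6 block, per pair index;
    bsa: one column per heavy type, in ascending type order.
    """
    npairs = n_pair_types(n_types)
    if form.kind == "step":
        return [
            f"pair{p}:bin{b}[{form.edges[b]},{form.edges[b + 1]})"
            for p in range(npairs) for b in range(form.n_bins)
        ]
    if form.kind == "vdw":
        return ([f"pair{p}:r^-8" for p in range(npairs)]
                + [f"pair{p}:r^-6" for p in range(npairs)])
    if form.kind == "bsa":
        if heavy_type_indices is None:
            raise ValueError("bsa layout needs the heavy type indices")
        return [f"heavy_type{t}:bsa" for t in heavy_type_indices]
    raise ValueError(f"unknown form kind {form.kind!r}")


def form_to_dict(form: PotentialForm) -> dict:
    if form.kind == "step":
        return {"kind": "step", "edges": list(form.edges)}
    if form.kind == "vdw":
        return {"kind": "vdw", "clash_floor": form.clash_floor,
                "cutoff": form.cutoff}
    return {"kind": "bsa", "probe_radius": form.probe_radius,
            "n_points": form.n_points}


def form_from_dict(d: dict) -> PotentialForm:
    kind = d["kind"]
    if kind == "step":
        return StepForm(edges=tuple(d["edges"]))
    if kind == "vdw":
        return VdwForm(clash_floor=d["clash_floor"], cutoff=d["cutoff"])
    if kind == "bsa":
        return BsaForm(probe_radius=d["probe_radius"],
                       n_points=d.get("n_points", 960))
    raise ValueError(f"unknown form kind {kind!r}")


@dataclass
class ParameterVector:
    """Trained potential parameters, laid out to match a feature grid.

    ``values`` is the flat vector such that ``score = features @ values``.
    For the vdw form the layout is ``[alpha_0..alpha_{P-1}, -beta_0..]``:
    the minus sign of the attractive term is baked into the stored values,
    and the physical ``(sigma, epsilon)`` view is derived.
    """

    form: PotentialForm
    values: np.ndarray
    n_types: int
    table_hash: Optional[str] = None
    heavy_type_indices: Optional[Tuple[int, ...]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        expected = n_features(
            self.form, self.n_types,
            None if self.heavy_type_indices is None
            else len(self.heavy_type_indices))
        if len(self.values) != expected:
            raise LayoutError(
                f"{len(self.values)} values but layout expects {expected}")

    # ---- vdw views -------------------------------------------------------
    def _require_vdw(self) -> int:
        if self.form.kind != "vdw":
            raise LayoutError("sigma/epsilon views exist only for vdw form")
        return n_pair_types(self.n_types)

    @property
    def alpha(self) -> np.ndarray:
        p = self._require_vdw()
        return self.values[:p]

    @property
    def beta(self) -> np.ndarray:
        p = self._require_vdw()
        return -self.values[p:]

    @property
    def sigma(self) -> np.ndarray:
        """Per pair: sigma = sqrt(alpha / beta) (zero where beta == 0)."""
        a, b = self.alpha, self.beta
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.sqrt(np.where(b > 0, a / np.where(b > 0, b, 1.0), 0.0))
        return s

    @property
    def epsilon(self) -> np.ndarray:
        """Per pair: eps = beta / sigma^6 (zero where sigma == 0)."""
        s = self.sigma
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s > 0, self.beta / np.where(s > 0, s, 1.0) ** 6, 0.0)

    @classmethod
    def from_sigma_epsilon(cls, sigma, epsilon, n_types: int,
                           form: Optional[VdwForm] = None,
                           table_hash: Optional[str] = None) -> "ParameterVector":
        sigma = np.asarray(sigma, dtype=np.float64)
        epsilon = np.asarray(epsilon, dtype=np.float64)
        alpha = epsilon * sigma ** 8
        beta = epsilon * sigma ** 6
        return cls(form=form or VdwForm(),
                   values=np.concatenate([alpha, -beta]),
                   n_types=n_types, table_hash=table_hash)


def save_parameters(pv: ParameterVector, path) -> None:
    doc = {
        "form": form_to_dict(pv.form),
        "n_types": pv.n_types,
        "table_hash": pv.table_hash,
        "heavy_type_indices": (None if pv.heavy_type_indices is None
                               else list(pv.heavy_type_indices)),
        "values": pv.values.tolist(),
        "meta": pv.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_parameters(path) -> ParameterVector:
    with open(path) as fh:
        doc = json.load(fh)
    hti = doc.get("heavy_type_indices")
    return ParameterVector(
        form=form_from_dict(doc["form"]),
        values=np.asarray(doc["values"], dtype=np.float64),
        n_types=doc["n_types"],
        table_hash=doc.get("table_hash"),
        heavy_type_indices=None if hti is None else tuple(hti),
        meta=doc.get("meta", {}),
    )
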