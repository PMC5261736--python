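"""Linear-regression training of potential parameters.

Parameters are fitted so that the linear score reproduces a quality-derived
target per decoy: either the negative of a quality-increasing assessment
(stars, Fnat), or the negative reciprocal of a deviation-type assessment
(Irmsd, Lrmsd), so that better decoys always receive more negative targets.
Feature rows are fraction-normalised (each row divided by its own sum) to
stop complexes with large interfaces from dominating the fit.

Ordinary least squares and non-negative least squares are provided; NNLS
is the natural choice for vdw potentials, whose parameters
``alpha = eps sigma^8`` and ``beta = eps sigma^6`` are non-negative by
construction (the attractive minus sign is applied in the design matrix,
not the coefficients).

Cross-validation splits the training complexes into k folds, trains on
k-1, and combines the per-fold parameter sets: for step/BSA potentials
each set is scaled by the standard deviation of its own entries and the
scaled sets are averaged; for vdw potentials the single set with the best
validation performance is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .features import FeatureGrid
from .potentials import ParameterVector, PotentialForm
from .quality import QualityRecord
from .structure import n_pair_types

__all__ = [
    "regression_targets",
    "fraction_normalize",
    "fit_linear",
    "crossval_average",
    "fit_grids",
]

_RECIPROCAL_EPS = 1e-3

_QUALITY_INCREASING = {"stars", "fnat"}
_DEVIATION = {"irmsd", "lrmsd"}


def regression_targets(records: Sequence[QualityRecord],
                       mode: str = "negative",
                       assessment: str = "stars") -> np.ndarray:
    """Per-decoy regression target y (more negative = better decoy).

    ``negative`` mode: ``y = -q`` — meant for quality-increasing
    assessments (stars, fnat).  ``negative-reciprocal`` mode:
    ``y = -1/q`` for ``q > 1e-3`` else 0 — meant for deviation-type
    assessments (irmsd, lrmsd), where small deviations become strongly
    negative.
    """
    if assessment not in _QUALITY_INCREASING | _DEVIATION:
        raise ValueError(f"unknown assessment {assessment!r}")
    q = np.array([getattr(r, assessment) for r in records], dtype=np.float64)
    if mode == "negative":
        return -q
    if mode == "negative-reciprocal":
        out = np.zeros_like(q)
        ok = q > _RECIPROCAL_EPS
        out[ok] = -1.0 / q[ok]
        return out
    raise ValueError(f"unknown target mode {mode!r}")


def fraction_normalize(matrix: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Divide each feature row by its own sum.

    All-zero rows are left zero and flagged.  Returns
    ``(normalized, zero_row_flags)``.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    sums = matrix.sum(axis=1)
    zero = sums == 0
    out = matrix.copy()
    out[~zero] /= sums[~zero, None]
    return out, zero


def fit_linear(x: np.ndarray, y: np.ndarray, mode: str = "ols") -> np.ndarray:
    """Least-squares coefficients w minimising ||X w - y||^2.

    ``mode="nnls"`` additionally constrains w >= 0 elementwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.ndim != 2 or x.shape[0] != len(y):
        raise ValueError("X rows must match len(y)")
    if x.shape[0] < 1:
        raise ValueError("need at least one sample")
    if not np.any(x):
        raise ValueError("degenerate all-zero design matrix")
    if mode == "ols":
        w, *_ = np.linalg.lstsq(x, y, rcond=None)
        return w
    if mode == "nnls":
        w, _ = _scipy_nnls(x, y)
        return w
    raise ValueError(f"unknown fit mode {mode!r}")


def fit_grids(grids: Sequence[FeatureGrid],
              records_per_complex: Sequence[Sequence[QualityRecord]],
              mode: str = "ols",
              target_mode: str = "negative",
              assessment: str = "stars",
              normalize: bool = True) -> ParameterVector:
    """Fit one parameter set on pooled decoys of several complexes.

    For the vdw form the design matrix is ``[f8, -f6]`` so that NNLS
    coefficients are the non-negative ``(alpha, beta)``; the returned
    parameter vector stores ``(alpha, -beta)`` in scoring convention.
    """
    if not grids:
        raise ValueError("no grids")
    ref = grids[0]
    rows: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    for g, recs in zip(grids, records_per_complex):
        m = g.matrix
        if normalize:
            m, _ = fraction_normalize(m)
        rows.append(m)
        ys.append(regression_targets(recs, target_mode, assessment))
    x = np.vstack(rows)
    y = np.concatenate(ys)
    if ref.form.kind == "vdw":
        npairs = n_pair_types(ref.n_types)
        design = np.hstack([x[:, :npairs], -x[:, npairs:]])
        w = fit_linear(design, y, mode)
        values = np.concatenate([w[:npairs], -w[npairs:]])
    else:
        values = fit_linear(x, y, mode)
    return ParameterVector(
        form=ref.form, values=values, n_types=ref.n_types,
        table_hash=ref.table_hash,
        heavy_type_indices=ref.heavy_type_indices,
        meta={"trainer": f"lr-{mode}", "target_mode": target_mode,
              "assessment": assessment},
    )


def _scaled_average(param_sets: Sequence[ParameterVector]) -> ParameterVector:
    """Divide each set by the std of its own entries, then average."""
    scaled = []
    for pv in param_sets:
        sd = float(np.std(pv.values))
        scaled.append(pv.values / sd if sd > 0 else pv.values)
    ref = param_sets[0]
    return ParameterVector(
        form=ref.form, values=np.mean(scaled, axis=0),
        n_types=ref.n_types, table_hash=ref.table_hash,
        heavy_type_indices=ref.heavy_type_indices,
        meta={"trainer": "crossval-scaled-average",
              "n_sets": len(param_sets)},
    )


def crossval_average(
    n_complexes: int,
    trainer: Callable[[Sequence[int]], ParameterVector],
    k: int = 5,
    validator: Optional[Callable[[ParameterVector, Sequence[int]], float]] = None,
    select_best: bool = False,
) -> Tuple[ParameterVector, List[float]]:
    """k-fold cross-validation over complexes with parameter combination.

    ``trainer(train_indices)`` returns one parameter set; ``validator``
    scores a set on the held-out fold (higher = better).  With
    ``select_best=False`` (step/BSA convention) the per-fold sets are
    std-scaled and averaged; with ``select_best=True`` (vdw convention)
    the set with the best validation score is returned.

    Returns ``(parameters, validation_scores)``.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n_complexes < k:
        raise ValueError(f"cannot split {n_complexes} complexes into {k} folds")
    if select_best and validator is None:
        raise ValueError("select_best requires a validator")
    indices = np.arange(n_complexes)
    folds = [list(f) for f in np.array_split(indices, k)]
    sets: List[ParameterVector] = []
    scores: List[float] = []
    for held_out in folds:
        train = [i for i in indices if i not in held_out]
        pv = trainer(train)
        sets.append(pv)
        scores.append(float(validator(pv, held_out))
                      if validator is not None else float("nan"))
    if select_best:
        best = int(np.argmax(scores))
        chosen = sets[best]
        chosen.meta = dict(chosen.meta,
                           crossval="select-best", fold=best,
                           validation_score=scores[best])
        return chosen, scores
    return _scaled_average(sets), scores
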