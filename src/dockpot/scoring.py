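"""Scoring and ranking of decoys from precomputed feature grids."""

from __future__ import annotations

import numpy as np

from .features import FeatureGrid
from .potentials import LayoutError, ParameterVector, form_to_dict

__all__ = ["score", "rank_decoys"]


def score(grid: FeatureGrid, params: ParameterVector) -> np.ndarray:
    """Score every decoy in a grid: one matrix-vector product.

    Lower (more negative) scores indicate better poses.  Raises
    :class:`LayoutError` on any form/table mismatch.
    """
    if form_to_dict(grid.form) != form_to_dict(params.form):
        raise LayoutError(
            f"grid form {form_to_dict(grid.form)} != parameter form "
            f"{form_to_dict(params.form)}")
    if grid.n_types != params.n_types:
        raise LayoutError("grid and parameters use different type counts")
    if (params.table_hash is not None
            and params.table_hash != grid.table_hash):
        raise LayoutError("grid and parameters come from different "
                          "typing tables")
    if grid.matrix.shape[1] != len(params.values):
        raise LayoutError("feature/parameter length mismatch")
    return grid.matrix @ params.values


def rank_decoys(scores: np.ndarray) -> np.ndarray:
    """Rank decoys by score: rank 1 = lowest (best) score.

    Ties are broken by stable input order, so top-N metrics are
    reproducible.
    """
    scores = np.asarray(scores)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores must be a non-empty 1-D array")
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(scores), dtype=np.intp)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks
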