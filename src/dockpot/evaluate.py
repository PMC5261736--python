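"""Scoring-performance assessments and parameter-contribution analysis.

Three assessments mirror standard docking-rescoring practice:

* top-N success — for what fraction of complexes does the potential place
  the native (or any near-native, >= 1 CAPRI star) pose within the best N?
* enrichment — what fraction of all near-native decoys lands in the
  best-scored percentile slice of the ensemble?
* random baseline — the same metrics under uniformly random rankings,
  estimated by seeded shuffling.

The contribution analysis explains *why* a potential discriminates: for
each parameter sigma_AB the contribution of a decoy class is the parameter
times the class-mean feature normalised by the overall mean,
``p = sigma * nc_class / nc_tot``; the discriminating contribution is
``dp = sigma * |nc_nearnat - nc_incorrect| / nc_tot`` (also returned as
the signed difference ``p_incorrect - p_nearnat``).  A parameter whose
sign contradicts the ordering of the class means is flagged as a false
positive/negative contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import FeatureGrid, compute_features
from .potentials import LayoutError, ParameterVector
from .scoring import rank_decoys, score

__all__ = [
    "topn_success",
    "enrichment_fraction",
    "insert_native",
    "class_contribution",
    "discriminating_contribution",
    "ContributionRecord",
    "random_baseline",
    "EvaluationReport",
    "evaluate_potential",
]

DEFAULT_TOP_N = (1, 10, 100, 500, 1000)
DEFAULT_PERCENTILES = (0.001, 0.01, 0.02, 0.05)


def topn_success(ranks: np.ndarray, hits: np.ndarray, n: int) -> bool:
    """True iff any decoy flagged in ``hits`` has rank <= n."""
    ranks = np.asarray(ranks)
    hits = np.asarray(hits, dtype=bool)
    if ranks.shape != hits.shape:
        raise ValueError("ranks and hit flags must align")
    return bool(np.any(hits & (ranks <= n)))


def _slice_size(percentile: float, n: int) -> int:
    return max(1, math.ceil(percentile * n))


def enrichment_fraction(ranks: np.ndarray, hits: np.ndarray,
                        percentile: float) -> float:
    """Fraction of all hits captured in the best-scored percentile slice.

    The slice holds ``ceil(percentile * n)`` decoys (at least one).
    Requires at least one hit in the ensemble.
    """
    ranks = np.asarray(ranks)
    hits = np.asarray(hits, dtype=bool)
    total = int(hits.sum())
    if total == 0:
        raise ValueError("no hits in decoy set; enrichment undefined")
    top = _slice_size(percentile, len(ranks))
    return float(np.sum(hits & (ranks <= top)) / total)


def insert_native(grid: FeatureGrid, native) -> FeatureGrid:
    """Append the native pose's feature row to a grid and flag it.

    ``native`` is a typed structure sharing the grid's typing table.
    The returned grid records the native row index so every assessment
    can include or exclude it.
    """
    if native.table is None \
            or native.table.content_hash() != grid.table_hash:
        raise LayoutError("native structure typed with a different table")
    row = compute_features(native, grid.form)
    out = FeatureGrid(
        complex_id=grid.complex_id,
        matrix=np.vstack([grid.matrix, row[None, :]]),
        form=grid.form, n_types=grid.n_types, table_hash=grid.table_hash,
        decoy_ids=list(grid.decoy_ids) + ["native"],
        heavy_type_indices=grid.heavy_type_indices,
        native_row=grid.n_decoys,
    )
    return out


# ---------------------------------------------------------------------------
# Parameter contributions
# ---------------------------------------------------------------------------

def class_contribution(sigma: float, nc_class: float, nc_tot: float) -> float:
    """Contribution of one decoy class: ``sigma * nc_class / nc_tot``.

    Defined as 0 when the overall mean feature ``nc_tot`` is zero.
    """
    if nc_tot == 0:
        return 0.0
    return sigma * nc_class / nc_tot


@dataclass
class ContributionRecord:
    """Discriminating contribution of one parameter."""
    dp_abs: float            # sigma * |nc_nn - nc_inc| / nc_tot
    dp_signed: float         # p_incorrect - p_nearnat
    p_nearnat: float
    p_incorrect: float
    false_positive: bool     # sigma > 0 but contacts favour near-natives
    false_negative: bool     # sigma < 0 but contacts favour incorrect


def discriminating_contribution(sigma: float, nc_nearnat: float,
                                nc_incorrect: float,
                                nc_tot: float) -> ContributionRecord:
    """Both the absolute and the signed discriminating contribution.

    A false-positive contribution has a positive (penalising) parameter
    although the mean feature is *higher* in near-native decoys; a
    false-negative has a negative (favourable) parameter although the
    mean feature is higher in incorrect decoys.
    """
    p_nn = class_contribution(sigma, nc_nearnat, nc_tot)
    p_inc = class_contribution(sigma, nc_incorrect, nc_tot)
    dp_abs = sigma * abs(nc_nearnat - nc_incorrect) / nc_tot if nc_tot else 0.0
    return ContributionRecord(
        dp_abs=dp_abs,
        dp_signed=p_inc - p_nn,
        p_nearnat=p_nn,
        p_incorrect=p_inc,
        false_positive=sigma > 0 and nc_nearnat > nc_incorrect,
        false_negative=sigma < 0 and nc_nearnat < nc_incorrect,
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Aggregate scoring assessment over a set of complexes."""
    success: Dict[int, float] = field(default_factory=dict)
    enrichment: Dict[float, float] = field(default_factory=dict)
    per_complex_best_rank: List[Optional[int]] = field(default_factory=list)
    n_complexes: int = 0
    n_enrichment_complexes: int = 0

    def as_dict(self) -> dict:
        return {
            "success": {str(k): v for k, v in self.success.items()},
            "enrichment": {str(k): v for k, v in self.enrichment.items()},
            "per_complex_best_rank": self.per_complex_best_rank,
            "n_complexes": self.n_complexes,
            "n_enrichment_complexes": self.n_enrichment_complexes,
        }


def _report_from_ranks(ranks_per_complex: Sequence[np.ndarray],
                       hits_per_complex: Sequence[np.ndarray],
                       top_n: Sequence[int],
                       percentiles: Sequence[float]) -> EvaluationReport:
    rep = EvaluationReport(n_complexes=len(ranks_per_complex))
    succ = {n: 0 for n in top_n}
    enr = {p: [] for p in percentiles}
    for ranks, hits in zip(ranks_per_complex, hits_per_complex):
        hits = np.asarray(hits, dtype=bool)
        if hits.any():
            rep.per_complex_best_rank.append(int(np.min(ranks[hits])))
            for p in percentiles:
                enr[p].append(enrichment_fraction(ranks, hits, p))
        else:
            # no qualifying decoy: counted as failure for success rates,
            # excluded from enrichment averages
            rep.per_complex_best_rank.append(None)
        for n in top_n:
            succ[n] += int(topn_success(ranks, hits, n))
    rep.success = {n: succ[n] / len(ranks_per_complex) for n in top_n}
    rep.enrichment = {p: (float(np.mean(v)) if v else float("nan"))
                      for p, v in enr.items()}
    rep.n_enrichment_complexes = sum(
        1 for r, h in zip(ranks_per_complex, hits_per_complex)
        if np.asarray(h, dtype=bool).any())
    return rep


def evaluate_potential(grids: Sequence[FeatureGrid],
                       params: ParameterVector,
                       hits_per_complex: Sequence[np.ndarray],
                       top_n: Sequence[int] = DEFAULT_TOP_N,
                       percentiles: Sequence[float] = DEFAULT_PERCENTILES,
                       ) -> EvaluationReport:
    """Score every complex with a potential and aggregate the assessments.

    ``hits_per_complex`` flags the qualifying decoys per complex (e.g.
    near-natives with >= 1 star, or only the inserted native row).
    """
    ranks = [rank_decoys(score(g, params)) for g in grids]
    return _report_from_ranks(ranks, hits_per_complex, top_n, percentiles)


def random_baseline(n_decoys_per_complex: Sequence[int],
                    hits_per_complex: Sequence[np.ndarray],
                    n_shuffles: int = 1000, seed: int = 0,
                    top_n: Sequence[int] = DEFAULT_TOP_N,
                    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
                    ) -> EvaluationReport:
    """Expected assessments under uniformly random scoring.

    Every metric is averaged over ``n_shuffles`` random rankings per
    complex; reproducible for a fixed seed.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    succ = {n: 0.0 for n in top_n}
    enr = {p: [] for p in percentiles}
    best_ranks: List[Optional[int]] = []
    n_enr = 0
    for n_dec, hits in zip(n_decoys_per_complex, hits_per_complex):
        hits = np.asarray(hits, dtype=bool)
        c_succ = {n: 0 for n in top_n}
        c_enr = {p: 0.0 for p in percentiles}
        c_best = 0.0
        for _ in range(n_shuffles):
            ranks = rng.permutation(n_dec) + 1
            for n in top_n:
                c_succ[n] += int(topn_success(ranks, hits, n))
            if hits.any():
                for p in percentiles:
                    c_enr[p] += enrichment_fraction(ranks, hits, p)
                c_best += float(np.min(ranks[hits]))
        for n in top_n:
            succ[n] += c_succ[n] / n_shuffles
        if hits.any():
            n_enr += 1
            for p in percentiles:
                enr[p].append(c_enr[p] / n_shuffles)
            best_ranks.append(int(round(c_best / n_shuffles)))
        else:
            best_ranks.append(None)
    n_c = len(n_decoys_per_complex)
    return EvaluationReport(
        success={n: succ[n] / n_c for n in top_n},
        enrichment={p: (float(np.mean(v)) if v else float("nan"))
                    for p, v in enr.items()},
        per_complex_best_rank=best_ranks,
        n_complexes=n_c,
        n_enrichment_complexes=n_enr,
    )
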