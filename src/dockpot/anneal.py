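"""Rank-weighted Monte-Carlo simulated annealing of potential parameters.

The trainer maximises a target function built directly from the scoring
behaviour: for every complex the decoys are scored and ranked under the
current parameters, and each decoy contributes the product of its
per-complex-normalised quality weight and a ranking weight that rises
(linearly or quadratically) from the last rank to 1 at rank 1,

    t = sum_c sum_i  wq_{i,c} * wr(rank_{i,c}).

A single randomly chosen parameter is perturbed per step; the move is
accepted with the Metropolis probability ``min(1, exp((t_new - t_old)/T))``
(the target is maximised, so uphill moves are always accepted).  The
temperature follows a "ziczac" schedule: an exponential decay envelope
modulated by a sin^2 oscillation between the envelope and envelope/ratio.
Move sizes adapt toward a target acceptance rate.  Only precomputed
feature grids are touched inside the loop, so each step is a handful of
matrix-vector products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .features import FeatureGrid
from .potentials import (ParameterVector, PotentialForm, VdwForm,
                         form_to_dict, n_features)
from .scoring import rank_decoys
from .structure import n_pair_types

__all__ = [
    "AnnealConfig",
    "AnnealTrace",
    "UntrainableError",
    "ranking_weight",
    "target_function",
    "metropolis_accept",
    "ziczac_temperature",
    "MoveState",
    "propose_move",
    "anneal",
]


class UntrainableError(ValueError):
    """No complex carries nonzero quality weight; nothing to optimise."""


@dataclass
class AnnealConfig:
    """Annealing schedule and move parameters.

    Defaults follow the training recipe used for the shipped potentials:
    300,000 steps for step/BSA potentials (100,000 for vdw), temperature
    decaying from 50 down to 0.05 (0.1% of the start), a ziczac schedule
    with envelope ratio 3 and 10 oscillations, adaptive move size starting
    at 1, and early stopping when the best target value improves by less
    than ``convergence_rtol`` (relative) over a 2,000-step window; the
    stagnation check is only armed once the temperature envelope is
    within a factor 2 of its end value, since a flat record during the
    hot exploration phase does not indicate convergence.
    For vdw potentials the moves live in (sigma, epsilon) space clamped to
    sigma in [1.5, 6] A and epsilon in [0, 50].
    """

    steps: int = 300_000
    t0: float = 50.0
    t_end: Optional[float] = None        # default: t0 / 1000
    envelope_ratio: float = 3.0
    oscillations: int = 10
    ranking_scheme: str = "linear"       # or "quadratic"
    d0: float = 1.0
    adapt_window: int = 100
    adapt_target: float = 0.3
    adapt_up: float = 1.1
    adapt_down: float = 0.9
    sigma_bounds: Tuple[float, float] = (1.5, 6.0)
    epsilon_bounds: Tuple[float, float] = (0.0, 50.0)
    value_bounds: Optional[Tuple[float, float]] = None   # step/bsa clamps
    convergence_window: int = 2_000
    convergence_rtol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_end is None:
            self.t_end = self.t0 / 1000.0
        if self.steps <= self.convergence_window:
            raise ValueError("steps must exceed the convergence window")
        if self.envelope_ratio <= 1:
            raise ValueError("envelope_ratio must exceed 1")
        if self.ranking_scheme not in ("linear", "quadratic"):
            raise ValueError("ranking_scheme must be linear or quadratic")


@dataclass
class AnnealTrace:
    """Per-step diagnostics of one annealing run."""
    t_values: np.ndarray          # target value of the current state
    temperatures: np.ndarray
    accepted: np.ndarray          # bool
    move_sizes: np.ndarray        # adaptive factor d at each step
    best_t: np.ndarray            # best-so-far target value
    n_steps: int = 0

    def trim(self) -> "AnnealTrace":
        n = self.n_steps
        return AnnealTrace(self.t_values[:n], self.temperatures[:n],
                           self.accepted[:n], self.move_sizes[:n],
                           self.best_t[:n], n)


def ranking_weight(rank, n: int, scheme: str = "linear"):
    """Weight of a rank: 1 at rank 1, decreasing toward the last rank.

    linear: ``(n - rank + 1) / n``; quadratic: the square of that.
    Accepts scalar or array ranks.
    """
    rank = np.asarray(rank)
    if np.any(rank < 1) or np.any(rank > n):
        raise ValueError("rank out of range")
    w = (n - rank + 1) / n
    if scheme == "quadratic":
        w = w ** 2
    elif scheme != "linear":
        raise ValueError(f"unknown ranking scheme {scheme!r}")
    return float(w) if w.ndim == 0 else w


def target_function(scores_per_complex: Sequence[np.ndarray],
                    weights_per_complex: Sequence[np.ndarray],
                    scheme: str = "linear") -> float:
    """Rank-based training target; higher is better."""
    t = 0.0
    for scores, wq in zip(scores_per_complex, weights_per_complex):
        wq = np.asarray(wq)
        if wq.sum() == 0:
            continue
        ranks = rank_decoys(np.asarray(scores))
        t += float(wq @ ranking_weight(ranks, len(ranks), scheme))
    return t


def metropolis_accept(t_new: float, t_old: float, temperature: float,
                      u: float) -> bool:
    """Accept iff ``u < min(1, exp((t_new - t_old) / T))``."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    delta = (t_new - t_old) / temperature
    if delta >= 0:
        return True
    return u < np.exp(max(delta, -700.0))


def ziczac_temperature(step: int, total: int, t0: float, t_end: float,
                       ratio: float = 3.0, oscillations: int = 10) -> float:
    """Oscillating annealing temperature.

    The upper envelope decays exponentially from ``t0`` to ``t_end``;
    a sin^2 modulation swings the temperature between the envelope and
    envelope/ratio, starting and (for an even oscillation count) ending
    on the envelope itself.
    """
    if not 0 <= step <= total:
        raise ValueError("step out of range")
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    frac = step / total
    t_hi = t0 * (t_end / t0) ** frac
    mod = np.sin(np.pi * oscillations * frac + np.pi / 2.0) ** 2
    return float(t_hi * (1.0 / ratio + (1.0 - 1.0 / ratio) * mod))


@dataclass
class MoveState:
    """Adaptive move-size state."""
    d: float = 1.0
    window: int = 100
    target: float = 0.3
    up: float = 1.1
    down: float = 0.9
    recent: List[bool] = field(default_factory=list)

    def record(self, accepted: bool) -> None:
        self.recent.append(accepted)
        if len(self.recent) >= self.window:
            rate = float(np.mean(self.recent))
            self.d *= self.up if rate > self.target else self.down
            self.recent.clear()


def propose_move(params: np.ndarray, state: MoveState,
                 rng: np.random.Generator,
                 lower: Optional[np.ndarray] = None,
                 upper: Optional[np.ndarray] = None) -> np.ndarray:
    """Perturb one uniformly chosen parameter by +/- Uniform(0, d).

    The result is clamped to per-parameter bounds where given.  Moves are
    additive in the natural parameter space (plain values for step/BSA,
    sigma/epsilon for vdw).
    """
    new = params.copy()
    i = int(rng.integers(len(params)))
    new[i] += rng.uniform(-state.d, state.d)
    if lower is not None:
        new[i] = max(new[i], lower[i])
    if upper is not None:
        new[i] = min(new[i], upper[i])
    return new


# ---------------------------------------------------------------------------
# Natural <-> scoring parameter spaces
# ---------------------------------------------------------------------------

def _natural_init(form: PotentialForm, n_params: int, npairs: int) -> np.ndarray:
    if form.kind == "vdw":
        x = np.empty(2 * npairs)
        x[:npairs] = 3.0   # sigma (A)
        x[npairs:] = 1.0   # epsilon
        return x
    return np.zeros(n_params)


def _natural_bounds(form: PotentialForm, config: AnnealConfig,
                    n_params: int, npairs: int):
    if form.kind == "vdw":
        lower = np.empty(2 * npairs)
        upper = np.empty(2 * npairs)
        lower[:npairs], upper[:npairs] = config.sigma_bounds
        lower[npairs:], upper[npairs:] = config.epsilon_bounds
        return lower, upper
    if config.value_bounds is not None:
        lo, hi = config.value_bounds
        return np.full(n_params, lo), np.full(n_params, hi)
    return None, None


def _to_values(form: PotentialForm, x: np.ndarray, npairs: int) -> np.ndarray:
    if form.kind == "vdw":
        sigma, eps = x[:npairs], x[npairs:]
        alpha = eps * sigma ** 8
        beta = eps * sigma ** 6
        return np.concatenate([alpha, -beta])
    return x


def anneal(grids: Sequence[FeatureGrid],
           quality_weights: Sequence[np.ndarray],
           config: AnnealConfig) -> Tuple[ParameterVector, AnnealTrace]:
    """Train a potential by simulated annealing over precomputed grids.

    Parameters
    ----------
    grids:
        One feature grid per training complex, all layout-compatible.
    quality_weights:
        Per-complex normalised quality weights (one array per grid);
        complexes whose weights are all zero are skipped.
    config:
        Schedule, move and convergence settings; ``config.seed`` makes the
        run bit-reproducible.

    Returns the best-so-far parameters and the full step trace.
    """
    if not grids:
        raise ValueError("no training grids")
    ref = grids[0]
    for g in grids[1:]:
        if not ref.compatible_with(g):
            raise ValueError("training grids are not layout-compatible")
    weights = [np.asarray(w, dtype=np.float64) for w in quality_weights]
    if len(weights) != len(grids):
        raise ValueError("one weight array per grid required")
    active = [i for i, w in enumerate(weights) if w.sum() > 0]
    if not active:
        raise UntrainableError("every complex has all-zero quality weights")
    mats = [grids[i].matrix for i in active]
    wqs = [weights[i] for i in active]

    form = ref.form
    npairs = n_pair_types(ref.n_types)
    n_params = ref.matrix.shape[1] if form.kind != "vdw" else 2 * npairs

    rng = np.random.default_rng(config.seed)
    x = _natural_init(form, n_params, npairs)
    lower, upper = _natural_bounds(form, config, n_params, npairs)
    state = MoveState(d=config.d0, window=config.adapt_window,
                      target=config.adapt_target, up=config.adapt_up,
                      down=config.adapt_down)

    def evaluate(xv: np.ndarray) -> float:
        values = _to_values(form, xv, npairs)
        return target_function([m @ values for m in mats], wqs,
                               config.ranking_scheme)

    t_cur = evaluate(x)
    best_x = x.copy()
    best_t = t_cur

    S = config.steps
    trace = AnnealTrace(np.empty(S), np.empty(S), np.zeros(S, dtype=bool),
                        np.empty(S), np.empty(S))
    window = config.convergence_window
    best_hist = np.empty(S + 1)
    best_hist[0] = best_t

    for s in range(S):
        temp = ziczac_temperature(s + 1, S, config.t0, config.t_end,
                                  config.envelope_ratio, config.oscillations)
        proposal = propose_move(x, state, rng, lower, upper)
        t_new = evaluate(proposal)
        u = rng.uniform()
        ok = metropolis_accept(t_new, t_cur, temp, u)
        if ok:
            x = proposal
            t_cur = t_new
            if t_cur > best_t:
                best_t = t_cur
                best_x = x.copy()
        state.record(ok)
        trace.t_values[s] = t_cur
        trace.temperatures[s] = temp
        trace.accepted[s] = ok
        trace.move_sizes[s] = state.d
        trace.best_t[s] = best_t
        best_hist[s + 1] = best_t
        trace.n_steps = s + 1
        # stagnation can only mean convergence once the schedule is cold:
        # during the hot phase new records are naturally rare, so the
        # check is armed when the decay envelope nears its floor
        envelope = config.t0 * (config.t_end / config.t0) ** ((s + 1) / S)
        if s + 1 >= window and envelope <= 2.0 * config.t_end:
            prev = best_hist[s + 1 - window]
            denom = max(abs(best_t), 1e-12)
            if (best_t - prev) / denom < config.convergence_rtol:
                break

    params = ParameterVector(
        form=form, values=_to_values(form, best_x, npairs),
        n_types=ref.n_types, table_hash=ref.table_hash,
        heavy_type_indices=ref.heavy_type_indices,
        meta={"trainer": "mc-anneal", "steps_run": trace.n_steps,
              "best_t": best_t, "seed": config.seed,
              "ranking_scheme": config.ranking_scheme},
    )
    return params, trace.trim()
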