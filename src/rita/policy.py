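"""Recurrent individual treatment assignment (RITA).

RITA is a probabilistic two-arm assignment policy that learns per individual
from pooled response ranks, without ever estimating treatment effects.  Each
period it executes:

1. Assign individual ``i`` to arm A with probability ``τ_Ai`` (B otherwise).
2. Observe the treatment response ``Δy_i = y_t,i − y_{t−1,i}``.
3. Rank all responses pooled across both arms: rank 1 for the smallest
   change, ``obs`` for the largest.
4. Update the individual mean rank (IMR) of the arm the individual was
   assigned to: the running mean of that arm's received ranks.  The other
   arm's IMR is untouched.  Both IMRs start at ``obs/2``.
5. Update the assignment probability.  For an individual assigned to A with
   rank r:

       τ_A' = (r / obs) · (r / IMR_B) ** (n_A − 1)

   where ``n_A`` counts A-assignments so far (including this period).  The
   first factor is the rescaled individual rank, the second the relative rank
   against the alternative arm's history, and the exponent is a learning
   parameter that makes the relative rank count exponentially more as
   evidence accumulates.  An individual assigned to B updates ``τ_B``
   symmetrically and ``τ_A = 1 − τ_B``.
6. Clamp ``τ_A`` into ``[λ_l, λ_u]`` (defaults 0.05/0.95) so some exploration
   always remains.

The per-individual bookkeeping lives in :class:`RitaState`; the functional
operations (`update_imr`, `update_probability`, …) are composed by
:func:`step`, and :class:`RitaPolicy` adapts them to the simulation engine's
propose/observe protocol.
"""

from __future__ import annotations

import dataclasses as dc
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PolicyConfig",
    "RitaState",
    "RitaPolicy",
    "init_states",
    "draw_assignments",
    "rank_responses",
    "update_imr",
    "update_probability",
    "clamp_probability",
    "apply_updates",
    "step",
]


@dc.dataclass(frozen=True)
class PolicyConfig:
    """Tunables of the assignment policy.

    lambda_l, lambda_u
        Exploration bounds clamping every assignment probability; with the
        defaults 0.05/0.95 no individual is ever assigned deterministically.
    tie_rule
        How tied responses are ranked: ``"random"`` (seeded random order, the
        default) or ``"average"`` (average ranks re-indexed to a permutation,
        ties resolved by individual index).
    eq10_literal
        If True, use the literal asymmetric update for B-assignments,
        ``1 − τ_A = (1 − r/obs)·(IMR_A/r)**(n_B−1)``, instead of the
        symmetric mirror.  The literal form moves probability mass away from
        B precisely when B performs well; it is retained only for comparison.
    """

    lambda_l: float = 0.05
    lambda_u: float = 0.95
    tie_rule: str = "random"
    eq10_literal: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_l < self.lambda_u < 1.0):
            raise ValueError("need 0 < lambda_l < lambda_u < 1")
        if self.tie_rule not in ("random", "average"):
            raise ValueError("tie_rule must be 'random' or 'average'")


@dc.dataclass(frozen=True)
class RitaState:
    """Per-individual algorithm state.

    ``imr_a``/``imr_b`` are the per-arm individual mean ranks, equal to
    ``rank_sum/count`` once the arm has been received and ``obs/2`` before.
    ``tau_a`` is the clamped probability of assignment to A for the next
    period; ``tau_a_unclamped`` the raw update kept for diagnostics.
    """

    tau_a: float
    imr_a: float
    imr_b: float
    count_a: int = 0
    count_b: int = 0
    rank_sum_a: float = 0.0
    rank_sum_b: float = 0.0
    tau_a_unclamped: float = 0.5


def init_states(obs: int) -> list[RitaState]:
    """Fresh states: τ_A = ½ and both mean ranks at the neutral obs/2."""
    if obs < 2:
        raise ValueError("obs must be at least 2")
    half = obs / 2.0
    return [RitaState(tau_a=0.5, imr_a=half, imr_b=half) for _ in range(obs)]


def draw_assignments(
    states: Sequence[RitaState], rng: np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli assignment: A with probability ``tau_a``."""
    tau = np.array([s.tau_a for s in states])
    return np.where(rng.random(len(states)) < tau, "A", "B")


def rank_responses(
    delta_y: np.ndarray,
    tie_rule: str = "random",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pooled response ranks: a permutation of 1..obs, increasing in Δy.

    Responses from both arms are ranked together.  Ties are broken at random
    (seeded) by default, or by individual index under ``tie_rule="average"``
    (average ranks re-indexed to integers).
    """
    delta_y = np.asarray(delta_y, dtype=float)
    if not np.all(np.isfinite(delta_y)):
        raise ValueError("responses must be finite")
    n = len(delta_y)
    if tie_rule == "random":
        if rng is None:
            raise ValueError("tie_rule='random' needs an rng")
        tiebreak = rng.random(n)
    elif tie_rule == "average":
        tiebreak = np.arange(n)
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    order = np.lexsort((tiebreak, delta_y))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def update_imr(state: RitaState, arm: str, rank: int) -> RitaState:
    """Fold this period's rank into the assigned arm's running mean rank."""
    if arm == "A":
        count = state.count_a + 1
        rank_sum = state.rank_sum_a + rank
        return dc.replace(
            state, count_a=count, rank_sum_a=rank_sum, imr_a=rank_sum / count
        )
    if arm == "B":
        count = state.count_b + 1
        rank_sum = state.rank_sum_b + rank
        return dc.replace(
            state, count_b=count, rank_sum_b=rank_sum, imr_b=rank_sum / count
        )
    raise ValueError(f"unknown arm {arm!r}")


def update_probability(
    state: RitaState, arm: str, rank: int, obs: int, eq10_literal: bool = False
) -> float:
    """Raw (pre-clamp) next-period τ_A after this period's assignment.

    Must be called after :func:`update_imr`, so the assigned arm's count
    already includes the current period and the learning exponent is
    ``count − 1`` (zero on the first assignment to an arm).
    """
    r = float(rank)
    with np.errstate(over="ignore"):
        if arm == "A":
            if state.count_a < 1:
                raise ValueError("update_imr must run before update_probability")
            tau_a = (r / obs) * float(
                np.float64(r / state.imr_b) ** (state.count_a - 1)
            )
            return tau_a
        if arm == "B":
            if state.count_b < 1:
                raise ValueError("update_imr must run before update_probability")
            if eq10_literal:
                tau_b = (1.0 - r / obs) * float(
                    np.float64(state.imr_a / r) ** (state.count_b - 1)
                )
            else:
                tau_b = (r / obs) * float(
                    np.float64(r / state.imr_a) ** (state.count_b - 1)
                )
            return 1.0 - tau_b
    raise ValueError(f"unknown arm {arm!r}")


def clamp_probability(tau: float, cfg: PolicyConfig) -> float:
    """Clamp τ_A so both arms' probabilities respect the exploration bounds."""
    lo = max(cfg.lambda_l, 1.0 - cfg.lambda_u)
    hi = min(cfg.lambda_u, 1.0 - cfg.lambda_l)
    return float(min(max(tau, lo), hi))


def apply_updates(
    states: Sequence[RitaState],
    assignments: Sequence[str],
    ranks: np.ndarray,
    cfg: PolicyConfig,
) -> list[RitaState]:
    """Per-individual IMR + probability update + clamp, for known ranks."""
    obs = len(states)
    out = []
    for st, arm, rank in zip(states, assignments, ranks):
        st = update_imr(st, arm, int(rank))
        tau = update_probability(st, arm, int(rank), obs, cfg.eq10_literal)
        st = dc.replace(
            st, tau_a_unclamped=tau, tau_a=clamp_probability(tau, cfg)
        )
        out.append(st)
    return out


def step(
    states: Sequence[RitaState],
    assignments: Sequence[str],
    delta_y: np.ndarray,
    cfg: PolicyConfig,
    rng: np.random.Generator,
) -> list[RitaState]:
    """One full post-assignment update: rank, IMR, probability, clamp.

    Pure with respect to its inputs; returns new states.
    """
    if not (len(states) == len(assignments) == len(delta_y)):
        raise ValueError("states, assignments and delta_y must have equal length")
    ranks = rank_responses(np.asarray(delta_y), cfg.tie_rule, rng)
    return apply_updates(states, assignments, ranks, cfg)


class RitaPolicy:
    """Engine-facing adapter: propose assignments, observe responses.

    Parameters
    ----------
    config
        :class:`PolicyConfig`; defaults reproduce the standard setup
        (bounds 0.05/0.95, random tie-breaks, mirrored update).
    record_history
        Keep a per-period state dump retrievable via :meth:`state_frame`.
    """

    name = "rita"

    def __init__(self, config: PolicyConfig | None = None,
                 record_history: bool = False) -> None:
        self.config = config or PolicyConfig()
        self.record_history = record_history
        self.states: list[RitaState] | None = None
        self._rng: np.random.Generator | None = None
        self._period = 0
        self._history: list[pd.DataFrame] = []

    def reset(self, obs: int, rng: np.random.Generator,
              observed: dict | None = None) -> None:
        self.states = init_states(obs)
        self._rng = rng
        self._period = 0
        self._history = []

    def propose(self) -> np.ndarray:
        if self.states is None:
            raise RuntimeError("policy not reset")
        return draw_assignments(self.states, self._rng)

    def observe(self, assignments: np.ndarray, delta_y: np.ndarray) -> None:
        self._period += 1
        delta_y = np.asarray(delta_y, dtype=float)
        ranks = rank_responses(delta_y, self.config.tie_rule, self._rng)
        self.states = apply_updates(self.states, assignments, ranks, self.config)
        if self.record_history:
            self._history.append(self._snapshot(assignments, delta_y, ranks))

    def _snapshot(self, assignments, delta_y, ranks) -> pd.DataFrame:
        s = self.states
        return pd.DataFrame(
            {
                "period": self._period,
                "id": np.arange(len(s)),
                "arm": assignments,
                "delta_y": delta_y,
                "rank": ranks,
                "imr_A": [x.imr_a for x in s],
                "imr_B": [x.imr_b for x in s],
                "count_A": [x.count_a for x in s],
                "count_B": [x.count_b for x in s],
                "tau_A_unclamped": [x.tau_a_unclamped for x in s],
                "tau_A": [x.tau_a for x in s],
            }
        )

    def state_frame(self) -> pd.DataFrame:
        """Recorded per-period state dump (requires ``record_history=True``)."""
        if not self._history:
            return pd.DataFrame(
                columns=["period", "id", "arm", "delta_y", "rank", "imr_A",
                         "imr_B", "count_A", "count_B", "tau_A_unclamped",
                         "tau_A"]
            )
        return pd.concat(self._history, ignore_index=True)
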