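"""Longitudinal simulation loop and paired policy comparisons.

Each period the engine asks the policy for assignments, generates the
treatment response Δy = effect(assigned arm) + ε with ε ~ N(0, noise_sd),
accumulates the outcome, and feeds (assignments, Δy) back to the policy.
Policies never see the per-individual effects, the latent draws, or — unless
they explicitly request observed covariates — the group label.

Randomness is organised as named substreams of one master seed (population,
outcome noise, and one stream per policy name), so that in a head-to-head
comparison every policy faces the bit-identical population and, by default,
the identical noise realisation per (individual, period).  With that pairing
the per-individual difference in cumulative gain between two policies
isolates their assignment decisions.
"""

from __future__ import annotations

import dataclasses as dc
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .worlds import Individual, WorldSpec, get_world, make_population

__all__ = ["PeriodRecord", "Trajectory", "simulate", "run_comparison"]

DEFAULT_NOISE_SD = 0.1


@dc.dataclass(frozen=True)
class PeriodRecord:
    """One (individual, period) cell of the panel."""

    period: int
    id: int
    arm: str
    delta_y: float
    y: float


@dc.dataclass
class Trajectory:
    """Complete rectangular panel of one policy run.

    ``y`` has ``T+1`` rows (row 0 is the baseline outcome y0); ``assignments``
    and ``delta_y`` have ``T`` rows.  ``effect_a``/``effect_b``/``g`` are the
    generator's ground truth, carried for evaluation only — policies never
    see them.
    """

    world_id: int
    policy_name: str
    seed: int
    obs: int
    periods: int
    ids: np.ndarray
    g: np.ndarray
    effect_a: np.ndarray
    effect_b: np.ndarray
    assignments: np.ndarray  # (T, obs) of "A"/"B"
    delta_y: np.ndarray      # (T, obs)
    y: np.ndarray            # (T+1, obs)

    @property
    def y0(self) -> np.ndarray:
        return self.y[0]

    def gains(self, period: int | None = None) -> np.ndarray:
        """Per-individual cumulative gain y_period − y_0 (default: final)."""
        if period is None:
            period = self.periods
        return self.y[period] - self.y[0]

    def records(self) -> list[PeriodRecord]:
        return [
            PeriodRecord(t + 1, int(i), str(self.assignments[t, i]),
                         float(self.delta_y[t, i]), float(self.y[t + 1, i]))
            for t in range(self.periods)
            for i in range(self.obs)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long-format panel: period, id, policy, arm, delta_y, y."""
        T, n = self.periods, self.obs
        return pd.DataFrame(
            {
                "period": np.repeat(np.arange(1, T + 1), n),
                "id": np.tile(self.ids, T),
                "policy": self.policy_name,
                "arm": self.assignments.ravel(),
                "delta_y": self.delta_y.ravel(),
                "y": self.y[1:].ravel(),
            }
        )


def _population_arrays(pop: Sequence[Individual]):
    ids = np.array([p.id for p in pop])
    g = np.array([p.g for p in pop])
    eff_a = np.array([p.effect_a for p in pop])
    eff_b = np.array([p.effect_b for p in pop])
    y0 = np.array([p.y0 for p in pop])
    return ids, g, eff_a, eff_b, y0


def simulate(
    world: str | WorldSpec,
    policy,
    obs: int = 1000,
    periods: int = 60,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    population: Sequence[Individual] | None = None,
    noise: np.ndarray | None = None,
) -> Trajectory:
    """Run one policy over ``periods`` periods on a world's population.

    ``population`` and ``noise`` may be supplied to share them across runs
    (as :func:`run_comparison` does); otherwise they are drawn from the
    master seed's "population" and "noise" substreams.  The policy's own
    randomness uses the substream keyed by its name, so runs are reproducible
    and independent of any other policy run under the same seed.
    """
    spec = get_world(world)
    if periods < 1:
        raise ValueError("periods must be at least 1")
    if population is None:
        population = make_population(spec, obs, substream(seed, "population"))
    if len(population) != obs:
        raise ValueError("population size does not match obs")
    ids, g, eff_a, eff_b, y0 = _population_arrays(population)
    if noise is None:
        noise = noise_sd * substream(seed, "noise").standard_normal((periods, obs))
    if noise.shape != (periods, obs):
        raise ValueError("noise must have shape (periods, obs)")

    policy.reset(obs, substream(seed, "policy", policy.name), observed={"G": g})

    y = np.empty((periods + 1, obs))
    y[0] = y0
    assignments = np.empty((periods, obs), dtype="<U1")
    delta = np.empty((periods, obs))
    for t in range(periods):
        arms = np.asarray(policy.propose())
        if not np.isin(arms, ("A", "B")).all():
            bad = sorted(set(arms) - {"A", "B"})
            raise ValueError(f"policy proposed invalid arm(s): {bad}")
        d = np.where(arms == "A", eff_a, eff_b) + noise[t]
        y[t + 1] = y[t] + d
        assignments[t] = arms
        delta[t] = d
        policy.observe(arms, d)

    return Trajectory(
        world_id=spec.world_id, policy_name=policy.name, seed=seed, obs=obs,
        periods=periods, ids=ids, g=g, effect_a=eff_a, effect_b=eff_b,
        assignments=assignments, delta_y=delta, y=y,
    )


def run_comparison(
    world: str | WorldSpec,
    policies: Sequence,
    obs: int = 1000,
    periods: int = 60,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    shared_noise: bool = True,
) -> list[Trajectory]:
    """Run several policies on the identical population, paired by default.

    All policies face the same latent draws and baseline outcomes.  With
    ``shared_noise=True`` (default) the outcome-noise realisation is also
    shared per (individual, period), so per-individual gain differences are
    exact paired counterfactuals of the assignment decisions;
    ``shared_noise=False`` gives each policy an independent noise stream.
    Policy-internal randomness always uses independent substreams keyed by
    policy name, so the result for a policy does not depend on list order.
    """
    if len(policies) < 2:
        raise ValueError("need at least two policies to compare")
    # duplicate names share a policy substream, so two runs of the same
    # policy within one comparison come out identical by construction
    spec = get_world(world)
    population = make_population(spec, obs, substream(seed, "population"))
    shared = (
        noise_sd * substream(seed, "noise").standard_normal((periods, obs))
        if shared_noise
        else None
    )
    out = []
    for policy in policies:
        noise = shared
        if noise is None:
            noise = noise_sd * substream(
                seed, "noise", policy.name
            ).standard_normal((periods, obs))
        out.append(
            simulate(spec, policy, obs=obs, periods=periods, seed=seed,
                     noise_sd=noise_sd, population=population, noise=noise)
        )
    return out
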