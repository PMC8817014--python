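"""Synthetic two-arm populations with heterogeneous treatment effects.

Each simulated person carries a fixed pair of per-period treatment effects,
one for intervention A and one for intervention B.  The effect of arm
``I ∈ {A, B}`` for individual ``i`` follows the constrained decomposition

    h_I(L_i, G_i) = u_I(L_i) * (1 + o_I(G_i)),

where ``u_I(L_i)`` is a latent (unobserved) draw, normal or degenerate, and
``o_I(G_i) = g / s_I`` is an observed-group interaction with a binary group
indicator ``g`` (``G`` for arm A, ``1−G`` for arm B in the shipped presets)
and divisor ``s_I`` (``s_I = 0`` disables the interaction).

Four preset "worlds" span the interesting regimes:

* ``world1`` — constant effects (A: 0.8, B: 0.6); no heterogeneity.
* ``world2`` — latent heterogeneity only, same population means as world 1.
* ``world3`` — latent + observed-group heterogeneity, means still 0.8 vs 0.6.
* ``world4`` — equal population means (0.8 each) but A is better for G=1 and
  B for G=0, so the population-average contrast carries no information about
  which arm any individual should receive.

Assignment policies never observe these effects; they are ground truth used
by the outcome generator and, after the fact, by the evaluation layer.
"""

from __future__ import annotations

import dataclasses as dc
import io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

ARMS = ("A", "B")

#: Baseline-outcome distribution: y0 ~ N(Y0_MEAN, Y0_SD).
Y0_MEAN = 10.0
Y0_SD = 1.0


@dc.dataclass(frozen=True)
class ArmSpec:
    """Generative parameters of one arm's individual treatment effect.

    Parameters
    ----------
    latent_mean, latent_sd
        Mean and standard deviation of the latent effect draw ``u_I``.
        ``latent_sd = 0`` gives a degenerate (constant) latent effect.
    interaction_scale
        Divisor ``s`` of the observed-group interaction ``u·g/s``;
        ``0`` disables the interaction entirely.
    interaction_group
        Which level of the binary group indicator G activates the
        interaction (the indicator used is ``1`` when ``G == interaction_group``).
    """

    latent_mean: float
    latent_sd: float
    interaction_scale: float = 0.0
    interaction_group: int = 1

    def indicator(self, g: np.ndarray | int) -> np.ndarray | int:
        """Binary interaction indicator for group value(s) ``g``."""
        return np.asarray(g == self.interaction_group, dtype=float)

    def multiplier(self, g: np.ndarray | int) -> np.ndarray | float:
        """The factor ``1 + g_ind / s`` applied to the latent draw."""
        if self.interaction_scale == 0:
            return np.ones_like(np.asarray(g, dtype=float))
        return 1.0 + self.indicator(g) / self.interaction_scale


@dc.dataclass(frozen=True)
class WorldSpec:
    """One simulation regime: both arms' effect generators plus the group mix.

    ``mean_effect_a``/``mean_effect_b`` are the declared population-average
    effects; :func:`world_ate` recovers them from the generative parameters,
    which is checked by the test suite for every preset.
    """

    world_id: int
    mean_effect_a: float
    mean_effect_b: float
    arm_a: ArmSpec
    arm_b: ArmSpec
    group_fraction: float = 0.5
    group_assignment: str = "exact"  # "exact" half-split or "bernoulli"

    def __post_init__(self) -> None:
        if not 0.0 <= self.group_fraction <= 1.0:
            raise ValueError("group_fraction must lie in [0, 1]")
        if self.group_assignment not in ("exact", "bernoulli"):
            raise ValueError("group_assignment must be 'exact' or 'bernoulli'")

    def arm(self, arm: str) -> ArmSpec:
        if arm == "A":
            return self.arm_a
        if arm == "B":
            return self.arm_b
        raise ValueError(f"unknown arm {arm!r}; expected 'A' or 'B'")

    # --- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dc.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WorldSpec":
        d = dict(d)
        d["arm_a"] = ArmSpec(**d["arm_a"])
        d["arm_b"] = ArmSpec(**d["arm_b"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WorldSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dc.dataclass(frozen=True)
class Individual:
    """One simulated person's latent and observed attributes.

    ``effect_a`` and ``effect_b`` are the per-period treatment effects implied
    by the world; they are constant within an individual across periods.
    """

    id: int
    g: int
    e_la: float
    e_lb: float
    effect_a: float
    effect_b: float
    y0: float


#: The four shipped simulation regimes.
WORLD_PRESETS: dict[str, WorldSpec] = {
    "world1": WorldSpec(
        world_id=1,
        mean_effect_a=0.8,
        mean_effect_b=0.6,
        arm_a=ArmSpec(latent_mean=0.8, latent_sd=0.0),
        arm_b=ArmSpec(latent_mean=0.6, latent_sd=0.0),
    ),
    "world2": WorldSpec(
        world_id=2,
        mean_effect_a=0.8,
        mean_effect_b=0.6,
        arm_a=ArmSpec(latent_mean=0.8, latent_sd=0.4),
        arm_b=ArmSpec(latent_mean=0.6, latent_sd=0.3),
    ),
    "world3": WorldSpec(
        world_id=3,
        mean_effect_a=0.8,
        mean_effect_b=0.6,
        arm_a=ArmSpec(latent_mean=0.7, latent_sd=0.35,
                      interaction_scale=3.5, interaction_group=1),
        arm_b=ArmSpec(latent_mean=0.5, latent_sd=0.25,
                      interaction_scale=2.5, interaction_group=0),
    ),
    "world4": WorldSpec(
        world_id=4,
        mean_effect_a=0.8,
        mean_effect_b=0.8,
        arm_a=ArmSpec(latent_mean=0.7, latent_sd=0.35,
                      interaction_scale=3.5, interaction_group=1),
        arm_b=ArmSpec(latent_mean=0.7, latent_sd=0.35,
                      interaction_scale=3.5, interaction_group=0),
    ),
}


def get_world(name_or_spec: str | WorldSpec) -> WorldSpec:
    """Resolve a preset name (``"world1"``…``"world4"``) or pass a spec through."""
    if isinstance(name_or_spec, WorldSpec):
        return name_or_spec
    try:
        return WORLD_PRESETS[name_or_spec]
    except KeyError:
        raise KeyError(
            f"unknown world {name_or_spec!r}; known presets: "
            f"{sorted(WORLD_PRESETS)}"
        ) from None


def heterogeneous_effect(
    spec: WorldSpec, arm: str, g: np.ndarray | int, latent: np.ndarray | float
):
    """Per-period treatment effect implied by a latent draw and group status.

    Implements ``h = u · (1 + g_ind/s)`` for the given arm.
    """
    a = spec.arm(arm)
    return np.asarray(latent, dtype=float) * a.multiplier(g)


def world_ate(spec: WorldSpec, arm: str, group: int | None = None) -> float:
    """Closed-form expected treatment effect of ``arm``.

    With ``group`` given, returns ``E[u]·(1 + g_ind/s)`` for that subgroup;
    with ``group=None``, the group_fraction-weighted population mean.
    """
    a = spec.arm(arm)
    if group is not None:
        return float(a.latent_mean * a.multiplier(int(group)))
    p1 = spec.group_fraction
    return float(
        p1 * world_ate(spec, arm, 1) + (1.0 - p1) * world_ate(spec, arm, 0)
    )


def make_population(
    spec: str | WorldSpec, obs: int, seed: int | np.random.Generator
) -> list[Individual]:
    """Draw ``obs`` individuals from a world.

    Group labels are an exact rounded split (then shuffled) by default, or iid
    Bernoulli when ``spec.group_assignment == "bernoulli"``.  Latent effects
    are iid normal per arm; baseline outcomes ``y0 ~ N(10, 1)``.
    Identical seeds give bit-identical populations.
    """
    spec = get_world(spec)
    if obs < 2:
        raise ValueError("obs must be at least 2")
    rng = np.random.default_rng(seed)

    if spec.group_assignment == "bernoulli":
        g = (rng.random(obs) < spec.group_fraction).astype(int)
    else:
        n1 = int(round(spec.group_fraction * obs))
        g = np.zeros(obs, dtype=int)
        g[:n1] = 1
        rng.shuffle(g)

    e_la = spec.arm_a.latent_mean + spec.arm_a.latent_sd * rng.standard_normal(obs)
    e_lb = spec.arm_b.latent_mean + spec.arm_b.latent_sd * rng.standard_normal(obs)
    eff_a = heterogeneous_effect(spec, "A", g, e_la)
    eff_b = heterogeneous_effect(spec, "B", g, e_lb)
    y0 = Y0_MEAN + Y0_SD * rng.standard_normal(obs)

    return [
        Individual(
            id=i, g=int(g[i]), e_la=float(e_la[i]), e_lb=float(e_lb[i]),
            effect_a=float(eff_a[i]), effect_b=float(eff_b[i]), y0=float(y0[i]),
        )
        for i in range(obs)
    ]


def optimal_arm(ind: Individual) -> str:
    """Ground-truth better arm for one individual; exact ties go to A."""
    return "A" if ind.effect_a >= ind.effect_b else "B"


def optimal_arms(pop: Sequence[Individual]) -> np.ndarray:
    """Vector of :func:`optimal_arm` over a population."""
    return np.array([optimal_arm(ind) for ind in pop])


def population_frame(pop: Iterable[Individual]) -> pd.DataFrame:
    """Tabular view of a population (one row per individual)."""
    return pd.DataFrame(
        [(p.id, p.g, p.e_la, p.e_lb, p.effect_a, p.effect_b, p.y0) for p in pop],
        columns=["id", "G", "e_LA", "e_LB", "effect_A", "effect_B", "y0"],
    )


def write_population(pop: Iterable[Individual], path) -> None:
    """Export a population as delimited text (CSV)."""
    population_frame(pop).to_csv(path, index=False)
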