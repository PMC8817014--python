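"""Run configuration: defaults, YAML round-trip, policy construction."""

from __future__ import annotations

import dataclasses as dc

import yaml

from .baselines import ModeratorPolicy, RctBaselinePolicy
from .policy import PolicyConfig, RitaPolicy
from .worlds import WorldSpec, get_world

KNOWN_POLICIES = ("baseline", "rita", "moderator")

#: Above this many panel records (obs × periods), per-period trajectory and
#: state dumps are skipped unless explicitly requested.
DUMP_GUARD_RECORDS = 100_000


@dc.dataclass
class RunConfig:
    """Everything needed to reproduce one run bit-for-bit.

    ``world`` is a preset name or an inline :class:`WorldSpec` mapping; the
    defaults (obs=1000, 60 periods, noise sd 0.1, bounds 0.05/0.95) are the
    standard study conditions.
    """

    world: str | dict = "world1"
    obs: int = 1000
    periods: int = 60
    policies: tuple[str, ...] = ("baseline", "rita")
    noise_sd: float = 0.1
    seed: int = 0
    lambda_l: float = 0.05
    lambda_u: float = 0.95
    tie_rule: str = "random"
    eq10_literal: bool = False
    shared_noise: bool = True
    dump_records: bool | None = None  # None: auto size guard

    def __post_init__(self) -> None:
        self.policies = tuple(self.policies)
        unknown = [p for p in self.policies if p not in KNOWN_POLICIES]
        if unknown:
            raise ValueError(
                f"unknown policy name(s) {unknown}; known: {list(KNOWN_POLICIES)}"
            )
        self.world_spec  # validates the world name/spec eagerly

    @property
    def world_spec(self) -> WorldSpec:
        if isinstance(self.world, dict):
            return WorldSpec.from_dict(self.world)
        return get_world(self.world)

    @property
    def policy_config(self) -> PolicyConfig:
        return PolicyConfig(
            lambda_l=self.lambda_l, lambda_u=self.lambda_u,
            tie_rule=self.tie_rule, eq10_literal=self.eq10_literal,
        )

    def build_policies(self, record_history: bool = False) -> list:
        built = []
        for name in self.policies:
            if name == "baseline":
                built.append(RctBaselinePolicy())
            elif name == "moderator":
                built.append(ModeratorPolicy())
            elif name == "rita":
                built.append(
                    RitaPolicy(self.policy_config, record_history=record_history)
                )
        return built

    def should_dump(self) -> bool:
        if self.dump_records is not None:
            return self.dump_records
        return self.obs * self.periods <= DUMP_GUARD_RECORDS

    # --- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dc.asdict(self)
        d["policies"] = list(self.policies)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dc.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
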