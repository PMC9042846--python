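"""Run configuration for the dynamic-network giving-game simulator.

A session is fully described by a :class:`SimulationConfig`: network size and
density, number of rounds, how often ties may be rewired, the two experimental
manipulations (baseline endowment inequality and wealth productivity), the
payoff multiplier, the behavior model driving the synthetic agents, and a seed.

All validation is collected up front: constructing a config from a mapping
reports *every* offending field at once rather than failing on the first.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

COOPERATION_LEVELS = (0, 10, 20, 30, 40, 50)
MAX_COOPERATION = 50


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration fields.

    ``errors`` holds one human-readable message per problem.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration: " + "; ".join(self.errors))


@dataclass(frozen=True)
class MultiplierSpec:
    """Payoff multiplier applied to each MU a giver sends to a neighbor.

    Under the ``control`` regime every MU given is doubled, independent of
    wealth.  Under the ``productivity`` regime the multiplier grows with the
    giver's endowment E as ``clamp(1 + slope * E / reference_endowment, floor,
    cap)`` — linear, equal to 2 at the reference (mean) endowment so the two
    regimes coincide there, floored above 1 so the prisoner's-dilemma ordering
    T > R > P > S is preserved for every feasible endowment.

    ``basis`` selects whether the giver's current wealth or their initial
    endowment feeds the multiplier.
    """

    regime: str = "control"  # {"control", "productivity"}
    reference_endowment: float = 1000.0
    slope: float = 1.0
    floor: float = 1.1
    cap: float = 3.0
    basis: str = "current_endowment"  # {"current_endowment", "initial_endowment"}

    def validate(self, errors: list[str], prefix: str = "multiplier.") -> None:
        if self.regime not in ("control", "productivity"):
            errors.append(f"{prefix}regime must be 'control' or 'productivity', got {self.regime!r}")
        if self.basis not in ("current_endowment", "initial_endowment"):
            errors.append(f"{prefix}basis must be 'current_endowment' or 'initial_endowment', got {self.basis!r}")
        if not self.floor > 1:
            errors.append(f"{prefix}floor must exceed 1 (preserves T > R > P > S), got {self.floor}")
        if self.cap < self.floor:
            errors.append(f"{prefix}cap must be >= floor, got cap={self.cap} floor={self.floor}")
        if self.reference_endowment <= 0:
            errors.append(f"{prefix}reference_endowment must be positive, got {self.reference_endowment}")

    def multiplier(self, giver_endowment: float) -> float:
        """Multiplier m(E) for a giver with endowment ``giver_endowment``."""
        if self.regime == "control":
            return 2.0
        raw = 1.0 + self.slope * giver_endowment / self.reference_endowment
        return min(max(raw, self.floor), self.cap)


@dataclass(frozen=True)
class BehaviorParams:
    """Parameters of the synthetic-agent behavior models.

    ``model`` selects the family: ``random_increment`` draws cooperation
    uniformly from the six allowed levels and rewires at random (all weight
    fields are ignored); ``conditional`` reacts to neighbors' past cooperation
    and — under wealth productivity — their endowments.

    Weight units: ``reciprocity_weight`` is MU of own giving per MU of mean
    neighbor giving; ``wealth_weight`` is MU per standard deviation of mean
    neighbor endowment; logit weights are per MU (cooperation, giving signal)
    or per standardized endowment (wealth).
    """

    model: str = "conditional"  # {"random_increment", "conditional"}

    # cooperation decision (conditional model)
    base_level: float = 20.0
    reciprocity_weight: float = 0.6
    wealth_weight: float = 5.0
    noise_sd: float = 8.0

    # tie severance: P(drop) = sigmoid(intercept + slope * deficit + round_w * round)
    # where deficit = 50 - mean neighbor cooperation last round
    drop_intercept: float = -3.0
    drop_slope: float = 0.06
    drop_round_weight: float = 0.0
    # conditional on dropping: multinomial logit over neighbors
    drop_coop_weight: float = -0.1
    drop_wealth_weight: float = 0.5

    # proposal: multinomial logit over candidates
    choice_coop_weight: float = 0.05
    choice_wealth_weight: float = 0.3
    # reported partner-selection wealth effect roughly doubles under productivity
    choice_wealth_productivity_multiplier: float = 2.0
    propose_probability: float = 1.0

    # acceptance: logistic in proposer's giving signal and standardized wealth
    accept_all: bool = False
    accept_intercept: float = -1.0
    accept_coop_weight: float = 0.05
    accept_wealth_weight: float = 0.3

    # used only by the random_increment model
    drop_probability: float = 0.5

    def validate(self, errors: list[str], prefix: str = "behavior.") -> None:
        if self.model not in ("random_increment", "conditional"):
            errors.append(f"{prefix}model must be 'random_increment' or 'conditional', got {self.model!r}")
        for name in ("propose_probability", "drop_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{prefix}{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            errors.append(f"{prefix}noise_sd must be non-negative, got {self.noise_sd}")
        import math

        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                errors.append(f"{prefix}{f.name} must be finite, got {v}")


#: Named behavior profiles. "null" is the minimally structured reference
#: behavior used for the inequality envelope: uniform-random cooperation,
#: random drop/propose, accept-all. "empirical-like" is a conditional model
#: whose weights are signed to match the qualitative regularities observed in
#: comparable human experiments (reciprocity, wealth-biased partner choice
#: that doubles under productivity, defector-biased severance).
PROFILES: dict[str, BehaviorParams] = {
    "null": BehaviorParams(
        model="random_increment",
        accept_all=True,
        drop_probability=0.5,
        propose_probability=0.5,
    ),
    "empirical-like": BehaviorParams(model="conditional"),
}


def behavior_profile(name: str) -> BehaviorParams:
    """Look up a named behavior profile; raises ConfigError for unknown names."""
    try:
        return PROFILES[name]
    except KeyError:
        raise ConfigError([f"unknown behavior profile {name!r}; known: {sorted(PROFILES)}"]) from None


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one simulated session.

    Defaults mirror the reference experimental design: 27 agents on an
    Erdős–Rényi graph of density 0.167 (about four ties each), 19 rounds, a
    tie-update phase every three rounds (six phases in total), mean endowment
    1000 MU, and — when ``baseline_inequality`` is set — an initial endowment
    Gini of 0.3.
    """

    n_agents: int = 27
    density: float = 0.167
    n_rounds: int = 19
    update_interval: int = 3
    baseline_inequality: bool = False
    wealth_productivity: bool = False
    endowment_mean: float = 1000.0
    endowment_gini: float | None = None  # None -> 0.3 if baseline_inequality else 0.0
    multiplier: MultiplierSpec = field(default_factory=MultiplierSpec)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    seed: int = 0

    def __post_init__(self) -> None:
        # the two flags must stay consistent with their dependent fields
        if self.multiplier.regime == "control" and self.wealth_productivity:
            object.__setattr__(
                self, "multiplier", dataclasses.replace(self.multiplier, regime="productivity")
            )
        elif self.multiplier.regime == "productivity" and not self.wealth_productivity:
            object.__setattr__(self, "wealth_productivity", True)
        errors: list[str] = []
        self.validate(errors)
        if errors:
            raise ConfigError(errors)

    @property
    def initial_gini(self) -> float:
        if self.endowment_gini is not None:
            return self.endowment_gini
        return 0.3 if self.baseline_inequality else 0.0

    @property
    def n_update_phases(self) -> int:
        return self.n_rounds // self.update_interval

    def validate(self, errors: list[str]) -> None:
        if self.n_agents < 2:
            errors.append(f"n_agents must be >= 2, got {self.n_agents}")
        if not 0 < self.density <= 1:
            errors.append(f"density must be in (0, 1], got {self.density}")
        if self.n_rounds < 0:
            errors.append(f"n_rounds must be non-negative, got {self.n_rounds}")
        if self.update_interval < 1:
            errors.append(f"update_interval must be >= 1, got {self.update_interval}")
        if self.endowment_mean <= 0:
            errors.append(f"endowment_mean must be positive, got {self.endowment_mean}")
        if self.endowment_gini is not None and not 0 <= self.endowment_gini < 1:
            errors.append(f"endowment_gini must be in [0, 1), got {self.endowment_gini}")
        if not isinstance(self.seed, int):
            errors.append(f"seed must be an integer, got {self.seed!r}")
        self.multiplier.validate(errors)
        self.behavior.validate(errors)


def _build_nested(cls, data: Any, prefix: str, errors: list[str]):
    """Instantiate a nested dataclass from a mapping, rejecting unknown keys."""
    if isinstance(data, cls):
        return data
    if not isinstance(data, dict):
        errors.append(f"{prefix} must be a mapping, got {type(data).__name__}")
        return cls()
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        errors.append(f"unknown key {prefix}{key!r}")
    kwargs = {k: v for k, v in data.items() if k in known}
    return cls(**kwargs)


def config_from_dict(data: dict[str, Any]) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a plain mapping.

    Unknown keys are rejected by name; all problems are reported together in a
    single :class:`ConfigError`.  A ``behavior`` value may be a profile name
    string instead of a mapping.
    """
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError([f"configuration root must be a mapping, got {type(data).__name__}"])
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key in sorted(set(data) - known):
        errors.append(f"unknown key {key!r}")
    kwargs = {k: v for k, v in data.items() if k in known}
    if "multiplier" in kwargs:
        kwargs["multiplier"] = _build_nested(MultiplierSpec, kwargs["multiplier"], "multiplier.", errors)
    if "behavior" in kwargs:
        if isinstance(kwargs["behavior"], str):
            try:
                kwargs["behavior"] = behavior_profile(kwargs["behavior"])
            except ConfigError as exc:
                errors.extend(exc.errors)
                kwargs.pop("behavior")
        else:
            kwargs["behavior"] = _build_nested(BehaviorParams, kwargs["behavior"], "behavior.", errors)
    try:
        config = SimulationConfig(**kwargs)
    except ConfigError as exc:
        raise ConfigError(errors + exc.errors) from None
    except TypeError as exc:
        raise ConfigError(errors + [str(exc)]) from None
    if errors:
        raise ConfigError(errors)
    return config


def config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    """Plain-mapping form of a config; round-trips through config_from_dict."""
    d = dataclasses.asdict(config)
    return d
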