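"""Synthetic agents: parameterized stand-ins for human participants.

Each agent makes four kinds of decisions — how much to give each round, which
tie (if any) to sever, whom (if anyone) to propose a new tie to, and whether
to accept an incoming proposal.  Agents only ever see what participants in the
reference design saw: each neighbor's last cooperation level and the amount
received from them, neighbors' endowments, and (during tie selection) each
candidate's endowment and what that candidate's partners received from them in
the previous round.

Two model families are provided.  ``random_increment`` is a minimally
structured null: cooperation uniform over the six allowed levels, random
severance and proposal, acceptance always granted.  ``conditional`` encodes
the qualitative regularities reported for this class of experiment —
conditional cooperation (reciprocity), extra giving toward wealthy neighbors
under wealth productivity, severance aimed at defectors, and partner choice
biased toward generous and wealthy candidates, with the wealth bias doubled
under productivity.

Every policy is a pure function of its inputs and the supplied random
generator stream, so a session replayed with the same seed reproduces every
decision exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import COOPERATION_LEVELS, BehaviorParams

_LEVELS = np.asarray(COOPERATION_LEVELS, dtype=float)


@dataclass(frozen=True)
class NeighborView:
    """What an agent knows about one current neighbor."""

    neighbor_id: int
    last_cooperation: int | None  # MU the neighbor gave last round, if observed
    last_received: int | None  # MU this agent received from the neighbor last round
    endowment: float
    endowment_z: float  # standardized against the network's current distribution


@dataclass(frozen=True)
class Observation:
    """An agent's information set at decision time."""

    agent_id: int
    round: int
    own_endowment: float
    neighbors: tuple[NeighborView, ...]
    wealth_productivity: bool
    baseline_inequality: bool


@dataclass(frozen=True)
class CandidateInfo:
    """What an agent sees about a potential new partner (or a proposer).

    ``giving_signal`` is the mean post-multiplier amount the candidate's
    partners received from them in the previous round — the benefit they
    actually delivered, not their raw cooperation level — or ``None`` if the
    candidate had no partners last round.
    """

    candidate_id: int
    endowment: float
    endowment_z: float
    giving_signal: float | None


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _logit_choice(utilities: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an index from a multinomial logit with the given utilities."""
    u = np.asarray(utilities, dtype=float)
    u = u - u.max()
    p = np.exp(u)
    p /= p.sum()
    return int(rng.choice(len(p), p=p))


def _fill_signal(candidates: list[CandidateInfo]) -> np.ndarray:
    """Giving signals with missing values replaced by the group mean.

    Candidates who had no partners last round carry no giving signal; they are
    imputed at the mean of the observed signals (0 if none observed) so that
    isolation is not mechanically penalized.
    """
    raw = [c.giving_signal for c in candidates]
    observed = [s for s in raw if s is not None]
    fill = float(np.mean(observed)) if observed else 0.0
    return np.asarray([fill if s is None else s for s in raw], dtype=float)


# ---------------------------------------------------------------------------
# policies


def random_increment_policy(obs: Observation, rng: np.random.Generator) -> int:
    """Uniform draw from the six allowed cooperation levels {0, 10, ..., 50}."""
    return int(rng.choice(len(COOPERATION_LEVELS)) * 10)


def conditional_policy(obs: Observation, params: BehaviorParams, rng: np.random.Generator) -> int:
    """Reciprocity- and wealth-conditioned cooperation.

    latent = base + rho * mean(neighbor last cooperation)
                  + omega * 1[productivity] * mean neighbor endowment (standardized)
                  + Gaussian noise,
    clamped to [0, 50] and rounded to the nearest 10-MU increment.  With no
    history yet (round 1) the agent plays its base level.
    """
    coop_hist = [nv.last_cooperation for nv in obs.neighbors if nv.last_cooperation is not None]
    latent = params.base_level
    if coop_hist:
        latent += params.reciprocity_weight * float(np.mean(coop_hist))
        if params.wealth_weight and obs.wealth_productivity:
            mean_z = float(np.mean([nv.endowment_z for nv in obs.neighbors]))
            latent += params.wealth_weight * mean_z
        if params.noise_sd > 0:
            latent += params.noise_sd * rng.standard_normal()
    return _to_increment(latent)


def _to_increment(latent: float) -> int:
    clamped = min(max(latent, 0.0), 50.0)
    return int(round(clamped / 10.0)) * 10


def severance_policy(
    obs: Observation, params: BehaviorParams, rng: np.random.Generator
) -> int | None:
    """Decide whether to sever a tie and, if so, which neighbor loses it.

    Drop/no-drop is logistic in the mean cooperation deficit of the
    neighborhood (50 minus mean last giving; neighbors with no history count
    at the neutral 25) and in the round index.  Conditional on dropping, the
    target is drawn from a multinomial logit with utility
    gamma_c * cooperation + gamma_w * standardized endowment; a negative
    gamma_c aims severance at defectors.
    """
    if not obs.neighbors:
        return None
    coop = np.asarray(
        [25.0 if nv.last_cooperation is None else float(nv.last_cooperation) for nv in obs.neighbors]
    )
    deficit = 50.0 - float(coop.mean())
    p_drop = _sigmoid(
        params.drop_intercept + params.drop_slope * deficit + params.drop_round_weight * obs.round
    )
    if rng.random() >= p_drop:
        return None
    z = np.asarray([nv.endowment_z for nv in obs.neighbors])
    util = params.drop_coop_weight * coop + params.drop_wealth_weight * z
    return obs.neighbors[_logit_choice(util, rng)].neighbor_id


def proposal_policy(
    candidates: list[CandidateInfo],
    params: BehaviorParams,
    rng: np.random.Generator,
    wealth_productivity: bool = False,
) -> int | None:
    """Choose a candidate to propose a new tie to, or None.

    Multinomial logit over candidates with utility
    beta_c * giving_signal + beta_w * standardized endowment; under wealth
    productivity beta_w is scaled by ``choice_wealth_productivity_multiplier``
    (default 2, mirroring the reported doubling of the wealth effect in
    partner selection).  Proposing is optional: with probability
    ``1 - propose_probability`` the agent abstains.
    """
    if not candidates:
        return None
    if params.propose_probability < 1.0 and rng.random() >= params.propose_probability:
        return None
    beta_w = params.choice_wealth_weight
    if wealth_productivity:
        beta_w *= params.choice_wealth_productivity_multiplier
    signals = _fill_signal(candidates)
    z = np.asarray([c.endowment_z for c in candidates])
    util = params.choice_coop_weight * signals + beta_w * z
    return candidates[_logit_choice(util, rng)].candidate_id


def acceptance_policy(
    proposer: CandidateInfo, params: BehaviorParams, rng: np.random.Generator
) -> bool:
    """Accept or reject an incoming tie proposal.

    Logistic in the proposer's giving signal and standardized endowment; the
    ``accept_all`` configuration short-circuits to True (used by the null
    profile and envelope simulations).
    """
    if params.accept_all:
        return True
    signal = _fill_signal([proposer])[0]
    p = _sigmoid(
        params.accept_intercept
        + params.accept_coop_weight * signal
        + params.accept_wealth_weight * proposer.endowment_z
    )
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# behavior model contract


class BehaviorModel:
    """Bundle of the four decision policies, parameterized by BehaviorParams.

    The environment calls these with the acting agent's information set; the
    model never touches simulator state directly.
    """

    def __init__(self, params: BehaviorParams):
        self.params = params

    def decide_cooperation(self, obs: Observation, rng: np.random.Generator) -> int:
        raise NotImplementedError

    def decide_drop(self, obs: Observation, rng: np.random.Generator) -> int | None:
        raise NotImplementedError

    def decide_propose(
        self, candidates: list[CandidateInfo], rng: np.random.Generator, *, wealth_productivity: bool = False
    ) -> int | None:
        raise NotImplementedError

    def decide_accept(self, proposer: CandidateInfo, rng: np.random.Generator) -> bool:
        return acceptance_policy(proposer, self.params, rng)


class RandomIncrementModel(BehaviorModel):
    """Null behavior: uniform cooperation, random rewiring, accept-all."""

    def decide_cooperation(self, obs: Observation, rng: np.random.Generator) -> int:
        return random_increment_policy(obs, rng)

    def decide_drop(self, obs: Observation, rng: np.random.Generator) -> int | None:
        if not obs.neighbors or rng.random() >= self.params.drop_probability:
            return None
        return obs.neighbors[int(rng.choice(len(obs.neighbors)))].neighbor_id

    def decide_propose(
        self, candidates: list[CandidateInfo], rng: np.random.Generator, *, wealth_productivity: bool = False
    ) -> int | None:
        if not candidates or rng.random() >= self.params.propose_probability:
            return None
        return candidates[int(rng.choice(len(candidates)))].candidate_id


class ConditionalModel(BehaviorModel):
    """Reactive behavior with reciprocity, wealth bias and partner choice."""

    def decide_cooperation(self, obs: Observation, rng: np.random.Generator) -> int:
        return conditional_policy(obs, self.params, rng)

    def decide_drop(self, obs: Observation, rng: np.random.Generator) -> int | None:
        return severance_policy(obs, self.params, rng)

    def decide_propose(
        self, candidates: list[CandidateInfo], rng: np.random.Generator, *, wealth_productivity: bool = False
    ) -> int | None:
        return proposal_policy(candidates, self.params, rng, wealth_productivity)


def make_behavior(params: BehaviorParams) -> BehaviorModel:
    """Instantiate the model family selected by ``params.model``."""
    if params.model == "random_increment":
        return RandomIncrementModel(params)
    if params.model == "conditional":
        return ConditionalModel(params)
    raise ValueError(f"unknown behavior model {params.model!r}")
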