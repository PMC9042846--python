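"""The experimental environment: networked iterated giving game with rewiring.

Agents sit on an undirected network.  Each round every connected agent picks a
single cooperation level c in {0, 10, 20, 30, 40, 50} MU and gives c to *each*
neighbor; each neighbor receives c times a multiplier (a flat doubling in the
control payoff regime, an increasing function of the giver's wealth under
wealth productivity).  Because the multiplier exceeds 1, every dyad is a
prisoner's dilemma: per round and per tie, the temptation, reward, punishment
and sucker payoffs are ordered T > R > P > S.

Every ``update_interval`` rounds a tie-update phase runs: each connected
agent, in randomized order, may unilaterally sever one tie and propose one new
tie; proposals are collected and then resolved by the targets, who may accept
or reject.  Agents whose degree is zero at the end of a phase are recorded as
isolated at that phase (they keep their wealth, make no giving decisions while
isolated, and may rejoin if someone proposes to them).

All randomness flows through a single seeded ``numpy.random.Generator``;
replaying a session with the same configuration and seed reproduces every
transfer and tie event exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .agents import BehaviorModel, CandidateInfo, NeighborView, Observation, make_behavior
from .config import COOPERATION_LEVELS, MultiplierSpec, SimulationConfig


class ProtocolError(RuntimeError):
    """A decision set violates the game protocol (missing or invalid moves)."""


class InfeasibleGiniError(ValueError):
    """The requested endowment Gini cannot be realized under the constraints."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class AgentState:
    agent_id: int
    endowment: float
    initial_endowment: float
    last_cooperation: int | None = None
    isolated_at: int | None = None  # first update phase (1-based) at which degree hit 0


@dataclass(frozen=True)
class TransferRecord:
    """One directed give: amount_received = amount_sent x multiplier, rounded
    half-up to integer MU."""

    round: int
    giver: int
    receiver: int
    amount_sent: int
    multiplier_applied: float
    amount_received: int


@dataclass(frozen=True)
class TieUpdateEvent:
    """One actor's decisions in one update phase.

    ``accepted`` is present exactly when ``proposed_to`` is.
    """

    update_phase: int
    actor: int
    dropped: int | None
    proposed_to: int | None
    accepted: bool | None


@dataclass
class NetworkState:
    """Full mutable state of one session."""

    round: int
    graph: nx.Graph
    agents: dict[int, AgentState]
    transfer_log: list[TransferRecord] = field(default_factory=list)
    tie_event_log: list[TieUpdateEvent] = field(default_factory=list)
    initial_edges: tuple[tuple[int, int], ...] = ()

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    def degree(self, agent_id: int) -> int:
        return int(self.graph.degree(agent_id))

    def active_agents(self) -> list[int]:
        """Agents currently holding at least one tie, in id order."""
        return [i for i in sorted(self.agents) if self.graph.degree(i) > 0]

    def transfers_in_round(self, round_index: int) -> list[TransferRecord]:
        """Transfer records of one round (log is ordered by round)."""
        out = []
        for rec in reversed(self.transfer_log):
            if rec.round < round_index:
                break
            if rec.round == round_index:
                out.append(rec)
        out.reverse()
        return out


# ---------------------------------------------------------------------------
# endowments


def _rounded_ladder(n: int, mean: float, step: float, round_to: float) -> np.ndarray:
    offsets = (np.arange(n) - (n - 1) / 2.0) * step
    if round_to > 0:
        offsets = np.sign(offsets) * np.floor(np.abs(offsets) / round_to + 0.5) * round_to
    return mean + offsets


def gini_of(values) -> float:
    """Gini via the sorted-vector identity (duplicated here to keep the
    generator self-contained; the metrics module exposes the public one)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    mu = x.mean()
    if mu <= 0:
        raise ValueError("Gini undefined for non-positive mean")
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * n * mu))


def generate_endowments(
    n: int,
    mean: float,
    target_gini: float,
    rng: np.random.Generator | None = None,
    round_to: float = 10.0,
) -> np.ndarray:
    """Deterministic endowment vector with the requested mean and Gini.

    Construction: an arithmetic ladder symmetric about the mean, whose step is
    chosen (closed form, refined by bisection once values are rounded to the
    nearest ``round_to`` MU) so the Gini coefficient of the rounded vector is
    within 5e-3 of the target.  Symmetric rounding of the offsets keeps the
    arithmetic mean exact.  ``rng`` is accepted for interface uniformity but
    unused: assignment of endowments to agents is permuted elsewhere.

    Raises :class:`InfeasibleGiniError` when no ladder satisfies the
    non-negativity and rounding constraints (e.g. large Gini at small n).
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if not 0 <= target_gini < 1:
        raise ValueError(f"target_gini must be in [0, 1), got {target_gini}")
    tol = 5e-3
    if target_gini == 0:
        return np.full(n, float(mean))
    # closed form for a continuous ladder: G = step * (n^2 - 1) / (6 n mean)
    step_exact = 6.0 * n * mean * target_gini / (n * n - 1.0)
    step_max = 2.0 * mean / (n - 1)  # keeps the smallest entry >= 0
    if step_exact > step_max * (1 + 1e-12):
        raise InfeasibleGiniError(
            f"Gini {target_gini} not reachable with non-negative ladder at n={n}, mean={mean}"
        )
    step_exact = min(step_exact, step_max)

    def g(step: float) -> float:
        return gini_of(_rounded_ladder(n, mean, step, round_to))

    best_step, best_err = step_exact, abs(g(step_exact) - target_gini)
    if best_err > tol:
        lo, hi = 0.0, step_max
        for _ in range(100):
            mid = (lo + hi) / 2.0
            gm = g(mid)
            if abs(gm - target_gini) < best_err:
                best_step, best_err = mid, abs(gm - target_gini)
            if gm < target_gini:
                lo = mid
            else:
                hi = mid
    if best_err > tol:
        raise InfeasibleGiniError(
            f"Gini {target_gini} infeasible within {tol} after rounding to {round_to} MU "
            f"at n={n}, mean={mean} (best achievable error {best_err:.4g})"
        )
    return _rounded_ladder(n, mean, best_step, round_to)


# ---------------------------------------------------------------------------
# initialization


def generate_initial_network(config: SimulationConfig, rng: np.random.Generator) -> NetworkState:
    """Erdős–Rényi G(n, p) network with endowments randomly assigned to agents.

    Each of the C(n, 2) possible ties is present independently with
    probability ``config.density``.  Graphs are used as drawn: no
    connectivity repair, so degree-zero agents can occur from round 0.
    """
    n = config.n_agents
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    r, c = np.triu_indices(n, k=1)
    mask = rng.random(len(r)) < config.density
    graph.add_edges_from(zip(r[mask].tolist(), c[mask].tolist()))
    endowments = generate_endowments(n, config.endowment_mean, config.initial_gini)
    endowments = endowments[rng.permutation(n)]
    agents = {
        i: AgentState(agent_id=i, endowment=float(e), initial_endowment=float(e))
        for i, e in enumerate(endowments)
    }
    return NetworkState(
        round=0,
        graph=graph,
        agents=agents,
        initial_edges=tuple(sorted(tuple(sorted(e)) for e in graph.edges)),
    )


# ---------------------------------------------------------------------------
# payoffs


def benefit_received(amount_sent: int, giver_endowment: float, spec: MultiplierSpec) -> int:
    """MU the receiver gets when ``amount_sent`` is given by an agent with
    endowment ``giver_endowment``, rounded half-up to integer MU.

    Control: exactly 2 x amount_sent.  Productivity: amount_sent x m(E) with
    m non-decreasing in E (see :class:`MultiplierSpec`).
    """
    if amount_sent not in COOPERATION_LEVELS:
        raise ProtocolError(
            f"cooperation must be one of {COOPERATION_LEVELS}, got {amount_sent}"
        )
    if not math.isfinite(giver_endowment):
        raise ValueError(f"giver endowment must be finite, got {giver_endowment}")
    return _round_half_up(amount_sent * spec.multiplier(giver_endowment))


def play_round(
    state: NetworkState, decisions: dict[int, int], spec: MultiplierSpec
) -> NetworkState:
    """Apply one round of simultaneous giving.

    Every agent with at least one tie must appear in ``decisions`` with a
    valid 10-MU increment; each pays its chosen amount per neighbor and
    receives each neighbor's amount times that neighbor's multiplier.  The
    multiplier is evaluated on round-start wealth (or initial endowment, per
    the spec basis), so moves are order-independent.  Two transfer records —
    one per direction, zero amounts included — are logged per tie.
    """
    active = state.active_agents()
    missing = [i for i in active if i not in decisions]
    if missing:
        raise ProtocolError(f"missing cooperation decision for active agents {missing}")
    bad = {i: c for i, c in decisions.items() if c not in COOPERATION_LEVELS}
    if bad:
        raise ProtocolError(f"invalid cooperation increments {bad}; allowed {COOPERATION_LEVELS}")

    r = state.round + 1
    if spec.basis == "initial_endowment":
        basis = {i: a.initial_endowment for i, a in state.agents.items()}
    else:
        basis = {i: a.endowment for i, a in state.agents.items()}
    deltas = dict.fromkeys(state.agents, 0)
    for a, b in sorted(tuple(sorted(e)) for e in state.graph.edges):
        for giver, receiver in ((a, b), (b, a)):
            c = decisions[giver]
            m = spec.multiplier(basis[giver])
            got = _round_half_up(c * m)
            state.transfer_log.append(
                TransferRecord(
                    round=r,
                    giver=giver,
                    receiver=receiver,
                    amount_sent=c,
                    multiplier_applied=m,
                    amount_received=got,
                )
            )
            deltas[giver] -= c
            deltas[receiver] += got
    for i, d in deltas.items():
        state.agents[i].endowment += d
    for i in active:
        state.agents[i].last_cooperation = decisions[i]
    state.round = r
    return state


# ---------------------------------------------------------------------------
# observations


def _endowment_stats(state: NetworkState) -> tuple[float, float]:
    e = np.asarray([a.endowment for a in state.agents.values()], dtype=float)
    sd = float(e.std())
    return float(e.mean()), (sd if sd > 0 else 1.0)  # SD=1 guards constant wealth


def _giving_signals(state: NetworkState) -> dict[int, float]:
    """Mean post-multiplier amount each agent's partners received from them in
    the previous round; agents with no transfers last round are absent."""
    totals: dict[int, list[int]] = {}
    for rec in state.transfers_in_round(state.round):
        totals.setdefault(rec.giver, []).append(rec.amount_received)
    return {i: float(np.mean(v)) for i, v in totals.items()}


def build_observation(state: NetworkState, agent_id: int, config: SimulationConfig) -> Observation:
    """Assemble the information set visible to one agent right now."""
    mean, sd = _endowment_stats(state)
    received_from = {
        rec.giver: rec.amount_received
        for rec in state.transfers_in_round(state.round)
        if rec.receiver == agent_id
    }
    neighbors = tuple(
        NeighborView(
            neighbor_id=j,
            last_cooperation=state.agents[j].last_cooperation,
            last_received=received_from.get(j),
            endowment=state.agents[j].endowment,
            endowment_z=(state.agents[j].endowment - mean) / sd,
        )
        for j in sorted(state.graph.neighbors(agent_id))
    )
    return Observation(
        agent_id=agent_id,
        round=state.round,
        own_endowment=state.agents[agent_id].endowment,
        neighbors=neighbors,
        wealth_productivity=config.wealth_productivity,
        baseline_inequality=config.baseline_inequality,
    )


def _candidate_info(state: NetworkState, candidate_id: int, mean: float, sd: float,
                    signals: dict[int, float]) -> CandidateInfo:
    e = state.agents[candidate_id].endowment
    return CandidateInfo(
        candidate_id=candidate_id,
        endowment=e,
        endowment_z=(e - mean) / sd,
        giving_signal=signals.get(candidate_id),
    )


# ---------------------------------------------------------------------------
# tie updates


def run_tie_update(
    state: NetworkState,
    update_phase: int,
    behavior: BehaviorModel,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> NetworkState:
    """One rewiring phase: severances, then collected proposals, then isolation.

    Connected agents act in a randomized order.  Severances apply immediately
    and unilaterally (an edge dropped by both endpoints is removed once).
    Proposals are resolved only after every actor has moved: each target
    independently accepts or rejects, so an agent may gain several ties, or be
    dropped by several neighbors, in one phase.  Isolated agents do not act
    but stay in the candidate pool and can rejoin through incoming proposals.
    Afterwards any agent at degree zero whose isolation has not been recorded
    gets ``isolated_at = update_phase``.
    """
    mean, sd = _endowment_stats(state)
    signals = _giving_signals(state)
    actors = state.active_agents()
    order = [actors[k] for k in rng.permutation(len(actors))] if actors else []
    proposals: list[tuple[int, int]] = []
    decisions: dict[int, tuple[int | None, int | None]] = {}
    for actor in order:
        obs = build_observation(state, actor, config)
        dropped = None
        if obs.neighbors:
            dropped = behavior.decide_drop(obs, rng)
            if dropped is not None and state.graph.has_edge(actor, dropped):
                state.graph.remove_edge(actor, dropped)
        candidates = [
            _candidate_info(state, j, mean, sd, signals)
            for j in sorted(state.agents)
            if j != actor and not state.graph.has_edge(actor, j)
        ]
        target = behavior.decide_propose(
            candidates, rng, wealth_productivity=config.wealth_productivity
        )
        if target is not None:
            proposals.append((actor, target))
        decisions[actor] = (dropped, target)

    accepted_map: dict[int, bool] = {}
    for actor, target in proposals:
        ok = behavior.decide_accept(_candidate_info(state, actor, mean, sd, signals), rng)
        accepted_map[actor] = ok
        if ok and actor != target and not state.graph.has_edge(actor, target):
            state.graph.add_edge(actor, target)

    for actor in order:
        dropped, target = decisions[actor]
        state.tie_event_log.append(
            TieUpdateEvent(
                update_phase=update_phase,
                actor=actor,
                dropped=dropped,
                proposed_to=target,
                accepted=accepted_map.get(actor) if target is not None else None,
            )
        )

    for i, agent in state.agents.items():
        if state.graph.degree(i) == 0 and agent.isolated_at is None:
            agent.isolated_at = update_phase
    return state


# ---------------------------------------------------------------------------
# session driver


def run_session(config: SimulationConfig, behavior: BehaviorModel | None = None):
    """Run a full session; returns ``(final_state, metric_series)``.

    Rounds proceed payoffs-first; after every ``update_interval``-th round a
    tie-update phase fires (19 rounds at interval 3 gives phases after rounds
    3, 6, 9, 12, 15 and 18 — six in total).  Fully deterministic given the
    config seed.
    """
    from .metrics import summarize_session  # local import avoids a cycle

    rng = np.random.default_rng(config.seed)
    if behavior is None:
        behavior = make_behavior(config.behavior)
    state = generate_initial_network(config, rng)
    phase = 0
    for r in range(1, config.n_rounds + 1):
        decisions = {
            i: behavior.decide_cooperation(build_observation(state, i, config), rng)
            for i in state.active_agents()
        }
        play_round(state, decisions, config.multiplier)
        if r % config.update_interval == 0:
            phase += 1
            run_tie_update(state, phase, behavior, rng, config)
    return state, summarize_session(state, config)
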