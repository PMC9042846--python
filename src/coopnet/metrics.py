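"""Descriptive statistics for simulated sessions.

Covers the quantities the study design is summarized by: per-round mean
cooperation, Gini coefficients of endowments (raw and productivity-adjusted)
and of degrees, tie-churn and isolate counts, and a discrete-time
product-limit (Kaplan–Meier) curve for survival against network isolation
over the six update phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .game_env import NetworkState, TransferRecord, _round_half_up

logger = logging.getLogger(__name__)


class UndefinedGiniError(ValueError):
    """Gini is undefined (all-zero or negative-mean input)."""


class LedgerIntegrityError(RuntimeError):
    """A transfer log violates its own arithmetic contract."""


def gini(values, clamp_negative: bool = False) -> float:
    """Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 mean).

    Computed via the O(n log n) sorted identity
    ``G = sum_i (2i - n - 1) x_(i) / (n^2 mean)`` which agrees with the
    pairwise double sum to machine precision.  Negative entries are rejected
    unless ``clamp_negative`` is set, in which case they are treated as zero
    wealth (the ledger itself keeps true values); an all-zero vector raises
    :class:`UndefinedGiniError`.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise UndefinedGiniError("Gini undefined for empty input")
    if (x < 0).any():
        if not clamp_negative:
            raise UndefinedGiniError("negative values; pass clamp_negative=True to floor at 0")
        x = np.maximum(x, 0.0)
    x = np.sort(x)
    mu = x.mean()
    if mu == 0:
        raise UndefinedGiniError("Gini undefined for all-zero input")
    n = x.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * n * mu))


def _gini_clamped(values) -> tuple[float, int]:
    x = np.asarray(values, dtype=float)
    n_clamped = int((x < 0).sum())
    return gini(x, clamp_negative=True), n_clamped


def adjusted_endowments(initial, transfer_log: list[TransferRecord]) -> np.ndarray:
    """Counterfactual final endowments with productivity gains removed.

    Replays the ledger with every multiplier replaced by the control value 2
    (costs unchanged), yielding the wealth each agent would hold had every MU
    given simply been doubled.  On a control-regime ledger this is exactly the
    raw final wealth.  Agent ids must index ``initial``.

    Raises :class:`LedgerIntegrityError` if any record's received amount does
    not equal its sent amount times its multiplier (rounded half-up).
    """
    out = np.asarray(initial, dtype=float).copy()
    for rec in transfer_log:
        if rec.amount_received != _round_half_up(rec.amount_sent * rec.multiplier_applied):
            raise LedgerIntegrityError(
                f"record {rec} violates amount_received = round(amount_sent x multiplier)"
            )
        out[rec.giver] -= rec.amount_sent
        out[rec.receiver] += 2 * rec.amount_sent
    return out


def degree_gini(state: NetworkState, include_isolates: bool = True) -> float:
    """Gini of the degree distribution, optionally over connected agents only."""
    degrees = [state.graph.degree(i) for i in sorted(state.agents)]
    if not include_isolates:
        degrees = [d for d in degrees if d > 0]
    if not degrees or all(d == 0 for d in degrees):
        raise UndefinedGiniError("all degrees zero; degree Gini undefined")
    return gini(degrees)


@dataclass(frozen=True)
class SurvivalCurve:
    """Discrete-time product-limit estimate over update phases 1..K."""

    phases: np.ndarray  # 1..K
    n_at_risk: np.ndarray
    events: np.ndarray  # newly isolated at each phase
    survival: np.ndarray  # S(k) = prod_{j<=k} (1 - d_j / n_j)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phase": self.phases,
                "n_at_risk": self.n_at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def km_survival(isolation_phases, n_phases: int) -> SurvivalCurve:
    """Kaplan–Meier survival against first isolation.

    ``isolation_phases`` holds, per agent, the 1-based update phase at which
    they first reached degree zero, or ``None`` if they stayed connected
    through every phase (censored at the end of follow-up).
    """
    phases = [p for p in isolation_phases if p is not None]
    if any(not 1 <= p <= n_phases for p in phases):
        raise ValueError(f"isolation phases must lie in 1..{n_phases}")
    n = len(list(isolation_phases))
    at_risk = np.zeros(n_phases, dtype=int)
    events = np.zeros(n_phases, dtype=int)
    surv = np.ones(n_phases)
    alive = n
    s = 1.0
    for k in range(1, n_phases + 1):
        d = sum(1 for p in phases if p == k)
        at_risk[k - 1] = alive
        events[k - 1] = d
        if alive > 0:
            s *= 1.0 - d / alive
        surv[k - 1] = s
        alive -= d
    return SurvivalCurve(np.arange(1, n_phases + 1), at_risk, events, surv)


@dataclass
class MetricSeries:
    """Per-round summary of one session (one row per round, round 0 included).

    Columns: round, mean_cooperation, endowment_gini, endowment_gini_adjusted,
    degree_gini, active_count, isolate_count, cum_severances, cum_formed_ties.
    """

    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    def final(self) -> pd.Series:
        return self.data.iloc[-1]


def cooperation_endowment_association(state: NetworkState, config: SimulationConfig) -> float:
    """Partial association between giving and neighbors' wealth.

    Replays the session and regresses each agent's per-round cooperation on
    the standardized mean endowment of their neighbors at decision time,
    controlling for the mean of the neighbors' previous-round giving (the
    reciprocity input).  Controlling matters: reciprocity alone clusters
    cooperative agents into wealthy neighborhoods, so the *raw* correlation is
    positive even when behavior ignores wealth.  Returns the endowment
    coefficient in MU per standard deviation; NaN if the design is degenerate
    (fewer than 10 usable decisions or no endowment variation).
    """
    ids = sorted(state.agents)
    endow = {i: state.agents[i].initial_endowment for i in ids}
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    graph.add_edges_from(state.initial_edges)
    events_by_phase: dict[int, list] = {}
    for ev in state.tie_event_log:
        events_by_phase.setdefault(ev.update_phase, []).append(ev)
    transfers_by_round: dict[int, list[TransferRecord]] = {}
    for rec in state.transfer_log:
        transfers_by_round.setdefault(rec.round, []).append(rec)

    last_coop: dict[int, int] = {}
    rows: list[tuple[float, float, float]] = []  # (coop, mean_nbr_lastcoop, mean_nbr_z)
    phase = 0
    for r in range(1, state.round + 1):
        recs = transfers_by_round.get(r, [])
        coop_by_giver = {rec.giver: rec.amount_sent for rec in recs}
        e = np.asarray([endow[i] for i in ids], dtype=float)
        mu, sd = float(e.mean()), float(e.std()) or 1.0
        for giver, c in coop_by_giver.items():
            nbrs = list(graph.neighbors(giver))
            hist = [last_coop[j] for j in nbrs if j in last_coop]
            if not hist:
                continue  # cold start: policy plays base level regardless
            mean_z = float(np.mean([(endow[j] - mu) / sd for j in nbrs]))
            rows.append((float(c), float(np.mean(hist)), mean_z))
        for rec in recs:
            endow[rec.giver] -= rec.amount_sent
            endow[rec.receiver] += rec.amount_received
        last_coop.update(coop_by_giver)
        if r % config.update_interval == 0:
            phase += 1
            for ev in events_by_phase.get(phase, []):
                if ev.dropped is not None and graph.has_edge(ev.actor, ev.dropped):
                    graph.remove_edge(ev.actor, ev.dropped)
            for ev in events_by_phase.get(phase, []):
                if ev.accepted and ev.actor != ev.proposed_to:
                    graph.add_edge(ev.actor, ev.proposed_to)
    if len(rows) < 10:
        return float("nan")
    y, recip, z = np.asarray(rows).T
    if z.std() == 0 or recip.std() == 0:
        return float("nan")
    X = np.column_stack([np.ones_like(y), recip, z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[2])


def isolation_events(state: NetworkState) -> list[int | None]:
    """Per-agent first-isolation phase (None = never isolated), in id order."""
    return [state.agents[i].isolated_at for i in sorted(state.agents)]


def summarize_session(state: NetworkState, config: SimulationConfig) -> MetricSeries:
    """Rebuild the per-round metric series from the session's event logs.

    The series is computed by *replay*: endowments are re-accumulated from the
    transfer log (and, in parallel, with every multiplier forced to the
    control doubling for the adjusted Gini), and the graph is re-evolved from
    the initial edge list through the logged tie events.  The replayed final
    wealth must match the live ledger exactly, which doubles as an integrity
    check.  Negative wealth is floored at zero inside Gini computations only.
    """
    import networkx as nx

    n = state.n_agents
    ids = sorted(state.agents)
    initial = np.asarray([state.agents[i].initial_endowment for i in ids], dtype=float)
    endow = initial.copy()
    adj = initial.copy()
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    graph.add_edges_from(state.initial_edges)

    transfers_by_round: dict[int, list[TransferRecord]] = {}
    for rec in state.transfer_log:
        transfers_by_round.setdefault(rec.round, []).append(rec)
    events_by_phase: dict[int, list] = {}
    for ev in state.tie_event_log:
        events_by_phase.setdefault(ev.update_phase, []).append(ev)

    rows = []
    n_clamped_total = 0
    cum_sever = 0
    cum_formed = 0

    def snapshot(round_index: int, mean_coop: float) -> None:
        nonlocal n_clamped_total
        g_raw, c1 = _gini_clamped(endow)
        g_adj, c2 = _gini_clamped(adj)
        n_clamped_total += c1 + c2
        degrees = [graph.degree(i) for i in ids]
        g_deg = gini(degrees) if any(degrees) else float("nan")
        rows.append(
            {
                "round": round_index,
                "mean_cooperation": mean_coop,
                "endowment_gini": g_raw,
                "endowment_gini_adjusted": g_adj,
                "degree_gini": g_deg,
                "active_count": sum(1 for d in degrees if d > 0),
                "isolate_count": sum(1 for d in degrees if d == 0),
                "cum_severances": cum_sever,
                "cum_formed_ties": cum_formed,
            }
        )

    snapshot(0, float("nan"))
    phase = 0
    for r in range(1, state.round + 1):
        recs = transfers_by_round.get(r, [])
        coop_by_giver: dict[int, int] = {}
        for rec in recs:
            if rec.amount_received != _round_half_up(rec.amount_sent * rec.multiplier_applied):
                raise LedgerIntegrityError(f"inconsistent record {rec}")
            endow[rec.giver] -= rec.amount_sent
            endow[rec.receiver] += rec.amount_received
            adj[rec.giver] -= rec.amount_sent
            adj[rec.receiver] += 2 * rec.amount_sent
            coop_by_giver[rec.giver] = rec.amount_sent
        mean_coop = float(np.mean(list(coop_by_giver.values()))) if coop_by_giver else float("nan")
        if r % config.update_interval == 0:
            phase += 1
            # within a phase all severances precede all tie formations
            for ev in events_by_phase.get(phase, []):
                if ev.dropped is not None:
                    cum_sever += 1
                    if graph.has_edge(ev.actor, ev.dropped):
                        graph.remove_edge(ev.actor, ev.dropped)
            for ev in events_by_phase.get(phase, []):
                if ev.accepted:
                    cum_formed += 1
                    if ev.actor != ev.proposed_to:
                        graph.add_edge(ev.actor, ev.proposed_to)
        snapshot(r, mean_coop)

    live = np.asarray([state.agents[i].endowment for i in ids], dtype=float)
    if not np.array_equal(endow, live):
        raise LedgerIntegrityError("replayed endowments disagree with the live ledger")
    if {tuple(sorted(e)) for e in graph.edges} != state.edges:
        raise LedgerIntegrityError("replayed edge set disagrees with the live graph")
    if n_clamped_total:
        logger.warning(
            "floored %d negative-wealth entries at 0 while computing Gini", n_clamped_total
        )
    return MetricSeries(pd.DataFrame(rows))
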