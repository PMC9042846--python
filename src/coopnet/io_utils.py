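"""Configuration files, event-log serialization and run manifests.

Config files are YAML (JSON is a YAML subset) mirroring the
:class:`~coopnet.config.SimulationConfig` field names exactly; unknown keys
are rejected by name.  Event logs are JSON-lines with a schema-versioned
``init`` header carrying everything needed to reconstruct and replay the
session — initial endowments, initial edges — followed by one record per
transfer and tie event, so a written run can be re-read and its metrics
recomputed without access to the original process.

CSV outputs are UTF-8, comma-separated, LF-terminated, no index column,
floats at 6 significant digits; the JSONL channel keeps full precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import yaml

from . import __version__
from .config import ConfigError, SimulationConfig, config_from_dict, config_to_dict
from .game_env import AgentState, NetworkState, TieUpdateEvent, TransferRecord
from .metrics import MetricSeries, SurvivalCurve

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.6g"


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a simulation config from a YAML/JSON file.

    An empty file yields the full-default configuration (27 agents, density
    0.167, 19 rounds, updates every 3 rounds).  All schema violations are
    reported together.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError([f"configuration root must be a mapping, got {type(data).__name__}"])
    return config_from_dict(data)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_digest(config: SimulationConfig) -> str:
    """SHA-256 of the canonicalized config; stable under key reordering of the
    source file because it hashes the parsed, sorted representation."""
    canonical = json.dumps(config_to_dict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written beside every run's data files."""

    config_digest: str
    seed: int
    version: str = __version__
    schema_version: int = SCHEMA_VERSION
    inventory: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# event log (JSONL)


def _event_records(state: NetworkState):
    yield {
        "type": "init",
        "schema_version": SCHEMA_VERSION,
        "n_agents": state.n_agents,
        "endowments": [state.agents[i].initial_endowment for i in sorted(state.agents)],
        "edges": [list(e) for e in state.initial_edges],
        "n_rounds": state.round,
    }
    for rec in state.transfer_log:
        yield {"type": "transfer", **dataclasses.asdict(rec)}
    for ev in state.tie_event_log:
        yield {"type": "tie_update", **dataclasses.asdict(ev)}


def write_events(state: NetworkState, path: str | Path) -> int:
    """Write the JSONL event log; returns the number of event lines (the init
    header excluded, so the count equals |transfer_log| + |tie_event_log|)."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in _event_records(state):
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
            if rec["type"] != "init":
                n += 1
    return n


def state_from_events(path: str | Path) -> NetworkState:
    """Reconstruct a NetworkState (final wealth, graph, logs, isolation marks)
    by replaying a written event log."""
    transfers: list[TransferRecord] = []
    tie_events: list[TieUpdateEvent] = []
    header = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            kind = rec.pop("type")
            if kind == "init":
                header = rec
            elif kind == "transfer":
                transfers.append(TransferRecord(**rec))
            elif kind == "tie_update":
                tie_events.append(TieUpdateEvent(**rec))
            else:
                raise ValueError(f"unknown event type {kind!r}")
    if header is None:
        raise ValueError("event log has no init header")
    endowments = header["endowments"]
    agents = {
        i: AgentState(agent_id=i, endowment=float(e), initial_endowment=float(e))
        for i, e in enumerate(endowments)
    }
    graph = nx.Graph()
    graph.add_nodes_from(agents)
    graph.add_edges_from(tuple(e) for e in header["edges"])
    state = NetworkState(
        round=header["n_rounds"],
        graph=graph,
        agents=agents,
        transfer_log=transfers,
        tie_event_log=tie_events,
        initial_edges=tuple(sorted(tuple(e) for e in header["edges"])),
    )
    # replay wealth
    for rec in transfers:
        agents[rec.giver].endowment -= rec.amount_sent
        agents[rec.receiver].endowment += rec.amount_received
    # replay graph and isolation marks phase by phase
    phases = sorted({ev.update_phase for ev in tie_events})
    for phase in phases:
        evs = [ev for ev in tie_events if ev.update_phase == phase]
        for ev in evs:
            if ev.dropped is not None and graph.has_edge(ev.actor, ev.dropped):
                graph.remove_edge(ev.actor, ev.dropped)
        for ev in evs:
            if ev.accepted and ev.actor != ev.proposed_to:
                graph.add_edge(ev.actor, ev.proposed_to)
        for i, agent in agents.items():
            if graph.degree(i) == 0 and agent.isolated_at is None:
                agent.isolated_at = phase
    return state


# ---------------------------------------------------------------------------
# output bundle


def edge_snapshot_rows(state: NetworkState, update_interval: int) -> list[tuple[int, int, int]]:
    """(phase, agent_a, agent_b) rows: phase 0 is the initial graph, phase k
    the graph after the k-th update phase."""
    graph = nx.Graph()
    graph.add_nodes_from(state.agents)
    graph.add_edges_from(state.initial_edges)
    rows = [(0, a, b) for a, b in sorted(tuple(sorted(e)) for e in graph.edges)]
    phases = sorted({ev.update_phase for ev in state.tie_event_log})
    for phase in phases:
        evs = [ev for ev in state.tie_event_log if ev.update_phase == phase]
        for ev in evs:
            if ev.dropped is not None and graph.has_edge(ev.actor, ev.dropped):
                graph.remove_edge(ev.actor, ev.dropped)
        for ev in evs:
            if ev.accepted and ev.actor != ev.proposed_to:
                graph.add_edge(ev.actor, ev.proposed_to)
        rows.extend((phase, a, b) for a, b in sorted(tuple(sorted(e)) for e in graph.edges))
    return rows


def write_outputs(
    state: NetworkState,
    series: MetricSeries,
    survival: SurvivalCurve,
    config: SimulationConfig,
    out_dir: str | Path,
) -> RunManifest:
    """Write the full output bundle atomically; returns the manifest.

    Files: ``metrics.csv`` (one row per round), ``survival.csv`` (one row per
    update phase), ``edges.csv`` (phase-stamped edge lists), ``events.jsonl``
    and ``manifest.json``.  Everything is staged in a temporary directory and
    moved into place, so an unwritable target fails before any partial write.
    Re-running with the same seed reproduces every data file byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir} is not writable")
    manifest = RunManifest(config_digest=config_digest(config), seed=config.seed)
    with tempfile.TemporaryDirectory(dir=out_dir) as tmp:
        tmp = Path(tmp)
        series.data.to_csv(tmp / "metrics.csv", index=False, float_format=_FLOAT_FMT)
        survival.to_frame().to_csv(tmp / "survival.csv", index=False, float_format=_FLOAT_FMT)
        with open(tmp / "edges.csv", "w", encoding="utf-8") as fh:
            fh.write("phase,agent_a,agent_b\n")
            for row in edge_snapshot_rows(state, config.update_interval):
                fh.write("%d,%d,%d\n" % row)
        write_events(state, tmp / "events.jsonl")
        manifest.inventory = ["metrics.csv", "survival.csv", "edges.csv", "events.jsonl"]
        with open(tmp / "manifest.json", "w", encoding="utf-8") as fh:
            fh.write(manifest.to_json() + "\n")
        for name in manifest.inventory + ["manifest.json"]:
            os.replace(tmp / name, out_dir / name)
    return manifest


def read_metrics(path: str | Path) -> MetricSeries:
    import pandas as pd

    return MetricSeries(pd.read_csv(path))


def summarize_written_run(events_path: str | Path, config: SimulationConfig) -> MetricSeries:
    """Recompute the metric series from a written event log by replay."""
    from .metrics import summarize_session

    return summarize_session(state_from_events(events_path), config)
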