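"""Replicated experiment grids and the null inequality envelope.

The study design crosses two manipulations — baseline endowment inequality
(initial Gini 0.3 vs. 0) and wealth productivity (wealth-dependent multiplier
vs. flat doubling) — into a 2 x 2 grid.  ``run_condition_grid`` runs seeded
replicate sessions for each cell; ``null_gini_envelope`` reproduces the
reference numerical simulation that brackets how much endowment inequality
the mechanics alone can generate: full sessions with minimally structured
agents (uniform-random 10-MU increments, random rewiring, accept-all),
pooling both initial endowment settings, summarized by the central 95%
interval of final-round Gini coefficients.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import SimulationConfig, behavior_profile
from .game_env import run_session
from .metrics import MetricSeries

#: (baseline_inequality, wealth_productivity) cells in canonical order
CONDITIONS: tuple[tuple[bool, bool], ...] = tuple(itertools.product((False, True), (False, True)))


def condition_label(baseline_inequality: bool, wealth_productivity: bool) -> str:
    a = "inequality" if baseline_inequality else "equality"
    b = "productivity" if wealth_productivity else "control"
    return f"{a}-{b}"


@dataclass(frozen=True)
class ExperimentGrid:
    """A replicated 2 x 2 experiment.

    Replicate seeds derive deterministically from ``base_seed``: condition
    index times replicates plus replicate index (or just the replicate index
    when ``paired`` — every condition then shares its initial network and
    endowment-assignment draws, a variance-reduction device).
    """

    replicates: int = 10
    base_seed: int = 0
    profile: str = "empirical-like"
    paired: bool = False
    base_config: SimulationConfig = field(default_factory=SimulationConfig)

    def seed_for(self, condition_index: int, replicate: int) -> int:
        if self.paired:
            return self.base_seed + replicate
        return self.base_seed + condition_index * self.replicates + replicate

    def config_for(self, condition_index: int, replicate: int) -> SimulationConfig:
        ineq, prod = CONDITIONS[condition_index]
        mult = dataclasses.replace(
            self.base_config.multiplier, regime="productivity" if prod else "control"
        )
        return dataclasses.replace(
            self.base_config,
            baseline_inequality=ineq,
            wealth_productivity=prod,
            endowment_gini=None,
            multiplier=mult,
            behavior=behavior_profile(self.profile),
            seed=self.seed_for(condition_index, replicate),
        )


def run_condition_grid(grid: ExperimentGrid) -> dict[str, list[MetricSeries]]:
    """Run every cell of the grid; returns per-condition replicate series."""
    out: dict[str, list[MetricSeries]] = {}
    for ci, (ineq, prod) in enumerate(CONDITIONS):
        label = condition_label(ineq, prod)
        out[label] = []
        for rep in range(grid.replicates):
            _, series = run_session(grid.config_for(ci, rep))
            out[label].append(series)
    return out


@dataclass(frozen=True)
class EnvelopeResult:
    """Null-behavior distribution of final endowment Gini with its 95% band."""

    ginis: np.ndarray
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile
    replicates: int
    config_digest: str


def null_gini_envelope(
    overrides: dict[str, Any] | None = None,
    replicates: int = 1000,
    base_seed: int = 0,
    *,
    profile: str = "null",
    regime: str = "control",
    pool_endowment_settings: bool = True,
    tie_dynamics: bool = True,
) -> EnvelopeResult:
    """Distribution of final-round raw endowment Gini under null behavior.

    Each replicate is a full default-length session (19 rounds on an
    Erdős–Rényi(27, 0.167) network) with agents drawing cooperation uniformly
    from the six allowed increments, dropping and proposing ties at random and
    accepting every proposal.  Equal-endowment and Gini-0.3 starts alternate
    across replicates (pooled), and payoffs use the control doubling; both
    choices, the behavior profile, and whether rewiring runs at all are
    switchable.  Returns the per-replicate Ginis and the central 95% interval
    (type-7 / linear-interpolation percentiles).
    """
    from .io_utils import config_digest  # deferred: io_utils imports config only

    if replicates < 2:
        raise ValueError("need at least 2 replicates for an envelope")
    overrides = dict(overrides or {})
    behavior = behavior_profile(profile)
    if not tie_dynamics:
        behavior = dataclasses.replace(behavior, drop_probability=0.0, propose_probability=0.0)
    ginis = np.empty(replicates)
    template = None
    for rep in range(replicates):
        ineq = pool_endowment_settings and rep % 2 == 1
        config = SimulationConfig(
            baseline_inequality=ineq,
            wealth_productivity=(regime == "productivity"),
            behavior=behavior,
            seed=base_seed + rep,
            **overrides,
        )
        if template is None:
            template = config
        _, series = run_session(config)
        ginis[rep] = series.final()["endowment_gini"]
    lower, upper = np.percentile(ginis, [2.5, 97.5])
    return EnvelopeResult(
        ginis=ginis,
        lower=float(lower),
        upper=float(upper),
        replicates=replicates,
        config_digest=config_digest(template),
    )


def condition_contrasts(
    series_by_condition: dict[str, list[MetricSeries]],
    metrics: tuple[str, ...] = ("mean_cooperation", "endowment_gini"),
    n_boot: int = 1000,
    seed: int = 0,
    last_k: int = 4,
) -> pd.DataFrame:
    """Pairwise condition differences with percentile bootstrap intervals.

    For every ordered condition pair and metric, reports the difference of
    replicate means per round and averaged over the last ``last_k`` rounds
    (the window in which cooperation has typically stabilized), with 95%
    percentile bootstrap intervals over replicates.
    """
    if len(series_by_condition) < 2:
        raise ValueError("need at least 2 conditions to contrast")
    for label, lst in series_by_condition.items():
        if len(lst) < 2:
            raise ValueError(f"condition {label!r} has fewer than 2 replicates")
    rng = np.random.default_rng(seed)
    # replicate x round matrices per condition and metric
    mats = {
        label: {m: np.vstack([s.data[m].to_numpy() for s in lst]) for m in metrics}
        for label, lst in series_by_condition.items()
    }
    rounds = next(iter(series_by_condition.values()))[0].data["round"].to_numpy()
    rows = []
    labels = sorted(series_by_condition)
    for a, b in itertools.combinations(labels, 2):
        for m in metrics:
            xa, xb = mats[a][m], mats[b][m]
            windows: list[tuple[Any, np.ndarray, np.ndarray]] = [
                (int(r), xa[:, k : k + 1], xb[:, k : k + 1]) for k, r in enumerate(rounds)
            ]
            windows.append((f"last{last_k}", xa[:, -last_k:], xb[:, -last_k:]))
            for scope, wa, wb in windows:
                if np.isnan(wa).all() or np.isnan(wb).all():
                    continue  # e.g. round 0 has no cooperation yet
                da = np.nanmean(wa, axis=1)
                db = np.nanmean(wb, axis=1)
                diff = float(np.nanmean(da) - np.nanmean(db))
                boot = np.empty(n_boot)
                for t in range(n_boot):
                    ia = rng.integers(0, len(da), len(da))
                    ib = rng.integers(0, len(db), len(db))
                    boot[t] = np.nanmean(da[ia]) - np.nanmean(db[ib])
                lo, hi = np.percentile(boot, [2.5, 97.5])
                rows.append(
                    {
                        "condition_a": a,
                        "condition_b": b,
                        "metric": m,
                        "scope": scope,
                        "difference": diff,
                        "ci_low": float(lo),
                        "ci_high": float(hi),
                    }
                )
    return pd.DataFrame(rows)
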