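# Methods

## The game

Agents occupy the nodes of an undirected graph.  One session consists of
`n_rounds` rounds (default 19).  Each round, every agent with at least one
tie picks a single cooperation level c ∈ {0, 10, 20, 30, 40, 50} MU and pays
c to *each* neighbor (total cost c × degree); each neighbor receives c·m,
where m is the payoff multiplier.  Giving is simultaneous: multipliers are
evaluated on round-start wealth, so outcomes are independent of processing
order.  Received amounts are rounded half-up to integer MU (MU is an integer
currency); with that convention final wealth replays *exactly* from the
transfer log, which the metrics module verifies on every summarization.

Per tie and per round the payoff deltas are the classic prisoner's-dilemma
quadruple: T = 50·m (defect against a cooperator), R = 50·m − 50 (mutual
cooperation), P = 0, S = −50.  T > R > P > S holds whenever m > 1, which the
multiplier floor guarantees (see below).

An agent's wealth may go negative (a poor agent giving 50 to several
neighbors can overdraw).  The ledger keeps true values; Gini computations
floor negatives at zero and log a count, since the Gini coefficient is not
defined for negative wealth.

## The multiplier

Control regime: m = 2 exactly ("each MU given is doubled"), independent of
wealth.  Productivity regime:

    m(E) = clamp(1 + slope · E / E₀,  floor, cap),
    defaults slope = 1, E₀ = 1000 MU, floor = 1.1, cap = 3.

The linear-with-clamp form is the simplest increasing function that (a)
coincides with the control doubling at the mean endowment E₀, so the two
regimes are payoff-equivalent for an average-wealth giver, and (b) keeps
m > 1 everywhere, preserving the PD ordering even for a destitute giver.  The
basis is the giver's *current* wealth by default; `basis="initial_endowment"`
switches to the starting endowment for designs where displayed wealth is
static.

## Endowments

`generate_endowments(n, mean, target_gini)` builds an arithmetic ladder
symmetric about the mean.  For a ladder with step d the Gini is exactly
G = d(n² − 1)/(6 n · mean), so the step is solved in closed form; offsets are
then rounded to the nearest 10 MU (symmetrically, keeping the mean exact to
the last bit), and if rounding moves the Gini off target the step is refined
by bisection.  The result is deterministic; a separate permutation draw
assigns values to agents.  Targets are rejected as infeasible when no
non-negative ladder reaches them (the cap is G = (n+1)/(3n), ≈ 0.346 at
n = 27) or when rounding granularity makes the tolerance (±0.005)
unreachable, e.g. tiny n with small means.  The defaults — n = 27, mean
1000 MU, Gini 0.3 in the inequality condition, 0 otherwise — are the study
design's values; the distribution's *shape* beyond (mean, Gini) is a design
choice, since only those two moments are specified.

## Networks and tie updates

Initial graphs are Erdős–Rényi G(n, p) with p = 0.167 (≈ 4 ties per agent at
n = 27), used as drawn — no connectivity repair, so isolates can exist from
round 0.  After every `update_interval`-th round (default 3; six phases in a
19-round session) a tie-update phase runs:

1. Connected agents act in an order freshly randomized from the session RNG.
2. Each actor may sever at most one tie (applied immediately, unilateral; an
   edge dropped by both endpoints is removed once) and propose at most one
   new tie to any non-neighbor.
3. Proposals are resolved only after all actors have moved; each target
   accepts or rejects independently.  An agent can thus gain several ties,
   or be dropped by several neighbors, in one phase.
4. Agents at degree zero after resolution are recorded as isolated at that
   phase (first time only — the input to the survival curve).  Isolated
   agents make no giving or rewiring decisions but remain visible in the
   candidate pool and can rejoin through incoming proposals; rejoining does
   not erase the isolation record.

## Behavior models

Agents see only what participants in the reference design saw: each
neighbor's last cooperation and the amount received from them, neighbors'
wealth, and — during tie selection — each candidate's wealth and "giving
signal" (the mean post-multiplier amount the candidate's partners received
from them in the previous round; candidates with no partners last round
carry no signal and are imputed at the group mean so isolation is not
mechanically penalized).  Wealth enters all policies standardized by the
network's current endowment mean and SD (SD set to 1 when wealth is
constant).

**`null` profile** (the envelope's behavior): cooperation uniform on the six
levels; each phase the agent drops a uniformly random neighbor with
probability 0.5 and proposes to a uniformly random candidate with
probability 0.5; all proposals accepted.  The 0.5s keep expected tie churn
roughly density-neutral; they are explicit parameters
(`drop_probability`, `propose_probability`), not constants.

**`empirical-like` profile**: a conditional model whose weights are *signed*
to match the qualitative regularities reported for this class of experiment;
no fitting to human data is performed (none is available), so magnitudes are
defaults, not estimates.

- Cooperation: latent = base (20 MU) + 0.6 × mean neighbor last giving
  + 5 MU × standardized mean neighbor wealth (productivity condition only)
  + N(0, 8 MU); clamped to [0, 50], rounded to the nearest 10.  With no
  history (round 1) the agent plays its base level.
- Severance: P(drop) = logistic(−3 + 0.06 × mean cooperation deficit), where
  the deficit is 50 minus the neighborhood's mean last giving (neighbors
  without history count at the neutral 25); a fully cooperative neighborhood
  gives P ≈ 0.047.  Target choice is a multinomial logit with utility
  −0.1 × cooperation + 0.5 × standardized wealth (defectors and, per the
  control-condition finding, the wealthy are preferentially dropped).
- Proposal: multinomial logit over candidates with utility 0.05 × giving
  signal + β_w × standardized wealth, β_w = 0.3 in control and doubled to
  0.6 under productivity (the reported ≈2× wealth effect in partner
  selection).
- Acceptance: logistic(−1 + 0.05 × signal + 0.3 × standardized wealth).

All policies are pure functions of (inputs, RNG stream); a session replayed
with the same seed reproduces every decision, transfer and tie event.

## Metrics

- **Gini**: sorted-form identity G = Σᵢ(2i − n − 1)x₍ᵢ₎ / (n² x̄), equal to
  the O(n²) pairwise mean absolute difference normalized by 2x̄; tested
  against the brute-force double sum to 1e-12.
- **Adjusted endowments**: the ledger replayed with every multiplier forced
  to 2 (costs unchanged) — the counterfactual wealth with productivity's
  infused value removed.  Exactly the identity on control-regime ledgers.
- **Degree Gini**: reported both including isolates (wealth persists, so the
  population is everyone) and over connected agents only.
- **Isolation survival**: discrete-time Kaplan–Meier product-limit
  S(k) = Π_{j≤k}(1 − d_j/n_j) over the six phases, with first isolation as
  the event and survival-to-end as censoring.  A covariate-adjusted
  proportional-hazards fit is deliberately out of scope; the descriptive
  curve is the target.
- **Cooperation–wealth association**: per-session OLS of each decision on
  the standardized mean neighbor wealth *controlling for the reciprocity
  input* (mean neighbor last giving).  The control matters: reciprocity
  clusters cooperative agents into wealthy neighborhoods, so the raw
  correlation is positive even when behavior ignores wealth; the partial
  coefficient isolates the wealth channel (positive iff the wealth weight is
  on).

Metric series are rebuilt from the logs by replay rather than accumulated
live, so a written event log is sufficient to reproduce every number
(`coopnet metrics`); the replay doubles as an integrity check against the
live ledger.

## The null Gini envelope

`null_gini_envelope` runs replicate full-length sessions under the `null`
profile with control payoffs, alternating equal and Gini-0.3 initial
endowments across replicates (pooled), and reports the 2.5th and 97.5th
percentiles (inclusive / type-7 quantiles, whose convention shifts bounds by
~0.002 at 1000 replicates) of the final-round raw endowment Gini.

At the defaults (1000 replicates) the band computes to ≈ [0.13, 0.24],
narrower than the reference band of [0.07, 0.27] reported for the analogous
simulation whose exact behavioral rule is not printed.  The discrepancy is
documented rather than tuned away, and the envelope's four structural
switches allow it to be re-run under other readings (300-replicate
sensitivity, seed 11):

| variant                                | band           |
|----------------------------------------|----------------|
| default (drop .5 / propose .5, control) | [0.127, 0.236] |
| productivity payoffs                    | [0.141, 0.247] |
| static network (no rewiring)            | [0.137, 0.250] |
| drop 0 / propose 1                      | [0.099, 0.176] |
| drop 1 / propose 1                      | [0.104, 0.198] |
| drop 1 / propose 0.25                   | [0.107, 0.262] |

High-churn, rarely-rejoining dynamics (last row) widen the band most, by
producing more isolates whose frozen wealth fattens both Gini tails; no
examined reading reaches a lower bound of 0.07 while preserving the stated
protocol (uniform giving triples mean wealth over 19 rounds, and the degree
spread of G(27, 0.167) alone keeps the final Gini above ≈ 0.10).

## Problem sizes and numerical conventions

Tests and the acceptance script use the design's native scale throughout
(27 agents, 19 rounds); replicated checks use 50–100 sessions for exact
ledger properties, 400–1000 replicates for percentile estimates, and 500
draws for the mean-degree check — enough for the Monte-Carlo error of each
statistic to sit well inside its decision band.  Ties in multinomial logits
are broken by the sampled uniform variate; logit utilities are max-shifted
before exponentiation; percentile estimates use NumPy's default linear
interpolation; rounding of received MU is half-up.

## What the synthetic agents do and do not show

The generator emulates the *mechanics* of the reference experiment (payoffs,
information sets, rewiring protocol) and the *signs* of reported behavioral
regularities.  It does not emulate human heterogeneity, learning, end-game
reasoning (deliberately: agents never see the horizon), or the magnitudes of
human effects.  Passing tests therefore validate the environment, the
metrics and the direction of mechanism-level predictions — not quantitative
claims about human behavior.
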