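"""Behavior policies: supports, closed-form logits, monotonicity, purity."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopnet import BehaviorParams, behavior_profile
from coopnet.agents import (
    CandidateInfo,
    NeighborView,
    Observation,
    acceptance_policy,
    conditional_policy,
    make_behavior,
    proposal_policy,
    random_increment_policy,
    severance_policy,
)

LEVELS = {0, 10, 20, 30, 40, 50}


def obs_with_neighbors(coops, zs=None, round=5, productivity=False):
    zs = zs if zs is not None else [0.0] * len(coops)
    neighbors = tuple(
        NeighborView(neighbor_id=k, last_cooperation=c, last_received=None,
                     endowment=1000.0 + 500 * z, endowment_z=z)
        for k, (c, z) in enumerate(zip(coops, zs))
    )
    return Observation(agent_id=99, round=round, own_endowment=1000.0,
                       neighbors=neighbors, wealth_productivity=productivity,
                       baseline_inequality=False)


def cand(cid, z=0.0, signal=None):
    return CandidateInfo(candidate_id=cid, endowment=1000 + 500 * z, endowment_z=z,
                         giving_signal=signal)


# ---------------------------------------------------------------------------
# random increment policy


def test_random_policy_support_and_uniformity():
    rng = np.random.default_rng(0)
    obs = obs_with_neighbors([30])
    draws = np.array([random_increment_policy(obs, rng) for _ in range(60_000)])
    assert set(np.unique(draws)) <= LEVELS
    p = 1 / 6
    tol = 3 * math.sqrt(p * (1 - p) / 60_000)
    for level in LEVELS:
        assert abs((draws == level).mean() - p) < tol
    assert abs(draws.mean() - 25.0) < 3 * 17.08 / math.sqrt(60_000)


# ---------------------------------------------------------------------------
# conditional cooperation


def test_pure_reciprocity_fixed_point():
    params = BehaviorParams(base_level=0, reciprocity_weight=1.0, wealth_weight=0.0, noise_sd=0.0)
    obs = obs_with_neighbors([30, 30, 30])
    assert conditional_policy(obs, params, np.random.default_rng(0)) == 30


def test_cold_start_plays_base_level():
    params = BehaviorParams(base_level=20, noise_sd=0.0)
    obs = obs_with_neighbors([None, None])
    assert conditional_policy(obs, params, np.random.default_rng(0)) == 20


def test_cold_start_base_level_is_clamped_and_rounded():
    assert conditional_policy(
        obs_with_neighbors([None]), BehaviorParams(base_level=77.0, noise_sd=0.0),
        np.random.default_rng(0)) == 50
    assert conditional_policy(
        obs_with_neighbors([None]), BehaviorParams(base_level=-4.0, noise_sd=0.0),
        np.random.default_rng(0)) == 0


def test_wealth_response_monotone_under_productivity():
    """Holding reciprocity input fixed, giving is non-decreasing in mean
    neighbor endowment when the wealth channel is on."""
    params = BehaviorParams(base_level=10, reciprocity_weight=0.5, wealth_weight=10.0, noise_sd=0.0)
    out = [
        conditional_policy(obs_with_neighbors([30, 30], zs=[z, z], productivity=True),
                           params, np.random.default_rng(0))
        for z in np.linspace(-2, 2, 17)
    ]
    assert all(b >= a for a, b in zip(out, out[1:]))
    assert out[-1] > out[0]
    # with the productivity flag off, the channel is inert
    flat = {
        conditional_policy(obs_with_neighbors([30, 30], zs=[z, z], productivity=False),
                           params, np.random.default_rng(0))
        for z in np.linspace(-2, 2, 17)
    }
    assert len(flat) == 1


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    coops=st.lists(st.sampled_from(sorted(LEVELS)), min_size=1, max_size=6),
    base=st.floats(-20, 80),
    rho=st.floats(0, 1.5),
    noise=st.floats(0, 30),
    seed=st.integers(0, 1000),
)
def test_conditional_output_always_valid_increment(coops, base, rho, noise, seed):
    params = BehaviorParams(base_level=base, reciprocity_weight=rho, noise_sd=noise)
    out = conditional_policy(obs_with_neighbors(coops), params, np.random.default_rng(seed))
    assert out in LEVELS


# ---------------------------------------------------------------------------
# severance


def test_cooperative_neighborhood_rarely_dropped():
    params = BehaviorParams(drop_intercept=-3.0, drop_slope=0.06, drop_round_weight=0.0)
    obs = obs_with_neighbors([50, 50, 50])
    rng = np.random.default_rng(1)
    drops = sum(severance_policy(obs, params, rng) is not None for _ in range(1000))
    assert drops / 1000 < 0.05  # sigmoid(-3) = 0.047


def test_singleton_neighbor_is_the_drop_target():
    params = BehaviorParams(drop_intercept=50.0)  # always drop
    obs = obs_with_neighbors([0])
    assert severance_policy(obs, params, np.random.default_rng(0)) == 0


def test_defector_chosen_with_closed_form_logit_probability():
    """Two neighbors, coop 0 vs 50, equal wealth, gamma_c = -0.1:
    P(defector) = 1 / (1 + e^(50 * -0.1)) = 0.9933."""
    params = BehaviorParams(drop_intercept=50.0, drop_coop_weight=-0.1, drop_wealth_weight=0.0)
    obs = obs_with_neighbors([0, 50])
    rng = np.random.default_rng(2)
    n = 2000
    hits = sum(severance_policy(obs, params, rng) == 0 for _ in range(n))
    expected = 1 / (1 + math.exp(-5.0))
    assert abs(hits / n - expected) < 3 * math.sqrt(expected * (1 - expected) / n) + 1e-9


# ---------------------------------------------------------------------------
# proposals


def test_empty_candidate_list_yields_none():
    assert proposal_policy([], BehaviorParams(), np.random.default_rng(0)) is None


def test_wealth_dominant_logit_picks_richest():
    params = BehaviorParams(choice_coop_weight=0.0, choice_wealth_weight=50.0,
                            propose_probability=1.0)
    cands = [cand(0, z=-1.0), cand(1, z=0.0), cand(2, z=1.5)]
    rng = np.random.default_rng(3)
    picks = [proposal_policy(cands, params, rng) for _ in range(200)]
    assert picks.count(2) == 200


def test_identical_candidates_split_evenly():
    params = BehaviorParams(propose_probability=1.0)
    cands = [cand(0, z=0.2, signal=40.0), cand(1, z=0.2, signal=40.0)]
    rng = np.random.default_rng(4)
    picks = np.array([proposal_policy(cands, params, rng) for _ in range(2000)])
    assert abs((picks == 0).mean() - 0.5) < 3 * 0.5 / math.sqrt(2000)


def test_productivity_doubles_wealth_weight_in_choice():
    """The same candidate field is chosen more wealth-sensitively under
    productivity: hand-computed two-candidate logit probabilities."""
    params = BehaviorParams(choice_coop_weight=0.0, choice_wealth_weight=0.5,
                            choice_wealth_productivity_multiplier=2.0,
                            propose_probability=1.0)
    cands = [cand(0, z=1.0), cand(1, z=0.0)]
    n = 4000
    for prod, beta in ((False, 0.5), (True, 1.0)):
        rng = np.random.default_rng(5)
        hits = sum(
            proposal_policy(cands, params, rng, wealth_productivity=prod) == 0
            for _ in range(n)
        )
        expected = 1 / (1 + math.exp(-beta))
        assert abs(hits / n - expected) < 3 * math.sqrt(expected * (1 - expected) / n)


def test_missing_giving_signal_imputed_at_group_mean():
    """A candidate with no partners last round is not mechanically penalized:
    against an observed signal of 30, imputation makes the two identical."""
    params = BehaviorParams(choice_coop_weight=1.0, choice_wealth_weight=0.0,
                            propose_probability=1.0)
    cands = [cand(0, signal=30.0), cand(1, signal=None)]
    rng = np.random.default_rng(6)
    picks = np.array([proposal_policy(cands, params, rng) for _ in range(2000)])
    assert abs((picks == 0).mean() - 0.5) < 3 * 0.5 / math.sqrt(2000)


# ---------------------------------------------------------------------------
# acceptance


def test_accept_all_configuration():
    params = BehaviorParams(accept_all=True, accept_intercept=-100.0)
    rng = np.random.default_rng(7)
    assert all(acceptance_policy(cand(0, z=-3.0, signal=0.0), params, rng) for _ in range(50))


def test_strongly_negative_intercept_rejects():
    params = BehaviorParams(accept_intercept=-5.0, accept_coop_weight=0.0,
                            accept_wealth_weight=0.0)
    rng = np.random.default_rng(8)
    rate = np.mean([acceptance_policy(cand(0), params, rng) for _ in range(1000)])
    assert rate < 0.05


def test_identical_proposers_get_identical_probability():
    params = BehaviorParams(accept_intercept=0.0)
    a = [acceptance_policy(cand(0, z=0.5, signal=20.0), params, np.random.default_rng(s))
         for s in range(200)]
    b = [acceptance_policy(cand(1, z=0.5, signal=20.0), params, np.random.default_rng(s))
         for s in range(200)]
    assert a == b  # exchangeable given the same rng stream


# ---------------------------------------------------------------------------
# contract


def test_policies_are_pure_given_rng_stream():
    params = behavior_profile("empirical-like")
    model = make_behavior(params)
    obs = obs_with_neighbors([10, 40, 20], zs=[0.5, -0.5, 1.0], productivity=True)
    out1 = [model.decide_cooperation(obs, np.random.default_rng(9)) for _ in range(5)]
    out2 = [model.decide_cooperation(obs, np.random.default_rng(9)) for _ in range(5)]
    assert out1 == out2


def test_profile_lookup():
    assert behavior_profile("null").model == "random_increment"
    assert behavior_profile("empirical-like").model == "conditional"
    with pytest.raises(Exception):
        behavior_profile("nonexistent")


def test_random_model_ignores_weights():
    p1 = behavior_profile("null")
    p2 = dataclasses.replace(p1, reciprocity_weight=99.0, wealth_weight=-99.0)
    obs = obs_with_neighbors([50, 50])
    a = [make_behavior(p1).decide_cooperation(obs, np.random.default_rng(s)) for s in range(50)]
    b = [make_behavior(p2).decide_cooperation(obs, np.random.default_rng(s)) for s in range(50)]
    assert a == b
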