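import dataclasses as dc

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rita.policy import (
    PolicyConfig,
    RitaPolicy,
    RitaState,
    apply_updates,
    clamp_probability,
    draw_assignments,
    init_states,
    rank_responses,
    step,
    update_imr,
    update_probability,
)

CFG = PolicyConfig()


def fresh_state(obs=1000):
    return init_states(obs)[0]


# --- initialization ---------------------------------------------------------


@pytest.mark.parametrize("obs,half", [(1000, 500.0), (4, 2.0)])
def test_init_states_neutral(obs, half):
    states = init_states(obs)
    assert len(states) == obs
    assert all(s.tau_a == 0.5 and s.imr_a == half and s.imr_b == half
               and s.count_a == 0 and s.count_b == 0 for s in states)


def test_init_states_requires_two_individuals():
    with pytest.raises(ValueError):
        init_states(1)


# --- assignment draws -------------------------------------------------------


def test_degenerate_probabilities_are_deterministic(rng):
    states = [dc.replace(fresh_state(4), tau_a=1.0),
              dc.replace(fresh_state(4), tau_a=0.0)]
    arms = draw_assignments(states, rng)
    assert list(arms) == ["A", "B"]


def test_fair_probability_gives_half_assignment_rate(rng):
    n = 100_000
    arms = draw_assignments(init_states(n), rng)
    se = 0.5 / np.sqrt(n)
    assert abs(np.mean(arms == "A") - 0.5) < 3 * se


# --- ranking ----------------------------------------------------------------


def test_ranks_strictly_ordered_input(rng):
    assert rank_responses(np.array([0.1, 0.5, 0.3]), rng=rng).tolist() == [1, 3, 2]


def test_random_tie_break_yields_a_permutation(rng):
    seen = set()
    for _ in range(20):
        r = rank_responses(np.array([0.2, 0.2]), "random", rng)
        seen.add(tuple(r))
        assert sorted(r) == [1, 2]
    assert seen == {(1, 2), (2, 1)}


def test_average_tie_rule_is_deterministic_by_index(rng):
    r = rank_responses(np.array([0.2, 0.1, 0.2]), "average", rng)
    assert r.tolist() == [2, 1, 3]


def test_non_finite_responses_rejected(rng):
    with pytest.raises(ValueError):
        rank_responses(np.array([0.1, np.nan]), rng=rng)


@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=200))
def test_ranks_are_a_permutation(delta):
    rng = np.random.default_rng(0)
    ranks = rank_responses(np.array(delta), "random", rng)
    assert sorted(ranks) == list(range(1, len(delta) + 1))


# --- individual mean ranks --------------------------------------------------


def test_imr_updates_only_the_assigned_arm():
    s = update_imr(fresh_state(), "A", 600)
    assert (s.imr_a, s.imr_b, s.count_a, s.count_b) == (600.0, 500.0, 1, 0)
    s = update_imr(s, "A", 400)
    assert s.imr_a == 500.0 and s.count_a == 2
    t = update_imr(fresh_state(), "B", 250)
    assert (t.imr_b, t.imr_a) == (250.0, 500.0)


def test_imr_equals_rank_sum_over_count():
    s = fresh_state()
    for r in (600, 400, 100):
        s = update_imr(s, "A", r)
    assert s.imr_a == pytest.approx(s.rank_sum_a / s.count_a)
    assert s.count_a + s.count_b == 3


# --- probability update -----------------------------------------------------


def test_first_update_uses_individual_rank_only():
    # first assignment: learning exponent 0, so tau is the rescaled rank
    s = update_imr(fresh_state(), "A", 600)
    assert update_probability(s, "A", 600, 1000) == pytest.approx(0.6)


def test_second_update_applies_relative_rank_drift():
    s = update_imr(update_imr(fresh_state(), "A", 600), "A", 600)
    assert s.imr_b == 500.0
    assert update_probability(s, "A", 600, 1000) == pytest.approx(0.72)


def test_unit_factors_give_probability_one():
    s = fresh_state()
    for _ in range(5):
        s = update_imr(s, "A", 1000)
    s = dc.replace(s, imr_b=1000.0)
    assert update_probability(s, "A", 1000, 1000) == pytest.approx(1.0)


def test_update_probability_requires_prior_imr_update():
    with pytest.raises(ValueError):
        update_probability(fresh_state(), "A", 600, 1000)


def test_mirrored_b_update():
    s = update_imr(fresh_state(), "B", 250)
    # tau_B = 0.25 * (250/500)^0, so tau_A = 0.75
    assert update_probability(s, "B", 250, 1000) == pytest.approx(0.75)


def test_literal_b_branch_differs_from_mirror():
    s = update_imr(fresh_state(), "B", 250)
    # literal: 1 - tau_A = (1 - 0.25) * (500/250)^0 = 0.75
    assert update_probability(s, "B", 250, 1000, eq10_literal=True) == pytest.approx(0.25)


def test_monotone_reinforcement_in_assignment_count():
    """With the opposite arm's mean rank fixed, repeated assignments push tau
    toward the arm iff the rank beats that mean rank."""
    taus_up, taus_down = [], []
    for count in range(1, 8):
        s = dc.replace(fresh_state(), count_a=count, imr_b=500.0)
        taus_up.append(update_probability(s, "A", 600, 1000))
        taus_down.append(update_probability(s, "A", 400, 1000))
    assert all(b >= a for a, b in zip(taus_up, taus_up[1:]))
    assert all(b <= a for a, b in zip(taus_down, taus_down[1:]))


def test_extreme_exponent_does_not_overflow():
    s = dc.replace(fresh_state(), count_a=400, imr_b=1.0)
    tau = update_probability(s, "A", 1000, 1000)
    assert np.isinf(tau) or tau > 1
    assert clamp_probability(tau, CFG) == 0.95


# --- clamping ---------------------------------------------------------------


@pytest.mark.parametrize("tau,expected", [(1.2, 0.95), (0.01, 0.05), (0.6, 0.6)])
def test_clamp_default_bounds(tau, expected):
    assert clamp_probability(tau, CFG) == pytest.approx(expected)


def test_clamp_general_bounds_protect_both_arms():
    cfg = PolicyConfig(lambda_l=0.2, lambda_u=0.95)
    # tau_B = 1 - tau_A must also stay >= 0.2, so tau_A caps at 0.8
    assert clamp_probability(0.9, cfg) == pytest.approx(0.8)


def test_invalid_bounds_rejected():
    with pytest.raises(ValueError):
        PolicyConfig(lambda_l=0.9, lambda_u=0.1)


# --- one full step ----------------------------------------------------------


def test_step_hand_computed_four_individuals(rng):
    """Frozen arithmetic for a 4-person period, worked by hand from the
    update rules (ranks 1,4,3,2; exponent 0 throughout)."""
    states = init_states(4)
    arms = np.array(["A", "A", "B", "B"])
    delta = np.array([0.1, 0.5, 0.3, 0.2])
    out = step(states, arms, delta, CFG, rng)
    assert [s.tau_a for s in out] == pytest.approx([0.25, 0.95, 0.25, 0.5])
    assert [s.tau_a_unclamped for s in out] == pytest.approx([0.25, 1.0, 0.25, 0.5])
    assert [s.imr_a for s in out] == pytest.approx([1.0, 4.0, 2.0, 2.0])
    assert [s.imr_b for s in out] == pytest.approx([2.0, 2.0, 3.0, 2.0])


def test_step_tau_set_invariant_under_ties(rng):
    # identical responses: random tie-break permutes ranks, so the tau values
    # are the same multiset no matter who gets which rank
    states = init_states(4)
    arms = np.array(["A"] * 4)
    out = step(states, arms, np.zeros(4), CFG, rng)
    assert sorted(s.tau_a for s in out) == pytest.approx([0.25, 0.5, 0.75, 0.95])


def test_top_rank_twice_hits_upper_clamp(rng):
    states = init_states(4)
    arms = np.array(["A", "B", "B", "B"])
    delta1 = np.array([0.9, 0.1, 0.2, 0.3])
    out = step(states, arms, delta1, CFG, rng)
    delta2 = np.array([0.8, 0.1, 0.2, 0.3])
    out = step(out, arms, delta2, CFG, rng)
    assert out[0].tau_a == 0.95


def test_step_is_pure(rng):
    states = init_states(4)
    before = [dc.replace(s) for s in states]
    step(states, np.array(["A"] * 4), np.arange(4.0), CFG, rng)
    assert states == before


def test_step_length_mismatch(rng):
    with pytest.raises(ValueError):
        step(init_states(4), np.array(["A"] * 3), np.arange(4.0), CFG, rng)


def test_arm_relabelling_symmetry(rng):
    """Swapping every A/B label mirrors the tau trajectory (tau -> 1 - tau)
    when ranks are unchanged, under the default symmetric update."""
    n, T = 6, 3
    gen = np.random.default_rng(9)
    arms = np.where(gen.random((T, n)) < 0.5, "A", "B")
    deltas = gen.normal(size=(T, n))
    s1, s2 = init_states(n), init_states(n)
    for t in range(T):
        ranks = rank_responses(deltas[t], "average", None)
        s1 = apply_updates(s1, arms[t], ranks, CFG)
        swapped = np.where(arms[t] == "A", "B", "A")
        s2 = apply_updates(s2, swapped, ranks, CFG)
    for a, b in zip(s1, s2):
        assert a.tau_a == pytest.approx(1.0 - b.tau_a)
        assert a.imr_a == pytest.approx(b.imr_b)
        assert a.count_a == b.count_b


def test_probabilities_normalized_and_bounded_after_steps(rng):
    states = init_states(8)
    gen = np.random.default_rng(4)
    for _ in range(5):
        arms = np.where(gen.random(8) < 0.5, "A", "B")
        states = step(states, arms, gen.normal(size=8), CFG, rng)
    for s in states:
        assert 0.05 <= s.tau_a <= 0.95  # tau_B = 1 - tau_A bounded too


# --- engine-facing adapter --------------------------------------------------


def test_policy_adapter_matches_functional_updates(rng):
    pol = RitaPolicy(record_history=True)
    pol.reset(5, np.random.default_rng(3))
    arms = pol.propose()
    delta = np.arange(5.0)
    pol.observe(arms, delta)
    frame = pol.state_frame()
    assert set(frame.columns) >= {"period", "id", "arm", "rank", "imr_A",
                                  "imr_B", "tau_A", "tau_A_unclamped"}
    assert sorted(frame["rank"]) == [1, 2, 3, 4, 5]
    assert frame["tau_A"].between(0.05, 0.95).all()


def test_policy_requires_reset():
    with pytest.raises(RuntimeError):
        RitaPolicy().propose()
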