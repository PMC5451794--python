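"""Stage-game mechanics: race, roles, payoffs, reinforcement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boldfish import (
    DomainError,
    GameParams,
    InvalidStateError,
    PersonalityState,
    SuccessTable,
    assign_roles,
    build_default_success_table,
    compute_payoffs,
    initiator_distribution,
    play_stage_game,
    sample_decision_times,
    select_initiator,
    update_initiator_trait,
)
from boldfish.game import ROLE_FOLLOWER, ROLE_FREE_RIDER, ROLE_INITIATOR

traits_strategy = st.lists(
    st.floats(min_value=0.01, max_value=0.99), min_size=1, max_size=8
)


class TestDecisionTimes:
    def test_mean_matches_inverse_trait(self, rng):
        """Exponential decision times have mean 1/s_i (checked at 4 SE)."""
        state = PersonalityState(np.full(3, 0.5))
        draws = np.array([sample_decision_times(state, rng) for _ in range(100_000)])
        se = 2.0 / np.sqrt(draws.shape[0])  # std of Exp(0.5) is 2
        assert np.all(np.abs(draws.mean(axis=0) - 2.0) < 4 * se)

    def test_rate_ordering_between_agents(self, rng):
        """A boldness ratio of 4 gives a decision-time ratio of 1/4."""
        state = PersonalityState(np.array([0.2, 0.8]))
        draws = np.array([sample_decision_times(state, rng) for _ in range(100_000)])
        means = draws.mean(axis=0)
        assert means[1] / means[0] == pytest.approx(0.25, rel=0.05)

    def test_draws_are_nonnegative(self, rng, state6):
        assert np.all(sample_decision_times(state6, rng) >= 0)

    @pytest.mark.parametrize("bad", [np.array([]), np.array([0.0, 0.5]), np.array([1.0])])
    def test_invalid_traits_rejected(self, bad):
        with pytest.raises((DomainError, InvalidStateError)):
            PersonalityState(bad)


class TestInitiatorSelection:
    @pytest.mark.parametrize(
        "times, winner",
        [((3.2, 1.1, 5.0), 1), ((0.7,), 0), ((2.0, 2.0), 0)],
    )
    def test_argmin_with_low_index_tie_break(self, times, winner):
        assert select_initiator(times) == winner

    def test_empty_vector_rejected(self):
        with pytest.raises(InvalidStateError):
            select_initiator([])

    def test_distribution_proportional_to_traits(self):
        """Six equal traits → uniform 1/6; (0.6, 0.3) → (2/3, 1/3)."""
        equal = initiator_distribution(PersonalityState(np.full(6, 0.42)))
        np.testing.assert_allclose(equal, 1 / 6)
        skew = initiator_distribution(PersonalityState(np.array([0.6, 0.3])))
        np.testing.assert_allclose(skew, [2 / 3, 1 / 3])


class TestRoleAssignment:
    def test_follower_probability_is_one_minus_trait_squared(self, rng):
        """Non-initiator with s=0.6 follows with probability 0.64 (3 SE)."""
        state = PersonalityState(np.array([0.5, 0.6]))
        m = 100_000
        hits = sum(
            assign_roles(state, 0, rng)[1] == ROLE_FOLLOWER for _ in range(m)
        )
        se = np.sqrt(0.64 * 0.36 / m)
        assert abs(hits / m - 0.64) < 3 * se

    def test_nearly_shy_agent_always_follows(self, rng):
        state = PersonalityState(np.array([0.5, 1e-9]))
        roles = [assign_roles(state, 0, rng)[1] for _ in range(1000)]
        assert all(role == ROLE_FOLLOWER for role in roles)

    def test_singleton_group(self, rng):
        state = PersonalityState(np.array([0.5]))
        assert assign_roles(state, 0, rng) == (ROLE_INITIATOR,)

    def test_out_of_range_initiator_rejected(self, rng, state6):
        with pytest.raises(InvalidStateError):
            assign_roles(state6, 6, rng)


class TestPayoffs:
    @pytest.mark.parametrize(
        "outcome, c_pay, d_pay", [(1, 1.0, 2.0), (0, -1.0, 0.0)]
    )
    def test_snowdrift_payoffs_b2_c1(self, params, outcome, c_pay, d_pay):
        """With b=2, c=1: success pays cooperators 1 and free-riders 2;
        failure costs cooperators 1 while free-riders break even."""
        roles = (ROLE_INITIATOR, ROLE_FOLLOWER, ROLE_FREE_RIDER)
        np.testing.assert_allclose(
            compute_payoffs(roles, outcome, params), [c_pay, c_pay, d_pay]
        )

    def test_all_cooperators_total(self, params):
        roles = (ROLE_INITIATOR,) + (ROLE_FOLLOWER,) * 5
        total = compute_payoffs(roles, 1, params).sum()
        assert total == pytest.approx(6 * (params.benefit - params.cost))


class TestTraitUpdate:
    @pytest.mark.parametrize(
        "s, r, lam, expected",
        [(0.5, 1, 0.9, 0.95), (0.5, 0, 0.4, 0.30), (0.8, 1, 0.4, 0.88)],
    )
    def test_reinforcement_rule(self, s, r, lam, expected):
        params = GameParams(update_rate=lam)
        state = PersonalityState(np.array([s]))
        new = update_initiator_trait(state, 0, r, params)
        assert new.traits[0] == pytest.approx(expected, abs=1e-15)

    def test_only_initiator_changes(self, params, state6):
        new = update_initiator_trait(state6, 2, 1, params)
        mask = np.arange(6) != 2
        np.testing.assert_array_equal(new.traits[mask], state6.traits[mask])
        assert new.traits[2] != state6.traits[2]

    @given(
        s=st.floats(min_value=1e-12, max_value=1.0, exclude_max=True),
        lam=st.floats(min_value=1e-6, max_value=1.0, exclude_max=True),
        r=st.integers(min_value=0, max_value=1),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_trait_stays_in_open_interval(self, s, lam, r):
        """Updates never escape (0, 1), even under float rounding."""
        params = GameParams(update_rate=lam) if 0 < lam < 1 else None
        if params is None:
            return
        state = PersonalityState(np.array([s]))
        new = update_initiator_trait(state, 0, r, params)
        assert 0.0 < new.traits[0] < 1.0


class TestStageGame:
    def test_forced_success_single_agent(self, rng):
        """N=1 with certain success: the lone agent initiates, cooperates,
        earns b−c, and its boldness moves toward 1."""
        params = GameParams(n_agents=1)
        table = SuccessTable({("O1", 1): 1.0})
        state = PersonalityState(np.array([0.5]))
        rec = play_stage_game(state, "O1", table, params, rng)
        assert rec.n_cooperators == 1 and rec.outcome == 1
        assert rec.payoffs[0] == pytest.approx(params.benefit - params.cost)
        assert rec.traits_after.traits[0] > 0.5

    def test_forced_failure_shrinks_initiator_trait(self, rng, params, state6):
        table = SuccessTable({("O1", n): 0.0 for n in range(1, 7)})
        rec = play_stage_game(state6, "O1", table, params, rng)
        assert rec.outcome == 0
        assert rec.traits_after.traits[rec.initiator] < state6.traits[rec.initiator]

    def test_same_seed_reproduces_task(self, params, default_table, state6):
        recs = [
            play_stage_game(
                state6, "O2", default_table, params, np.random.default_rng(7)
            )
            for _ in range(2)
        ]
        a, b = recs
        assert a.initiator == b.initiator and a.roles == b.roles
        np.testing.assert_array_equal(
            a.role_assignment.decision_times, b.role_assignment.decision_times
        )
        np.testing.assert_array_equal(a.payoffs, b.payoffs)
        np.testing.assert_array_equal(
            a.traits_after.traits, b.traits_after.traits
        )

    @given(traits=traits_strategy, seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_role_partition_and_payoff_conservation(self, traits, seed):
        """Every task: one initiator, roles partition N, n_C = followers + 1,
        and Σ payoffs = N·r·b − n_C·c."""
        params = GameParams(n_agents=len(traits))
        table = build_default_success_table(len(traits))
        state = PersonalityState(np.array(traits))
        rec = play_stage_game(
            state, "O1", table, params, np.random.default_rng(seed)
        )
        roles = rec.roles
        assert roles.count(ROLE_INITIATOR) == 1
        assert len(roles) == params.n_agents
        assert rec.n_cooperators == roles.count(ROLE_FOLLOWER) + 1
        expected_total = (
            params.n_agents * rec.outcome * params.benefit
            - rec.n_cooperators * params.cost
        )
        assert rec.payoffs.sum() == pytest.approx(expected_total)

    def test_fast_mode_matches_race_distribution(self, rng):
        """Direct categorical sampling of the winner agrees with the
        explicit race (chi-square on 20k tasks each)."""
        from scipy.stats import chi2_contingency

        traits = np.array([0.1, 0.3, 0.5, 0.7])
        params = GameParams(n_agents=4)
        table = build_default_success_table(4)
        counts = np.zeros((2, 4))
        state = PersonalityState(traits)
        for row, fast in enumerate([False, True]):
            for _ in range(20_000):
                rec = play_stage_game(
                    state, "O1", table, params, rng, fast=fast
                )
                counts[row, rec.initiator] += 1
        _, p, _, _ = chi2_contingency(counts)
        assert p > 0.001
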