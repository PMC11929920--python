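"""The trust-game environment: state, round transition, termination, episodes."""

import numpy as np
import pytest

from commonpool.game import (ConfigurationError, GameConfig,
                             RoundValidationError, apply_round, init_state,
                             run_episode, run_session, sample_episode_length,
                             sustainable_keep_fraction)
from commonpool.mechanisms import EqualMechanism
from commonpool.players import FreeRiderPlayer, SustainerPlayer


class TestInitState:
    def test_pool_starts_at_carrying_capacity(self):
        state = init_state(GameConfig(p=4, R0=200, r=0.4))
        assert state.R == 200 and state.t == 0
        assert np.all(state.prev_offers == 0)
        assert np.all(state.prev_contributions == 0)
        assert state.depleted_at is None

    def test_parameter_passthrough_and_degenerate_single_player(self):
        assert init_state(GameConfig(R0=1)).R == 1
        assert init_state(GameConfig(p=1)).R == 200

    @pytest.mark.parametrize("kwargs", [
        {"p": 0}, {"R0": 0}, {"r": -1.5},
        {"min_rounds": 25, "end_prob": 0.0},
        {"min_rounds": 25, "end_prob": 1.5},
        {"end_prob": 0.2},  # geometric rule without a minimum length
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GameConfig(**kwargs)


class TestApplyRound:
    def test_single_player_growth_credit(self):
        """An offer of 2 reciprocated with 1 yields surplus 1 and credits
        the pool with 1.4."""
        cfg = GameConfig(p=1, R0=200, r=0.4)
        state = init_state(cfg)
        state2, rec = apply_round(state, [2.0], [1.0], cfg)
        assert rec.surpluses[0] == pytest.approx(1.0)
        assert state2.R == pytest.approx(200 - 2 + 1.4)

    def test_replenishment_fixed_point(self, config):
        state = init_state(config)
        offers = [50.0] * 4
        contribs = [50.0 / 1.4] * 4
        state2, rec = apply_round(state, offers, contribs, config)
        assert state2.R == pytest.approx(200.0)

    def test_hand_evaluated_update(self, config):
        state = init_state(config)
        state.R = 150.0
        state2, rec = apply_round(state, [10] * 4, [10] * 4, config)
        # delta = -40 + 1.4 * 40 = 16
        assert state2.R == pytest.approx(166.0)
        assert rec.R_after == pytest.approx(166.0)

    def test_cap_binds(self, config):
        state = init_state(config)
        state.R = 195.0
        state2, _ = apply_round(state, [10] * 4, [10] * 4, config)
        assert state2.R == pytest.approx(200.0)  # 211 capped at R0

    def test_full_allocation_no_reciprocation_depletes(self, config):
        state = init_state(config)
        state.R = 100.0
        state2, rec = apply_round(state, [25] * 4, [0] * 4, config)
        assert state2.R == 0.0
        assert state2.depleted_at == 0

    def test_conservation_identity(self, config):
        rng = np.random.default_rng(0)
        state = init_state(config)
        for _ in range(50):
            w = rng.dirichlet(np.ones(5))
            offers = w[:4] * state.R
            contribs = rng.uniform(0, 1, 4) * offers
            state, rec = apply_round(state, offers, contribs, config)
            assert rec.offers.sum() + rec.retained == pytest.approx(
                rec.R_before, rel=1e-9)
            assert rec.R_after == pytest.approx(
                min(config.R0, rec.R_before - rec.offers.sum()
                    + 1.4 * rec.contributions.sum()), rel=1e-9)
            assert 0 <= state.R <= config.R0

    @pytest.mark.parametrize("offers,contribs,msg", [
        ([300, 0, 0, 0], [0] * 4, "offers sum"),
        ([-1, 0, 0, 0], [0] * 4, "negative offer at player index 0"),
        ([10] * 4, [11, 0, 0, 0], "exceeds offer at player index 0"),
        ([10] * 4, [0, -2, 0, 0], "negative contribution at player index 1"),
    ])
    def test_validation_names_offender(self, config, offers, contribs, msg):
        state = init_state(config)
        with pytest.raises(RoundValidationError, match=msg):
            apply_round(state, offers, contribs, config)


class TestEpisodeLength:
    def test_fixed_horizon(self):
        rng = np.random.default_rng(0)
        assert sample_episode_length(GameConfig(T=40), rng) == 40

    def test_immediate_geometric_termination(self):
        cfg = GameConfig(min_rounds=25, end_prob=1.0)
        rng = np.random.default_rng(0)
        assert sample_episode_length(cfg, rng) == 25

    def test_geometric_mean_length(self):
        """Mean of min_rounds + Geometric(0.2) survival count is 29."""
        cfg = GameConfig(min_rounds=25, end_prob=0.2)
        rng = np.random.default_rng(123)
        draws = [sample_episode_length(cfg, rng) for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(29.0, abs=0.1)
        assert min(draws) >= 25


class TestRunEpisode:
    def test_free_riders_under_equal_split(self, config):
        """Four pure free riders exhaust the pool on round 1; total surplus
        is exactly the initial pool."""
        players = [FreeRiderPlayer() for _ in range(4)]
        log = run_episode(EqualMechanism(), players, config, seed=0)
        assert log.horizon == 40
        assert np.allclose(log.rounds[0].offers, 50.0)
        assert log.rounds[0].R_after == 0.0
        assert log.total_surplus() == pytest.approx(200.0)
        # after depletion everything is zero
        for rec in log.rounds[1:]:
            assert np.all(rec.offers == 0)
            assert np.all(rec.contributions == 0)

    def test_sustainers_hold_the_pool_at_capacity(self, config):
        players = [SustainerPlayer() for _ in range(4)]
        log = run_episode(EqualMechanism(), players, config, seed=0)
        assert np.allclose(log.pool_trajectory(), 200.0)

    def test_bitwise_reproducible(self, config, mixed_population):
        logs = []
        for _ in range(2):
            players = mixed_population.sample(np.random.default_rng(5))
            logs.append(run_episode(EqualMechanism(), players, config, seed=7))
        a, b = logs
        assert a.offers_matrix().tobytes() == b.offers_matrix().tobytes()
        assert a.contributions_matrix().tobytes() == b.contributions_matrix().tobytes()

    def test_truncate_on_depletion_flag(self):
        cfg = GameConfig(truncate_on_depletion=True)
        players = [FreeRiderPlayer() for _ in range(4)]
        log = run_episode(EqualMechanism(), players, cfg, seed=0)
        assert log.horizon == 1

    def test_consecutive_game_session_resets_pool(self):
        cfg = GameConfig(min_rounds=25, end_prob=0.2, n_consecutive_games=3)
        players = [SustainerPlayer() for _ in range(4)]
        logs = run_session(EqualMechanism(), players, cfg, seed=0)
        assert [log.game_index for log in logs] == [0, 1, 2]
        for log in logs:
            assert log.rounds[0].R_before == 200.0
            assert log.horizon >= 25

    def test_integer_contribution_mode(self):
        cfg = GameConfig(integer_contributions=True)
        players = [SustainerPlayer() for _ in range(4)]
        log = run_episode(EqualMechanism(), players, cfg, seed=0)
        contribs = log.contributions_matrix()
        assert np.allclose(contribs, np.floor(contribs))
        # 50 / 1.4 = 35.71... floors to 35
        assert log.rounds[0].contributions[0] == 35.0


def test_sustainable_keep_fraction_rounds_to_29_percent():
    frac = sustainable_keep_fraction(0.4)
    assert frac == pytest.approx(2 / 7)
    assert round(100 * frac) == 29
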