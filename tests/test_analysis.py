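"""Metrics: Gini, per-game summaries, exclusions, lagged regressions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commonpool.analysis import (episode_metrics, exclusion_events, gini,
                                 lagged_offer_regression, summarize_condition)
from commonpool.game import GameConfig, run_episode
from commonpool.mechanisms import EqualMechanism, ProportionalMechanism
from commonpool.players import (ArchetypeSpec, FreeRiderPlayer, Population,
                                SustainerPlayer, generate_fixture_logs)

from conftest import make_log


def gini_pairwise_oracle(x):
    """O(n^2) definition: mean |x_i - x_j| over all ordered pairs, divided
    by twice the mean."""
    x = np.asarray(x, dtype=float)
    if x.sum() == 0:
        return 0.0
    diffs = np.abs(x[:, None] - x[None, :])
    return diffs.mean() / (2 * x.mean())


class TestGini:
    def test_examples(self):
        assert gini([5, 5, 5, 5]) == 0.0
        assert gini([1, 0, 0, 0]) == pytest.approx(0.75)
        assert gini([0, 0, 0, 0]) == 0.0  # collapse: nobody gets anything

    def test_scale_invariance(self):
        x = [3.0, 1.0, 4.0, 1.5]
        assert gini(np.array(x) * 2) == pytest.approx(gini(x))

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            gini([1.0, -0.5])

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 100))
    def test_matches_pairwise_oracle(self, seed, n):
        x = np.random.default_rng(seed).uniform(0, 50, size=n)
        assert gini(x) == pytest.approx(gini_pairwise_oracle(x), abs=1e-12)


class TestEpisodeMetrics:
    def test_all_sustainer_game(self, config):
        log = run_episode(EqualMechanism(), [SustainerPlayer() for _ in range(4)],
                          config, seed=0)
        m = episode_metrics(log)
        assert m.sustained and m.depletion_trial == 40
        assert m.surplus_gini == 0.0
        assert m.mean_active_players == 4.0

    def test_free_rider_collapse_game(self, config):
        log = run_episode(EqualMechanism(), [FreeRiderPlayer() for _ in range(4)],
                          config, seed=0)
        m = episode_metrics(log)
        assert m.total_surplus == pytest.approx(200.0)
        assert m.depletion_trial == 1 and not m.sustained
        assert m.mean_active_players == pytest.approx(4 / 40)

    def test_constructed_surplus_gini(self):
        offers = [[1, 0]] * 3
        contribs = [[0, 0]] * 3
        log = make_log(offers, contribs)
        m = episode_metrics(log)
        assert np.allclose(m.per_player_surplus, [3, 0])
        assert m.surplus_gini == pytest.approx(0.5)

    def test_relabelling_invariance(self, config, mixed_population):
        log = generate_fixture_logs(mixed_population, ["equal"], 1, config,
                                    seed=4)[0]
        m = episode_metrics(log)
        perm = np.array([3, 1, 0, 2])
        for rec in log.rounds:
            rec.offers[:] = rec.offers[perm]
            rec.contributions[:] = rec.contributions[perm]
            rec.surpluses[:] = rec.surpluses[perm]
        m2 = episode_metrics(log)
        assert m2.total_surplus == pytest.approx(m.total_surplus)
        assert m2.surplus_gini == pytest.approx(m.surplus_gini)
        assert np.allclose(m2.per_player_surplus, m.per_player_surplus[perm])


class TestExclusions:
    def test_hand_traced_reinclusion(self):
        col = [50, 0.5, 0.2, 30, 30, 30]
        offers = np.column_stack([col, [30] * 6])
        log = make_log(offers, np.zeros_like(offers))
        events = exclusion_events(log)
        assert len(events) == 1
        ev = events[0]
        assert (ev.player, ev.start_trial, ev.duration, ev.reincluded) == \
            (0, 2, 2, True)

    def test_no_events_when_always_included(self):
        offers = np.full((5, 2), 10.0)
        log = make_log(offers, np.zeros_like(offers))
        assert exclusion_events(log) == []

    def test_terminal_exclusion_not_reincluded(self):
        col = [50.0] * 38 + [0.0, 0.0]
        offers = np.column_stack([col, [30.0] * 40])
        log = make_log(offers, np.zeros_like(offers))
        ev = exclusion_events(log)[0]
        assert (ev.start_trial, ev.duration, ev.reincluded) == (39, 2, False)

    def test_durations_partition_sub_threshold_runs(self, config,
                                                    mixed_population):
        logs = generate_fixture_logs(mixed_population, ["proportional"], 4,
                                     config, seed=6)
        for log in logs:
            offers = log.offers_matrix()
            for i in range(4):
                dur = sum(ev.duration for ev in exclusion_events(log)
                          if ev.player == i)
                # count sub-threshold trials inside runs opened by an
                # inclusion -> exclusion transition
                col = offers[:, i] < 1.0
                run_total = 0
                in_run = False
                for t in range(len(col)):
                    if col[t]:
                        if t > 0 and not col[t - 1]:
                            in_run = True
                        if in_run:
                            run_total += 1
                    else:
                        in_run = False
                assert dur == run_total


class TestLaggedRegression:
    def test_exact_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        logs = []
        for g in range(6):
            contribs = rng.uniform(0, 5, size=(12, 2))
            offers = np.zeros_like(contribs)
            offers[0] = 10.0
            offers[1:] = 2.0 * contribs[:-1]
            logs.append(make_log(offers, np.minimum(contribs, offers)))
        # rebuild exact relation (make_log clipped contributions to offers)
        for log in logs:
            for t in range(1, len(log.rounds)):
                log.rounds[t].offers[:] = 2.0 * log.rounds[t - 1].contributions
        res = lagged_offer_regression(logs)
        lag_m1 = res.median[list(res.lags).index(-1)]
        others = [m for lag, m in zip(res.lags, res.median) if lag != -1]
        assert lag_m1 == pytest.approx(2.0, abs=1e-8)
        assert np.allclose(others, 0.0, atol=1e-8)

    def test_constant_offers_yield_zero_weights(self):
        offers = np.full((12, 2), 10.0)
        contribs = np.random.default_rng(1).uniform(0, 5, size=(12, 2))
        log = make_log(offers, np.minimum(contribs, offers))
        res = lagged_offer_regression([log])
        assert np.allclose(res.median, 0.0)

    def test_proportional_mechanism_mass_at_lag_minus_one(self, config):
        pop = Population([
            ArchetypeSpec("sustainer", noise_sd=0.1),
            ArchetypeSpec("conditional", noise_sd=0.1),
        ])
        logs = generate_fixture_logs(pop, ["proportional"], 8, config, seed=7)
        res = lagged_offer_regression(logs, normalize=True)
        idx = {lag: i for i, lag in enumerate(res.lags)}
        m1 = abs(res.median[idx[-1]])
        for lag in res.lags:
            if lag != -1:
                assert abs(res.median[idx[lag]]) < m1


class TestConditionSummary:
    def test_single_game_mean_is_itself(self, config):
        log = run_episode(EqualMechanism(), [SustainerPlayer() for _ in range(4)],
                          config, seed=0)
        table = summarize_condition([episode_metrics(log)])
        assert table["n_games"] == 1
        assert table["mean"]["total_surplus"] == pytest.approx(
            log.total_surplus())
        assert table["corr_surplus_gini_sustained"] is None

    def test_identical_games_have_undefined_correlation(self, config):
        log = run_episode(EqualMechanism(), [SustainerPlayer() for _ in range(4)],
                          config, seed=0)
        ms = [episode_metrics(log)] * 3
        table = summarize_condition(ms)
        assert table["corr_surplus_gini_sustained"] is None

    def test_three_game_arithmetic(self):
        logs = [
            make_log([[4, 0]] * 2, [[0, 0]] * 2),
            make_log([[2, 2]] * 2, [[0, 0]] * 2),
            make_log([[0, 8]] * 2, [[0, 0]] * 2),
        ]
        ms = [episode_metrics(log) for log in logs]
        table = summarize_condition(ms)
        assert table["mean"]["total_surplus"] == pytest.approx((8 + 8 + 16) / 3)
        assert table["mean"]["surplus_gini"] == pytest.approx(
            np.mean([0.5, 0.0, 0.5]))
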