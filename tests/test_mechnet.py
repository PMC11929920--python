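"""Graph-network mechanism: structure, equivariance, feasibility, training."""

import numpy as np
import pytest

from commonpool.autodiff import Var
from commonpool.game import GameConfig, GameState, init_state, run_episode
from commonpool.mechanisms import EqualMechanism
from commonpool.mechnet import (GNNMechanism, MechanismHyper, MechCheckpoint,
                                TrainConfig, build_graph,
                                init_mechanism_params, mechanism_forward,
                                offers_from_weights, select_mechanism,
                                train_mechanism)
from commonpool.players import ArchetypeSpec, Population, SustainerPlayer

SMALL = MechanismHyper(hidden=8, memory=4)


def forward_once(params, hyper, nodes, u, memory=None):
    if memory is None and hyper.recurrent:
        memory = np.zeros((1, hyper.p, hyper.memory))
    w, m = mechanism_forward(
        {k: Var(x) for k, x in params.items()}, hyper,
        Var(nodes[None]), Var(np.atleast_1d(u)[None]),
        Var(memory) if memory is not None else None)
    return w.value[0], (m.value[0] if m is not None else None)


class TestGraphConstruction:
    def test_node_and_edge_counts(self, config):
        graph = build_graph(init_state(config), config)
        assert graph.nodes.shape == (4, 3)
        assert graph.edges is None  # edge attributes start empty
        from commonpool.mechnet import _edge_pairs

        assert len(_edge_pairs(4)) == 12

    def test_opening_round_features(self, config):
        graph = build_graph(init_state(config), config)
        assert np.allclose(graph.nodes[:, :2], 0.0)
        assert np.allclose(graph.nodes[:, 2], 1.0)  # pool at capacity
        assert graph.globals_[0] == pytest.approx(1.0)


class TestForward:
    def test_weights_on_simplex(self):
        rng = np.random.default_rng(0)
        params = init_mechanism_params(SMALL, rng)
        nodes = rng.uniform(0, 1, size=(4, 3))
        w, _ = forward_once(params, SMALL, nodes, [0.5])
        assert w.shape == (5,)
        assert np.all(w > 0) and w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_opening_move(self):
        """Symmetric round-0 inputs force equal player weights for any
        parameter draw."""
        for seed in range(5):
            params = init_mechanism_params(SMALL, np.random.default_rng(seed))
            nodes = np.tile([0.0, 0.0, 1.0], (4, 1))
            w, _ = forward_once(params, SMALL, nodes, [1.0])
            assert np.allclose(w[:4], w[0], atol=1e-12)

    @pytest.mark.parametrize("recurrent", [True, False])
    def test_permutation_equivariance(self, recurrent):
        hyper = MechanismHyper(hidden=8, memory=4, recurrent=recurrent)
        rng = np.random.default_rng(1)
        for _ in range(5):
            params = init_mechanism_params(hyper, rng)
            nodes = rng.uniform(0, 1, size=(4, 3))
            mem = rng.normal(size=(1, 4, 4)) if recurrent else None
            perm = rng.permutation(4)
            w, m = forward_once(params, hyper, nodes, [0.7], mem)
            w_p, m_p = forward_once(
                params, hyper, nodes[perm], [0.7],
                mem[:, perm, :] if mem is not None else None)
            assert np.allclose(w_p[:4], w[perm], atol=1e-9)
            assert w_p[4] == pytest.approx(w[4], abs=1e-9)
            if recurrent:
                assert np.allclose(m_p, m[perm], atol=1e-9)

    def test_memory_distinguishes_histories(self, config):
        """The recurrent block conditions on the episode history: replaying
        a state with different accumulated memory changes the allocation."""
        rng = np.random.default_rng(3)
        params = init_mechanism_params(SMALL, rng)
        nodes = rng.uniform(0, 1, size=(4, 3))
        w_fresh, _ = forward_once(params, SMALL, nodes, [0.5])
        mem = rng.normal(size=(1, 4, 4))
        w_hist, _ = forward_once(params, SMALL, nodes, [0.5], mem)
        assert not np.allclose(w_fresh, w_hist, atol=0, rtol=1e-3)


class TestOffersFromWeights:
    def test_direct_product(self):
        offers, retained = offers_from_weights([0.2] * 5, 100.0)
        assert np.allclose(offers, 20.0) and retained == pytest.approx(20.0)

    def test_zero_pool(self):
        offers, retained = offers_from_weights([0.2] * 5, 0.0)
        assert np.all(offers == 0) and retained == 0.0

    def test_conservation(self):
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(5))
        offers, retained = offers_from_weights(w, 137.0)
        assert offers.sum() + retained == pytest.approx(137.0, rel=1e-12)


class TestLiveMechanism:
    @pytest.mark.parametrize("recurrent", [True, False])
    def test_feasibility_over_full_episode(self, config, recurrent):
        hyper = MechanismHyper(hidden=8, memory=4, recurrent=recurrent)
        params = init_mechanism_params(hyper, np.random.default_rng(0))
        mech = GNNMechanism(params, hyper)
        players = [SustainerPlayer() for _ in range(4)]
        log = run_episode(mech, players, config, seed=0)
        for rec in log.rounds:
            assert rec.offers.sum() + rec.retained == pytest.approx(
                rec.R_before, rel=1e-9)
            assert np.all(rec.offers >= 0)
        assert np.allclose(log.rounds[0].offers, log.rounds[0].offers[0])

    def test_deterministic_policy(self, config):
        params = init_mechanism_params(SMALL, np.random.default_rng(0))
        players = [SustainerPlayer() for _ in range(4)]
        a = run_episode(GNNMechanism(params, SMALL), players, config, seed=1)
        b = run_episode(GNNMechanism(params, SMALL), players, config, seed=1)
        assert a.offers_matrix().tobytes() == b.offers_matrix().tobytes()


class TestTrainingLoop:
    def test_short_training_is_deterministic(self, config, mixed_population):
        tc = TrainConfig(batch_size=2, total_updates=4, checkpoint_interval=4,
                         rollout_horizon=5, eval_episodes=2, seed=0)
        a = train_mechanism(mixed_population, tc, config, SMALL)[-1]
        b = train_mechanism(mixed_population, tc, config, SMALL)[-1]
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_pathwise_sample_mode_runs(self, config, mixed_population):
        tc = TrainConfig(batch_size=2, total_updates=2, checkpoint_interval=2,
                         rollout_horizon=5, eval_episodes=2, seed=0,
                         gradient_mode="pathwise_sample")
        pop = Population([ArchetypeSpec("sustainer")])
        # scripted players have no sampling; exercise the mode via BC clones
        from commonpool.cloning import BCEnsemble, BCHyper, init_bc_params

        hyper = BCHyper(n_bins=5, encoder_widths=(8,), memory_width=4,
                        decoder_widths=(8,))
        members = [(init_bc_params(hyper, np.random.default_rng(0)), hyper)]
        cks = train_mechanism(BCEnsemble(members=members), tc, config, SMALL)
        assert len(cks) == 1 and np.isfinite(cks[-1].train_surplus)

    def test_select_mechanism_tie_breaks_to_later(self):
        params = init_mechanism_params(SMALL, np.random.default_rng(0))
        cks = [
            MechCheckpoint(step=1, params=params, hyper=SMALL,
                           train_surplus=0.0, eval_surplus=5.0),
            MechCheckpoint(step=2, params=params, hyper=SMALL,
                           train_surplus=0.0, eval_surplus=5.0),
            MechCheckpoint(step=3, params=params, hyper=SMALL,
                           train_surplus=0.0, eval_surplus=4.0),
        ]
        assert select_mechanism(cks).step == 2
        assert select_mechanism(cks[:1]).step == 1
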