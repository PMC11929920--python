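"""Graph-network allocation mechanism and its gradient training loop.

The mechanism observes each round as a fully connected directed graph:
one vertex per player carrying (previous endowment, previous
contribution, current pool), empty edge attributes, and the pool as the
global attribute (all normalised).  Two graph blocks are applied —
edges, then nodes, then the global, with shared update functions and sum
aggregation, which makes the policy permutation-equivariant and its
opening move uniform.  The second block's node update is a GRU whose
hidden state persists across rounds of an episode.  The four node
outputs and the global output are softmax-normalised into five
allocation weights: four offers plus the share retained in the pool.

Training maximises cumulative player surplus by backpropagating through
a differentiable rollout of the game against virtual players acting via
their expected contribution (or a straight-through sampled variant).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Var
from .cloning import BCEnsemble, BCHyper, _bc_step
from .game import GameConfig, GameState, run_episode
from .mechanisms import MechanismPolicy
from .nn import (Adam, LRSchedule, apply_linear, gru_step, init_gru,
                 init_linear, read_grads, wrap_params)
from .players import ArchetypeSpec, Population

__all__ = [
    "GraphObservation",
    "MechanismHyper",
    "TrainConfig",
    "MechCheckpoint",
    "build_graph",
    "init_mechanism_params",
    "gnn_block",
    "mechanism_forward",
    "offers_from_weights",
    "GNNMechanism",
    "train_mechanism",
    "select_mechanism",
    "evaluate_mechanism",
]


@dataclass
class GraphObservation:
    """Node features (p, 3), empty edge attributes, global pool feature."""

    nodes: np.ndarray
    edges: Optional[np.ndarray]
    globals_: np.ndarray


def build_graph(state: GameState, config: GameConfig) -> GraphObservation:
    norm = config.norm
    nodes = np.stack(
        [
            state.prev_offers / norm,
            state.prev_contributions / norm,
            np.full(config.p, state.R / norm),
        ],
        axis=-1,
    )
    return GraphObservation(nodes=nodes, edges=None,
                            globals_=np.array([state.R / norm]))


@dataclass(frozen=True)
class MechanismHyper:
    """Network sizes of the two graph blocks."""

    hidden: int = 32        # width of every nonlinear FC update
    memory: int = 16        # GRU hidden size of the block-2 node update
    recurrent: bool = True  # False gives the memoryless variant
    node_dim: int = 3
    global_dim: int = 1
    p: int = 4


def init_mechanism_params(hyper: MechanismHyper,
                          rng: np.random.Generator) -> dict:
    params: dict = {}
    H, dv, du = hyper.hidden, hyper.node_dim, hyper.global_dim
    # block 1: edge inputs are (v_s, v_r, u) — edge attributes start empty
    init_linear(params, "b1.edge", 2 * dv + du, H, rng)
    init_linear(params, "b1.node", H + dv + du, H, rng)
    init_linear(params, "b1.glob", H + H + du, H, rng)
    # block 2 consumes the block-1 graph (all attribute widths H)
    init_linear(params, "b2.edge", 3 * H + H, H, rng)
    if hyper.recurrent:
        init_gru(params, "b2.node_gru", H + H + H, hyper.memory, rng)
    else:
        init_linear(params, "b2.node_fc", H + H + H, hyper.memory, rng)
    init_linear(params, "b2.node_proj", hyper.memory, H, rng)
    init_linear(params, "b2.node_out", H, 1, rng)
    init_linear(params, "b2.glob_proj", H + 1 + H, H, rng)
    init_linear(params, "b2.glob_out", H, 1, rng)
    return params


def _edge_pairs(p: int) -> list[tuple[int, int]]:
    return [(s, r) for s in range(p) for r in range(p) if s != r]


def _edge_index(p: int):
    pairs = _edge_pairs(p)
    s_idx = np.array([s for s, _ in pairs])
    r_idx = np.array([r for _, r in pairs])
    # incoming[r] = indices of edges whose receiver is r (p - 1 each)
    incoming = np.array([[ei for ei, (_, rr) in enumerate(pairs) if rr == r]
                         for r in range(p)])
    return s_idx, r_idx, incoming


def _apply_flat(v: dict, name: str, x: Var, act: bool = True) -> Var:
    """Shared linear map over the last axis of a (..., d) tensor."""
    shape = x.shape
    out = apply_linear(v, name, x.reshape(-1, shape[-1]))
    if act:
        out = ad.relu(out)
    return out.reshape(*shape[:-1], out.shape[-1])


def gnn_block(
    v: dict,
    prefix: str,
    nodes: Var,
    u: Var,
    p: int,
    edges: Optional[Var] = None,
) -> tuple[Var, Var, Var]:
    """Generic single graph block: edges, then nodes, then the global.

    ``nodes`` has shape (B, p, dv), ``u`` (B, du).  Returns updated
    (edges (B, E, de'), nodes (B, p, dv'), globals (B, du')) where the
    same update functions are shared across all edges and nodes and
    aggregation is by sum — the source of permutation equivariance.
    """
    s_idx, r_idx, incoming = _edge_index(p)
    B = nodes.shape[0]
    E = len(s_idx)
    u_e = ad.broadcast_to(u.reshape(B, 1, -1), (B, E, u.shape[-1]))
    parts = [] if edges is None else [edges]
    parts += [nodes[:, s_idx, :], nodes[:, r_idx, :], u_e]
    new_edges = _apply_flat(v, f"{prefix}.edge", ad.concat(parts, axis=-1))
    agg = new_edges[:, incoming, :].sum(axis=2)  # (B, p, H)
    u_n = ad.broadcast_to(u.reshape(B, 1, -1), (B, p, u.shape[-1]))
    new_nodes = _apply_flat(v, f"{prefix}.node",
                            ad.concat([agg, nodes, u_n], axis=-1))
    new_u = ad.relu(apply_linear(
        v, f"{prefix}.glob",
        ad.concat([new_edges.sum(axis=1), new_nodes.sum(axis=1), u], axis=-1)))
    return new_edges, new_nodes, new_u


def mechanism_forward(
    v: dict,
    hyper: MechanismHyper,
    nodes: Var,
    u: Var,
    memory: Optional[Var],
) -> tuple[Var, Optional[Var]]:
    """Full two-block policy.

    ``nodes`` (B, p, 3), ``u`` (B, 1), ``memory`` (B, p, memory) or None.
    Returns (weights (B, p + 1) on the simplex, new memory).
    """
    p = hyper.p
    s_idx, r_idx, incoming = _edge_index(p)
    B = nodes.shape[0]
    E = len(s_idx)
    e1, v1, u1 = gnn_block(v, "b1", nodes, u, p)
    u_e = ad.broadcast_to(u1.reshape(B, 1, -1), (B, E, u1.shape[-1]))
    e2 = _apply_flat(v, "b2.edge",
                     ad.concat([e1, v1[:, s_idx, :], v1[:, r_idx, :], u_e],
                               axis=-1))
    agg = e2[:, incoming, :].sum(axis=2)  # (B, p, H)
    u_n = ad.broadcast_to(u1.reshape(B, 1, -1), (B, p, u1.shape[-1]))
    x = ad.concat([agg, v1, u_n], axis=-1)
    if hyper.recurrent:
        h_flat = gru_step(v, "b2.node_gru", x.reshape(B * p, x.shape[-1]),
                          memory.reshape(B * p, hyper.memory))
        new_memory = h_flat.reshape(B, p, hyper.memory)
        h = new_memory
    else:
        h = _apply_flat(v, "b2.node_fc", x)
        new_memory = None
    node_scalars = _apply_flat(v, "b2.node_out",
                               _apply_flat(v, "b2.node_proj", h),
                               act=False)  # (B, p, 1)
    gproj = ad.relu(apply_linear(
        v, "b2.glob_proj",
        ad.concat([e2.sum(axis=1), node_scalars.sum(axis=1), u1], axis=-1)))
    glob_scalar = apply_linear(v, "b2.glob_out", gproj)  # (B, 1)
    logits = ad.concat([node_scalars.reshape(B, p), glob_scalar], axis=-1)
    weights = ad.softmax(logits, axis=-1)
    return weights, new_memory


def offers_from_weights(weights: np.ndarray, R: float) -> tuple[np.ndarray, float]:
    """Split the pool by the softmax weights: p offers plus retained share."""
    w = np.asarray(weights, dtype=float)
    offers = w[:-1] * R
    return offers, float(w[-1] * R)


class GNNMechanism(MechanismPolicy):
    """Trained (or freshly initialised) graph-network mechanism as a live
    allocation policy; per-episode node memory is cleared by ``reset``."""

    def __init__(self, params: dict, hyper: MechanismHyper,
                 name: str = "gnn"):
        self.params = params
        self.hyper = hyper
        self.name = name
        self.reset()

    def reset(self) -> None:
        self._mem = (np.zeros((1, self.hyper.p, self.hyper.memory))
                     if self.hyper.recurrent else None)
        self._vars = {k: Var(w) for k, w in self.params.items()}

    def act(self, state: GameState, config: GameConfig):
        graph = build_graph(state, config)
        weights, mem = mechanism_forward(
            self._vars, self.hyper,
            Var(graph.nodes[None]), Var(graph.globals_[None]),
            Var(self._mem) if self._mem is not None else None,
        )
        if mem is not None:
            self._mem = mem.value
        return offers_from_weights(weights.value[0], state.R)


# -- differentiable virtual players ----------------------------------------


class DiffScriptedPlayer:
    """Differentiable counterpart of the scripted archetypes (expected
    action: archetype noise enters at its mean, i.e. not at all)."""

    def __init__(self, spec: ArchetypeSpec, r: float = 0.4):
        self.spec = spec
        self.r = r

    def init_mem(self) -> dict:
        return {"prev_offers": None, "triggered": False}

    def step(self, offers: Var, prev_c: Var, pool: Var, i: int, mem: dict):
        e = offers[:, i]
        frac_target = 1.0 / (1.0 + self.r)
        kind = self.spec.kind
        if kind == "free_rider":
            c = e * (self.spec.base_fraction or 0.0)
        elif kind == "sustainer":
            c = e * frac_target
        elif kind == "conditional":
            po = mem["prev_offers"]
            if po is None:
                c = e * frac_target
            else:
                p = offers.shape[1]
                fracs = []
                for j in range(p):
                    if j == i:
                        continue
                    denom = ad.maximum(po[:, j], 1.0)
                    fracs.append(ad.clip(prev_c[:, j] / denom, 0.0, 1.0))
                mean_frac = ad.vsum(fracs) / float(len(fracs))
                # fall back to the target where others were unobservable
                observable = po.value[:, [j for j in range(p) if j != i]].max(axis=1) >= 1.0
                c = e * ad.where(observable, mean_frac, frac_target)
        elif kind == "grim":
            po = mem["prev_offers"]
            if po is not None and not bool(np.all(mem["triggered"])):
                p = offers.shape[1]
                trig = np.zeros(e.shape, dtype=bool)
                for j in range(p):
                    if j == i:
                        continue
                    seen = po.value[:, j] >= 1.0
                    frac = np.divide(prev_c.value[:, j],
                                     np.maximum(po.value[:, j], 1e-9))
                    trig |= seen & (frac < self.spec.trigger_threshold)
                mem["triggered"] = np.logical_or(mem["triggered"], trig)
            c = e * ad.where(np.broadcast_to(mem["triggered"], e.shape),
                             0.0, frac_target)
        else:
            raise ValueError(kind)
        mem["prev_offers"] = offers
        return c, mem


class DiffBCPlayer:
    """A behavioural clone acting differentiably.

    ``expected_action`` uses c = e * sum_b softmax_b (b + 0.5) / N.
    ``pathwise_sample`` draws the categorical-uniform sample but carries the
    expectation's gradient (a straight-through estimator of the sample
    gradient)."""

    def __init__(self, params: dict, hyper: BCHyper,
                 mode: str = "expected_action",
                 rng: Optional[np.random.Generator] = None):
        self.params = params
        self.hyper = hyper
        self.mode = mode
        self.rng = rng or np.random.default_rng(0)
        self._vars = {k: Var(w) for k, w in params.items()}

    def init_mem(self):
        if self.hyper.recurrent:
            return Var(np.zeros((1, self.hyper.memory_width)))
        return None

    def step(self, offers: Var, prev_c: Var, pool: Var, i: int, mem):
        p = offers.shape[1]
        roll = lambda a: ad.concat([a[:, i:], a[:, :i]], axis=1)
        norm = 200.0
        obs = ad.concat([roll(offers) / norm, roll(prev_c) / norm,
                         pool.reshape(-1, 1) / norm], axis=-1)
        logits, mem = _bc_step(self._vars, self.hyper, obs, mem)
        probs = ad.softmax(logits, axis=-1)
        N = self.hyper.n_bins
        centers = (np.arange(N) + 0.5) / N
        exp_frac = (probs * centers).sum(axis=-1)
        e = offers[:, i]
        if self.mode == "pathwise_sample":
            pr = probs.value[0] / probs.value[0].sum()
            b = int(self.rng.choice(N, p=pr))
            u = float(self.rng.random())
            sampled = (b + u) / N
            # sampled value with the expectation's gradient attached
            frac = exp_frac + (sampled - float(exp_frac.value[0]))
        else:
            frac = exp_frac
        return e * frac, mem


def _make_diff_players(source, rng: np.random.Generator, p: int, r: float,
                       mode: str):
    if isinstance(source, BCEnsemble):
        idx = rng.integers(len(source.members), size=p)
        return [DiffBCPlayer(*source.members[i], mode=mode,
                             rng=np.random.default_rng(rng.integers(2**31)))
                for i in idx]
    if isinstance(source, Population):
        sidx = rng.choice(len(source.specs), size=p, replace=True,
                          p=source.weights)
        return [DiffScriptedPlayer(source.specs[i], r=r) for i in sidx]
    raise TypeError(f"cannot build virtual players from {type(source)!r}")


def _eval_players(source, rng: np.random.Generator, p: int):
    if isinstance(source, BCEnsemble):
        return source.sample_players(rng, p)
    if isinstance(source, Population):
        return source.sample(rng)
    raise TypeError(type(source))


# -- training ---------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe for the mechanism."""

    batch_size: int = 256
    lr_start: float = 1e-3
    lr_decay: float = 0.05
    lr_interval: int = 1000
    lr_floor: float = 1e-5
    total_updates: int = 500_000
    checkpoint_interval: int = 50_000
    rollout_horizon: int = 40
    gradient_mode: str = "expected_action"  # or "pathwise_sample"
    eval_episodes: int = 32
    seed: int = 0


@dataclass
class MechCheckpoint:
    step: int
    params: dict
    hyper: MechanismHyper
    train_surplus: float
    eval_surplus: Optional[float] = None


def _diff_rollout(v: dict, hyper: MechanismHyper, players, horizon: int,
                  game_config: GameConfig) -> Var:
    """Differentiable episode; returns total surplus (scalar Var)."""
    p = game_config.p
    norm = game_config.norm
    R = Var(np.array([game_config.R0]))
    prev_e = Var(np.zeros((1, p)))
    prev_c = Var(np.zeros((1, p)))
    mech_mem = (Var(np.zeros((1, p, hyper.memory)))
                if hyper.recurrent else None)
    mems = [pl.init_mem() for pl in players]
    total = Var(np.zeros(1))
    thr = game_config.offer_unit_threshold
    for _ in range(horizon):
        pool_feat = (R / norm).reshape(1, 1)
        nodes = ad.stack(
            [ad.concat([prev_e[:, i:i + 1] / norm, prev_c[:, i:i + 1] / norm,
                        pool_feat], axis=-1) for i in range(p)],
            axis=1,
        )
        weights, mech_mem = mechanism_forward(v, hyper, nodes, pool_feat,
                                              mech_mem)
        offers = weights[:, :p] * R.reshape(1, 1)
        contribs = []
        for i, pl in enumerate(players):
            c, mems[i] = pl.step(offers, prev_c, R, i, mems[i])
            c = ad.where(offers.value[:, i] >= thr, c, 0.0)
            contribs.append(c)
        c_all = ad.stack(contribs, axis=1)
        surplus = (offers - c_all).sum(axis=1)
        total = total + surplus
        delta = -offers.sum(axis=1) + (1.0 + game_config.r) * c_all.sum(axis=1)
        R = ad.maximum(ad.minimum(R + delta, game_config.R0), 0.0)
        prev_e, prev_c = offers, c_all
    return total.sum()


def evaluate_mechanism(params: dict, hyper: MechanismHyper, player_source,
                       game_config: GameConfig, n_episodes: int,
                       seed: int) -> float:
    """Mean total surplus over a fixed seed set (non-differentiable path)."""
    vals = []
    for ep in range(n_episodes):
        rng = np.random.default_rng((seed, ep))
        players = _eval_players(player_source, rng, game_config.p)
        mech = GNNMechanism(params, hyper)
        log = run_episode(mech, players, game_config, seed=int(seed + 31 * ep))
        vals.append(log.total_surplus())
    return float(np.mean(vals))


def train_mechanism(
    player_source: Union[BCEnsemble, Population],
    train_config: TrainConfig,
    game_config: Optional[GameConfig] = None,
    hyper: Optional[MechanismHyper] = None,
    verbose: bool = False,
) -> list[MechCheckpoint]:
    """Gradient-train the graph-network mechanism against virtual players.

    Each update rolls out ``batch_size`` episodes (each with a fresh group
    sampled with replacement from the player source), sums the cumulative
    player surplus, and ascends its gradient through the differentiable
    environment and players with Adam.  Periodic checkpoints carry an
    evaluation surplus measured on a fixed seed set.  Deterministic given
    ``train_config.seed`` in expected_action mode.
    """
    if game_config is None:
        game_config = GameConfig()
    if hyper is None:
        hyper = MechanismHyper(p=game_config.p)
    rng = np.random.default_rng(train_config.seed)
    params = init_mechanism_params(hyper, rng)
    opt = Adam(params)
    sched = LRSchedule(train_config.lr_start, train_config.lr_decay,
                       train_config.lr_interval, train_config.lr_floor)
    checkpoints: list[MechCheckpoint] = []
    for step in range(train_config.total_updates):
        v = wrap_params(params)
        total = None
        for _ in range(train_config.batch_size):
            players = _make_diff_players(player_source, rng, game_config.p,
                                         game_config.r,
                                         train_config.gradient_mode)
            surplus = _diff_rollout(v, hyper, players,
                                    train_config.rollout_horizon, game_config)
            total = surplus if total is None else total + surplus
        loss = -(total / float(train_config.batch_size))
        loss.backward()
        grads = read_grads(v)
        for k, g in grads.items():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(
                    f"non-finite gradient in {k} at update {step}")
        opt.step(grads, sched(step))
        is_last = step == train_config.total_updates - 1
        if (step + 1) % train_config.checkpoint_interval == 0 or is_last:
            ck = MechCheckpoint(
                step=step + 1, params=copy.deepcopy(params), hyper=hyper,
                train_surplus=float(-loss.value),
            )
            ck.eval_surplus = evaluate_mechanism(
                ck.params, hyper, player_source, game_config,
                train_config.eval_episodes, seed=train_config.seed + 997)
            checkpoints.append(ck)
            if verbose:
                print(f"[train-mech] step {step + 1} "
                      f"train {ck.train_surplus:.1f} eval {ck.eval_surplus:.1f}")
    return checkpoints


def select_mechanism(checkpoints: Sequence[MechCheckpoint],
                     eval_protocol=None) -> MechCheckpoint:
    """Checkpoint with the highest evaluation surplus; ties take the later
    checkpoint.  ``eval_protocol`` may re-score: (player_source,
    game_config, n_episodes, seed)."""
    if not checkpoints:
        raise ValueError("no checkpoints")
    scored = []
    for ck in checkpoints:
        if eval_protocol is not None:
            source, cfg, n_ep, seed = eval_protocol
            s = evaluate_mechanism(ck.params, ck.hyper, source, cfg, n_ep, seed)
        else:
            s = ck.eval_surplus if ck.eval_surplus is not None else ck.train_surplus
        scored.append(s)
    best = max(range(len(scored)), key=lambda i: (scored[i], i))
    return checkpoints[best]
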