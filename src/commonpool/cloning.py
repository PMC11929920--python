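"""Behavioural cloning: recurrent probabilistic virtual players.

A clone is an FC–GRU–FC network mapping a 9-dimensional observation
(the offers to all players this round, all players' contributions last
round, and the pool size — everything divided by the normaliser, 200 by
default) to logits over ``N`` bins that partition the proportion of the
received offer to reciprocate.  At inference the modal bin is taken and
the contribution drawn uniformly within it; a deterministic expectation
mode and full categorical sampling are also provided.

Observations are ego-centric: the focal player occupies slot 0 (players
saw themselves listed first), so one trained network can sit in any seat.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Var
from .game import EpisodeLog, GameConfig, run_episode
from .nn import (Adam, LRSchedule, apply_linear, gru_step, init_gru,
                 init_linear, read_grads, wrap_params)
from .players import PlayerPolicy

__all__ = [
    "BCHyper",
    "BCCheckpoint",
    "BCEnsemble",
    "contribution_to_bin",
    "bin_to_contribution",
    "init_bc_params",
    "bc_forward",
    "build_bc_dataset",
    "train_bc",
    "evaluate_cross_entropy",
    "BCPolicy",
    "bc_act",
    "assemble_ensemble",
    "score_checkpoints",
]


@dataclass(frozen=True)
class BCHyper:
    """Architecture and optimisation recipe for a behavioural clone."""

    n_bins: int = 10
    encoder_widths: tuple = (64, 64)
    memory_width: int = 32
    decoder_widths: tuple = (64, 64)
    recurrent: bool = True  # False gives the memoryless ablation
    batch_size: int = 256
    lr_start: float = 5e-4
    lr_decay: float = 0.05
    lr_interval: int = 1000
    lr_floor: float = 5e-6
    total_updates: int = 700_000
    checkpoint_interval: int = 50_000
    seed: int = 0
    p: int = 4

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        if min(self.encoder_widths) < 1 or min(self.decoder_widths) < 1:
            raise ValueError("layer widths must be positive")

    @property
    def obs_dim(self) -> int:
        return 2 * self.p + 1


# -- bin codec --------------------------------------------------------------


def contribution_to_bin(c: float, e: float, N: int) -> int:
    """Bin index of contribution ``c`` out of offer ``e``; bins partition the
    proportion space [0, 1] into N equal intervals, the top one closed."""
    if c < 0 or c > e + 1e-9:
        raise ValueError(f"contribution {c} outside [0, {e}]")
    if e <= 0:
        return 0
    return min(int(np.floor(N * c / e)), N - 1)


def bin_to_contribution(bin_index: int, u: float, e: float, N: int) -> float:
    """Contribution at uniform position ``u`` in [0,1) within the bin."""
    return e * (bin_index + u) / N


# -- network ---------------------------------------------------------------


def init_bc_params(hyper: BCHyper, rng: np.random.Generator) -> dict:
    params: dict = {}
    d = hyper.obs_dim
    for i, w in enumerate(hyper.encoder_widths):
        init_linear(params, f"enc{i}", d, w, rng)
        d = w
    if hyper.recurrent:
        init_gru(params, "gru", d, hyper.memory_width, rng)
        d = hyper.memory_width
    else:
        init_linear(params, "mem_fc", d, hyper.memory_width, rng)
        d = hyper.memory_width
    for i, w in enumerate(hyper.decoder_widths):
        init_linear(params, f"dec{i}", d, w, rng)
        d = w
    init_linear(params, "head", d, hyper.n_bins, rng)
    return params


def _bc_step(v: dict, hyper: BCHyper, x: Var, h: Optional[Var]) -> tuple[Var, Optional[Var]]:
    for i in range(len(hyper.encoder_widths)):
        x = ad.relu(apply_linear(v, f"enc{i}", x))
    if hyper.recurrent:
        h = gru_step(v, "gru", x, h)
        x = h
    else:
        x = ad.relu(apply_linear(v, "mem_fc", x))
    for i in range(len(hyper.decoder_widths)):
        x = ad.relu(apply_linear(v, f"dec{i}", x))
    logits = apply_linear(v, "head", x)
    return logits, h


def bc_forward(params: dict, obs_seq: np.ndarray,
               hyper: BCHyper) -> np.ndarray:
    """Logits for every step of an observation sequence (T, obs_dim) or a
    batch (T, B, obs_dim); recurrent state threads through the episode."""
    obs = np.asarray(obs_seq, dtype=float)
    squeeze = obs.ndim == 2
    if squeeze:
        obs = obs[:, None, :]
    v = {k: Var(w) for k, w in params.items()}
    T, B, _ = obs.shape
    h = Var(np.zeros((B, hyper.memory_width))) if hyper.recurrent else None
    out = []
    for t in range(T):
        logits, h = _bc_step(v, hyper, Var(obs[t]), h)
        out.append(logits.value)
    res = np.stack(out, axis=0)
    return res[:, 0, :] if squeeze else res


# -- dataset ---------------------------------------------------------------


def _ego_obs(offers: np.ndarray, prev_contribs: np.ndarray, pool: float,
             own_index: int, norm: float) -> np.ndarray:
    roll = lambda a: np.roll(np.asarray(a, dtype=float), -own_index)
    return np.concatenate([roll(offers), roll(prev_contribs), [pool]]) / norm


def build_bc_dataset(logs: Sequence[EpisodeLog], hyper: BCHyper):
    """One training sequence per player per game.

    Returns ``(obs, targets, mask)`` with shapes (S, T, obs_dim), (S, T),
    (S, T); sequences shorter than the longest are zero-padded.  Rounds
    where the focal offer is below one unit are masked out of the loss —
    the zero contribution there is forced, not behavioural.
    """
    seqs = []
    for log in logs:
        norm = log.config.norm
        for i in range(log.config.p):
            obs_rows, tgt_rows, mask_rows = [], [], []
            prev_c = np.zeros(log.config.p)
            for rec in log.rounds:
                obs_rows.append(_ego_obs(rec.offers, prev_c, rec.R_before, i, norm))
                e, c = rec.offers[i], rec.contributions[i]
                if e >= 1.0:
                    tgt_rows.append(contribution_to_bin(c, e, hyper.n_bins))
                    mask_rows.append(1.0)
                else:
                    tgt_rows.append(0)
                    mask_rows.append(0.0)
                prev_c = rec.contributions
            seqs.append((np.array(obs_rows), np.array(tgt_rows, dtype=int),
                         np.array(mask_rows)))
    if not seqs:
        raise ValueError("no episodes in the training logs")
    T_max = max(s[0].shape[0] for s in seqs)
    S = len(seqs)
    obs = np.zeros((S, T_max, hyper.obs_dim))
    tgt = np.zeros((S, T_max), dtype=int)
    mask = np.zeros((S, T_max))
    for j, (o, t_, m) in enumerate(seqs):
        obs[j, : o.shape[0]] = o
        tgt[j, : o.shape[0]] = t_
        mask[j, : o.shape[0]] = m
    return obs, tgt, mask


# -- training --------------------------------------------------------------


@dataclass
class BCCheckpoint:
    step: int
    params: dict
    train_loss: float
    hyper: BCHyper


def _sequence_loss(v: dict, hyper: BCHyper, obs: np.ndarray, tgt: np.ndarray,
                   mask: np.ndarray) -> Var:
    """Masked mean cross-entropy over a (B, T, ...) batch, BPTT over T."""
    B, T, _ = obs.shape
    h = Var(np.zeros((B, hyper.memory_width))) if hyper.recurrent else None
    total = None
    for t in range(T):
        logits, h = _bc_step(v, hyper, Var(obs[:, t, :]), h)
        logp = ad.log_softmax(logits, axis=-1)
        picked = logp[np.arange(B), tgt[:, t]]
        step_loss = -(picked * mask[:, t]).sum()
        total = step_loss if total is None else total + step_loss
    denom = max(mask.sum(), 1.0)
    return total / denom


def train_bc(logs: Sequence[EpisodeLog], hyper: BCHyper,
             verbose: bool = False) -> list[BCCheckpoint]:
    """Supervised imitation training; returns the checkpoint stream.

    Deterministic given ``hyper.seed``.  Minibatches are sequences (one per
    player per game); the loss is cross-entropy between predicted bin
    logits and the bin of the actually chosen contribution, optimised by
    Adam under the annealing learning-rate schedule.
    """
    obs, tgt, mask = build_bc_dataset(logs, hyper)
    rng = np.random.default_rng(hyper.seed)
    params = init_bc_params(hyper, rng)
    opt = Adam(params)
    sched = LRSchedule(hyper.lr_start, hyper.lr_decay, hyper.lr_interval,
                       hyper.lr_floor)
    S = obs.shape[0]
    checkpoints: list[BCCheckpoint] = []
    B = min(hyper.batch_size, S)
    for step in range(hyper.total_updates):
        idx = rng.choice(S, size=B, replace=False)
        v = wrap_params(params)
        loss = _sequence_loss(v, hyper, obs[idx], tgt[idx], mask[idx])
        loss.backward()
        opt.step(read_grads(v), sched(step))
        is_last = step == hyper.total_updates - 1
        if (step + 1) % hyper.checkpoint_interval == 0 or is_last:
            checkpoints.append(
                BCCheckpoint(step=step + 1, params=copy.deepcopy(params),
                             train_loss=float(loss.value), hyper=hyper)
            )
            if verbose:
                print(f"[train-bc] step {step + 1} loss {loss.value:.4f} "
                      f"lr {sched(step):.2e}")
    return checkpoints


def evaluate_cross_entropy(params: dict, hyper: BCHyper,
                           logs: Sequence[EpisodeLog]) -> float:
    """Mean held-out cross-entropy (nats per behavioural decision)."""
    obs, tgt, mask = build_bc_dataset(logs, hyper)
    v = {k: Var(w) for k, w in params.items()}
    loss = _sequence_loss(v, hyper, obs, tgt, mask)
    return float(loss.value)


# -- inference -------------------------------------------------------------


def bc_act(params: dict, hyper: BCHyper, logits: np.ndarray, e: float,
           mode: str, rng: Optional[np.random.Generator] = None) -> float:
    """Turn per-step bin logits into a contribution.

    ``argmax_uniform``: modal bin (ties to the lowest index), then uniform
    within the bin.  ``sample_full``: categorical over bins, then uniform.
    ``expectation``: deterministic mean  e * sum_b softmax_b (b + 0.5) / N.
    Offers below one unit force a zero contribution.
    """
    if e < 1.0:
        return 0.0
    N = hyper.n_bins
    z = logits - logits.max()
    probs = np.exp(z) / np.exp(z).sum()
    if mode == "argmax_uniform":
        b = int(np.argmax(logits))
        u = float(rng.random()) if rng is not None else 0.5
        c = bin_to_contribution(b, u, e, N)
    elif mode == "sample_full":
        b = int(rng.choice(N, p=probs))
        c = bin_to_contribution(b, float(rng.random()), e, N)
    elif mode == "expectation":
        c = e * float((probs * (np.arange(N) + 0.5)).sum()) / N
    else:
        raise ValueError(f"unknown inference mode {mode!r}")
    return min(max(c, 0.0), e)


class BCPolicy(PlayerPolicy):
    """A trained clone acting as a live player (satisfies PlayerPolicy)."""

    def __init__(self, params: dict, hyper: BCHyper,
                 mode: str = "argmax_uniform", seed: int = 0,
                 name: str = "bc", normalizer: float = 200.0):
        self.params = params
        self.hyper = hyper
        self.mode = mode
        self.normalizer = normalizer
        self._seed = seed
        self._episode = 0
        self.name = name
        self.reset()

    def reset(self) -> None:
        self._rng = np.random.default_rng((self._seed, self._episode))
        self._episode += 1
        self._h = np.zeros((1, self.hyper.memory_width))
        self._vars = {k: Var(w) for k, w in self.params.items()}

    def observe_and_act(self, offers_all, prev_contribs_all, pool, own_index):
        obs = _ego_obs(offers_all, prev_contribs_all, pool, own_index,
                       norm=self.normalizer)
        logits, h = _bc_step(self._vars, self.hyper, Var(obs[None, :]),
                             Var(self._h) if self.hyper.recurrent else None)
        if self.hyper.recurrent:
            self._h = h.value
        return bc_act(self.params, self.hyper, logits.value[0],
                      float(offers_all[own_index]), self.mode, self._rng)


@dataclass
class BCEnsemble:
    """A group of trained clones.

    ``sample_players`` draws members with replacement per episode slot (the
    training regime); ``fixed_slots`` pins one member per seat (the
    analysis regime)."""

    members: list  # list of (params, hyper)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    def sample_players(self, rng: np.random.Generator, p: int = 4,
                       mode: str = "argmax_uniform") -> list[BCPolicy]:
        idx = rng.integers(len(self.members), size=p)
        return [
            BCPolicy(*self.members[i], mode=mode,
                     seed=int(rng.integers(2**31)), name=f"bc{i}")
            for i in idx
        ]

    def fixed_slots(self, p: int = 4, mode: str = "argmax_uniform",
                    seed: int = 0) -> list[BCPolicy]:
        return [
            BCPolicy(*self.members[i % len(self.members)], mode=mode,
                     seed=seed + i, name=f"bc{i % len(self.members)}")
            for i in range(p)
        ]


def score_checkpoints(
    checkpoints: Sequence[BCCheckpoint],
    baseline_mechanisms: Sequence,
    random_mechanism,
    config: Optional[GameConfig] = None,
    n_episodes: int = 4,
    lam: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Selection score: surplus under hand-coded baselines minus
    ``lam`` times surplus under the random mechanism.

    High baseline surplus means the clone plays the game competently; low
    random-mechanism surplus penalises degenerate keep-everything clones
    that profit regardless of what they are offered."""
    scores = np.empty(len(checkpoints))
    for ci, ck in enumerate(checkpoints):
        def mean_surplus(mech) -> float:
            vals = []
            for ep in range(n_episodes):
                players = [
                    BCPolicy(ck.params, ck.hyper, seed=seed + 7 * ep + j)
                    for j in range(ck.hyper.p)
                ]
                log = run_episode(mech, players, config or GameConfig(),
                                  seed=seed + ep)
                vals.append(log.total_surplus())
            return float(np.mean(vals))

        base = np.mean([mean_surplus(m) for m in baseline_mechanisms])
        rand = mean_surplus(random_mechanism)
        scores[ci] = base - lam * rand
    return scores


def assemble_ensemble(
    checkpoints: Sequence[BCCheckpoint],
    m: int = 4,
    baseline_mechanisms: Optional[Sequence] = None,
    random_mechanism=None,
    config: Optional[GameConfig] = None,
    n_episodes: int = 4,
    lam: float = 1.0,
    seed: int = 0,
) -> BCEnsemble:
    """Select the top-m checkpoints by the simulation score above."""
    from .mechanisms import (EqualMechanism, MixedMechanism,
                             ProportionalMechanism, RandomMechanism)

    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    if baseline_mechanisms is None:
        baseline_mechanisms = [EqualMechanism(), MixedMechanism(),
                               ProportionalMechanism()]
    if random_mechanism is None:
        random_mechanism = RandomMechanism(seed=seed)
    if len(checkpoints) <= m:
        chosen = list(checkpoints)
    else:
        scores = score_checkpoints(checkpoints, baseline_mechanisms,
                                   random_mechanism, config, n_episodes,
                                   lam, seed)
        order = np.argsort(-scores, kind="stable")[:m]
        chosen = [checkpoints[i] for i in order]
    return BCEnsemble(members=[(ck.params, ck.hyper) for ck in chosen])
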