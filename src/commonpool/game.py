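"""Iterated multiplayer trust game over a regenerating common pool.

On each round a mechanism (the social planner) splits the current pool
``R_t`` into offers ``e_i`` to the ``p`` players plus a retained amount.
Each player chooses a contribution ``0 <= c_i <= e_i`` back to the pool;
contributions grow by the factor ``(1 + r)`` on return, and the player's
surplus for the round is ``s_i = e_i - c_i``.  The pool update is

    R_{t+1} = min(R0, R_t - sum(e) + (1 + r) * sum(c))

so the pool is capped at its carrying capacity ``R0`` and, once at zero,
can never recover (no offers can be made from an empty pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GameConfig",
    "GameState",
    "RoundRecord",
    "EpisodeLog",
    "init_state",
    "apply_round",
    "sample_episode_length",
    "run_episode",
    "run_session",
    "sustainable_keep_fraction",
]

_REL_TOL = 1e-9


class ConfigurationError(ValueError):
    """Raised for an invalid game configuration."""


class RoundValidationError(ValueError):
    """Raised when offers or contributions violate the game contract."""


@dataclass(frozen=True)
class GameConfig:
    """Static parameters of the trust game.

    Parameters
    ----------
    p : number of players (>= 1; the canonical game uses 4).
    R0 : initial and maximum pool size, in resource units.
    r : growth factor applied to contributions returned to the pool.
    T : fixed episode horizon in rounds (used when ``end_prob`` is None).
    min_rounds, end_prob : geometric termination rule — the episode lasts
        at least ``min_rounds`` rounds and afterwards ends with probability
        ``end_prob`` after each additional round.
    n_consecutive_games : number of games played back to back by one group.
    offer_unit_threshold : offers below this are undeliverable in practice —
        the receiving player is forced to contribute 0; also the depletion /
        active-player threshold used by the analysis metrics.
    integer_contributions : restrict contributions to whole units, matching
        an interface where reciprocation is incremented in integers.
    normalizer : divisor applied to observations fed to neural players and
        mechanisms (defaults to R0).
    truncate_on_depletion : end the episode once the pool falls below
        ``offer_unit_threshold`` instead of running out the horizon.
    """

    p: int = 4
    R0: float = 200.0
    r: float = 0.4
    T: int = 40
    min_rounds: Optional[int] = None
    end_prob: Optional[float] = None
    n_consecutive_games: int = 1
    offer_unit_threshold: float = 1.0
    integer_contributions: bool = False
    normalizer: Optional[float] = None
    truncate_on_depletion: bool = False

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ConfigurationError(f"player count p={self.p} must be >= 1")
        if self.R0 <= 0:
            raise ConfigurationError(f"R0={self.R0} must be positive")
        if self.r <= -1:
            raise ConfigurationError(f"growth factor r={self.r} must exceed -1")
        if self.end_prob is not None:
            if not (0 < self.end_prob <= 1):
                raise ConfigurationError(
                    f"end_prob={self.end_prob} must lie in (0, 1]"
                )
            if self.min_rounds is None or self.min_rounds < 1:
                raise ConfigurationError(
                    "geometric termination needs min_rounds >= 1"
                )
        elif self.T < 1:
            raise ConfigurationError(f"horizon T={self.T} must be >= 1")

    @property
    def norm(self) -> float:
        return float(self.normalizer if self.normalizer is not None else self.R0)


@dataclass
class GameState:
    """Dynamic per-round state: 0-based round index, pool, last actions."""

    t: int
    R: float
    prev_offers: np.ndarray
    prev_contributions: np.ndarray
    depleted_at: Optional[int] = None


@dataclass(frozen=True)
class RoundRecord:
    """One round of play: everything needed to re-derive the pool update."""

    t: int
    R_before: float
    offers: np.ndarray
    contributions: np.ndarray
    surpluses: np.ndarray
    retained: float
    R_after: float

    @property
    def trial(self) -> int:
        """1-based display index ('trial 40' is the last round of T=40)."""
        return self.t + 1


@dataclass
class EpisodeLog:
    """A complete episode: config, identities, per-round records."""

    config: GameConfig
    mechanism_id: str
    player_ids: list[str]
    rounds: list[RoundRecord] = field(default_factory=list)
    seed: Optional[int] = None
    game_index: int = 0

    @property
    def horizon(self) -> int:
        return len(self.rounds)

    def offers_matrix(self) -> np.ndarray:
        """(T, p) array of offers."""
        return np.array([rec.offers for rec in self.rounds])

    def contributions_matrix(self) -> np.ndarray:
        return np.array([rec.contributions for rec in self.rounds])

    def surplus_matrix(self) -> np.ndarray:
        return np.array([rec.surpluses for rec in self.rounds])

    def pool_trajectory(self) -> np.ndarray:
        """(T,) pool sizes after each round."""
        return np.array([rec.R_after for rec in self.rounds])

    def total_surplus(self) -> float:
        return float(self.surplus_matrix().sum()) if self.rounds else 0.0

    def per_player_surplus(self) -> np.ndarray:
        if not self.rounds:
            return np.zeros(self.config.p)
        return self.surplus_matrix().sum(axis=0)


def sustainable_keep_fraction(r: float) -> float:
    """Largest keep-fraction under which universal compliance sustains the pool.

    If every player keeps fraction ``f`` of an offer and contributes the rest,
    the pool replenishes exactly when ``(1 + r)(1 - f) = 1``, i.e.
    ``f = r / (1 + r)`` (about 29% for r = 0.4).
    """
    return r / (1.0 + r)


def init_state(config: GameConfig) -> GameState:
    """Fresh state: pool at carrying capacity, no history."""
    return GameState(
        t=0,
        R=float(config.R0),
        prev_offers=np.zeros(config.p),
        prev_contributions=np.zeros(config.p),
    )


def _validate_round(
    R: float, offers: np.ndarray, contributions: np.ndarray, config: GameConfig
) -> None:
    tol = _REL_TOL * max(1.0, abs(R))
    neg = np.where(offers < -tol)[0]
    if neg.size:
        raise RoundValidationError(f"negative offer at player index {neg[0]}")
    if offers.sum() > R + tol:
        raise RoundValidationError(
            f"offers sum to {offers.sum():.6g} > pool {R:.6g}"
        )
    neg_c = np.where(contributions < -tol)[0]
    if neg_c.size:
        raise RoundValidationError(
            f"negative contribution at player index {neg_c[0]}"
        )
    over = np.where(contributions > offers + tol)[0]
    if over.size:
        raise RoundValidationError(
            f"contribution exceeds offer at player index {over[0]}"
        )
    if config.integer_contributions:
        frac = np.abs(contributions - np.round(contributions))
        bad = np.where(frac > 1e-9)[0]
        if bad.size:
            raise RoundValidationError(
                f"non-integer contribution at player index {bad[0]}"
            )


def apply_round(
    state: GameState,
    offers: Sequence[float],
    contributions: Sequence[float],
    config: GameConfig,
) -> tuple[GameState, RoundRecord]:
    """Advance the game one round and return the new state plus its record."""
    offers = np.asarray(offers, dtype=float)
    contributions = np.asarray(contributions, dtype=float)
    _validate_round(state.R, offers, contributions, config)
    offers = np.clip(offers, 0.0, None)
    contributions = np.clip(contributions, 0.0, offers)

    surpluses = offers - contributions
    retained = state.R - offers.sum()
    delta = -offers.sum() + (1.0 + config.r) * contributions.sum()
    R_after = min(config.R0, state.R + delta)
    R_after = max(R_after, 0.0)

    record = RoundRecord(
        t=state.t,
        R_before=state.R,
        offers=offers,
        contributions=contributions,
        surpluses=surpluses,
        retained=retained,
        R_after=R_after,
    )
    depleted_at = state.depleted_at
    if depleted_at is None and R_after < config.offer_unit_threshold:
        depleted_at = state.t
    new_state = GameState(
        t=state.t + 1,
        R=R_after,
        prev_offers=offers,
        prev_contributions=contributions,
        depleted_at=depleted_at,
    )
    return new_state, record


def sample_episode_length(config: GameConfig, rng: np.random.Generator) -> int:
    """Sample the episode horizon.

    Fixed rule: always ``T``.  Geometric rule: ``min_rounds`` plus the number
    of post-minimum survival draws, each surviving with probability
    ``1 - end_prob`` (mean ``min_rounds + (1 - end_prob) / end_prob``).
    """
    if config.end_prob is None:
        return config.T
    length = config.min_rounds
    while rng.random() >= config.end_prob:
        length += 1
    return length


def run_session(
    mechanism,
    players: Sequence,
    config: GameConfig,
    seed: int,
    mechanism_id: Optional[str] = None,
) -> list[EpisodeLog]:
    """Play ``config.n_consecutive_games`` games back to back with the same
    group; the pool resets to the maximum at each new game and every policy's
    per-episode memory is cleared (players keep no carry-over state between
    games beyond what their policies relearn in play)."""
    return [
        run_episode(mechanism, players, config, seed=seed + 7919 * g,
                    mechanism_id=mechanism_id, game_index=g)
        for g in range(config.n_consecutive_games)
    ]


def run_episode(
    mechanism,
    players: Sequence,
    config: GameConfig,
    seed: int,
    mechanism_id: Optional[str] = None,
    game_index: int = 0,
) -> EpisodeLog:
    """Roll out one full episode of mechanism vs players.

    Round order: the mechanism observes the state and produces offers and a
    retained amount; each player observes all current offers, all previous
    contributions and the pool, then contributes; the pool updates.  Players
    offered less than ``offer_unit_threshold`` are forced to contribute 0.
    By default a depleted pool does not end the episode — remaining rounds
    are played out with zero offers — so per-trial metrics are defined over
    the full horizon.
    """
    if len(players) != config.p:
        raise ConfigurationError(
            f"need {config.p} players, got {len(players)}"
        )
    rng = np.random.default_rng(seed)
    length = sample_episode_length(config, rng)
    mechanism.reset()
    for player in players:
        player.reset()
    state = init_state(config)
    log = EpisodeLog(
        config=config,
        mechanism_id=mechanism_id or getattr(mechanism, "name", "mechanism"),
        player_ids=[getattr(pl, "name", f"player{i}") for i, pl in enumerate(players)],
        seed=seed,
        game_index=game_index,
    )
    for _ in range(length):
        offers, _retained = mechanism.act(state, config)
        offers = np.clip(np.asarray(offers, dtype=float), 0.0, None)
        total = offers.sum()
        if total > state.R:  # guard tiny numerical overshoot from mechanisms
            offers = offers * (state.R / total) if total > 0 else offers
        contributions = np.empty(config.p)
        for i, player in enumerate(players):
            # players always observe (stateful policies track history) but a
            # sub-unit offer forces the contribution to zero
            c = float(
                player.observe_and_act(
                    offers, state.prev_contributions, state.R, i
                )
            )
            if offers[i] < config.offer_unit_threshold:
                c = 0.0
            else:
                if config.integer_contributions:
                    c = float(np.floor(c))
                c = min(max(c, 0.0), offers[i])
            contributions[i] = c
        state, record = apply_round(state, offers, contributions, config)
        log.rounds.append(record)
        if config.truncate_on_depletion and state.R < config.offer_unit_threshold:
            break
    return log
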