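"""Scripted synthetic player archetypes and the fixture-log generator.

Archetypes express their behaviour as a *reciprocation fraction* of the
offer they received.  The sustainable fraction is 1/(1+r): if everyone
contributes that share of a full-pool allocation, replenishment exactly
offsets the draw-down and the pool never moves.

Archetypes:

- ``sustainer`` — always contributes fraction 1/(1+r), optionally noisy,
  optionally lapsing (a zero-contribution round at random), which gives
  imitation learners a history-dependent signal to explain.
- ``free_rider`` — contributes a fixed (default zero) fraction.
- ``conditional`` — matches the mean of the other players' previous
  reciprocation fractions.
- ``grim`` — contributes the sustainer fraction until any other player's
  observed fraction drops below a trigger threshold, then defects forever.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .game import EpisodeLog, GameConfig, run_episode
from .mechanisms import MechanismPolicy, WeightedMechanism, make_mechanism

__all__ = [
    "PlayerPolicy",
    "ArchetypeSpec",
    "SustainerPlayer",
    "FreeRiderPlayer",
    "ConditionalCooperatorPlayer",
    "GrimTriggerPlayer",
    "Population",
    "make_player",
    "generate_fixture_logs",
]


class PlayerPolicy:
    """Contract for a player.

    ``reset()`` clears per-episode memory.  ``observe_and_act(offers_all,
    prev_contribs_all, pool, own_index)`` returns this round's contribution,
    bounded by the player's own offer (zero when the offer is below one
    resource unit).
    """

    name = "player"

    def reset(self) -> None:
        pass

    def observe_and_act(
        self,
        offers_all: np.ndarray,
        prev_contribs_all: np.ndarray,
        pool: float,
        own_index: int,
    ) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class ArchetypeSpec:
    """Config-file description of one archetype."""

    kind: str  # sustainer | free_rider | conditional | grim
    base_fraction: Optional[float] = None
    noise_sd: float = 0.0
    lapse_prob: float = 0.0
    trigger_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in {"sustainer", "free_rider", "conditional", "grim"}:
            raise ValueError(f"unknown archetype kind {self.kind!r}")
        if self.base_fraction is not None and not (0 <= self.base_fraction <= 1):
            raise ValueError("base_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


class _FractionPlayer(PlayerPolicy):
    """Base class: archetypes produce a fraction; noise is applied to the
    fraction (not the amount) and truncated to [0, 1], so the contribution
    contract holds by construction."""

    def __init__(self, r: float = 0.4, noise_sd: float = 0.0, seed: int = 0):
        self.r = r
        self.noise_sd = noise_sd
        self._seed = seed
        self._episode = 0
        self.reset()

    @property
    def sustainer_fraction(self) -> float:
        return 1.0 / (1.0 + self.r)

    def reset(self) -> None:
        self._rng = np.random.default_rng((self._seed, self._episode))
        self._episode += 1

    def _fraction(self, offers_all, prev_contribs_all, pool, own_index) -> float:
        raise NotImplementedError

    def observe_and_act(self, offers_all, prev_contribs_all, pool, own_index):
        frac = self._fraction(offers_all, prev_contribs_all, pool, own_index)
        if self.noise_sd > 0:
            frac += self._rng.normal(0.0, self.noise_sd)
        frac = min(max(frac, 0.0), 1.0)
        e = offers_all[own_index]
        if e < 1.0:
            return 0.0
        return frac * e


class SustainerPlayer(_FractionPlayer):
    """Contributes the sustainable fraction 1/(1+r); may lapse to 0 for a
    round with probability ``lapse_prob``."""

    name = "sustainer"

    def __init__(self, r: float = 0.4, noise_sd: float = 0.0,
                 lapse_prob: float = 0.0, seed: int = 0):
        self.lapse_prob = lapse_prob
        super().__init__(r=r, noise_sd=noise_sd, seed=seed)

    def _fraction(self, offers_all, prev_contribs_all, pool, own_index):
        if self.lapse_prob > 0 and self._rng.random() < self.lapse_prob:
            return 0.0
        return self.sustainer_fraction


class FreeRiderPlayer(_FractionPlayer):
    """Keeps (almost) everything: fixed contribution fraction, default 0."""

    name = "free_rider"

    def __init__(self, base_fraction: float = 0.0, r: float = 0.4,
                 noise_sd: float = 0.0, seed: int = 0):
        self.base_fraction = base_fraction
        super().__init__(r=r, noise_sd=noise_sd, seed=seed)

    def _fraction(self, offers_all, prev_contribs_all, pool, own_index):
        return self.base_fraction


class ConditionalCooperatorPlayer(_FractionPlayer):
    """Matches the mean reciprocation fraction of the *other* players on the
    previous round; starts from the sustainable target.

    Fractions are tracked from observed offers and contributions, so the
    policy is stateful (it must remember last round's offers)."""

    name = "conditional"

    def reset(self) -> None:
        super().reset()
        self._prev_offers: Optional[np.ndarray] = None

    def _fraction(self, offers_all, prev_contribs_all, pool, own_index):
        if self._prev_offers is None:
            frac = self.sustainer_fraction
        else:
            others = [
                prev_contribs_all[j] / self._prev_offers[j]
                for j in range(len(offers_all))
                if j != own_index and self._prev_offers[j] >= 1.0
            ]
            frac = float(np.clip(np.mean(others), 0.0, 1.0)) if others else \
                self.sustainer_fraction
        self._prev_offers = np.asarray(offers_all, dtype=float).copy()
        return frac


class GrimTriggerPlayer(_FractionPlayer):
    """Sustainer until any other player's observed fraction drops below the
    trigger threshold; thereafter contributes nothing, forever."""

    name = "grim"

    def __init__(self, r: float = 0.4, noise_sd: float = 0.0,
                 trigger_threshold: float = 0.1, seed: int = 0):
        self.trigger_threshold = trigger_threshold
        super().__init__(r=r, noise_sd=noise_sd, seed=seed)

    def reset(self) -> None:
        super().reset()
        self._triggered = False
        self._prev_offers: Optional[np.ndarray] = None

    def _fraction(self, offers_all, prev_contribs_all, pool, own_index):
        if self._prev_offers is not None and not self._triggered:
            for j in range(len(offers_all)):
                if j == own_index or self._prev_offers[j] < 1.0:
                    continue
                if prev_contribs_all[j] / self._prev_offers[j] < self.trigger_threshold:
                    self._triggered = True
                    break
        self._prev_offers = np.asarray(offers_all, dtype=float).copy()
        return 0.0 if self._triggered else self.sustainer_fraction


def make_player(spec: ArchetypeSpec, r: float = 0.4, seed: int = 0) -> PlayerPolicy:
    if spec.kind == "sustainer":
        return SustainerPlayer(r=r, noise_sd=spec.noise_sd,
                               lapse_prob=spec.lapse_prob, seed=seed)
    if spec.kind == "free_rider":
        return FreeRiderPlayer(base_fraction=spec.base_fraction or 0.0,
                               r=r, noise_sd=spec.noise_sd, seed=seed)
    if spec.kind == "conditional":
        return ConditionalCooperatorPlayer(r=r, noise_sd=spec.noise_sd, seed=seed)
    if spec.kind == "grim":
        return GrimTriggerPlayer(r=r, noise_sd=spec.noise_sd,
                                 trigger_threshold=spec.trigger_threshold, seed=seed)
    raise ValueError(spec.kind)


@dataclass
class Population:
    """A pool of archetype specs from which p-player groups are sampled."""

    specs: list[ArchetypeSpec]
    r: float = 0.4
    p: int = 4
    weights: Optional[Sequence[float]] = None

    def sample(self, rng: np.random.Generator) -> list[PlayerPolicy]:
        idx = rng.choice(len(self.specs), size=self.p, replace=True,
                         p=self.weights)
        return [
            make_player(self.specs[i], r=self.r,
                        seed=int(rng.integers(2**31)))
            for i in idx
        ]


def generate_fixture_logs(
    population: Population,
    mechanism_specs: Sequence,
    n_games: int,
    config: Optional[GameConfig] = None,
    seed: int = 0,
) -> list[EpisodeLog]:
    """Generate synthetic training/evaluation logs with no external data.

    ``mechanism_specs`` entries are either mechanism names (``"equal"``,
    ``"random"``, ...), ``("weighted", None)`` — meaning a fresh
    w ~ Uniform[0, 1] per game, mirroring the data-collection design where
    the mixing parameter was sampled randomly on each game — or ready
    ``MechanismPolicy`` instances.  Deterministic given ``seed``.
    """
    if config is None:
        config = GameConfig()
    rng = np.random.default_rng(seed)
    logs: list[EpisodeLog] = []
    for g in range(n_games):
        spec = mechanism_specs[int(rng.integers(len(mechanism_specs)))]
        if isinstance(spec, MechanismPolicy):
            mech = spec
        elif isinstance(spec, tuple) and spec[0] == "weighted" and spec[1] is None:
            mech = WeightedMechanism(float(rng.uniform()))
        elif isinstance(spec, str):
            mech = make_mechanism(spec, seed=int(rng.integers(2**31)))
        else:
            name, params = spec
            mech = make_mechanism(name, seed=int(rng.integers(2**31)),
                                  **(params or {}))
        players = population.sample(rng)
        log = run_episode(
            mech, players, config,
            seed=int(rng.integers(2**31)), game_index=g,
        )
        logs.append(log)
    return logs
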