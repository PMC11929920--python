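"""Hand-coded allocation mechanisms.

The weighted family interpolates between an equal split (w = 1) and a
split proportional to last round's contributions (w = 0):

    e_i = w * R / p + (1 - w) * R * c_{i,t-1} / sum_j c_{j,t-1}

with an equal split on the opening round.  The interpolating mechanism
conditions the mixing weight on the pool itself, w = (R / R0)^k, so
allocation is egalitarian only when the pool is near its carrying
capacity and near-proportional otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .game import GameConfig, GameState, run_episode

__all__ = [
    "MechanismPolicy",
    "WeightedBaselineSpec",
    "InterpolatingSpec",
    "weighted_offers",
    "random_offers",
    "interpolating_weight",
    "WeightedMechanism",
    "EqualMechanism",
    "ProportionalMechanism",
    "MixedMechanism",
    "RandomMechanism",
    "InterpolatingMechanism",
    "calibrate_interpolating_exponent",
    "default_exponent_grid",
    "make_mechanism",
]


class MechanismPolicy:
    """Contract for an allocation mechanism.

    ``reset()`` clears per-episode memory; ``act(state, config)`` returns
    ``(offers, retained)`` with non-negative offers summing (with the
    retained amount) to the current pool.
    """

    name = "mechanism"

    def reset(self) -> None:  # stateless by default
        pass

    def act(self, state: GameState, config: GameConfig):
        raise NotImplementedError


@dataclass(frozen=True)
class WeightedBaselineSpec:
    """Mixing weight w in [0, 1] and unallocated pool fraction in [0, 0.4]."""

    w: float
    residual_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError(f"mixing weight w={self.w} must lie in [0, 1]")
        if not (0.0 <= self.residual_fraction <= 0.4):
            raise ValueError(
                f"residual_fraction={self.residual_fraction} must lie in [0, 0.4]"
            )


@dataclass(frozen=True)
class InterpolatingSpec:
    """Pool-conditioned mixing exponent k > 0 plus its calibration grid."""

    k: float
    grid: tuple = ()

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"exponent k={self.k} must be positive")


def weighted_offers(
    spec: WeightedBaselineSpec, state: GameState, config: GameConfig
) -> tuple[np.ndarray, float]:
    """Offers of the weighted equal/proportional family.

    The opening round is always an equal split.  When nobody contributed on
    the previous round the proportional component allocates zero to every
    player (the whole group is excluded from that share).
    """
    R_alloc = (1.0 - spec.residual_fraction) * state.R
    p = config.p
    equal = np.full(p, R_alloc / p)
    if state.t == 0:
        offers = equal
    else:
        c_prev = state.prev_contributions
        total_c = c_prev.sum()
        if total_c > 0:
            proportional = R_alloc * c_prev / total_c
        else:
            proportional = np.zeros(p)
        offers = spec.w * equal + (1.0 - spec.w) * proportional
    retained = state.R - offers.sum()
    return offers, retained


def random_offers(
    state: GameState, rng: np.random.Generator, p: int = 4
) -> tuple[np.ndarray, float]:
    """Dirichlet(1) split of the pool into p offers plus a retained share."""
    proportions = rng.dirichlet(np.ones(p + 1))
    offers = proportions[:p] * state.R
    retained = float(proportions[p] * state.R)
    return offers, retained


def interpolating_weight(k: float, R: float, R0: float) -> float:
    """Pool-conditioned mixing weight w = (R / R0)^k."""
    if R <= 0:
        return 0.0
    return float((R / R0) ** k)


class WeightedMechanism(MechanismPolicy):
    """Fixed-w member of the weighted baseline family."""

    def __init__(self, w: float, residual_fraction: float = 0.0, name: Optional[str] = None):
        self.spec = WeightedBaselineSpec(w=w, residual_fraction=residual_fraction)
        self.name = name or f"weighted(w={w:g})"

    def act(self, state: GameState, config: GameConfig):
        return weighted_offers(self.spec, state, config)


class EqualMechanism(WeightedMechanism):
    def __init__(self, residual_fraction: float = 0.0):
        super().__init__(1.0, residual_fraction, name="equal")


class ProportionalMechanism(WeightedMechanism):
    def __init__(self, residual_fraction: float = 0.0):
        super().__init__(0.0, residual_fraction, name="proportional")


class MixedMechanism(WeightedMechanism):
    def __init__(self, residual_fraction: float = 0.0):
        super().__init__(0.5, residual_fraction, name="mixed")


class RandomMechanism(MechanismPolicy):
    """Dirichlet(1) random split; stochastic, seeded per episode via reset."""

    name = "random"

    def __init__(self, seed: int = 0):
        self._seed = seed
        self._episode = 0
        self.reset()

    def reset(self) -> None:
        self._rng = np.random.default_rng((self._seed, self._episode))
        self._episode += 1

    def act(self, state: GameState, config: GameConfig):
        return random_offers(state, self._rng, config.p)


class InterpolatingMechanism(MechanismPolicy):
    """Weighted baseline whose mixing weight tracks the pool: w = (R/R0)^k."""

    def __init__(self, k: float):
        self.spec = InterpolatingSpec(k=k)
        self.name = f"interpolating(k={k:g})"

    def act(self, state: GameState, config: GameConfig):
        w = interpolating_weight(self.spec.k, state.R, config.R0)
        return weighted_offers(WeightedBaselineSpec(w=w), state, config)


def default_exponent_grid() -> np.ndarray:
    """101 candidate exponents k = exp(g) for g in {-5, -4.9, ..., 5}."""
    return np.exp(np.arange(-5.0, 5.0 + 1e-9, 0.1))


def calibrate_interpolating_exponent(
    player_population,
    grid: Optional[Sequence[float]] = None,
    n_episodes: int = 20,
    config: Optional[GameConfig] = None,
    seed: int = 0,
) -> tuple[float, "pd.DataFrame"]:
    """Pick the interpolation exponent maximising mean total surplus.

    Each candidate k plays ``n_episodes`` episodes against player sets drawn
    from ``player_population`` (an object with ``sample(rng) -> list of
    players``).  Matched seeds are used across candidates.  Ties break
    toward the larger (more proportional) exponent.

    Returns ``(best_k, table)`` where the table has one row per candidate
    with its mean and std of total surplus.
    """
    import pandas as pd

    if grid is None:
        grid = default_exponent_grid()
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("exponent grid must be non-empty")
    if config is None:
        config = GameConfig()

    rows = []
    best_k = None
    best_mean = -np.inf
    for k in grid:
        mech = InterpolatingMechanism(k)
        surpluses = []
        for ep in range(n_episodes):
            rng = np.random.default_rng((seed, ep))
            players = player_population.sample(rng)
            log = run_episode(mech, players, config, seed=int(1_000_003 * ep + seed))
            surpluses.append(log.total_surplus())
        mean = float(np.mean(surpluses))
        rows.append(
            {"k": float(k), "log_k": float(np.log(k)),
             "mean_surplus": mean, "std_surplus": float(np.std(surpluses))}
        )
        if mean >= best_mean:  # >= so ties go to the larger k (grid ascends)
            best_mean = mean
            best_k = float(k)
    table = pd.DataFrame(rows)
    return best_k, table


def make_mechanism(name: str, seed: int = 0, **params) -> MechanismPolicy:
    """Instantiate a mechanism by config-file name."""
    name = name.lower()
    if name == "equal":
        return EqualMechanism(**params)
    if name == "proportional":
        return ProportionalMechanism(**params)
    if name == "mixed":
        return MixedMechanism(**params)
    if name == "random":
        return RandomMechanism(seed=seed, **params)
    if name == "weighted":
        return WeightedMechanism(**params)
    if name == "interpolating":
        return InterpolatingMechanism(**params)
    raise ValueError(f"unknown mechanism {name!r}")
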