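"""Descriptive metrics over episode logs.

Implements the full evaluation battery: total and per-player surplus,
the Gini coefficient of aggregate player surplus, per-trial offer Gini
against pool size, economic-inclusivity indices (active players,
depletion trial, sustained flag), exclusion events, and the lagged
offer–reciprocation regressions characterising each mechanism's policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .game import EpisodeLog

__all__ = [
    "gini",
    "MetricsSummary",
    "ExclusionEvent",
    "LagCoefficients",
    "episode_metrics",
    "exclusion_events",
    "lagged_offer_regression",
    "summarize_condition",
]


def gini(values: Sequence[float]) -> float:
    """Gini coefficient: mean absolute pairwise difference over twice the
    mean.  Defined as 0 for an all-equal or all-zero vector (after a total
    collapse in welfare nobody gets anything, which is perfect equality).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("gini needs a 1-d vector with at least one value")
    if np.any(x < 0):
        raise ValueError("gini is defined for non-negative values")
    total = x.sum()
    if total == 0:
        return 0.0
    n = x.size
    xs = np.sort(x)
    # identity: sum_ij |x_i - x_j| = 2 * sum_i (2i - n + 1) * x_(i)
    i = np.arange(1, n + 1)
    mad = 2.0 * np.sum((2 * i - n - 1) * xs) / (n * n)
    return float(mad / (2.0 * total / n))


@dataclass
class MetricsSummary:
    """Per-game metrics mirroring the headline evaluation panels."""

    total_surplus: float
    per_player_surplus: np.ndarray
    surplus_gini: float
    mean_active_players: float
    depletion_trial: int          # 1-based; horizon if never depleted
    sustained: bool               # pool >= threshold on the last trial
    offer_gini_by_trial: np.ndarray   # (T,) Gini of the offers each trial
    pool_by_trial: np.ndarray         # (T,) pool before each trial
    horizon: int


def episode_metrics(log: EpisodeLog, threshold: float = 1.0) -> MetricsSummary:
    """All headline metrics for a single game.

    ``depletion_trial`` is the first (1-based) trial on which the pool
    drops below ``threshold`` (the horizon when it never does); an *active
    player* receives an offer of at least ``threshold`` on a trial; the
    game is *sustained* when the pool is at least the threshold on the
    final trial.
    """
    if not log.rounds:
        raise ValueError("cannot summarise an empty episode")
    offers = log.offers_matrix()
    surpluses = log.surplus_matrix()
    pool_after = log.pool_trajectory()
    per_player = surpluses.sum(axis=0)
    T = log.horizon

    below = np.where(pool_after < threshold)[0]
    depletion_trial = int(below[0] + 1) if below.size else T
    active = (offers >= threshold).sum(axis=1)
    offer_ginis = np.array([gini(row) for row in offers])
    pool_before = np.array([rec.R_before for rec in log.rounds])
    return MetricsSummary(
        total_surplus=float(surpluses.sum()),
        per_player_surplus=per_player,
        surplus_gini=gini(per_player),
        mean_active_players=float(active.mean()),
        depletion_trial=depletion_trial,
        sustained=bool(pool_after[-1] >= threshold),
        offer_gini_by_trial=offer_ginis,
        pool_by_trial=pool_before,
        horizon=T,
    )


@dataclass(frozen=True)
class ExclusionEvent:
    """A run of consecutive sub-threshold offers to a previously included
    player.  ``reincluded`` is False when the run reaches the final trial
    (start + duration - 1 == horizon: the diagonal of the duration plot)."""

    player: int
    start_trial: int  # 1-based trial of the first sub-threshold offer
    duration: int
    reincluded: bool


def exclusion_events(log: EpisodeLog,
                     threshold: float = 1.0) -> list[ExclusionEvent]:
    """Exclusions: a player who received >= threshold on the previous trial
    gets an offer below threshold; the event lasts for the consecutive run
    of sub-threshold offers."""
    offers = log.offers_matrix()
    T, p = offers.shape
    events: list[ExclusionEvent] = []
    for i in range(p):
        t = 1
        while t < T:
            if offers[t - 1, i] >= threshold and offers[t, i] < threshold:
                start = t
                while t < T and offers[t, i] < threshold:
                    t += 1
                events.append(ExclusionEvent(
                    player=i, start_trial=start + 1, duration=t - start,
                    reincluded=t < T,
                ))
            else:
                t += 1
    return events


@dataclass
class LagCoefficients:
    """OLS weights of the current offer on the focal player's reciprocation
    at lags -4..+4, fitted per trial; the median across trials is the
    mechanism's signature."""

    lags: np.ndarray                 # (9,) lag offsets
    per_trial: pd.DataFrame          # rows: trials; columns: lag weights
    median: np.ndarray               # (9,) medians over trials
    skipped_trials: int = 0


def lagged_offer_regression(
    logs: Sequence[EpisodeLog],
    lags: Sequence[int] = range(-4, 5),
    normalize: bool = False,
) -> LagCoefficients:
    """Regress the offer at trial t on the player's contributions at
    t-4 ... t+4, one OLS fit per trial with (game, player) rows pooled
    within the condition.  Trials lacking the full lag window are skipped;
    a zero-variance design yields zero weights for the offending columns
    (constant-offer mechanisms are legitimate inputs).  With ``normalize``
    the variables are z-scored per trial so weights are comparable across
    trials with different pool levels.
    """
    lags = np.array(list(lags), dtype=int)
    horizon = min(log.horizon for log in logs)
    rows = []
    skipped = 0
    for t in range(horizon):
        if t + lags.min() < 0 or t + lags.max() >= horizon:
            continue
        ys, Xs = [], []
        for log in logs:
            offers = log.offers_matrix()
            contribs = log.contributions_matrix()
            for i in range(log.config.p):
                ys.append(offers[t, i])
                Xs.append([contribs[t + lag, i] for lag in lags])
        y = np.asarray(ys)
        X = np.asarray(Xs)
        if normalize:
            y_sd = y.std()
            y = (y - y.mean()) / y_sd if y_sd > 0 else np.zeros_like(y)
            sd = X.std(axis=0)
            keep = sd > 0
            Xn = np.zeros_like(X)
            Xn[:, keep] = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
            X = Xn
        else:
            keep = X.std(axis=0) > 0
        if not np.any(keep) or y.std() == 0:
            beta = np.zeros(lags.size)
        else:
            try:
                design = X[:, keep]
                if not normalize:  # unnormalised fits carry an intercept
                    design = np.column_stack([design, np.ones(len(y))])
                sol, *_ = np.linalg.lstsq(design, y, rcond=None)
                beta = np.zeros(lags.size)
                beta[keep] = sol[: int(keep.sum())]
            except np.linalg.LinAlgError:
                skipped += 1
                continue
        rows.append({"trial": t + 1,
                     **{f"lag_{lag}": b for lag, b in zip(lags, beta)}})
    per_trial = pd.DataFrame(rows)
    if per_trial.empty:
        median = np.zeros(lags.size)
    else:
        median = per_trial[[f"lag_{lag}" for lag in lags]].median().to_numpy()
    return LagCoefficients(lags=lags, per_trial=per_trial, median=median,
                           skipped_trials=skipped)


def summarize_condition(summaries: Sequence[MetricsSummary],
                        label: str = "") -> dict:
    """Condition-level table: one row per game plus means, the sustained /
    depleted split, and the surplus–Gini Pearson correlation within each
    subset (reported as None when undefined)."""
    if not summaries:
        raise ValueError("need at least one game")
    per_game = pd.DataFrame(
        {
            "total_surplus": [s.total_surplus for s in summaries],
            "surplus_gini": [s.surplus_gini for s in summaries],
            "mean_active_players": [s.mean_active_players for s in summaries],
            "depletion_trial": [s.depletion_trial for s in summaries],
            "sustained": [s.sustained for s in summaries],
        }
    )
    if label:
        per_game.insert(0, "condition", label)

    def corr(df: pd.DataFrame) -> Optional[float]:
        if len(df) < 2:
            return None
        x, y = df["total_surplus"], df["surplus_gini"]
        if x.std() == 0 or y.std() == 0:
            return None
        return float(np.corrcoef(x, y)[0, 1])

    sustained = per_game[per_game["sustained"]]
    depleted = per_game[~per_game["sustained"]]
    numeric = ["total_surplus", "surplus_gini", "mean_active_players",
               "depletion_trial"]
    return {
        "per_game": per_game,
        "mean": per_game[numeric].mean().to_dict(),
        "mean_sustained": sustained[numeric].mean().to_dict() if len(sustained) else None,
        "mean_depleted": depleted[numeric].mean().to_dict() if len(depleted) else None,
        "n_games": len(per_game),
        "n_sustained": int(per_game["sustained"].sum()),
        "corr_surplus_gini_sustained": corr(sustained),
        "corr_surplus_gini_depleted": corr(depleted),
    }
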