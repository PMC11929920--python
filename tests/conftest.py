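import numpy as np
import pytest

from commonpool.game import EpisodeLog, GameConfig, RoundRecord
from commonpool.players import ArchetypeSpec, Population


@pytest.fixture
def config():
    return GameConfig()


@pytest.fixture
def mixed_population():
    """Sustainers, free riders and conditional cooperators in one pool."""
    return Population([
        ArchetypeSpec("sustainer"),
        ArchetypeSpec("free_rider"),
        ArchetypeSpec("conditional"),
    ])


@pytest.fixture
def sustainer_population():
    return Population([ArchetypeSpec("sustainer")])


def make_log(offers, contributions, config=None, mechanism_id="manual",
             R0=None):
    """Assemble an EpisodeLog from offer/contribution matrices, deriving the
    pool trajectory from the game's own update rule."""
    offers = np.asarray(offers, dtype=float)
    contributions = np.asarray(contributions, dtype=float)
    T, p = offers.shape
    if config is None:
        config = GameConfig(p=p, R0=R0 or max(200.0, offers.sum(axis=1).max()))
    log = EpisodeLog(config=config, mechanism_id=mechanism_id,
                     player_ids=[f"p{i}" for i in range(p)], seed=0)
    R = config.R0
    for t in range(T):
        e, c = offers[t], contributions[t]
        R_after = min(config.R0, R - e.sum() + (1 + config.r) * c.sum())
        log.rounds.append(RoundRecord(
            t=t, R_before=R, offers=e, contributions=c, surpluses=e - c,
            retained=R - e.sum(), R_after=R_after,
        ))
        R = R_after
    return log
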