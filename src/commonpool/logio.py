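"""Episode-log serialisation and run configuration.

Logs are JSON Lines: a header line carrying the game configuration and
identities, then one line per round.  Numeric fields use ``repr`` round-
trip floats, so a write → read cycle is lossless.  A flattened CSV
export (one row per game × trial × player) feeds external analysis.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .game import EpisodeLog, GameConfig, RoundRecord

__all__ = [
    "write_episode_log",
    "read_episode_log",
    "write_logs",
    "read_logs",
    "logs_to_frame",
    "RunConfig",
    "load_run_config",
]


class LogParseError(ValueError):
    """Malformed episode-log file; carries the offending line number."""


def _config_to_dict(config: GameConfig) -> dict:
    return dataclasses.asdict(config)


def _config_from_dict(d: dict) -> GameConfig:
    return GameConfig(**d)


def write_episode_log(log: EpisodeLog, path) -> Path:
    """Serialise one episode as JSON Lines (header line, then rounds)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "type": "header",
        "config": _config_to_dict(log.config),
        "mechanism_id": log.mechanism_id,
        "player_ids": log.player_ids,
        "seed": log.seed,
        "game_index": log.game_index,
    }
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        for rec in log.rounds:
            fh.write(json.dumps({
                "type": "round",
                "t": rec.t,
                "R_before": rec.R_before,
                "offers": list(rec.offers),
                "contributions": list(rec.contributions),
                "surpluses": list(rec.surpluses),
                "retained": rec.retained,
                "R_after": rec.R_after,
            }) + "\n")
    return path


def read_episode_log(path) -> EpisodeLog:
    path = Path(path)
    log: Optional[EpisodeLog] = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise LogParseError(f"{path}:{lineno}: invalid JSON ({exc})")
            kind = obj.get("type")
            if kind == "header":
                log = EpisodeLog(
                    config=_config_from_dict(obj["config"]),
                    mechanism_id=obj["mechanism_id"],
                    player_ids=obj["player_ids"],
                    seed=obj.get("seed"),
                    game_index=obj.get("game_index", 0),
                )
            elif kind == "round":
                if log is None:
                    raise LogParseError(f"{path}:{lineno}: round before header")
                try:
                    log.rounds.append(RoundRecord(
                        t=obj["t"],
                        R_before=obj["R_before"],
                        offers=np.array(obj["offers"], dtype=float),
                        contributions=np.array(obj["contributions"], dtype=float),
                        surpluses=np.array(obj["surpluses"], dtype=float),
                        retained=obj["retained"],
                        R_after=obj["R_after"],
                    ))
                except KeyError as exc:
                    raise LogParseError(f"{path}:{lineno}: missing field {exc}")
            else:
                raise LogParseError(f"{path}:{lineno}: unknown record type {kind!r}")
    if log is None:
        raise LogParseError(f"{path}:1: no header line")
    return log


def write_logs(logs: Sequence[EpisodeLog], directory) -> list[Path]:
    directory = Path(directory)
    return [
        write_episode_log(log, directory / f"game_{log.game_index:05d}.jsonl")
        for log in logs
    ]


def read_logs(directory) -> list[EpisodeLog]:
    directory = Path(directory)
    return [read_episode_log(p) for p in sorted(directory.glob("*.jsonl"))]


def logs_to_frame(logs: Sequence[EpisodeLog]) -> pd.DataFrame:
    """Tidy table: one row per (game, trial, player)."""
    rows = []
    for log in logs:
        for rec in log.rounds:
            for i in range(log.config.p):
                rows.append({
                    "game": log.game_index,
                    "mechanism": log.mechanism_id,
                    "trial": rec.trial,
                    "player": i,
                    "offer": rec.offers[i],
                    "contribution": rec.contributions[i],
                    "surplus": rec.surpluses[i],
                    "pool_before": rec.R_before,
                    "pool_after": rec.R_after,
                    "retained": rec.retained,
                })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RunConfig:
    """Top-level YAML run configuration (versioned schema).

    All stage randomness derives from ``seed`` (split per stage)."""

    game: GameConfig
    mechanisms: list        # entries: {name: ..., params: {...}}
    population: list        # entries: {kind: ..., params..., weight: ...}
    seed: int = 0
    output_dir: str = "runs"
    version: int = 1

    def population_object(self):
        from .players import ArchetypeSpec, Population

        specs, weights = [], []
        for entry in self.population:
            entry = dict(entry)
            weights.append(float(entry.pop("weight", 1.0)))
            specs.append(ArchetypeSpec(**entry))
        w = np.array(weights)
        return Population(specs=specs, r=self.game.r, p=self.game.p,
                          weights=list(w / w.sum()))

    def mechanism_objects(self):
        from .mechanisms import make_mechanism

        out = []
        for entry in self.mechanisms:
            if isinstance(entry, str):
                entry = {"name": entry}
            out.append(make_mechanism(entry["name"], seed=self.seed,
                                      **(entry.get("params") or {})))
        return out


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    version = raw.get("version", 1)
    if version != 1:
        raise ValueError(f"unsupported config version {version}")
    return RunConfig(
        game=GameConfig(**(raw.get("game") or {})),
        mechanisms=raw.get("mechanisms") or ["equal"],
        population=raw.get("population") or [{"kind": "sustainer"}],
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir", "runs"),
        version=version,
    )
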