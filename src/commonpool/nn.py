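"""Small neural-network toolkit on top of :mod:`commonpool.autodiff`.

Parameters live in a flat ``dict[str, np.ndarray]`` (a "named-array
archive"); each training step wraps them into autodiff leaves, builds the
graph, and reads gradients back.  Provides fully connected layers, a GRU
cell, the Adam optimiser and the annealing learning-rate schedule used by
both training loops (multiply by ``1 - decay`` every ``interval`` updates,
floored at ``lr_floor``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Var, concat, matmul, sigmoid, tanh

__all__ = [
    "glorot",
    "init_linear",
    "apply_linear",
    "init_gru",
    "gru_step",
    "wrap_params",
    "read_grads",
    "Adam",
    "LRSchedule",
    "save_checkpoint",
    "load_checkpoint",
]

Params = dict


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_linear(params: Params, name: str, n_in: int, n_out: int,
                rng: np.random.Generator) -> None:
    params[f"{name}.W"] = glorot(rng, n_in, n_out)
    params[f"{name}.b"] = np.zeros(n_out)


def apply_linear(v: dict, name: str, x: Var) -> Var:
    return matmul(x, v[f"{name}.W"]) + v[f"{name}.b"]


def init_gru(params: Params, name: str, n_in: int, n_hidden: int,
             rng: np.random.Generator) -> None:
    # gates stacked as [update z | reset r | candidate n]
    for gate in ("z", "r", "n"):
        params[f"{name}.W{gate}"] = glorot(rng, n_in, n_hidden)
        params[f"{name}.U{gate}"] = glorot(rng, n_hidden, n_hidden)
        params[f"{name}.b{gate}"] = np.zeros(n_hidden)


def gru_step(v: dict, name: str, x: Var, h: Var) -> Var:
    """One GRU update: h' = (1 - z) * n + z * h."""
    z = sigmoid(matmul(x, v[f"{name}.Wz"]) + matmul(h, v[f"{name}.Uz"]) + v[f"{name}.bz"])
    r = sigmoid(matmul(x, v[f"{name}.Wr"]) + matmul(h, v[f"{name}.Ur"]) + v[f"{name}.br"])
    n = tanh(matmul(x, v[f"{name}.Wn"]) + matmul(r * h, v[f"{name}.Un"]) + v[f"{name}.bn"])
    return (1.0 - z) * n + z * h


def wrap_params(params: Params) -> dict:
    """Wrap numpy parameters as gradient-tracking autodiff leaves."""
    return {k: Var(w, requires_grad=True) for k, w in params.items()}


def read_grads(param_vars: dict) -> Params:
    return {
        k: (v.grad if v.grad is not None else np.zeros_like(v.value))
        for k, v in param_vars.items()
    }


@dataclass
class LRSchedule:
    """Exponentially annealed learning rate with a floor."""

    start: float
    decay: float = 0.05
    interval: int = 1000
    floor: float = 0.0

    def __call__(self, step: int) -> float:
        lr = self.start * (1.0 - self.decay) ** (step // self.interval)
        return max(lr, self.floor)


class Adam:
    """Adam optimiser over a flat parameter dict (in-place updates)."""

    def __init__(self, params: Params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(w) for k, w in params.items()}
        self.v = {k: np.zeros_like(w) for k, w in params.items()}
        self.t = 0

    def step(self, grads: Params, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, w in self.params.items():
            g = grads[k]
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for {k}")
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            w -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def save_checkpoint(path, params: Params, meta: Optional[dict] = None) -> Path:
    """Flat named-array archive (.npz) with an embedded metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = dict(params)
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta or {}).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path) -> tuple[Params, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"].tobytes()).decode())
        params = {k: archive[k].copy() for k in archive.files if k != "__meta__"}
    return params, meta
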