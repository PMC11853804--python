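"""Three-armed multi-armed bandit environment with binary outcomes.

Outcomes are coded 1/2 at this API (the user-facing convention used in all
serialized output); callers that need 0-based observation indices subtract
one at the boundary.  Arm probabilities are stationary across trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["BanditConfig", "pull", "pull_many", "DEFAULT_OUTCOME1_PROBS"]

#: Per-arm probability of the (generally preferred) outcome 1.
DEFAULT_OUTCOME1_PROBS = (0.8, 0.2, 0.2)


@dataclass(frozen=True)
class BanditConfig:
    """Stationary bandit: per-arm probability of outcome 1, plus a seed
    recorded for provenance (the rng is passed explicitly to ``pull``)."""

    outcome1_probs: tuple = DEFAULT_OUTCOME1_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.outcome1_probs)
        object.__setattr__(self, "outcome1_probs", probs)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("outcome1_probs must lie in [0, 1]")
        if len(probs) < 1:
            raise ValueError("need at least one arm")

    @property
    def n_arms(self) -> int:
        return len(self.outcome1_probs)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def pull(config: BanditConfig, arm: int, rng: np.random.Generator) -> int:
    """Pull one arm; returns outcome 1 with the arm's configured
    probability, else outcome 2."""
    if not 0 <= arm < config.n_arms:
        raise ValueError(f"invalid arm index {arm} (have {config.n_arms} arms)")
    return 1 if rng.random() < config.outcome1_probs[arm] else 2


def pull_many(
    config: BanditConfig, arm: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised repeated pulls of a single arm (outcomes in {1, 2})."""
    if not 0 <= arm < config.n_arms:
        raise ValueError(f"invalid arm index {arm} (have {config.n_arms} arms)")
    return np.where(rng.random(n) < config.outcome1_probs[arm], 1, 2)
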