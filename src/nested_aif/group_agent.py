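"""Group-level agent: sensory copier + internal POMDP agents + vote aggregator.

The group agent is a fixed Markov-blanket composition: a sensory agent that
copies the environment outcome to every internal agent, N internal
active-inference agents that each emit a vote (an arm choice), and an
active agent that aggregates the votes into the group action.  The
per-trial (observation, group action) pairs are the group's blanket states
and are the only data the fitting module sees.

Trial micro-order (recorded in trajectory metadata): votes -> aggregation
-> environment outcome -> sensory relay -> belief update on the next trial.
Internal agents condition on their OWN vote (they only ever observe the
sensory relay), not on the realized group action; with the known-A,
deterministic-B task model this choice has no behavioural consequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .aif_core import AgentState, GenerativeModel, agent_step
from .bandit_env import BanditConfig, pull

__all__ = [
    "AGGREGATION_MODES",
    "GroupConfig",
    "GroupTrajectory",
    "sensory_relay",
    "aggregate_votes",
    "run_group_simulation",
    "group_action_law",
]

AGGREGATION_MODES = ("probabilistic", "deterministic")


@dataclass(frozen=True)
class GroupConfig:
    """Composition and run length of one group simulation."""

    internal_models: tuple
    aggregation: str = "probabilistic"
    n_trials: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "internal_models", tuple(self.internal_models))
        if len(self.internal_models) < 1:
            raise ValueError("need at least one internal agent")
        if self.aggregation not in AGGREGATION_MODES:
            raise ValueError(
                f"aggregation must be one of {AGGREGATION_MODES}, "
                f"got {self.aggregation!r}"
            )
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def n_internal(self) -> int:
        return len(self.internal_models)


@dataclass
class GroupTrajectory:
    """Blanket-state record of a group run (all indices 0-based in memory).

    ``actions[t]`` is the group's arm choice, ``observations[t]`` the
    bandit outcome (0 = outcome 1, 1 = outcome 2), ``votes[t, i]`` the vote
    of internal agent ``i``.  ``metadata`` snapshots the provenance
    (aggregation mode, seeds, trial order).
    """

    actions: np.ndarray
    observations: np.ndarray
    votes: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.actions)

    @property
    def n_trials(self) -> int:
        return len(self.actions)

    @property
    def n_internal(self) -> int:
        return self.votes.shape[1] if self.votes.ndim == 2 else 0


def sensory_relay(observation: int) -> int:
    """The sensory agent: an identity map from the environment outcome to
    the observation broadcast to every internal agent."""
    return observation


def aggregate_votes(
    votes: Sequence[int], mode: str, rng: np.random.Generator
) -> int:
    """The active agent: turn N internal votes into one group action.

    ``probabilistic`` samples an action with probability proportional to
    its vote count; ``deterministic`` returns the plurality action, ties
    broken uniformly at random.
    """
    votes = np.asarray(votes, dtype=int)
    if votes.size == 0:
        raise ValueError("cannot aggregate an empty vote vector")
    if mode == "probabilistic":
        return int(votes[rng.integers(votes.size)])
    if mode == "deterministic":
        counts = np.bincount(votes)
        winners = np.flatnonzero(counts == counts.max())
        return int(winners[rng.integers(winners.size)])
    raise ValueError(f"unknown aggregation mode {mode!r}")


def run_group_simulation(
    group: GroupConfig,
    bandit: BanditConfig,
    rng: Optional[np.random.Generator] = None,
) -> GroupTrajectory:
    """Simulate the group agent on the bandit for ``group.n_trials`` trials.

    Randomness flows through named substreams spawned from ``group.seed``
    (agents, aggregator, environment) so runs are bit-reproducible; an
    explicit ``rng`` overrides the seed and drives everything.
    """
    if rng is None:
        agents_rng, agg_rng, env_rng = (
            np.random.default_rng(s)
            for s in np.random.SeedSequence(group.seed).spawn(3)
        )
    else:
        agents_rng = agg_rng = env_rng = rng

    models = group.internal_models
    states: List[AgentState] = [AgentState(belief=m.D) for m in models]

    n_trials = group.n_trials
    actions = np.empty(n_trials, dtype=int)
    observations = np.empty(n_trials, dtype=int)
    votes = np.empty((n_trials, len(models)), dtype=int)

    relayed: Optional[int] = None  # 0-based observation, None on trial 0
    for t in range(n_trials):
        for i, model in enumerate(models):
            vote, _, states[i] = agent_step(model, states[i], relayed, agents_rng)
            votes[t, i] = vote
        actions[t] = aggregate_votes(votes[t], group.aggregation, agg_rng)
        outcome = pull(bandit, int(actions[t]), env_rng)  # coded 1/2
        observations[t] = outcome - 1
        relayed = sensory_relay(observations[t])

    metadata = {
        "n_internal": group.n_internal,
        "aggregation": group.aggregation,
        "n_trials": n_trials,
        "seed": group.seed,
        "bandit_outcome1_probs": list(bandit.outcome1_probs),
        "internal_alphas": [m.alpha for m in models],
        "internal_preferences": [m.C.tolist() for m in models],
        "trial_order": "votes->aggregate->outcome->relay->update",
    }
    return GroupTrajectory(
        actions=actions, observations=observations, votes=votes, metadata=metadata
    )


def _majority_distribution(
    dists: np.ndarray, rng: Optional[np.random.Generator], n_samples: int
) -> np.ndarray:
    """Distribution of the tie-broken plurality vote.

    Exact enumeration of all vote assignments when the joint space is small
    enough; Monte Carlo otherwise (heterogeneous agents at large N).
    """
    n_agents, n_actions = dists.shape
    if n_actions**n_agents <= 3**8:
        out = np.zeros(n_actions)
        for assignment in itertools.product(range(n_actions), repeat=n_agents):
            p = 1.0
            for i, a in enumerate(assignment):
                p *= dists[i, a]
            if p == 0.0:
                continue
            counts = np.bincount(assignment, minlength=n_actions)
            winners = np.flatnonzero(counts == counts.max())
            out[winners] += p / winners.size
        return out
    if rng is None:
        rng = np.random.default_rng(0)
    cum = dists.cumsum(axis=1)
    out = np.zeros(n_actions)
    for _ in range(n_samples):
        draws = (rng.random((n_agents, 1)) < cum).argmax(axis=1)
        counts = np.bincount(draws, minlength=n_actions)
        winners = np.flatnonzero(counts == counts.max())
        out[winners] += 1.0 / winners.size
    return out / n_samples


def group_action_law(
    internal_distributions: Sequence[np.ndarray],
    mode: str,
    rng: Optional[np.random.Generator] = None,
    n_samples: int = 100_000,
) -> np.ndarray:
    """Analytic (or enumerated) per-trial group-action distribution.

    Probabilistic aggregation: exactly the arithmetic mean of the internal
    action distributions.  Deterministic aggregation: the distribution of
    the uniformly tie-broken plurality, enumerated exactly for small joint
    vote spaces and Monte-Carlo approximated above.
    """
    dists = np.asarray(internal_distributions, dtype=float)
    if dists.ndim != 2:
        raise ValueError("expected a 2-D array of per-agent distributions")
    if mode == "probabilistic":
        return dists.mean(axis=0)
    if mode == "deterministic":
        return _majority_distribution(dists, rng, n_samples)
    raise ValueError(f"unknown aggregation mode {mode!r}")
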