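"""Altruistic rescue driven by empathized pain as intrinsic reward.

Two agents share the grid world: agentB explores the danger zone and will
inevitably collide with the dangerous object, turning red; agentA sits in
the safety zone with a trained affective-empathy network.  AgentA perceives
agentB's color, and the empathized pain state this induces in its own
emotion module is the *only* reward signal: a per-step penalty while the
shared pain persists, a positive relief reward on the step it clears, and a
small step cost otherwise.  Tabular Q-learning over (agentA cell, passage
flag) then discovers the rescue policy — go to the switch, open the
passage, let agentB escape — without any externally specified task reward.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Hashable

import numpy as np
import pandas as pd

from .ae_snn import EmpathyNetwork, observe_other
from .gridworld import (
    ACTIONS,
    AgentState,
    Cell,
    GridWorld,
    perceive_other,
    random_walk_policy,
    shortest_path,
    step,
)

__all__ = [
    "QTable",
    "IntrinsicRewardModel",
    "RescueScenario",
    "EmpathyOracle",
    "empathic_reward",
    "q_update",
    "train_rescue",
    "run_rescue_episode",
]

State = Hashable


@dataclass
class QTable:
    """Tabular state-action values with epsilon-greedy action selection."""

    alpha: float = 0.1
    gamma: float = 0.9
    epsilon: float = 0.1
    #: value assumed for unvisited state-action pairs.  Zero-initialization
    #: with an all-negative ambient reward turns every under-visited region
    #: into an implicit positive pseudo-reward (optimism in the face of
    #: uncertainty), which would draw even a reward-blind agent around the
    #: arena; a neutral prior equal to the discounted ambient step cost
    #: removes that artifact.
    default_value: float = 0.0
    values: dict[tuple[State, str], float] = field(default_factory=dict)

    def q(self, s: State, a: str) -> float:
        return self.values.get((s, a), self.default_value)

    def max_q(self, s: State) -> float:
        return max(self.q(s, a) for a in ACTIONS)

    def greedy_action(self, s: State, rng: np.random.Generator) -> str:
        qs = np.array([self.q(s, a) for a in ACTIONS])
        best = np.flatnonzero(qs == qs.max())
        return ACTIONS[int(rng.choice(best))]

    def select_action(self, s: State, rng: np.random.Generator, epsilon: float | None = None) -> str:
        eps = self.epsilon if epsilon is None else epsilon
        if rng.random() < eps:
            return ACTIONS[int(rng.integers(len(ACTIONS)))]
        return self.greedy_action(s, rng)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"state": repr(s), "action": a, "value": v}
            for (s, a), v in sorted(self.values.items(), key=lambda kv: repr(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["state", "action", "value"])


def q_update(
    q: QTable, s: State, a: str, r: float, s_next: State, terminal: bool = False
) -> QTable:
    """One tabular Q-learning backup: Q(s,a) += alpha (r + gamma max Q(s',.) - Q(s,a)).

    A terminal transition (goal reached) backs up the reward alone.
    """
    target = r if terminal else r + q.gamma * q.max_q(s_next)
    q.values[(s, a)] = q.q(s, a) + q.alpha * (target - q.q(s, a))
    return q


@dataclass(frozen=True)
class IntrinsicRewardModel:
    """Reward from the observer's own emotion transitions, nothing else."""

    relief_reward: float = 10.0
    pain_penalty: float = -1.0
    step_cost: float = -0.01

    def __post_init__(self) -> None:
        if not (self.relief_reward > 0 >= self.step_cost):
            raise ValueError("need relief_reward > 0 >= step_cost")

    def reward(self, pain_before: bool, pain_after: bool) -> float:
        if pain_before and not pain_after:
            return self.relief_reward
        if pain_after:
            return self.pain_penalty
        return self.step_cost


class EmpathyOracle:
    """Cached empathized-pain response of a fixed trained network.

    ``observe_other`` is deterministic for a fixed network, so the response
    to each percept label is simulated once and reused across RL steps.
    """

    def __init__(self, net: EmpathyNetwork):
        self.net = net
        self._cache: dict[str, bool] = {}

    def pain(self, percept: str) -> bool:
        if percept not in self._cache:
            obs = observe_other(self.net, percept)
            if obs.overt_action_emitted:
                raise RuntimeError("observation must not emit an overt action")
            self._cache[percept] = obs.emotion_active.get("pain", False)
        return self._cache[percept]


def empathic_reward(
    net: EmpathyNetwork,
    percept: str,
    previous_pain: bool,
    model: IntrinsicRewardModel | None = None,
    oracle: EmpathyOracle | None = None,
) -> float:
    """Intrinsic reward for one observation step.

    Runs the observer's network on the percept of the other agent and maps
    the resulting empathized-pain transition to a scalar: relief on the
    pain -> no-pain transition, a penalty while empathized pain persists, a
    small step cost otherwise.
    """
    model = model or IntrinsicRewardModel()
    oracle = oracle or EmpathyOracle(net)
    return model.reward(previous_pain, oracle.pain(percept))


@dataclass
class RescueScenario:
    """Two-agent rescue setup: trained empathizer A, trapped explorer B."""

    net: EmpathyNetwork
    world: GridWorld = field(default_factory=GridWorld)
    agentA_start: Cell = (7, 5)
    agentB_start: Cell = (1, 1)
    reward_model: IntrinsicRewardModel = field(default_factory=IntrinsicRewardModel)
    max_rescue_steps: int = 40
    max_pre_pain_steps: int = 2000

    def __post_init__(self) -> None:
        if self.world.zone_of(self.agentA_start) != "safety":
            raise ValueError("agentA must start in the safety zone")
        if self.world.zone_of(self.agentB_start) != "danger":
            raise ValueError("agentB must start in the danger zone")
        if self.world.zone_of(self.world.switch_cell) != "safety":
            raise ValueError("the switch must be unreachable for agentB")

    def fresh_world(self) -> GridWorld:
        return copy.deepcopy(self.world)


@dataclass
class EpisodeRecord:
    success: bool
    steps_to_rescue: int
    total_reward: float
    events: list[tuple[int, str]]
    agentA_colors: set[str]
    switch_step: int | None
    #: per-turn (step, agentA cell, agentB cell, passage_open, colorA, colorB)
    trajectory: list[tuple] = field(default_factory=list)


def _agentB_move(world: GridWorld, agentB: AgentState, rng: np.random.Generator) -> tuple[AgentState, list[str]]:
    """AgentB's turn: random walk while trapped; once the passage is open it
    heads for the safety zone spontaneously and immediately."""
    if world.passage_open and world.zone_of(agentB.cell) != "safety":
        safety_cells = [c for c in world.cells("safety")]
        path = shortest_path(world, agentB.cell, safety_cells)
        if path is not None and len(path) > 1:
            nxt = path[1]
            d = (nxt[0] - agentB.cell[0], nxt[1] - agentB.cell[1])
            # issue the command whose (possibly inverted) execution moves
            # along the path
            want = {(0, -1): "up", (0, 1): "down", (-1, 0): "left", (1, 0): "right"}[d]
            inverse = {"up": "down", "down": "up", "left": "right", "right": "left"}
            command = inverse[want] if agentB.damaged else want
            return step(world, agentB, command)
    return step(world, agentB, random_walk_policy(rng))


def run_rescue_episode(
    scenario: RescueScenario,
    q: QTable,
    rng: np.random.Generator,
    greedy: bool = False,
    learn: bool = True,
    oracle: EmpathyOracle | None = None,
) -> EpisodeRecord:
    """Run one rescue episode.

    AgentB random-walks until it is in pain; then agentA acts one step per
    agentB step, selecting actions epsilon-greedily (greedily if ``greedy``)
    and, if ``learn``, updating the Q-table from its intrinsic reward.
    Success requires the passage open, agentB recovered in the safety zone
    and agentA's empathized pain cleared.
    """
    world = scenario.fresh_world()
    oracle = oracle or EmpathyOracle(scenario.net)
    agentA = AgentState(id="A", cell=scenario.agentA_start, zone="safety")
    agentB = AgentState(id="B", cell=scenario.agentB_start, zone="danger")
    events: list[tuple[int, str]] = []

    # phase 1: B explores until the collision puts it in pain
    for _ in range(scenario.max_pre_pain_steps):
        agentB, evs = step(world, agentB, random_walk_policy(rng))
        if "collision" in evs:
            events.append((0, "B-pain"))
            break
    else:
        return EpisodeRecord(False, 0, 0.0, events, {agentA.color}, None)

    total_reward = 0.0
    colors = {agentA.color}
    trajectory: list[tuple] = []
    pain_before = oracle.pain(perceive_other(agentA, agentB))
    switch_step = None
    success = False
    steps = 0
    for t in range(1, scenario.max_rescue_steps + 1):
        steps = t
        s = (agentA.cell, world.passage_open)
        action = q.select_action(s, rng, epsilon=0.0 if greedy else None)
        agentA, evsA = step(world, agentA, action)
        colors.add(agentA.color)
        if "switch" in evsA:
            switch_step = t
            events.append((t, "switch"))

        agentB, evsB = _agentB_move(world, agentB, rng)
        if "recovery" in evsB:
            events.append((t, "B-recovery"))

        pain_after = oracle.pain(perceive_other(agentA, agentB))
        if pain_before and not pain_after:
            events.append((t, "A-relief"))
        r = scenario.reward_model.reward(pain_before, pain_after)
        total_reward += r
        s_next = (agentA.cell, world.passage_open)
        rescued = (
            world.passage_open
            and agentB.zone == "safety"
            and not agentB.damaged
            and not pain_after
        )
        # the rescue ends the episode, not the world: the final transition
        # bootstraps from the ambient prior like any other, so episode
        # termination itself carries no implicit reward
        if learn:
            q_update(q, s, action, r, s_next)
        pain_before = pain_after
        trajectory.append(
            (t, agentA.cell, agentB.cell, world.passage_open, agentA.color, agentB.color)
        )
        if rescued:
            success = True
            break
    return EpisodeRecord(
        success, steps, total_reward, events, colors, switch_step, trajectory
    )


def train_rescue(
    scenario: RescueScenario,
    episodes: int = 200,
    seed: int = 0,
    epsilon_decay: float = 0.99,
    min_epsilon: float = 0.01,
) -> tuple[QTable, pd.DataFrame]:
    """Train the rescue policy; returns the Q-table and a per-episode log."""
    rng = np.random.default_rng(seed)
    model = scenario.reward_model
    q = QTable()
    q.default_value = model.step_cost / (1.0 - q.gamma)
    oracle = EmpathyOracle(scenario.net)
    eps0 = q.epsilon
    rows = []
    for ep in range(1, episodes + 1):
        q.epsilon = max(min_epsilon, eps0 * epsilon_decay**ep)
        rec = run_rescue_episode(scenario, q, rng, oracle=oracle)
        rows.append(
            {
                "episode": ep,
                "steps_to_rescue": rec.steps_to_rescue,
                "success": rec.success,
                "total_reward": rec.total_reward,
            }
        )
    q.epsilon = eps0
    return q, pd.DataFrame(rows)
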