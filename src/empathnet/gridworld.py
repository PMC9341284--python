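"""Grid-world environment: zones, walls, danger object, switch and passage.

A wall column splits the arena into a danger zone (left, containing a
dangerous object) and a safety zone (right, containing a switch).  Touching
the switch permanently opens a passage cell in the wall.  Agents are
pentagons occupying one cell; colliding with the dangerous object impairs
the motor system so that every subsequent command executes inverted
(right moves left, up moves down) until the agent enters the safety zone,
where it recovers immediately.

The agent's own damage is detected through the Artificial Pain model: it
predicts its next pose with the healthy moving rule (walls included) and
compares against the pose actually reached; any mismatch yields positive
free energy, i.e. pain.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .artificial_pain import (
    DIRECTIONS,
    FreeEnergyReport,
    PentagonPose,
    free_energy_grid,
    predict_next_pose,
)

__all__ = [
    "GridWorld",
    "AgentState",
    "ACTIONS",
    "pentagon_pose",
    "step",
    "sense_self",
    "perceive_other",
    "random_walk_policy",
    "shortest_path",
    "explore",
]

ACTIONS = ("up", "down", "left", "right")

# Fixed pentagon vertex offsets within a cell, as fractions of the cell
# length, centroid at the cell centre.  The template never rotates: the
# heading is metadata (the tip conceptually points along it), and a fixed
# template keeps pose differences purely translational, which is all the
# free-energy damage score measures.  Offsets are dyadic fractions so that
# translated poses compare exactly (the pain flag tests free energy > 0
# with no tolerance).
_PENTAGON_UNIT = np.array(
    [
        [0.5000, 0.15625],
        [0.8125, 0.40625],
        [0.6875, 0.78125],
        [0.3125, 0.78125],
        [0.1875, 0.40625],
    ]
)

Cell = tuple[int, int]


def pentagon_pose(cell: Cell, cell_length: float) -> PentagonPose:
    """Pose of the pentagon template placed in a grid cell."""
    col, row = cell
    origin = np.array([col * cell_length, row * cell_length])
    return PentagonPose.from_array(origin + _PENTAGON_UNIT * cell_length)


@dataclass
class GridWorld:
    """Arena geometry plus the mutable passage flag."""

    width: int = 11
    height: int = 7
    cell_length: float = 25.0
    wall_col: int = 5
    danger_cell: Cell = (2, 3)
    switch_cell: Cell = (9, 1)
    passage_cells: frozenset[Cell] = frozenset({(5, 3)})
    passage_open: bool = False
    walls: frozenset[Cell] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.walls:
            self.walls = frozenset((self.wall_col, r) for r in range(self.height))
        self.passage_cells = frozenset(self.passage_cells)
        if not self.passage_cells <= self.walls:
            raise ValueError("passage cells must be wall cells")
        if self.zone_of(self.danger_cell) != "danger":
            raise ValueError("the dangerous object must sit in the danger zone")
        if self.zone_of(self.switch_cell) != "safety":
            raise ValueError("the switch must sit in the safety zone")

    def contains(self, col: int, row: int) -> bool:
        return 0 <= col < self.width and 0 <= row < self.height

    def passable(self, col: int, row: int) -> bool:
        if not self.contains(col, row):
            return False
        if (col, row) in self.walls:
            return self.passage_open and (col, row) in self.passage_cells
        return True

    def zone_of(self, cell: Cell) -> str:
        col, _ = cell
        if col < self.wall_col:
            return "danger"
        if col > self.wall_col:
            return "safety"
        return "passage"

    def cells(self, zone: str | None = None) -> list[Cell]:
        out = []
        for col in range(self.width):
            for row in range(self.height):
                cell = (col, row)
                if cell in self.walls and cell not in self.passage_cells:
                    continue
                if cell in self.walls and not self.passage_open:
                    continue
                if zone is None or self.zone_of(cell) == zone:
                    out.append(cell)
        return out


@dataclass
class AgentState:
    """One pentagon agent: position, motor integrity and overt color."""

    id: str
    cell: Cell
    heading: str = "up"
    damaged: bool = False
    color: str = "green"
    zone: str = "danger"

    @property
    def pose(self) -> PentagonPose:
        raise AttributeError("use pose_in(world); the pose depends on the cell length")

    def pose_in(self, world: GridWorld) -> PentagonPose:
        return pentagon_pose(self.cell, world.cell_length)


def step(world: GridWorld, agent: AgentState, command: str) -> tuple[AgentState, list[str]]:
    """Execute one movement command, applying the damage/switch/recovery rules.

    A damaged agent moves one cell in the *inverted* direction (both axes).
    Blocked moves leave the agent in place.  Moving onto the dangerous
    object impairs the agent; occupying the switch cell opens the passage
    permanently; entering the safety zone restores the normal state.
    """
    if command not in DIRECTIONS:
        raise ValueError(f"unknown command {command!r}")
    if not world.contains(*agent.cell):
        raise RuntimeError(f"agent {agent.id} is outside the grid at {agent.cell}")
    dc, dr = DIRECTIONS[command]
    if agent.damaged:
        dc, dr = -dc, -dr
    target = (agent.cell[0] + dc, agent.cell[1] + dr)
    new_cell = target if world.passable(*target) else agent.cell

    events: list[str] = []
    damaged = agent.damaged
    if new_cell == world.danger_cell and not damaged:
        damaged = True
        events.append("collision")
    if new_cell == world.switch_cell and not world.passage_open:
        world.passage_open = True
        events.append("switch")
    zone = world.zone_of(new_cell)
    if zone == "safety" and damaged:
        damaged = False
        events.append("recovery")
    return (
        replace(
            agent,
            cell=new_cell,
            heading=command,
            damaged=damaged,
            color="red" if damaged else "green",
            zone=zone,
        ),
        events,
    )


def sense_self(
    before: AgentState,
    after: AgentState,
    command: str,
    world: GridWorld,
) -> FreeEnergyReport:
    """Artificial Pain check for the step just taken.

    Predicts the pose the healthy moving rule implies for ``command`` from
    the pre-step pose and compares it with the pose actually reached.  Any
    damage-induced deviation yields positive free energy (pain).
    """
    predicted = predict_next_pose(before.pose_in(world), command, world)
    return free_energy_grid(predicted, after.pose_in(world))


def perceive_other(observer: AgentState, target: AgentState) -> str:
    """Overt-action percept of the target's color, as consumed by the AE-SNN."""
    return {"red": "perceive-red", "green": "perceive-green"}[target.color]


def random_walk_policy(rng: np.random.Generator) -> str:
    """Uniform draw over the four movement commands."""
    return ACTIONS[int(rng.integers(len(ACTIONS)))]


def shortest_path(
    world: GridWorld,
    start: Cell,
    goal: Cell | Iterable[Cell],
    assume_passage_open: bool | None = None,
) -> list[Cell] | None:
    """BFS shortest path over passable cells (None if unreachable)."""
    goals = {goal} if isinstance(goal, tuple) else set(goal)
    saved = world.passage_open
    if assume_passage_open is not None:
        world.passage_open = assume_passage_open
    try:
        frontier: deque[Cell] = deque([start])
        prev: dict[Cell, Cell | None] = {start: None}
        while frontier:
            cell = frontier.popleft()
            if cell in goals:
                path = [cell]
                while prev[path[-1]] is not None:
                    path.append(prev[path[-1]])  # type: ignore[arg-type]
                return path[::-1]
            for dc, dr in DIRECTIONS.values():
                nxt = (cell[0] + dc, cell[1] + dr)
                if nxt not in prev and world.passable(*nxt):
                    prev[nxt] = cell
                    frontier.append(nxt)
        return None
    finally:
        world.passage_open = saved


def explore(
    world: GridWorld,
    agent: AgentState,
    n_steps: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, AgentState]:
    """Random-walk exploration with Artificial Pain sensing at every step.

    Returns the per-step episode record (position, damage, color, zone,
    events and the free-energy trace) and the final agent state.
    """
    rows = []
    for k in range(1, n_steps + 1):
        command = random_walk_policy(rng)
        before = agent
        agent, events = step(world, agent, command)
        report = sense_self(before, agent, command, world)
        rows.append(
            {
                "step": k,
                "agent_id": agent.id,
                "column": agent.cell[0],
                "row": agent.cell[1],
                "damaged": agent.damaged,
                "color": agent.color,
                "zone": agent.zone,
                "event": "+".join(events),
                "fe_raw": report.fe_raw,
                "fe_clipped": report.fe_clipped,
                "pain": report.pain,
            }
        )
    return pd.DataFrame(rows), agent
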