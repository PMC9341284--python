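"""Artificial Pain: free-energy prediction error as a body-damage signal.

Under unit-variance Gaussian assumptions the free energy of an agent's
self-model reduces to a half-sum of squared prediction errors.  Three forms
are provided:

* the generic two-term form ``1/2 (s - g_s(phi_hat))^2 + 1/2 (phi_hat - mu_phi)^2``
  over a single sensory channel;
* the robot three-term form splitting sensation into vision and
  proprioception and adding the environmental dynamic
  ``1/2 (phi_hat - g_phi(phi_prev, a_prev))^2``;
* the grid-world form: the plain sum of squared coordinate differences
  between the predicted and actual pentagon pose of the agent.

Whenever the free energy is strictly positive the body deviates from its
self-model's prediction and the agent is in the pain state; at zero it is in
the normal state.  For plotting, grid-world free energy is clipped at 3125
(one grid unit of displacement at all five vertices); the pain flag always
uses the raw value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

__all__ = [
    "FE_CLIP",
    "PentagonPose",
    "FreeEnergyReport",
    "GenericFreeEnergyInputs",
    "free_energy_general",
    "free_energy_grid",
    "predict_next_pose",
    "DIRECTIONS",
]

#: Plotting ceiling for grid-world free energy: 5 vertices * 25^2.
FE_CLIP = 3125.0

#: Cardinal movement commands in cell units. "up" decreases the row/Y value,
#: "right" increases the column/X value.
DIRECTIONS: dict[str, tuple[int, int]] = {
    "up": (0, -1),
    "down": (0, 1),
    "left": (-1, 0),
    "right": (1, 0),
}


@dataclass(frozen=True)
class PentagonPose:
    """Five (X, Y) vertex coordinates of the pentagon-shaped agent."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) != 5:
            raise ValueError("a pentagon pose has exactly five vertices")
        arr = self.array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("vertex coordinates must be finite")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PentagonPose":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5, 2):
            raise ValueError(f"expected a (5, 2) vertex array, got {arr.shape}")
        return cls(tuple(map(tuple, arr)))

    def array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def translated(self, dx: float, dy: float) -> "PentagonPose":
        return PentagonPose.from_array(self.array() + np.array([dx, dy]))

    def centroid(self) -> tuple[float, float]:
        c = self.array().mean(axis=0)
        return float(c[0]), float(c[1])


@dataclass(frozen=True)
class FreeEnergyReport:
    """Free energy of one time step plus the derived pain flag.

    ``pain`` is true iff the raw free energy is strictly positive;
    ``fe_clipped`` is the value recorded for traces/plots, capped at
    :data:`FE_CLIP`.
    """

    fe_raw: float
    fe_clipped: float
    pain: bool

    @classmethod
    def from_raw(cls, fe_raw: float) -> "FreeEnergyReport":
        if fe_raw < 0:
            raise ValueError("free energy cannot be negative")
        return cls(fe_raw=fe_raw, fe_clipped=min(fe_raw, FE_CLIP), pain=fe_raw > 0)


@dataclass
class GenericFreeEnergyInputs:
    """Inputs for the generic Gaussian free-energy forms.

    Supply ``sensory`` and ``g_s`` for the two-term form, or ``s_vision``,
    ``s_proprio``, ``g_sv``, ``g_sp``, ``g_phi``, ``phi_prev`` and
    ``action_prev`` for the robot three-term form.  Generators must be pure
    functions.  Variances are fixed to one, which is what reduces the free
    energy to the half-sum-of-squares forms implemented here.
    """

    phi_hat: float | np.ndarray
    mu_phi: float | np.ndarray | None = None
    sensory: float | np.ndarray | None = None
    g_s: Callable | None = None
    s_vision: float | np.ndarray | None = None
    s_proprio: float | np.ndarray | None = None
    g_sv: Callable | None = None
    g_sp: Callable | None = None
    g_phi: Callable | None = None
    phi_prev: float | np.ndarray | None = None
    action_prev: object | None = None


def _half_sq(x) -> float:
    return 0.5 * float(np.sum(np.square(np.asarray(x, dtype=float))))


def free_energy_general(inputs: GenericFreeEnergyInputs) -> float:
    """Evaluate the generic or the split-sensor (robot) free-energy form."""
    split = inputs.s_vision is not None or inputs.s_proprio is not None
    if split:
        missing = [
            name
            for name in ("s_vision", "s_proprio", "g_sv", "g_sp", "g_phi", "phi_prev")
            if getattr(inputs, name) is None
        ]
        if missing:
            raise ValueError(f"split-sensor form needs {', '.join(missing)}")
        fe = _half_sq(np.asarray(inputs.s_vision) - np.asarray(inputs.g_sv(inputs.phi_hat)))
        fe += _half_sq(np.asarray(inputs.s_proprio) - np.asarray(inputs.g_sp(inputs.phi_hat)))
        fe += _half_sq(
            np.asarray(inputs.phi_hat)
            - np.asarray(inputs.g_phi(inputs.phi_prev, inputs.action_prev))
        )
        return fe
    if inputs.sensory is None or inputs.g_s is None or inputs.mu_phi is None:
        raise ValueError("generic form needs sensory, g_s and mu_phi")
    fe = _half_sq(np.asarray(inputs.sensory) - np.asarray(inputs.g_s(inputs.phi_hat)))
    fe += _half_sq(np.asarray(inputs.phi_hat) - np.asarray(inputs.mu_phi))
    return fe


def free_energy_grid(predicted: PentagonPose, actual: PentagonPose) -> FreeEnergyReport:
    """Grid-world free energy: sum of squared vertex-coordinate differences.

    A uniform one-cell (25-unit) displacement of all five vertices gives
    3125; a two-cell (50-unit) displacement gives 12500 — the extreme values
    a single damaged move can produce.
    """
    diff = predicted.array() - actual.array()
    fe_raw = float(np.sum(diff**2))
    return FreeEnergyReport.from_raw(fe_raw)


class _GridLike(Protocol):
    cell_length: float

    def contains(self, col: int, row: int) -> bool: ...

    def passable(self, col: int, row: int) -> bool: ...


def predict_next_pose(current: PentagonPose, command: str, world: _GridLike) -> PentagonPose:
    """Predicted pose after one commanded move under the healthy moving rule.

    The predictor knows the moving rule in advance, including walls and grid
    bounds: a blocked move predicts no displacement.  Only damage-induced
    deviation from this rule therefore produces non-zero free energy.
    """
    if command not in DIRECTIONS:
        raise ValueError(f"unknown movement command {command!r}")
    cx, cy = current.centroid()
    L = world.cell_length
    col, row = int(cx // L), int(cy // L)
    if not world.contains(col, row):
        raise ValueError(f"pose centroid cell ({col}, {row}) lies outside the grid")
    dc, dr = DIRECTIONS[command]
    if world.contains(col + dc, row + dr) and world.passable(col + dc, row + dr):
        return current.translated(dc * L, dr * L)
    return current
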