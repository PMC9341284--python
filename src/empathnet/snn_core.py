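"""Time-stepped spiking-network primitives.

Leaky integrate-and-fire (LIF) populations advanced by explicit Euler
integration, spike-timing-dependent plasticity (STDP) weight updates, and a
plain spike-raster record that serializes to CSV.

The LIF membrane follows

    tau_m * du/dt = -(u - u_rest) + R * I(t)

with a hard threshold ``u_th``: on crossing, the neuron emits a spike and the
potential is reset to ``u_reset``.  STDP is the classic exponential pair rule:
with ``dt_pair = t_pre - t_post``, a pre-before-post pair (``dt_pair < 0``)
potentiates by ``A_plus * exp(dt_pair / tau_plus)`` and a post-before-pre pair
depresses by ``A_minus * exp(-dt_pair / tau_minus)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LIFParameters",
    "NeuronPopulation",
    "SpikeRaster",
    "STDPParameters",
    "SynapseMatrix",
    "lif_step",
    "stdp_delta",
    "apply_stdp",
    "record_raster",
    "write_raster",
    "read_raster",
]

NEVER = -np.inf  # sentinel for "has not spiked yet"


@dataclass(frozen=True)
class LIFParameters:
    """Constants of the leaky integrate-and-fire neuron.

    Defaults are the model's printed values: ``u_rest = u_reset = 0`` mV,
    ``tau_m = 30`` ms, ``u_th = 60`` mV.  ``R`` is a dimensionless scale on
    the input current; ``dt`` the Euler step in ms.
    """

    u_rest: float = 0.0
    u_reset: float = 0.0
    u_th: float = 60.0
    tau_m: float = 30.0
    R: float = 1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not self.u_th > self.u_rest:
            raise ValueError("u_th must exceed u_rest")
        if not self.tau_m > 0:
            raise ValueError("tau_m must be positive")
        if not (0 < self.dt < self.tau_m):
            raise ValueError("dt must satisfy 0 < dt < tau_m")


@dataclass
class NeuronPopulation:
    """A homogeneous block of LIF neurons.

    ``last_spike_times`` holds the most recent firing time per neuron in ms,
    with ``-inf`` meaning the neuron has never fired.
    """

    size: int
    potentials: np.ndarray
    last_spike_times: np.ndarray

    @classmethod
    def at_rest(cls, size: int, params: LIFParameters) -> "NeuronPopulation":
        return cls(
            size=size,
            potentials=np.full(size, params.u_rest, dtype=float),
            last_spike_times=np.full(size, NEVER, dtype=float),
        )

    def __post_init__(self) -> None:
        if len(self.potentials) != self.size or len(self.last_spike_times) != self.size:
            raise ValueError("potential/spike-time vectors must have length size")


def lif_step(
    pop: NeuronPopulation,
    input_current: np.ndarray,
    params: LIFParameters,
    t: float = 0.0,
) -> tuple[NeuronPopulation, np.ndarray]:
    """Advance a population one Euler step; return it with the fired indices.

    Any neuron whose potential reaches ``u_th`` is reported as fired, has its
    ``last_spike_time`` set to ``t`` and its potential reset to ``u_reset``.
    """
    input_current = np.asarray(input_current, dtype=float)
    if input_current.shape != (pop.size,):
        raise ValueError(
            f"input_current has shape {input_current.shape}, expected ({pop.size},)"
        )
    if not np.all(np.isfinite(input_current)):
        raise ValueError("input_current contains non-finite values")

    u = pop.potentials
    u += (params.dt / params.tau_m) * (-(u - params.u_rest) + params.R * input_current)
    fired = np.flatnonzero(u >= params.u_th)
    if fired.size:
        u[fired] = params.u_reset
        pop.last_spike_times[fired] = t
    return pop, fired


@dataclass(frozen=True)
class STDPParameters:
    """Constants of the exponential pair-based STDP rule.

    Defaults are the printed values ``A_plus = 0.25``, ``A_minus = 0.01``,
    ``tau_plus = tau_minus = 10`` ms.  ``window`` truncates pairing at
    5 * tau, where the exponential has decayed below 1% of its peak.
    Plastic weights live in ``[w_min, w_max]``.
    """

    A_plus: float = 0.25
    A_minus: float = 0.01
    tau_plus: float = 10.0
    tau_minus: float = 10.0
    window: float = 50.0
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        for name in ("A_plus", "A_minus", "tau_plus", "tau_minus", "window"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be below w_max")


def stdp_delta(t_pre: float, t_post: float, params: STDPParameters) -> float:
    """Weight change for one pre/post spike pair.

    ``dt_pair = t_pre - t_post``; negative values (pre fires first)
    potentiate, positive values depress, coincident or out-of-window pairs
    contribute nothing.
    """
    if not (np.isfinite(t_pre) and np.isfinite(t_post)):
        raise ValueError("spike times must be finite")
    dt_pair = t_pre - t_post
    if dt_pair == 0.0 or abs(dt_pair) > params.window:
        return 0.0
    if dt_pair < 0:
        return params.A_plus * float(np.exp(dt_pair / params.tau_plus))
    return -params.A_minus * float(np.exp(-dt_pair / params.tau_minus))


@dataclass
class SpikeRaster:
    """An ordered record of spikes as (module label, neuron index, time ms)."""

    modules: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    neurons: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __len__(self) -> int:
        return len(self.times)

    def select(self, module: str) -> "SpikeRaster":
        keep = self.modules == module
        return SpikeRaster(self.modules[keep], self.neurons[keep], self.times[keep])

    def neuron_times(self, module: str, neuron: int) -> np.ndarray:
        sub = self.select(module)
        return np.sort(sub.times[sub.neurons == neuron])

    def fired_neurons(self, module: str) -> np.ndarray:
        """Sorted unique indices of neurons that fired at least once."""
        return np.unique(self.select(module).neurons)

    def onset(self, module: str) -> float:
        """Time of the first spike in a module (nan if it never fired)."""
        sub = self.select(module)
        return float(sub.times.min()) if len(sub) else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "module": self.modules,
                "neuron_index": self.neurons,
                "time_ms": self.times,
            }
        )


def record_raster(events: Iterable[tuple[str, int, float]]) -> SpikeRaster:
    """Build a raster from (module, neuron, time) events, sorted by time."""
    rows = list(events)
    if not rows:
        return SpikeRaster()
    modules = np.array([r[0] for r in rows], dtype=object)
    neurons = np.array([r[1] for r in rows], dtype=int)
    times = np.array([r[2] for r in rows], dtype=float)
    if np.any(times < 0):
        raise ValueError("spike times must be non-negative")
    order = np.argsort(times, kind="stable")
    return SpikeRaster(modules[order], neurons[order], times[order])


def merge_rasters(*rasters: SpikeRaster) -> SpikeRaster:
    events: list[tuple[str, int, float]] = []
    for r in rasters:
        events.extend(zip(r.modules, r.neurons, r.times))
    return record_raster(events)


def write_raster(raster: SpikeRaster, path: str | Path) -> Path:
    """Serialize to CSV with columns module,neuron_index,time_ms."""
    path = Path(path)
    raster.to_frame().to_csv(path, index=False)
    return path


def read_raster(path: str | Path) -> SpikeRaster:
    df = pd.read_csv(path)
    return record_raster(
        zip(df["module"].astype(str), df["neuron_index"].astype(int), df["time_ms"].astype(float))
    )


@dataclass
class SynapseMatrix:
    """A pre x post weight matrix with fixed polarity and optional plasticity.

    Weights are stored as non-negative magnitudes; an inhibitory matrix (or an
    inhibitory column of a mixed matrix, via ``post_sign``) contributes
    non-positive current.  ``gain`` converts a unit weight into injected
    current per presynaptic spike; ``mask`` encodes structural connectivity
    (absent synapses never carry current and never learn).
    """

    weights: np.ndarray
    polarity: str = "excitatory"  # "excitatory" | "inhibitory" | "mixed"
    plastic: bool = False
    gain: float = 1.0
    mask: np.ndarray | None = None
    post_sign: np.ndarray | None = None  # required iff polarity == "mixed"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.polarity not in ("excitatory", "inhibitory", "mixed"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.polarity == "mixed":
            if self.post_sign is None:
                raise ValueError("mixed polarity requires post_sign")
            self.post_sign = np.asarray(self.post_sign, dtype=float)
            if self.post_sign.shape != (self.weights.shape[1],):
                raise ValueError("post_sign must have one entry per post neuron")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.weights.shape:
                raise ValueError("mask shape must match weights")
            self.weights = self.weights * self.mask
        if np.any(self.weights < 0):
            raise ValueError("weights are stored as non-negative magnitudes")

    @property
    def n_pre(self) -> int:
        return self.weights.shape[0]

    @property
    def n_post(self) -> int:
        return self.weights.shape[1]

    def signs(self) -> np.ndarray:
        if self.polarity == "excitatory":
            return np.ones(self.n_post)
        if self.polarity == "inhibitory":
            return -np.ones(self.n_post)
        return self.post_sign  # type: ignore[return-value]

    def effective(self) -> np.ndarray:
        """Signed current matrix: gain * magnitude * polarity (masked)."""
        w = self.weights if self.mask is None else self.weights * self.mask
        return self.gain * w * self.signs()[None, :]

    def current(self, pre_spiking: np.ndarray) -> np.ndarray:
        """Post-synaptic current from a boolean/0-1 presynaptic spike vector."""
        pre_spiking = np.asarray(pre_spiking, dtype=float)
        if pre_spiking.shape != (self.n_pre,):
            raise ValueError("presynaptic spike vector has the wrong length")
        return pre_spiking @ self.effective()


def apply_stdp(
    syn: SynapseMatrix,
    pre_raster: SpikeRaster,
    post_raster: SpikeRaster,
    params: STDPParameters,
    pre_module: str | None = None,
    post_module: str | None = None,
) -> SynapseMatrix:
    """Accumulate pairwise STDP onto a plastic matrix and clamp to bounds.

    Every (pre spike, post spike) pair within ``params.window`` contributes
    :func:`stdp_delta` to the corresponding weight magnitude.  For inhibitory
    synapses the same delta grows the magnitude of the (negative-effect)
    weight, so correlated firing strengthens inhibition.  Structurally absent
    synapses (mask false) are untouched.
    """
    if not syn.plastic:
        raise ValueError("apply_stdp called on a non-plastic SynapseMatrix")
    pre = pre_raster if pre_module is None else pre_raster.select(pre_module)
    post = post_raster if post_module is None else post_raster.select(post_module)
    if len(pre) and pre.neurons.max() >= syn.n_pre:
        raise ValueError("presynaptic neuron index out of range")
    if len(post) and post.neurons.max() >= syn.n_post:
        raise ValueError("postsynaptic neuron index out of range")

    if len(pre) and len(post):
        dt_pair = pre.times[:, None] - post.times[None, :]
        delta = np.zeros_like(dt_pair)
        pot = dt_pair < 0
        dep = dt_pair > 0
        delta[pot] = params.A_plus * np.exp(dt_pair[pot] / params.tau_plus)
        delta[dep] = -params.A_minus * np.exp(-dt_pair[dep] / params.tau_minus)
        delta[np.abs(dt_pair) > params.window] = 0.0

        change = np.zeros_like(syn.weights)
        np.add.at(change, (pre.neurons[:, None], post.neurons[None, :]), delta)
        if syn.mask is not None:
            change = change * syn.mask
        syn.weights = np.clip(syn.weights + change, params.w_min, params.w_max)
    return syn
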