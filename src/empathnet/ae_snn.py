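"""The affective-empathy spiking network (AE-SNN).

Three population-coded LIF modules — emotion, motor, perception — wired so
that mirror neurons and anti-mirror neurons emerge from STDP during action
execution and re-afference:

* Emotion -> motor wiring is fixed ("hereditary"): each emotion block excites
  the motor ensemble of its overt action, except M1 neurons, which receive
  input exclusively from SMA neurons (the SMA->M1 gate).
* Perception -> motor synapses are plastic: inhibitory onto SMA neurons,
  excitatory onto the remaining non-M1 motor neurons, structurally absent
  onto M1.  During an execution epoch the motor ensemble fires continuously
  and, after a 200 ms re-afference delay, the matching perception block fires
  too; STDP then strengthens the matched perception->motor synapses, turning
  the perception-reachable motor neurons into mirror neurons.
* Motor -> emotion wiring is the transpose of emotion -> motor and is used in
  reverse during observation: mirror-neuron firing activates the matched
  emotion block, which is the empathic representation of the other's state.

Because observation leaves SMA (inhibited) and M1 (gated) silent, the motor
firing pattern differs between executing an action and observing it — the
anti-mirror/self-other signature.  The emotion -> motor pathway carries
current only when the emotion originates from the agent's own pain model
(``efferent_gate``); an empathically activated emotion block is a readout and
does not trigger overt action.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .snn_core import (
    LIFParameters,
    NeuronPopulation,
    SpikeRaster,
    STDPParameters,
    SynapseMatrix,
    apply_stdp,
    lif_step,
    record_raster,
)

__all__ = [
    "EMOTIONS",
    "COLOR_OF_EMOTION",
    "PERCEPT_OF_EMOTION",
    "EMOTION_OF_PERCEPT",
    "ModuleSpec",
    "TrainingSchedule",
    "EmpathyNetwork",
    "ObservationResult",
    "build_network",
    "run_execution_epoch",
    "train",
    "observe_other",
    "execute_emotion",
    "classify_neurons",
    "infer_emotion_from_motor",
    "empathy_test",
    "epochs_to_empathy",
    "NEURON_TYPE_LABELS",
]

EMOTIONS = ("pain", "normal")
COLOR_OF_EMOTION = {"pain": "red", "normal": "green"}
PERCEPT_OF_EMOTION = {"pain": "perceive-red", "normal": "perceive-green"}
EMOTION_OF_PERCEPT = {v: k for k, v in PERCEPT_OF_EMOTION.items()}

#: Fraction of an action's motor ensemble (incl. M1) that must fire before
#: the overt action (color change) is emitted.
OVERT_FRACTION = 0.9


def _default_emotion_coding() -> dict[str, tuple[int, int]]:
    return {"pain": (0, 20), "normal": (20, 40)}


def _default_perception_coding() -> dict[str, tuple[int, int]]:
    return {"perceive-red": (0, 20), "perceive-green": (20, 40)}


def _default_motor_partition() -> dict[str, tuple[int, ...]]:
    # 50 motor neurons: 5+5 SMA, 10 M1 (4 per action + 2 wired to both SMA
    # groups), 24 single-emotion mirror candidates, 6 dual-emotion candidates
    # split by which perception block may reach them.  The smallest partition
    # that realizes all eight motor neuron types.
    return {
        "sma:pain": tuple(range(0, 5)),
        "sma:normal": tuple(range(5, 10)),
        "m1:pain": tuple(range(10, 14)),
        "m1:normal": tuple(range(14, 18)),
        "m1:both": (18, 19),
        "mirror:pain": tuple(range(20, 32)),
        "mirror:normal": tuple(range(32, 44)),
        "shared:percept-pain": (44, 45),
        "shared:percept-normal": (46, 47),
        "shared:both": (48, 49),
    }


@dataclass
class ModuleSpec:
    """Population sizes and index-block layout of the three modules."""

    n_emotion: int = 40
    n_motor: int = 50
    n_perception: int = 40
    emotion_coding: dict[str, tuple[int, int]] = field(default_factory=_default_emotion_coding)
    perception_coding: dict[str, tuple[int, int]] = field(
        default_factory=_default_perception_coding
    )
    motor_partition: dict[str, tuple[int, ...]] = field(default_factory=_default_motor_partition)

    def __post_init__(self) -> None:
        for coding, n, what in (
            (self.emotion_coding, self.n_emotion, "emotion"),
            (self.perception_coding, self.n_perception, "perception"),
        ):
            covered: set[int] = set()
            for label, (lo, hi) in coding.items():
                if not (0 <= lo < hi <= n):
                    raise ValueError(f"{what} block {label!r} out of range")
                block = set(range(lo, hi))
                if covered & block:
                    raise ValueError(f"{what} blocks overlap at {label!r}")
                covered |= block
            if covered != set(range(n)):
                raise ValueError(f"{what} blocks must cover all {n} neurons")
        covered = set()
        for label, idx in self.motor_partition.items():
            if not idx:
                raise ValueError(f"motor partition block {label!r} is empty")
            block = set(idx)
            if covered & block:
                raise ValueError(f"motor partition blocks overlap at {label!r}")
            if not block <= set(range(self.n_motor)):
                raise ValueError(f"motor partition block {label!r} out of range")
            covered |= block
        if covered != set(range(self.n_motor)):
            raise ValueError("motor partition must cover the motor population")

    # --- index helpers -------------------------------------------------
    def emotion_block(self, label: str) -> np.ndarray:
        if label not in self.emotion_coding:
            raise ValueError(f"unknown emotion label {label!r}")
        lo, hi = self.emotion_coding[label]
        return np.arange(lo, hi)

    def percept_block(self, percept: str) -> np.ndarray:
        if percept not in self.perception_coding:
            raise ValueError(f"unknown percept label {percept!r}")
        lo, hi = self.perception_coding[percept]
        return np.arange(lo, hi)

    def part(self, key: str) -> np.ndarray:
        return np.asarray(self.motor_partition[key], dtype=int)

    def sma_indices(self, emotion: str | None = None) -> np.ndarray:
        if emotion is None:
            return np.concatenate([self.part("sma:pain"), self.part("sma:normal")])
        return self.part(f"sma:{emotion}")

    def m1_indices(self, emotion: str | None = None) -> np.ndarray:
        if emotion is None:
            return np.concatenate(
                [self.part("m1:pain"), self.part("m1:normal"), self.part("m1:both")]
            )
        return np.concatenate([self.part(f"m1:{emotion}"), self.part("m1:both")])

    def mirror_candidates(self, emotion: str) -> np.ndarray:
        """Non-SMA, non-M1 motor neurons wired from this emotion block."""
        return np.concatenate(
            [
                self.part(f"mirror:{emotion}"),
                self.part("shared:percept-pain"),
                self.part("shared:percept-normal"),
                self.part("shared:both"),
            ]
        )

    def emotion_targets(self, emotion: str) -> np.ndarray:
        """Motor neurons receiving fixed excitation from an emotion block."""
        return np.concatenate([self.sma_indices(emotion), self.mirror_candidates(emotion)])

    def motor_ensemble(self, emotion: str) -> np.ndarray:
        """All motor neurons that fire when this emotion's action executes."""
        return np.sort(np.concatenate([self.emotion_targets(emotion), self.m1_indices(emotion)]))


@dataclass
class TrainingSchedule:
    """Timing of an execution + re-afference training epoch (all in ms)."""

    motor_to_action_latency: float = 100.0
    action_to_perception_latency: float = 100.0
    motor_firing_duration: float = 400.0
    epochs: int = 100
    epoch_gap: float = 300.0

    @property
    def total_delay(self) -> float:
        return self.motor_to_action_latency + self.action_to_perception_latency

    @property
    def epoch_sim_duration(self) -> float:
        # long enough to capture the last re-afferent perception volley
        return self.motor_firing_duration + self.total_delay + 50.0

    def __post_init__(self) -> None:
        if not self.motor_firing_duration > self.total_delay:
            raise ValueError(
                "motor_firing_duration must exceed the re-afference delay so "
                "motor and perception firing overlap"
            )


@dataclass
class EmpathyNetwork:
    """Populations and synapse matrices of the AE-SNN."""

    spec: ModuleSpec
    lif: LIFParameters
    stdp: STDPParameters
    populations: dict[str, NeuronPopulation]
    W_emotion_motor: SynapseMatrix
    W_motor_emotion: SynapseMatrix
    W_sma_m1: SynapseMatrix
    W_perception_motor: SynapseMatrix

    def reset_potentials(self) -> None:
        for pop in self.populations.values():
            pop.potentials[:] = self.lif.u_rest

    @property
    def unit_impulse(self) -> float:
        """Single-step current that takes a rested neuron to threshold."""
        return self.lif.u_th * self.lif.tau_m / (self.lif.R * self.lif.dt)


@dataclass
class ObservationResult:
    """Outcome of presenting a percept to a trained network."""

    emotion_spike_counts: np.ndarray
    raster: SpikeRaster
    overt_action: str | None
    emotion_active: dict[str, bool]

    @property
    def overt_action_emitted(self) -> bool:
        return self.overt_action is not None


def build_network(
    spec: ModuleSpec | None = None,
    lif: LIFParameters | None = None,
    stdp: STDPParameters | None = None,
) -> EmpathyNetwork:
    """Construct the AE-SNN with fixed wiring and near-zero plastic weights.

    Fixed synapses carry, per unit weight, the current that a full
    presynaptic block volley needs to drive a rested postsynaptic neuron to
    threshold on the next step, so one block volley reliably propagates.
    Plastic excitatory weights start at 0; plastic inhibitory weights onto
    SMA start at a small magnitude (0.01) so STDP has a direction to grow.
    The construction is fully deterministic.
    """
    spec = spec or ModuleSpec()
    lif = lif or LIFParameters()
    stdp = stdp or STDPParameters()

    unit_impulse = lif.u_th * lif.tau_m / (lif.R * lif.dt)
    emo_block = min(hi - lo for lo, hi in spec.emotion_coding.values())
    per_block = min(hi - lo for lo, hi in spec.perception_coding.values())
    sma_block = min(len(spec.part(f"sma:{e}")) for e in EMOTIONS)

    w_em = np.zeros((spec.n_emotion, spec.n_motor))
    for emotion in EMOTIONS:
        rows = spec.emotion_block(emotion)
        w_em[np.ix_(rows, spec.emotion_targets(emotion))] = 1.0
        # SMA receives a double-weight hereditary drive so that learned
        # perception->SMA self-inhibition never blocks the agent's own
        # action execution (it only matters for gating during observation).
        w_em[np.ix_(rows, spec.sma_indices(emotion))] = 2.0
    W_emotion_motor = SynapseMatrix(w_em, "excitatory", plastic=False, gain=unit_impulse / emo_block)
    # bidirectional emotion<->motor wiring: the reverse direction is the
    # transpose, used to infer the emotion behind an observed motor pattern
    W_motor_emotion = SynapseMatrix(
        w_em.T.copy(), "excitatory", plastic=False, gain=unit_impulse / emo_block
    )

    w_sm = np.zeros((spec.n_motor, spec.n_motor))
    for emotion in EMOTIONS:
        w_sm[np.ix_(spec.part(f"sma:{emotion}"), spec.part(f"m1:{emotion}"))] = 1.0
        w_sm[np.ix_(spec.part(f"sma:{emotion}"), spec.part("m1:both"))] = 1.0
    W_sma_m1 = SynapseMatrix(w_sm, "excitatory", plastic=False, gain=unit_impulse / sma_block)

    # perception -> motor: plastic; inhibitory onto SMA columns, excitatory
    # elsewhere, structurally absent onto M1; dual-emotion mirror candidates
    # are reachable only from their designated perception block.
    post_sign = np.ones(spec.n_motor)
    post_sign[spec.sma_indices()] = -1.0
    mask = np.ones((spec.n_perception, spec.n_motor), dtype=bool)
    mask[:, spec.m1_indices()] = False
    for percept in spec.perception_coding:
        other_rows = np.setdiff1d(np.arange(spec.n_perception), spec.percept_block(percept))
        emotion = EMOTION_OF_PERCEPT[percept]
        mask[np.ix_(other_rows, spec.part(f"shared:percept-{emotion}"))] = False
    w_pm = np.zeros((spec.n_perception, spec.n_motor))
    w_pm[:, spec.sma_indices()] = 0.01
    W_perception_motor = SynapseMatrix(
        w_pm,
        "mixed",
        plastic=True,
        gain=unit_impulse / per_block,
        mask=mask,
        post_sign=post_sign,
    )

    populations = {
        "emotion": NeuronPopulation.at_rest(spec.n_emotion, lif),
        "motor": NeuronPopulation.at_rest(spec.n_motor, lif),
        "perception": NeuronPopulation.at_rest(spec.n_perception, lif),
    }
    return EmpathyNetwork(
        spec=spec,
        lif=lif,
        stdp=stdp,
        populations=populations,
        W_emotion_motor=W_emotion_motor,
        W_motor_emotion=W_motor_emotion,
        W_sma_m1=W_sma_m1,
        W_perception_motor=W_perception_motor,
    )


def _simulate(
    net: EmpathyNetwork,
    duration: float,
    *,
    drive_emotion: tuple[str, float] | None = None,
    drive_percept: tuple[str, float] | None = None,
    reafference_delay: float | None = None,
    efferent_gate: bool = True,
    t0: float = 0.0,
) -> SpikeRaster:
    """Clocked simulation of the whole network.

    ``drive_emotion``/``drive_percept`` are (label, duration) sustained
    external drives of 2 * u_th onto the labelled block.  When
    ``reafference_delay`` is set together with ``drive_emotion``, the overt
    action becomes visible to the agent itself ``delay`` ms after the motor
    ensemble's first spike: the matching perception block receives a
    to-threshold impulse at exactly that moment (so perception onset lags
    motor onset by the full delay) followed by the same sustained drive for
    as long as the action remains visibly in progress.  ``efferent_gate``
    enables the fixed emotion->motor pathway (execution); it is off during
    observation.
    """
    lif = net.lif
    spec = net.spec
    dt = lif.dt
    steps = int(round(duration / dt))
    drive_amp = 2.0 * lif.u_th
    net.reset_potentials()

    prev = {
        "emotion": np.zeros(spec.n_emotion),
        "motor": np.zeros(spec.n_motor),
        "perception": np.zeros(spec.n_perception),
    }
    events: list[tuple[str, int, float]] = []

    ensemble = None
    percept_rows: np.ndarray | None = None
    delay_steps = 0
    # visible persistence of the overt action between motor volleys, in steps
    vis_steps = int(round(25.0 / dt))
    onset_step: int | None = None
    last_ensemble_step = -1
    if reafference_delay is not None:
        if drive_emotion is None:
            raise ValueError("re-afference requires a driven emotion")
        emotion = drive_emotion[0]
        ensemble = spec.motor_ensemble(emotion)
        percept_rows = spec.percept_block(PERCEPT_OF_EMOTION[emotion])
        delay_steps = int(round(reafference_delay / dt))

    for k in range(1, steps + 1):
        t = k * dt
        # The emotion<->motor wiring is bidirectional but carries current in
        # one direction at a time: forward (emotion drives motor) while the
        # agent executes its own emotion, reverse (motor infers emotion)
        # while it observes.  Running both directions at once would just
        # reverberate the loop at the integration rate.
        if efferent_gate:
            I_emotion = np.zeros(spec.n_emotion)
        else:
            I_emotion = net.W_motor_emotion.current(prev["motor"])
        if drive_emotion is not None and t <= drive_emotion[1]:
            I_emotion[spec.emotion_block(drive_emotion[0])] += drive_amp

        I_motor = net.W_sma_m1.current(prev["motor"]) + net.W_perception_motor.current(
            prev["perception"]
        )
        if efferent_gate:
            I_motor += net.W_emotion_motor.current(prev["emotion"])

        I_percept = np.zeros(spec.n_perception)
        if drive_percept is not None and t <= drive_percept[1]:
            I_percept[spec.percept_block(drive_percept[0])] += drive_amp
        if percept_rows is not None and onset_step is not None:
            j = k - delay_steps  # the moment now being perceived
            if j == onset_step:
                I_percept[percept_rows] += net.unit_impulse
            elif onset_step < j <= last_ensemble_step + vis_steps:
                I_percept[percept_rows] += drive_amp

        for name, current in (("emotion", I_emotion), ("motor", I_motor), ("perception", I_percept)):
            pop = net.populations[name]
            _, fired = lif_step(pop, current, lif, t=t0 + t)
            spiking = np.zeros(pop.size)
            spiking[fired] = 1.0
            prev[name] = spiking
            events.extend((name, int(i), t0 + t) for i in fired)
        if ensemble is not None and prev["motor"][ensemble].any():
            last_ensemble_step = k
            if onset_step is None:
                onset_step = k

    return record_raster(events)


def run_execution_epoch(
    net: EmpathyNetwork,
    emotion: str,
    schedule: TrainingSchedule,
    learn: bool = True,
    t0: float = 0.0,
) -> SpikeRaster:
    """One action-execution epoch with re-afference, optionally learning.

    The emotion block fires first, driving the wired motor ensemble (via SMA
    also M1) continuously; after ``schedule.total_delay`` the matching
    perception block echoes the motor volleys.  With ``learn``, STDP is then
    applied to the plastic perception->motor synapses over this epoch's
    spike pairs.
    """
    if emotion not in net.spec.emotion_coding:
        raise ValueError(f"unknown emotion label {emotion!r}")
    raster = _simulate(
        net,
        schedule.epoch_sim_duration,
        drive_emotion=(emotion, schedule.motor_firing_duration),
        reafference_delay=schedule.total_delay,
        efferent_gate=True,
        t0=t0,
    )
    if learn:
        apply_stdp(
            net.W_perception_motor,
            raster,
            raster,
            net.stdp,
            pre_module="perception",
            post_module="motor",
        )
    return raster


def _weight_summary(net: EmpathyNetwork) -> dict[str, float]:
    """Mean matched-block weights of the three Fig-9A synapse classes."""
    spec = net.spec
    w = net.W_perception_motor.weights
    sma_vals, mirror_vals = [], []
    for emotion in EMOTIONS:
        rows = spec.percept_block(PERCEPT_OF_EMOTION[emotion])
        sma_vals.append(w[np.ix_(rows, spec.sma_indices(emotion))])
        mask = net.W_perception_motor.mask
        cols = spec.mirror_candidates(emotion)
        sub = np.ix_(rows, cols)
        mirror_vals.append(w[sub][mask[sub]])
    m1 = w[:, spec.m1_indices()]
    return {
        "w_perception_sma": float(np.mean(np.concatenate([v.ravel() for v in sma_vals]))),
        "w_perception_m1": float(np.max(m1)) if m1.size else 0.0,
        "w_perception_mirror": float(np.mean(np.concatenate([v.ravel() for v in mirror_vals]))),
    }


def train(
    net: EmpathyNetwork,
    emotions: Sequence[str] = EMOTIONS,
    schedule: TrainingSchedule | None = None,
    snapshots: list[np.ndarray] | None = None,
    probe=None,
) -> tuple[EmpathyNetwork, pd.DataFrame]:
    """Run ``schedule.epochs`` execution epochs per emotion, recording the
    per-epoch weight summaries of the three plastic synapse classes
    (perception->SMA inhibitory, perception->M1, perception->mirror).

    ``snapshots``, if given, receives a copy of the full plastic weight
    matrix after every epoch.  ``probe(net, epoch)`` is called after each
    epoch (all emotions trained once); raising ``StopIteration`` from it
    stops training early.
    """
    schedule = schedule or TrainingSchedule()
    rows = [{"epoch": 0, **_weight_summary(net)}]
    epoch_period = schedule.epoch_sim_duration + schedule.epoch_gap
    t0 = 0.0
    for epoch in range(1, schedule.epochs + 1):
        for emotion in emotions:
            run_execution_epoch(net, emotion, schedule, learn=True, t0=t0)
            t0 += epoch_period
        rows.append({"epoch": epoch, **_weight_summary(net)})
        if snapshots is not None:
            snapshots.append(net.W_perception_motor.weights.copy())
        if probe is not None:
            try:
                probe(net, epoch)
            except StopIteration:
                break
    return net, pd.DataFrame(rows)


def observe_other(
    net: EmpathyNetwork,
    percept: str,
    duration: float = 150.0,
) -> ObservationResult:
    """Present an overt-action percept alone (action observation).

    The perception block is driven externally; learned excitatory synapses
    activate the matching mirror neurons, learned inhibition silences SMA
    (hence M1 stays gated off), and the reverse motor->emotion wiring
    activates the matching emotion block.  No overt action is emitted unless
    an implausibly large share of a full motor ensemble fires.
    """
    if percept == "":
        # empty percept: nothing to observe, no activation by construction
        return ObservationResult(
            emotion_spike_counts=np.zeros(net.spec.n_emotion),
            raster=SpikeRaster(),
            overt_action=None,
            emotion_active={label: False for label in net.spec.emotion_coding},
        )
    if percept not in net.spec.perception_coding:
        raise ValueError(f"unknown percept label {percept!r}")
    raster = _simulate(
        net,
        duration,
        drive_percept=(percept, duration),
        efferent_gate=False,
    )
    counts = np.zeros(net.spec.n_emotion)
    emo = raster.select("emotion")
    np.add.at(counts, emo.neurons, 1)
    active = {
        label: bool(np.count_nonzero(counts[net.spec.emotion_block(label)] > 0)
                    >= (len(net.spec.emotion_block(label)) + 1) // 2)
        for label in net.spec.emotion_coding
    }
    return ObservationResult(
        emotion_spike_counts=counts,
        raster=raster,
        overt_action=_overt_action(net, raster),
        emotion_active=active,
    )


def _overt_action(net: EmpathyNetwork, raster: SpikeRaster) -> str | None:
    """Color emitted iff >= OVERT_FRACTION of an action's ensemble fired."""
    fired = set(raster.fired_neurons("motor").tolist())
    for emotion in net.spec.emotion_coding:
        ensemble = net.spec.motor_ensemble(emotion)
        if len(fired & set(ensemble.tolist())) >= OVERT_FRACTION * len(ensemble):
            return COLOR_OF_EMOTION.get(emotion, emotion)
    return None


def execute_emotion(
    net: EmpathyNetwork,
    emotion: str,
    duration: float = 100.0,
) -> tuple[str | None, SpikeRaster]:
    """Drive an emotion block as the agent's own state: full motor
    activation including M1, emitting the mapped overt color."""
    if emotion not in net.spec.emotion_coding:
        raise ValueError(f"unknown emotion label {emotion!r}")
    raster = _simulate(
        net,
        duration,
        drive_emotion=(emotion, duration),
        efferent_gate=True,
    )
    return _overt_action(net, raster), raster


NEURON_TYPE_LABELS = {
    (True, False, False, False): "EXEC-ONLY(1)",
    (True, False, True, False): "MN(1)",
    (False, True, False, False): "EXEC-ONLY(2)",
    (False, True, False, True): "MN(2)",
    (True, True, True, False): "MN(1)-BOTH-EXEC",
    (True, True, False, True): "MN(2)-BOTH-EXEC",
    (True, True, True, True): "MN(1,2)",
    (True, True, False, False): "ANTI-MN",
}


def classify_neurons(
    net: EmpathyNetwork,
    actions: Sequence[str] = EMOTIONS,
) -> tuple[list[str], pd.DataFrame]:
    """Probe every motor neuron under execute/observe of both actions and
    assign the neuron type its binary response profile implies.

    Returns the per-neuron labels and a census table (one row per realized
    profile with its count).
    """
    if len(actions) != 2:
        raise ValueError("classification probes exactly two actions")
    profiles = []
    for emotion in actions:
        _, raster = execute_emotion(net, emotion)
        profiles.append(np.isin(np.arange(net.spec.n_motor), raster.fired_neurons("motor")))
    for emotion in actions:
        obs = observe_other(net, PERCEPT_OF_EMOTION[emotion])
        profiles.append(
            np.isin(np.arange(net.spec.n_motor), obs.raster.fired_neurons("motor"))
        )
    profile_matrix = np.stack(profiles, axis=1)  # (n_motor, 4)
    labels = []
    for row in profile_matrix:
        key = tuple(bool(x) for x in row)
        labels.append(NEURON_TYPE_LABELS.get(key, f"OTHER{tuple(int(x) for x in key)}"))
    census = (
        pd.DataFrame(
            {
                "exec_1": profile_matrix[:, 0],
                "exec_2": profile_matrix[:, 1],
                "observe_1": profile_matrix[:, 2],
                "observe_2": profile_matrix[:, 3],
                "type": labels,
            }
        )
        .groupby(["exec_1", "exec_2", "observe_1", "observe_2", "type"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return labels, census


def infer_emotion_from_motor(net: EmpathyNetwork, motor_activation: np.ndarray) -> np.ndarray:
    """Emotion drive implied by a motor activation pattern, through the
    reverse fixed wiring (M1 has no emotion projection)."""
    motor_activation = np.asarray(motor_activation, dtype=float)
    if motor_activation.shape != (net.spec.n_motor,):
        raise ValueError(
            f"motor activation has shape {motor_activation.shape}, "
            f"expected ({net.spec.n_motor},)"
        )
    return net.W_motor_emotion.current(motor_activation)


def empathy_test(net: EmpathyNetwork, emotion: str = "pain") -> dict[str, bool]:
    """Pass/fail empathy probe: observing the emotion's percept alone must
    activate exactly that emotion block, with M1 silent and no overt action."""
    obs = observe_other(net, PERCEPT_OF_EMOTION[emotion])
    m1_fired = np.intersect1d(obs.raster.fired_neurons("motor"), net.spec.m1_indices())
    target_active = obs.emotion_active[emotion]
    cross_talk = any(v for k, v in obs.emotion_active.items() if k != emotion)
    result = {
        "target_active": target_active,
        "cross_talk": cross_talk,
        "m1_silent": m1_fired.size == 0,
        "overt_action_emitted": obs.overt_action_emitted,
    }
    result["passed"] = (
        target_active and not cross_talk and result["m1_silent"] and not obs.overt_action_emitted
    )
    return result


def epochs_to_empathy(
    net: EmpathyNetwork,
    emotions: Sequence[str] = EMOTIONS,
    schedule: TrainingSchedule | None = None,
    probe_emotion: str = "pain",
) -> int | None:
    """Train epoch by epoch; return the first epoch at which the empathy
    probe passes (None if it never does within the schedule)."""
    schedule = schedule or TrainingSchedule()
    first_pass: list[int] = []

    def probe(n: EmpathyNetwork, epoch: int) -> None:
        if empathy_test(n, probe_emotion)["passed"]:
            first_pass.append(epoch)
            raise StopIteration

    train(net, emotions, schedule, probe=probe)
    return first_pass[0] if first_pass else None
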