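# Methods

This note documents the model implemented in `empathnet`, the numerical
choices behind it, and what the synthetic experiments do and do not show.

## Artificial Pain

Pain is defined as a positive free energy of the agent's self-model. Under
Gaussian assumptions with unit variances the free energy reduces to a
half-sum of squared prediction errors; the package exposes

* the generic two-term form `½(s − g_s(φ̂))² + ½(φ̂ − μ_φ)²` and the robot
  three-term form (vision + proprioception + environmental dynamic) as
  `free_energy_general`, with caller-supplied generating functions — the
  learning of those generators (e.g. by motor babbling) is out of scope;
* the grid-world form `free_energy_grid`: the plain sum of squared vertex
  coordinate differences between predicted and actual pentagon pose.

The pain flag is `FE > 0`, tested exactly (no tolerance). Two consequences:

* the pentagon template uses dyadic vertex offsets so translated poses
  compare exactly in floating point — a blocked move yields FE = 0 to the
  last bit, never 1e-30-size dust that would flip the pain flag;
* the predictor knows the full healthy moving rule *including walls and
  bounds*, so a healthy agent pressing into a wall predicts "no movement"
  and feels nothing. Only damage-induced deviation produces pain: a damaged
  move mispredicts by one cell (FE = 5·25² = 3125, when one side is
  blocked) or two cells (FE = 5·50² = 12500).

Traces clip FE at 3125 for plotting; the pain flag always uses the raw
value. A damaged step can in principle be painless when both the predicted
and the inverted move are blocked simultaneously (a one-cell corridor);
with the default arena this affects at most isolated steps. The pentagon
template is not rotated to the heading: the damage score only measures
translations, and rotating the actual but not the predicted pose would
manufacture spurious pain on every turn.

## The spiking network

Three LIF populations (emotion 40, motor 50, perception 40; explicit Euler,
dt = 1 ms, τ_m = 30 ms, u_th = 60 mV, u_rest = u_reset = 0 mV; no refractory
period beyond the reset). Population coding: pain = emotion 0–19, normal =
20–39; perceive-red = perception 0–19, perceive-green = 20–39.

**Motor partition** (50 neurons; configurable, this is one realization):

| group | indices | role |
|---|---|---|
| SMA(1), SMA(2) | 0–4, 5–9 | action initiation; inhibited by perception |
| M1(1), M1(2), M1(both) | 10–13, 14–17, 18–19 | muscles; input *only* from SMA |
| mirror(1), mirror(2) | 20–31, 32–43 | single-emotion mirror candidates |
| shared (percept-1 / percept-2 / both) | 44–45, 46–47, 48–49 | dual-emotion candidates |

The dual-emotion candidates are reachable from only one (or both) perception
blocks; together with the M1 wiring (4+4 single-action, 2 dual) this is the
smallest partition that realizes all eight motor neuron types: exec-only,
mirror, both-exec mirror variants, dual mirror, and anti-mirror.

**Current scale.** The model's source gives the LIF/STDP constants but no
current magnitudes. We size fixed synapses so that one full presynaptic
block volley drives a rested postsynaptic neuron to threshold on the next
Euler step: per-connection current `u_th·τ_m/(dt·block_size)` (1800/20 = 90
for the 20-neuron blocks, 1800/5 = 360 for SMA→M1). External drives are
sustained at `2·u_th` = 120, giving a volley every 21 ms (the discrete
crossing of `u(t) = 120(1 − e^{−t/τ_m}) = 60`). SMA receives a double-weight
hereditary drive so that learned perception→SMA self-inhibition can never
block the agent's *own* execution; the inhibition matters for gating during
observation. Plastic synapses use the same 90 gain, so a fully potentiated
perception block volley (w = 1) fires a mirror neuron exactly like a fixed
synapse would.

**Directional use of the bidirectional emotion↔motor wiring.** The fixed
emotion→motor pathway carries current only while the agent executes its own
emotion (efferent gate on); during observation the reverse direction
(motor→emotion, the transpose matrix) carries current instead and the
emotion activation is the empathic readout. Running both directions
simultaneously would short-circuit into a reverberating loop firing at the
integration rate; using one direction at a time matches the causal chains
the model embodies (emotion→motor→perception when acting,
perception→motor→emotion when observing) and yields the self–other
signature for free: during observation SMA has no excitatory input at all,
hence M1 — wired exclusively to SMA — is structurally silent.

**Training epoch.** The driven emotion block fires first (sustained drive
for 400 ms), the wired motor ensemble follows one step later and keeps
firing ("execution is continuous"); 200 ms after the first motor spike the
matching perception block receives a to-threshold impulse followed by the
same sustained drive while the action remains visible. Re-afference is thus
the perception of a *sustained overt state* (the color), not a per-spike
echo of the motor train: the onset impulse makes the perception onset lag
the motor onset by exactly the 100 ms + 100 ms physiological delay, and the
single stable volley phase keeps the STDP pairings potentiation-dominated
(a per-spike echo proliferates spike phases until learned inhibition
self-selects depression pairings and decays). Epochs are separated by
300 ms of silence (potentials reset), so STDP windows never straddle
epochs. Spike pairing is all-pairs within a 5·τ = 50 ms window (beyond it
the exponential is < 1% of peak); a coincident pair (Δt = 0) contributes
nothing. Plastic weights live in [0, 1]; excitatory ones start at 0,
inhibitory perception→SMA magnitudes at 0.01 so STDP has a direction to
grow. For inhibitory synapses the same STDP delta grows the *magnitude*:
correlated firing strengthens inhibition.

With the printed A⁺ = 0.25 and ~9 perception volleys per epoch pairing at
~10 ms lags, the matched excitatory weights reach the bound within two
epochs and the empathy probe already passes after epoch 1; the remaining
98 epochs of the default schedule simply hold the saturated weights (the
trajectories are monotone by construction once clamped). The default
schedule trains both emotion–action channels (pain→red, normal→green), 100
epochs each, which the neuron census requires.

**Probes.** Execution probes drive an emotion block for 100 ms (shorter
than the re-afference delay, so perception stays silent); observation
probes drive a perception block for 150 ms with the efferent gate off. A
motor ensemble emits its overt action (color) only when ≥ 90% of the
ensemble, M1 included, fires within the probe — during observation only the
matched mirror subset (16/29) fires, so the observer never changes color.
An emotion block counts as "active" when at least half its neurons spike;
in practice activation is all-or-none because blocks are synchronized. The
cross-talk margin is structural: observing red drives the pain block
through 16 motor neurons but the normal block through only 4 (the shared
candidates), whose accumulated drive stays a factor ~2 below threshold.

## Grid world

11 × 7 cells of length 25; a full wall column at x = 5 with one passage
cell (5, 3) opened permanently by the switch at (9, 1); dangerous object at
(2, 3). Damage inverts both axes of every command (the model's source
states the left/right example; symmetric inversion is assumed). Entering
any safety-zone cell (x > 5) clears damage immediately. Collision is
registered when the agent moves onto the object's cell; the resulting
mispredictions on subsequent moves are what the pain model detects.

## Rescue task

AgentB random-walks in the danger zone until the inevitable collision;
from then on agentA takes one step per agentB step. The Q-state is
(agentA's cell, passage flag) — agentB's position is deliberately hidden;
only its color percept reaches agentA, through the same `observe_other`
pathway as in phase 1 (the response per percept is cached, being
deterministic for a fixed network). Rewards are a pure function of agentA's
own emotion transitions: −1 per step of empathized pain, +10 on the
pain→no-pain transition, −0.01 otherwise. Once the passage opens, agentB
heads for the safety zone along the shortest path ("enters spontaneously
and immediately"), issuing inverted commands while damaged so its impaired
motor system still executes the intended moves.

Q-learning uses α = 0.1, γ = 0.9, ε = 0.1 decaying by 0.99 per episode
(floor 0.01), 300 episodes, and a 40-step episode budget after pain onset.
Two numerical choices matter:

* **Neutral prior.** Unvisited state–action pairs default to
  `step_cost/(1 − γ)` = −0.1, the fixed point of the ambient step cost,
  rather than 0. Zero-initialization under all-negative rewards is
  optimistic: every under-visited region acts as an implicit bonus and even
  a reward-blind agent would sweep the arena and find the switch far above
  chance, which would void the ablation control entirely.
* **Termination bootstraps from the prior.** The rescue ends the episode,
  not the world; backing up a literal 0 for "episode over" would again make
  termination itself a reward for a negative-ambient process.

With these, an agent whose empathy network is left untrained receives a
flat reward signal, its table stays at the prior everywhere, and its
behavior is *exactly* the random policy — the measured chance rate
(~25–30% within the 40-step budget) — while the trained agent converges to
the BFS-optimal path to the switch.

## What the synthetic experiments show — and what they do not

The grid world, the two-color overt-action space and the two-emotion
repertoire are the model's own study conditions, not data: all quantities
(free-energy endpoints, 200 ms delay, eight neuron types, BFS-optimal
rescue) are exact or deterministic properties of the construction, and the
tests verify them as such. Passing them shows the mechanism is coherent —
that mirror neurons, self–other differentiation and empathy-driven reward
*can* emerge from these ingredients — not that it scales to rich sensory
streams, many emotions, graded pain intensity, hormone-level dynamics, or
physical embodiment, none of which are modeled. The SMA→M1 gate is a
deliberate functional simplification of a complex biological mechanism.
Problem sizes used throughout (130 neurons, 100 + 100 training epochs,
300 rescue episodes, 10-seed replication) were chosen as the smallest
configuration that exhibits every qualitative phenomenon; all runs are
deterministic given (config, seed).
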