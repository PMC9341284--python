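# empathnet

A computational-neuroscience sandbox for **affective empathy**: how an agent
that has *experienced* pain can come to *feel* another agent's pain, and why
that shared feeling is enough to drive altruistic rescue behavior.

The package is aimed at researchers in brain-inspired AI and computational
modeling of emotion who want a small, fully reproducible reference
implementation of the mirror-neuron account of empathy — every neuron,
synapse and reward in the model is inspectable, and every experiment is a
deterministic function of a configuration file and a seed.

## The model

Three components, run in two experimental phases:

**1. Artificial Pain (free-energy damage score).** Under unit-variance
Gaussian assumptions, the free energy of the agent's self-model reduces to a
sum of squared prediction errors. In the grid world the agent is a pentagon
with five vertices (X_i, Y_i), and

    FE = Σ_i (X_pre,i − X_act,i)² + Σ_i (Y_pre,i − Y_act,i)²

comparing the pose predicted by the healthy moving rule against the pose
actually reached. FE = 0 is the normal state; FE > 0 flags body damage and
puts the agent in the *pain* state. With a grid unit of 25 a damaged move
yields FE ∈ {3125, 12500}.

**2. AE-SNN (affective-empathy spiking network).** Three population-coded
modules of leaky integrate-and-fire neurons (emotion 40, motor 50,
perception 40) with

    τ_m du/dt = −(u − u_rest) + R·I(t),   spike and reset at u_th

(u_rest = u_reset = 0 mV, τ_m = 30 ms, u_th = 60 mV), trained by the
exponential STDP pair rule (A⁺ = 0.25, A⁻ = 0.01, τ± = 10 ms). Emotion→motor
wiring is fixed ("hereditary"); primary-motor (M1) neurons receive input only
from supplementary-motor (SMA) neurons. During action execution the motor
ensemble fires continuously and the agent *perceives its own overt action*
200 ms later (re-afference); STDP then strengthens the matched
perception→motor synapses, turning them into **mirror neurons**, while
perception→SMA inhibition grows and M1 stays structurally unreachable —
producing **anti-mirror neurons** that fire only for one's own actions.
After training, merely observing another agent's pain color activates the
observer's own pain emotion block, with M1 silent and no overt action: the
motor firing pattern itself distinguishes self from other.

**3. Intrinsic-reward rescue.** AgentB explores the danger zone, collides
with the dangerous object, and turns red. AgentA (safety zone) perceives the
color, empathizes, and its own emotion transitions are the *only* reward of
a tabular Q-learner (−1 per step of shared pain, +10 on relief, −0.01
otherwise): it learns to press the switch that opens the passage through
which agentB escapes.

## Worked example

```sh
empathnet phase1 --seed 3 --out results/run     # empathy development
empathnet phase2 --seed 3 --out results/run     # altruistic rescue
empathnet census --seed 3 --out results/run     # motor-neuron typing
empathnet report --out results/run              # plots from the CSVs
```

`phase1` explores the grid world (the agent collides once and spends 386 of
400 steps in the pain state — the free-energy trace in `fe_trace.csv` jumps
to the clipped 3125 at the collision), then trains the network and prints

```json
{"empathy_test": {"target_active": true, "cross_talk": false,
                  "m1_silent": true, "overt_action_emitted": false,
                  "passed": true},
 "collisions": 1, "pain_steps": 386, "final_mirror_weight": 1.0}
```

i.e. after training, presenting the perceive-red pattern alone activates the
pain emotion block (empathy), with M1 silent and no color change.
`phase2` prints

```json
{"greedy_success": true, "greedy_switch_step": 6, "bfs_steps_to_switch": 6,
 "agentA_stayed_green": true,
 "event_order": ["B-pain", "switch", "B-recovery", "A-relief"],
 "final_success_rate": 1.0, "m1_silent_during_observation": true}
```

the learned greedy policy reaches the switch in 6 steps — exactly the
breadth-first-search shortest path — and the causal chain of every rescue is
B's pain → switch → B's recovery → A's relief, with agentA staying green
throughout (it feels the pain but does not express it). `census` reports the
eight motor-neuron types, e.g. 12 mirror neurons per action and 2
anti-mirror neurons:

```json
{"n_profile_classes": 8,
 "counts": {"EXEC-ONLY(1)": 9, "MN(1)": 12, "EXEC-ONLY(2)": 9, "MN(2)": 12,
            "MN(1)-BOTH-EXEC": 2, "MN(2)-BOTH-EXEC": 2, "MN(1,2)": 2,
            "ANTI-MN": 2}}
```

All outputs are CSV + JSON; `report` regenerates the PNG figures from the
CSVs alone. See `docs/methods.md` for the modeling details and their
rationale.

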