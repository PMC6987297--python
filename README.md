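# lsasim

Spiking networks that learn by switching off their own stimulation.

`lsasim` is a simulator for **learning by stimulation avoidance (LSA)**: the
emergent learning dynamics of spiking neural networks with symmetric
spike-timing dependent plasticity (STDP) embedded in closed sensorimotor
loops. When some output pattern of the network stops an external stimulus,
the synapses that produced it are potentiated; when an output pattern starts
a stimulus, they are depressed — even though the plasticity rule itself
knows nothing about the environment. The package is aimed at computational
neuroscientists studying how reactive and predictive behavior can arise from
local plasticity plus embodiment.

## The rule and the loop

For a presynaptic neuron *i*, postsynaptic neuron *j* and lag
Δt = t_j − t_i between their spikes, the weight w_ij changes by

    +Δw  if 0 < Δt < 20 ms   (LTP: i fired just before j)
    −Δw  if 0 < −Δt < 20 ms  (LTD: i fired just after j)

with |w_ij| clipped to [0, w_max]. In an embodiment where an output spike
*removes* the stimulation of the input neuron, the input spikes that would
have followed the output spike never occur, so LTD pairings are suppressed
and the input→output weight grows; where an output spike *starts*
stimulation, LTD dominates and the weight shrinks. Learning requires four
conditions, each of which has a preset experiment and an ablation here:
**connectivity** (sensory information can reach the motor neurons through
low-delay paths), **controllability** (some output actually affects the
stimulus source), a **time condition** (the sensory-motor loop must close
within the STDP memory window τ ≈ 20 ms), and — for learning to *predict*
paired stimuli with an inhibitory comparator — **predictability** (a
reliable interval between anticipatory and target stimulus).

Neurons are two-variable Izhikevich units (regular-spiking excitatory,
fast-spiking inhibitory) stepped at 1 ms; see `docs/methods.md` for every
model and calibration decision.

## Worked example

Reproduce the reinforcement mechanism in the 3-neuron circuit (input,
output, and a hidden neuron that fires only from background noise):

```bash
lsa run minimal_reinforcement --seed 0 --seeds 20 --out results/reinf
lsa report results/reinf
```

which prints (seed 0, 20 seeds × 200 s):

```
mean_dw_input_output: 7.995
mean_dw_input_hidden: 0.3650000000000003
p_value: 1.7014950590333053e-50
hidden_to_output_ratio: 0.04565353345841155
contrast_verdict: True
```

Reading: the input→output weight climbed from 2.0 to its bound (Δw ≈ +8.0,
one-sided p ≈ 10⁻⁵⁰ across seeds) because output spikes suspend the
stimulation, while the input→hidden weight — identical in every respect
except that the hidden neuron cannot affect the environment — barely moved
(≈ 5 % of the output change). `lsa report` renders the weight trajectories.
The same interface runs `minimal_weakening`, `controllability_ablation`
(a yoked random-stimulation arm), `wall_avoidance` (a 1-D robot that learns
to turn away from walls), `connectivity_sweep`, `prediction_learning` /
`predictability_ablation` (inhibitory cancellation of a predictable
stimulus), and the two critical-delay sweeps, e.g.

```bash
lsa sweep 2n --delays 0,5,10,15,20,25,30 --seed 0 --seeds 10
```

The library API mirrors the presets: build a `Topology`
(`build_minimal_circuit`, `build_random_network`), pick an environment
(`ReinforcementEnv`, `WallWorldEnv`, ...), and call
`close_loop(topo, env, STDPConfig(), duration_ms, seed)`; everything a run
produces (spikes, weight trajectories, event log, trial log) comes back in
one `RunResult`.

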