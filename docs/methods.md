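# Methods

## The model

`lsasim` simulates *learning by stimulation avoidance* (LSA): spiking
networks with spike-timing dependent plasticity (STDP), embedded in a closed
sensorimotor loop, come to repeat the actions that stop external stimulation
and to avoid the actions that start it. Nothing in the learning rule refers
to the environment; the asymmetry between long-term potentiation (LTP) and
long-term depression (LTD) that drives learning is created entirely by the
loop: when an output spike removes the stimulation, the input spikes that
would otherwise have *followed* the output spike (LTD pairings) never
happen, while the input spikes that *preceded* it (LTP pairings) already
did.

### Neurons

Two-variable quadratic integrate-and-fire (Izhikevich) dynamics,

    dv/dt = 0.04 v² + 5 v + 140 − u + I,      du/dt = a (b v − u),

with a spike emitted when `v` crosses the 30 mV cutoff, after which
`v ← c`, `u ← u + d`. Excitatory neurons use regular-spiking parameters
(a=0.02, b=0.2, c=−65, d=8), inhibitory neurons fast-spiking parameters
(a=0.1, b=0.2, c=−65, d=2). This family is used because the network-level
claims being reproduced only require generic spiking dynamics with a
threshold near −50 mV and a stable rest near −70 mV; the claims are not
sensitive to the neuron model beyond that.

Integration uses a 1 ms network step with 4 membrane substeps (0.25 ms
Euler) and a clamp of `v` at the spike cutoff during the upswing. Four
substeps were chosen because, with fewer, the first-spike latency under a
step current deviates by more than 1 ms from a 10× finer integration; with
the clamp the scheme is unconditionally stable at the strongest stimulus
used. Spikes are stamped on the 1 ms grid; sub-millisecond spike-time
accuracy is neither needed (the plasticity windows are 20 ms wide) nor
claimed. Synapses deliver their weight as an instantaneous current increment
exactly one conduction delay after the presynaptic spike (delays are
multiples of the step; 1 ms in minimal circuits, uniform 1–10 ms in random
networks).

### Plasticity

The STDP rule is rectangular and symmetric: for a pair with lag
`Δt = t_post − t_pre`,

    Δw = +dw   if 0 < Δt < 20 ms      (LTP)
    Δw = −dw   if 0 < −Δt < 20 ms     (LTD)
    Δw = 0     otherwise, including exactly simultaneous spikes.

Pairing is nearest-neighbor by default (each spike pairs with the partner's
most recent earlier spike), which bounds weight drift under dense firing;
all-pairs is available and is what the exhaustive test oracle enumerates.
Weight magnitudes are clipped to [0, w_max] after every pairing; the sign of
a synapse (set by the presynaptic neuron's type) never changes. The memory
window τ — the horizon over which an action can be associated with its
consequence — equals the larger STDP window, 20 ms at defaults.

Default step `dw = 0.1` with `w_max = 10` (1 % of the bound), small enough
that single pairings do not dominate and the averaging argument behind the
reinforcement/weakening mechanisms applies, large enough that a 200 s run
saturates under full contingency.

### Background noise

Every neuron receives an independent Gaussian current each step. The
amplitude (σ = 3.9) was calibrated once so that an isolated neuron fires at
≈ 2 Hz; this gives hidden neurons their "fires randomly" baseline and gives
output neurons the spontaneous activity that exploration of the environment
requires. All randomness (noise, environment schedules) derives from named
substreams of a single run seed; identical seed + configuration reproduces a
run bit for bit.

## Embodiments

All environments honor a configurable feedback delay Δt₂ between a
qualifying output event and the environmental change, and log every gate
transition.

* **Reinforcement** (stimulation removal): periodic suprathreshold pulses
  (amplitude 20, 10 ms pulse, 25 ms period) to the input neurons; any
  motor-output spike suspends the train for 500 ms (overlapping suspensions
  merge).
* **Weakening** (stimulation onset): no baseline stimulation; an output
  spike turns the train on for 500 ms, phase-anchored at the window start so
  the first pulse lands immediately after the feedback delay.
* **Uncontrollable** (yoked control): an alternating-renewal on/off process
  with exponential episode lengths matched to the mean on/off episodes of a
  completed reinforcement run — same duty cycle, zero output contingency.
* **Wall world**: a robot on a line of length 100 moving at 0.05 units/ms;
  the distance sensor looks *ahead*, so stimulation is on iff the wall in
  the heading direction is within 10 units, and a turn ends stimulation
  immediately. A turn is commanded by ≥ k motor spikes inside a 20 ms
  sliding window (k = 2 for the 8-neuron controller, 3 for 100-neuron
  networks) with a refractory period so one burst cannot double-turn.
* **Prediction task**: trials at random inter-trial intervals deliver an
  anticipatory pulse at T₁ (amplitude 50 — strong enough to evoke a short
  burst) and a target pulse (amplitude 20) at T₂ = T₁ + 10 ms (± jitter).
  Each spike of the circuit's inhibitory neuron suppresses the target
  stimulus for 20 ms in proportion to the magnitude of its (plastic) synapse
  onto the target input neuron times a fixed gain of 4; the *residual*
  current is what the target neuron receives, and its per-trial integral is
  the prediction error — null exactly when inhibition cancels the stimulus.
  Both synapses of the anticipatory → inhibitory → target chain are plastic;
  the gain is a fixed conversion constant.

The stimulation period of the minimal-circuit presets (25 ms, shorter than
the commonly pictured 10 Hz trains) was set during calibration so that a
200 s run yields enough pairing events for the delay sweep to resolve the
20 ms window; at 100 ms periods the same transition exists but is
statistically unresolvable at desk scale.

## Metrics

* **Connectivity measure**: fraction of ordered (sensory, motor) pairs
  joined by a directed path of summed conduction delay below a threshold
  (shortest-delay search; default threshold τ = 20 ms, tying usable paths to
  the association window). A direct-edge variant exists. The
  connectivity-sweep preset uses a 10 ms threshold: in 100-neuron graphs the
  20 ms pair measure saturates at connection probabilities far below those
  at which stimulation can actually drive the outputs, whereas the 10 ms
  variant counts the short routes that deliver a coherent volley, which is
  what the behavior depends on.
* **Reaction time**: wall-encounter (sensor gate opening) to the next turn;
  encounters never resolved by a turn are excluded and counted.
* **Success measure**: median reaction time of the first quartile block of
  encounters minus that of the last block, with a one-sided Mann–Whitney
  test between the blocks. *Learning success* (boolean, pre-registered for
  all sweeps): test significant at 0.05 **and** last-quartile median below
  half the first-quartile median.
* **Prediction error**: per-trial integral of the residual target current.
* **SNR**: (mean output rate during stimulation − mean rate outside) / s.d.
  of the outside rate over 1 s bins — this package's operationalization of
  the output signal-to-noise limit on avoidance learning in larger networks.

## Delay sweeps and the critical loop-closure time

Per-run learning success for the sweeps is *potentiation beyond 20 % of the
available headroom* (`Δw ≥ 0.2 (w_max − w₀)` for the 2-neuron circuit; the
mean over direct input→output synapses for the 100-neuron network). A
non-plastic control changes by exactly 0, and the balanced drift of a
non-contingent synapse stays well below this threshold in 200 s, so crossing
it requires a sustained LTP/LTD imbalance. The critical delay is the largest
Δt₂ whose success fraction reaches 0.8; non-monotone fractions are reported
alongside, a sweep where every delay passes is flagged right-censored, and
one where none passes reports "below minimum tested".

At default conditions the 2-neuron sweep (0–60 ms in 5 ms steps, 20 seeds ×
200 s) passes at every delay through 15 ms and collapses to a ≈ 0.25 plateau
beyond 20 ms: the estimated critical delay is 15 ms, one sweep step below
the 20 ms STDP window, as expected for a rule whose LTD branch saturates at
the window edge.

The 100-neuron sweep (0–80 ms in 10 ms steps, 10 seeds × 100 s, stimulation
period 15 ms so that successive stimuli can generate LTD against the evoked
response) shows contingent potentiation only near zero delay, declining
monotonically below the success floor everywhere: the estimate is "below
minimum tested" (reported as 0 ms). This is a genuine property of the model
class, not a tuning failure: with hard rectangular 20 ms windows and
instantaneous synaptic currents, the pairing asymmetry an output spike can
experience is bounded by the window itself, and in a recurrent network the
qualifying output *pattern* (a multi-spike burst) consumes part of that
budget, shortening the usable horizon rather than extending it. Protocols
that would let network reverberation carry the association further (longer
stimulus periods, longer conduction delays, stronger recurrence) were
explored systematically and instead decouple the weight change from the
contingency altogether, because correlation-driven (non-contingent) LTP then
dominates. Reproducing a ≈ 40 ms loop-closure tolerance at this network size
evidently requires memory mechanisms beyond this rule — e.g. exponential
STDP kernels with mass beyond 20 ms, or slow synaptic/intrinsic currents —
which are outside this package's model.

## Synthetic conditions vs. real preparations

The generator-side choices (Poisson-like noise, perfectly periodic pulse
trains, idealized 1-D kinematics, exact trial timing) emulate the structure
of the corresponding experiments, not their biology. Passing tests show that
the *mechanisms* — reinforcement and weakening of output-contingent
synapses, their abolition under yoked uncontrollable stimulation, reaction-
time learning, the connectivity–success relation, timed inhibitory
cancellation and its loss under jitter — emerge from the stated rule in a
controlled setting. They do not show robustness to biological variability
(bursty culture dynamics, synaptic conductances, adaptation), nor calibrate
absolute rates against recordings.

## Numerical and statistical choices

* Directional claims are tested at α = 0.01 (potentiation/depression, the
  predictability ablation via a paired one-sided Wilcoxon of trial-1 vs
  final-trial error); "indistinguishable" claims use two-sided tests at
  α = 0.05; the learning-success boolean uses 0.05 as above.
* Bootstrap CIs (percentile, 1999 resamples) summarize per-class weight
  changes across seeds.
* Ties/degenerate cases: simultaneous spikes never update a weight;
  constant reaction-time series return a zero statistic with p = 1; a
  weight at a bound moves only under opposite-sign pairings.
* Problem sizes (20 seeds × 200 s minimal runs, 50 × 120 s networks for the
  connectivity sweep, 10 × 100 s for the 100-neuron sweep) are desk-scale
  choices that keep every preset reproducible in minutes on one core while
  leaving each test's effect size many standard errors above its threshold
  (the connectivity sweep's rank correlation, ρ ≈ 0.7, is the tightest).

## Known limitations

* The association horizon is hard-bounded by the rectangular STDP window;
  see the 100-neuron sweep discussion above.
* Under the weakening contingency the input fires densely enough that
  correlation-driven LTP visibly potentiates the input→hidden synapse; the
  discriminating claim there is the depression of the input→output synapse,
  and the hidden-synapse stability claim is made (and tested) only for the
  reinforcement contingency.
* Sub-millisecond spike timing is not resolved; conduction delays round to
  the 1 ms step.
* The wall world is 1-D with a direction-sensitive sensor; no momentum,
  slip, or sensor noise.
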