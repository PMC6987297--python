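"""Closed-loop environments coupling output spikes to external stimulation.

Each environment implements the same small protocol used by
:func:`close_loop`:

``reset(rng)``            reinitialize internal state from a Generator;
``currents(t, dt, I)``    add this step's external currents into ``I``
                          (called with the time at the *start* of the step);
``update(t, dt, spiked, state)``  observe the spikes stamped ``t`` (the end
                          of the step just computed).

Environmental consequences of a qualifying output event at time ``s`` take
effect at ``s + delay_ms`` (the feedback delay, the loop-closure time the
reactive-behavior time condition constrains).  State changes of the
stimulation gate are logged as ``(t, event, value)`` rows.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, asdict

import numpy as np

from .neural_core import (NetworkState, SpikeRecord, Topology, Role,
                          background_noise, init_state, step, sync_weights,
                          DEFAULT_NOISE_SIGMA)
from .plasticity import STDPConfig, apply_stdp_on_spike

__all__ = [
    "StimulusGenerator", "LoopConfig", "WallWorld", "PredictionTask",
    "ReinforcementEnv", "WeakeningEnv", "UncontrollableEnv", "WallWorldEnv",
    "PredictionTaskEnv", "RunResult", "close_loop",
]


@dataclass
class StimulusGenerator:
    """Periodic suprathreshold pulse train delivered to target neurons."""

    targets: np.ndarray
    amplitude: float = 20.0
    pulse_ms: float = 10.0
    period_ms: float = 100.0
    active: bool = True

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=np.int64)
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.pulse_ms <= 0 or self.period_ms <= 0:
            raise ValueError("durations must be positive")

    def pulsing(self, t: float, phase0: float = 0.0) -> bool:
        return (t - phase0) % self.period_ms < self.pulse_ms


@dataclass
class LoopConfig:
    """Feedback timing: delay between output event and environmental change,
    and how long the change lasts."""

    delay_ms: float = 0.0        # feedback delay (loop-closure time)
    removal_ms: float = 500.0    # stimulation-off duration (reinforcement)
    on_ms: float = 500.0         # stimulation-on duration (weakening)

    def __post_init__(self):
        if self.delay_ms < 0:
            raise ValueError("feedback delay must be >= 0")
        if self.removal_ms <= 0 or self.on_ms <= 0:
            raise ValueError("durations must be positive")


class _OutputDetector:
    """Qualifying output event: >= k motor spikes inside a sliding window.

    With k=1 (minimal circuits) every motor-output spike qualifies.  An
    optional refractory period suppresses retriggering by one burst.
    """

    def __init__(self, output_ids, k: int = 1, window_ms: float = 20.0,
                 refractory_ms: float = 0.0):
        self.mask = None
        self.output_ids = np.asarray(output_ids, dtype=np.int64)
        self.k = int(k)
        self.window_ms = float(window_ms)
        self.refractory_ms = float(refractory_ms)
        self._recent: deque[float] = deque()
        self._refract_until = -np.inf

    def reset(self, n: int) -> None:
        self.mask = np.zeros(n, dtype=bool)
        self.mask[self.output_ids] = True
        self._recent.clear()
        self._refract_until = -np.inf

    def observe(self, t: float, spiked: np.ndarray) -> bool:
        c = int(np.count_nonzero(self.mask[spiked]))
        if c == 0:
            return False
        if self.k == 1:
            return t >= self._refract_until and self._fire(t)
        rec = self._recent
        for _ in range(c):
            rec.append(t)
        lo = t - self.window_ms
        while rec and rec[0] <= lo:
            rec.popleft()
        if len(rec) >= self.k and t >= self._refract_until:
            rec.clear()
            return self._fire(t)
        return False

    def _fire(self, t: float) -> bool:
        self._refract_until = t + self.refractory_ms
        return True


class _IntervalUnion:
    """Merged union of future/ongoing intervals appended in start order."""

    def __init__(self):
        self._iv: deque[list[float]] = deque()

    def clear(self):
        self._iv.clear()

    def add(self, start: float, end: float) -> None:
        if self._iv and start <= self._iv[-1][1]:
            if end > self._iv[-1][1]:
                self._iv[-1][1] = end
        else:
            self._iv.append([start, end])

    def covers(self, t: float) -> bool:
        iv = self._iv
        while iv and iv[0][1] <= t:
            iv.popleft()
        return bool(iv) and iv[0][0] <= t

    def current_end(self, t: float) -> float | None:
        return self._iv[0][1] if self.covers(t) else None


class _EnvBase:
    def __init__(self):
        self.event_log: list[tuple[float, str, float]] = []
        self._gate = None

    def log(self, t: float, event: str, value: float = 0.0) -> None:
        self.event_log.append((t, event, float(value)))

    def _log_gate(self, t: float, gate: bool) -> None:
        if gate != self._gate:
            self.log(t, "stim_on" if gate else "stim_off")
            self._gate = gate

    def events_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.event_log, columns=["t_ms", "event", "value"])


class ReinforcementEnv(_EnvBase):
    """Fig-3A-style embodiment: firing the output *removes* stimulation.

    Baseline periodic stimulation of the input neurons; a qualifying output
    spike at ``s`` suspends it during ``(s + delay, s + delay + removal]``;
    overlapping suspensions merge.  Behaviors that stop stimulation are
    thereby reinforced through the LTP/LTD imbalance they create.
    """

    def __init__(self, stim: StimulusGenerator, loop: LoopConfig,
                 output_ids, k_spikes: int = 1, window_ms: float = 20.0,
                 refractory_ms: float = 0.0):
        super().__init__()
        self.stim = stim
        self.loop = loop
        self.detector = _OutputDetector(output_ids, k_spikes, window_ms,
                                        refractory_ms)
        self._susp = _IntervalUnion()

    def reset(self, rng=None, n: int | None = None) -> None:
        self.event_log = []
        self._gate = None
        self._susp.clear()
        self.detector.reset(n)

    def gate_open(self, t: float) -> bool:
        return self.stim.active and not self._susp.covers(t)

    def currents(self, t: float, dt: float, I: np.ndarray) -> None:
        gate = self.gate_open(t)
        self._log_gate(t, gate)
        if gate and self.stim.pulsing(t):
            I[self.stim.targets] += self.stim.amplitude

    def update(self, t: float, dt: float, spiked: np.ndarray,
               state: NetworkState | None = None) -> None:
        if self.detector.observe(t, spiked):
            s = t + self.loop.delay_ms
            self._susp.add(s, s + self.loop.removal_ms)


class WeakeningEnv(_EnvBase):
    """Fig-3B-style embodiment: firing the output *starts* stimulation.

    No baseline stimulation; a qualifying output spike at ``s`` turns the
    pulse train on during ``(s + delay, s + delay + on_ms]`` (pulse phase
    anchored at the window start, so the first pulse begins at ``s+delay``).
    """

    def __init__(self, stim: StimulusGenerator, loop: LoopConfig,
                 output_ids, k_spikes: int = 1, window_ms: float = 20.0,
                 refractory_ms: float = 0.0):
        super().__init__()
        self.stim = stim
        self.loop = loop
        self.detector = _OutputDetector(output_ids, k_spikes, window_ms,
                                        refractory_ms)
        self._on = _IntervalUnion()

    def reset(self, rng=None, n: int | None = None) -> None:
        self.event_log = []
        self._gate = None
        self._on.clear()
        self.detector.reset(n)

    def gate_open(self, t: float) -> bool:
        return self.stim.active and self._on.covers(t)

    def currents(self, t: float, dt: float, I: np.ndarray) -> None:
        gate = self.gate_open(t)
        self._log_gate(t, gate)
        if gate:
            start = self._on._iv[0][0]
            if self.stim.pulsing(t, phase0=start):
                I[self.stim.targets] += self.stim.amplitude

    def update(self, t: float, dt: float, spiked: np.ndarray,
               state: NetworkState | None = None) -> None:
        if self.detector.observe(t, spiked):
            s = t + self.loop.delay_ms
            self._on.add(s, s + self.loop.on_ms)


class UncontrollableEnv(_EnvBase):
    """Yoked random stimulation: same statistics, no output contingency.

    The on/off gate follows an alternating-renewal (Poisson on/off) process
    with exponential episode durations; output spikes are ignored entirely.
    Use :meth:`yoked_to` to match the mean episode durations (and hence the
    duty cycle) of a completed reinforcement run.
    """

    def __init__(self, stim: StimulusGenerator, mean_on_ms: float,
                 mean_off_ms: float):
        super().__init__()
        self.stim = stim
        self.mean_on_ms = float(mean_on_ms)
        self.mean_off_ms = float(mean_off_ms)
        self._rng = None
        self._state_on = True
        self._next_flip = 0.0

    @classmethod
    def yoked_to(cls, event_log, stim: StimulusGenerator,
                 total_ms: float) -> "UncontrollableEnv":
        """Match duty cycle to the gate episodes of a reinforcement log."""
        on_eps, off_eps = _gate_episodes(event_log, total_ms)
        mean_on = float(np.mean(on_eps)) if on_eps else total_ms
        mean_off = float(np.mean(off_eps)) if off_eps else total_ms
        return cls(stim, mean_on, mean_off)

    def reset(self, rng, n: int | None = None) -> None:
        self.event_log = []
        self._gate = None
        self._rng = rng
        self._state_on = True
        self._next_flip = rng.exponential(self.mean_on_ms)

    def gate_open(self, t: float) -> bool:
        while t >= self._next_flip:
            self._state_on = not self._state_on
            mean = self.mean_on_ms if self._state_on else self.mean_off_ms
            self._next_flip += self._rng.exponential(mean)
        return self.stim.active and self._state_on

    def currents(self, t: float, dt: float, I: np.ndarray) -> None:
        gate = self.gate_open(t)
        self._log_gate(t, gate)
        if gate and self.stim.pulsing(t):
            I[self.stim.targets] += self.stim.amplitude

    def update(self, t, dt, spiked, state=None) -> None:
        pass  # no output can stop it


def _gate_episodes(event_log, total_ms: float):
    """(on, off) episode durations from stim_on/stim_off transitions."""
    on_eps, off_eps = [], []
    last_t, last_state = 0.0, True
    for t, ev, _ in event_log:
        if ev == "stim_on" and not last_state:
            off_eps.append(t - last_t)
            last_t, last_state = t, True
        elif ev == "stim_off" and last_state:
            on_eps.append(t - last_t)
            last_t, last_state = t, False
    (on_eps if last_state else off_eps).append(total_ms - last_t)
    return on_eps, off_eps


@dataclass
class WallWorld:
    """1-D line world: a robot shuttles between two walls.

    The distance sensor looks *ahead*: stimulation is active iff the distance
    to the wall in the heading direction is at most ``sensor_range`` (so
    turning away ends the stimulation at once, which is what closes the
    avoidance loop).
    """

    length: float = 100.0
    position: float = 50.0
    heading: int = 1
    speed: float = 0.05          # units per ms
    sensor_range: float = 10.0

    def __post_init__(self):
        if not 0 <= self.position <= self.length:
            raise ValueError("position outside the line")
        if self.heading not in (-1, 1):
            raise ValueError("heading must be -1 or +1")

    def distance_ahead(self) -> float:
        return (self.length - self.position if self.heading > 0
                else self.position)

    def at_wall(self) -> bool:
        return self.distance_ahead() <= self.sensor_range


class WallWorldEnv(_EnvBase):
    """Closed-loop 1-D wall avoidance (the reactive-behavior task).

    Sensor neurons receive the pulse train while a wall is within sensor
    range ahead (pulse phase anchored at the encounter).  A qualifying motor
    burst (>= k spikes in the sliding window) issues a turn command that
    takes effect one feedback delay later.  Events: wall_enter, wall_leave,
    turn, stim_on/stim_off.
    """

    def __init__(self, world: WallWorld, stim: StimulusGenerator,
                 loop: LoopConfig, output_ids, k_spikes: int = 2,
                 window_ms: float = 20.0, refractory_ms: float = 200.0):
        super().__init__()
        self.world = world
        self._world0 = WallWorld(**asdict(world))
        self.stim = stim
        self.loop = loop
        self.detector = _OutputDetector(output_ids, k_spikes, window_ms,
                                        refractory_ms)
        self._pending_turns: deque[float] = deque()
        self._encounter_t0 = 0.0

    def reset(self, rng=None, n: int | None = None) -> None:
        self.event_log = []
        self._gate = None
        self.world = WallWorld(**asdict(self._world0))
        self._pending_turns.clear()
        self.detector.reset(n)

    def currents(self, t: float, dt: float, I: np.ndarray) -> None:
        w = self.world
        while self._pending_turns and self._pending_turns[0] <= t:
            self._pending_turns.popleft()
            w.heading = -w.heading
            self.log(t, "turn", w.heading)
        w.position = min(w.length, max(0.0, w.position + w.heading * w.speed * dt))
        gate = self.stim.active and w.at_wall()
        if gate and not self._gate:
            self.log(t, "wall_enter", w.position)
            self._encounter_t0 = t
        elif self._gate and not gate:
            self.log(t, "wall_leave", w.position)
        self._log_gate(t, gate)
        if gate and self.stim.pulsing(t, phase0=self._encounter_t0):
            I[self.stim.targets] += self.stim.amplitude

    def update(self, t: float, dt: float, spiked: np.ndarray,
               state: NetworkState | None = None) -> None:
        if self.detector.observe(t, spiked):
            self._pending_turns.append(t + self.loop.delay_ms)


@dataclass
class PredictionTask:
    """Anticipatory/target stimulus pair parameters.

    A trial delivers an anticipatory pulse at T1 (random inter-trial
    interval) and a target pulse at T2 = T1 + interval (+- jitter).  With
    zero jitter every trial satisfies T2 - T1 = interval exactly.
    """

    interval_ms: float = 10.0          # Delta = T2 - T1
    jitter_ms: float = 0.0             # half-width of uniform jitter
    iti_range_ms: tuple[float, float] = (1000.0, 3000.0)
    amplitude: float = 20.0            # target stimulus amplitude
    anticipatory_amplitude: float = 30.0   # drives a short burst at T1
    pulse_ms: float = 10.0
    gain: float = 2.0                  # current per unit inhibitory weight
    suppression_ms: float = 20.0       # persistence of one inhibitory spike

    def __post_init__(self):
        if self.interval_ms <= 0:
            raise ValueError("inter-stimulus interval must be positive")
        if self.jitter_ms < 0:
            raise ValueError("jitter must be >= 0")


class PredictionTaskEnv(_EnvBase):
    """Prediction-error embodiment for the 3-neuron predictive circuit.

    The inhibitory neuron's spikes, weighted by the (plastic) magnitude of
    its synapse onto the target input neuron and a fixed cancellation gain,
    suppress the external target stimulus; the *residual* current is what the
    target input neuron actually receives.  Per-trial log records T1, T2, the
    residual integral (the prediction error; null iff inhibition exactly
    opposes the stimulus) and the full stimulus integral.
    """

    def __init__(self, task: PredictionTask, anticipatory_id: int = 0,
                 inhibitory_id: int = 1, target_id: int = 2):
        super().__init__()
        self.task = task
        self.aid = anticipatory_id
        self.iid = inhibitory_id
        self.tid = target_id
        self.trial_log: list[dict] = []

    def reset(self, rng, n: int | None = None) -> None:
        self.event_log = []
        self.trial_log = []
        self._gate = None
        self._rng = rng
        self._tokens: deque[tuple[float, float, float]] = deque()
        self._syn_delay = None   # read from the topology on first spike
        self._schedule(0.0)

    def _schedule(self, t: float) -> None:
        task = self.task
        self.T1 = t + self._rng.uniform(*task.iti_range_ms)
        jit = task.jitter_ms * self._rng.uniform(-1.0, 1.0)
        self.T2 = max(self.T1 + 1.0, self.T1 + task.interval_ms + jit)
        self._resid = 0.0
        self._full = 0.0
        self._inh_times: list[float] = []
        self._t1_logged = False
        self._t2_logged = False

    def inhibitory_level(self, t: float) -> float:
        tok = self._tokens
        while tok and tok[0][1] <= t:
            tok.popleft()
        return self.task.gain * sum(s for (a, b, s) in tok if a <= t)

    def currents(self, t: float, dt: float, I: np.ndarray) -> None:
        task = self.task
        if self.T1 <= t < self.T1 + task.pulse_ms:
            if not self._t1_logged:
                self.log(t, "trial_T1", self.T1)
                self._t1_logged = True
            I[self.aid] += task.anticipatory_amplitude
        in_pulse = self.T2 <= t < self.T2 + task.pulse_ms
        if in_pulse:
            if not self._t2_logged:
                self.log(t, "trial_T2", self.T2)
                self._t2_logged = True
            resid = max(0.0, task.amplitude - self.inhibitory_level(t))
            I[self.tid] += resid
            self._resid += resid * dt
            self._full += task.amplitude * dt
        if t >= self.T2 + task.pulse_ms:
            self.trial_log.append({
                "T1": self.T1, "T2": self.T2,
                "residual_integral": self._resid,
                "full_integral": self._full,
                "inhibition_times": list(self._inh_times),
            })
            self._schedule(t)

    def update(self, t: float, dt: float, spiked: np.ndarray,
               state: NetworkState) -> None:
        if self.iid in spiked:
            if self._syn_delay is None:
                self._syn_delay = float(state.topo.delays[self.iid, self.tid])
            strength = abs(state.weight(self.iid, self.tid))
            arr = t + self._syn_delay
            self._tokens.append((arr, arr + self.task.suppression_ms,
                                 strength))
            if self.T1 - 100.0 < t < self.T2 + self.task.pulse_ms:
                self._inh_times.append(t)


# ---------------------------------------------------------------------------
# the master closed-loop runner
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Everything one closed-loop run produced."""

    topo: Topology
    seed: int
    duration_ms: float
    spikes: SpikeRecord
    event_log: list
    weight_times: np.ndarray      # sample times (ms)
    weight_samples: np.ndarray    # (n_samples, n_synapses) flat weights
    syn_src: np.ndarray
    syn_dst: np.ndarray
    initial_weights: np.ndarray   # dense (n, n)
    final_weights: np.ndarray     # dense (n, n)
    trial_log: list | None = None

    def weight_change(self, i: int, j: int) -> float:
        return float(self.final_weights[i, j] - self.initial_weights[i, j])

    def weights_dataframe(self):
        import pandas as pd

        rows = []
        for k, t in enumerate(self.weight_times):
            for s in range(len(self.syn_src)):
                rows.append((t, int(self.syn_src[s]), int(self.syn_dst[s]),
                             self.weight_samples[k, s]))
        return pd.DataFrame(rows, columns=["t_ms", "src", "dst", "weight"])

    def events_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.event_log,
                            columns=["t_ms", "event", "value"])


def close_loop(topo: Topology, env, stdp: STDPConfig | None,
               duration_ms: float, seed: int, dt: float = 1.0,
               noise_sigma: float = DEFAULT_NOISE_SIGMA,
               weight_sample_ms: float = 1000.0,
               record_spikes: bool = True) -> RunResult:
    """Run the full sensorimotor loop and return its records.

    Per step: the environment is queried for external currents, the network
    advances one dt, STDP is applied to the new spikes, and the environment
    observes them (feedback honoring its configured delay).  Noise and
    environment randomness derive from independent substreams of ``seed``,
    so the whole trajectory is reproducible bit-for-bit.
    """
    if hasattr(env, "detector") and env.detector.output_ids.size:
        if np.any(env.detector.output_ids >= topo.n):
            raise ValueError("environment output ids outside the topology")
    ss = np.random.SeedSequence(seed)
    s_noise, s_env = ss.spawn(2)
    state = init_state(topo, dt=dt)
    noise = background_noise(topo.n, noise_sigma, seed=s_noise)
    env.reset(rng=np.random.default_rng(s_env), n=topo.n)

    initial = topo.weights.copy()
    spikes = SpikeRecord()
    n_steps = int(round(duration_ms / dt))
    sample_every = max(1, int(round(weight_sample_ms / dt)))
    w_times = [0.0]
    w_samples = [state.wflat.copy()]

    use_stdp = stdp is not None
    for k in range(n_steps):
        t0 = state.t
        cur = noise.next()
        env.currents(t0, dt, cur)
        spiked = step(state, topo, cur)
        t1 = state.t
        if spiked.size:
            if use_stdp:
                apply_stdp_on_spike(state, spiked, t1, stdp)
            env.update(t1, dt, spiked, state)
            if record_spikes:
                spikes.append(t1, spiked)
        if (k + 1) % sample_every == 0:
            w_times.append(t1)
            w_samples.append(state.wflat.copy())

    sync_weights(state, topo)
    return RunResult(
        topo=topo, seed=seed, duration_ms=duration_ms, spikes=spikes,
        event_log=list(env.event_log),
        weight_times=np.array(w_times),
        weight_samples=np.array(w_samples),
        syn_src=state._src, syn_dst=state._dst,
        initial_weights=initial, final_weights=topo.weights.copy(),
        trial_log=getattr(env, "trial_log", None),
    )
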