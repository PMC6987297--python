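"""Closed-loop environments: gating contracts, yoking, wall kinematics,
prediction trials, and the master runner."""

import numpy as np
import pytest

from lsasim import neural_core as nc
from lsasim.embodiments import (LoopConfig, PredictionTask,
                                PredictionTaskEnv, ReinforcementEnv,
                                StimulusGenerator, UncontrollableEnv,
                                WallWorld, WallWorldEnv, WeakeningEnv,
                                _gate_episodes, close_loop)
from lsasim.plasticity import STDPConfig
from lsasim import runner


def collect_currents(env, n, duration_ms, spike_times=(), output_id=1,
                     rng_seed=0):
    """Drive an environment open-loop with scripted output spikes; returns
    the per-step current delivered to neuron 0."""
    env.reset(rng=np.random.default_rng(rng_seed), n=n)
    spikes = {float(t) for t in spike_times}
    out = np.zeros(int(duration_ms))
    for k in range(int(duration_ms)):
        cur = np.zeros(n)
        env.currents(float(k), 1.0, cur)
        out[k] = cur[0]
        t_end = float(k + 1)
        spiked = np.array([output_id] if t_end in spikes else [],
                          dtype=np.int64)
        env.update(t_end, 1.0, spiked, None)
    return out


def make_reinf(delay=0.0, removal=500.0, period=100.0):
    stim = StimulusGenerator(targets=np.array([0]), period_ms=period)
    return ReinforcementEnv(stim, LoopConfig(delay_ms=delay,
                                             removal_ms=removal), [1])


class TestReinforcement:
    def test_no_spikes_strictly_periodic(self):
        cur = collect_currents(make_reinf(), 2, 1000.0)
        on = np.flatnonzero(cur > 0)
        assert len(on) == 10 * 10  # 10 pulses of 10 ms
        # pulse onsets every 100 ms
        onsets = on[np.diff(np.concatenate([[-10], on])) > 1]
        assert np.array_equal(onsets, np.arange(0, 1000, 100))

    def test_spike_suspends_immediately(self):
        cur = collect_currents(make_reinf(delay=0.0), 2, 2000.0,
                               spike_times=[1000.0])
        assert np.all(cur[1000:1500] == 0.0)
        assert np.any(cur[1500:1600] > 0)  # resumes afterwards

    def test_overlapping_suspensions_merge(self):
        env = make_reinf(delay=0.0, removal=200.0)
        cur = collect_currents(env, 2, 2000.0, spike_times=[1000.0, 1010.0])
        assert np.all(cur[1000:1210] == 0.0)
        assert np.any(cur[1210:1310] > 0)

    def test_feedback_delay_shifts_suspension(self):
        cur = collect_currents(make_reinf(delay=30.0), 2, 2000.0,
                               spike_times=[1000.0])
        # stimulation continues during the loop delay, stops after it
        assert np.any(cur[1000:1010] > 0)
        assert np.all(cur[1030:1530] == 0.0)


class TestWeakening:
    def test_silent_without_spikes(self):
        stim = StimulusGenerator(targets=np.array([0]))
        env = WeakeningEnv(stim, LoopConfig(), [1])
        cur = collect_currents(env, 2, 3000.0)
        assert np.all(cur == 0.0)

    def test_first_pulse_at_spike_plus_delay(self):
        stim = StimulusGenerator(targets=np.array([0]))
        env = WeakeningEnv(stim, LoopConfig(delay_ms=30.0, on_ms=300.0), [1])
        cur = collect_currents(env, 2, 2000.0, spike_times=[1000.0])
        assert np.all(cur[:1030] == 0.0)
        assert cur[1030] > 0.0
        assert np.all(cur[1330:] == 0.0)


class TestUncontrollable:
    def test_schedule_independent_of_output(self):
        stim = StimulusGenerator(targets=np.array([0]))
        env = UncontrollableEnv(stim, mean_on_ms=300.0, mean_off_ms=500.0)
        a = collect_currents(env, 2, 5000.0, spike_times=[])
        env2 = UncontrollableEnv(stim, mean_on_ms=300.0, mean_off_ms=500.0)
        b = collect_currents(env2, 2, 5000.0,
                             spike_times=np.arange(100.0, 5000.0, 100.0))
        assert np.array_equal(a, b)

    def test_yoked_duty_cycle_matches(self):
        """Long-run gate duty of the yoked arm within +-10% of the source
        reinforcement run."""
        res = runner.minimal_circuit_run("lsa3", "reinforcement", seed=5,
                                         duration_ms=400_000.0)
        on, off = _gate_episodes(res.event_log, 400_000.0)
        duty_src = sum(on) / 400_000.0
        stim = StimulusGenerator(targets=np.array([0]), period_ms=30.0)
        env = UncontrollableEnv.yoked_to(res.event_log, stim, 400_000.0)
        env.reset(rng=np.random.default_rng(77), n=2)
        cur = np.zeros(2)
        open_steps = 0
        for k in range(400_000):
            open_steps += env.gate_open(float(k))
            env.currents(float(k), 1.0, cur)
        duty_yoked = open_steps / 400_000.0
        assert abs(duty_yoked - duty_src) < 0.1 * duty_src


class TestWallWorld:
    def test_reaches_sensor_range_on_schedule(self):
        world = WallWorld(length=100.0, position=50.0, heading=1,
                          speed=0.05, sensor_range=10.0)
        stim = StimulusGenerator(targets=np.array([0]))
        env = WallWorldEnv(world, stim, LoopConfig(), [1])
        env.reset(rng=np.random.default_rng(0), n=2)
        cur = np.zeros(2)
        t_expected = (50.0 - 10.0) / 0.05  # 800 ms
        for k in range(2000):
            cur[:] = 0
            env.currents(float(k), 1.0, cur)
            if env.world.at_wall():
                break
        assert abs(float(k) - t_expected) <= 1.0

    def test_turn_ends_stimulation(self):
        world = WallWorld(position=95.0, heading=1)
        stim = StimulusGenerator(targets=np.array([0]))
        env = WallWorldEnv(world, stim, LoopConfig(), [1], k_spikes=1)
        env.reset(rng=np.random.default_rng(0), n=2)
        cur = np.zeros(2)
        env.currents(0.0, 1.0, cur)
        assert env.world.at_wall()
        env.update(1.0, 1.0, np.array([1]), None)  # motor spike -> turn
        cur[:] = 0
        env.currents(1.0, 1.0, cur)
        assert env.world.heading == -1
        assert not env.world.at_wall()     # wall now behind
        events = [e for _, e, _ in env.event_log]
        assert "turn" in events and "wall_leave" in events

    def test_parks_at_wall_without_turns(self):
        world = WallWorld(position=95.0, heading=1)
        stim = StimulusGenerator(targets=np.array([0]))
        env = WallWorldEnv(world, stim, LoopConfig(), [1])
        env.reset(rng=np.random.default_rng(0), n=2)
        cur = np.zeros(2)
        stim_steps = 0
        for k in range(1000):
            cur[:] = 0
            env.currents(float(k), 1.0, cur)
            stim_steps += env.world.at_wall()
        assert env.world.position == world.length  # clamped
        assert stim_steps == 1000

    def test_position_validation(self):
        with pytest.raises(ValueError):
            WallWorld(position=150.0, length=100.0)


class TestPredictionTask:
    def make_env(self, jitter=0.0, **kw):
        task = PredictionTask(interval_ms=10.0, jitter_ms=jitter,
                              iti_range_ms=(200.0, 400.0), **kw)
        return PredictionTaskEnv(task)

    def run_trials(self, env, inhib_schedule, duration_ms=20_000.0):
        """Open-loop trial driver; ``inhib_schedule(t, env)`` may inject
        inhibitory tokens directly."""
        topo = nc.build_minimal_circuit("predictive3", 5.0)
        state = nc.init_state(topo)
        env.reset(rng=np.random.default_rng(3), n=3)
        cur = np.zeros(3)
        for k in range(int(duration_ms)):
            cur[:] = 0
            if inhib_schedule:
                inhib_schedule(float(k), env)
            env.currents(float(k), 1.0, cur)
        return env.trial_log

    def test_zero_jitter_exact_interval(self):
        env = self.make_env()
        log = self.run_trials(env, None)
        assert len(log) > 10
        for tr in log:
            assert tr["T2"] - tr["T1"] == pytest.approx(10.0)

    def test_no_inhibition_full_error(self):
        env = self.make_env()
        log = self.run_trials(env, None)
        full = env.task.amplitude * env.task.pulse_ms
        for tr in log:
            assert tr["residual_integral"] == pytest.approx(full)

    def test_perfect_cancellation_null_error(self):
        env = self.make_env(gain=1.0)
        # inject a standing token strong enough to cancel the stimulus
        def schedule(t, e):
            if not e._tokens:
                e._tokens.append((0.0, 1e9, e.task.amplitude))
        log = self.run_trials(env, schedule)
        for tr in log:
            assert tr["residual_integral"] == 0.0

    def test_half_cancellation_half_error(self):
        env = self.make_env(gain=1.0)
        def schedule(t, e):
            if not e._tokens:
                e._tokens.append((0.0, 1e9, e.task.amplitude / 2))
        log = self.run_trials(env, schedule)
        full = env.task.amplitude * env.task.pulse_ms
        for tr in log:
            assert tr["residual_integral"] == pytest.approx(full / 2)


class TestCloseLoop:
    def test_zero_duration(self, lsa3):
        env = make_reinf()
        res = close_loop(lsa3, env, STDPConfig(), 0.0, seed=0)
        assert len(res.spikes) == 0
        assert np.array_equal(res.initial_weights, res.final_weights)

    def test_reproducible_from_seed(self, lsa3):
        res1 = runner.minimal_circuit_run("lsa3", "reinforcement", seed=3,
                                          duration_ms=20_000.0)
        res2 = runner.minimal_circuit_run("lsa3", "reinforcement", seed=3,
                                          duration_ms=20_000.0)
        assert np.array_equal(res1.spikes.times, res2.spikes.times)
        assert np.array_equal(res1.final_weights, res2.final_weights)
        assert res1.event_log == res2.event_log

    def test_role_mismatch_rejected(self, lsa3):
        stim = StimulusGenerator(targets=np.array([0]))
        env = ReinforcementEnv(stim, LoopConfig(), output_ids=[7])
        with pytest.raises(ValueError):
            close_loop(lsa3, env, STDPConfig(), 1000.0, seed=0)

    def test_event_log_replay_consistency(self):
        """Every stimulation gate change in the log is explained by the
        environment's rule applied to the recorded output spikes."""
        res = runner.minimal_circuit_run("lsa3", "reinforcement", seed=9,
                                         duration_ms=60_000.0)
        out_spikes = res.spikes.train(1)
        P = runner.MINIMAL
        # replay: suspension = union of (s+delay, s+delay+removal]
        offs = [t for t, e, _ in res.event_log if e == "stim_off"]
        ons = [t for t, e, _ in res.event_log if e == "stim_on"]
        susp_end = -np.inf
        expected_off, expected_on = [], []
        gate = True
        for t in np.arange(0.0, 60_000.0):
            s_end = None
            covered = np.any((out_spikes <= t)
                             & (t < out_spikes + P["removal_ms"]))
            if covered != (not gate):
                if covered:
                    expected_off.append(t)
                else:
                    expected_on.append(t)
                gate = not covered
        assert offs == expected_off
        assert ons[1:] == expected_on  # first stim_on logs the initial state
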