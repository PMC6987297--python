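"""Connectivity measure, reaction times, success measure, weight summaries,
prediction error, SNR."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lsasim import metrics as mx
from lsasim import neural_core as nc
from lsasim.neural_core import Role, Topology


def make_topo(n, edges, roles=None, delays=None):
    """Small explicit topology: edges = [(i, j, delay_ms), ...]."""
    if roles is None:
        roles = [Role.SENSORY] + [Role.HIDDEN] * (n - 2) + [Role.MOTOR]
    w = np.zeros((n, n))
    d = np.zeros((n, n))
    conn = np.zeros((n, n), dtype=bool)
    for i, j, dl in edges:
        conn[i, j] = True
        w[i, j] = 1.0
        d[i, j] = dl
    return Topology(n=n, roles=np.array(roles, dtype=np.int8), weights=w,
                    delays=d, connected=conn,
                    plastic=np.zeros_like(conn))


def brute_force_connectivity(topo, threshold):
    """Exhaustive simple-path enumeration over all input-output pairs."""
    hits = 0
    pairs = list(itertools.product(topo.input_ids, topo.output_ids))
    for src, dst in pairs:
        found = False
        stack = [(src, 0.0, frozenset({src}))]
        while stack and not found:
            node, acc, seen = stack.pop()
            for nxt in np.flatnonzero(topo.connected[node]):
                nacc = acc + topo.delays[node, nxt]
                if nacc > threshold:
                    continue
                if nxt == dst:
                    found = True
                    break
                if nxt not in seen:
                    stack.append((nxt, nacc, seen | {nxt}))
        hits += found
    return hits / len(pairs)


class TestConnectivity:
    def test_no_paths_zero(self):
        topo = make_topo(3, [(1, 0, 1.0)])
        assert mx.connectivity_measure(topo) == 0.0

    def test_all_direct_one(self):
        topo = make_topo(4, [(0, 3, 1.0), (1, 3, 1.0)],
                         roles=[Role.SENSORY, Role.SENSORY, Role.HIDDEN,
                                Role.MOTOR])
        assert mx.connectivity_measure(topo, 20.0) == 1.0

    def test_threshold_excludes_slow_paths(self):
        topo = make_topo(3, [(0, 1, 15.0), (1, 2, 15.0)])
        assert mx.connectivity_measure(topo, 20.0) == 0.0
        assert mx.connectivity_measure(topo, 30.0) == 1.0

    def test_direct_only_variant(self):
        topo = make_topo(3, [(0, 1, 1.0), (1, 2, 1.0)])
        assert mx.connectivity_measure(topo, 20.0) == 1.0
        assert mx.connectivity_measure(topo, 20.0, direct_only=True) == 0.0

    def test_no_inputs_raises(self):
        topo = make_topo(2, [(0, 1, 1.0)],
                         roles=[Role.HIDDEN, Role.MOTOR])
        with pytest.raises(ValueError):
            mx.connectivity_measure(topo)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        """Dijkstra-based measure equals brute-force simple-path search on
        random graphs with <= 6 neurons."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        roles = [Role.SENSORY, Role.MOTOR] + \
            [Role.HIDDEN] * (n - 2)
        edges = []
        for i in range(n):
            for j in range(n):
                if i != j and rng.random() < 0.4:
                    edges.append((i, j, float(rng.integers(1, 15))))
        topo = make_topo(n, edges, roles=roles)
        thr = float(rng.integers(5, 30))
        assert mx.connectivity_measure(topo, thr) == pytest.approx(
            brute_force_connectivity(topo, thr))

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_threshold(self, seed):
        topo = nc.build_random_network(40, 0.08, 0.2, 4, 4, seed=seed)
        vals = [mx.connectivity_measure(topo, t)
                for t in (2.0, 5.0, 10.0, 20.0, 40.0)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)


class TestReactionTimes:
    def test_hand_enumerated_log(self):
        log = [(500.0, "wall_enter", 0.0), (620.0, "turn", -1.0),
               (2000.0, "wall_enter", 0.0), (2030.0, "turn", 1.0),
               (5000.0, "wall_enter", 0.0), (5900.0, "turn", -1.0)]
        rts = mx.reaction_times(log)
        assert np.array_equal(rts.values, [120.0, 30.0, 900.0])
        assert rts.meta["unresolved"] == 0

    def test_unresolved_encounters_excluded(self):
        log = [(100.0, "wall_enter", 0.0)]
        rts = mx.reaction_times(log)
        assert len(rts) == 0
        assert rts.meta["unresolved"] == 1

    def test_timestamp_shift_invariance(self):
        base = [(500.0, "wall_enter", 0), (620.0, "turn", 0),
                (2000.0, "wall_enter", 0), (2100.0, "turn", 0),
                (3000.0, "wall_enter", 0), (3500.0, "turn", 0),
                (4000.0, "wall_enter", 0), (4050.0, "turn", 0),
                (5000.0, "wall_enter", 0), (5500.0, "turn", 0),
                (6000.0, "wall_enter", 0), (6100.0, "turn", 0),
                (7000.0, "wall_enter", 0), (7200.0, "turn", 0),
                (8000.0, "wall_enter", 0), (8010.0, "turn", 0)]
        shifted = [(t + 12345.0, e, v) for t, e, v in base]
        s1 = mx.success_measure(mx.reaction_times(base))
        s2 = mx.success_measure(mx.reaction_times(shifted))
        assert s1 == s2


class TestSuccessMeasure:
    def test_strictly_decreasing_significant(self):
        rts = mx.MetricSeries("rt", np.arange(16),
                              np.linspace(1000, 10, 16))
        stat, p = mx.success_measure(rts)
        assert stat > 0
        assert p < 0.05
        assert mx.learning_success(rts)

    def test_constant_rts_null(self):
        rts = mx.MetricSeries("rt", np.arange(16), np.full(16, 200.0))
        stat, p = mx.success_measure(rts)
        assert stat == 0.0
        assert p == 1.0
        assert not mx.learning_success(rts)

    def test_too_few_encounters(self):
        rts = mx.MetricSeries("rt", np.arange(4), np.full(4, 100.0))
        with pytest.raises(ValueError):
            mx.success_measure(rts)

    def test_shuffled_rts_rarely_significant(self):
        """Permutation fixture: shuffling a decreasing series destroys the
        significance in >= 95% of shuffles."""
        rng = np.random.default_rng(0)
        vals = np.linspace(1000, 10, 24)
        n_sig = 0
        for _ in range(100):
            shuffled = rng.permutation(vals)
            rts = mx.MetricSeries("rt", np.arange(24), shuffled)
            _, p = mx.success_measure(rts)
            n_sig += p < 0.05
        assert n_sig <= 5


class TestWeightSummary:
    class FakeRun:
        def __init__(self, changes):
            self.changes = changes

        def weight_change(self, i, j):
            return self.changes[(i, j)]

    def test_identical_runs_zero_width_ci(self):
        runs = [self.FakeRun({(0, 1): 2.0}) for _ in range(5)]
        df = mx.weight_change_summary(runs, {"c": [(0, 1)]})
        row = df.iloc[0]
        assert row["ci_lo"] == row["ci_hi"] == 2.0

    def test_frozen_plasticity_all_zero(self):
        runs = [self.FakeRun({(0, 1): 0.0}) for _ in range(4)]
        df = mx.weight_change_summary(runs, {"c": [(0, 1)]})
        assert df.iloc[0]["mean_change"] == 0.0

    def test_known_drift_recovered(self):
        rng = np.random.default_rng(4)
        runs = [self.FakeRun({(0, 1): 3.0 + rng.normal(0, 0.5)})
                for _ in range(30)]
        df = mx.weight_change_summary(runs, {"c": [(0, 1)]})
        row = df.iloc[0]
        assert row["ci_lo"] < 3.0 < row["ci_hi"]
        assert row["p_increase"] < 0.01

    def test_empty_class_rejected(self):
        runs = [self.FakeRun({}), self.FakeRun({})]
        with pytest.raises(ValueError):
            mx.weight_change_summary(runs, {"c": []})


class TestPredictionError:
    def test_values_from_trial_log(self):
        log = [{"residual_integral": 200.0}, {"residual_integral": 100.0},
               {"residual_integral": 0.0}]
        series = mx.prediction_error_per_trial(log)
        assert np.array_equal(series.values, [200.0, 100.0, 0.0])

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            mx.prediction_error_per_trial([])


class TestSNR:
    @staticmethod
    def fixture_record(on_rate, off_rate, n_out=2, total=20_000.0):
        """Deterministic alternating stim-on/off epochs with fixed rates."""
        rng = np.random.default_rng(0)
        log, times, ids = [], [], []
        t = 0.0
        on = True
        while t < total:
            log.append((t, "stim_on" if on else "stim_off", 0.0))
            rate = on_rate if on else off_rate
            for nid in range(n_out):
                k = int(rate * 1.0)  # spikes per second in a 1 s epoch
                times.extend(np.linspace(t, t + 999.0, k))
                ids.extend([nid] * k)
            t += 1000.0
            on = not on
        order = np.argsort(times)
        rec = nc.SpikeRecord()
        for i in order:
            rec.append(times[i], np.array([ids[i]]))
        return rec, log

    def test_hand_computed_ratio(self):
        rec, log = self.fixture_record(on_rate=20, off_rate=5)
        snr = mx.snr_estimate(rec, log, [0, 1], 20_000.0)
        # off-epochs have exactly 5 Hz in every bin -> sd 0; modulated
        assert snr == np.inf

    def test_no_modulation_near_zero(self):
        rec, log = self.fixture_record(on_rate=5, off_rate=5)
        snr = mx.snr_estimate(rec, log, [0, 1], 20_000.0)
        assert snr == 0.0 or abs(snr) < 0.5

    def test_requires_unstimulated_epochs(self):
        rec, _ = self.fixture_record(5, 5)
        log = [(0.0, "stim_on", 0.0)]
        with pytest.raises(ValueError):
            mx.snr_estimate(rec, log, [0, 1], 20_000.0)

    def test_small_circuit_larger_snr_than_network(self):
        """Same stimulus: the 3-neuron circuit's output SNR exceeds the
        100-neuron network's (more internal noise converging on outputs)."""
        from lsasim.embodiments import (LoopConfig, StimulusGenerator,
                                        UncontrollableEnv, close_loop)

        def run_snr(topo, seed):
            stim = StimulusGenerator(targets=topo.input_ids,
                                     amplitude=20.0, period_ms=30.0)
            env = UncontrollableEnv(stim, mean_on_ms=2000.0,
                                    mean_off_ms=2000.0)
            res = close_loop(topo, env, None, 60_000.0, seed,
                             noise_sigma=3.9)
            return mx.snr_estimate(res.spikes, res.event_log,
                                   topo.output_ids, 60_000.0)

        small = nc.build_minimal_circuit("lsa3", 8.0)
        big = nc.build_random_network(100, 0.1, 0.2, 10, 10, seed=1)
        snr_small = np.mean([run_snr(small, s) for s in range(3)])
        snr_big = np.mean([run_snr(big, s) for s in range(3)])
        assert snr_small > snr_big
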