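"""Quantities used to state the learning conditions and outcomes.

Connectivity measure (fraction of sensory->motor pairs joined by a low-delay
path), wall-task reaction times and the success measure built on them,
per-class weight-change summaries, per-trial prediction error, and a
signal-to-noise operationalization for output neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "MetricSeries", "connectivity_measure", "reaction_times",
    "success_measure", "learning_success", "weight_change_summary",
    "prediction_error_per_trial", "snr_estimate",
]

#: Significance level for the pre-registered learning-success boolean.
SUCCESS_ALPHA = 0.05


@dataclass
class MetricSeries:
    """Named (index, value) series with units; indices sorted."""

    name: str
    index: np.ndarray
    values: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.index = np.asarray(self.index, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.index) != len(self.values):
            raise ValueError("index/value length mismatch")
        if np.any(np.diff(self.index) < 0):
            raise ValueError("indices must be sorted")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self):
        return len(self.values)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"metric": self.name, "index": self.index,
                             "value": self.values, "units": self.units})


def connectivity_measure(topo, delay_threshold_ms: float = 20.0,
                         direct_only: bool = False) -> float:
    """Fraction of (input, output) pairs joined by a low-delay path.

    A pair counts if some directed path from the sensory neuron to the motor
    neuron has summed conduction delay <= the threshold (default: the STDP
    memory window, tying usable paths to the association horizon).  With
    ``direct_only`` only single synapses count.
    """
    inp, out = topo.input_ids, topo.output_ids
    if inp.size == 0 or out.size == 0:
        raise ValueError("topology needs >= 1 input and >= 1 output neuron")
    if direct_only:
        sub = topo.connected[np.ix_(inp, out)] & \
            (topo.delays[np.ix_(inp, out)] <= delay_threshold_ms)
        return float(np.count_nonzero(sub)) / (inp.size * out.size)
    graph = sparse.csr_matrix(
        (topo.delays[topo.connected],
         np.nonzero(topo.connected)), shape=(topo.n, topo.n))
    dist = dijkstra(graph, directed=True, indices=inp)
    ok = dist[:, out] <= delay_threshold_ms
    return float(np.count_nonzero(ok)) / (inp.size * out.size)


def reaction_times(event_log) -> MetricSeries:
    """Per-encounter delay between reaching a wall and turning away from it.

    Encounters with no subsequent turn before the run (or the next encounter
    resolution) ends are excluded from the series and counted in
    ``meta['unresolved']``.
    """
    rows = _as_rows(event_log)
    enc_t, rts = [], []
    unresolved = 0
    pending = None
    for t, ev, _ in rows:
        if ev == "wall_enter":
            if pending is not None:
                unresolved += 1
            pending = t
        elif ev == "turn" and pending is not None:
            enc_t.append(pending)
            rts.append(t - pending)
            pending = None
    if pending is not None:
        unresolved += 1
    return MetricSeries("reaction_time", np.array(enc_t), np.array(rts),
                        units="ms", meta={"unresolved": unresolved})


def success_measure(rts: MetricSeries, min_encounters: int = 8):
    """Decrease of reaction time over the run.

    Statistic: median RT of the first quartile block of encounters minus the
    median RT of the last quartile block (positive = improvement), with a
    one-sided Mann-Whitney rank test between the two blocks.
    Returns ``(statistic_ms, p_value)``.
    """
    n = len(rts)
    if n < min_encounters:
        raise ValueError(f"need >= {min_encounters} encounters, got {n}")
    q = max(2, n // 4)
    first, last = rts.values[:q], rts.values[-q:]
    statistic = float(np.median(first) - np.median(last))
    if np.ptp(rts.values) == 0:
        return 0.0, 1.0
    p = stats.mannwhitneyu(first, last, alternative="greater").pvalue
    return statistic, float(p)


def learning_success(rts: MetricSeries, min_encounters: int = 8,
                     alpha: float = SUCCESS_ALPHA,
                     ratio: float = 0.5) -> bool:
    """Pre-registered boolean: significant RT decrease AND the last-quartile
    median below ``ratio`` of the first-quartile median.  False when the run
    produced too few resolved encounters to evaluate."""
    if len(rts) < min_encounters:
        return False
    stat, p = success_measure(rts, min_encounters)
    q = max(2, len(rts) // 4)
    first = np.median(rts.values[:q])
    last = np.median(rts.values[-q:])
    return bool(p < alpha and first > 0 and last < ratio * first)


def weight_change_summary(results, classes: dict, n_boot: int = 1999,
                          seed: int = 0):
    """Per-synapse-class mean weight change with bootstrap CI across seeds.

    ``results`` is a sequence of RunResult; ``classes`` maps a class name to
    a list of (src, dst) synapses.  For each class the per-seed mean of
    (final - initial) is reduced to a mean, a 95% bootstrap CI, and one-sided
    t-test p-values against zero in both directions.
    """
    import pandas as pd

    if len(results) < 2:
        raise ValueError("need >= 2 seeds for a CI")
    rng = np.random.default_rng(seed)
    rows = []
    for name, syns in classes.items():
        if not syns:
            raise ValueError(f"class {name!r} has no synapses")
        per_seed = np.array([
            np.mean([r.weight_change(i, j) for (i, j) in syns])
            for r in results])
        mean = per_seed.mean()
        if np.allclose(per_seed, per_seed[0]):
            lo = hi = mean
            p_inc = 0.0 if mean > 0 else 1.0
            p_dec = 0.0 if mean < 0 else 1.0
        else:
            idx = rng.integers(0, len(per_seed), (n_boot, len(per_seed)))
            boots = per_seed[idx].mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            p_inc = stats.ttest_1samp(per_seed, 0.0,
                                      alternative="greater").pvalue
            p_dec = stats.ttest_1samp(per_seed, 0.0,
                                      alternative="less").pvalue
        rows.append((name, mean, lo, hi, float(p_inc), float(p_dec),
                     len(per_seed)))
    return pd.DataFrame(rows, columns=["class", "mean_change", "ci_lo",
                                       "ci_hi", "p_increase", "p_decrease",
                                       "n_seeds"])


def prediction_error_per_trial(trial_log) -> MetricSeries:
    """Time-integral of the residual target current, per trial (charge
    units: current x ms).  Zero iff inhibition fully cancelled the target
    stimulus in that trial."""
    if not trial_log:
        raise ValueError("empty trial log")
    vals = np.array([tr["residual_integral"] for tr in trial_log])
    return MetricSeries("prediction_error", np.arange(len(vals)), vals,
                        units="current*ms")


def snr_estimate(spikes, event_log, output_ids, total_ms: float,
                 bin_ms: float = 1000.0) -> float:
    """Output signal-to-noise ratio of stimulation-driven firing.

    (mean output firing rate during stimulation-on epochs minus the mean
    rate outside them) divided by the s.d. of the outside rate across
    ``bin_ms`` bins.  This is this package's operationalization of the
    network-size/noise limit on stimulation-avoidance learning.
    """
    output_ids = np.asarray(output_ids)
    rows = _as_rows(event_log)
    on_iv = _on_intervals(rows, total_ms)
    if not on_iv:
        raise ValueError("run contains no stimulated epochs")
    off_iv = _complement(on_iv, total_ms)
    if not off_iv:
        raise ValueError("run contains no unstimulated epochs")
    t = spikes.times
    mask = np.isin(spikes.ids, output_ids)
    t = t[mask]

    def _rate(iv):
        dur = sum(b - a for a, b in iv)
        cnt = sum(np.count_nonzero((t >= a) & (t < b)) for a, b in iv)
        return cnt / dur * 1000.0 / output_ids.size if dur > 0 else 0.0

    r_on = _rate(on_iv)
    r_off = _rate(off_iv)
    off_bins = []
    for a, b in off_iv:
        edges = np.arange(a, b, bin_ms)
        for e in edges:
            hi = min(e + bin_ms, b)
            if hi - e >= bin_ms / 2:
                off_bins.append(_rate([(e, hi)]))
    sd = float(np.std(off_bins, ddof=1)) if len(off_bins) > 1 else 0.0
    if sd == 0.0:
        return np.inf if r_on > r_off else 0.0
    return float((r_on - r_off) / sd)


# -- helpers ----------------------------------------------------------------

def _as_rows(event_log):
    if hasattr(event_log, "itertuples"):
        return [(r.t_ms, r.event, r.value) for r in event_log.itertuples()]
    return list(event_log)


def _on_intervals(rows, total_ms):
    iv = []
    start = None
    state = None
    for t, ev, _ in rows:
        if ev == "stim_on":
            start, state = t, True
        elif ev == "stim_off" and state:
            iv.append((start, t))
            state = False
    if state:
        iv.append((start, total_ms))
    return iv


def _complement(iv, total_ms):
    out = []
    prev = 0.0
    for a, b in iv:
        if a > prev:
            out.append((prev, a))
        prev = b
    if prev < total_ms:
        out.append((prev, total_ms))
    return out
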