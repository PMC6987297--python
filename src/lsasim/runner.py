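"""Preset experiments, sweep drivers, critical-delay estimation, file I/O.

Each preset reproduces one study condition: the minimal reinforcement /
weakening circuits, the controllability ablation with a yoked random arm,
the 1-D wall-avoidance robot, the connectivity sweep, prediction learning
and its predictability ablation, and the two critical-feedback-delay sweeps.
Preset parameters are frozen study conditions (see docs/methods.md for the
calibration rationale); ``ExperimentConfig`` exposes the handful a user may
reasonably override (duration, seeds, output directory).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .neural_core import (DEFAULT_NOISE_SIGMA, Topology,
                          build_feedforward, build_minimal_circuit,
                          build_random_network)
from .plasticity import STDPConfig
from .embodiments import (LoopConfig, PredictionTask, PredictionTaskEnv,
                          ReinforcementEnv, StimulusGenerator,
                          UncontrollableEnv, WallWorld, WallWorldEnv,
                          WeakeningEnv, RunResult, close_loop)
from . import metrics

__all__ = ["ExperimentConfig", "ExperimentResult", "PRESETS",
           "run_experiment", "estimate_critical_delay", "report",
           "minimal_circuit_run", "wall_run", "wall_run_random",
           "prediction_run", "delay_success_2n", "delay_success_100n"]

NOISE_SIGMA = DEFAULT_NOISE_SIGMA

# frozen preset conditions -------------------------------------------------
MINIMAL = dict(w0=2.0, stim_amp=20.0, pulse_ms=10.0, period_ms=25.0,
               removal_ms=500.0, dw=0.1, duration_ms=200_000.0)
WALL = dict(n_input=4, n_output=4, w0=1.0, dw=0.05, stim_amp=20.0,
            pulse_ms=10.0, period_ms=30.0, k_spikes=2, window_ms=20.0,
            refractory_ms=200.0, duration_ms=200_000.0)
PREDICTION = dict(w_ai=6.0, w_ib=1.0, interval_ms=10.0, target_amp=20.0,
                  anticipatory_amp=50.0, gain=4.0, suppression_ms=20.0,
                  iti_ms=(800.0, 2000.0), dw=0.3, duration_ms=300_000.0,
                  ablation_jitter_ms=40.0)
NET100 = dict(n=100, p_connect=0.1, frac_inhibitory=0.2, n_input=10,
              n_output=10)
SWEEP_2N = dict(delays=tuple(range(0, 61, 5)), n_seeds=20,
                duration_ms=200_000.0)
SWEEP_100N = dict(delays=tuple(range(0, 81, 10)), n_seeds=10,
                  duration_ms=100_000.0, stim_amp=20.0, pulse_ms=10.0,
                  period_ms=15.0, k_spikes=3, window_ms=20.0,
                  refractory_ms=100.0, dw=0.1)
CONNECTIVITY = dict(n_networks=50, p_max=0.25, n_zero=3, stim_amp=30.0,
                    pulse_ms=15.0, period_ms=30.0, k_spikes=3,
                    refractory_ms=300.0, dw=0.2, duration_ms=120_000.0,
                    delay_threshold_ms=10.0)

#: Pre-registered per-run learning-success rule for the delay sweeps:
#: the (mean) input->output potentiation must reach this fraction of the
#: available headroom w_max - w0 (a non-plastic control changes by exactly 0).
SUCCESS_HEADROOM_FRACTION = 0.2


@dataclass
class ExperimentConfig:
    """Config for one preset run; round-trips losslessly through YAML."""

    preset: str
    seeds: list[int] = field(default_factory=lambda: list(range(20)))
    duration_ms: float | None = None   # None -> preset default
    out_dir: str | None = None
    weight_sample_ms: float = 1000.0

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("seed list must be non-empty")
        if self.duration_ms is not None and self.duration_ms <= 0:
            raise ValueError("duration must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ExperimentResult:
    """Summary statistics plus the manifest of files a preset wrote."""

    preset: str
    summary: dict
    manifest: list[str]
    config: ExperimentConfig
    version: str = __version__

    def save_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"preset": self.preset, "summary": self.summary,
                       "manifest": self.manifest,
                       "config": dataclasses.asdict(self.config),
                       "version": self.version}, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# single-run builders used by presets, sweeps and the acceptance checks
# ---------------------------------------------------------------------------

def minimal_circuit_run(kind: str, env_kind: str, seed: int,
                        delay_ms: float = 0.0,
                        duration_ms: float | None = None,
                        yoke_from: RunResult | None = None,
                        weight_sample_ms: float = 1000.0) -> RunResult:
    """One closed-loop run of a minimal circuit under a chosen embodiment.

    ``env_kind``: 'reinforcement', 'weakening', or 'uncontrollable' (the
    latter duty-matched to ``yoke_from`` when given).
    """
    P = MINIMAL
    dur = P["duration_ms"] if duration_ms is None else duration_ms
    topo = build_minimal_circuit(kind, P["w0"])
    stim = StimulusGenerator(targets=topo.input_ids, amplitude=P["stim_amp"],
                             pulse_ms=P["pulse_ms"], period_ms=P["period_ms"])
    loop = LoopConfig(delay_ms=delay_ms, removal_ms=P["removal_ms"],
                      on_ms=P["removal_ms"])
    if env_kind == "reinforcement":
        env = ReinforcementEnv(stim, loop, topo.output_ids)
    elif env_kind == "weakening":
        env = WeakeningEnv(stim, loop, topo.output_ids)
    elif env_kind == "uncontrollable":
        if yoke_from is not None:
            env = UncontrollableEnv.yoked_to(yoke_from.event_log, stim,
                                             yoke_from.duration_ms)
        else:
            env = UncontrollableEnv(stim, mean_on_ms=300.0, mean_off_ms=1700.0)
    else:
        raise ValueError(f"unknown environment kind {env_kind!r}")
    return close_loop(topo, env, STDPConfig(dw=P["dw"]), dur, seed,
                      noise_sigma=NOISE_SIGMA,
                      weight_sample_ms=weight_sample_ms)


def wall_run(seed: int, duration_ms: float | None = None) -> RunResult:
    """Wall-avoidance run with the small feedforward sensor->motor circuit."""
    P = WALL
    dur = P["duration_ms"] if duration_ms is None else duration_ms
    topo = build_feedforward(P["n_input"], P["n_output"], P["w0"])
    stim = StimulusGenerator(targets=topo.input_ids, amplitude=P["stim_amp"],
                             pulse_ms=P["pulse_ms"], period_ms=P["period_ms"])
    env = WallWorldEnv(WallWorld(), stim, LoopConfig(), topo.output_ids,
                       k_spikes=P["k_spikes"], window_ms=P["window_ms"],
                       refractory_ms=P["refractory_ms"])
    return close_loop(topo, env, STDPConfig(dw=P["dw"]), dur, seed,
                      noise_sigma=NOISE_SIGMA)


def wall_run_random(seed: int, p_connect: float,
                    duration_ms: float | None = None) -> tuple[RunResult, float]:
    """Wall-avoidance run with a 100-neuron random network; returns the run
    and the network's low-delay connectivity measure."""
    P = CONNECTIVITY
    dur = P["duration_ms"] if duration_ms is None else duration_ms
    topo = build_random_network(NET100["n"], p_connect,
                                NET100["frac_inhibitory"],
                                NET100["n_input"], NET100["n_output"],
                                seed=seed)
    conn = metrics.connectivity_measure(topo, P["delay_threshold_ms"])
    stim = StimulusGenerator(targets=topo.input_ids, amplitude=P["stim_amp"],
                             pulse_ms=P["pulse_ms"], period_ms=P["period_ms"])
    env = WallWorldEnv(WallWorld(), stim, LoopConfig(), topo.output_ids,
                       k_spikes=P["k_spikes"], window_ms=20.0,
                       refractory_ms=P["refractory_ms"])
    res = close_loop(topo, env, STDPConfig(dw=P["dw"]), dur, seed,
                     noise_sigma=NOISE_SIGMA)
    return res, conn


def prediction_run(seed: int, jitter_ms: float = 0.0,
                   duration_ms: float | None = None) -> RunResult:
    """Prediction-learning run with the 3-neuron predictive circuit."""
    P = PREDICTION
    dur = P["duration_ms"] if duration_ms is None else duration_ms
    topo = build_minimal_circuit("predictive3", P["w_ai"],
                                 inhibitory_weight=P["w_ib"])
    task = PredictionTask(interval_ms=P["interval_ms"], jitter_ms=jitter_ms,
                          iti_range_ms=P["iti_ms"],
                          amplitude=P["target_amp"],
                          anticipatory_amplitude=P["anticipatory_amp"],
                          gain=P["gain"], suppression_ms=P["suppression_ms"])
    env = PredictionTaskEnv(task)
    return close_loop(topo, env, STDPConfig(dw=P["dw"]), dur, seed,
                      noise_sigma=NOISE_SIGMA)


def delay_success_2n(delay_ms: float, seed: int,
                     duration_ms: float | None = None) -> bool:
    """Per-run learning-success boolean for the two-neuron delay sweep:
    potentiation of the single input->output weight beyond the headroom
    fraction a non-plastic control (change exactly 0) could never show."""
    res = minimal_circuit_run("lsa2", "reinforcement", seed,
                              delay_ms=delay_ms, duration_ms=duration_ms)
    threshold = SUCCESS_HEADROOM_FRACTION * (res.topo.w_max - MINIMAL["w0"])
    return res.weight_change(0, 1) >= threshold


def delay_success_100n(delay_ms: float, seed: int,
                       duration_ms: float | None = None) -> bool:
    """Per-run learning success for the 100-neuron avoidance sweep: mean
    potentiation of the direct input->output synapses beyond the headroom
    fraction."""
    P = SWEEP_100N
    dur = P["duration_ms"] if duration_ms is None else duration_ms
    topo = build_random_network(NET100["n"], NET100["p_connect"],
                                NET100["frac_inhibitory"],
                                NET100["n_input"], NET100["n_output"],
                                seed=seed)
    inp, out = topo.input_ids, topo.output_ids
    w0 = topo.weights.copy()
    stim = StimulusGenerator(targets=inp, amplitude=P["stim_amp"],
                             pulse_ms=P["pulse_ms"], period_ms=P["period_ms"])
    env = ReinforcementEnv(stim, LoopConfig(delay_ms=delay_ms), out,
                           k_spikes=P["k_spikes"], window_ms=P["window_ms"],
                           refractory_ms=P["refractory_ms"])
    res = close_loop(topo, env, STDPConfig(dw=P["dw"]), dur, seed,
                     noise_sigma=NOISE_SIGMA)
    direct = topo.connected[np.ix_(inp, out)]
    if not direct.any():
        return False
    change = (res.final_weights - w0)[np.ix_(inp, out)][direct].mean()
    headroom = (topo.w_max - w0[np.ix_(inp, out)])[direct].mean()
    return change >= SUCCESS_HEADROOM_FRACTION * headroom


# ---------------------------------------------------------------------------
# critical-delay estimation
# ---------------------------------------------------------------------------

def estimate_critical_delay(success_fn, delays, seeds,
                            success_floor: float = 0.8) -> dict:
    """Sweep the feedback delay and estimate the critical loop-closure time.

    ``success_fn(delay_ms, seed) -> bool``; ``delays`` sorted ascending
    (>= 3 values); ``seeds`` iterable (>= 5 per delay).  The critical delay
    is the largest delay whose success fraction reaches the floor.  Returns
    per-delay fractions, the estimate (None if no delay reaches the floor:
    'below minimum tested'), plus censoring/monotonicity flags.
    """
    delays = list(delays)
    seeds = list(seeds)
    if len(delays) < 3 or sorted(delays) != delays:
        raise ValueError("need >= 3 sorted delays")
    if len(seeds) < 5:
        raise ValueError("need >= 5 seeds per delay")
    fractions = {}
    for d in delays:
        wins = sum(bool(success_fn(d, s)) for s in seeds)
        fractions[d] = wins / len(seeds)
    passing = [d for d in delays if fractions[d] >= success_floor]
    critical = max(passing) if passing else None
    non_monotone = []
    vals = [fractions[d] >= success_floor for d in delays]
    for i in range(1, len(vals)):
        if vals[i] and not vals[i - 1]:
            non_monotone.append(delays[i])
    return {
        "delays": delays,
        "success_fractions": [fractions[d] for d in delays],
        "critical_delay_ms": critical,
        "right_censored": critical == delays[-1] if passing else False,
        "below_minimum": not passing,
        "non_monotone_at": non_monotone,
        "n_seeds": len(seeds),
        "success_floor": success_floor,
    }


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _weight_contrast(results, kind="lsa3"):
    """Per-class input->output vs input->hidden weight-change summary."""
    classes = {"input_to_output": [(0, 1)]}
    if kind == "lsa3":
        classes["input_to_hidden"] = [(0, 2)]
    return metrics.weight_change_summary(results, classes)


def _save_runs(results, out: Path, tag: str):
    files = []
    for r in results:
        p = out / f"spikes_{tag}_s{r.seed}.csv"
        r.spikes.save_csv(p)
        files.append(str(p))
        p = out / f"weights_{tag}_s{r.seed}.csv"
        r.weights_dataframe().to_csv(p, index=False)
        files.append(str(p))
        p = out / f"events_{tag}_s{r.seed}.csv"
        r.events_dataframe().to_csv(p, index=False)
        files.append(str(p))
    return files


def _preset_minimal(config, env_kind):
    dur = config.duration_ms
    results = [minimal_circuit_run("lsa3", env_kind, s, duration_ms=dur,
                                   weight_sample_ms=config.weight_sample_ms)
               for s in config.seeds]
    df = _weight_contrast(results)
    row_out = df[df["class"] == "input_to_output"].iloc[0]
    row_hid = df[df["class"] == "input_to_hidden"].iloc[0]
    direction = "p_increase" if env_kind == "reinforcement" else "p_decrease"
    summary = {
        "mean_dw_input_output": row_out["mean_change"],
        "mean_dw_input_hidden": row_hid["mean_change"],
        "p_value": row_out[direction],
        "hidden_to_output_ratio": (abs(row_hid["mean_change"])
                                   / abs(row_out["mean_change"])
                                   if row_out["mean_change"] else np.inf),
        "contrast_verdict": bool(
            row_out[direction] < 0.01
            and abs(row_hid["mean_change"]) < 0.25 * abs(row_out["mean_change"])),
    }
    return results, df, summary


def preset_minimal_reinforcement(config: ExperimentConfig, out: Path):
    results, df, summary = _preset_minimal(config, "reinforcement")
    files = _save_runs(results, out, "reinforcement")
    df.to_csv(out / "weight_summary.csv", index=False)
    files.append(str(out / "weight_summary.csv"))
    return summary, files


def preset_minimal_weakening(config: ExperimentConfig, out: Path):
    results, df, summary = _preset_minimal(config, "weakening")
    files = _save_runs(results, out, "weakening")
    df.to_csv(out / "weight_summary.csv", index=False)
    files.append(str(out / "weight_summary.csv"))
    return summary, files


def preset_controllability_ablation(config: ExperimentConfig, out: Path):
    """Controllable (reinforcement) arm vs yoked random-stimulation arm."""
    dur = config.duration_ms
    ctrl = [minimal_circuit_run("lsa3", "reinforcement", s, duration_ms=dur)
            for s in config.seeds]
    yoked = [minimal_circuit_run("lsa3", "uncontrollable", s + 100_000,
                                 duration_ms=dur, yoke_from=rc)
             for s, rc in zip(config.seeds, ctrl)]
    dw_out_c = np.array([r.weight_change(0, 1) for r in ctrl])
    dw_out_u = np.array([r.weight_change(0, 1) for r in yoked])
    dw_hid_u = np.array([r.weight_change(0, 2) for r in yoked])
    p_ctrl = stats.ttest_1samp(dw_out_c, 0.0, alternative="greater").pvalue
    p_indist = stats.ttest_ind(dw_out_u, dw_hid_u).pvalue
    summary = {
        "controllable_mean_dw_output": dw_out_c.mean(),
        "controllable_p_increase": float(p_ctrl),
        "uncontrollable_mean_dw_output": dw_out_u.mean(),
        "uncontrollable_mean_dw_hidden": dw_hid_u.mean(),
        "p_output_vs_hidden_uncontrollable": float(p_indist),
        "verdict": bool(p_ctrl < 0.01 and p_indist > 0.05),
    }
    files = _save_runs(ctrl, out, "controllable")
    files += _save_runs(yoked, out, "yoked")
    return summary, files


def preset_wall_avoidance(config: ExperimentConfig, out: Path):
    rows, files = [], []
    n_success = 0
    for s in config.seeds:
        res = wall_run(s, duration_ms=config.duration_ms)
        rts = metrics.reaction_times(res.event_log)
        ok = metrics.learning_success(rts)
        n_success += ok
        q = max(2, len(rts) // 4) if len(rts) >= 8 else 0
        rows.append({
            "seed": s, "n_encounters": len(rts),
            "unresolved": rts.meta["unresolved"],
            "first_quartile_median_rt": (float(np.median(rts.values[:q]))
                                         if q else np.nan),
            "last_quartile_median_rt": (float(np.median(rts.values[-q:]))
                                        if q else np.nan),
            "success": bool(ok),
        })
        p = out / f"events_wall_s{s}.csv"
        res.events_dataframe().to_csv(p, index=False)
        files.append(str(p))
    df = pd.DataFrame(rows)
    df.to_csv(out / "wall_summary.csv", index=False)
    files.append(str(out / "wall_summary.csv"))
    med_ratio = float(np.nanmedian(df["last_quartile_median_rt"]
                                   / df["first_quartile_median_rt"]))
    summary = {
        "success_fraction": n_success / len(config.seeds),
        "median_rt_ratio_last_over_first": med_ratio,
        "verdict": bool(n_success / len(config.seeds) >= 0.8),
    }
    return summary, files


def preset_connectivity_sweep(config: ExperimentConfig, out: Path):
    """Networks spanning connectivity 0-1 on the wall task: rank
    correlation between the connectivity measure and learning success."""
    P = CONNECTIVITY
    n = P["n_networks"]
    ps = np.concatenate([np.zeros(P["n_zero"]),
                         np.linspace(0.003, P["p_max"], n - P["n_zero"])])
    rows = []
    base = config.seeds[0]
    for i, p_conn in enumerate(ps):
        res, conn = wall_run_random(base + i, float(p_conn),
                                    duration_ms=config.duration_ms)
        rts = metrics.reaction_times(res.event_log)
        if len(rts) >= 8:
            stat, pv = metrics.success_measure(rts)
            ok = metrics.learning_success(rts)
        else:
            stat, pv, ok = 0.0, 1.0, False
        rows.append({"p_connect": float(p_conn), "connectivity": conn,
                     "success_stat_ms": stat, "success_p": pv,
                     "success": bool(ok), "n_encounters": len(rts)})
    df = pd.DataFrame(rows)
    df.to_csv(out / "connectivity_sweep.csv", index=False)
    sig = -np.log10(np.maximum(df["success_p"], 1e-12))
    rho = float(stats.spearmanr(df["connectivity"], sig).statistic)
    zero = df[df["connectivity"] == 0]
    summary = {
        "spearman_connectivity_vs_success": rho,
        "n_zero_connectivity": int(len(zero)),
        "zero_connectivity_successes": int(zero["success"].sum()),
        "verdict": bool(rho > 0.5 and zero["success"].sum() == 0),
    }
    return summary, [str(out / "connectivity_sweep.csv")]


def _prediction_summary(config, jitter):
    firsts, lasts, d1f = [], [], []
    per_seed = []
    for s in config.seeds:
        res = prediction_run(s, jitter_ms=jitter,
                             duration_ms=config.duration_ms)
        errs = metrics.prediction_error_per_trial(res.trial_log).values
        firsts.append(errs[:10].mean())
        lasts.append(errs[-10:].mean())
        d1f.append(errs[0] - errs[-1])
        per_seed.append(errs)
    d1f = np.array(d1f)
    if np.any(d1f != 0):
        p_decrease = stats.wilcoxon(d1f, alternative="greater").pvalue
    else:
        p_decrease = 1.0
    return {
        "jitter_ms": jitter,
        "mean_error_first10": float(np.mean(firsts)),
        "mean_error_last10": float(np.mean(lasts)),
        "last_over_first_ratio": float(np.mean(lasts) / np.mean(firsts)),
        "p_final_below_trial1": float(p_decrease),
    }, per_seed


def preset_prediction_learning(config: ExperimentConfig, out: Path):
    summary, per_seed = _prediction_summary(config, 0.0)
    df = pd.DataFrame([{"seed": s, "trial": i, "error": e}
                       for s, errs in zip(config.seeds, per_seed)
                       for i, e in enumerate(errs)])
    df.to_csv(out / "prediction_errors.csv", index=False)
    summary["verdict"] = bool(summary["last_over_first_ratio"] < 0.5)
    return summary, [str(out / "prediction_errors.csv")]


def preset_predictability_ablation(config: ExperimentConfig, out: Path):
    jit = PREDICTION["ablation_jitter_ms"]
    summary, per_seed = _prediction_summary(config, jit)
    df = pd.DataFrame([{"seed": s, "trial": i, "error": e}
                       for s, errs in zip(config.seeds, per_seed)
                       for i, e in enumerate(errs)])
    df.to_csv(out / "prediction_errors_jittered.csv", index=False)
    # "no significant decrease": alpha 0.01, the package's level for
    # directional claims
    summary["verdict"] = bool(summary["p_final_below_trial1"] > 0.01)
    return summary, [str(out / "prediction_errors_jittered.csv")]


def preset_critical_delay_2n(config: ExperimentConfig, out: Path):
    P = SWEEP_2N
    seeds = config.seeds[:P["n_seeds"]] if len(config.seeds) >= 5 \
        else config.seeds
    est = estimate_critical_delay(
        lambda d, s: delay_success_2n(d, s, duration_ms=config.duration_ms),
        list(P["delays"]), seeds)
    pd.DataFrame({"delay_ms": est["delays"],
                  "success_fraction": est["success_fractions"]}
                 ).to_csv(out / "delay_sweep_2n.csv", index=False)
    return est, [str(out / "delay_sweep_2n.csv")]


def preset_critical_delay_100n(config: ExperimentConfig, out: Path):
    P = SWEEP_100N
    seeds = config.seeds[:P["n_seeds"]] if len(config.seeds) >= 5 \
        else config.seeds
    est = estimate_critical_delay(
        lambda d, s: delay_success_100n(d, s, duration_ms=config.duration_ms),
        list(P["delays"]), seeds)
    pd.DataFrame({"delay_ms": est["delays"],
                  "success_fraction": est["success_fractions"]}
                 ).to_csv(out / "delay_sweep_100n.csv", index=False)
    return est, [str(out / "delay_sweep_100n.csv")]


PRESETS = {
    "minimal_reinforcement": preset_minimal_reinforcement,
    "minimal_weakening": preset_minimal_weakening,
    "controllability_ablation": preset_controllability_ablation,
    "wall_avoidance": preset_wall_avoidance,
    "connectivity_sweep": preset_connectivity_sweep,
    "prediction_learning": preset_prediction_learning,
    "predictability_ablation": preset_predictability_ablation,
    "critical_delay_2n": preset_critical_delay_2n,
    "critical_delay_100n": preset_critical_delay_100n,
}


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run a preset end to end, writing all artifacts under its out_dir."""
    if config.preset not in PRESETS:
        raise ValueError(f"unknown preset {config.preset!r}; choose from "
                         f"{sorted(PRESETS)}")
    out = Path(config.out_dir or f"results_{config.preset}")
    out.mkdir(parents=True, exist_ok=True)
    summary, files = PRESETS[config.preset](config, out)
    config.to_yaml(out / "config.yaml")
    files.append(str(out / "config.yaml"))
    result = ExperimentResult(preset=config.preset, summary=summary,
                              manifest=files, config=config)
    result.save_summary(out / "summary.json")
    return result


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(result_dir) -> list[str]:
    """Render figures for a completed experiment directory.

    Weight trajectories for the minimal presets, RT-per-encounter curves for
    wall runs, error-per-trial curves for prediction runs, success-vs-delay
    curves for sweeps.  Returns the figure paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(result_dir)
    summary_path = out / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(
            f"no summary.json in {out}; expected a completed experiment "
            "directory with summary.json and its manifest files")
    figures = []

    weight_files = sorted(out.glob("weights_*.csv"))
    if weight_files:
        fig, ax = plt.subplots(figsize=(7, 4))
        for i, f in enumerate(weight_files[:10]):
            df = pd.read_csv(f)
            for (src, dst), grp in df.groupby(["src", "dst"]):
                ax.plot(grp["t_ms"] / 1000, grp["weight"],
                        alpha=0.6, lw=1,
                        label=f"{src}->{dst}" if i == 0 else None)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("synaptic weight")
        ax.legend(loc="best", fontsize=8)
        fig.savefig(out / "weight_trajectories.png", dpi=120)
        plt.close(fig)
        figures.append(str(out / "weight_trajectories.png"))

    event_files = sorted(out.glob("events_wall_*.csv"))
    if event_files:
        fig, ax = plt.subplots(figsize=(7, 4))
        for f in event_files[:10]:
            rts = metrics.reaction_times(pd.read_csv(f))
            if len(rts):
                ax.semilogy(np.arange(len(rts)), rts.values, alpha=0.5)
        ax.set_xlabel("wall encounter")
        ax.set_ylabel("reaction time (ms)")
        fig.savefig(out / "reaction_times.png", dpi=120)
        plt.close(fig)
        figures.append(str(out / "reaction_times.png"))

    for name in ("prediction_errors.csv", "prediction_errors_jittered.csv"):
        f = out / name
        if f.exists():
            df = pd.read_csv(f)
            fig, ax = plt.subplots(figsize=(7, 4))
            mean_by_trial = df.groupby("trial")["error"].mean()
            ax.plot(mean_by_trial.index, mean_by_trial.values)
            ax.set_xlabel("trial")
            ax.set_ylabel("prediction error (current x ms)")
            pth = out / (f.stem + ".png")
            fig.savefig(pth, dpi=120)
            plt.close(fig)
            figures.append(str(pth))

    for name in ("delay_sweep_2n.csv", "delay_sweep_100n.csv"):
        f = out / name
        if f.exists():
            df = pd.read_csv(f)
            fig, ax = plt.subplots(figsize=(6, 4))
            ax.plot(df["delay_ms"], df["success_fraction"], "o-")
            ax.axhline(0.8, ls="--", color="grey")
            ax.set_xlabel("feedback delay (ms)")
            ax.set_ylabel("learning-success fraction")
            ax.set_ylim(-0.05, 1.05)
            pth = out / (f.stem + ".png")
            fig.savefig(pth, dpi=120)
            plt.close(fig)
            figures.append(str(pth))
    return figures
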