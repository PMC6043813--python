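"""Experiment suite: validation cases, development, lateral inhibition, sweeps.

Four experiment families cover the model's behaviour:

* **validation** — Cases 1-3 from the shared rough topographic map
  (Case 1: STDP + rewiring with correlated input; Case 2: STDP only;
  Case 3: STDP + rewiring, uncorrelated input), reporting the full metric
  table with shuffled controls and Wilcoxon signed-rank tests, aggregated
  over trials as mean +- SEM.
* **development** — map formation from minimal (one-to-one), random-p or
  empty initial connectivity, with the occupancy trajectory and the
  formation/removal counts in 3 s chunks.
* **inhibition** — the Case 3 variant with inhibitory lateral synapses,
  which bounds the target-layer rate and stabilises the map.
* **sweep** — single-run sensitivity grids over parameter axes (e.g. the
  STDP area ratio B and depression time constant tau_minus, or sigma_stim
  and sigma_form_lat), each cell seeded independently so cells can run in
  any order.  When sigma_stim is swept the bump peak rate is rescaled so
  the layer-mean input rate stays at f_mean.

A mapping is flagged unstable when the final feedforward fan-in drops
below S_max/4 or the target-layer population rate in the last tenth of
the run exceeds five times the nominal input rate f_mean.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .topology import GridLayer
from .neurons import NeuronParams
from .synapses import STDPParams
from .rewiring import RewiringParams, bin_events
from .stimulus import StimulusParams, rescale_f_peak
from .init_connectivity import InitSpec, generate_initial_table
from .engine import SimConfig, SimResult, run, summary_stats, weight_proportion, \
    rate_timeseries
from .metrics import MetricsReport, metrics_report, rf_summary

__all__ = [
    "ExperimentSpec", "ParamBundle", "shared_topographic_map",
    "run_validation", "run_development", "run_inhibition_variant",
    "run_sweep", "is_unstable", "aggregate_reports",
]


@dataclass(frozen=True)
class ExperimentSpec:
    name: str = "validation"
    case: int = 1
    init_mode: str = "topographic"
    lateral_polarity: str = "exc"
    duration_s: float = 300.0
    trials: int = 1
    seed_base: int = 0
    sweep_axes: dict = field(default_factory=dict)  # param name -> value list

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")


@dataclass(frozen=True)
class ParamBundle:
    """All model parameter sets plus the grid, carried together."""

    layer: GridLayer = field(default_factory=GridLayer)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    stdp: STDPParams = field(default_factory=STDPParams)
    rewiring: RewiringParams = field(default_factory=RewiringParams)

    def override(self, **kv) -> "ParamBundle":
        """Return a bundle with named parameters replaced, wherever they
        live; ``sigma_stim`` additionally rescales ``f_peak``."""
        out = self
        for key, value in kv.items():
            for attr in ("stimulus", "neuron", "stdp", "rewiring"):
                obj = getattr(out, attr)
                if key in {f.name for f in dc_fields(obj)}:
                    out = replace(out, **{attr: replace(obj, **{key: value})})
                    break
            else:
                raise KeyError(f"unknown parameter {key!r}")
        if "sigma_stim" in kv:
            stim = out.stimulus
            out = replace(out, stimulus=replace(
                stim, f_peak=rescale_f_peak(stim.sigma_stim, stim, out.layer)))
        return out


def shared_topographic_map(bundle: ParamBundle, seed: int,
                           lateral_inh: bool = False):
    """The single rough topographic map reused as the start of all trials."""
    rng = np.random.default_rng(seed)
    return generate_initial_table("topographic", bundle.layer, bundle.rewiring,
                                  rng, lateral_inh=lateral_inh)


def is_unstable(result: SimResult, bundle: ParamBundle,
                s_max: int = 32) -> bool:
    """Instability flag: collapsed feedforward fan-in or runaway activity."""
    stats = summary_stats(result)
    if stats["mean_ff_fan_in"] < s_max / 4:
        return True
    tail = result.tgt_step_counts[-max(1, result.tgt_step_counts.size // 10):]
    tail_rate = tail.sum() / (result.layer.n * tail.size
                              * result.config.dt / 1000.0)
    return tail_rate > 5.0 * bundle.stimulus.f_mean


def _single_trial(spec: ExperimentSpec, bundle: ParamBundle, seed: int,
                  initial_table, snapshot_interval_s: float = 0.0,
                  record_events: bool = False) -> SimResult:
    cfg = SimConfig(duration_s=spec.duration_s, seed=seed, case=spec.case,
                    lateral_polarity=spec.lateral_polarity,
                    snapshot_interval_s=snapshot_interval_s,
                    record_events=record_events)
    return run(cfg, bundle.stimulus, bundle.neuron, bundle.stdp,
               bundle.rewiring, initial_table, bundle.layer)


def aggregate_reports(reports: list[MetricsReport]) -> pd.DataFrame:
    """Mean and standard error of the mean of every metric across trials."""
    labels = list(reports[0].means)
    rows = []
    for label in labels:
        vals = np.array([r.means[label] for r in reports])
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append((label, vals.mean(), sem))
    return pd.DataFrame(rows, columns=["quantity", "mean", "sem"])


def run_validation(spec: ExperimentSpec, bundle: ParamBundle | None = None,
                   out_dir=None) -> dict:
    """Cases 1-3 from the shared topographic map; per-trial metric reports
    plus the cross-trial aggregate."""
    bundle = bundle or ParamBundle()
    lateral_inh = spec.lateral_polarity == "inh"
    initial = shared_topographic_map(bundle, spec.seed_base, lateral_inh)
    reports, stats = [], []
    for trial in range(spec.trials):
        seed = spec.seed_base + 1 + trial
        res = _single_trial(spec, bundle, seed, initial)
        rep = metrics_report(res.initial_table, res.final_table, bundle.layer,
                             bundle.rewiring, np.random.default_rng(seed))
        st = summary_stats(res)
        st["weight_proportion"] = weight_proportion(res, bundle.stdp.w_max)
        st["unstable"] = is_unstable(res, bundle, initial.s_max)
        reports.append(rep)
        stats.append(st)
    out = {"spec": spec, "reports": reports, "stats": stats,
           "aggregate": aggregate_reports(reports)}
    if out_dir is not None:
        _write_outputs(out, spec, bundle, out_dir)
    return out


def run_development(spec: ExperimentSpec, bundle: ParamBundle | None = None,
                    out_dir=None) -> dict:
    """Map formation from minimal/random/empty connectivity.

    As validation, plus the connectivity-fraction trajectory (occupied
    slots over the one-layer all-to-all count, from snapshots) and the
    formation/removal counts binned into 3 s chunks.
    """
    bundle = bundle or ParamBundle()
    lateral_inh = spec.lateral_polarity == "inh"
    reports, stats, trajectories, event_bins = [], [], [], []
    for trial in range(spec.trials):
        seed = spec.seed_base + 1 + trial
        rng = np.random.default_rng(seed)
        initial = generate_initial_table(spec.init_mode, bundle.layer,
                                         bundle.rewiring, rng,
                                         lateral_inh=lateral_inh)
        res = _single_trial(spec, bundle, seed, initial,
                            snapshot_interval_s=12.0, record_events=True)
        rep = metrics_report(res.initial_table, res.final_table, bundle.layer,
                             bundle.rewiring, np.random.default_rng(seed))
        st = summary_stats(res)
        st["weight_proportion"] = weight_proportion(res, bundle.stdp.w_max)
        traj = pd.DataFrame({
            "t_s": [t / 1000.0 for t, _ in res.snapshots],
            "connectivity_fraction": [tab.n_synapses() / bundle.layer.n ** 2
                                      for _, tab in res.snapshots]})
        reports.append(rep)
        stats.append(st)
        trajectories.append(traj)
        event_bins.append(bin_events(res.events))
    out = {"spec": spec, "reports": reports, "stats": stats,
           "occupancy": trajectories, "event_bins": event_bins,
           "aggregate": aggregate_reports(reports)}
    if out_dir is not None:
        _write_outputs(out, spec, bundle, out_dir)
    return out


def run_inhibition_variant(spec: ExperimentSpec | None = None,
                           bundle: ParamBundle | None = None,
                           out_dir=None) -> dict:
    """Case 3 with inhibitory lateral synapses; adds the rate trajectory."""
    spec = spec or ExperimentSpec(name="inhibition", case=3,
                                  lateral_polarity="inh")
    spec = replace(spec, case=3, lateral_polarity="inh")
    bundle = bundle or ParamBundle()
    initial = shared_topographic_map(bundle, spec.seed_base, lateral_inh=True)
    reports, stats, rate_series = [], [], []
    for trial in range(spec.trials):
        seed = spec.seed_base + 1 + trial
        res = _single_trial(spec, bundle, seed, initial)
        rep = metrics_report(res.initial_table, res.final_table, bundle.layer,
                             bundle.rewiring, np.random.default_rng(seed))
        st = summary_stats(res)
        st["weight_proportion"] = weight_proportion(res, bundle.stdp.w_max)
        st["unstable"] = is_unstable(res, bundle, initial.s_max)
        t, r = rate_timeseries(res)
        reports.append(rep)
        stats.append(st)
        rate_series.append(pd.DataFrame({"t_s": t, "rate_hz": r}))
    out = {"spec": spec, "reports": reports, "stats": stats,
           "rate_series": rate_series, "aggregate": aggregate_reports(reports)}
    if out_dir is not None:
        _write_outputs(out, spec, bundle, out_dir)
    return out


def run_sweep(spec: ExperimentSpec, bundle: ParamBundle | None = None,
              out_dir=None) -> pd.DataFrame:
    """Single-run sensitivity grid over the spec's sweep axes.

    Returns a long-format table with one row per cell: the axis values,
    final weighted sigma_aff and AD (feedforward), summary stats and the
    instability flag.  Cell seeds are ``seed_base XOR cell_index``, so
    results do not depend on execution order.
    """
    if not spec.sweep_axes:
        raise ValueError("sweep requires at least one axis")
    bundle = bundle or ParamBundle()
    axes = list(spec.sweep_axes.items())
    rows = []
    for idx, values in enumerate(itertools.product(*(v for _, v in axes))):
        cell = dict(zip((k for k, _ in axes), values))
        b = bundle.override(**cell)
        seed = (spec.seed_base ^ idx) & 0x7FFFFFFF
        initial = shared_topographic_map(b, seed,
                                         spec.lateral_polarity == "inh")
        res = _single_trial(spec, b, seed + 1, initial)
        fw = rf_summary(res.final_table, b.layer, "ff", "weight")
        row = dict(cell)
        row["cell"] = idx
        row["sigma_aff_weight"] = float(np.nanmean(fw["sigma_aff"].values))
        row["ad_weight"] = float(np.nanmean(fw["ad"].values))
        row.update(summary_stats(res))
        row["unstable"] = is_unstable(res, b, initial.s_max)
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_provenance(spec, bundle, out_dir)
        df.to_csv(out_dir / "sweep.csv", index=False)
    return df


# -- output helpers ------------------------------------------------------

def _write_provenance(spec: ExperimentSpec, bundle: ParamBundle, out_dir: Path):
    from .io import params_to_config, write_config
    cfg = params_to_config(SimConfig(duration_s=spec.duration_s,
                                     seed=spec.seed_base, case=spec.case,
                                     lateral_polarity=spec.lateral_polarity),
                           bundle.stimulus, bundle.neuron, bundle.stdp,
                           bundle.rewiring, bundle.layer)
    cfg["experiment"] = spec.name
    cfg["init_mode"] = spec.init_mode
    cfg["trials"] = spec.trials
    cfg.pop("sweep_axes", None)
    for k, v in spec.sweep_axes.items():
        cfg[f"sweep_{k}"] = ",".join(str(x) for x in v)
    write_config(cfg, out_dir / "config.txt")


def _write_outputs(out: dict, spec: ExperimentSpec, bundle: ParamBundle,
                   out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_provenance(spec, bundle, out_dir)
    out["aggregate"].to_csv(out_dir / "metrics_aggregate.csv", index=False)
    for i, rep in enumerate(out["reports"]):
        rep.to_frame().to_csv(out_dir / f"metrics_trial{i}.csv", index=False)
    pd.DataFrame(out["stats"]).to_csv(out_dir / "summary_stats.csv", index=False)
    for key in ("occupancy", "event_bins", "rate_series"):
        for i, df in enumerate(out.get(key, [])):
            df.to_csv(out_dir / f"{key}_trial{i}.csv", index=False)
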