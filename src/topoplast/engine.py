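"""Clock-driven simulation engine.

Each 1 ms step proceeds in a fixed order: (1) the stimulus bump is
relocated if due and source spikes are sampled; (2) the previous step's
spikes arrive through the one-step axonal delay, applying conductance
increments and the depression half of STDP, while the potentiation half
runs for postsynaptic spikes as they become visible; (3) the target-layer
membranes are integrated, collecting new spikes; (4) the structural
rewiring batch runs against the previous step's pooled spike set; (5)
recording.  All randomness flows through a single seeded generator, so a
run is bit-reproducible from its configuration and seed.

The STDP trace bookkeeping enforces the pair rule's timing semantics: a
spike pair that lands at lag zero (as a self-pairing does at an autapse
when the back-propagation delay is on) contributes no weight change,
because trace increments are applied only after the step's depression and
potentiation updates have consumed the traces.

The hot loop operates directly on the slot-table arrays; the rewiring
batch draws random numbers in exactly the same order as
:func:`topoplast.rewiring.attempt_rewiring`, of which it is the batched
form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .topology import GridLayer, pairwise_sq_distances
from .neurons import NeuronParams, NeuronState, step as neuron_step
from .synapses import STDPParams, SynapticSlotTable, SOURCE, TARGET
from .rewiring import RewiringParams, RewiringEvent, attempts_per_step
from .stimulus import StimulusParams, initial_field, maybe_relocate, sample_spikes

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimResult", "run", "summary_stats", "rate_timeseries"]


@dataclass(frozen=True)
class SimConfig:
    dt: float = 1.0                   # ms
    duration_s: float = 300.0         # simulated seconds
    seed: int = 0
    case: int = 1                     # 1: STDP+rewiring, correlated input
                                      # 2: STDP only, correlated input
                                      # 3: STDP+rewiring, uncorrelated input
    lateral_polarity: str = "exc"     # "exc" | "inh"
    inh_plastic: bool = True          # STDP acts on inhibitory-synapse magnitudes
    record_spikes: bool = False       # keep the full spike raster
    record_events: bool = True        # keep the rewiring event log
    snapshot_interval_s: float = 12.0 # 0 -> only initial and final snapshots
    log_every_s: float = 0.0          # progress logging period (0 = quiet)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be > 0")
        if self.case not in (1, 2, 3):
            raise ValueError("case must be 1, 2 or 3")
        if self.lateral_polarity not in ("exc", "inh"):
            raise ValueError("lateral_polarity must be 'exc' or 'inh'")

    @property
    def rewiring_enabled(self) -> bool:
        return self.case != 2

    @property
    def correlated_input(self) -> bool:
        return self.case != 3


@dataclass
class SimResult:
    config: SimConfig
    layer: GridLayer
    initial_table: SynapticSlotTable
    final_table: SynapticSlotTable
    src_spike_counts: np.ndarray          # total spikes per source neuron
    tgt_spike_counts: np.ndarray          # total spikes per target neuron
    tgt_step_counts: np.ndarray           # target population spikes per step
    snapshots: list = field(default_factory=list)   # (t_ms, SynapticSlotTable)
    events: list = field(default_factory=list)      # non-abort RewiringEvents
    n_aborted: int = 0
    raster: list = field(default_factory=list)      # (t_ms, layer, id) if recorded


def run(config: SimConfig,
        stimulus_params: StimulusParams | None = None,
        neuron_params: NeuronParams | None = None,
        stdp_params: STDPParams | None = None,
        rewiring_params: RewiringParams | None = None,
        initial_table: SynapticSlotTable | None = None,
        layer: GridLayer | None = None) -> SimResult:
    """Simulate the two-layer network; defaults reproduce the standard setup."""
    layer = layer or GridLayer(16, 16)
    n = layer.n
    stim = stimulus_params or StimulusParams()
    stim = replace(stim, correlated=config.correlated_input)
    npar = neuron_params or NeuronParams()
    spar = stdp_params or STDPParams()
    rpar = rewiring_params or RewiringParams(theta_g=spar.w_max / 2.0)
    if initial_table is None:
        initial_table = SynapticSlotTable(n)
    if initial_table.n_target != n:
        raise ValueError("initial table does not match the layer size")

    rng = np.random.default_rng(config.seed)
    dt = config.dt
    n_steps = int(round(config.duration_s * 1000.0 / dt))
    lateral_inh = config.lateral_polarity == "inh"

    table = initial_table.copy()
    pre, lay, w, is_inh = table.pre, table.layer, table.w, table.is_inh
    gid = np.where(pre >= 0, pre + n * lay.astype(np.int64), -1)

    # formation-probability lookups over all (post, pre) pairs
    d2 = pairwise_sq_distances(layer)
    P_ff = rpar.p_form_ff * np.exp(-d2 / (2 * rpar.sigma_form_ff ** 2))
    P_lat = rpar.p_form_lat * np.exp(-d2 / (2 * rpar.sigma_form_lat ** 2))

    n_att, every_n = attempts_per_step(rpar.f_rew, dt)
    state = NeuronState.resting(n, npar)
    tr_pre = np.zeros(2 * n)   # presynaptic traces, source then target block
    tr_post = np.zeros(n)
    decay_plus = np.exp(-dt / spar.tau_plus)
    decay_minus = np.exp(-dt / spar.tau_minus)
    dep_amt = spar.A_minus * spar.scale
    pot_amt = spar.A_plus * spar.scale

    field_ = initial_field(stim, layer, rng)
    p_spike = 1.0 - np.exp(-field_.rates * dt / 1000.0)

    src_prev = np.zeros(n, bool)
    tgt_prev = np.zeros(n, bool)
    spk2n = np.zeros(2 * n, bool)

    src_counts = np.zeros(n, np.int64)
    tgt_counts = np.zeros(n, np.int64)
    tgt_step_counts = np.zeros(n_steps, np.int32)
    result = SimResult(config, layer, initial_table.copy(), table,
                       src_counts, tgt_counts, tgt_step_counts)
    result.snapshots.append((0.0, table.copy()))
    snap_steps = (int(round(config.snapshot_interval_s * 1000.0 / dt))
                  if config.snapshot_interval_s else 0)
    log_steps = (int(round(config.log_every_s * 1000.0 / dt))
                 if config.log_every_s else 0)
    n_formed = n_removed = 0

    for istep in range(n_steps):
        t = istep * dt

        # (1) stimulus
        new_field = maybe_relocate(field_, t, stim, layer, rng)
        if new_field is not field_:
            field_ = new_field
            p_spike = 1.0 - np.exp(-field_.rates * dt / 1000.0)
        src_now = rng.random(n) < p_spike

        # (2) delivery + STDP for spikes emitted in the previous step
        spk2n[:n] = src_prev
        spk2n[n:] = tgt_prev
        occ = pre >= 0
        arr = occ & spk2n[gid]
        tr_pre *= decay_plus
        tr_post *= decay_minus

        any_arr = arr.any()
        if any_arr:
            dep_mask = arr if config.inh_plastic else arr & ~is_inh
            np.copyto(w, np.maximum(w - dep_amt * tr_post[:, None], spar.w_min),
                      where=dep_mask)
        if spar.backprop_delay and tgt_prev.any():
            pot_rows = occ & tgt_prev[:, None]
            if not config.inh_plastic:
                pot_rows &= ~is_inh
            np.copyto(w, np.minimum(w + pot_amt * tr_pre[gid], spar.w_max),
                      where=pot_rows)
            tr_post[tgt_prev] += 1.0
        tr_pre[:n][src_prev] += 1.0
        tr_pre[n:][tgt_prev] += 1.0

        if any_arr:
            wa = np.where(arr, w, 0.0)
            dg_inh = np.where(is_inh, wa, 0.0).sum(axis=1)
            dg_exc = wa.sum(axis=1) - dg_inh
        else:
            dg_exc = dg_inh = 0.0

        # (3) membrane integration
        _, tgt_now = neuron_step(state, npar, dg_exc, dg_inh, dt)
        if not spar.backprop_delay and tgt_now.any():
            # postsynaptic spikes are visible immediately; exclude this
            # step's own arrivals (lag-zero pairs contribute nothing)
            pot_rows = occ & tgt_now[:, None]
            if not config.inh_plastic:
                pot_rows &= ~is_inh
            np.copyto(w, np.minimum(w + pot_amt * (tr_pre[gid] - arr), spar.w_max),
                      where=pot_rows)
            tr_post[tgt_now] += 1.0

        # (4) rewiring batch against the previous step's pooled spike set
        if config.rewiring_enabled and istep % every_n == 0:
            spk_ids = np.flatnonzero(spk2n)
            nspk = spk_ids.size
            for _ in range(n_att):
                post = int(rng.integers(n))
                slot = int(rng.integers(table.s_max))
                if pre[post, slot] < 0:
                    if nspk == 0:
                        result.n_aborted += 1
                        continue
                    g = int(spk_ids[int(rng.integers(nspk))])
                    pre_id, pre_layer = g % n, g // n
                    p = (P_ff if pre_layer == SOURCE else P_lat)[post, pre_id]
                    if rng.random() < p:
                        pre[post, slot] = pre_id
                        lay[post, slot] = pre_layer
                        w[post, slot] = rpar.g_max
                        is_inh[post, slot] = lateral_inh and pre_layer == TARGET
                        gid[post, slot] = g
                        n_formed += 1
                        if config.record_events:
                            result.events.append(RewiringEvent(
                                t, "formation", post, slot, pre_layer, pre_id))
                    else:
                        result.n_aborted += 1
                else:
                    g_syn = w[post, slot]
                    p_elim = (rpar.p_elim_dep if g_syn < rpar.theta_g
                              else rpar.p_elim_pot)
                    if rng.random() < p_elim:
                        if config.record_events:
                            result.events.append(RewiringEvent(
                                t, "elimination", post, slot,
                                int(lay[post, slot]), int(pre[post, slot])))
                        pre[post, slot] = -1
                        w[post, slot] = 0.0
                        is_inh[post, slot] = False
                        gid[post, slot] = -1
                        n_removed += 1
                    else:
                        result.n_aborted += 1

        # (5) recording
        src_counts += src_now
        tgt_counts += tgt_now
        tgt_step_counts[istep] = tgt_now.sum()
        if config.record_spikes:
            for i in np.flatnonzero(src_now):
                result.raster.append((t + dt, "source", int(i)))
            for i in np.flatnonzero(tgt_now):
                result.raster.append((t + dt, "target", int(i)))
        if snap_steps and istep and istep % snap_steps == 0:
            result.snapshots.append((t + dt, table.copy()))
        if log_steps and istep and istep % log_steps == 0:
            logger.info("t=%.1fs formations=%d eliminations=%d occupancy=%d",
                        (t + dt) / 1000.0, n_formed, n_removed, int(occ.sum()))

        src_prev, tgt_prev = src_now, tgt_now

    result.snapshots.append((n_steps * dt, table.copy()))
    return result


def summary_stats(result: SimResult) -> dict:
    """Headline statistics of a finished run.

    mean target rate (Hz), final mean feedforward/lateral fan-in per target
    neuron, total occupancy fraction of the one-layer all-to-all count, and
    mean weight as a proportion of the maximum over existing synapses.
    """
    n = result.layer.n
    table = result.final_table
    occ = table.occupied
    w_occ = table.w[occ]
    return {
        "mean_target_rate_hz": float(result.tgt_spike_counts.sum()
                                     / (n * result.config.duration_s)),
        "mean_ff_fan_in": float(table.fan_in("ff").mean()),
        "mean_lat_fan_in": float(table.fan_in("lat").mean()),
        "connectivity_fraction": float(occ.sum() / (n * n)),
        "mean_weight": float(w_occ.mean()) if w_occ.size else 0.0,
    }


def weight_proportion(result: SimResult, g_max: float = 0.2) -> float:
    """Mean weight over existing synapses as a proportion of g_max."""
    w_occ = result.final_table.w[result.final_table.occupied]
    return float(w_occ.mean() / g_max) if w_occ.size else 0.0


def rate_timeseries(result: SimResult, bin_s: float = 1.2):
    """Target-layer population rate (Hz per neuron) in fixed time chunks.

    Returns (bin_centres_s, rates_hz); the trailing partial chunk is
    dropped.
    """
    if bin_s > result.config.duration_s:
        raise ValueError("bin exceeds simulation duration")
    steps_per_bin = int(round(bin_s * 1000.0 / result.config.dt))
    counts = result.tgt_step_counts
    nbins = counts.size // steps_per_bin
    c = counts[:nbins * steps_per_bin].reshape(nbins, steps_per_bin).sum(axis=1)
    rates = c / (result.layer.n * bin_s)
    centres = (np.arange(nbins) + 0.5) * bin_s
    return centres, rates
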