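"""Structural plasticity: distance-dependent formation, weight-dependent removal.

Rewiring proceeds as timer-driven attempts at a fixed rate ``f_rew``: with
fast rewiring several attempts run every time step (10 per step at 10 kHz
and dt = 1 ms), with slow rewiring one attempt runs every few steps.  Each
attempt picks one synaptic slot uniformly at random (a target neuron, then
one of its S_max slots) and takes exactly one of three actions:

* empty slot -> *formation*: a presynaptic partner is drawn uniformly from
  the neurons that spiked in the previous time step (pooled over both
  layers; abort if none did), and a full-strength synapse is created with
  probability ``p_form * exp(-delta^2 / (2 sigma_form^2))`` where delta is
  the toroidal distance between partner and target.  The peak probability
  and width are those of the partner's projection (feedforward or
  lateral).
* occupied slot -> *elimination*: the synapse is removed with probability
  ``p_elim_dep`` if its weight is below the threshold ``theta_g``
  (= g_max/2), else with the much smaller ``p_elim_pot``; eliminated
  synapses are not replaced within the same attempt.
* otherwise the attempt aborts.

Drawing the partner uniformly from the previous step's spikers makes the
formation rule activity-gated without biasing toward any neuron index, and
couples it to STDP: depressed synapses are pruned ~180x more readily than
potentiated ones, so input selectivity learnt by STDP is embedded into the
connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import GridLayer, torus_distance, id_to_coord
from .synapses import SynapticSlotTable, SOURCE, TARGET

__all__ = [
    "RewiringParams", "RewiringEvent", "attempts_per_step",
    "formation_probability", "select_partner", "attempt_rewiring",
    "bin_events",
]


@dataclass(frozen=True)
class RewiringParams:
    f_rew: float = 10_000.0       # Hz, attempt rate
    p_form_ff: float = 0.16       # peak formation probability, feedforward
    p_form_lat: float = 1.0       # peak formation probability, lateral
    sigma_form_ff: float = 2.5    # grid units
    sigma_form_lat: float = 1.0   # grid units
    p_elim_dep: float = 0.0245    # elimination probability, depressed synapse
    p_elim_pot: float = 1.36e-4   # elimination probability, potentiated synapse
    theta_g: float = 0.1          # conductance threshold (= g_max / 2)

    def __post_init__(self) -> None:
        for name in ("p_form_ff", "p_form_lat", "p_elim_dep", "p_elim_pot"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.f_rew <= 0:
            raise ValueError("f_rew must be > 0")

    @property
    def g_max(self) -> float:
        """Weight of newly formed (full-strength) synapses."""
        return 2.0 * self.theta_g


@dataclass(frozen=True)
class RewiringEvent:
    t: float
    kind: str                     # "formation" | "elimination" | "abort"
    post_id: int
    slot: int
    pre_layer: int | None = None  # 0 = source, 1 = target
    pre_id: int | None = None


def attempts_per_step(f_rew: float, dt: float):
    """Attempt schedule ``(n_attempts, every_n_steps)``.

    Fast rewiring: ``round(f_rew * dt / 1000)`` attempts each step.
    Slow rewiring (rate below one per step): a single attempt every
    ``round(1000 / (f_rew * dt))`` steps.
    """
    if f_rew <= 0:
        raise ValueError("f_rew must be > 0")
    per_step = round(f_rew * dt / 1000.0)
    if per_step >= 1:
        return per_step, 1
    return 1, round(1000.0 / (f_rew * dt))


def formation_probability(delta, sigma_form: float, p_form: float):
    """Gaussian kernel of the formation rule, peak p_form at distance 0."""
    if sigma_form <= 0:
        raise ValueError("sigma_form must be > 0")
    return p_form * np.exp(-np.asarray(delta, float) ** 2 / (2 * sigma_form ** 2))


def select_partner(last_step_spikes, rng: np.random.Generator):
    """Uniform draw from the previous step's spikers, or None (abort).

    ``last_step_spikes`` is a sequence of ``(neuron_id, layer)`` pairs
    pooled over the source and target layers.  The draw is uniform over the
    set regardless of neuron index or listing order.
    """
    spikes = list(last_step_spikes)
    if not spikes:
        return None
    return spikes[int(rng.integers(len(spikes)))]


def attempt_rewiring(table: SynapticSlotTable, params: RewiringParams,
                     last_step_spikes, rng: np.random.Generator, t: float,
                     layer: GridLayer, lateral_inh: bool = False) -> RewiringEvent:
    """One rewiring attempt on a uniformly chosen (target neuron, slot)."""
    post = int(rng.integers(table.n_target))
    slot = int(rng.integers(table.s_max))

    if table.pre[post, slot] < 0:  # potential synapse: formation rule
        partner = select_partner(last_step_spikes, rng)
        if partner is None:
            return RewiringEvent(t, "abort", post, slot)
        pre_id, pre_layer = int(partner[0]), int(partner[1])
        delta = torus_distance(id_to_coord(pre_id, layer),
                               id_to_coord(post, layer), layer)
        if pre_layer == SOURCE:
            p = formation_probability(delta, params.sigma_form_ff, params.p_form_ff)
        else:
            p = formation_probability(delta, params.sigma_form_lat, params.p_form_lat)
        if rng.random() < p:
            is_inh = lateral_inh and pre_layer == TARGET
            table.add(post, slot, pre_id, pre_layer, params.g_max, is_inh)
            return RewiringEvent(t, "formation", post, slot, pre_layer, pre_id)
        return RewiringEvent(t, "abort", post, slot)

    # existing synapse: elimination rule
    g_syn = table.w[post, slot]
    p_elim = params.p_elim_dep if g_syn < params.theta_g else params.p_elim_pot
    if rng.random() < p_elim:
        ev = RewiringEvent(t, "elimination", post, slot,
                           int(table.layer[post, slot]), int(table.pre[post, slot]))
        table.remove(post, slot)
        return ev
    return RewiringEvent(t, "abort", post, slot)


def bin_events(events, bin_s: float = 3.0):
    """Formation/elimination counts aggregated into fixed time chunks.

    Returns a pandas DataFrame with columns (t_s, formations, eliminations),
    one row per chunk, covering [0, max event time].
    """
    import pandas as pd

    ev = [e for e in events if e.kind != "abort"]
    if not ev:
        return pd.DataFrame(columns=["t_s", "formations", "eliminations"])
    t_s = np.array([e.t for e in ev]) / 1000.0
    kind = np.array([e.kind for e in ev])
    nbins = int(np.floor(t_s.max() / bin_s)) + 1
    idx = np.minimum((t_s / bin_s).astype(int), nbins - 1)
    form = np.bincount(idx[kind == "formation"], minlength=nbins)
    elim = np.bincount(idx[kind == "elimination"], minlength=nbins)
    return pd.DataFrame({"t_s": (np.arange(nbins) + 0.5) * bin_s,
                         "formations": form, "eliminations": elim})
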