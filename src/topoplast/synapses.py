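"""Synaptic slot store and additive pair-based STDP.

Connectivity lives in a per-target-neuron table of ``S_max`` slots; each
slot is empty (a *potential synapse*) or holds one synapse identified by
its presynaptic neuron and layer, weight, delay and sign.  Multapses
(repeated pre/post pairs) and autapses (self-connections in the lateral
projection) are both legal; feedforward and lateral afferents compete for
the same slots.

The plasticity rule is the classical additive pair rule: a pre-before-post
pairing with lag ``dt = t_post - t_pre > 0`` potentiates by
``A_plus * exp(-dt/tau_plus)``, a post-before-pre pairing depresses by
``A_minus * exp(dt/tau_minus)``, exactly coincident pairs change nothing,
and weights are clipped to ``[w_min, w_max]``.  Pairing is all-to-all via
exponentially decaying pre- and post-synaptic traces.  The depression
amplitude is tied to the potentiation amplitude through the area ratio
``B = A_minus tau_minus / (A_plus tau_plus)``; ``B > 1`` biases the rule
toward depression.  By default amplitudes are interpreted as fractions of
``w_max`` (set ``absolute_update=True`` for bare conductance increments).

Autapse timing: spikes reach a neuron's own synapse instantly as a
presynaptic event, but with ``backprop_delay`` (the default) the synapse
learns of the postsynaptic spike one step late, so the self-pairing lands
at lag zero and drives no weight change.  Without the back-propagation
delay the self-pairing is post-before-pre at the axonal delay and every
spike maximally depresses the autapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "STDPParams", "SpikeTraces", "SynapticSlotTable",
    "derive_A_minus", "stdp_weight_change", "on_pre_spike", "on_post_spike",
    "autapse_timing",
]

SOURCE, TARGET = 0, 1  # layer codes in the slot table


def derive_A_minus(A_plus: float, B: float, tau_plus: float, tau_minus: float) -> float:
    """Depression amplitude from the depression/potentiation area ratio B."""
    if min(A_plus, B, tau_plus, tau_minus) <= 0:
        raise ValueError("all STDP parameters must be > 0")
    return B * A_plus * tau_plus / tau_minus


@dataclass(frozen=True)
class STDPParams:
    A_plus: float = 0.1
    B: float = 1.2
    tau_plus: float = 20.0
    tau_minus: float = 64.0
    w_min: float = 0.0
    w_max: float = 0.2          # = g_max
    backprop_delay: bool = True
    absolute_update: bool = False

    @property
    def A_minus(self) -> float:
        return derive_A_minus(self.A_plus, self.B, self.tau_plus, self.tau_minus)

    @property
    def scale(self) -> float:
        """Multiplier turning A_± into a conductance change."""
        return 1.0 if self.absolute_update else self.w_max


def stdp_weight_change(delta_t: float, params: STDPParams) -> float:
    """Signed conductance change for a single pre/post pairing.

    ``delta_t = t_post - t_pre`` as seen at the synapse. The caller clips
    the updated weight to ``[w_min, w_max]``.
    """
    if delta_t > 0:
        return params.A_plus * params.scale * float(np.exp(-delta_t / params.tau_plus))
    if delta_t < 0:
        return -params.A_minus * params.scale * float(np.exp(delta_t / params.tau_minus))
    return 0.0


@dataclass
class SpikeTraces:
    """Per-neuron exponential spike-history traces.

    ``pre`` decays with tau_plus and accumulates presynaptic arrivals;
    ``post`` decays with tau_minus and accumulates (visible) postsynaptic
    spikes. One scalar pair per neuron suffices for all-to-all pairing
    because every synapse of a neuron shares the same delay.
    """

    pre: np.ndarray
    post: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "SpikeTraces":
        return cls(np.zeros(n), np.zeros(n))

    def decay(self, dt: float, params: STDPParams) -> None:
        self.pre *= np.exp(-dt / params.tau_plus)
        self.post *= np.exp(-dt / params.tau_minus)


def on_pre_spike(weight: float, post_trace: float, params: STDPParams) -> float:
    """Depression applied when a presynaptic spike arrives at the synapse."""
    w = weight - params.A_minus * params.scale * post_trace
    return float(np.clip(w, params.w_min, params.w_max))


def on_post_spike(weight: float, pre_trace: float, params: STDPParams) -> float:
    """Potentiation applied when the postsynaptic neuron spikes."""
    w = weight + params.A_plus * params.scale * pre_trace
    return float(np.clip(w, params.w_min, params.w_max))


def autapse_timing(spike_time: float, backprop_delay: bool, delay: float = 1.0):
    """(t_pre_seen, t_post_seen) at an autapse for one somatic spike.

    The spike is instantly a presynaptic event but its effect applies after
    the axonal delay; the synapse sees the postsynaptic spike after the
    back-propagation delay (equal to the axonal delay) if enabled, else
    immediately.  With the delay both events coincide (lag 0, no change);
    without it the pairing is post-before-pre at lag ``-delay``.
    """
    t_pre_seen = spike_time + delay
    t_post_seen = spike_time + (delay if backprop_delay else 0.0)
    return t_pre_seen, t_post_seen


class SynapticSlotTable:
    """Fixed-capacity afferent store: ``S_max`` slots per target neuron.

    Array-of-slots representation: ``pre[j, s]`` is the presynaptic neuron
    id (or -1 for an empty slot), ``layer[j, s]`` the presynaptic layer
    (0 = source, 1 = target), ``w[j, s]`` the conductance weight and
    ``is_inh[j, s]`` the synapse sign.  All synapses share one axonal
    delay.
    """

    def __init__(self, n_target: int, s_max: int = 32, delay: float = 1.0):
        if s_max < 1:
            raise ValueError("s_max must be >= 1")
        self.n_target = n_target
        self.s_max = s_max
        self.delay = delay
        self.pre = np.full((n_target, s_max), -1, dtype=np.int64)
        self.layer = np.zeros((n_target, s_max), dtype=np.int8)
        self.w = np.zeros((n_target, s_max), dtype=float)
        self.is_inh = np.zeros((n_target, s_max), dtype=bool)

    # -- queries ---------------------------------------------------------
    @property
    def occupied(self) -> np.ndarray:
        return self.pre >= 0

    def fan_in(self, projection: str | None = None) -> np.ndarray:
        """Occupied slots per target neuron, optionally per projection."""
        occ = self.occupied
        if projection == "ff":
            occ = occ & (self.layer == SOURCE)
        elif projection == "lat":
            occ = occ & (self.layer == TARGET)
        elif projection is not None:
            raise ValueError("projection must be 'ff', 'lat' or None")
        return occ.sum(axis=1)

    def n_synapses(self) -> int:
        return int(self.occupied.sum())

    def afferents(self, post_id: int, projection: str | None = None):
        """(pre_ids, weights) of a neuron's existing afferents."""
        occ = self.occupied[post_id]
        if projection == "ff":
            occ = occ & (self.layer[post_id] == SOURCE)
        elif projection == "lat":
            occ = occ & (self.layer[post_id] == TARGET)
        return self.pre[post_id, occ], self.w[post_id, occ]

    # -- mutation --------------------------------------------------------
    def add(self, post_id: int, slot: int, pre_id: int, pre_layer: int,
            weight: float, is_inh: bool = False) -> None:
        if self.pre[post_id, slot] >= 0:
            raise ValueError("slot already occupied")
        self.pre[post_id, slot] = pre_id
        self.layer[post_id, slot] = pre_layer
        self.w[post_id, slot] = weight
        self.is_inh[post_id, slot] = is_inh

    def remove(self, post_id: int, slot: int) -> None:
        self.pre[post_id, slot] = -1
        self.w[post_id, slot] = 0.0
        self.is_inh[post_id, slot] = False

    def free_slot(self, post_id: int) -> int | None:
        empties = np.flatnonzero(~self.occupied[post_id])
        return int(empties[0]) if empties.size else None

    def copy(self) -> "SynapticSlotTable":
        t = SynapticSlotTable(self.n_target, self.s_max, self.delay)
        t.pre = self.pre.copy()
        t.layer = self.layer.copy()
        t.w = self.w.copy()
        t.is_inh = self.is_inh.copy()
        return t

    # -- snapshot rows ---------------------------------------------------
    def to_rows(self) -> np.ndarray:
        """Structured rows (pre_layer, pre_id, post_id, g_syn, delay, syn_type)."""
        post, slot = np.nonzero(self.occupied)
        rows = np.zeros(post.size, dtype=[("pre_layer", "i1"), ("pre_id", "i8"),
                                          ("post_id", "i8"), ("g_syn", "f8"),
                                          ("delay_ms", "f8"), ("inh", "?")])
        rows["pre_layer"] = self.layer[post, slot]
        rows["pre_id"] = self.pre[post, slot]
        rows["post_id"] = post
        rows["g_syn"] = self.w[post, slot]
        rows["delay_ms"] = self.delay
        rows["inh"] = self.is_inh[post, slot]
        return rows

    @classmethod
    def from_rows(cls, rows, n_target: int, s_max: int = 32,
                  delay: float = 1.0) -> "SynapticSlotTable":
        t = cls(n_target, s_max, delay)
        for r in rows:
            slot = t.free_slot(int(r["post_id"]))
            if slot is None:
                raise ValueError(f"fan-in of neuron {r['post_id']} exceeds S_max")
            t.add(int(r["post_id"]), slot, int(r["pre_id"]), int(r["pre_layer"]),
                  float(r["g_syn"]), bool(r["inh"]))
            t.delay = float(r["delay_ms"])
        return t
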