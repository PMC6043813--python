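"""Conductance-based leaky integrate-and-fire dynamics.

Sub-threshold membrane dynamics follow

    tau_m dV/dt = (V_rest - V) + g_exc (E_exc - V) + g_inh (E_inh - V)

where the synaptic conductances are normalised by the leak conductance and
therefore dimensionless; each decays exponentially with its own time
constant and is incremented by the weight of every arriving spike.  The
integrator is exponential Euler: over one step the membrane decays toward
the instantaneous steady state

    V_inf = (V_rest + g_exc E_exc + g_inh E_inh) / (1 + g_exc + g_inh)

with effective time constant tau_m / (1 + g_exc + g_inh), which is exact
for conductances held constant over the step.  On crossing threshold the
neuron spikes, is reset, and stays clamped at V_reset for the refractory
period, bounding the firing rate at 1000/(tau_refract + dt) Hz.

During the refractory period the neuron neither integrates nor receives
synaptic input: by default conductance increments arriving while
refractory are discarded (existing conductance still decays); set
``refractory_discard_input=False`` to let input accumulate instead, as
most general-purpose simulators do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NeuronParams", "NeuronState", "step"]


@dataclass(frozen=True)
class NeuronParams:
    """Membrane and synapse-kinetics constants (units: mV, ms, nF)."""

    V_rest: float = -70.0
    V_reset: float = -70.0
    V_thr: float = -54.0
    E_exc: float = 0.0
    E_inh: float = -70.0   # = V_rest: purely shunting inhibition
    tau_m: float = 20.0
    tau_exc: float = 5.0
    tau_inh: float = 5.0
    tau_refract: float = 5.0
    cm: float = 20.0       # carried for completeness; the normalised-conductance
                           # form of the membrane equation does not use it
    refractory_discard_input: bool = True

    def __post_init__(self) -> None:
        if not (self.V_reset <= self.V_rest < self.V_thr < self.E_exc):
            raise ValueError("require V_reset <= V_rest < V_thr < E_exc")
        for name in ("tau_m", "tau_exc", "tau_inh", "tau_refract"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class NeuronState:
    """Per-neuron state vectors; scalars broadcast to a population of one."""

    V: np.ndarray
    g_exc: np.ndarray
    g_inh: np.ndarray
    refract_remaining: np.ndarray

    @classmethod
    def resting(cls, n: int, params: NeuronParams) -> "NeuronState":
        return cls(
            V=np.full(n, params.V_rest, float),
            g_exc=np.zeros(n),
            g_inh=np.zeros(n),
            refract_remaining=np.zeros(n),
        )


def step(state: NeuronState, params: NeuronParams,
         delta_g_exc, delta_g_inh, dt: float = 1.0):
    """Advance the population one time step in place.

    Order of operations: (1) add conductance increments, (2) decay the
    conductances, (3) integrate the membrane (refractory neurons are held at
    V_reset instead), (4) detect threshold crossings.

    Returns
    -------
    (state, spiked) : the mutated state and a boolean spike vector.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    refractory = state.refract_remaining > 0

    dge = np.broadcast_to(np.asarray(delta_g_exc, float), state.V.shape)
    dgi = np.broadcast_to(np.asarray(delta_g_inh, float), state.V.shape)
    if params.refractory_discard_input:
        dge = np.where(refractory, 0.0, dge)
        dgi = np.where(refractory, 0.0, dgi)
    state.g_exc = (state.g_exc + dge) * np.exp(-dt / params.tau_exc)
    state.g_inh = (state.g_inh + dgi) * np.exp(-dt / params.tau_inh)

    gtot = 1.0 + state.g_exc + state.g_inh
    V_inf = (params.V_rest + state.g_exc * params.E_exc
             + state.g_inh * params.E_inh) / gtot
    V_new = V_inf + (state.V - V_inf) * np.exp(-dt * gtot / params.tau_m)

    state.V = np.where(refractory, params.V_reset, V_new)
    state.refract_remaining = np.maximum(state.refract_remaining - dt * refractory, 0.0)

    spiked = (~refractory) & (state.V >= params.V_thr)
    state.V = np.where(spiked, params.V_reset, state.V)
    state.refract_remaining = np.where(spiked, params.tau_refract,
                                       state.refract_remaining)

    if not np.all(np.isfinite(state.V)):
        raise FloatingPointError("non-finite membrane potential: integration failed")
    return state, spiked
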