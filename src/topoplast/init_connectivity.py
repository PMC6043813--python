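"""Initial connectivity generators.

Three starting conditions are used by the experiments:

* ``topographic`` — a fully formed rough topographic map: for each target
  neuron, presynaptic partners are drawn uniformly from the relevant layer
  and accepted with the distance-dependent formation probability until 16
  feedforward and 16 lateral afferents exist.  Rejection sampling
  reproduces the formation rule's acceptance distribution exactly;
  multapses arise naturally, and so do lateral autapses because the peak
  lateral formation probability is 1 at distance 0.
* ``random_p`` — fixed-probability connectivity: each target neuron gets
  ``round(p n / 2)`` feedforward and as many lateral afferents drawn
  uniformly over the grid (10% total at the default p = 0.10).
* ``one_to_one`` — minimal connectivity: exactly one feedforward synapse
  from the co-located source neuron (and ``empty`` for no synapses at
  all).

All generated synapses start at full strength g_max.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import GridLayer, pairwise_sq_distances
from .rewiring import RewiringParams
from .synapses import SynapticSlotTable, SOURCE, TARGET

__all__ = [
    "InitSpec", "generate_topographic", "generate_random_p",
    "generate_one_to_one", "generate_initial_table",
]


@dataclass(frozen=True)
class InitSpec:
    mode: str = "topographic"     # topographic | random_p | one_to_one | empty
    n_ff_afferents: int = 16
    n_lat_afferents: int = 16
    p_random: float = 0.10        # split evenly feedforward/lateral
    s_max: int = 32
    initial_weight: float | None = None   # default: g_max from the wiring params

    def __post_init__(self) -> None:
        if self.mode not in ("topographic", "random_p", "one_to_one", "empty"):
            raise ValueError(f"unknown init mode {self.mode!r}")
        if self.n_ff_afferents + self.n_lat_afferents > self.s_max:
            raise ValueError("requested afferents exceed synaptic capacity S_max")
        if not 0 <= self.p_random <= 1:
            raise ValueError("p_random must be in [0, 1]")


def generate_topographic(layer: GridLayer, spec: InitSpec,
                         rewiring_params: RewiringParams,
                         rng: np.random.Generator,
                         lateral_inh: bool = False) -> SynapticSlotTable:
    """Rough topographic map via the formation rule's rejection sampler."""
    w0 = spec.initial_weight if spec.initial_weight is not None else rewiring_params.g_max
    d2 = pairwise_sq_distances(layer)
    table = SynapticSlotTable(layer.n, spec.s_max)
    plans = [(SOURCE, spec.n_ff_afferents, rewiring_params.p_form_ff,
              rewiring_params.sigma_form_ff, False),
             (TARGET, spec.n_lat_afferents, rewiring_params.p_form_lat,
              rewiring_params.sigma_form_lat, lateral_inh)]
    for post in range(layer.n):
        slot = 0
        for pre_layer, count, p_form, sigma, is_inh in plans:
            accepted = 0
            p_row = p_form * np.exp(-d2[post] / (2 * sigma ** 2))
            while accepted < count:
                cand = int(rng.integers(layer.n))
                if rng.random() < p_row[cand]:
                    table.add(post, slot, cand, pre_layer, w0, is_inh)
                    slot += 1
                    accepted += 1
    return table


def generate_random_p(layer: GridLayer, spec: InitSpec,
                      rng: np.random.Generator, g_max: float = 0.2,
                      lateral_inh: bool = False) -> SynapticSlotTable:
    """Fixed-probability connectivity, balanced feedforward/lateral."""
    w0 = spec.initial_weight if spec.initial_weight is not None else g_max
    per_proj = round(spec.p_random * layer.n / 2)
    if 2 * per_proj > spec.s_max:
        raise ValueError("p_random implies fan-in above S_max")
    table = SynapticSlotTable(layer.n, spec.s_max)
    for post in range(layer.n):
        slot = 0
        for pre_layer, is_inh in ((SOURCE, False), (TARGET, lateral_inh)):
            for pre in rng.integers(layer.n, size=per_proj):
                table.add(post, slot, int(pre), pre_layer, w0, is_inh)
                slot += 1
    return table


def generate_one_to_one(layer: GridLayer, spec: InitSpec,
                        g_max: float = 0.2) -> SynapticSlotTable:
    """Minimal connectivity: one feedforward synapse from the co-located
    source neuron; deterministic."""
    w0 = spec.initial_weight if spec.initial_weight is not None else g_max
    table = SynapticSlotTable(layer.n, spec.s_max)
    for post in range(layer.n):
        table.add(post, 0, post, SOURCE, w0)
    return table


def generate_initial_table(mode: str, layer: GridLayer,
                           rewiring_params: RewiringParams,
                           rng: np.random.Generator,
                           spec: InitSpec | None = None,
                           lateral_inh: bool = False) -> SynapticSlotTable:
    """Dispatch on the initial-connectivity mode."""
    spec = spec if spec is not None else InitSpec(mode=mode)
    if spec.mode != mode:
        spec = InitSpec(mode=mode, n_ff_afferents=spec.n_ff_afferents,
                        n_lat_afferents=spec.n_lat_afferents,
                        p_random=spec.p_random, s_max=spec.s_max,
                        initial_weight=spec.initial_weight)
    if mode == "topographic":
        return generate_topographic(layer, spec, rewiring_params, rng, lateral_inh)
    if mode == "random_p":
        return generate_random_p(layer, spec, rng, rewiring_params.g_max, lateral_inh)
    if mode == "one_to_one":
        return generate_one_to_one(layer, spec, rewiring_params.g_max)
    if mode == "empty":
        return SynapticSlotTable(layer.n, spec.s_max)
    raise ValueError(f"unknown init mode {mode!r}")
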