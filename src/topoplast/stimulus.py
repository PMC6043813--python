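"""Poisson source-layer input.

Two firing protocols drive the source layer. Without input correlations
every source neuron fires at the flat mean rate ``f_mean``. With
correlations the rate field is a Gaussian bump on the torus,

    r(i) = f_base + f_peak * exp(-d(s, i)^2 / (2 sigma_stim^2)),

whose centre ``s`` is redrawn uniformly over the grid every ``t_stim`` ms.
The default peak (152.8 Hz at sigma_stim = 2 on a 16x16 torus) makes the
layer-mean rate come out at f_mean = 20 Hz; :func:`rescale_f_peak` recovers
this calibration for any bump width so that sweeps over sigma_stim hold the
mean input rate fixed.

Spikes are sampled per 1 ms step with at most one spike per neuron per
step, with probability ``1 - exp(-r dt)`` (the probability of at least one
Poisson event), mirroring the one-spike-per-step resolution of
address-event representation hardware; the cap only matters at kHz-range
rates reached by punctiform stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import GridLayer, TorusPoint, torus_distance

__all__ = [
    "StimulusParams", "RateField", "rates_for_centre", "rescale_f_peak",
    "maybe_relocate", "sample_spikes",
]


@dataclass(frozen=True)
class StimulusParams:
    f_mean: float = 20.0        # Hz, layer-mean rate (uncorrelated mode rate)
    f_base: float = 5.0         # Hz, noise floor under the bump
    f_peak: float = 152.8       # Hz, bump amplitude above the floor
    sigma_stim: float = 2.0     # grid units, bump width
    t_stim: float = 20.0        # ms, centre relocation interval
    correlated: bool = True


@dataclass
class RateField:
    """Instantaneous per-neuron Poisson rates plus the active bump centre."""

    rates: np.ndarray           # Hz, one entry per source neuron
    centre: TorusPoint | None   # None in the uncorrelated protocol
    expires_at: float           # ms, when the centre is redrawn


def rates_for_centre(s: TorusPoint, params: StimulusParams,
                     layer: GridLayer) -> np.ndarray:
    """Gaussian-bump rates (Hz) for every source neuron, toroidal distances."""
    if params.sigma_stim <= 0:
        raise ValueError("sigma_stim must be > 0")
    d = torus_distance(np.array([s.x, s.y]), layer.coords(), layer)
    return params.f_base + params.f_peak * np.exp(
        -d ** 2 / (2 * params.sigma_stim ** 2))


def rescale_f_peak(sigma_stim: float, params: StimulusParams,
                   layer: GridLayer) -> float:
    """Peak rate that keeps the layer-mean rate at f_mean for this bump width.

    Solves mean_i[f_base + f_peak G(i)] = f_mean for f_peak, where G is the
    torus Gaussian; by translation symmetry the result is centre-independent.
    """
    if params.f_mean <= params.f_base:
        raise ValueError("f_mean must exceed f_base")
    if sigma_stim <= 0:
        raise ValueError("sigma_stim must be > 0")
    d = torus_distance(np.zeros(2), layer.coords(), layer)
    gauss_sum = np.exp(-d ** 2 / (2 * sigma_stim ** 2)).sum()
    return (params.f_mean - params.f_base) * layer.n / gauss_sum


def initial_field(params: StimulusParams, layer: GridLayer,
                  rng: np.random.Generator, t: float = 0.0) -> RateField:
    """Rate field at simulation start (draws a first centre if correlated)."""
    if not params.correlated:
        return RateField(np.full(layer.n, params.f_mean), None, np.inf)
    cid = int(rng.integers(layer.n))
    s = TorusPoint(float(cid % layer.width), float(cid // layer.width))
    return RateField(rates_for_centre(s, params, layer), s, t + params.t_stim)


def maybe_relocate(field: RateField, t: float, params: StimulusParams,
                   layer: GridLayer, rng: np.random.Generator) -> RateField:
    """Redraw the bump centre (uniform over grid positions) when it expires."""
    if not params.correlated or t < field.expires_at:
        return field
    cid = int(rng.integers(layer.n))
    s = TorusPoint(float(cid % layer.width), float(cid // layer.width))
    return RateField(rates_for_centre(s, params, layer), s, t + params.t_stim)


def sample_spikes(field: RateField, dt: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Boolean spike vector for one step: at most one spike per neuron."""
    p = 1.0 - np.exp(-field.rates * dt / 1000.0)
    return rng.random(field.rates.shape) < p
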