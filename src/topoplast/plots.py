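"""Optional matplotlib figures for the standard experiment outputs.

Import of matplotlib is deferred so the core package works without it.
Each function returns the Axes it drew on; pass ``ax`` to compose panels.
"""

from __future__ import annotations

import numpy as np

from .topology import GridLayer
from .metrics import weight_by_distance_profile

__all__ = ["plot_weight_profile", "plot_rate_series", "plot_occupancy",
           "plot_rewiring_activity"]


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt
    return plt.subplots()[1]


def plot_weight_profile(table, projection: str, layer: GridLayer, ax=None,
                        weighted: bool = True):
    """Bar chart of synaptic mass (or count) per discrete distance."""
    ax = _axes(ax)
    prof = weight_by_distance_profile(table, projection, layer)
    y = prof["total_weight"] if weighted else prof["count"]
    ax.bar(prof["distance"], y, width=0.08)
    ax.set_xlabel("distance (grid units)")
    ax.set_ylabel("total weight" if weighted else "synapse count")
    ax.set_title(f"{projection} profile")
    return ax


def plot_rate_series(series, ax=None, **plot_kw):
    """Population-rate trajectory from a (t_s, rate_hz) DataFrame."""
    ax = _axes(ax)
    ax.plot(series["t_s"], series["rate_hz"], **plot_kw)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("target rate (Hz)")
    return ax


def plot_occupancy(trajectory, ax=None, **plot_kw):
    """Connectivity-fraction trajectory from a development run."""
    ax = _axes(ax)
    ax.plot(trajectory["t_s"], 100 * trajectory["connectivity_fraction"],
            **plot_kw)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("connectivity (% of all-to-all)")
    return ax


def plot_rewiring_activity(event_bins, ax=None):
    """Stacked formations/eliminations per time chunk."""
    ax = _axes(ax)
    ax.bar(event_bins["t_s"], event_bins["formations"], width=2.8,
           label="formations")
    ax.bar(event_bins["t_s"], -event_bins["eliminations"].astype(float),
           width=2.8, label="eliminations")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("events / chunk")
    ax.legend()
    return ax
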