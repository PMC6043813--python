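"""Plain-text file formats: configs, spike rasters, connectivity snapshots.

All formats are whitespace-separated columnar text with a ``#``-prefixed
header line, plus a flat ``key = value`` configuration format whose keys
follow the standard parameter names (``s_max``, ``sigma_form_ff``, ...).
"""

from __future__ import annotations

from dataclasses import fields as dc_fields
from pathlib import Path

import numpy as np

from .topology import GridLayer
from .neurons import NeuronParams
from .synapses import STDPParams, SynapticSlotTable
from .rewiring import RewiringParams
from .stimulus import StimulusParams
from .engine import SimConfig

__all__ = [
    "write_config", "read_config", "config_to_params", "params_to_config",
    "write_raster", "read_raster", "write_snapshot", "read_snapshot",
    "write_events",
]

_LAYER_NAMES = {0: "source", 1: "target"}
_LAYER_CODES = {"source": 0, "target": 1}


# -- flat key = value configs -------------------------------------------

def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for key, val in cfg.items():
            fh.write(f"{key} = {val}\n")


def _parse_value(text: str):
    text = text.strip()
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def read_config(path) -> dict:
    cfg = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        if not _:
            raise ValueError(f"malformed config line: {line!r}")
        cfg[key.strip()] = _parse_value(val)
    return cfg


_PREFIXES = {
    "sim": SimConfig, "stim": StimulusParams, "neuron": NeuronParams,
    "stdp": STDPParams, "rewiring": RewiringParams,
}


def params_to_config(sim: SimConfig, stim: StimulusParams,
                     neuron: NeuronParams, stdp: STDPParams,
                     rewiring: RewiringParams,
                     layer: GridLayer | None = None) -> dict:
    """Flatten all parameter sets into one key-value mapping."""
    cfg = {}
    if layer is not None:
        cfg["width"], cfg["height"] = layer.width, layer.height
    for obj in (sim, stim, neuron, stdp, rewiring):
        for f in dc_fields(obj):
            cfg[f.name.lower()] = getattr(obj, f.name)
    return cfg


def config_to_params(cfg: dict):
    """Rebuild (SimConfig, StimulusParams, NeuronParams, STDPParams,
    RewiringParams, GridLayer) from a flat mapping; unknown keys raise."""
    cfg = dict(cfg)
    width = int(cfg.pop("width", 16))
    height = int(cfg.pop("height", 16))
    out = []
    for cls in (SimConfig, StimulusParams, NeuronParams, STDPParams,
                RewiringParams):
        names = {f.name.lower(): f.name for f in dc_fields(cls)}
        kwargs = {names[k]: cfg.pop(k) for k in list(cfg) if k in names}
        out.append(cls(**kwargs))
    if cfg:
        raise ValueError(f"unknown config keys: {sorted(cfg)}")
    return (*out, GridLayer(width, height))


# -- spike rasters ------------------------------------------------------

def write_raster(raster, path) -> None:
    """Rows of (t_ms, layer, neuron_id)."""
    with open(path, "w") as fh:
        fh.write("# t_ms layer neuron_id\n")
        for t, layer_name, nid in raster:
            fh.write(f"{t:.1f} {layer_name} {nid}\n")


def read_raster(path):
    out = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        t, layer_name, nid = line.split()
        out.append((float(t), layer_name, int(nid)))
    return out


# -- connectivity snapshots ---------------------------------------------

def write_snapshot(table: SynapticSlotTable, path, t_ms: float = 0.0) -> None:
    rows = table.to_rows()
    with open(path, "w") as fh:
        fh.write("# t_ms pre_layer pre_id post_id g_syn delay_ms syn_type\n")
        for r in rows:
            fh.write(f"{t_ms:.1f} {_LAYER_NAMES[int(r['pre_layer'])]} "
                     f"{r['pre_id']} {r['post_id']} {r['g_syn']:.6g} "
                     f"{r['delay_ms']:.1f} {'inh' if r['inh'] else 'exc'}\n")


def read_snapshot(path, n_target: int, s_max: int = 32) -> SynapticSlotTable:
    table = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        _t, pre_layer, pre_id, post_id, g_syn, delay, syn_type = line.split()
        if table is None:
            table = SynapticSlotTable(n_target, s_max, float(delay))
        post = int(post_id)
        slot = table.free_slot(post)
        if slot is None:
            raise ValueError(f"fan-in of neuron {post} exceeds S_max")
        table.add(post, slot, int(pre_id), _LAYER_CODES[pre_layer],
                  float(g_syn), syn_type == "inh")
    return table if table is not None else SynapticSlotTable(n_target, s_max)


def write_events(events, path) -> None:
    """Rewiring event log, one row per non-abort event."""
    with open(path, "w") as fh:
        fh.write("# t_ms kind post_id slot pre_layer pre_id\n")
        for e in events:
            if e.kind == "abort":
                continue
            fh.write(f"{e.t:.1f} {e.kind} {e.post_id} {e.slot} "
                     f"{_LAYER_NAMES[e.pre_layer]} {e.pre_id}\n")
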