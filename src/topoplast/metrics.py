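"""Receptive-field quality metrics.

A target neuron's afferent receptive field is summarised by two numbers:

* ``sigma_aff`` — the spread of the field: the per-axis weighted standard
  deviation of afferent positions about the best candidate centre,

      sigma_aff(x) = sqrt( sum_i w_i d(x, x_i)^2 / (2 sum_i w_i) ),

  minimised over candidate centres x on the torus (d is the toroidal
  distance; the factor 2 in the denominator averages the two axes of the
  squared radial distance, so an isotropic Gaussian field of per-axis
  width s yields sigma_aff ~ s).
* ``AD`` — the absolute deviation: the toroidal distance from the
  minimising centre (the preferred location) to the neuron's ideal
  location, i.e. its co-located source neuron for the feedforward
  projection or itself for the lateral one.

The centre search is two-stage: every integer grid location is evaluated,
then a 0.1-unit lattice within +-1 unit of the integer winner; ties break
on the first candidate in row-major scan order.  Weighted variants use the
synaptic weights g_syn; connectivity ("conn") variants set all weights to
one, so multapses count with multiplicity.

Shuffled controls pair each measured value with a null: weight shuffling
permutes a neuron's weights over its existing synapses of the same
projection (topology untouched); connectivity shuffling regenerates the
same per-neuron synapse counts with the distance-dependent formation
sampler.  Paired per-neuron comparisons use two-sided Wilcoxon
signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .topology import GridLayer, TorusPoint
from .synapses import SynapticSlotTable, SOURCE, TARGET
from .rewiring import RewiringParams

__all__ = [
    "sigma_aff_search", "absolute_deviation", "shuffle_weights",
    "shuffle_connectivity", "wsr_compare", "weight_by_distance_profile",
    "rf_summary", "MetricsReport", "metrics_report",
]


def _wrapped_sq_dist(cand: np.ndarray, aff: np.ndarray, size: np.ndarray) -> np.ndarray:
    """(n_cand, n_aff) squared toroidal distances."""
    d = np.abs(cand[:, None, :] - aff[None, :, :])
    d = np.minimum(d, size - d)
    return (d ** 2).sum(axis=2)


def sigma_aff_search(afferents, layer: GridLayer):
    """Minimise the weighted per-axis spread over candidate centres.

    Parameters
    ----------
    afferents : sequence of ((x, y), weight) pairs, or an (xy array, weight
        array) tuple.
    layer : grid geometry providing the torus dimensions.

    Returns
    -------
    (preferred, sigma) : the minimising :class:`TorusPoint` and the spread
        at the minimum (grid units).
    """
    if isinstance(afferents, tuple) and len(afferents) == 2:
        xy, w = np.asarray(afferents[0], float), np.asarray(afferents[1], float)
    else:
        xy = np.array([[a[0][0], a[0][1]] for a in afferents], float)
        w = np.array([a[1] for a in afferents], float)
    if xy.size == 0:
        raise ValueError("empty afferent list")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("total afferent weight must be > 0")
    size = np.array([layer.width, layer.height], float)

    # stage 1: all integer grid locations, row-major order
    cand1 = layer.coords()
    v1 = _wrapped_sq_dist(cand1, xy, size) @ w
    i1 = int(np.argmin(v1))
    bx, by = cand1[i1]

    # stage 2: 0.1 lattice within +-1 unit of the integer winner
    offs = np.round(np.arange(-10, 11) * 0.1, 10)
    gx, gy = np.meshgrid(bx + offs, by + offs)   # row-major scan of the window
    cand2 = np.stack([gx.ravel() % size[0], gy.ravel() % size[1]], axis=1)
    v2 = _wrapped_sq_dist(cand2, xy, size) @ w
    i2 = int(np.argmin(v2))

    if v2[i2] < v1[i1]:
        best, val = cand2[i2], v2[i2]
    else:
        best, val = cand1[i1], v1[i1]
    return TorusPoint(best[0], best[1]), float(np.sqrt(val / (2.0 * wsum)))


def absolute_deviation(preferred: TorusPoint, ideal: TorusPoint,
                       layer: GridLayer) -> float:
    """Toroidal distance from the preferred to the ideal location."""
    from .topology import torus_distance
    return float(torus_distance(preferred, ideal, layer))


def rf_summary(table: SynapticSlotTable, layer: GridLayer,
               projection: str = "ff", variant: str = "weight") -> pd.DataFrame:
    """Per-neuron preferred location, sigma_aff and AD for one projection.

    Neurons with no afferents of the projection (or zero total weight) get
    NaN rows; means over the summary should skip them.
    """
    if variant not in ("weight", "conn"):
        raise ValueError("variant must be 'weight' or 'conn'")
    coords = layer.coords()
    rows = np.full((table.n_target, 4), np.nan)
    for post in range(table.n_target):
        pre_ids, w = table.afferents(post, projection)
        if pre_ids.size == 0:
            continue
        if variant == "conn":
            w = np.ones_like(w)
        elif w.sum() <= 0:
            continue
        preferred, sigma = sigma_aff_search((coords[pre_ids], w), layer)
        ad = absolute_deviation(preferred, TorusPoint(*coords[post]), layer)
        rows[post] = (preferred.x, preferred.y, sigma, ad)
    return pd.DataFrame(rows, columns=["preferred_x", "preferred_y",
                                       "sigma_aff", "ad"])


def shuffle_weights(table: SynapticSlotTable,
                    rng: np.random.Generator) -> SynapticSlotTable:
    """Permute each neuron's weights among its synapses of the same
    projection; the topology and the weight multiset are preserved."""
    out = table.copy()
    for post in range(table.n_target):
        for proj_layer in (SOURCE, TARGET):
            mask = table.occupied[post] & (table.layer[post] == proj_layer)
            idx = np.flatnonzero(mask)
            if idx.size > 1:
                out.w[post, idx] = table.w[post, idx[rng.permutation(idx.size)]]
    return out


def shuffle_connectivity(table: SynapticSlotTable, params: RewiringParams,
                         layer: GridLayer,
                         rng: np.random.Generator) -> SynapticSlotTable:
    """Regenerate each neuron's afferents (same per-projection counts) with
    the distance-dependent formation sampler; weights are unitary."""
    from .topology import pairwise_sq_distances
    d2 = pairwise_sq_distances(layer)
    out = SynapticSlotTable(table.n_target, table.s_max, table.delay)
    plans = ((SOURCE, params.p_form_ff, params.sigma_form_ff),
             (TARGET, params.p_form_lat, params.sigma_form_lat))
    for post in range(table.n_target):
        slot = 0
        for proj_layer, p_form, sigma in plans:
            count = int((table.occupied[post]
                         & (table.layer[post] == proj_layer)).sum())
            p_row = p_form * np.exp(-d2[post] / (2 * sigma ** 2))
            accepted = 0
            while accepted < count:
                cand = int(rng.integers(layer.n))
                if rng.random() < p_row[cand]:
                    out.add(post, slot, cand, proj_layer, 1.0)
                    slot += 1
                    accepted += 1
    return out


def wsr_compare(values_a, values_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-neuron metrics.

    NaN pairs (neurons excluded from either summary) are dropped; identical
    vectors give p = 1 (no detectable effect).
    """
    a, b = np.asarray(values_a, float), np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = a[keep] - b[keep]
    if np.allclose(d, 0):
        return 1.0
    return float(stats.wilcoxon(d, zero_method="wilcox",
                                alternative="two-sided").pvalue)


def weight_by_distance_profile(table: SynapticSlotTable, projection: str,
                               layer: GridLayer) -> pd.DataFrame:
    """Synapse count and mean weight per discrete toroidal distance.

    Groups the projection's synapses by the (exact) distance between pre
    and post; returns columns (distance, count, mean_weight, total_weight).
    """
    coords = layer.coords()
    size = np.array([layer.width, layer.height], float)
    occ = table.occupied & (table.layer == (SOURCE if projection == "ff" else TARGET))
    post, slot = np.nonzero(occ)
    if post.size == 0:
        return pd.DataFrame(columns=["distance", "count", "mean_weight",
                                     "total_weight"])
    pre = table.pre[post, slot]
    d = np.abs(coords[pre] - coords[post])
    d = np.minimum(d, size - d)
    d2 = (d ** 2).sum(axis=1)
    key = np.round(d2 * 4).astype(int)   # 4*d^2 is integral on a unit grid
    df = pd.DataFrame({"key": key, "w": table.w[post, slot]})
    g = df.groupby("key")["w"]
    out = pd.DataFrame({"distance": np.sqrt(g.count().index.values / 4.0),
                        "count": g.count().values,
                        "mean_weight": g.mean().values,
                        "total_weight": g.sum().values})
    return out.reset_index(drop=True)


@dataclass
class MetricsReport:
    """Means, shuffled-control means and WSR p-values for one simulation."""

    means: dict = field(default_factory=dict)       # label -> mean value
    pvalues: dict = field(default_factory=dict)     # label -> WSR p
    per_neuron: dict = field(default_factory=dict)  # label -> vector
    excluded: dict = field(default_factory=dict)    # label -> neurons skipped

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.means.items()]
        rows += [(f"p(WSR {k})", v) for k, v in self.pvalues.items()]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def metrics_report(init_table: SynapticSlotTable | None,
                   fin_table: SynapticSlotTable,
                   layer: GridLayer, params: RewiringParams,
                   rng: np.random.Generator,
                   projection: str = "ff") -> MetricsReport:
    """Full Table-style report: init/fin metrics, shuffles and WSR tests."""
    rep = MetricsReport()

    def put(label: str, frame: pd.DataFrame, col: str) -> None:
        v = frame[col].values
        rep.per_neuron[label] = v
        rep.means[label] = float(np.nanmean(v)) if np.any(~np.isnan(v)) else 0.0
        rep.excluded[label] = int(np.isnan(v).sum())

    if init_table is not None:
        finit = rf_summary(init_table, layer, projection, "conn")
        put("sigma_aff_init", finit, "sigma_aff")
        put("ad_init", finit, "ad")

    f_conn = rf_summary(fin_table, layer, projection, "conn")
    f_weight = rf_summary(fin_table, layer, projection, "weight")
    conn_shuf = rf_summary(shuffle_connectivity(fin_table, params, layer, rng),
                           layer, projection, "conn")
    weight_shuf = rf_summary(shuffle_weights(fin_table, rng),
                             layer, projection, "weight")

    put("sigma_aff_fin_conn", f_conn, "sigma_aff")
    put("sigma_aff_fin_conn_shuf", conn_shuf, "sigma_aff")
    put("sigma_aff_fin_weight", f_weight, "sigma_aff")
    put("sigma_aff_fin_weight_shuf", weight_shuf, "sigma_aff")
    put("ad_fin_conn", f_conn, "ad")
    put("ad_fin_conn_shuf", conn_shuf, "ad")
    put("ad_fin_weight", f_weight, "ad")
    put("ad_fin_weight_shuf", weight_shuf, "ad")

    for a, b in (("sigma_aff_fin_conn", "sigma_aff_fin_conn_shuf"),
                 ("sigma_aff_fin_weight", "sigma_aff_fin_weight_shuf"),
                 ("ad_fin_conn", "ad_fin_conn_shuf"),
                 ("ad_fin_weight", "ad_fin_weight_shuf")):
        rep.pvalues[f"{a} vs {b}"] = wsr_compare(rep.per_neuron[a],
                                                 rep.per_neuron[b])
    return rep
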