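"""Toroidal grid geometry.

Both neuronal layers live on a rectangular mesh with periodic boundary
conditions (a torus), with one neuron per integer grid position and a grid
spacing of one unit.  Neuron ids map to coordinates row-major and 0-based:
``id = y * width + x``.  All distances in the model are Euclidean distances
on the torus, i.e. each axis offset is wrapped to ``min(|d|, size - |d|)``
before squaring; the two layers are treated as spatially coincident, so the
same metric serves within-layer and between-layer distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridLayer", "TorusPoint", "id_to_coord", "coord_to_id",
    "torus_distance", "pairwise_sq_distances",
]


@dataclass(frozen=True)
class GridLayer:
    """A rectangular sheet of neurons at integer torus coordinates."""

    width: int = 16
    height: int = 16
    name: str = "source"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n(self) -> int:
        return self.width * self.height

    def coords(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions of every neuron, id order."""
        ids = np.arange(self.n)
        return np.stack([ids % self.width, ids // self.width], axis=1).astype(float)


@dataclass(frozen=True)
class TorusPoint:
    """A continuous location on the torus, coordinates reduced to the domain."""

    x: float
    y: float

    def reduced(self, layer: GridLayer) -> "TorusPoint":
        return TorusPoint(self.x % layer.width, self.y % layer.height)


def id_to_coord(nid: int, layer: GridLayer) -> TorusPoint:
    """Row-major, 0-based id -> (x, y)."""
    if not 0 <= nid < layer.n:
        raise ValueError(f"neuron id {nid} out of range for {layer.n}-neuron layer")
    return TorusPoint(float(nid % layer.width), float(nid // layer.width))


def coord_to_id(p: TorusPoint, layer: GridLayer) -> int:
    """Inverse of :func:`id_to_coord`; requires integer coordinates."""
    x, y = int(round(p.x)) % layer.width, int(round(p.y)) % layer.height
    return y * layer.width + x


def torus_distance(a, b, layer: GridLayer) -> float | np.ndarray:
    """Euclidean distance with periodic boundary conditions.

    ``a`` and ``b`` may be :class:`TorusPoint` instances or arrays of shape
    (..., 2); broadcasting applies.  Per axis the wrapped offset
    ``min(|d|, size - |d|)`` is used, so the maximum possible distance is
    ``hypot(width/2, height/2)``.
    """
    pa = np.asarray([a.x, a.y], float) if isinstance(a, TorusPoint) else np.asarray(a, float)
    pb = np.asarray([b.x, b.y], float) if isinstance(b, TorusPoint) else np.asarray(b, float)
    size = np.array([layer.width, layer.height], float)
    d = np.abs(pa - pb) % size
    d = np.minimum(d, size - d)
    out = np.sqrt((d ** 2).sum(axis=-1))
    return float(out) if out.ndim == 0 else out


def pairwise_sq_distances(layer: GridLayer) -> np.ndarray:
    """(n, n) matrix of squared toroidal distances between all neuron pairs.

    Precomputed once per simulation; with coincident layers it serves both
    the feedforward and the lateral projection.
    """
    c = layer.coords()
    size = np.array([layer.width, layer.height], float)
    d = np.abs(c[:, None, :] - c[None, :, :])
    d = np.minimum(d, size - d)
    return (d ** 2).sum(axis=2)
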