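"""Geographic distances and distance-class binning.

Distances are always returned in metres.  Planar coordinates are used as
given; geographic coordinates (decimal degrees) are projected with a local
equirectangular projection about the mean latitude, which is accurate to
well under 0.1% at the patch scales (< 10 km) this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datatypes import InputError

EARTH_RADIUS_M = 6_371_008.8


def project_lonlat(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Project lon/lat degrees to local planar metres (equirectangular)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lat0 = np.deg2rad(lat.mean())
    x = EARTH_RADIUS_M * np.deg2rad(lon) * np.cos(lat0)
    y = EARTH_RADIUS_M * np.deg2rad(lat)
    return np.column_stack([x, y])


def pairwise_distance(coords: np.ndarray, mode: str = "planar") -> np.ndarray:
    """Full symmetric n x n matrix of pairwise distances in metres.

    Parameters
    ----------
    coords : (n, 2) array
        ``(x, y)`` metres when ``mode='planar'``; ``(lon, lat)`` degrees
        when ``mode='geographic'``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise InputError("coords must be an (n, 2) array")
    if mode == "geographic":
        coords = project_lonlat(coords[:, 0], coords[:, 1])
    elif mode != "planar":
        raise InputError(f"unknown coordinate mode: {mode!r}")
    if len(coords) < 2:
        return np.zeros((len(coords), len(coords)))
    return squareform(pdist(coords))


def haversine_matrix(lonlat: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix in metres (reference for validation)."""
    lon = np.deg2rad(np.asarray(lonlat, dtype=float)[:, 0])
    lat = np.deg2rad(np.asarray(lonlat, dtype=float)[:, 1])
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class DistanceClassSpec:
    """How pairwise distances are binned into distance classes.

    ``equal_count`` places class edges at quantiles of the observed
    positive pairwise distances so every class holds roughly the same
    number of pairs (SPAGeDi practice); ``fixed_edges`` uses explicit
    edges in metres.  Intervals are half-open, lower-closed, except the
    last class which also includes its upper edge.
    """

    mode: str = "equal_count"
    n_classes: int = 10
    edges: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("equal_count", "fixed_edges"):
            raise InputError(f"unknown distance-class mode {self.mode!r}")
        if self.mode == "fixed_edges":
            if self.edges is None or len(self.edges) < 2:
                raise InputError("fixed_edges mode needs >= 2 edges")
            e = np.asarray(self.edges, dtype=float)
            if not np.all(np.diff(e) > 0):
                raise InputError("edges must be strictly increasing")
        elif self.n_classes < 1:
            raise InputError("n_classes must be >= 1")

    def resolve_edges(self, distances: np.ndarray) -> np.ndarray:
        """Concrete, strictly increasing class edges for these distances."""
        if self.mode == "fixed_edges":
            return np.asarray(self.edges, dtype=float)
        d = np.asarray(distances, dtype=float)
        d = d[d > 0]
        if d.size == 0:
            raise InputError("no positive pairwise distances to bin")
        q = np.linspace(0.0, 1.0, self.n_classes + 1)
        edges = np.unique(np.quantile(d, q))
        if edges.size < 2:
            edges = np.array([d.min(), d.max() + 1.0])
        return edges

    def assign(self, distances: np.ndarray, edges: np.ndarray) -> np.ndarray:
        """Class index per distance; -1 for distances outside all classes."""
        d = np.asarray(distances, dtype=float)
        idx = np.searchsorted(edges, d, side="right") - 1
        idx[d == edges[-1]] = len(edges) - 2  # close the last interval
        idx[(d < edges[0]) | (d > edges[-1])] = -1
        return idx
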