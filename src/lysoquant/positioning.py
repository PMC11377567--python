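"""Radial lysosome positioning within a cell.

Each lysosome is assigned a normalized position along the ray cast from the
nucleus centroid through the lysosome centroid: 0 where the ray exits the
nuclear membrane, 1 where it reaches the plasma membrane.  Fractions are
binned into a fraction-vs-distance profile, the standard readout for
lysosome redistribution towards the cell periphery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point

from .errors import DomainError
from .io import CellGeometry

__all__ = ["RadialProfile", "radial_fraction", "bin_profile", "cell_profile"]

_EPS = 1e-9


@dataclass
class RadialProfile:
    """Binned fraction of lysosomes per normalized radial distance."""

    bin_edges: np.ndarray
    fractions: np.ndarray
    n_lysosomes: int
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise DomainError("bin edges must be strictly increasing")
        if self.n_lysosomes > 0 and abs(self.fractions.sum() - 1.0) > 1e-9:
            raise DomainError("profile fractions must sum to 1")

    @property
    def empty(self) -> bool:
        return self.n_lysosomes == 0


def _ray_crossings(origin: np.ndarray, direction: np.ndarray, polygon, t_max: float) -> np.ndarray:
    """Parameter values t > 0 where origin + t*direction crosses the polygon boundary."""
    far = origin + direction * t_max
    ray = LineString([origin, far])
    inter = polygon.exterior.intersection(ray)
    if inter.is_empty:
        return np.array([])
    if inter.geom_type == "Point":
        pts = [inter]
    elif inter.geom_type in ("MultiPoint", "GeometryCollection"):
        pts = [g for g in inter.geoms if g.geom_type == "Point"]
        # a ray grazing along an edge contributes a segment; take its endpoints
        for g in inter.geoms:
            if g.geom_type == "LineString":
                pts.extend(Point(c) for c in g.coords)
    elif inter.geom_type == "LineString":
        pts = [Point(c) for c in inter.coords]
    else:
        pts = []
    ts = [float(np.dot(np.array(p.coords[0]) - origin, direction)) for p in pts]
    return np.array(sorted(t for t in ts if t > _EPS))


def radial_fraction(cell: CellGeometry, lysosome) -> float:
    """Normalized nuclear-membrane-to-plasma-membrane position of one lysosome.

    Casts the ray from the nucleus centroid through the lysosome centroid;
    with P_n the ray's exit through the nuclear boundary and P_c the nearest
    crossing of the cell boundary beyond P_n, returns
    ``|lysosome - P_n| / |P_c - P_n|`` clamped to [0, 1].
    """
    lys = np.asarray(lysosome, dtype=float)
    nucleus = cell.nucleus
    cell_poly = cell.cell
    p = Point(lys)
    if nucleus.contains(p):
        raise DomainError("lysosome lies inside the nucleus")
    if not cell_poly.covers(p):
        raise DomainError("lysosome lies outside the cell polygon")
    origin = np.array([nucleus.centroid.x, nucleus.centroid.y])
    delta = lys - origin
    dist = np.hypot(*delta)
    if dist < _EPS:
        raise DomainError("degenerate ray: lysosome at the nucleus centroid")
    direction = delta / dist
    # long enough to exit any polygon in the scene
    minx, miny, maxx, maxy = cell_poly.bounds
    t_max = 2.0 * float(np.hypot(maxx - minx, maxy - miny)) + dist

    t_nuc = _ray_crossings(origin, direction, nucleus, t_max)
    if t_nuc.size == 0:
        raise DomainError("ray does not cross the nuclear boundary")
    t_n = float(t_nuc[-1])  # exit point of the nucleus along the ray
    t_cell = _ray_crossings(origin, direction, cell_poly, t_max)
    t_beyond = t_cell[t_cell > t_n + _EPS]
    if t_beyond.size == 0:
        # lysosome (and nucleus exit) on the plasma membrane itself
        t_c = float(t_cell[-1]) if t_cell.size else t_n
    else:
        t_c = float(t_beyond[0])  # nearest crossing past P_n
    span = t_c - t_n
    if span <= _EPS:
        return 1.0
    f = (dist - t_n) / span
    if f < 0 or f > 1:
        if f < -1e-6 or f > 1 + 1e-6:
            warnings.warn(
                f"radial fraction {f:.4f} outside [0, 1]; clamped", stacklevel=2
            )
    return float(min(max(f, 0.0), 1.0))


def bin_profile(fractions, n_bins: int = 10, cell_id: str = "cell0") -> RadialProfile:
    """Bin radial fractions into an equal-width profile on [0, 1].

    The final bin is right-closed, so f = 1.0 lands in the last bin.  An
    empty input yields an empty (flagged) profile rather than an error.
    """
    if n_bins < 2:
        raise DomainError("n_bins must be >= 2")
    fr = np.asarray(list(fractions), dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    if fr.size == 0:
        return RadialProfile(edges, np.zeros(n_bins), 0, cell_id)
    if fr.min() < 0 or fr.max() > 1:
        raise DomainError("fractions must lie in [0, 1]")
    counts, _ = np.histogram(fr, bins=edges)
    return RadialProfile(edges, counts / fr.size, int(fr.size), cell_id)


def cell_profile(cell: CellGeometry, n_bins: int = 10) -> RadialProfile:
    """Profile of a cell's organelle centroids (from its geometry file)."""
    if cell.organelle_centroids is None or len(cell.organelle_centroids) == 0:
        return bin_profile([], n_bins, cell.cell_id)
    fr = [radial_fraction(cell, c) for c in cell.organelle_centroids]
    return bin_profile(fr, n_bins, cell.cell_id)
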