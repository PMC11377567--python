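"""Readers and writers for the formats the pipeline touches.

Conventions
-----------
Arrays are indexed 0-based as ``(row, col)``.  Geometry files (and all polygon
vertex lists) use ``(x, y) = (col, row)`` with the origin at the centre of the
top-left pixel.  Point-in-polygon tests use the even-odd rule with boundary
points counting as inside.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import Point, Polygon

from .errors import FormatError, InvariantError, SchemaError

__all__ = [
    "Image2D",
    "ImageStack",
    "CellGeometry",
    "ResultTable",
    "read_image",
    "write_image",
    "read_geometry",
    "write_geometry",
    "write_results",
    "read_results",
    "polygon_mask",
]

_TIFF_MAGIC = (b"II*\x00", b"MM\x00*", b"II+\x00", b"MM\x00+")


@dataclass
class Image2D:
    """A single-channel 2D intensity image.

    Parameters
    ----------
    pixels
        2D array of finite, non-negative intensities (arbitrary units).
    pixel_size
        Physical side length of one pixel in micrometres, if known.  The
        source acquisitions state no pixel size, so geometry defaults to
        pixel units.
    channel_name
        Free-text channel label, e.g. ``"ch0"`` or ``"mCherry-Gal3"``.
    """

    pixels: np.ndarray
    pixel_size: float | None = None
    channel_name: str = "ch0"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InvariantError("Image2D requires a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise InvariantError("Image2D intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageStack:
    """An ordered list of same-shape planes (z sections and/or channels)."""

    planes: list[Image2D]
    axis: str = "z"

    def __post_init__(self) -> None:
        if not self.planes:
            raise InvariantError("ImageStack requires at least one plane")
        shapes = {p.shape for p in self.planes}
        if len(shapes) > 1:
            raise InvariantError(f"planes disagree in shape: {sorted(shapes)}")
        names = [p.channel_name for p in self.planes]
        if self.axis == "channel" and len(set(names)) != len(names):
            raise InvariantError("channel names must be unique")

    def __len__(self) -> int:
        return len(self.planes)

    def __getitem__(self, i: int) -> Image2D:
        return self.planes[i]

    def channel(self, name: str) -> Image2D:
        for p in self.planes:
            if p.channel_name == name:
                return p
        raise KeyError(name)


def _as_polygon(vertices) -> Polygon:
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise InvariantError("polygon needs >= 3 (x, y) vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise InvariantError("polygon is self-intersecting or degenerate")
    return poly


@dataclass
class CellGeometry:
    """One cell's manually traced outline, nucleus, and organelle centroids.

    Vertices are ``(x, y)`` pixel coordinates.  The nucleus polygon must lie
    inside the cell polygon (boundary contact allowed).
    """

    cell_polygon: np.ndarray
    nucleus_polygon: np.ndarray
    organelle_centroids: np.ndarray | None = None
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.cell_polygon = np.asarray(self.cell_polygon, dtype=float)
        self.nucleus_polygon = np.asarray(self.nucleus_polygon, dtype=float)
        cell = _as_polygon(self.cell_polygon)
        nuc = _as_polygon(self.nucleus_polygon)
        if not cell.covers(nuc):
            raise InvariantError(
                f"nucleus polygon extends outside cell polygon for cell_id={self.cell_id!r}"
            )
        if self.organelle_centroids is not None:
            self.organelle_centroids = np.asarray(self.organelle_centroids, dtype=float).reshape(-1, 2)

    @property
    def cell(self) -> Polygon:
        return _as_polygon(self.cell_polygon)

    @property
    def nucleus(self) -> Polygon:
        return _as_polygon(self.nucleus_polygon)

    def contains(self, x: float, y: float) -> bool:
        """Even-odd containment in the cell polygon; boundary counts inside."""
        return self.cell.covers(Point(x, y))


@dataclass
class ResultTable:
    """Per-cell / per-object measurements plus run provenance.

    ``provenance`` always records the parameters (and seed, when randomness
    is involved) that produced the table, so any CSV on disk can be traced
    back to its run configuration.
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if "parameters" not in self.provenance:
            self.provenance["parameters"] = {}

    def __len__(self) -> int:
        return len(self.data)


def read_image(path: str | Path) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    Channel names come from page descriptions when present, otherwise the
    positional defaults ``ch0, ch1, ...``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:4] not in _TIFF_MAGIC:
        raise FormatError(
            f"{path} is not a TIFF: bad magic bytes at byte offset 0 ({magic!r})"
        )
    try:
        with tifffile.TiffFile(path) as tif:
            planes = []
            for i, page in enumerate(tif.pages):
                arr = page.asarray()
                name = None
                if page.description:
                    name = page.description.strip() or None
                planes.append(Image2D(np.asarray(arr, float), channel_name=name or f"ch{i}"))
    except FormatError:
        raise
    except Exception as exc:  # corrupt interior structure
        raise FormatError(f"failed to parse TIFF {path}: {exc}") from exc
    return ImageStack(planes)


def write_image(stack: ImageStack | Image2D, path: str | Path) -> None:
    """Write an image or stack as a multi-page float32 TIFF."""
    if isinstance(stack, Image2D):
        stack = ImageStack([stack])
    data = np.stack([p.pixels for p in stack.planes]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack", metadata=None)


_GEOMETRY_COLUMNS = {"cell_id", "role", "vertex_index", "x", "y"}
_ROLES = {"cell", "nucleus", "organelle"}


def read_geometry(path: str | Path) -> list[CellGeometry]:
    """Read per-cell ROI polygons from CSV.

    Expected columns: ``cell_id, role, vertex_index, x, y`` with
    ``role`` one of ``cell``, ``nucleus``, ``organelle``.  Organelle rows are
    treated as centroid points (their ``vertex_index`` orders them).
    """
    df = pd.read_csv(path)
    missing = _GEOMETRY_COLUMNS - set(df.columns)
    if missing:
        raise SchemaError(f"geometry file missing columns: {sorted(missing)}")
    bad = set(df["role"].unique()) - _ROLES
    if bad:
        raise SchemaError(f"unknown geometry roles: {sorted(bad)}")
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        polys = {}
        for role in ("cell", "nucleus"):
            sub = grp[grp["role"] == role].sort_values("vertex_index")
            if sub.empty:
                raise SchemaError(f"cell_id={cell_id!r} lacks a {role} polygon")
            polys[role] = sub[["x", "y"]].to_numpy(float)
        org = grp[grp["role"] == "organelle"].sort_values("vertex_index")
        centroids = org[["x", "y"]].to_numpy(float) if len(org) else None
        out.append(
            CellGeometry(polys["cell"], polys["nucleus"], centroids, cell_id=str(cell_id))
        )
    return out


def write_geometry(geometries: list[CellGeometry], path: str | Path) -> None:
    rows = []
    for g in geometries:
        for role, verts in (("cell", g.cell_polygon), ("nucleus", g.nucleus_polygon)):
            for i, (x, y) in enumerate(verts):
                rows.append((g.cell_id, role, i, x, y))
        if g.organelle_centroids is not None:
            for i, (x, y) in enumerate(g.organelle_centroids):
                rows.append((g.cell_id, "organelle", i, x, y))
    pd.DataFrame(rows, columns=["cell_id", "role", "vertex_index", "x", "y"]).to_csv(
        path, index=False
    )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_results(table: ResultTable, path: str | Path) -> None:
    """Write a result CSV plus a YAML provenance sidecar.

    Floats are written with 12 significant digits so a read-back reproduces
    them bit-exactly for decimally representable values.
    """
    path = Path(path)
    table.data.to_csv(path, index=False, float_format="%.12g")
    from . import __version__

    prov = dict(table.provenance)
    prov.setdefault("software", f"lysoquant {__version__}")
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(prov, fh, sort_keys=True)


def read_results(path: str | Path) -> ResultTable:
    path = Path(path)
    df = pd.read_csv(path)
    prov = {}
    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            prov = yaml.safe_load(fh) or {}
    return ResultTable(df, prov)


def polygon_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize an ``(x, y)`` polygon to a boolean mask of ``shape``.

    A pixel belongs to the mask when its centre lies inside (or on) the
    polygon under the even-odd rule.
    """
    from skimage.draw import polygon2mask

    verts = np.asarray(vertices, dtype=float)
    # polygon2mask expects (row, col) = (y, x)
    mask = polygon2mask(shape, verts[:, ::-1])
    return mask
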