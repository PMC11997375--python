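"""Raster maps over the rectangular simulation domain.

A :class:`RasterMap` is a grid of scalar values (habitat quality, elevation,
carrying capacity, precipitation, ...) spanning a :class:`~continuum.kernels.Bounds`.
Row 0 of the grid corresponds to ``y_max`` (image convention) so that PNG
files read in look the way they do in an image viewer; CSV files are read
with their first row also mapped to the top of the domain (pass
``flip=True`` to invert).

Value lookup supports two conventions that both appear in raster-based
simulation practice: ``nearest`` treats each pixel's value as constant over
the rectangle it visually covers, while ``bilinear``/``bicubic`` anchor each
pixel's value at the pixel *center* and interpolate between centers.

Out-of-bounds queries clamp to the edge value.  This silently extends the
map beyond the domain — deliberate, to avoid NaN cascades when dispersal
lands individuals exactly on a boundary, but be aware of it when a map is
meant to be hostile outside its support.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .kernels import Bounds, Kernel

__all__ = [
    "RasterMap",
    "read_raster",
    "map_value",
    "smooth_map",
    "sample_nearby_point",
    "write_raster_csv",
    "write_raster_png",
]

_INTERP_ORDER = {"nearest": 0, "bilinear": 1, "bicubic": 3}


@dataclass
class RasterMap:
    """A gridded scalar field over a rectangular domain.

    Parameters
    ----------
    values : (rows, cols) array of finite reals; row 0 is the top (y_max).
    bounds : the rectangle the grid spans.
    interpolation : default lookup mode, one of nearest/bilinear/bicubic.
    """

    values: np.ndarray
    bounds: Bounds
    interpolation: str = "bilinear"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("raster values must be a 2D grid with >=1 row and column")
        if not np.all(np.isfinite(v)):
            raise ValueError("raster values must all be finite")
        if self.interpolation not in _INTERP_ORDER:
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        self.values = v

    # -- geometry --------------------------------------------------------

    @property
    def shape(self):
        return self.values.shape

    @property
    def cell_size(self):
        """(dx, dy) extent of one pixel."""
        rows, cols = self.values.shape
        return self.bounds.width / cols, self.bounds.height / rows

    @property
    def cell_area(self) -> float:
        dx, dy = self.cell_size
        return dx * dy

    def cell_centers(self):
        """(x_centers, y_centers) with y ordered to match rows (top first)."""
        rows, cols = self.values.shape
        dx, dy = self.cell_size
        xs = self.bounds.x_min + (np.arange(cols) + 0.5) * dx
        ys = self.bounds.y_max - (np.arange(rows) + 0.5) * dy
        return xs, ys

    def _frac_index(self, points):
        """Fractional (row, col) pixel-center coordinates of query points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        dx, dy = self.cell_size
        col = (p[:, 0] - self.bounds.x_min) / dx - 0.5
        row = (self.bounds.y_max - p[:, 1]) / dy - 0.5
        return row, col

    # -- lookup ----------------------------------------------------------

    def value_at(self, points, mode: str | None = None):
        """Map value at arbitrary 2D locations (clamped to edges)."""
        mode = mode or self.interpolation
        order = _INTERP_ORDER[mode]
        p = np.asarray(points, dtype=float)
        scalar = p.ndim == 1
        row, col = self._frac_index(p)
        rows, cols = self.values.shape
        if mode == "nearest":
            # pixel-rectangle semantics: round the fractional center index
            r = np.clip(np.round(row).astype(int), 0, rows - 1)
            c = np.clip(np.round(col).astype(int), 0, cols - 1)
            out = self.values[r, c]
        else:
            out = ndimage.map_coordinates(
                self.values, [row, col], order=order, mode="nearest"
            )
        return float(out[0]) if scalar else out

    def flipped(self) -> "RasterMap":
        """Return a copy with rows inverted (top <-> bottom)."""
        return replace(self, values=self.values[::-1].copy())

    # convenience wrappers around the module-level operations
    def smooth(self, kernel: Kernel, edge: str = "renormalize") -> "RasterMap":
        return smooth_map(self, kernel, edge=edge)

    def sample_nearby_point(self, x, kernel, rng, **kw):
        return sample_nearby_point(self, x, kernel, rng, **kw)


def read_raster(
    path,
    format: str | None = None,
    value_range=None,
    bounds: Bounds | None = None,
    flip: bool = False,
    interpolation: str = "bilinear",
) -> RasterMap:
    """Read a raster map from an 8-bit monochrome PNG or a rectangular CSV grid.

    PNG pixel values p in [0, 255] are mapped affinely onto
    ``lo + (hi - lo) * p / 255`` for ``value_range=(lo, hi)``.  CSV values are
    taken verbatim (``value_range`` is ignored).  ``bounds`` defaults to the
    pixel-count rectangle ``[0, cols] x [0, rows]``.
    """
    path = str(path)
    if format is None:
        format = "png" if path.lower().endswith(".png") else "csv"
    if format == "png":
        from PIL import Image

        img = Image.open(path)
        if img.mode not in ("L", "I", "I;16", "1"):
            raise ValueError(f"PNG must be monochrome; got mode {img.mode!r}")
        arr = np.asarray(img.convert("L"), dtype=float)
        if value_range is not None:
            lo, hi = value_range
            arr = lo + (hi - lo) * arr / 255.0
    elif format == "csv":
        rows = []
        with open(path, newline="") as fh:
            for rec in _csv.reader(fh):
                if rec:
                    rows.append([float(v) for v in rec])
        if not rows:
            raise ValueError(f"empty csv raster {path}")
        ncol = len(rows[0])
        if any(len(r) != ncol for r in rows):
            raise ValueError(f"non-rectangular csv raster {path}")
        arr = np.asarray(rows, dtype=float)
    else:
        raise ValueError(f"unknown raster format {format!r}")
    if flip:
        arr = arr[::-1]
    if bounds is None:
        bounds = Bounds(0.0, float(arr.shape[1]), 0.0, float(arr.shape[0]))
    return RasterMap(arr, bounds, interpolation=interpolation)


def write_raster_csv(map: RasterMap, path) -> None:
    np.savetxt(path, map.values, delimiter=",", fmt="%.17g")


def write_raster_png(map: RasterMap, path, value_range=None) -> None:
    """Write as 8-bit monochrome PNG, affinely rescaled onto [0, 255]."""
    from PIL import Image

    v = map.values
    if value_range is None:
        lo, hi = float(v.min()), float(v.max())
    else:
        lo, hi = value_range
    span = hi - lo if hi > lo else 1.0
    pix = np.clip(np.round((v - lo) / span * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(pix, mode="L").save(str(path))


def map_value(map: RasterMap, location, mode: str | None = None):
    """Value of the map at ``location`` (see :meth:`RasterMap.value_at`)."""
    return map.value_at(location, mode=mode)


def smooth_map(map: RasterMap, kernel: Kernel, edge: str = "renormalize") -> RasterMap:
    """Kernel smoothing: each output cell is a kernel-weighted combination of
    input cells within ``kernel.max_distance`` (center-to-center distances).

    edge="renormalize" (default)
        weights are normalised to sum to 1 for every output cell, so edge
        cells average over fewer neighbors and a constant map is an exact
        fixed point.
    edge="zero"
        plain zero-padded convolution with weights (kernel density x cell
        area).  This is the right mode for turning a per-area *count* map
        into the kernel-smoothed local density of individuals: the field
        really is depressed near edges, where nobody lives outside.
    """
    if map.values.size == 0:
        raise ValueError("cannot smooth an empty map")
    if edge not in ("renormalize", "zero"):
        raise ValueError("edge must be 'renormalize' or 'zero'")
    dx, dy = map.cell_size
    if kernel.scale < min(dx, dy):
        import warnings

        warnings.warn(
            f"smoothing kernel scale {kernel.scale} is below the map cell size "
            f"({dx:.3g} x {dy:.3g}); the result is dominated by discretization",
            stacklevel=2,
        )
    nx = int(np.ceil(kernel.max_distance / dx))
    ny = int(np.ceil(kernel.max_distance / dy))
    ox, oy = np.meshgrid(np.arange(-nx, nx + 1) * dx, np.arange(-ny, ny + 1) * dy)
    w = kernel.density_at(np.hypot(ox, oy))
    if edge == "renormalize":
        num = ndimage.convolve(map.values, w, mode="constant", cval=0.0)
        den = ndimage.convolve(np.ones_like(map.values), w, mode="constant", cval=0.0)
        out = num / den
    else:
        out = ndimage.convolve(map.values, w * map.cell_area, mode="constant", cval=0.0)
    return replace(map, values=out)


def sample_nearby_point(
    map: RasterMap,
    x,
    kernel: Kernel,
    rng: np.random.Generator,
    max_tries: int = 200,
    allow_fail: bool = False,
):
    """Sample points y with density proportional to ``m(y) * rho((y-x)/sigma)``.

    Rejection sampling: propose from the kernel truncated at its
    ``max_distance``, accept with probability ``m(y) / m_max``.  ``x`` may be
    a single location or an (n, 2) array (one draw per row).  When no
    positive map mass is reachable this raises, unless ``allow_fail`` is
    set, in which case the failed rows are returned as NaN.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    pts = np.atleast_2d(x).astype(float)
    if np.any(map.values < 0):
        raise ValueError("sample_nearby_point needs a nonnegative map")
    m_max = float(map.values.max())
    if m_max <= 0:
        raise ValueError("map has no positive mass anywhere")
    out = np.full_like(pts, np.nan)
    active = np.arange(pts.shape[0])
    for _ in range(max_tries):
        if active.size == 0:
            break
        prop = pts[active] + kernel.sample(active.size, rng, truncate=True)
        m = np.maximum(map.value_at(prop), 0.0)
        # the map's weight is zero outside its domain (lookups clamp, but a
        # sampled destination must actually lie on the map)
        m = np.where(map.bounds.contains(prop), m, 0.0)
        acc = rng.random(active.size) * m_max < m
        out[active[acc]] = prop[acc]
        active = active[~acc]
    if active.size and not allow_fail:
        raise RuntimeError(
            f"rejection sampling failed for {active.size} points after "
            f"{max_tries} rounds: no positive map mass within "
            f"{kernel.max_distance} of those locations?"
        )
    return out[0] if scalar else out
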