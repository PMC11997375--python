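"""Synthetic landscape generators.

These emulate the kinds of rasters real studies pull from GIS sources —
a conical mountain (elevation / elevation-driven carrying capacity), a
meandering river mask (aquatic habitat), a smooth precipitation gradient —
without shipping any imagery: everything is produced programmatically on a
requested grid and can be written to CSV/PNG with the landscape writers.
All are synthetic stand-ins, not digitizations of any real landscape.
"""

from __future__ import annotations

import numpy as np

from .kernels import Bounds
from .landscape import RasterMap

__all__ = [
    "uniform_map",
    "cone_map",
    "river_mask_map",
    "gradient_map",
    "seasonal_sinusoid",
]


def _grid(bounds: Bounds, rows: int, cols: int):
    dx = bounds.width / cols
    dy = bounds.height / rows
    xs = bounds.x_min + (np.arange(cols) + 0.5) * dx
    ys = bounds.y_max - (np.arange(rows) + 0.5) * dy
    return np.meshgrid(xs, ys)


def uniform_map(bounds: Bounds, value: float = 1.0, rows: int = 32, cols: int = 32) -> RasterMap:
    """A constant map (the homogeneous-landscape baseline)."""
    return RasterMap(np.full((rows, cols), float(value)), bounds)


def cone_map(
    bounds: Bounds,
    peak: float = 12.0,
    rows: int = 40,
    cols: int = 50,
    center=None,
    radius: float | None = None,
) -> RasterMap:
    """A conical mountain: ``peak`` at the center, declining linearly to 0
    at ``radius`` (default: half the smaller domain side) and 0 beyond."""
    cx = (bounds.x_min + bounds.x_max) / 2 if center is None else center[0]
    cy = (bounds.y_min + bounds.y_max) / 2 if center is None else center[1]
    if radius is None:
        radius = min(bounds.width, bounds.height) / 2.0
    X, Y = _grid(bounds, rows, cols)
    r = np.hypot(X - cx, Y - cy)
    return RasterMap(peak * np.clip(1.0 - r / radius, 0.0, None), bounds)


def river_mask_map(
    bounds: Bounds,
    width: float = 1.0,
    amplitude: float | None = None,
    wavelength: float | None = None,
    value: float = 1.0,
    rows: int = 40,
    cols: int = 60,
) -> RasterMap:
    """A binary mask tracing a sinusoidal river across the domain: ``value``
    within ``width``/2 of the channel centerline, 0 elsewhere."""
    if amplitude is None:
        amplitude = bounds.height / 4.0
    if wavelength is None:
        wavelength = bounds.width / 1.5
    X, Y = _grid(bounds, rows, cols)
    mid = (bounds.y_min + bounds.y_max) / 2.0
    channel = mid + amplitude * np.sin(2 * np.pi * (X - bounds.x_min) / wavelength)
    return RasterMap(np.where(np.abs(Y - channel) <= width / 2.0, value, 0.0), bounds)


def gradient_map(
    bounds: Bounds,
    lo: float = 0.0,
    hi: float = 1.0,
    axis: str = "x",
    rows: int = 40,
    cols: int = 40,
) -> RasterMap:
    """A linear gradient from ``lo`` to ``hi`` along x or y (e.g. a
    precipitation field for habitat-suitability survival modifiers)."""
    X, Y = _grid(bounds, rows, cols)
    if axis == "x":
        t = (X - bounds.x_min) / bounds.width
    elif axis == "y":
        t = (Y - bounds.y_min) / bounds.height
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return RasterMap(lo + (hi - lo) * t, bounds)


def seasonal_sinusoid(t, amplitude: float, period: float = 365.0, phase: float = 0.0):
    """A seasonal forcing with minimum 0 and maximum ``amplitude``:
    amplitude * (1 - cos(2 pi (t - phase) / period)) / 2."""
    t = np.asarray(t, dtype=float)
    out = amplitude * (1.0 - np.cos(2.0 * np.pi * (t - phase) / period)) / 2.0
    return out if out.ndim else float(out)
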