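"""Measurement toolkit for spatial simulations: neighborhood sizes, the
pair correlation function, mark connection functions, isolation-by-distance
curves, realized-density rasters, and the adaptive density tuner.

Neighborhood sizes are order-of-magnitude diagnostics: 4*pi*sigma^2*K is
roughly the number of other individuals within a circle of radius 2*sigma
at equilibrium.  Small mating neighborhoods (NM < 5) flag mate limitation;
small interaction neighborhoods (NX < 5) flag noisy local density and
elevated local-extinction risk; Wright's NW (from the effective dispersal
scale, if an estimate is supplied) measures the strength of local drift.

The pair correlation function g(r) is the density of pairs at distance r
relative to a Poisson pattern of the same intensity (1.0 = no clumping).
The default estimator uses the translation edge correction, which is
unbiased on rectangles; a torus option is available when patterns are
generated with periodic wrapping.

Mark connection proportions are reported in the *ordered-pair* convention:
the cross curve is the probability that an ordered pair at distance r is
(mark1, mark2), so for every bin

    2 * cross + same1 + same2 = 1       (exactly)

and random labeling with mark-1 probability p gives cross = p(1-p),
same1 = p^2, same2 = (1-p)^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .kernels import Bounds
from .genetics import genetic_distance_matrix
from .landscape import RasterMap

__all__ = [
    "NeighborhoodReport",
    "CurveEstimate",
    "neighborhood_sizes",
    "pair_correlation",
    "mark_connection",
    "ibd_curve",
    "density_raster",
    "adaptive_tuner",
]


@dataclass
class NeighborhoodReport:
    """NM, NX (and optionally NW): 4*pi*sigma^2*K for each scale."""

    NM: float
    NX: float
    NW: float | None = None
    warnings: tuple = ()


@dataclass
class CurveEstimate:
    """A binned distance curve with pair counts and a Monte Carlo
    standard-error estimate per bin (Poisson approximation on the pair
    counts; NaN where a bin is empty)."""

    bin_centers: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    mc_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "value": self.values,
                "n_pairs": self.n_pairs,
                "mc_sd": self.mc_sd,
            }
        )


def neighborhood_sizes(
    sigma_M: float, sigma_X: float, K: float, sigma_eff: float | None = None
) -> NeighborhoodReport:
    """Mating, interaction and (optionally) Wright neighborhood sizes.

    Emits a warning when NM < 5 (mate limitation likely) or NX < 5 (local
    density is noisy)."""
    for name, v in [("sigma_M", sigma_M), ("sigma_X", sigma_X), ("K", K)]:
        if not v > 0:
            raise ValueError(f"{name} must be positive (got {v})")
    if sigma_eff is not None and not sigma_eff > 0:
        raise ValueError("sigma_eff must be positive")
    NM = 4.0 * np.pi * sigma_M**2 * K
    NX = 4.0 * np.pi * sigma_X**2 * K
    NW = 4.0 * np.pi * sigma_eff**2 * K if sigma_eff is not None else None
    notes = []
    if NM < 5:
        notes.append(f"NM={NM:.2f} < 5: mate limitation may be a problem")
    if NX < 5:
        notes.append(f"NX={NX:.2f} < 5: local density will be noisy")
    for msg in notes:
        warnings.warn(msg, stacklevel=2)
    return NeighborhoodReport(NM=float(NM), NX=float(NX), NW=NW, warnings=tuple(notes))


# ---------------------------------------------------------------------------
# pair machinery


def _pairs_within(points, r_max, bounds: Bounds | None, torus: bool):
    """(i, j, distance) over unordered pairs with d <= r_max."""
    x = np.asarray(points, dtype=float)
    if torus:
        if bounds is None:
            raise ValueError("torus distances need bounds")
        period = (bounds.width, bounds.height)
        shifted = np.mod(x - [bounds.x_min, bounds.y_min], period)
        tree = cKDTree(shifted, boxsize=period)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if len(pairs) == 0:
            return pairs[:, 0] if len(pairs) else np.zeros(0, int), np.zeros(0, int), np.zeros(0)
        d = np.abs(shifted[pairs[:, 0]] - shifted[pairs[:, 1]])
        d = np.minimum(d, period - d)
        return pairs[:, 0], pairs[:, 1], np.hypot(d[:, 0], d[:, 1])
    tree = cKDTree(x)
    pairs = tree.query_pairs(r_max, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros(0, int), np.zeros(0, int), np.zeros(0)
    diff = x[pairs[:, 0]] - x[pairs[:, 1]]
    return pairs[:, 0], pairs[:, 1], np.hypot(diff[:, 0], diff[:, 1])


def _make_edges(bins, r_max):
    if np.isscalar(bins):
        return np.linspace(0.0, r_max, int(bins) + 1)
    return np.asarray(bins, dtype=float)


def pair_correlation(
    points,
    bounds: Bounds,
    bins=30,
    r_max: float | None = None,
    correction: str = "translation",
) -> CurveEstimate:
    """Pair correlation function g(r) with translation edge correction.

    ``bins`` may be a count (equal-width bins up to ``r_max``, default a
    quarter of the smaller domain side) or explicit edges.  Completely
    random (CSR) patterns give g = 1 in every bin.  ``correction="torus"``
    uses periodic distances and no edge weighting."""
    x = np.asarray(points, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    if bounds.area <= 0:
        raise ValueError("degenerate bounds")
    if correction not in ("translation", "torus"):
        raise ValueError(f"unknown edge correction {correction!r}")
    if r_max is None:
        r_max = min(bounds.width, bounds.height) / 4.0
    edges = _make_edges(bins, r_max)
    i, j, d = _pairs_within(x, edges[-1], bounds, torus=correction == "torus")
    centers = 0.5 * (edges[:-1] + edges[1:])
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    lam2 = n * (n - 1) / bounds.area**2  # unbiased lambda^2 under CSR
    which = np.digitize(d, edges) - 1
    ok = (which >= 0) & (which < len(centers))
    if correction == "translation":
        dx = np.abs(x[i, 0] - x[j, 0])
        dy = np.abs(x[i, 1] - x[j, 1])
        w = 1.0 / ((bounds.width - dx) * (bounds.height - dy))
    else:
        w = np.full(len(d), 1.0 / bounds.area)
    num = np.bincount(which[ok], weights=w[ok], minlength=len(centers))
    npairs = np.bincount(which[ok], minlength=len(centers))
    # ordered pairs = 2 x unordered
    values = 2.0 * num / (lam2 * annulus)
    with np.errstate(divide="ignore", invalid="ignore"):
        mc_sd = np.where(npairs > 0, values / np.sqrt(np.maximum(npairs, 1)), np.nan)
    return CurveEstimate(centers, values, npairs, mc_sd)


def mark_connection(points, marks, bounds: Bounds, bins=20, r_max: float | None = None):
    """Mark connection proportions for binary marks.

    Returns a dict with keys ``cross``, ``same1``, ``same2`` (mark values
    are sorted; mark1 = smaller).  ``cross`` is the ordered-pair proportion,
    so 2*cross + same1 + same2 = 1 holds exactly in every nonempty bin;
    empty bins carry NaN values (flagged via n_pairs = 0)."""
    x = np.asarray(points, dtype=float)
    marks = np.asarray(marks)
    if x.shape[0] < 2:
        raise ValueError("need at least two points")
    levels = np.unique(marks)
    if len(levels) > 2:
        raise ValueError("mark connection implemented for binary marks")
    is1 = marks == levels[0]
    if r_max is None:
        r_max = min(bounds.width, bounds.height) / 4.0
    edges = _make_edges(bins, r_max)
    centers = 0.5 * (edges[:-1] + edges[1:])
    i, j, d = _pairs_within(x, edges[-1], bounds, torus=False)
    which = np.digitize(d, edges) - 1
    ok = (which >= 0) & (which < len(centers))
    which, i, j = which[ok], i[ok], j[ok]
    both1 = is1[i] & is1[j]
    both2 = ~is1[i] & ~is1[j]
    mixed = ~(both1 | both2)
    nb = len(centers)
    n_all = np.bincount(which, minlength=nb).astype(float)
    n_11 = np.bincount(which[both1], minlength=nb)
    n_22 = np.bincount(which[both2], minlength=nb)
    n_12 = np.bincount(which[mixed], minlength=nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cross = np.where(n_all > 0, n_12 / (2.0 * n_all), np.nan)
        p_11 = np.where(n_all > 0, n_11 / n_all, np.nan)
        p_22 = np.where(n_all > 0, n_22 / n_all, np.nan)
        sd = lambda p: np.where(
            n_all > 0, np.sqrt(np.maximum(p * (1 - p), 0.0) / np.maximum(n_all, 1)), np.nan
        )
    return {
        "cross": CurveEstimate(centers, p_cross, n_12, sd(p_cross)),
        "same1": CurveEstimate(centers, p_11, n_11, sd(p_11)),
        "same2": CurveEstimate(centers, p_22, n_22, sd(p_22)),
    }


def ibd_curve(
    points,
    genotypes,
    bins=20,
    r_max: float | None = None,
    max_individuals: int = 1000,
    rng: np.random.Generator | None = None,
) -> CurveEstimate:
    """Isolation by distance: mean pairwise genetic distance (proportion of
    neutral-allele differences) per geographic-distance bin.  Subsamples to
    ``max_individuals`` for large snapshots."""
    x = np.asarray(points, dtype=float)
    g = np.asarray(genotypes)
    if x.shape[0] != g.shape[0]:
        raise ValueError("points and genotypes disagree in length")
    n = x.shape[0]
    if n > max_individuals:
        rng = rng or np.random.default_rng(0)
        sel = rng.choice(n, size=max_individuals, replace=False)
        x, g = x[sel], g[sel]
        n = max_individuals
    gd = genetic_distance_matrix(g)
    iu = np.triu_indices(n, k=1)
    geo = np.hypot(x[iu[0], 0] - x[iu[1], 0], x[iu[0], 1] - x[iu[1], 1])
    gen = gd[iu]
    if r_max is None:
        r_max = float(geo.max())
    edges = _make_edges(bins, r_max)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(geo, edges) - 1
    ok = (which >= 0) & (which < len(centers))
    which, gen = which[ok], gen[ok]
    nb = len(centers)
    cnt = np.bincount(which, minlength=nb).astype(float)
    tot = np.bincount(which, weights=gen, minlength=nb)
    tot2 = np.bincount(which, weights=gen**2, minlength=nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(cnt > 0, tot / cnt, np.nan)
        var = np.where(cnt > 1, tot2 / cnt - mean**2, np.nan)
        sd = np.sqrt(np.maximum(var, 0.0) / np.maximum(cnt, 1))
    return CurveEstimate(centers, mean, cnt.astype(int), sd)


def density_raster(points, bounds: Bounds, grid_dims) -> RasterMap:
    """Per-cell individual count divided by cell area; sum(value x area)
    equals the census exactly.  ``grid_dims`` = (rows, cols)."""
    rows, cols = grid_dims
    if rows < 1 or cols < 1:
        raise ValueError("grid_dims must be at least (1, 1)")
    x = np.atleast_2d(np.asarray(points, dtype=float)) if len(points) else np.zeros((0, 2))
    counts, _, _ = np.histogram2d(
        x[:, 0],
        x[:, 1],
        bins=[cols, rows],
        range=[[bounds.x_min, bounds.x_max], [bounds.y_min, bounds.y_max]],
    )
    values = counts.T[::-1]  # row 0 = y_max
    cell_area = (bounds.width / cols) * (bounds.height / rows)
    return RasterMap(values / cell_area, bounds)


def adaptive_tuner(adj: float, observed_density: float, K: float, alpha: float) -> float:
    """One update of the adaptive regulation multiplier:
    adj * exp(alpha * (observed - K)).

    The engine applies ``adj`` as survival scaling 1/(1 + adj*f*u); when the
    observed global density exceeds K the multiplier grows, strengthening
    regulation.  Tuning should stop after a burn-in: left on, it would
    cancel genuine responses to changing conditions."""
    if alpha <= 0 or adj <= 0:
        raise ValueError("alpha and adj must be positive")
    return float(adj * np.exp(alpha * (observed_density - K)))
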