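"""Two-dimensional interaction, dispersal, mating and movement kernels.

A kernel is a radially symmetric probability density over the plane,
parameterised by a family, a scale sigma, and a truncation radius
``max_distance`` (default 3*sigma).  The same object plays the roles of the
interaction scale (who counts toward local density), the dispersal scale
(how far offspring land from parents), the mating scale (how far away mates
are drawn from) and the movement scale (per-tick adult displacement) —
only the value of sigma and the use differ.

Families
--------
``gaussian``
    The bivariate normal density with per-axis standard deviation sigma.
``t`` (alias ``t_cross_section``)
    The density formed by rotating the Student-t cross section about the
    origin: proportional to ``(1 + ||x/sigma||^2/df)^(-(df+1)/2)``.  Note
    this is *not* the bivariate t; it has a closed-form normalising
    constant ``(df-1) / (2 pi df sigma^2)`` valid for df > 1.  The smaller
    ``df``, the more likely extremely long displacements are.
``flat``
    Constant on the disc of radius ``max_distance``, zero outside, mass 1.

Truncation applies to density *evaluation* (interactions are ignored
beyond ``max_distance``, with no renormalisation so the lost Gaussian mass
at the default 3*sigma is about 1.1%).  Displacement *sampling* is from the
untruncated kernel by default, matching how dispersal is usually simulated;
pass ``truncate=True`` for draws conditioned to land within
``max_distance``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Kernel",
    "Bounds",
    "kernel_density",
    "sample_displacement",
    "apply_boundary",
    "ReprisingError",
]

_FAMILIES = ("gaussian", "t", "flat")
_ALIASES = {"t_cross_section": "t", "normal": "gaussian", "n": "gaussian", "f": "flat"}

REPRISING_RETRY_CAP = 1000


class ReprisingError(RuntimeError):
    """Raised when conditioned (reprising) resampling fails to land inside
    the domain within the retry cap — a kernel/bounds mismatch (e.g. the
    kernel scale is enormous compared to the domain)."""


@dataclass(frozen=True)
class Kernel:
    """A radially symmetric 2D kernel with scale ``scale`` and truncation
    radius ``max_distance`` (defaults to ``3 * scale``)."""

    family: str
    scale: float
    df: float | None = None
    max_distance: float | None = None

    def __post_init__(self):
        fam = _ALIASES.get(self.family, self.family)
        object.__setattr__(self, "family", fam)
        if fam not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {_FAMILIES}")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("kernel scale must be a positive finite length")
        if self.max_distance is None:
            object.__setattr__(self, "max_distance", 3.0 * self.scale)
        if not (np.isfinite(self.max_distance) and self.max_distance > 0):
            raise ValueError("max_distance must be positive and finite")
        if fam == "t":
            if self.df is None or not np.isfinite(self.df) or self.df <= 1:
                # df <= 1 gives a non-normalizable density in 2D
                raise ValueError("t kernel requires finite df > 1")
        elif self.df is not None:
            raise ValueError(f"df is only meaningful for the t family, not {fam!r}")

    # -- density ---------------------------------------------------------

    def density_at(self, r, truncate: bool = True):
        """Kernel density (per unit area) at radial distance ``r``.

        Zero beyond ``max_distance`` unless ``truncate=False``.
        """
        r = np.asarray(r, dtype=float)
        if not np.all(np.isfinite(r)):
            raise ValueError("non-finite distance passed to kernel density")
        return self._density_r2(r**2, truncate=truncate)

    def _density_r2(self, r2, truncate: bool = True):
        """Density as a function of squared distance (hot-path form: every
        family depends on the displacement only through its norm)."""
        r2 = np.asarray(r2, dtype=float)
        s2 = self.scale**2
        if self.family == "gaussian":
            out = np.exp(-0.5 * r2 / s2) / (2.0 * np.pi * s2)
        elif self.family == "t":
            df = self.df
            norm = (df - 1.0) / (2.0 * np.pi * df * s2)
            out = norm * (1.0 + r2 / (df * s2)) ** (-(df + 1.0) / 2.0)
        else:  # flat: the disc of radius max_distance IS the support
            out = np.where(
                r2 <= self.max_distance**2, 1.0 / (np.pi * self.max_distance**2), 0.0
            )
        if truncate:
            out = np.where(r2 <= self.max_distance**2, out, 0.0)
        return out if out.ndim else float(out)

    def density(self, displacement, truncate: bool = True):
        """Kernel density at 2D ``displacement`` (shape (..., 2))."""
        d = np.asarray(displacement, dtype=float)
        if d.shape[-1] != 2:
            raise ValueError("displacement must have a trailing dimension of 2")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite displacement")
        return self.density_at(np.linalg.norm(d, axis=-1), truncate=truncate)

    def truncated_mass(self) -> float:
        """Total kernel mass within ``max_distance`` (<= 1)."""
        R = self.max_distance
        s2 = self.scale**2
        if self.family == "gaussian":
            return 1.0 - np.exp(-0.5 * R**2 / s2)
        if self.family == "t":
            return 1.0 - (1.0 + R**2 / (self.df * s2)) ** (-(self.df - 1.0) / 2.0)
        return 1.0

    # -- sampling --------------------------------------------------------

    def sample_radius(self, n: int, rng: np.random.Generator, truncate: bool = False):
        """Draw ``n`` radial distances from the radial marginal by inverse CDF."""
        u = rng.random(n)
        if truncate:
            u = u * self.radial_cdf(self.max_distance)
        s2 = self.scale**2
        if self.family == "gaussian":
            return np.sqrt(-2.0 * s2 * np.log1p(-u))
        if self.family == "t":
            p = (self.df - 1.0) / 2.0
            return np.sqrt(self.df * s2 * ((1.0 - u) ** (-1.0 / p) - 1.0))
        return self.max_distance * np.sqrt(u)

    def radial_cdf(self, r):
        """CDF of the (untruncated) radial distance ||X||."""
        r = np.asarray(r, dtype=float)
        s2 = self.scale**2
        if self.family == "gaussian":
            return 1.0 - np.exp(-0.5 * r**2 / s2)
        if self.family == "t":
            return 1.0 - (1.0 + r**2 / (self.df * s2)) ** (-(self.df - 1.0) / 2.0)
        return np.clip(r / self.max_distance, 0.0, 1.0) ** 2

    def sample(self, n: int, rng: np.random.Generator, truncate: bool = False):
        """Draw ``n`` i.i.d. 2D displacements.

        Construction is rotationally symmetric by design: the Gaussian uses
        independent normal coordinates (already symmetric); the other
        families draw a radius from the radial marginal and an angle
        uniform on [0, 2*pi).  Drawing each coordinate independently from a
        1D t would *not* be rotationally symmetric.
        """
        if n < 0:
            raise ValueError("n must be nonnegative")
        if self.family == "gaussian" and not truncate:
            return rng.normal(0.0, self.scale, size=(n, 2))
        r = self.sample_radius(n, rng, truncate=truncate)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


@dataclass(frozen=True)
class Bounds:
    """Rectangular simulation domain with a boundary-condition mode.

    Modes: ``reflecting`` (fold back in), ``absorbing`` (points outside are
    removed), ``reprising`` (the displacement is redrawn, conditioned on
    landing inside) and ``stopping`` (clamp to the nearest edge).
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    boundary_mode: str = "reprising"

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("bounds must satisfy x_min < x_max and y_min < y_max")
        if self.boundary_mode not in ("reflecting", "absorbing", "reprising", "stopping"):
            raise ValueError(f"unknown boundary mode {self.boundary_mode!r}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, points):
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (p[:, 0] >= self.x_min)
            & (p[:, 0] <= self.x_max)
            & (p[:, 1] >= self.y_min)
            & (p[:, 1] <= self.y_max)
        )

    def sample_uniform(self, n: int, rng: np.random.Generator):
        return np.column_stack(
            [
                rng.uniform(self.x_min, self.x_max, size=n),
                rng.uniform(self.y_min, self.y_max, size=n),
            ]
        )


# ---------------------------------------------------------------------------
# module-level operation wrappers


def kernel_density(kernel: Kernel, displacement):
    """Per-area weight rho(d/sigma)/sigma^2 of the kernel at ``displacement``;
    zero beyond the truncation radius."""
    return kernel.density(displacement)


def sample_displacement(kernel: Kernel, n: int, rng: np.random.Generator):
    """Draw ``n`` i.i.d. 2D displacement vectors from the (untruncated) kernel."""
    return kernel.sample(n, rng)


def _fold(values, lo, hi):
    """Reflect values into [lo, hi] by iterated folding (period 2*(hi-lo))."""
    span = hi - lo
    v = np.mod(values - lo, 2.0 * span)
    v = np.where(v > span, 2.0 * span - v, v)
    return v + lo


def apply_boundary(points, origins, bounds: Bounds, rng=None, kernel: Kernel | None = None):
    """Apply the bounds' boundary condition to proposed ``points``.

    ``origins`` are the launch positions (needed for reprising, where the
    displacement is redrawn from ``kernel`` conditioned on landing inside —
    resampled, never clipped).  Returns ``(new_points, keep)`` where
    ``keep`` is False only for absorbed points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    org = np.atleast_2d(np.asarray(origins, dtype=float))
    if org.shape[0] == 1 and pts.shape[0] > 1:
        org = np.broadcast_to(org, pts.shape).copy()
    keep = np.ones(pts.shape[0], dtype=bool)
    mode = bounds.boundary_mode

    if mode == "reflecting":
        pts[:, 0] = _fold(pts[:, 0], bounds.x_min, bounds.x_max)
        pts[:, 1] = _fold(pts[:, 1], bounds.y_min, bounds.y_max)
    elif mode == "stopping":
        pts[:, 0] = np.clip(pts[:, 0], bounds.x_min, bounds.x_max)
        pts[:, 1] = np.clip(pts[:, 1], bounds.y_min, bounds.y_max)
    elif mode == "absorbing":
        keep = bounds.contains(pts)
    elif mode == "reprising":
        if kernel is None or rng is None:
            raise ValueError("reprising boundaries need the kernel and an rng to redraw from")
        outside = ~bounds.contains(pts)
        tries = 0
        while outside.any():
            tries += 1
            if tries > REPRISING_RETRY_CAP:
                raise ReprisingError(
                    f"reprising failed after {REPRISING_RETRY_CAP} redraws for "
                    f"{int(outside.sum())} points: kernel scale {kernel.scale} is "
                    f"degenerate relative to bounds {bounds}"
                )
            idx = np.flatnonzero(outside)
            pts[idx] = org[idx] + kernel.sample(len(idx), rng)
            outside[idx] = ~bounds.contains(pts[idx])
    return pts, keep
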