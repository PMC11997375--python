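"""The per-tick simulation cycle: reproduction, movement, density, survival.

The life cycle follows the usual order for overlapping-generation
individual-based simulations: (1) mate choice, reproduction and offspring
dispersal; (2) adult movement; (3) local-density computation; (4) density-
dependent survival.  Census statistics are recorded at the *start* of a
tick, i.e. before reproduction, which is the phase the carrying-capacity
parameter K is calibrated to: the local density used for survival is
measured after reproduction, so it is divided by (1 + f-bar) as well as K
when converting to scaled density u (f-bar = f(1), the equilibrium
fecundity), and newly produced juveniles — and each individual itself —
count toward it.

Local density can be computed exactly (KD-tree range queries summing kernel
weights over every pair within the truncation radius) or via a grid
approximation (bin counts per unit area, smooth with the interaction
kernel, look the value up at each position), which agrees with the exact
computation to a few percent when cells are at most sigma_X/2 across.
Mate choice has the same two routes.

Everything stochastic draws from generators derived deterministically from
(seed, tick, stage), so a fixed seed reproduces a trajectory bit for bit
and adding a diagnostic never perturbs it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .genetics import SelectionModel, clone, inherit
from .kernels import Bounds, Kernel, apply_boundary
from .landscape import RasterMap, sample_nearby_point, smooth_map
from .regulation import RegulationModel

__all__ = [
    "SimConfig",
    "PopulationState",
    "RunResult",
    "Simulation",
    "local_density_exact",
    "local_density_grid",
    "choose_mate",
    "choose_mate_grid",
    "run",
]

FEMALE, MALE, NO_SEX = 0, 1, 2
K_FLOOR = 1e-6  # carrying-capacity floor in uninhabitable cells


# ---------------------------------------------------------------------------
# state


@dataclass
class PopulationState:
    """Struct-of-arrays population state (one row per individual)."""

    x: np.ndarray          # (n, 2) positions
    sex: np.ndarray        # int8: 0 female, 1 male, 2 none
    age: np.ndarray        # int32 ticks survived
    genotype: np.ndarray   # (n, L) allele counts in {0, 1, 2}
    ids: np.ndarray        # int64 unique
    u: np.ndarray          # cached scaled density from the last survival phase
    tagF: np.ndarray       # resource tally (resource-explicit models)
    bounds: Bounds
    tick: int = 0
    next_id: int = 0

    @property
    def census(self) -> int:
        return self.x.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotype.shape[1]

    def allele_frequency(self, locus: int = 0) -> float:
        if self.census == 0:
            return float("nan")
        return float(self.genotype[:, locus].sum() / (2.0 * self.census))

    def subset(self, mask) -> "PopulationState":
        return replace(
            self,
            x=self.x[mask],
            sex=self.sex[mask],
            age=self.age[mask],
            genotype=self.genotype[mask],
            ids=self.ids[mask],
            u=self.u[mask],
            tagF=self.tagF[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "x": self.x[:, 0],
                "y": self.x[:, 1],
                "sex": pd.Categorical.from_codes(
                    self.sex, categories=["F", "M", "none"]
                ),
                "age": self.age,
            }
        )
        for l in range(self.n_loci):
            df[f"k{l}"] = self.genotype[:, l]
        return df


@dataclass(kw_only=True)
class SimConfig:
    """Everything that defines a run.  ``seed`` fixes the full trajectory."""

    bounds: Bounds
    K: float
    regulation: RegulationModel
    interaction: Kernel
    dispersal: Kernel
    mating: Kernel | None = None          # None -> asexual (clonal) reproduction
    movement: Kernel | None = None        # None -> sessile adults
    selection: SelectionModel = field(default_factory=SelectionModel)
    k_map: RasterMap | None = None        # carrying capacity K(x); overrides K locally
    fecundity_map: RasterMap | None = None    # multiplicative modifier on fecundity
    survival_map: RasterMap | None = None     # multiplicative modifier on survival
    survival_modifier: Callable | None = None  # fn(pop, tick, rng) -> per-individual factor
    dioecious: bool = False
    min_mating_age: int = 0
    seed: int = 0
    fast_mode: bool = False               # grid-accelerated density and mate choice
    cell_size: float | None = None        # density grid cell; default interaction.scale / 2
    nonspatial: bool = False              # global density substituted for local
    n_loci: int = 1
    initial_allele_freq: float = 0.0      # locus 0
    initial_neutral_freq: float = 0.5     # loci 1..L-1
    tuner_alpha: float | None = None      # enable Box-6 style adaptive density tuning
    tuner_burn_in: int = 0                # tuning stops at this tick (0 = never tune)
    mate_cap_radius: float | None = None  # grid mate choice search cap

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.n_loci < 1:
            raise ValueError("need at least the selected locus (n_loci >= 1)")


@dataclass
class RunResult:
    """Per-tick record of a run: census and summary statistics (measured
    before reproduction), optional individual snapshots, extinction flag."""

    timeseries: pd.DataFrame
    snapshots: dict
    extinct: bool
    final: PopulationState
    config: SimConfig


# ---------------------------------------------------------------------------
# local density


def local_density_exact(positions, kernel: Kernel, torus: Bounds | None = None):
    """Kernel-smoothed local density n(x_i) at every individual.

    n(x_i) = sum_j rho_sigma(x_i - x_j) over all j *including* j = i,
    restricted to pairs within the kernel's max_distance.  ``torus`` wraps
    distances periodically over the given bounds (useful for edge-free
    expectations)."""
    x = np.asarray(positions, dtype=float)
    n = x.shape[0]
    self_term = kernel.density_at(0.0)
    if n == 0:
        return np.zeros(0)
    out = np.full(n, self_term)
    if n == 1:
        return out
    if torus is not None:
        period = (torus.width, torus.height)
        shifted = x - [torus.x_min, torus.y_min]
        tree = cKDTree(np.mod(shifted, period), boxsize=period)
        pairs = tree.query_pairs(kernel.max_distance, output_type="ndarray")
        if len(pairs):
            d = np.abs(shifted[pairs[:, 0]] - shifted[pairs[:, 1]])
            d = np.minimum(d, period - d)
            dist2 = d[:, 0] ** 2 + d[:, 1] ** 2
    else:
        tree = cKDTree(x)
        pairs = tree.query_pairs(kernel.max_distance, output_type="ndarray")
        if len(pairs):
            diff = x[pairs[:, 0]] - x[pairs[:, 1]]
            dist2 = diff[:, 0] ** 2 + diff[:, 1] ** 2
    if len(pairs):
        w = kernel._density_r2(dist2)
        out += np.bincount(pairs[:, 0], weights=w, minlength=n)
        out += np.bincount(pairs[:, 1], weights=w, minlength=n)
    return out


def density_count_map(
    positions, bounds: Bounds, cell_size: float, deposit: str = "nearest"
) -> RasterMap:
    """Per-unit-area count raster at the given cell size.

    ``deposit="nearest"`` bins each individual into the cell containing it;
    ``deposit="linear"`` splits each individual bilinearly over the four
    nearest cell centers (cloud-in-cell), which removes most of the
    position-quantization noise when the raster is later smoothed into a
    local-density field."""
    ncol = max(int(np.ceil(bounds.width / cell_size)), 1)
    nrow = max(int(np.ceil(bounds.height / cell_size)), 1)
    x = np.atleast_2d(np.asarray(positions, dtype=float)) if len(positions) else np.zeros((0, 2))
    dx = bounds.width / ncol
    dy = bounds.height / nrow
    if deposit == "nearest" or x.shape[0] == 0:
        counts, _, _ = np.histogram2d(
            x[:, 0],
            x[:, 1],
            bins=[ncol, nrow],
            range=[[bounds.x_min, bounds.x_max], [bounds.y_min, bounds.y_max]],
        )
        # histogram2d returns (x-bins, y-bins); transpose, flip rows so row 0 = y_max
        values = counts.T[::-1]
    elif deposit == "linear":
        fc = (x[:, 0] - bounds.x_min) / dx - 0.5
        fr = (bounds.y_max - x[:, 1]) / dy - 0.5
        c0 = np.floor(fc).astype(int)
        r0 = np.floor(fr).astype(int)
        wc = fc - c0
        wr = fr - r0
        values = np.zeros(nrow * ncol)
        for dr, dc, w in (
            (0, 0, (1 - wr) * (1 - wc)),
            (0, 1, (1 - wr) * wc),
            (1, 0, wr * (1 - wc)),
            (1, 1, wr * wc),
        ):
            r = np.clip(r0 + dr, 0, nrow - 1)
            cc = np.clip(c0 + dc, 0, ncol - 1)
            values += np.bincount(r * ncol + cc, weights=w, minlength=nrow * ncol)
        values = values.reshape(nrow, ncol)
    else:
        raise ValueError("deposit must be 'nearest' or 'linear'")
    return RasterMap(values / (dx * dy), bounds)


def local_density_grid(
    positions, kernel: Kernel, bounds: Bounds, cell_size: float | None = None
):
    """Grid-accelerated local density: bin to a per-area count map, smooth
    with the interaction kernel (zero-padded: density really is depressed at
    edges), then interpolate at each individual's position.

    Returns (per-individual densities, the smoothed RasterMap)."""
    if cell_size is None:
        cell_size = kernel.scale / 2.0
    if cell_size > kernel.scale / 2.0 + 1e-12:
        warnings.warn(
            f"density grid cell size {cell_size} exceeds half the interaction "
            f"scale {kernel.scale}; the approximation degrades",
            stacklevel=2,
        )
    raw = density_count_map(positions, bounds, cell_size, deposit="linear")
    smoothed = smooth_map(raw, kernel, edge="zero")
    if len(positions) == 0:
        return np.zeros(0), smoothed
    return smoothed.value_at(positions, mode="bilinear"), smoothed


# ---------------------------------------------------------------------------
# mate choice


def choose_mate(
    chooser_xy,
    candidate_xy,
    kernel: Kernel,
    rng: np.random.Generator,
    exclude_self: bool = False,
):
    """Kernel-weighted mate choice: candidate i within max_distance of a
    chooser is picked with probability rho(d_i/sigma) / sum_j rho(d_j/sigma).

    Returns an int array of candidate indices, -1 where no eligible
    candidate is in range (mate failure — a modeled outcome, not an error).
    ``exclude_self=True`` treats equal indices as the same individual
    (monoecious populations where choosers and candidates are one array)."""
    chooser_xy = np.atleast_2d(np.asarray(chooser_xy, dtype=float))
    candidate_xy = np.atleast_2d(np.asarray(candidate_xy, dtype=float))
    nc = chooser_xy.shape[0]
    mates = np.full(nc, -1, dtype=np.int64)
    if nc == 0 or candidate_xy.shape[0] == 0:
        return mates
    tree_c = cKDTree(chooser_xy)
    tree_m = cKDTree(candidate_xy)
    csr = tree_c.sparse_distance_matrix(
        tree_m, kernel.max_distance, output_type="coo_matrix"
    ).tocsr()  # sorts entries by chooser row
    col, dist, indptr = csr.indices, csr.data, csr.indptr
    w = kernel._density_r2(dist**2)
    if exclude_self:
        self_hit = col == np.repeat(np.arange(nc), np.diff(indptr))
        w = np.where(self_hit, 0.0, w)
    if len(col) == 0:
        return mates
    # weighted draw per row via one uniform + a cumulative-sum search
    cum = np.cumsum(w)
    counts = np.diff(indptr)
    nonempty = np.flatnonzero(counts > 0)
    starts = indptr[:-1][nonempty]
    ends = indptr[1:][nonempty]
    totals = cum[ends - 1] - np.where(starts > 0, cum[starts - 1], 0.0)
    ok = totals > 0  # rows whose only candidate was themselves have zero mass
    nonempty, starts, ends, totals = nonempty[ok], starts[ok], ends[ok], totals[ok]
    if len(nonempty) == 0:
        return mates
    base = np.where(starts > 0, cum[starts - 1], 0.0)
    targets = base + rng.random(len(nonempty)) * totals
    idx = np.clip(np.searchsorted(cum, targets, side="right"), starts, ends - 1)
    mates[nonempty] = col[idx]
    return mates


def choose_mate_grid(
    chooser_xy,
    candidate_xy,
    kernel: Kernel,
    bounds: Bounds,
    rng: np.random.Generator,
    cell_size: float | None = None,
    cap_radius: float | None = None,
    density_map: RasterMap | None = None,
):
    """Grid-accelerated mate choice: sample a point near each chooser with
    density proportional to (candidate density map x mating kernel), then
    take the candidate nearest that point.  Returns candidate indices, -1
    where sampling failed or no candidate lies within ``cap_radius``."""
    chooser_xy = np.atleast_2d(np.asarray(chooser_xy, dtype=float))
    candidate_xy = np.atleast_2d(np.asarray(candidate_xy, dtype=float))
    nc = chooser_xy.shape[0]
    mates = np.full(nc, -1, dtype=np.int64)
    if nc == 0 or candidate_xy.shape[0] == 0:
        return mates
    if cap_radius is None:
        cap_radius = kernel.max_distance
    if density_map is None:
        if cell_size is None:
            cell_size = kernel.scale / 2.0
        raw = density_count_map(candidate_xy, bounds, cell_size, deposit="linear")
        # smooth just enough to fill gaps between candidates: smoothing with
        # the full mating kernel would effectively double the mating scale
        fill = Kernel("gaussian", max(cell_size, kernel.scale / 4.0))
        density_map = smooth_map(raw, fill, edge="zero")
    pts = sample_nearby_point(density_map, chooser_xy, kernel, rng, allow_fail=True)
    ok = np.isfinite(pts[:, 0])
    if ok.any():
        tree = cKDTree(candidate_xy)
        d, idx = tree.query(pts[ok], distance_upper_bound=cap_radius)
        found = np.isfinite(d)
        rows = np.flatnonzero(ok)[found]
        mates[rows] = idx[found]
    return mates


# ---------------------------------------------------------------------------
# the simulation proper


class Simulation:
    """Owns a :class:`PopulationState` and advances it one tick at a time."""

    def __init__(self, config: SimConfig, pop: PopulationState | None = None):
        self.config = config
        self.adj = 1.0  # adaptive-tuner multiplier (Box-6 style)
        self.extinct = False
        self._clip_warned = False
        self.pop = pop if pop is not None else self._initial_population()
        self._init_density()

    # -- rngs ------------------------------------------------------------

    def _rng(self, stage: int, tick: int | None = None) -> np.random.Generator:
        t = self.pop.tick if tick is None else tick
        return np.random.default_rng([int(self.config.seed), int(t), int(stage)])

    # -- setup -----------------------------------------------------------

    def _initial_population(self) -> PopulationState:
        cfg = self.config
        rng = self._rng_init = np.random.default_rng([int(cfg.seed), 0, 99])
        if cfg.k_map is not None:
            n0 = int(round(float(np.sum(cfg.k_map.values)) * cfg.k_map.cell_area))
            x = _sample_map_weighted(cfg.k_map, n0, rng)
        else:
            n0 = int(round(cfg.K * cfg.bounds.area))
            x = cfg.bounds.sample_uniform(n0, rng)
        sex = (
            rng.integers(0, 2, size=n0).astype(np.int8)
            if cfg.dioecious
            else np.full(n0, NO_SEX, dtype=np.int8)
        )
        geno = np.zeros((n0, cfg.n_loci), dtype=np.int8)
        geno[:, 0] = rng.binomial(2, cfg.initial_allele_freq, size=n0)
        if cfg.n_loci > 1:
            geno[:, 1:] = rng.binomial(
                2, cfg.initial_neutral_freq, size=(n0, cfg.n_loci - 1)
            )
        return PopulationState(
            x=x,
            sex=sex,
            age=np.zeros(n0, dtype=np.int32),
            genotype=geno,
            ids=np.arange(n0, dtype=np.int64),
            u=np.zeros(n0),
            tagF=np.zeros(n0),
            bounds=cfg.bounds,
            tick=0,
            next_id=n0,
        )

    def _init_density(self):
        """Cache u from the initial configuration (pre-reproduction, so no
        (1 + f-bar) factor)."""
        pop, cfg = self.pop, self.config
        if pop.census == 0:
            self.extinct = True
            return
        n = self._density(pop.x)
        self.pop.u = n / self._k_local(pop.x)

    # -- helpers ---------------------------------------------------------

    def _density(self, positions):
        cfg = self.config
        if cfg.nonspatial:
            return np.full(len(positions), len(positions) / cfg.bounds.area)
        if cfg.fast_mode:
            dens, _ = local_density_grid(
                positions, cfg.interaction, cfg.bounds, cfg.cell_size
            )
            return dens
        return local_density_exact(positions, cfg.interaction)

    def _k_local(self, positions):
        cfg = self.config
        if cfg.k_map is None:
            return np.full(len(positions), cfg.K)
        return np.maximum(cfg.k_map.value_at(positions), K_FLOOR)

    # -- life-cycle phases ----------------------------------------------

    def reproduce(self):
        """Mate choice, offspring production (Poisson counts from the cached
        scaled density), inheritance and juvenile dispersal."""
        pop, cfg = self.pop, self.config
        rng = self._rng(1)
        if pop.census == 0:
            return
        f_u = cfg.regulation.fecundity(pop.u)
        k = pop.genotype[:, 0]
        if cfg.selection.mode == "fecundity":
            f_u = cfg.selection.fecundity_with_selection(k, f_u)
        if cfg.fecundity_map is not None:
            f_u = f_u * np.maximum(cfg.fecundity_map.value_at(pop.x), 0.0)

        if cfg.dioecious:
            choosers = np.flatnonzero(
                (pop.sex == FEMALE) & (pop.age >= cfg.min_mating_age)
            )
            candidates = np.flatnonzero(
                (pop.sex == MALE) & (pop.age >= cfg.min_mating_age)
            )
            # f is per-capita mean offspring; females bear for both sexes
            lam = 2.0 * np.maximum(f_u[choosers], 0.0)
            exclude_self = False
        else:
            choosers = np.flatnonzero(pop.age >= cfg.min_mating_age)
            candidates = choosers
            lam = np.maximum(f_u[choosers], 0.0)
            exclude_self = True

        sexual = cfg.mating is not None
        if sexual:
            if cfg.nonspatial:
                mates_local = _random_mates(
                    len(choosers), len(candidates), exclude_self, rng
                )
            elif cfg.fast_mode:
                mates_local = choose_mate_grid(
                    pop.x[choosers],
                    pop.x[candidates],
                    cfg.mating,
                    cfg.bounds,
                    rng,
                    cap_radius=cfg.mate_cap_radius,
                )
                if exclude_self:
                    # nearest-individual lookup may return the chooser itself
                    bad = mates_local == np.arange(len(choosers))
                    mates_local[bad] = -1
            else:
                mates_local = choose_mate(
                    pop.x[choosers],
                    pop.x[candidates],
                    cfg.mating,
                    rng,
                    exclude_self=exclude_self,
                )
            lam = np.where(mates_local >= 0, lam, 0.0)
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            return
        par_idx = np.repeat(choosers, counts)
        disp = cfg.dispersal.sample(total, rng)
        newx, keep = apply_boundary(
            pop.x[par_idx] + disp, pop.x[par_idx], cfg.bounds, rng, cfg.dispersal
        )
        if sexual:
            mate_idx = np.asarray(candidates)[np.repeat(mates_local, counts)]
            geno = inherit(
                pop.genotype[par_idx],
                pop.genotype[mate_idx],
                rng,
                cfg.selection.mu_neutral,
            )
        else:
            geno = clone(pop.genotype[par_idx], rng, cfg.selection.mu_neutral)
        sex = (
            rng.integers(0, 2, size=total).astype(np.int8)
            if cfg.dioecious
            else np.full(total, NO_SEX, dtype=np.int8)
        )
        if not keep.all():  # absorbing boundary removed some juveniles
            newx, geno, sex = newx[keep], geno[keep], sex[keep]
            total = newx.shape[0]
        self.pop = replace(
            pop,
            x=np.concatenate([pop.x, newx]),
            sex=np.concatenate([pop.sex, sex]),
            age=np.concatenate([pop.age, np.zeros(total, dtype=np.int32)]),
            genotype=np.concatenate([pop.genotype, geno]),
            ids=np.concatenate(
                [pop.ids, np.arange(pop.next_id, pop.next_id + total, dtype=np.int64)]
            ),
            u=np.concatenate([pop.u, np.zeros(total)]),
            tagF=np.concatenate([pop.tagF, np.zeros(total)]),
            next_id=pop.next_id + total,
        )

    def move(self):
        """Adult movement: displacement sampled from the movement kernel."""
        pop, cfg = self.pop, self.config
        if cfg.movement is None or pop.census == 0:
            return
        rng = self._rng(2)
        movers = pop.age >= 1
        nm = int(movers.sum())
        if nm == 0:
            return
        disp = cfg.movement.sample(nm, rng)
        newx, keep = apply_boundary(
            pop.x[movers] + disp, pop.x[movers], cfg.bounds, rng, cfg.movement
        )
        x = pop.x.copy()
        x[movers] = newx
        self.pop = replace(self.pop, x=x)
        if not keep.all():
            alive = np.ones(pop.census, dtype=bool)
            alive[np.flatnonzero(movers)[~keep]] = False
            self.pop = self.pop.subset(alive)

    def survive(self):
        """Density-dependent viability: density over *all* individuals
        (adults + juveniles), scaled by (1 + f-bar) * K_local, then an
        independent survival coin per individual."""
        pop, cfg = self.pop, self.config
        if pop.census == 0:
            return
        rng = self._rng(3)
        n = self._density(pop.x)
        fbar = cfg.regulation.equilibrium_fecundity
        u = n / ((1.0 + fbar) * self._k_local(pop.x))
        if cfg.tuner_alpha is not None:
            p = 1.0 / (1.0 + self.adj * fbar * u)
        else:
            p = 1.0 - cfg.regulation.mortality(u)
        if cfg.selection.mode == "mortality":
            p = p * cfg.selection.survival_factor(pop.genotype[:, 0])
            if not self._clip_warned and np.any(p > 1.0):
                warnings.warn(
                    "mortality-mode selection pushed survival above 1; clipping "
                    "(the realized advantage is smaller than s/2 per copy)",
                    stacklevel=2,
                )
                self._clip_warned = True
        if cfg.survival_map is not None:
            p = p * np.maximum(cfg.survival_map.value_at(pop.x), 0.0)
        if cfg.survival_modifier is not None:
            p = p * cfg.survival_modifier(pop, pop.tick, rng)
        p = np.clip(p, 0.0, 1.0)
        alive = rng.random(pop.census) < p
        newpop = pop.subset(alive)
        newpop.age = newpop.age + 1
        newpop.u = u[alive]
        self.pop = newpop
        if cfg.tuner_alpha is not None and pop.tick < cfg.tuner_burn_in:
            obs = self.pop.census / cfg.bounds.area
            self.adj *= float(np.exp(cfg.tuner_alpha * (obs - cfg.K)))

    def step(self):
        """Advance one tick (reproduce -> move -> density+survive)."""
        if self.pop.census == 0:
            self.extinct = True
            self.pop = replace(self.pop, tick=self.pop.tick + 1)
            return self.pop
        self.reproduce()
        self.move()
        self.survive()
        self.pop = replace(self.pop, tick=self.pop.tick + 1)
        if self.pop.census == 0:
            self.extinct = True
        return self.pop

    # -- driving ---------------------------------------------------------

    def run(self, ticks: int, snapshot_every: int = 0) -> RunResult:
        """Iterate ``ticks`` steps recording per-tick census statistics
        (before reproduction); flushes partial output on extinction."""
        rows = []
        snapshots: dict[int, pd.DataFrame] = {}
        for _ in range(ticks):
            self._record(rows, snapshots, snapshot_every)
            if self.extinct:
                break
            self.step()
        self._record(rows, snapshots, snapshot_every)
        ts = pd.DataFrame(rows, columns=["tick", "census", "mean_age", "allele_freq"])
        return RunResult(
            timeseries=ts,
            snapshots=snapshots,
            extinct=self.extinct,
            final=self.pop,
            config=self.config,
        )

    def _record(self, rows, snapshots, snapshot_every):
        pop = self.pop
        rows.append(
            {
                "tick": pop.tick,
                "census": pop.census,
                "mean_age": float(pop.age.mean()) if pop.census else float("nan"),
                "allele_freq": pop.allele_frequency(0),
            }
        )
        if snapshot_every and pop.tick % snapshot_every == 0:
            snapshots[pop.tick] = pop.to_frame()


def run(config: SimConfig, ticks: int, snapshot_every: int = 0) -> RunResult:
    """Build a :class:`Simulation` from ``config`` and run it."""
    return Simulation(config).run(ticks, snapshot_every=snapshot_every)


# ---------------------------------------------------------------------------
# small utilities


def _sample_map_weighted(map: RasterMap, n: int, rng: np.random.Generator):
    """n points with cell probability proportional to the map value, uniform
    within each cell."""
    v = np.maximum(map.values, 0.0).ravel()
    if v.sum() <= 0:
        raise ValueError("map has no positive mass to place individuals on")
    cells = rng.choice(v.size, size=n, p=v / v.sum())
    rows, cols = np.unravel_index(cells, map.values.shape)
    dx, dy = map.cell_size
    x = map.bounds.x_min + (cols + rng.random(n)) * dx
    y = map.bounds.y_max - (rows + rng.random(n)) * dy
    return np.column_stack([x, y])


def _random_mates(n_choosers, n_candidates, exclude_self, rng):
    """Uniform global mate choice (the nonspatial comparator)."""
    if n_candidates == 0:
        return np.full(n_choosers, -1, dtype=np.int64)
    mates = rng.integers(0, n_candidates, size=n_choosers)
    if exclude_self and n_candidates > 1:
        clash = mates == np.arange(n_choosers)
        while clash.any():
            mates[clash] = rng.integers(0, n_candidates, size=int(clash.sum()))
            clash = mates == np.arange(n_choosers)
    elif exclude_self and n_candidates == 1:
        return np.full(n_choosers, -1, dtype=np.int64)
    return mates
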