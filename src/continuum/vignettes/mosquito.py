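"""Stage-structured population on a seasonally forced aquatic habitat
(mosquito-style scenario).

Individuals are larvae for a fixed number of daily age classes (default 10)
and then mature into adults.  The two stages obey different rules:

* larvae never move; their survival is Beverton-Holt in the *total* larval
  density across all larval ages, scaled by a carrying capacity
  K(x, t) = K_base(x) + K_rain(t), where K_base is nonzero only on the
  water mask and K_rain is sinusoidal with period 365 ticks and minimum 0;
* adults survive at a constant per-tick probability (default 0.875, hence
  a mean adult lifespan of 8 days), move by a Gaussian displacement every
  tick, mate within a maximum mating distance and lay eggs at a point
  sampled within the dispersal radius weighted by K(x, t).

The Beverton-Holt strength theta for larvae (survival 1/(1 + theta * uL)
with uL = larval density / K) is solved numerically from the stationary
ten-class recursion so that the equilibrium total larval density equals K
under constant forcing: at stationarity the per-tick larval survival sL
must satisfy sL^k = 2 (1 - sA) / (sA * lambda) for k age classes, adult
survival sA and eggs-per-female lambda, and then theta = 1/sL - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from ..engine import FEMALE, MALE, PopulationState, choose_mate, local_density_exact
from ..kernels import Bounds, Kernel, apply_boundary
from ..landscape import RasterMap, sample_nearby_point
from ..synthmaps import seasonal_sinusoid

__all__ = ["StageStructure", "seasonal_K", "solve_larval_strength", "MosquitoModel"]


@dataclass
class StageStructure:
    """Configuration of the stage-structured scenario."""

    k_base: RasterMap
    k_rain_amplitude: float = 1.0
    k_rain_period: float = 365.0
    larval_classes: int = 10
    adult_survival: float = 0.875
    eggs_per_female: float = 10.0
    sigma_move: float = 0.5          # adult daily movement scale
    max_mating_distance: float = 1.0
    dispersal_radius: float = 2.0    # egg-laying search radius
    interaction: Kernel = field(default_factory=lambda: Kernel("gaussian", 0.5))
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.adult_survival < 1:
            raise ValueError("adult survival must be in (0, 1)")
        if self.larval_classes < 1:
            raise ValueError("need at least one larval class")

    @property
    def theta(self) -> float:
        return solve_larval_strength(
            self.eggs_per_female, self.adult_survival, self.larval_classes
        )


def seasonal_K(map_or_cfg, x, t):
    """Local larval carrying capacity K(x, t) = K_base(x) + K_rain(t)."""
    cfg = map_or_cfg
    base = cfg.k_base.value_at(x, mode="nearest")
    rain = seasonal_sinusoid(t, cfg.k_rain_amplitude, cfg.k_rain_period)
    return base + rain


def solve_larval_strength(
    eggs_per_female: float, adult_survival: float, larval_classes: int = 10
) -> float:
    """Beverton-Holt strength theta for larval survival 1/(1 + theta * uL),
    chosen so the stage-structured equilibrium larval density equals K.

    Solves the stationary recursion (constant forcing): with per-tick
    larval survival sL, recruits per adult per tick are
    (lambda/2) * sL^k, which must replace the adult per-tick loss
    (1 - sA)/sA; the root in sL gives theta = 1/sL - 1."""
    sA, lam, k = adult_survival, eggs_per_female, larval_classes
    target = 2.0 * (1.0 - sA) / (sA * lam)
    if target >= 1.0:
        raise ValueError(
            "egg production too low to sustain the population even with "
            "perfect larval survival"
        )
    sL = optimize.brentq(lambda s: s**k - target, 1e-9, 1.0 - 1e-12)
    return 1.0 / sL - 1.0


class MosquitoModel:
    """Owns the population state and advances the stage-structured cycle:
    adult movement, mating and egg laying, larval density-dependent
    survival, constant adult survival, maturation."""

    def __init__(self, cfg: StageStructure, n0_adults: int = 200):
        self.cfg = cfg
        self.bounds = cfg.k_base.bounds
        self.theta = cfg.theta
        rng = np.random.default_rng([cfg.seed, 0, 99])
        # seed adults on the wet habitat
        mass = np.maximum(cfg.k_base.values, 0.0)
        if mass.sum() == 0:
            raise ValueError("k_base has no wet habitat")
        from ..engine import _sample_map_weighted

        x = _sample_map_weighted(cfg.k_base, n0_adults, rng)
        self.pop = PopulationState(
            x=x,
            sex=rng.integers(0, 2, size=n0_adults).astype(np.int8),
            age=np.full(n0_adults, cfg.larval_classes, dtype=np.int32),
            genotype=np.zeros((n0_adults, 1), dtype=np.int8),
            ids=np.arange(n0_adults, dtype=np.int64),
            u=np.zeros(n0_adults),
            tagF=np.zeros(n0_adults),
            bounds=self.bounds,
            tick=0,
            next_id=n0_adults,
        )

    def _rng(self, stage):
        return np.random.default_rng([self.cfg.seed, self.pop.tick, stage])

    def _k_map_now(self, t) -> RasterMap:
        rain = seasonal_sinusoid(t, self.cfg.k_rain_amplitude, self.cfg.k_rain_period)
        return replace(self.cfg.k_base, values=self.cfg.k_base.values + rain)

    def is_adult(self):
        return self.pop.age >= self.cfg.larval_classes

    def step(self):
        cfg, pop = self.cfg, self.pop
        t = pop.tick
        adults = self.is_adult()

        # 1. adult movement
        rng = self._rng(2)
        na = int(adults.sum())
        if na:
            kmove = Kernel("gaussian", cfg.sigma_move)
            disp = kmove.sample(na, rng)
            newx, _ = apply_boundary(
                pop.x[adults] + disp, pop.x[adults], self.bounds, rng, kmove
            )
            x = pop.x.copy()
            x[adults] = newx
            pop = replace(pop, x=x)

        # 2. mating and egg laying at K-weighted sites
        rng = self._rng(1)
        kmap = self._k_map_now(t)
        females = np.flatnonzero(adults & (pop.sex == FEMALE))
        males = np.flatnonzero(adults & (pop.sex == MALE))
        n_new = 0
        if len(females) and len(males):
            mate_kernel = Kernel(
                "flat", cfg.max_mating_distance / 3.0, max_distance=cfg.max_mating_distance
            )
            mates = choose_mate(pop.x[females], pop.x[males], mate_kernel, rng)
            mated = females[mates >= 0]
            counts = rng.poisson(cfg.eggs_per_female, size=len(mated))
            par = np.repeat(mated, counts)
            if len(par):
                lay_kernel = Kernel(
                    "flat", cfg.dispersal_radius / 3.0, max_distance=cfg.dispersal_radius
                )
                sites = sample_nearby_point(
                    kmap, pop.x[par], lay_kernel, rng, allow_fail=True
                )
                ok = np.isfinite(sites[:, 0])
                sites = sites[ok]
                n_new = sites.shape[0]
                if n_new:
                    pop = replace(
                        pop,
                        x=np.concatenate([pop.x, sites]),
                        sex=np.concatenate(
                            [pop.sex, rng.integers(0, 2, n_new).astype(np.int8)]
                        ),
                        age=np.concatenate([pop.age, np.zeros(n_new, dtype=np.int32)]),
                        genotype=np.concatenate(
                            [pop.genotype, np.zeros((n_new, 1), dtype=np.int8)]
                        ),
                        ids=np.concatenate(
                            [
                                pop.ids,
                                np.arange(
                                    pop.next_id, pop.next_id + n_new, dtype=np.int64
                                ),
                            ]
                        ),
                        u=np.concatenate([pop.u, np.zeros(n_new)]),
                        tagF=np.concatenate([pop.tagF, np.zeros(n_new)]),
                        next_id=pop.next_id + n_new,
                    )

        # 3. survival: Beverton-Holt for larvae on total larval density,
        #    constant for adults
        rng = self._rng(3)
        adults = pop.age >= cfg.larval_classes
        larvae = ~adults
        p = np.full(pop.census, cfg.adult_survival)
        if larvae.any():
            nl = local_density_exact(pop.x[larvae], cfg.interaction)
            k_here = np.maximum(seasonal_K(cfg, pop.x[larvae], t), 1e-6)
            uL = nl / k_here
            p[larvae] = 1.0 / (1.0 + self.theta * uL)
        alive = rng.random(pop.census) < p
        pop = pop.subset(alive)
        pop.age = pop.age + 1
        self.pop = replace(pop, tick=t + 1)
        return self.pop

    def run(self, ticks: int) -> pd.DataFrame:
        rows = []
        for _ in range(ticks):
            adults = int(self.is_adult().sum())
            rows.append(
                {
                    "tick": self.pop.tick,
                    "adults": adults,
                    "larvae": self.pop.census - adults,
                }
            )
            if self.pop.census == 0:
                break
            self.step()
        adults = int(self.is_adult().sum())
        rows.append(
            {"tick": self.pop.tick, "adults": adults, "larvae": self.pop.census - adults}
        )
        return pd.DataFrame(rows)
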