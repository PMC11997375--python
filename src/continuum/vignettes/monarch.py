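"""Resource-explicit regulation (monarch/milkweed-style scenario).

Density feedback here is mediated by depletion of discrete resource
patches rather than by direct individual-to-individual competition.  Each
patch delivers a fixed amount of resource per tick, split *equally* among
the consumers within its interaction radius (so a patch that can feed 10
with 100 consumers nearby gives each 10%); a consumer in range of several
patches accumulates shares additively in its tally.  Individuals at or
above the mortality-check age then survive with probability min(1, tally)
— guaranteed if they collected at least one full unit — while younger
individuals are unaffected by this cull.  Tallies are reset every tick
before foraging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..engine import NO_SEX, PopulationState
from ..kernels import Bounds, Kernel, apply_boundary

__all__ = [
    "ResourcePatchSet",
    "resource_forage",
    "resource_cull",
    "resource_forage_and_cull",
    "MonarchModel",
]


@dataclass
class ResourcePatchSet:
    """Fixed resource patches (e.g. host plants).

    positions : (n_patches, 2) patch locations.
    inds_fed_per_patch : units of resource each patch delivers per tick
        (1 unit = enough to guarantee one individual's survival).
    radius : interaction radius within which consumers share a patch.
    check_age : age (ticks) at and above which the resource cull applies.
    """

    positions: np.ndarray
    inds_fed_per_patch: float = 10.0
    radius: float = 1.0
    check_age: int = 2

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))


def resource_forage(positions, patches: ResourcePatchSet):
    """Per-consumer resource tallies after one foraging phase.

    Every patch splits ``inds_fed_per_patch`` equally among the consumers
    within ``radius`` (delivering exactly that total whenever it has any
    customers); shares from multiple patches add."""
    x = np.atleast_2d(np.asarray(positions, dtype=float))
    tally = np.zeros(x.shape[0])
    if x.shape[0] == 0 or patches.positions.shape[0] == 0:
        return tally
    tree = cKDTree(x)
    customers = tree.query_ball_point(patches.positions, patches.radius)
    for group in customers:
        if group:
            tally[group] += patches.inds_fed_per_patch / len(group)
    return tally


def resource_cull(age, tally, check_age: int, rng: np.random.Generator):
    """Survival mask: individuals with age >= check_age survive with
    probability min(1, tally); younger individuals always pass."""
    age = np.asarray(age)
    tally = np.asarray(tally, dtype=float)
    at_risk = age >= check_age
    p = np.where(at_risk, np.minimum(tally, 1.0), 1.0)
    return rng.random(len(age)) < p


def resource_forage_and_cull(positions, age, patches: ResourcePatchSet, rng):
    """One foraging phase followed by the cull: returns (tallies, alive
    mask).  Convenience composition of :func:`resource_forage` and
    :func:`resource_cull`."""
    tally = resource_forage(positions, patches)
    alive = resource_cull(age, tally, patches.check_age, rng)
    return tally, alive


class MonarchModel:
    """Minimal resource-explicit population: adults (age >= check_age)
    reproduce and disperse; everyone forages; the resource cull is the only
    density-dependent mortality."""

    def __init__(
        self,
        bounds: Bounds,
        patches: ResourcePatchSet,
        fecundity: float = 1.0,
        dispersal: Kernel | None = None,
        n0: int = 100,
        seed: int = 0,
        reproduction_age: int | None = None,
    ):
        self.bounds = bounds
        self.patches = patches
        self.fecundity = fecundity
        # reproduction starts strictly after the first resource cull:
        # individuals must survive the pupal check before breeding,
        # otherwise growth is resource-independent and unbounded
        self.reproduction_age = (
            patches.check_age + 1 if reproduction_age is None else reproduction_age
        )
        self.dispersal = dispersal or Kernel("gaussian", 1.0)
        self.seed = seed
        rng = np.random.default_rng([seed, 0, 99])
        x = bounds.sample_uniform(n0, rng)
        self.pop = PopulationState(
            x=x,
            sex=np.full(n0, NO_SEX, dtype=np.int8),
            age=np.full(n0, patches.check_age, dtype=np.int32),
            genotype=np.zeros((n0, 1), dtype=np.int8),
            ids=np.arange(n0, dtype=np.int64),
            u=np.zeros(n0),
            tagF=np.zeros(n0),
            bounds=bounds,
            tick=0,
            next_id=n0,
        )

    def _rng(self, stage):
        return np.random.default_rng([self.seed, self.pop.tick, stage])

    def step(self):
        pop = self.pop
        t = pop.tick

        # reproduction by adults, offspring disperse
        rng = self._rng(1)
        adults = np.flatnonzero(pop.age >= self.reproduction_age)
        counts = rng.poisson(self.fecundity, size=len(adults))
        par = np.repeat(adults, counts)
        n_new = len(par)
        if n_new:
            disp = self.dispersal.sample(n_new, rng)
            newx, _ = apply_boundary(
                pop.x[par] + disp, pop.x[par], self.bounds, rng, self.dispersal
            )
            pop = replace(
                pop,
                x=np.concatenate([pop.x, newx]),
                sex=np.concatenate([pop.sex, np.full(n_new, NO_SEX, dtype=np.int8)]),
                age=np.concatenate([pop.age, np.zeros(n_new, dtype=np.int32)]),
                genotype=np.concatenate(
                    [pop.genotype, np.zeros((n_new, 1), dtype=np.int8)]
                ),
                ids=np.concatenate(
                    [pop.ids, np.arange(pop.next_id, pop.next_id + n_new, dtype=np.int64)]
                ),
                u=np.concatenate([pop.u, np.zeros(n_new)]),
                tagF=np.concatenate([pop.tagF, np.zeros(n_new)]),
                next_id=pop.next_id + n_new,
            )

        # foraging (tallies reset) then the resource cull
        rng = self._rng(3)
        tally = resource_forage(pop.x, self.patches)
        alive = resource_cull(pop.age, tally, self.patches.check_age, rng)
        pop = replace(pop, tagF=tally).subset(alive)
        pop.age = pop.age + 1
        self.pop = replace(pop, tick=t + 1)
        return self.pop

    def run(self, ticks: int) -> pd.DataFrame:
        rows = []
        for _ in range(ticks):
            rows.append(
                {
                    "tick": self.pop.tick,
                    "census": self.pop.census,
                    "adults": int((self.pop.age >= self.patches.check_age).sum()),
                }
            )
            if self.pop.census == 0:
                break
            self.step()
        rows.append(
            {
                "tick": self.pop.tick,
                "census": self.pop.census,
                "adults": int((self.pop.age >= self.patches.check_age).sum()),
            }
        )
        return pd.DataFrame(rows)
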