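"""Alpine habitat tracking under seasonal, stochastic and trending
temperature change (pika-style scenario).

One tick is one year.  Temperature at location x in year t is

    T(x, t) = T_elev(x) + T_fluct(t) + trend * t

where T_elev is an affine lapse model of the elevation map
(T_elev = T0 - lapse * elevation), T_fluct is an AR(1) process
(T_fluct(0) = 0; T_fluct(t) = p_fluct * T_fluct(t-1) + Normal(0, s_fluct))
whose parameters are the *persistence* and *shock*, and the trend defaults
to 0.016 degC per year.  Individuals survive the year only if the seasonal
extremes around the midpoint T stay inside the viability range
[-5, 28] degC: the within-year seasonal range s_seas narrows the window to
[-5 + s_seas/2, 28 - s_seas/2].  Inside the window, survival is the usual
Beverton-Holt mortality regulation 1 / (1 + f*u).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..engine import SimConfig, Simulation
from ..kernels import Bounds, Kernel
from ..landscape import RasterMap
from ..regulation import RegulationModel

__all__ = [
    "PikaClimate",
    "pika_temperature",
    "pika_survival",
    "habitable_fraction",
    "run_pika",
]

T_MIN, T_MAX = -5.0, 28.0


@dataclass
class PikaClimate:
    """Temperature model over an elevation raster.

    T0 : sea-level (elevation 0) mean temperature, degC.
    lapse : cooling per unit elevation (degC per map unit).
    p_fluct, s_fluct : AR(1) persistence and shock sd of year-to-year noise.
    s_seas : within-year seasonal range, degC (narrows the viability window).
    trend : warming rate, degC per tick (default 0.016).
    """

    elev_map: RasterMap
    T0: float = 20.0
    lapse: float = 1.0
    p_fluct: float = 0.5
    s_fluct: float = 0.0
    s_seas: float = 0.0
    trend: float = 0.016

    def __post_init__(self):
        if self.s_seas >= T_MAX - T_MIN:
            raise ValueError(
                f"s_seas={self.s_seas} leaves an empty viability window "
                f"(range is {T_MAX - T_MIN} degC wide)"
            )
        if not 0.0 <= self.p_fluct < 1.0:
            raise ValueError("p_fluct must be in [0, 1) for a stationary AR(1)")

    def t_elev(self, elevation):
        return self.T0 - self.lapse * np.asarray(elevation, dtype=float)

    def advance_fluct(self, state: float, rng: np.random.Generator) -> float:
        """One AR(1) step of the year-to-year fluctuation."""
        eps = rng.normal(0.0, self.s_fluct) if self.s_fluct > 0 else 0.0
        return self.p_fluct * state + eps

    @property
    def effective_window(self):
        return T_MIN + self.s_seas / 2.0, T_MAX - self.s_seas / 2.0


def pika_temperature(climate: PikaClimate, elevation, t, fluct_state, rng=None):
    """Midpoint temperature at the given elevation(s) in year t, and the
    advanced fluctuation state.  Pass ``rng=None`` to keep the state fixed
    (deterministic schedules)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    new_state = climate.advance_fluct(fluct_state, rng) if rng is not None else fluct_state
    T = climate.t_elev(elevation) + fluct_state + climate.trend * t
    return T, new_state


def pika_survival(T, s_seas, u, f):
    """Yearly survival probability: zero outside the seasonally narrowed
    viability window, else Beverton-Holt 1/(1 + f*u)."""
    if s_seas >= T_MAX - T_MIN:
        raise ValueError("s_seas leaves an empty viability window")
    T = np.asarray(T, dtype=float)
    u = np.asarray(u, dtype=float)
    inside = (T >= T_MIN + s_seas / 2.0) & (T <= T_MAX - s_seas / 2.0)
    out = np.where(inside, 1.0 / (1.0 + f * u), 0.0)
    return out if out.ndim else float(out)


def habitable_fraction(climate: PikaClimate, t, fluct_state: float = 0.0) -> float:
    """Fraction of map pixels whose midpoint temperature sits inside the
    effective viability window in year t (deterministic in t when the
    fluctuation state is supplied)."""
    T = climate.t_elev(climate.elev_map.values) + fluct_state + climate.trend * t
    lo, hi = climate.effective_window
    return float(np.mean((T >= lo) & (T <= hi)))


class _PikaGate:
    """Stateful survival modifier: multiplies survival by the 0/1 thermal
    viability of each individual's location, advancing the AR(1) state once
    per tick."""

    def __init__(self, climate: PikaClimate):
        self.climate = climate
        self.fluct = 0.0
        self.history: list[float] = []

    def __call__(self, pop, tick, rng):
        elev = self.climate.elev_map.value_at(pop.x)
        T = self.climate.t_elev(elev) + self.fluct + self.climate.trend * tick
        lo, hi = self.climate.effective_window
        self.history.append(habitable_fraction(self.climate, tick, self.fluct))
        self.fluct = self.climate.advance_fluct(self.fluct, rng)
        return ((T >= lo) & (T <= hi)).astype(float)


def run_pika(
    climate: PikaClimate,
    K: float = 5.0,
    f: float = 1.0,
    sigma: float = 1.0,
    ticks: int = 200,
    seed: int = 0,
):
    """Run the scenario on the climate's elevation map; the domain is the
    map's bounds.  Returns (RunResult, habitable-fraction series)."""
    b = climate.elev_map.bounds
    gate = _PikaGate(climate)
    cfg = SimConfig(
        bounds=Bounds(b.x_min, b.x_max, b.y_min, b.y_max, "reprising"),
        K=K,
        regulation=RegulationModel.beverton_holt_mortality(f),
        interaction=Kernel("gaussian", sigma),
        dispersal=Kernel("gaussian", sigma),
        mating=Kernel("gaussian", sigma),
        survival_modifier=gate,
        seed=seed,
    )
    result = Simulation(cfg).run(ticks)
    return result, np.asarray(gate.history)
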