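"""Case-study pipelines: climate gating, stage structure, habitat
suitability, and resource-explicit regulation."""

import numpy as np
import pandas as pd
import pytest

from continuum import Bounds, Kernel
from continuum.synthmaps import cone_map, gradient_map, river_mask_map, seasonal_sinusoid, uniform_map
from continuum.vignettes import (
    MonarchModel,
    MosquitoModel,
    PikaClimate,
    ResourcePatchSet,
    StageStructure,
    front_radius,
    habitable_fraction,
    occupancy_fraction,
    pika_survival,
    pika_temperature,
    precipitation_survival_modifier,
    resource_cull,
    resource_forage,
    run_pika,
    run_toad,
    seasonal_K,
    solve_larval_strength,
)


@pytest.fixture
def elev():
    return cone_map(Bounds(0, 10, 0, 10), peak=30.0, rows=16, cols=16)


class TestPikaClimate:
    def test_initial_temperature_is_lapse_model(self, elev):
        climate = PikaClimate(elev, T0=20.0, lapse=1.0, s_fluct=0.0)
        T, state = pika_temperature(climate, elevation=10.0, t=0, fluct_state=0.0)
        assert T == pytest.approx(10.0)
        assert state == 0.0

    def test_linear_trend_accumulates(self, elev):
        climate = PikaClimate(elev, T0=20.0, lapse=1.0, s_fluct=0.0, trend=0.016)
        T, _ = pika_temperature(climate, elevation=10.0, t=100, fluct_state=0.0)
        assert T == pytest.approx(10.0 + 1.6)

    def test_ar1_stationary_sd(self, elev, rng):
        p, s = 0.6, 2.0
        climate = PikaClimate(elev, p_fluct=p, s_fluct=s)
        state, series = 0.0, []
        for _ in range(20000):
            state = climate.advance_fluct(state, rng)
            series.append(state)
        expect = s / np.sqrt(1 - p**2)
        assert np.std(series[100:]) == pytest.approx(expect, rel=0.05)

    def test_empty_viability_window_rejected(self, elev):
        with pytest.raises(ValueError, match="window"):
            PikaClimate(elev, s_seas=40.0)


class TestPikaSurvival:
    def test_seasonal_narrowing_kills_at_minus_four(self):
        # midpoint -4 with a 4-degree seasonal range: winters hit -6
        assert pika_survival(-4.0, s_seas=4.0, u=1.0, f=1.0) == 0.0

    def test_inside_window_beverton_holt(self):
        assert pika_survival(10.0, s_seas=4.0, u=1.0, f=1.0) == pytest.approx(0.5)

    def test_edge_of_range_uncrowded(self):
        assert pika_survival(27.9, s_seas=0.0, u=0.0, f=1.0) == pytest.approx(1.0)

    def test_hot_side_kills_too(self):
        assert pika_survival(27.0, s_seas=4.0, u=0.0, f=1.0) == 0.0


class TestPikaLandscape:
    def test_habitable_fraction_deterministic_and_shifts_uphill(self, elev):
        climate = PikaClimate(elev, T0=30.0, lapse=1.0, s_fluct=0.0, s_seas=4.0, trend=0.05)
        h0a = habitable_fraction(climate, 0)
        h0b = habitable_fraction(climate, 0)
        assert h0a == h0b
        # a pixel at low elevation (hot) that is habitable early becomes
        # uninhabitable as the trend accumulates
        lo, hi = climate.effective_window
        T_low_elev = climate.t_elev(5.0)
        assert T_low_elev <= hi
        t_late = int((hi - T_low_elev) / climate.trend) + 10
        assert climate.t_elev(5.0) + climate.trend * t_late > hi

    def test_extinction_risk_rises_with_shock_sd(self):
        """Larger year-to-year shocks mean more runs die out: one or a few
        bad years displace the narrow thermal band entirely."""
        # steep mountain so the viable band is a narrow elevation annulus
        steep = cone_map(Bounds(0, 10, 0, 10), peak=40.0, rows=16, cols=16)
        extinct = {}
        for s_fluct in (1.0, 5.0):
            count = 0
            for seed in range(10):
                climate = PikaClimate(
                    steep, T0=35.0, lapse=1.0, p_fluct=0.5, s_fluct=s_fluct, s_seas=24.0
                )
                result, _ = run_pika(climate, K=4.0, sigma=0.8, ticks=100, seed=seed)
                count += result.extinct
            extinct[s_fluct] = count
        assert extinct[5.0] > extinct[1.0]


class TestSeasonalForcing:
    def test_sinusoid_period_and_minimum(self):
        t = np.arange(0, 730)
        k = seasonal_sinusoid(t, amplitude=2.0, period=365.0)
        assert k.min() == pytest.approx(0.0, abs=1e-12)
        assert seasonal_sinusoid(182.5, 2.0, 365.0) == pytest.approx(2.0, rel=1e-12)
        assert k.max() <= 2.0 + 1e-12
        assert seasonal_sinusoid(10.0, 2.0, 365.0) == pytest.approx(
            seasonal_sinusoid(375.0, 2.0, 365.0)
        )

    def test_seasonal_K_composition(self):
        b = Bounds(0, 10, 0, 10)
        river = river_mask_map(b, width=2.0, value=3.0)
        cfg = StageStructure(k_base=river, k_rain_amplitude=2.0, k_rain_period=100.0)
        x_wet = np.array([5.0, 5.0 + 0.0])  # on the channel at x=5? find a wet cell
        wet_idx = np.argwhere(river.values > 0)[0]
        xs, ys = river.cell_centers()
        x_wet = np.array([xs[wet_idx[1]], ys[wet_idx[0]]])
        x_dry = np.array([xs[0], ys[0]])
        assert river.value_at(x_dry, mode="nearest") == 0.0
        # at the trough of the rain cycle, K is just K_base
        assert seasonal_K(cfg, x_wet, 0.0) == pytest.approx(3.0)
        assert seasonal_K(cfg, x_dry, 0.0) == pytest.approx(0.0)
        # at the crest, both terms add
        assert seasonal_K(cfg, x_wet, 50.0) == pytest.approx(5.0)


class TestLarvalStrength:
    def test_matches_stationary_recursion_closed_form(self):
        lam, sA, k = 2.0, 0.875, 10
        theta = solve_larval_strength(lam, sA, k)
        sL = 1.0 / (1.0 + theta)
        assert sL**k == pytest.approx(2 * (1 - sA) / (sA * lam), rel=1e-10)

    def test_insufficient_eggs_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            solve_larval_strength(0.1, 0.5, 10)


class TestMosquito:
    @pytest.fixture
    def cfg(self):
        # larval carrying capacity must be generous: only a few percent of
        # eggs survive ten daily larval classes, so adult density is a small
        # fraction of K
        b = Bounds(0, 15, 0, 15)
        river = river_mask_map(b, width=1.5, value=16.0, rows=30, cols=30)
        return StageStructure(
            k_base=river,
            k_rain_amplitude=8.0,
            k_rain_period=80.0,
            eggs_per_female=10.0,
            seed=0,
        )

    def test_adult_survival_decay(self, cfg):
        """With reproduction switched off the adult cohort decays
        geometrically at 0.875 per day (mean lifespan 8 days)."""
        model = MosquitoModel(cfg, n0_adults=400)
        model.pop.sex[:] = 1  # males only: no eggs laid
        n0 = model.pop.census
        for _ in range(8):
            model.step()
        expect = n0 * 0.875**8
        sd = np.sqrt(n0 * 0.875**8 * (1 - 0.875**8))
        assert abs(model.pop.census - expect) < 4 * sd

    def test_larvae_die_where_K_zero(self, cfg):
        model = MosquitoModel(cfg, n0_adults=50)
        # drop larvae in a dry corner at the rain trough (K = 0 there)
        n_l = 30
        model.pop = model.pop.subset(np.zeros(model.pop.census, dtype=bool))
        import numpy as _np
        from dataclasses import replace

        pop = model.pop
        model.pop = replace(
            pop,
            x=_np.tile([0.5, 0.5], (n_l, 1)),
            sex=_np.zeros(n_l, dtype=_np.int8),
            age=_np.zeros(n_l, dtype=_np.int32),
            genotype=_np.zeros((n_l, 1), dtype=_np.int8),
            ids=_np.arange(n_l, dtype=_np.int64),
            u=_np.zeros(n_l),
            tagF=_np.zeros(n_l),
        )
        model.step()
        assert model.pop.census == 0

    def test_larvae_are_sessile_adults_move(self, cfg):
        model = MosquitoModel(cfg, n0_adults=100)
        model.step()  # produces eggs
        pop = model.pop
        larvae0 = pop.x[pop.age < cfg.larval_classes].copy()
        ids0 = pop.ids[pop.age < cfg.larval_classes]
        model.step()
        pop = model.pop
        for i, lid in enumerate(ids0):
            m = pop.ids == lid
            if m.any():
                assert np.allclose(pop.x[m][0], larvae0[i])

    def test_census_oscillates_at_forcing_period(self, cfg):
        """Larval census tracks the seasonal K; adults follow with a lag."""
        ts = MosquitoModel(cfg, n0_adults=300).run(400)
        larvae = ts.larvae.to_numpy()[100:]
        adults = ts.adults.to_numpy()[100:]
        assert ts.adults.iloc[-1] > 0
        # spectral peak of the larval series at the forcing period (80)
        detr = larvae - larvae.mean()
        freqs = np.fft.rfftfreq(len(detr))
        power = np.abs(np.fft.rfft(detr)) ** 2
        peak = freqs[1 + np.argmax(power[1:])]
        assert 1.0 / peak == pytest.approx(80.0, abs=8.0)
        # larvae lead adults: cross-correlation peaks at a positive lag
        a = adults - adults.mean()
        lags = np.arange(0, 30)
        cc = [np.corrcoef(detr[: len(detr) - l], a[l:])[0, 1] for l in lags]
        assert np.argmax(cc) > 0


class TestToad:
    def test_logistic_modifier_values(self):
        assert precipitation_survival_modifier(0.0, 0.0, 1.0) == pytest.approx(0.5)
        assert precipitation_survival_modifier(2.0, 0.0, 1.0) == pytest.approx(0.8808, abs=1e-4)
        assert precipitation_survival_modifier(1e4, 0.0, 1.0) == pytest.approx(1.0)
        assert precipitation_survival_modifier(-1e4, 0.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_occupancy_tracks_precipitation(self):
        b = Bounds(0, 20, 0, 20)
        precip = gradient_map(b, lo=-4.0, hi=4.0, axis="y", rows=20, cols=20)
        res = run_toad(precip, K=4.0, sigma=1.0, intro_point=(10.0, 10.0), ticks=50, seed=0)
        pop = res.final
        # equilibrium occupancy should be concentrated on the wet (high-y) half
        wet = (pop.x[:, 1] > 10.0).mean()
        assert wet > 0.7

    def test_fat_tailed_dispersal_advances_front_faster(self):
        b = Bounds(0, 40, 0, 40)
        precip = uniform_map(b, value=4.0)  # uniformly wet: pure expansion
        origin = (8.0, 8.0)
        fronts = {}
        for fam in ("t", "gaussian"):
            radii = []
            for seed in (0, 1, 2):
                res = run_toad(
                    precip,
                    beta_t=1.0,
                    K=3.0,
                    sigma=0.7,
                    dispersal_family=fam,
                    df=3.0,
                    intro_point=origin,
                    ticks=25,
                    seed=seed,
                )
                radii.append(front_radius(res.final.x, origin))
            fronts[fam] = np.mean(radii)
        assert fronts["t"] > fronts["gaussian"]


class TestMonarch:
    def test_equal_split_among_customers(self, rng):
        patches = ResourcePatchSet(np.array([[0.0, 0.0]]), inds_fed_per_patch=10.0, radius=1.0)
        x = rng.uniform(-0.5, 0.5, size=(100, 2))
        tally = resource_forage(x, patches)
        assert np.allclose(tally, 0.1)

    def test_shares_add_across_patches(self):
        patches = ResourcePatchSet(
            np.array([[0.0, 0.0], [0.5, 0.0]]), inds_fed_per_patch=10.0, radius=1.0
        )
        x = np.tile([0.25, 0.0], (10, 1))
        tally = resource_forage(x, patches)
        assert np.allclose(tally, 2.0)

    def test_full_unit_guarantees_survival(self, rng):
        age = np.full(500, 3)
        tally = np.full(500, 1.7)
        assert resource_cull(age, tally, check_age=2, rng=rng).all()

    def test_partial_tally_is_survival_probability(self, rng):
        n = 20000
        alive = resource_cull(np.full(n, 2), np.full(n, 0.3), 2, rng)
        assert alive.mean() == pytest.approx(0.3, abs=0.01)

    def test_young_unaffected_by_cull(self, rng):
        alive = resource_cull(np.zeros(100, dtype=int), np.zeros(100), 2, rng)
        assert alive.all()

    def test_forage_and_cull_composition(self, rng):
        from continuum.vignettes import resource_forage_and_cull

        patches = ResourcePatchSet(np.array([[0.0, 0.0]]), inds_fed_per_patch=20.0, radius=1.0)
        x = rng.uniform(-0.5, 0.5, size=(10, 2))
        age = np.full(10, 2)
        tally, alive = resource_forage_and_cull(x, age, patches, rng)
        assert np.allclose(tally, 2.0)
        assert alive.all()  # everyone collected a full unit

    def test_equilibrium_census_scales_with_resource(self):
        """Doubling the per-patch resource approximately doubles the
        equilibrium census in the resource-limited regime."""
        b = Bounds(0, 20, 0, 20)
        rng = np.random.default_rng(5)
        pos = b.sample_uniform(25, rng)
        census = {}
        for fed in (4.0, 8.0):
            patches = ResourcePatchSet(pos, inds_fed_per_patch=fed, radius=1.5)
            model = MonarchModel(b, patches, fecundity=1.5, n0=150, seed=1)
            ts = model.run(120)
            census[fed] = ts.census.tail(40).mean()
        assert census[8.0] / census[4.0] == pytest.approx(2.0, rel=0.15)
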