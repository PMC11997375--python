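"""Local density (exact and grid), mate choice, the life cycle, determinism."""

import numpy as np
import pytest
from scipy import stats

from continuum import (
    Bounds,
    Kernel,
    RasterMap,
    RegulationModel,
    SimConfig,
    Simulation,
    choose_mate,
    choose_mate_grid,
    local_density_exact,
    local_density_grid,
    run,
)
from continuum.diagnostics import pair_correlation
from tests.conftest import small_homogeneous_config


class TestLocalDensityExact:
    def test_single_individual_sees_only_itself(self):
        sx = 0.7
        n = local_density_exact(np.array([[3.0, 4.0]]), Kernel("gaussian", sx))
        assert n[0] == pytest.approx(1.0 / (2 * np.pi * sx**2), rel=1e-12)

    def test_two_individuals_closed_form(self):
        sx, d = 1.0, 1.3
        x = np.array([[0.0, 0.0], [d, 0.0]])
        n = local_density_exact(x, Kernel("gaussian", sx))
        expect = (1.0 + np.exp(-(d**2) / (2 * sx**2))) / (2 * np.pi * sx**2)
        assert n == pytest.approx([expect, expect], rel=1e-12)

    def test_uniform_torus_mean_density(self, rng):
        """On a torus the expected local density is the intensity plus the
        self term, up to the ~1% 3-sigma truncation loss."""
        b = Bounds(0, 20, 0, 20)
        lam = 25.0
        x = b.sample_uniform(int(lam * b.area), rng)
        sx = 0.5
        n = local_density_exact(x, Kernel("gaussian", sx), torus=b)
        expect = lam + 1.0 / (2 * np.pi * sx**2)
        assert n.mean() == pytest.approx(expect, rel=0.02)

    def test_empty_population(self):
        assert local_density_exact(np.zeros((0, 2)), Kernel("gaussian", 1.0)).size == 0


class TestLocalDensityGrid:
    def test_empty_population_gives_zero_map(self, unit_bounds):
        dens, m = local_density_grid(np.zeros((0, 2)), Kernel("gaussian", 1.0), unit_bounds)
        assert dens.size == 0
        assert np.all(m.values == 0)

    def test_single_individual_own_density(self, unit_bounds):
        sx = 1.0
        x = np.array([[5.3, 4.8]])
        dens, _ = local_density_grid(x, Kernel("gaussian", sx), unit_bounds, cell_size=sx / 4)
        assert dens[0] == pytest.approx(1.0 / (2 * np.pi * sx**2), rel=0.10)

    @pytest.mark.parametrize("cell_frac,tol", [(2, 0.05), (4, 0.02)])
    def test_clustered_points_match_exact(self, cell_frac, tol, rng):
        b = Bounds(0, 20, 0, 20)
        centers = b.sample_uniform(8, rng)
        pts = []
        while sum(len(p) for p in pts) < 1000:
            cand = centers[rng.integers(0, 8, 500)] + rng.normal(0, 1.5, (500, 2))
            pts.append(cand[b.contains(cand)])
        x = np.concatenate(pts)[:1000]
        k = Kernel("gaussian", 0.8)
        exact = local_density_exact(x, k)
        grid, _ = local_density_grid(x, k, b, cell_size=0.8 / cell_frac)
        rel = np.abs(grid - exact) / exact
        assert np.median(rel) < tol

    def test_oversized_cells_warn(self, unit_bounds, rng):
        x = unit_bounds.sample_uniform(50, rng)
        with pytest.warns(UserWarning, match="cell size"):
            local_density_grid(x, Kernel("gaussian", 1.0), unit_bounds, cell_size=2.0)


class TestChooseMate:
    def test_single_candidate_always_chosen(self, rng):
        m = choose_mate(np.zeros((50, 2)), np.array([[1.0, 0.0]]), Kernel("gaussian", 1.0), rng)
        assert np.all(m == 0)

    def test_equidistant_candidates_split_evenly(self, rng):
        cand = np.array([[1.0, 0.0], [-1.0, 0.0]])
        m = choose_mate(np.zeros((10000, 2)), cand, Kernel("gaussian", 1.0), rng)
        assert (m == 0).mean() == pytest.approx(0.5, abs=0.02)

    def test_weight_ratio_matches_kernel(self, rng):
        r = 1.0
        cand = np.array([[r, 0.0], [2 * r, 0.0]])
        m = choose_mate(np.zeros((20000, 2)), cand, Kernel("gaussian", r), rng)
        expect = np.exp(-0.5) / (np.exp(-0.5) + np.exp(-2.0))
        assert (m == 0).mean() == pytest.approx(expect, abs=0.01)

    def test_out_of_range_returns_none(self, rng):
        m = choose_mate(np.zeros((3, 2)), np.array([[50.0, 0.0]]), Kernel("gaussian", 1.0), rng)
        assert np.all(m == -1)

    def test_self_exclusion(self, rng):
        x = np.array([[0.0, 0.0], [40.0, 40.0]])  # mutually out of range
        m = choose_mate(x, x, Kernel("gaussian", 1.0), rng, exclude_self=True)
        assert np.all(m == -1)


class TestChooseMateGrid:
    def test_single_eligible_in_reach(self, unit_bounds, rng):
        cand = np.array([[5.5, 5.0]])
        m = choose_mate_grid(np.tile([5.0, 5.0], (20, 1)), cand, Kernel("gaussian", 1.0), unit_bounds, rng)
        assert np.all(m == 0)

    def test_empty_eligible_set(self, unit_bounds, rng):
        m = choose_mate_grid(np.zeros((4, 2)), np.zeros((0, 2)), Kernel("gaussian", 1.0), unit_bounds, rng)
        assert np.all(m == -1)

    def test_far_candidates_unreachable(self, unit_bounds, rng):
        cand = np.array([[9.9, 9.9]])
        m = choose_mate_grid(np.tile([0.5, 0.5], (10, 1)), cand, Kernel("gaussian", 0.5), unit_bounds, rng)
        assert np.all(m == -1)


class TestLifeCycle:
    def test_zero_fecundity_means_no_offspring(self):
        cfg = small_homogeneous_config(
            fecundity_map=RasterMap(np.zeros((4, 4)), Bounds(0, 15, 0, 15)), mating=None
        )
        sim = Simulation(cfg)
        n0 = sim.pop.census
        sim.reproduce()
        assert sim.pop.census == n0

    def test_monoecious_offspring_count_is_poisson_sum(self):
        cfg = small_homogeneous_config(bounds=Bounds(0, 50, 0, 50, "reprising"), K=4.0, mating=None)
        sim = Simulation(cfg)
        n0 = sim.pop.census  # 10^4 parents at u ~= 1
        f1 = cfg.regulation.fecundity(np.maximum(sim.pop.u, 0)).sum()
        sim.reproduce()
        born = sim.pop.census - n0
        assert abs(born - f1) < 3 * np.sqrt(f1)

    def test_dioecious_without_males_fails_to_mate(self):
        cfg = small_homogeneous_config(dioecious=True)
        sim = Simulation(cfg)
        sim.pop.sex[:] = 0  # all female
        n0 = sim.pop.census
        sim.reproduce()
        assert sim.pop.census == n0

    def test_lethal_modifier_kills_everyone(self):
        cfg = small_homogeneous_config(survival_modifier=lambda pop, tick, rng: np.zeros(pop.census))
        sim = Simulation(cfg)
        sim.step()
        assert sim.extinct
        assert sim.pop.census == 0

    def test_ages_increment_each_tick_survived(self):
        cfg = small_homogeneous_config()
        sim = Simulation(cfg)
        sim.step()
        ids0 = dict(zip(sim.pop.ids.tolist(), sim.pop.age.tolist()))
        sim.step()
        for i, a in zip(sim.pop.ids.tolist(), sim.pop.age.tolist()):
            if i in ids0:
                assert a == ids0[i] + 1

    def test_positions_always_inside_bounds(self):
        cfg = small_homogeneous_config(movement=Kernel("gaussian", 1.0))
        sim = Simulation(cfg)
        for _ in range(5):
            sim.step()
            assert cfg.bounds.contains(sim.pop.x).all()

    def test_empty_population_flags_extinction(self):
        cfg = small_homogeneous_config()
        sim = Simulation(cfg)
        sim.pop = sim.pop.subset(np.zeros(sim.pop.census, dtype=bool))
        sim.step()
        assert sim.extinct

    def test_identical_seeds_are_bit_identical(self):
        r1 = run(small_homogeneous_config(seed=7), 15)
        r2 = run(small_homogeneous_config(seed=7), 15)
        assert r1.timeseries.equals(r2.timeseries)
        assert np.array_equal(r1.final.x, r2.final.x)
        assert np.array_equal(r1.final.ids, r2.final.ids)

    def test_different_seeds_diverge(self):
        r1 = run(small_homogeneous_config(seed=1), 10)
        r2 = run(small_homogeneous_config(seed=2), 10)
        assert not np.array_equal(r1.final.x, r2.final.x)

    def test_zero_ticks_returns_initial_state_only(self):
        res = run(small_homogeneous_config(), 0)
        assert len(res.timeseries) == 1
        assert res.timeseries.census[0] == res.final.census

    def test_short_run_stays_near_carrying_capacity(self):
        cfg = small_homogeneous_config(fast_mode=True, seed=3)
        res = run(cfg, 120)
        target = cfg.K * cfg.bounds.area
        tail = res.timeseries.census.tail(60)
        assert tail.mean() == pytest.approx(target, rel=0.25)

    def test_nonspatial_mode_equilibrates_too(self):
        cfg = small_homogeneous_config(nonspatial=True, seed=4)
        res = run(cfg, 120)
        target = cfg.K * cfg.bounds.area
        assert res.timeseries.census.tail(60).mean() == pytest.approx(target, rel=0.25)


class TestClumping:
    def test_dispersal_kernel_orders_pair_correlation_peak(self):
        """Clumping at dispersal range is strongest for gaussian dispersal,
        weaker with fat-tailed kernels (more long-range dispersal), and
        weaker again with adult movement."""
        sd = 0.3
        b = Bounds(0, 12, 0, 12, "reprising")

        def peak(dispersal, movement=None, seed=11):
            cfg = SimConfig(
                bounds=b,
                K=10.0,
                regulation=RegulationModel.beverton_holt_mortality(1.0),
                interaction=Kernel("gaussian", sd),
                dispersal=dispersal,
                mating=None,
                movement=movement,
                seed=seed,
            )
            sim = Simulation(cfg)
            vals = []
            for t in range(150):
                sim.step()
                if t >= 100 and t % 2 == 0:
                    g = pair_correlation(sim.pop.x, b, bins=20, r_max=5 * sd)
                    vals.append(np.nanmax(g.values[:12]))  # peak within ~3 sd
            return float(np.mean(vals))

        p_gauss = peak(Kernel("gaussian", sd))
        p_t5 = peak(Kernel("t", sd, df=5.0))
        p_t3 = peak(Kernel("t", sd, df=3.0))
        p_move = peak(Kernel("gaussian", sd), movement=Kernel("gaussian", sd))
        assert p_gauss > p_t5 > p_t3
        assert p_move < p_gauss
        assert p_gauss > 1.05  # there is real clumping to order
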