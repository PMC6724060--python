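"""Forward simulator: growth, migration, colonisation dynamics."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from demescape import (Landscape, SimParams, logistic_step, make_deme_grid,
                       migrate_gdd, migrate_ldd, simulate_forward)
from demescape.demography import _truncated_gamma
from demescape.errors import ParameterError


def strip_grid(length, rows=1):
    land = Landscape(n_rows=rows, n_cols=length,
                     elevation=np.full((rows, length), 1600.0))
    return make_deme_grid(land, 1400.0)


class TestLogisticStep:
    def test_carrying_capacity_is_fixed_point(self):
        for r in (0.0, 0.3, 0.9):
            assert logistic_step(177.0, r, 177.0) == pytest.approx(177.0)

    def test_zero_growth_is_identity(self):
        assert logistic_step(100.0, 0.0, 177.0) == pytest.approx(100.0)

    def test_direct_evaluation(self):
        # 100 + 0.28*100*(1 - 100/177) = 100 + 2156/177
        assert logistic_step(100.0, 0.28, 177.0) == pytest.approx(
            100.0 + 2156.0 / 177.0, abs=1e-9)

    def test_invalid_capacity(self):
        with pytest.raises(ParameterError):
            logistic_step(10.0, 0.5, 0.0)


class TestMigrateGdd:
    def test_zero_rate_is_identity(self, flat_grid, rng):
        sizes = np.zeros(flat_grid.n_demes)
        sizes[0] = 50.0
        new, (dst, src, cnt) = migrate_gdd(sizes, 0.0, flat_grid, rng)
        np.testing.assert_array_equal(new, sizes)
        assert dst.size == 0

    def test_emigrants_split_equally_in_expectation(self, flat_grid):
        # interior deme, 4 neighbours, n=100, m=0.12 -> 3 per neighbour
        center = flat_grid.deme_at(2, 2)
        north = flat_grid.deme_at(1, 2)
        rng = np.random.default_rng(5)
        sizes = np.zeros(flat_grid.n_demes)
        total_out = np.zeros(10_000)
        north_in = np.zeros(10_000)
        for i in range(10_000):
            sizes[:] = 0.0
            sizes[center] = 100.0
            new, _ = migrate_gdd(sizes, 0.12, flat_grid, rng)
            total_out[i] = 100.0 - new[center]
            north_in[i] = new[north]
        se_out = total_out.std() / 100.0
        assert total_out.mean() == pytest.approx(12.0, abs=3 * se_out)
        se_n = north_in.std() / 100.0
        assert north_in.mean() == pytest.approx(3.0, abs=3 * se_n)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_population_conserved(self, flat_grid, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.uniform(0, 200, flat_grid.n_demes)
        total = sizes.sum()
        for _ in range(20):
            sizes, _ = migrate_gdd(sizes, 0.25, flat_grid, rng)
            assert sizes.sum() == pytest.approx(total, rel=1e-12)
            assert (sizes >= 0).all()


class TestMigrateLdd:
    def test_pldd_zero_matches_gdd(self, flat_grid):
        sizes = np.full(flat_grid.n_demes, 120.0)
        a, _ = migrate_ldd(sizes.copy(), 0.2, 0.0, 1.5, 6.0, 2, 100,
                           flat_grid, np.random.default_rng(3))
        b, _ = migrate_gdd(sizes.copy(), 0.2, flat_grid,
                           np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_truncated_distances_respect_bounds(self, rng):
        d = _truncated_gamma(10_000, 1.5, 6.0, 2.0, 100.0, rng)
        assert d.min() >= 2.0 and d.max() <= 100.0

    def test_population_conserved(self, rng):
        grid = strip_grid(40, rows=5)
        sizes = rng.uniform(0, 300, grid.n_demes)
        total = sizes.sum()
        for _ in range(10):
            sizes, _ = migrate_ldd(sizes, 0.2, 0.05, 1.5, 6.0, 2, 100,
                                   grid, rng)
            assert sizes.sum() == pytest.approx(total, rel=1e-12)


class TestSimulateForward:
    def test_single_deme_follows_logistic_iterate(self, single_deme_grid):
        p = SimParams(model="GDD", t_onset=50, n_ancestral=10,
                      growth_rate=0.4, migration_rate=0.2,
                      carrying_capacity=500, seed=1)
        trace = simulate_forward(single_deme_grid, p, 0)
        n = 10.0
        for g in range(1, 51):
            n = logistic_step(n, 0.4, 500.0)
            assert trace.sizes[g, 0] == pytest.approx(n, rel=1e-12)

    def test_constant_when_no_growth_no_migration(self, flat_grid):
        p = SimParams(model="GDD", t_onset=100, n_ancestral=80,
                      growth_rate=0.0, migration_rate=0.0,
                      carrying_capacity=80, seed=1)
        trace = simulate_forward(flat_grid, p, 3)
        assert (trace.sizes[:, 3] == 80.0).all()
        assert trace.sizes.sum() == pytest.approx(80.0 * 101)

    def test_same_seed_bit_identical(self, flat_grid):
        p = SimParams(model="GDD", t_onset=200, n_ancestral=50,
                      growth_rate=0.5, migration_rate=0.2,
                      carrying_capacity=150, seed=42)
        t1 = simulate_forward(flat_grid, p, 0)
        t2 = simulate_forward(flat_grid, p, 0)
        np.testing.assert_array_equal(t1.sizes, t2.sizes)
        np.testing.assert_array_equal(t1.imm_cnt, t2.imm_cnt)
        np.testing.assert_array_equal(t1.imm_src, t2.imm_src)

    def test_initial_state_all_in_origin(self, flat_grid):
        p = SimParams(model="GDD", t_onset=10, n_ancestral=123,
                      growth_rate=0.3, migration_rate=0.1,
                      carrying_capacity=200, seed=0)
        trace = simulate_forward(flat_grid, p, 7)
        assert trace.sizes[0, 7] == 123.0
        assert trace.sizes[0].sum() == 123.0

    def test_population_conserved_by_migration_each_generation(self, flat_grid):
        p = SimParams(model="GDD", t_onset=100, n_ancestral=60,
                      growth_rate=0.0, migration_rate=0.3,
                      carrying_capacity=60, seed=9)
        trace = simulate_forward(flat_grid, p, 12)
        # r=0: migration is the only operator, totals must stay put
        totals = trace.sizes.sum(axis=1)
        np.testing.assert_allclose(totals, 60.0, rtol=1e-12)

    def test_monotone_colonisation_gdd(self, flat_grid):
        p = SimParams(model="GDD", t_onset=300, n_ancestral=50,
                      growth_rate=0.5, migration_rate=0.2,
                      carrying_capacity=100, seed=3)
        trace = simulate_forward(flat_grid, p, 0)
        occupied = trace.sizes > 0
        ever = np.zeros(flat_grid.n_demes, bool)
        for g in range(trace.sizes.shape[0]):
            now = occupied[g] | ever
            assert now.sum() >= ever.sum()
            ever = now
        assert ever.all()  # fully suitable grid ends fully colonised

    def test_front_arrival_time_increases_with_distance(self):
        grid = strip_grid(25)
        first = np.zeros((100, 3))
        checkpoints = [6, 12, 24]
        for s in range(100):
            p = SimParams(model="GDD", t_onset=400, n_ancestral=50,
                          growth_rate=0.5, migration_rate=0.2,
                          carrying_capacity=100, seed=1000 + s)
            tr = simulate_forward(grid, p, 0)
            for j, d in enumerate(checkpoints):
                hit = np.nonzero(tr.sizes[:, d] > 0)[0]
                first[s, j] = hit[0] if hit.size else np.inf
        means = first.mean(axis=0)
        assert means[0] < means[1] < means[2]

    def test_ldd_colonises_distant_demes_earlier(self):
        """With 5% LDD the colonisation front reaches a deme 50 cells away
        stochastically earlier than under pure stepping-stone dispersal."""
        grid = strip_grid(55, rows=3)
        target = grid.deme_at(1, 51)
        t_gdd, t_ldd = [], []
        for s in range(100):
            common = dict(t_onset=600, n_ancestral=100, growth_rate=0.5,
                          migration_rate=0.2, carrying_capacity=100)
            pg = SimParams(model="GDD", seed=s, **common)
            pl = SimParams(model="LDD", ldd_fraction=0.05, seed=s, **common)
            for params, out in ((pg, t_gdd), (pl, t_ldd)):
                tr = simulate_forward(grid, params, grid.deme_at(1, 1))
                hit = np.nonzero(tr.sizes[:, target] > 0)[0]
                out.append(hit[0] if hit.size else tr.t_onset + 1)
        stat = mannwhitneyu(t_ldd, t_gdd, alternative="less")
        assert stat.pvalue < 0.01

    def test_stationary_collapse_shortens_trace(self, flat_grid):
        p = SimParams(model="GDD", t_onset=5000, n_ancestral=100,
                      growth_rate=0.5, migration_rate=0.2,
                      carrying_capacity=100, seed=4)
        tr = simulate_forward(flat_grid, p, 0, collapse_stationary=True)
        assert tr.stationary
        assert tr.n_explicit < 5000
        assert tr.sizes_at(5000).sum() == pytest.approx(
            100.0 * flat_grid.n_demes)


class TestTraceSerialization:
    def test_round_trip(self, flat_grid, tmp_path):
        p = SimParams(model="GDD", t_onset=120, n_ancestral=50,
                      growth_rate=0.5, migration_rate=0.2,
                      carrying_capacity=150, seed=6)
        trace = simulate_forward(flat_grid, p, 0)
        trace.save(tmp_path / "trace.npz")
        back = trace.load(tmp_path / "trace.npz")
        np.testing.assert_array_equal(back.sizes, trace.sizes)
        np.testing.assert_array_equal(back.imm_cnt, trace.imm_cnt)
        assert back.params == p
        assert back.t_onset == trace.t_onset
        assert back.origin_deme == trace.origin_deme


class TestSimParams:
    def test_gdd_forbids_ldd_fraction(self):
        with pytest.raises(ParameterError):
            SimParams(model="GDD", t_onset=10, n_ancestral=10,
                      growth_rate=0.3, migration_rate=0.1,
                      carrying_capacity=50, ldd_fraction=0.01)

    def test_ldd_requires_positive_fraction(self):
        with pytest.raises(ParameterError):
            SimParams(model="LDD", t_onset=10, n_ancestral=10,
                      growth_rate=0.3, migration_rate=0.1,
                      carrying_capacity=50, ldd_fraction=0.0)
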