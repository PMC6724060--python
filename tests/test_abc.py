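"""ABC rejection, regression adjustment, model choice and power machinery.

Most tests run on synthetic (Gaussian or linear-model) reference tables so
the statistical machinery is exercised independently of the simulator; a
few small end-to-end tables go through the full pipeline.
"""

import numpy as np
import pandas as pd
import pytest

from demescape import (Prior, PriorSpec, ReferenceTable, abc_reject,
                       abc_reject_epsilon, build_reference_table,
                       cv_model_choice, default_priors, model_posterior,
                       pods_parameter_power, posterior_summary,
                       power_study_design, regression_adjust, sample_prior)
from demescape.errors import EmptyPosteriorError, ParameterError


def gaussian_table(n, p=5, loc=0.0, seed=0, model="M", theta=None):
    """Synthetic table: p summary stats ~ N(loc, 1), one parameter column."""
    rng = np.random.default_rng(seed)
    ss = rng.normal(loc, 1.0, (n, p))
    theta = rng.uniform(0, 1, n) if theta is None else theta
    df = pd.DataFrame(ss, columns=[f"ss{i}" for i in range(p)])
    df.insert(0, "theta", theta)
    df.insert(0, "model", model)
    return ReferenceTable(df=df, param_names=["theta"],
                          ss_names=[f"ss{i}" for i in range(p)])


def linear_table(n, seed=0, noise=0.1, model="M"):
    """theta ~ U(0,1), SS = 2*theta + N(0, noise)."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 1, n)
    ss = 2 * theta + rng.normal(0, noise, n)
    df = pd.DataFrame({"model": model, "theta": theta, "ss0": ss})
    return ReferenceTable(df=df, param_names=["theta"], ss_names=["ss0"])


class TestPriors:
    def test_draws_respect_bounds(self):
        spec = default_priors("GDD")
        draws = sample_prior(spec, 10_000, seed=1)
        assert draws["t_onset"].between(15000, 20000).all()
        assert draws["n_ancestral"].between(100, 1000).all()
        assert draws["growth_rate"].between(0.2, 0.9).all()
        assert draws["migration_rate"].between(0.05, 0.30).all()
        assert draws["mu"].between(1e-7, 1e-5).all()
        assert "ldd_fraction" not in draws
        assert sample_prior(default_priors("LDD"), 100,
                            seed=1)["ldd_fraction"].between(0.001, 0.05).all()

    def test_uniform_mean_clt(self):
        draws = sample_prior(default_priors("GDD"), 10_000, seed=3)
        x = draws["n_ancestral"]
        se = (1000 - 100) / np.sqrt(12) / np.sqrt(10_000)
        assert x.mean() == pytest.approx(550.0, abs=3 * se)

    def test_single_draw_deterministic(self):
        a = sample_prior(default_priors("GDD"), 1, seed=9)
        b = sample_prior(default_priors("GDD"), 1, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ParameterError):
            Prior("x", "uniform", 2.0, 1.0)
        with pytest.raises(ParameterError):
            Prior("x", "loguniform", 0.0, 1.0)


class TestReferenceTable:
    @pytest.fixture(scope="class")
    def tiny_table(self):
        grid, sampling = power_study_design(12, 12)
        return build_reference_table("GDD", default_priors("GDD"), 3,
                                     grid, sampling, seed=5)

    def test_row_and_column_counts(self, tiny_table):
        assert tiny_table.n_rows + tiny_table.n_excluded == 3
        assert len(tiny_table.ss_names) == 31
        assert (tiny_table.df["model"] == "GDD").all()

    def test_identical_seed_identical_table(self):
        grid, sampling = power_study_design(12, 12)
        t1 = build_reference_table("GDD", default_priors("GDD"), 2,
                                   grid, sampling, seed=8)
        t2 = build_reference_table("GDD", default_priors("GDD"), 2,
                                   grid, sampling, seed=8)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_draws_within_priors(self, tiny_table):
        spec = default_priors("GDD")
        for p in spec.priors:
            assert tiny_table.df[p.name].between(p.lower, p.upper).all()

    def test_csv_round_trip(self, tiny_table, tmp_path):
        path = tmp_path / "table.csv"
        tiny_table.to_csv(path)
        back = ReferenceTable.read_csv(path, tiny_table.param_names)
        assert back.ss_names == tiny_table.ss_names
        np.testing.assert_allclose(back.ss_matrix(), tiny_table.ss_matrix())


class TestRejection:
    def test_retention_count(self):
        table = gaussian_table(1000)
        obs = np.zeros(5)
        assert abc_reject(table, obs, 0.1).n_retained == 100
        assert abc_reject(gaussian_table(10), np.zeros(5), 0.5).n_retained == 5

    def test_matches_brute_force_sort(self):
        table = gaussian_table(500, seed=2)
        obs = np.full(5, 0.3)
        sample = abc_reject(table, obs, 0.2)
        X = table.ss_matrix()
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med), axis=0)
        d = np.sqrt((((X - obs) / mad) ** 2).sum(axis=1))
        oracle = set(np.argsort(d)[:100])
        assert set(sample.table_indices) == oracle

    def test_epsilon_infinite_retains_all(self):
        table = gaussian_table(200)
        sample = abc_reject_epsilon(table, np.zeros(5), np.inf)
        assert sample.n_retained == 200

    def test_epsilon_at_kth_order_statistic(self):
        table = gaussian_table(300, seed=4)
        obs = np.zeros(5)
        d = np.sort(abc_reject_epsilon(table, obs, np.inf).distances)
        k = 30
        sample = abc_reject_epsilon(table, obs, (d[k - 1] + d[k]) / 2)
        assert sample.n_retained == k

    def test_epsilon_nestedness(self):
        table = gaussian_table(300, seed=6)
        obs = np.zeros(5)
        s1 = abc_reject_epsilon(table, obs, 1.0)
        s2 = abc_reject_epsilon(table, obs, 2.0)
        assert set(s1.table_indices) <= set(s2.table_indices)

    def test_empty_posterior_raises(self):
        table = gaussian_table(50, loc=100.0)
        with pytest.raises(EmptyPosteriorError):
            abc_reject_epsilon(table, np.zeros(5), 1e-6)

    def test_tolerance_equals_epsilon_at_order_statistic(self):
        """abc_reject at tolerance k/n and abc_reject_epsilon at the k-th
        order-statistic distance retain the same set."""
        table = gaussian_table(400, seed=8)
        obs = np.full(5, -0.2)
        s_tol = abc_reject(table, obs, 0.25)
        d = np.sort(abc_reject_epsilon(table, obs, np.inf).distances)
        s_eps = abc_reject_epsilon(table, obs, d[99])
        assert set(s_tol.table_indices) == set(s_eps.table_indices)

    def test_weights_normalised(self):
        sample = abc_reject(gaussian_table(100), np.zeros(5), 0.3)
        assert sample.weights.sum() == pytest.approx(1.0)
        assert (sample.weights >= 0).all()


class TestRegressionAdjustment:
    def test_zero_variance_ss_is_identity(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, 1, 100)
        df = pd.DataFrame({"model": "M", "theta": theta,
                           "ss0": np.ones(100), "ss1": np.full(100, 2.0)})
        table = ReferenceTable(df=df, param_names=["theta"],
                               ss_names=["ss0", "ss1"])
        obs = np.array([1.0, 2.0])
        with pytest.warns(UserWarning, match="zero-MAD"):
            sample = abc_reject(table, obs, 0.5)
            adj = regression_adjust(sample, table, obs)
        np.testing.assert_allclose(adj.params["theta"],
                                   sample.params["theta"], atol=1e-12)

    def test_improves_on_rejection_in_linear_model(self):
        # a wide tolerance makes the retained window visibly biased toward
        # the prior center, which the local-linear correction removes
        wins = 0
        truth_rng = np.random.default_rng(314)
        for trial in range(100):
            table = linear_table(1000, seed=trial, noise=0.05)
            truth = float(truth_rng.uniform(0.1, 0.9))
            obs = np.array([2 * truth])
            sample = abc_reject(table, obs, 0.5)
            adj = regression_adjust(sample, table, obs)
            e_rej = abs(np.average(sample.params["theta"],
                                   weights=sample.weights) - truth)
            e_adj = abs(np.average(adj.params["theta"],
                                   weights=adj.weights) - truth)
            wins += e_adj <= e_rej
        assert wins >= 80

    def test_clipping_respects_prior_bounds(self):
        table = linear_table(300, seed=1, noise=0.5)
        spec = PriorSpec(priors=[Prior("theta", "uniform", 0.0, 1.0)])
        obs = np.array([2.5])  # beyond the range of 2*theta
        sample = abc_reject(table, obs, 0.2)
        adj = regression_adjust(sample, table, obs, prior_spec=spec)
        assert adj.params["theta"].between(0.0, 1.0).all()


class TestModelChoice:
    def test_identical_tables_give_even_odds(self):
        tables = {"A": gaussian_table(2000, seed=1, model="A"),
                  "B": gaussian_table(2000, seed=2, model="B")}
        probs = model_posterior(tables, np.zeros(5), 0.1)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert probs["A"] == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("method", ["rejection", "mnlogistic"])
    def test_separable_clusters_identified(self, method):
        tables = {"A": gaussian_table(1000, loc=0.0, seed=3, model="A"),
                  "B": gaussian_table(1000, loc=8.0, seed=4, model="B")}
        probs = model_posterior(tables, np.zeros(5), 0.1, method=method)
        assert probs["A"] >= 0.95
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cv_perfectly_separable(self):
        tables = {"A": gaussian_table(300, loc=0.0, seed=5, model="A"),
                  "B": gaussian_table(300, loc=10.0, seed=6, model="B")}
        confusion, rates, mean_rate = cv_model_choice(tables, 20, 0.1, seed=1)
        assert mean_rate == 1.0
        assert confusion.loc["A"].sum() == 20
        assert confusion.loc["B"].sum() == 20

    def test_cv_identical_tables_near_chance(self):
        tables = {"A": gaussian_table(400, seed=7, model="A"),
                  "B": gaussian_table(400, seed=8, model="B")}
        _conf, _rates, mean_rate = cv_model_choice(tables, 40, 0.1, seed=2)
        assert 0.3 <= mean_rate <= 0.7


class TestPosteriorSummary:
    def test_degenerate_point_mass(self):
        s = posterior_summary(np.full(50, 3.25))
        assert s.mode == s.mean == s.median == 3.25
        assert s.hpdi_90 == (3.25, 3.25)

    def test_uniform_sample_hpdi_width(self):
        rng = np.random.default_rng(10)
        s = posterior_summary(rng.uniform(0, 1, 100_000))
        width = s.hpdi_90[1] - s.hpdi_90[0]
        assert width == pytest.approx(0.9, abs=0.02)

    def test_hpdi_inside_sample_range(self, rng):
        x = rng.normal(5, 2, 500)
        s = posterior_summary(x)
        assert x.min() <= s.hpdi_90[0] <= s.median <= s.hpdi_90[1] <= x.max()

    def test_needs_ten_draws(self):
        with pytest.raises(ParameterError):
            posterior_summary(np.arange(5.0))


class TestPodsPower:
    def test_exact_match_gives_zero_error(self):
        table = linear_table(200, seed=11)
        pod_row = table.df.iloc[[7]].reset_index(drop=True)
        pods = ReferenceTable(df=pod_row, param_names=["theta"],
                              ss_names=["ss0"])
        power = pods_parameter_power(table, pods, tolerance=0.1)
        # the POD's own row dominates the retained set: small median error
        assert abs(power.loc["theta", "bias"]) < 0.05

    def test_coverage_calibrated_in_linear_model(self):
        table = linear_table(2000, seed=12)
        pods = linear_table(150, seed=13)
        power = pods_parameter_power(table, pods, tolerance=0.1)
        assert 0.80 <= power.loc["theta", "coverage_90"] <= 0.97

    def test_rmse_shrinks_with_table_size(self):
        small = linear_table(200, seed=14)
        big = linear_table(2000, seed=14)
        pods = linear_table(60, seed=15)
        p_small = pods_parameter_power(small, pods, tolerance=0.1)
        p_big = pods_parameter_power(big, pods, tolerance=0.1)
        assert (p_big.loc["theta", "rmse"]
                < p_small.loc["theta", "rmse"])
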