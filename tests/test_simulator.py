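"""Individual-based simulator: development, selection, mutation, runs."""

import math

import numpy as np
import pytest

from labordiv import (
    ModelParams,
    SimConfig,
    Trajectory,
    build_links,
    coordination_cost,
    fitness_random,
    group_fecundities,
    grow_groups,
    mutate,
    next_generation,
    resolve_phenotypes,
    run_experiment,
    run_replicate,
    variability_test,
)
from labordiv.simulate import _develop, replicate_seeds


def make_config(l=1, m=10, epsilon=1.0, theta=0.025, **kw):
    defaults = dict(target_pop_size=200, generations=10, replicates=2, seed=3)
    defaults.update(kw)
    return SimConfig(params=ModelParams(l=l, m=m, epsilon=epsilon, theta=theta), **defaults)


class TestCoordinationCost:
    @pytest.mark.parametrize("shape", ["decelerating", "linear", "accelerating"])
    def test_endpoints_shared_across_shapes(self, shape):
        theta = 0.025
        assert coordination_cost(0.0, theta, shape) == pytest.approx(0.0)
        assert coordination_cost(1.0, theta, shape) == pytest.approx(
            theta * (1 - math.exp(-5)), abs=1e-12
        )

    def test_default_shape_value(self):
        assert coordination_cost(1.0, 0.025) == pytest.approx(0.0248316, abs=1e-6)

    def test_decelerating_concave_accelerating_convex(self):
        s = np.linspace(0, 1, 101)
        dec = np.diff(coordination_cost(s, 0.025, "decelerating"), 2)
        acc = np.diff(coordination_cost(s, 0.025, "accelerating"), 2)
        assert np.all(dec <= 1e-12)
        assert np.all(acc >= -1e-12)

    def test_costs_increase_with_coordination(self):
        s = np.linspace(0, 1, 51)
        for shape in ("decelerating", "linear", "accelerating"):
            assert np.all(np.diff(coordination_cost(s, 0.1, shape)) > 0)

    def test_negative_theta_rejected(self):
        with pytest.raises(ValueError):
            coordination_cost(0.5, -0.01)


class TestGrowGroups:
    def test_lineage_structure(self):
        p = ModelParams(l=2, m=3, epsilon=0.5)
        fq = np.array([[0.1, 0.9], [0.3, 0.7]])
        fs = np.zeros_like(fq)
        groups = grow_groups(fq, fs, p)
        assert groups.q.shape == (2, 6)
        np.testing.assert_array_equal(groups.lineage_of_cell, [0, 0, 0, 1, 1, 1])
        np.testing.assert_allclose(groups.q[0], [0.1, 0.1, 0.1, 0.9, 0.9, 0.9])

    def test_clonal_groups_share_genotype(self):
        p = ModelParams(l=1, m=5, epsilon=0.5)
        groups = grow_groups(np.array([[0.4]]), np.array([[0.2]]), p)
        assert np.unique(groups.q).size == 1 and np.unique(groups.s).size == 1

    @pytest.mark.parametrize("l,m", [(1, 6), (2, 3), (4, 5)])
    def test_whole_group_relatedness_is_one_over_l(self, l, m):
        """P(two members share a founder, sampling with replacement) = 1/l."""
        p = ModelParams(l=l, m=m, epsilon=0.5)
        groups = grow_groups(np.zeros((1, l)), np.zeros((1, l)), p)
        lin = groups.lineage_of_cell
        same = (lin[:, None] == lin[None, :]).mean()
        assert same == pytest.approx(1.0 / l)

    def test_founder_shape_mismatch_rejected(self):
        p = ModelParams(l=2, m=3, epsilon=0.5)
        with pytest.raises(ValueError):
            grow_groups(np.zeros((4, 3)), np.zeros((4, 3)), p)


class TestBuildLinks:
    def test_no_coordination_no_links(self):
        p = ModelParams(l=1, m=8, epsilon=1.0)
        groups = grow_groups(np.zeros((3, 1)), np.zeros((3, 1)), p)
        links = build_links(groups, np.random.default_rng(0))
        assert not links.any()

    def test_full_coordination_observes_everyone_else(self):
        p = ModelParams(l=2, m=4, epsilon=1.0)
        groups = grow_groups(np.zeros((2, 2)), np.ones((2, 2)), p)
        links = build_links(groups, np.random.default_rng(0))
        assert links.sum() == 2 * 8 * 7  # all ordered pairs, no self-links
        assert not links[:, np.arange(8), np.arange(8)].any()

    def test_in_degree_is_binomial_in_receiver_s(self):
        p = ModelParams(l=1, m=20, epsilon=1.0)
        G = 500
        groups = grow_groups(np.zeros((G, 1)), np.full((G, 1), 0.5), p)
        links = build_links(groups, np.random.default_rng(1))
        indeg = links.sum(axis=2).ravel()  # 10^4 draws of Binomial(19, 0.5)
        se = math.sqrt(19 * 0.25 / indeg.size)
        assert abs(indeg.mean() - 9.5) < 3 * se

    def test_own_lineage_scope_restricts_links(self):
        p = ModelParams(l=2, m=3, epsilon=1.0)
        groups = grow_groups(np.zeros((5, 2)), np.ones((5, 2)), p)
        links = build_links(groups, np.random.default_rng(2), scope="own_lineage")
        lin = groups.lineage_of_cell
        cross = lin[:, None] != lin[None, :]
        assert not (links & cross[None]).any()
        assert links.sum() == 5 * 6 * 2  # within a lineage of 3: 2 clone-mates each


class TestResolvePhenotypes:
    def test_no_links_no_target_no_helpers(self):
        p = ModelParams(l=1, m=10, epsilon=1.0)
        groups = grow_groups(np.zeros((4, 1)), np.zeros((4, 1)), p)
        build_links(groups, np.random.default_rng(0))
        helpers = resolve_phenotypes(groups, np.random.default_rng(0))
        assert not helpers.any()

    @pytest.mark.parametrize(
        "helper_seniors,expect_helper",
        [(2, False), (1, True)],  # observed 2/4 = 0.5 >= 0.4; 1/4 = 0.25 < 0.4
    )
    def test_threshold_rule_against_observed_fraction(self, helper_seniors, expect_helper):
        """A cell helps iff observed helper fraction falls below its target."""
        p = ModelParams(l=1, m=5, epsilon=1.0)
        # cells 0..1: q chosen so they deterministically fix their phenotype
        # before the focal cell 2 (q=0.4) is visited; cells 3,4 stay reproductive
        q_cells = np.array([1.0, 1.0, 0.4, 0.0, 0.0])
        q_cells[:helper_seniors] = 1.0
        q_cells[helper_seniors:2] = 0.0
        groups = grow_groups(q_cells.reshape(1, 5), np.zeros((1, 5)), ModelParams(l=5, m=1, epsilon=1.0))
        groups.links = np.zeros((1, 5, 5), dtype=bool)
        groups.links[0, 2, :] = True
        groups.links[0, 2, 2] = False  # focal observes the other four
        order = np.array([[0, 1, 3, 4, 2]])
        helpers = resolve_phenotypes(groups, np.random.default_rng(0), order=order)
        assert helpers[0, 2] == expect_helper

    def test_full_coordination_tracks_target_within_one_cell(self):
        p = ModelParams(l=1, m=10, epsilon=1.0)
        for q in (0.0, 0.2, 0.4, 0.55, 0.9, 1.0):
            for seed in range(5):
                groups = grow_groups(np.full((20, 1), q), np.ones((20, 1)), p)
                rng = np.random.default_rng(seed)
                build_links(groups, rng)
                resolve_phenotypes(groups, rng)
                assert np.all(np.abs(groups.P - q) <= 1.0 / p.n + 1e-12)

    def test_coordination_reduces_deviation_from_target(self):
        p = ModelParams(l=1, m=10, epsilon=1.0)
        q = 0.4
        devs = {}
        for s_level in (0.0, 1.0):
            groups = grow_groups(np.full((1000, 1), q), np.full((1000, 1), s_level), p)
            rng = np.random.default_rng(11)
            build_links(groups, rng)
            resolve_phenotypes(groups, rng)
            devs[s_level] = np.abs(groups.P - q).mean()
        assert devs[1.0] < devs[0.0]

    def test_random_lineage_helper_counts_are_binomial(self):
        """With s = 0 each lineage's helper count is Binomial(m, q)."""
        from scipy import stats

        p = ModelParams(l=1, m=10, epsilon=1.0)
        q = 0.3
        counts = []
        rng = np.random.default_rng(5)
        for _ in range(10):
            groups = grow_groups(np.full((1000, 1), q), np.zeros((1000, 1)), p)
            build_links(groups, rng)
            resolve_phenotypes(groups, rng)
            counts.append(groups.realized_helper.sum(axis=1))
        counts = np.concatenate(counts)  # 10^4 lineage draws
        k = np.arange(p.m + 1)
        expected = stats.binom.pmf(k, p.m, q) * counts.size
        observed = np.bincount(counts, minlength=p.m + 1).astype(float)
        # pool bins with small expectation into the tails
        keep = expected >= 5
        obs = np.concatenate([[observed[~keep & (k < 5)].sum()], observed[keep], [observed[~keep & (k >= 5)].sum()]])
        exp = np.concatenate([[expected[~keep & (k < 5)].sum()], expected[keep], [expected[~keep & (k >= 5)].sum()]])
        obs, exp = obs[exp > 0], exp[exp > 0]
        stat, pval = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert pval > 0.001


class TestFecundityAndSelection:
    def test_helpers_have_zero_fecundity(self):
        p = ModelParams(l=1, m=4, epsilon=0.5)
        groups = grow_groups(np.full((10, 1), 0.5), np.zeros((10, 1)), p)
        build_links(groups, np.random.default_rng(0))
        resolve_phenotypes(groups, np.random.default_rng(0))
        w = group_fecundities(groups, p)
        assert np.all(w[groups.realized_helper] == 0.0)

    def test_reproductive_fecundity_values(self):
        p = ModelParams(l=1, m=10, epsilon=1.0, theta=0.025)
        groups = grow_groups(np.zeros((1, 1)), np.zeros((1, 1)), p)
        groups.realized_helper = np.zeros((1, 10), dtype=bool)
        groups.realized_helper[0, :4] = True  # P = 0.4
        w = group_fecundities(groups, p)
        assert w[0, 5] == pytest.approx(0.4)  # s=0, eps=1, P=0.4
        p0 = ModelParams(l=1, m=10, epsilon=0.0, theta=0.025)
        groups.s[:] = 1.0
        w = group_fecundities(groups, p0)
        assert w[0, 5] == pytest.approx(1 - 0.025 * (1 - math.exp(-5)), abs=1e-9)

    def test_population_mean_fecundity_matches_analytic_expectation(self):
        """Monomorphic s=0 populations realize the random-specializer fitness."""
        for l, m, q in [(1, 10, 0.4), (2, 5, 0.3)]:
            p = ModelParams(l=l, m=m, epsilon=0.9)
            G = 20_000 // (l * m)
            cfg = make_config(l=l, m=m, epsilon=0.9, target_pop_size=20_000)
            rng = np.random.default_rng(17)
            groups, w = _develop(np.full((G, l), q), np.zeros((G, l)), cfg, rng)
            assert w.mean() == pytest.approx(fitness_random(q, q, p), abs=0.01)

    def test_single_reproductive_parent_takes_over(self):
        p = ModelParams(l=1, m=4, epsilon=0.5)
        cfg = make_config(l=1, m=4, epsilon=0.5, target_pop_size=20, p_mut=0.0)
        groups = grow_groups(np.linspace(0, 1, 5).reshape(5, 1), np.zeros((5, 1)), p)
        groups.realized_helper = np.ones((5, 4), dtype=bool)
        groups.realized_helper[2, 1] = False  # the only reproductive (q = 0.5)
        w = group_fecundities(groups, p)
        fq, fs = next_generation(groups, w, cfg, np.random.default_rng(0))
        assert np.all(fq == 0.5)

    def test_all_helpers_is_an_error(self):
        p = ModelParams(l=1, m=4, epsilon=0.5)
        cfg = make_config(l=1, m=4, epsilon=0.5, target_pop_size=20)
        groups = grow_groups(np.full((5, 1), 0.5), np.zeros((5, 1)), p)
        groups.realized_helper = np.ones((5, 4), dtype=bool)
        w = group_fecundities(groups, p)
        with pytest.raises(RuntimeError, match="fecundity"):
            next_generation(groups, w, cfg, np.random.default_rng(0))

    def test_uniform_fecundity_sampling_is_unbiased(self):
        """Equal weights give multinomial founder counts (chi-square sanity)."""
        from scipy import stats

        p = ModelParams(l=1, m=2, epsilon=0.5)
        cfg = make_config(l=1, m=2, epsilon=0.5, target_pop_size=20, p_mut=0.0)
        founder_q = np.linspace(0.05, 0.95, 10)
        groups = grow_groups(founder_q.reshape(10, 1), np.zeros((10, 1)), p)
        groups.realized_helper = np.zeros((10, 2), dtype=bool)
        w = group_fecundities(groups, p)  # all reproductive, equal weights
        rng = np.random.default_rng(23)
        tallies = np.zeros(10)
        draws = 1000
        for _ in range(draws):
            fq, _ = next_generation(groups, w, cfg, rng)
            for v in fq.ravel():
                tallies[np.argmin(np.abs(founder_q - v))] += 1
        _, pval = stats.chisquare(tallies)  # each founder value equally likely
        assert pval > 0.001


class TestMutation:
    def test_zero_rate_is_identity(self):
        cfg = make_config(p_mut=0.0)
        q = np.random.default_rng(0).random((50, 1))
        q2, s2 = mutate(q, q, cfg, np.random.default_rng(1))
        np.testing.assert_array_equal(q, q2)

    def test_mutation_distribution(self):
        cfg = make_config(p_mut=0.01, mut_sd=0.1)
        n = 400_000
        q = np.full((n, 1), 0.5)
        q2, _ = mutate(q, q, cfg, np.random.default_rng(2))
        changed = q2 != 0.5
        frac = changed.mean()
        assert frac == pytest.approx(0.01, abs=0.002)
        deviations = (q2 - 0.5)[changed]
        assert deviations.mean() == pytest.approx(0.0, abs=0.005)
        assert deviations.std() == pytest.approx(0.1, abs=0.01)

    def test_clamped_at_boundaries(self):
        cfg = make_config(p_mut=1.0, mut_sd=0.5)
        q = np.zeros((10_000, 1))
        q2, s2 = mutate(q, np.ones((10_000, 1)), cfg, np.random.default_rng(3))
        assert q2.min() >= 0.0 and q2.max() <= 1.0
        assert s2.min() >= 0.0 and s2.max() <= 1.0

    def test_locked_coordination_never_mutates(self):
        cfg = make_config(p_mut=1.0, s_locked_at_zero=True)
        s = np.zeros((1000, 1))
        _, s2 = mutate(s.copy(), s, cfg, np.random.default_rng(4))
        assert np.all(s2 == 0.0)


class TestRuns:
    def test_identical_seeds_identical_trajectories(self):
        cfg = make_config(generations=50, target_pop_size=200)
        t1 = run_replicate(cfg, seed=42)
        t2 = run_replicate(cfg, seed=42)
        np.testing.assert_array_equal(t1.mean_P, t2.mean_P)
        np.testing.assert_array_equal(t1.mean_q, t2.mean_q)
        t3 = run_replicate(cfg, seed=43)
        assert not np.array_equal(t1.mean_P, t3.mean_P)

    def test_trajectory_length_and_bounds(self):
        cfg = make_config(generations=30)
        traj = run_replicate(cfg)
        assert len(traj) == 30
        for arr in (traj.mean_q, traj.mean_s, traj.mean_P):
            assert np.all((arr >= 0) & (arr <= 1))

    def test_zero_generations_records_initial_state(self):
        cfg = make_config(generations=0, init_q=0.3)
        traj = run_replicate(cfg)
        assert len(traj) == 1
        assert traj.mean_q[0] == pytest.approx(0.3)

    def test_locked_coordination_stays_zero(self):
        cfg = make_config(generations=100, s_locked_at_zero=True)
        traj = run_replicate(cfg)
        assert np.all(traj.mean_s == 0.0)

    def test_experiment_summarizes_trailing_window(self):
        cfg = make_config(generations=40, replicates=3, record_fraction=0.25)
        res = run_experiment(cfg)
        traj = res.trajectories[0]
        expect = traj.mean_P[-10:].mean()
        assert res.per_replicate.loc[0, "mean_P"] == pytest.approx(expect)
        assert len(res.per_replicate) == 3
        summ = res.summary()
        assert set(summ["quantity"]) == {"mean_q", "mean_s", "mean_P"}

    def test_single_replicate_summary_equals_its_run(self):
        cfg = make_config(generations=20, replicates=1)
        res = run_experiment(cfg)
        summ = res.summary().set_index("quantity")
        assert summ.loc["mean_P", "mean"] == pytest.approx(
            res.trajectories[0].window_means()["mean_P"]
        )
        assert summ.loc["mean_P", "se"] == 0.0

    def test_adding_replicates_preserves_earlier_seeds(self):
        assert replicate_seeds(9, 3) == replicate_seeds(9, 5)[:3]


class TestVariabilityReport:
    @staticmethod
    def _traj(mean_s, mean_P, cfg):
        n = cfg.generations
        return Trajectory(
            mean_q=np.full(n, 0.5),
            mean_s=np.full(n, mean_s),
            mean_P=np.full(n, mean_P),
            config=cfg,
            seed=0,
        )

    def test_known_variance_ratio_recovered(self):
        cfg = make_config(generations=10)
        s_vals = [0.1, 0.3, 0.5, 0.7, 0.9]
        P_vals = [0.3, 0.4, 0.5, 0.6, 0.7]  # half the spread -> quarter variance
        trajs = [self._traj(s, P, cfg) for s, P in zip(s_vals, P_vals)]
        report = variability_test(trajs)
        assert report.ratio == pytest.approx(4.0)
        assert not report.degenerate
        assert 0 < report.p_value <= 1

    def test_identical_replicates_degenerate(self):
        cfg = make_config(generations=10)
        trajs = [self._traj(0.4, 0.5, cfg) for _ in range(4)]
        report = variability_test(trajs)
        assert report.degenerate

    def test_needs_two_replicates(self):
        cfg = make_config(generations=10)
        with pytest.raises(ValueError):
            variability_test([self._traj(0.4, 0.5, cfg)])
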