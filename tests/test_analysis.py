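"""Metrics, regressions, rank tests and the designed experiments."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synmet import analysis, fba, sampling
from synmet.universe import UniverseConfig, generate_universe


class TestComputeMetrics:
    def test_t1_minimal_metrics(self, t1_universe, t1_env, t1_spec):
        met = analysis.compute_metrics(frozenset({"R1", "R2"}), t1_universe,
                                       [t1_env], t1_spec)
        assert (met.R, met.B, met.N) == (2, 1, 1)
        assert met.S == pytest.approx(20.0, abs=1e-6)
        assert met.R_A_per_env == [3]  # R1, R2 + the source transport
        assert met.W_per_env == [pytest.approx(0.0, abs=1e-6)]

    def test_minimal_networks_have_all_internal_reactions_active(
            self, small_universe, small_envs, small_spec, rng):
        # in minimal networks every reaction is active in some environment;
        # with one dedicated route per pathway, internal-only R_A per env is
        # the route reactions serving that env plus all anabolic routes
        net = sampling.minimize_network(
            frozenset(small_universe.internal_reaction_ids()),
            small_universe, small_envs, small_spec, rng)
        per_env_active = set()
        for env in small_envs:
            sol = fba.maximize_biosynthetic_flux(
                net.internal_reactions, small_universe, env, small_spec)
            per_env_active |= {
                rid for rid, v in sol.fluxes.items()
                if rid in net.internal_reactions and abs(v) > 1e-6}
        assert per_env_active == set(net.internal_reactions)

    def test_metrics_deterministic(self, small_universe, small_envs,
                                   small_spec):
        g = frozenset(small_universe.internal_reaction_ids())
        a = analysis.compute_metrics(g, small_universe, small_envs, small_spec)
        b = analysis.compute_metrics(g, small_universe, small_envs, small_spec)
        assert (a.R, a.B, a.N) == (b.R, b.B, b.N)
        assert a.S == pytest.approx(b.S, abs=1e-9)
        assert a.R_A_per_env == b.R_A_per_env
        assert a.W_per_env == pytest.approx(b.W_per_env, abs=1e-9)


class TestLinearFit:
    def test_exact_line_recovered(self):
        x = np.arange(5.0)
        res = analysis.fit_linear_ci(x, 2 * x + 3)
        assert res.slope == pytest.approx(2.0, abs=1e-10)
        assert res.intercept == pytest.approx(3.0, abs=1e-10)
        assert res.ci_halfwidth == pytest.approx(0.0, abs=1e-8)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slope_identity_with_pearson(self, rng):
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        res = analysis.fit_linear_ci(x, y)
        r, _ = analysis.pearson_with_p(x, y)
        assert res.slope == pytest.approx(r * y.std(ddof=1) / x.std(ddof=1),
                                          abs=1e-10)
        assert res.r_squared == pytest.approx(r ** 2, abs=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(analysis.AnalysisError):
            analysis.fit_linear_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_ci_coverage_near_nominal(self):
        """95% t-interval covers the true slope in ~95% of replicates."""
        gen = np.random.default_rng(7)
        x = np.linspace(0, 1, 20)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = 2 * x + 3 + gen.normal(scale=0.5, size=x.size)
            res = analysis.fit_linear_ci(x, y)
            hits += abs(res.slope - 2.0) <= res.ci_halfwidth
        assert hits / n_rep == pytest.approx(0.95, abs=0.02)


class TestMultipleFit:
    def test_exact_plane_recovered(self):
        gen = np.random.default_rng(0)
        X = pd.DataFrame({"x1": gen.uniform(size=30),
                          "x2": gen.uniform(size=30)})
        y = 2 * X["x1"] + 3 * X["x2"] + 171
        coef, r2 = analysis.fit_multiple(X, y)
        assert coef["x1"] == pytest.approx(2.0, abs=1e-8)
        assert coef["x2"] == pytest.approx(3.0, abs=1e-8)
        assert coef["const"] == pytest.approx(171.0, abs=1e-7)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_r_squared_identity(self, rng):
        X = pd.DataFrame({"x1": rng.uniform(size=50),
                          "x2": rng.uniform(size=50)})
        y = X["x1"].values - X["x2"].values + rng.normal(size=50)
        coef, r2 = analysis.fit_multiple(X, y)
        pred = coef["const"] + coef["x1"] * X["x1"] + coef["x2"] * X["x2"]
        sse = float(((y - pred) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        assert r2 == pytest.approx(1 - sse / sst, abs=1e-10)

    def test_single_predictor_matches_simple_ols(self, rng):
        x = rng.uniform(size=25)
        y = 4 * x + rng.normal(size=25)
        coef, _ = analysis.fit_multiple(pd.DataFrame({"x": x}), y)
        simple = analysis.fit_linear_ci(x, y)
        assert coef["x"] == pytest.approx(simple.slope, abs=1e-10)
        assert coef["const"] == pytest.approx(simple.intercept, abs=1e-10)

    def test_rank_deficiency_rejected(self):
        X = pd.DataFrame({"x1": [1.0, 2, 3, 4, 5, 6],
                          "x2": [2.0, 4, 6, 8, 10, 12]})
        with pytest.raises(analysis.AnalysisError):
            analysis.fit_multiple(X, np.arange(6.0))


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.arange(10.0)
        r, _ = analysis.pearson_with_p(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_p_value_matches_exhaustive_permutation(self):
        """t-based p on the 7-organism table agrees with the exact
        permutation distribution over all 7! orderings."""
        records = analysis.load_table1()
        N = np.array([rec.N for rec in records], float)
        R = np.array([rec.R for rec in records], float)
        r_obs, p_t = analysis.pearson_with_p(N, R)
        from itertools import permutations
        count = 0
        total = 0
        for perm in permutations(range(7)):
            r_perm = stats.pearsonr(N[list(perm)], R)[0]
            count += abs(r_perm) >= abs(r_obs) - 1e-12
            total += 1
        p_exact = count / total
        assert p_t == pytest.approx(p_exact, abs=0.01)


class TestMannWhitney:
    def test_identical_samples_no_shift(self):
        a = [1.0, 2.0, 3.0, 4.0]
        _, p = analysis.mann_whitney_u(a, list(a))
        assert p > 0.5

    def test_exact_null_matches_enumeration_3v3(self):
        """For n=(3,3) the U statistic's null distribution has 20 equally
        likely rank arrangements; the exact p must match enumeration."""
        a, b = [1.0, 5.0, 6.0], [2.0, 3.0, 4.0]
        u_obs, p = analysis.mann_whitney_u(a, b)
        ranks = range(1, 7)
        u_values = []
        for a_ranks in combinations(ranks, 3):
            r1 = sum(a_ranks)
            u1 = r1 - 3 * 4 / 2
            u_values.append(max(u1, 9 - u1))  # two-sided: larger of U1, U2
        u_eff = max(u_obs, 9 - u_obs)
        p_exact = sum(u >= u_eff for u in u_values) / len(u_values)
        assert p == pytest.approx(p_exact, abs=1e-12)

    def test_strong_shift_reaches_reported_magnitude(self, rng):
        a = rng.normal(0.0, 0.5, size=80)
        b = rng.normal(10.0, 0.5, size=80)
        _, p = analysis.mann_whitney_u(a, b)
        assert p < 1e-10


class TestTable1:
    def test_printed_correlation_rounds_to_point_nine(self):
        report = analysis.table1_comparative()
        assert round(report["pearson_r_N_R"], 1) == 0.9
        assert report["p_value_N_R"] == pytest.approx(0.005, abs=0.001)

    def test_leave_one_out_stays_positive(self):
        records = analysis.load_table1()
        for i in range(len(records)):
            sub = records[:i] + records[i + 1:]
            report = analysis.table1_comparative(sub)
            assert report["pearson_r_N_R"] > 0

    def test_duplicate_rows_same_point_estimates(self):
        records = analysis.load_table1()
        once = analysis.table1_comparative(records)
        twice = analysis.table1_comparative(records * 2)
        assert twice["pearson_r_N_R"] == pytest.approx(
            once["pearson_r_N_R"], abs=1e-12)
        assert twice["n_organisms"] == 14


@pytest.fixture(scope="module")
def related_universe():
    # 5 related targets share a 3-reaction prefix (plus one step each);
    # 5 independent targets need 4-reaction routes: 3 + 5*1 < 5*4
    return generate_universe(UniverseConfig(
        n_carbon_sources=2, n_biomass_candidates=5, L_N=1, L_B=4,
        redundancy_factor=0, n_waste_branches=1, n_related_targets=5,
        related_prefix_len=3, seed=11))


class TestCompareTargetSets:
    def test_related_targets_need_fewer_reactions(self, related_universe):
        u = related_universe
        envs = [fba.Environment.minimal_medium(u, c) for c in u.carbon_sources]
        related = [t for t in u.biomass_candidates if t.startswith("relbm")]
        independent = [t for t in u.biomass_candidates
                       if not t.startswith("relbm")]
        bm_rel = fba.BiomassSpec.isostoichiometric(related)
        bm_rnd = fba.BiomassSpec.isostoichiometric(independent)
        rng = np.random.default_rng(3)
        report = analysis.compare_target_sets(u, envs, bm_rel, [bm_rnd],
                                              n_networks=4, rng=rng)
        # designed counts: catabolic 2*1 + (3 + 5) vs catabolic 2 + 5*4
        assert report["mean_R_related"] == pytest.approx(10.0)
        assert report["mean_R_random"] == pytest.approx(22.0)
        assert np.median(report["R_related"]) < np.median(report["R_random"])

    def test_identical_sets_show_no_difference(self, related_universe):
        u = related_universe
        envs = [fba.Environment.minimal_medium(u, u.carbon_sources[0])]
        targets = [t for t in u.biomass_candidates if not t.startswith("rel")]
        bm = fba.BiomassSpec.isostoichiometric(targets)
        rng = np.random.default_rng(5)
        report = analysis.compare_target_sets(u, envs, bm, [bm],
                                              n_networks=4, rng=rng)
        assert report["p_R"] > 0.05


class TestDesignExperiment:
    def test_slope_recovery_minimal_mode(self):
        u = generate_universe(UniverseConfig(
            n_carbon_sources=4, n_biomass_candidates=4, L_N=2, L_B=3,
            redundancy_factor=1, n_waste_branches=1, seed=21))
        rng = np.random.default_rng(2)
        table, regs = analysis.run_design_experiment(
            u, {"N": [1, 2, 3], "B": [1, 2, 3]}, replicates=2,
            mode="minimal", rng=rng)
        ok = table[table["status"] == "ok"]
        assert len(ok) == 18
        # designed law: R = L_N * N + L_B * B exactly
        assert np.allclose(ok["R"], 2 * ok["N"] + 3 * ok["B"])
        assert abs(regs["R~N"].slope - 2.0) <= regs["R~N"].ci_halfwidth + 1e-8
        assert abs(regs["R~B"].slope - 3.0) <= regs["R~B"].ci_halfwidth + 1e-8
        multi = regs["R~N+B"]["coefficients"]
        assert multi["N"] == pytest.approx(2.0, abs=1e-6)
        assert multi["B"] == pytest.approx(3.0, abs=1e-6)
        assert regs["R~N+B"]["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_single_cell_single_replicate_no_regression(self, small_universe):
        rng = np.random.default_rng(1)
        table, regs = analysis.run_design_experiment(
            small_universe, {"N": [2], "B": [1]}, replicates=1,
            mode="minimal", rng=rng)
        assert len(table) == 1
        assert regs == {}

    def test_failed_cell_recorded_run_continues(self, small_universe):
        rng = np.random.default_rng(1)
        # target R below the attainable minimal size fails that cell only
        table, _ = analysis.run_design_experiment(
            small_universe, {"N": [2], "B": [2], "R": [2, 20]}, replicates=1,
            mode="mcmc", rng=rng, mcmc_samples_per_start=1,
            burn_in_factor=1, thinning_factor=1)
        status = table.groupby(table["R"].notna())["status"].first()
        assert any(table["status"].str.startswith("failed"))
        assert (table["status"] == "ok").sum() >= 1

    def test_carbon_books_balance_in_results(self, small_universe):
        rng = np.random.default_rng(4)
        table, _ = analysis.run_design_experiment(
            small_universe, {"N": [2, 3], "B": [1, 2]}, replicates=1,
            mode="minimal", rng=rng)
        ok = table[table["status"] == "ok"]
        # uptake carbon = biomass carbon + waste; source 6C, targets 3C,
        # isostoichiometric weights: 10*6 = S*3*B + W per environment mean
        for _, row in ok.iterrows():
            assert 10 * 6 == pytest.approx(
                row["S"] * 3 * row["B"] + row["W_mean"], rel=1e-6)
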