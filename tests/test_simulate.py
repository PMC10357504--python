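import numpy as np
import pytest

from mr2.simulate import (ConfigError, ScenarioConfig,
                          residual_correlation_arguments,
                          empirical_outcome_correlation, extract_summary,
                          simulate_individual, simulate_summary,
                          theoretical_residual_correlation)


class TestScenarioConfig:
    def test_scenario_defaults_resolve(self):
        assert ScenarioConfig(scenario="III_undirected_pleiotropy").theta_a == 1.0
        assert ScenarioConfig(scenario="V_dependence").r_y == 0.6
        assert ScenarioConfig(scenario="II_confounding").r_y == 0.0
        null = ScenarioConfig(scenario="I_null")
        assert null.theta_xu == 0.0 and null.theta_yu == 0.0

    def test_explicit_values_survive(self):
        cfg = ScenarioConfig(scenario="III_undirected_pleiotropy", theta_a=0.25)
        assert cfg.theta_a == 0.25

    @pytest.mark.parametrize("kw", [
        dict(sparsity=1.5), dict(r_x=1.0), dict(overlap=2.0),
        dict(n_individuals=101), dict(scenario="bogus"),
        dict(n_outcomes=3, r_y=-0.9), dict(r_x=0.95),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            ScenarioConfig(**kw)


class TestSimulateIndividual:
    def test_null_scenario_structure(self):
        cfg = ScenarioConfig(scenario="I_null", n_individuals=4000,
                             n_variants=20, n_exposures=4, n_outcomes=2,
                             seed=1)
        ind = simulate_individual(cfg)
        assert np.all(ind.true_theta == 0.0)
        assert not ind.true_gamma.any()
        # confounder removed: Y carries no U term
        assert abs(np.corrcoef(ind.confounder, ind.outcomes[:, 0])[0, 1]) < 0.05

    def test_zero_pathway_matches_confounding_scenario(self):
        kw = dict(n_individuals=4000, n_variants=20, n_exposures=4,
                  n_outcomes=2, seed=3)
        a = simulate_individual(ScenarioConfig(
            scenario="III_undirected_pleiotropy", theta_a=0.0, **kw))
        b = simulate_individual(ScenarioConfig(
            scenario="II_confounding", **kw))
        np.testing.assert_array_equal(a.outcomes, b.outcomes)

    def test_directed_pathway_is_positive(self):
        cfg = ScenarioConfig(scenario="IV_directed_pleiotropy",
                             n_individuals=4000, n_variants=20,
                             n_exposures=4, n_outcomes=2, seed=2)
        ind = simulate_individual(cfg)
        assert np.all(ind.pathway > 0)

    def test_error_equicorrelation_recovered(self):
        cfg = ScenarioConfig(scenario="V_dependence", r_y=0.6,
                             n_individuals=20_000, n_variants=10,
                             n_exposures=4, n_outcomes=3, seed=5)
        ind = simulate_individual(cfg)
        eps = ind.outcomes - ind.exposures @ ind.true_theta.T \
            - np.outer(ind.confounder, np.full(3, cfg.theta_yu))
        C = np.corrcoef(eps, rowvar=False)
        off = C[np.triu_indices(3, 1)]
        assert np.all(np.abs(off - 0.6) < 0.02)

    def test_sparsity_count_exact(self):
        cfg = ScenarioConfig(scenario="II_confounding", n_individuals=2000,
                             n_variants=10, seed=9)
        ind = simulate_individual(cfg)
        assert ind.true_gamma.sum() == round(0.30 * 15 * 5)

    def test_exposure_correlation_near_target(self):
        cfg = ScenarioConfig(scenario="II_confounding", n_individuals=30_000,
                             n_variants=20, n_exposures=6, n_outcomes=2,
                             seed=11)
        C = np.corrcoef(simulate_individual(cfg).exposures, rowvar=False)
        off = C[np.triu_indices(6, 1)]
        assert abs(off.mean() - 0.6) < 0.04

    def test_seed_determinism(self):
        kw = dict(scenario="II_confounding", n_individuals=2000,
                  n_variants=10, n_exposures=3, n_outcomes=2)
        a = simulate_individual(ScenarioConfig(seed=4, **kw))
        b = simulate_individual(ScenarioConfig(seed=4, **kw))
        c = simulate_individual(ScenarioConfig(seed=5, **kw))
        np.testing.assert_array_equal(a.outcomes, b.outcomes)
        assert not np.array_equal(a.outcomes, c.outcomes)


class TestExtractSummary:
    def test_default_dimensions(self, small_dataset):
        _, summ = small_dataset
        assert (summ.n, summ.p, summ.q) == (40, 6, 3)

    def test_full_size_dimensions(self):
        summ, truth = simulate_summary(
            ScenarioConfig(scenario="II_confounding", seed=2))
        assert (summ.n, summ.p, summ.q) == (100, 15, 5)
        assert truth.true_theta.shape == (5, 15)

    def test_noiseless_linear_chain(self):
        """With X = G and Y = 2 X exactly, the per-variant outcome slope is
        twice the exposure slope."""
        from mr2.simulate import IndividualData
        rng = np.random.default_rng(0)
        N, n = 20_000, 5
        G = rng.binomial(2, 0.3, size=(N, n)).astype(float)
        X = G + 0.01 * rng.normal(size=(N, n))
        Y = 2.0 * X
        ind = IndividualData(G, X, np.zeros(N), np.zeros(N), Y,
                             2 * np.eye(n), np.eye(n, dtype=bool),
                             np.ones(n), np.full(n, 0.3),
                             ScenarioConfig(scenario="II_confounding",
                                            n_variants=n, n_exposures=n,
                                            n_outcomes=n,
                                            n_individuals=N))
        summ = extract_summary(ind)
        for i in range(n):
            assert summ.beta_y[i, i] == pytest.approx(
                2.0 * summ.beta_x[i, i], rel=0.05)

    def test_matches_bruteforce_per_variant_ols(self, small_dataset):
        ind, summ = small_dataset
        N2 = ind.genotypes.shape[0] // 2
        G1, X1 = ind.genotypes[:N2], ind.exposures[:N2]
        for i in [0, 7, 23]:
            g = G1[:, i]
            A = np.column_stack([np.ones(N2), g])
            coef, res, *_ = np.linalg.lstsq(A, X1[:, 0], rcond=None)
            assert summ.beta_x[i, 0] == pytest.approx(coef[1], rel=1e-8)
            dof = N2 - 2
            s2 = res[0] / dof
            se = np.sqrt(s2 / np.sum((g - g.mean()) ** 2))
            assert summ.se_x[i, 0] == pytest.approx(se, rel=1e-8)

    def test_overlap_controls_residual_correlation(self):
        """Shared-error correlation vanishes with disjoint outcome samples;
        pathway-driven correlation persists (genetic route)."""
        kw = dict(n_individuals=60_000, n_variants=40, n_exposures=5,
                  n_outcomes=3, overlap=0.0, h_ga=0.05, seed=21)

        def resid_corr(scenario, **extra):
            cfg = ScenarioConfig(scenario=scenario, **kw, **extra)
            ind = simulate_individual(cfg)
            summ = extract_summary(ind, cfg)
            resid = summ.beta_y - summ.beta_x @ ind.true_theta.T
            C = np.corrcoef(resid, rowvar=False)
            return C[np.triu_indices(3, 1)].mean()

        assert abs(resid_corr("V_dependence")) < 0.25
        assert resid_corr("III_undirected_pleiotropy", theta_a=2.0) > 0.4

    def test_overlap_insufficient_sample_raises(self):
        # 200 outcome individuals over 5 disjoint groups -> 40 < n + 2 = 52
        cfg = ScenarioConfig(scenario="II_confounding", n_individuals=400,
                             n_variants=50, n_exposures=3, overlap=0.0,
                             seed=0)
        ind = simulate_individual(cfg)
        with pytest.raises(ConfigError, match="overlap"):
            extract_summary(ind, cfg)


class TestResidualCorrelationTheory:
    def test_no_pleiotropy_no_shared_error_is_zero(self):
        assert theoretical_residual_correlation(0.0, 1.0, 1.0, 1.0, 0.0) == 0.0

    def test_direct_substitution(self):
        assert theoretical_residual_correlation(1, 1, 1, 1, 0) == pytest.approx(0.5)

    def test_monotone_in_theta_a(self):
        grid = [0.25, 0.5, 0.75, 1.0, 1.5, 2.0]
        vals = [theoretical_residual_correlation(t, 1.0, 1.0, 1.0, 0.0)
                for t in grid]
        assert np.all(np.diff(vals) > 0)

    def test_sign_invariance(self):
        a = theoretical_residual_correlation(-1.3, 1.0, 2.0, 1.0, 0.0)
        b = theoretical_residual_correlation(1.3, 1.0, 2.0, 1.0, 0.0)
        assert a == b > 0

    def test_inconsistent_covariance_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            theoretical_residual_correlation(0.0, 0.0, 1.0, 1.0, 5.0)

    def test_generator_tracks_theory_over_grid(self):
        """Residual correlation of the generated summary statistics (truth
        regressed out) follows the closed-form value across the pathway
        effect grid."""
        kw = dict(n_individuals=60_000, n_variants=50, n_exposures=8,
                  n_outcomes=3)
        for theta_a in (0.25, 1.0, 2.0):
            vals = []
            for seed in (1, 2, 3):
                cfg = ScenarioConfig(scenario="III_undirected_pleiotropy",
                                     theta_a=theta_a, seed=seed, **kw)
                ind = simulate_individual(cfg)
                summ = extract_summary(ind, cfg)
                resid = summ.beta_y - summ.beta_x @ ind.true_theta.T
                C = np.corrcoef(resid, rowvar=False)
                vals.append(C[np.triu_indices(3, 1)].mean())
            args = residual_correlation_arguments(cfg)
            theory = theoretical_residual_correlation(
                args["theta_a"], args["sigma2_a"], args["delta2"],
                args["delta2"], args["sigma_kk2"])
            assert np.mean(vals) == pytest.approx(theory, abs=0.15)


class TestEmpiricalOutcomeCorrelation:
    def test_identical_columns_give_one(self, rng):
        from mr2.data import SummaryData
        col = rng.normal(size=5)
        d = SummaryData([f"rs{i}" for i in range(5)], ["X1"], ["Y1", "Y2"],
                        rng.normal(size=(5, 1)), np.full((5, 1), 0.1),
                        np.column_stack([col, col]), np.full((5, 2), 0.1))
        C = empirical_outcome_correlation(d)
        assert C[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        from mr2.data import SummaryData
        n = 4000
        d = SummaryData([f"rs{i}" for i in range(n)], ["X1"], ["Y1", "Y2"],
                        rng.normal(size=(n, 1)), np.full((n, 1), 0.1),
                        rng.normal(size=(n, 2)), np.full((n, 2), 0.1))
        assert abs(empirical_outcome_correlation(d)[0, 1]) < 0.05

    def test_matches_textbook_formula_on_fixture(self):
        from mr2.data import SummaryData
        by = np.array([[1.0, 2.0, 0.5], [2.0, 1.5, 1.0], [3.0, 3.5, -1.0],
                       [4.0, 3.0, 0.0], [5.0, 5.0, 2.0]])
        d = SummaryData([f"rs{i}" for i in range(5)], ["X1"],
                        ["Y1", "Y2", "Y3"], np.zeros((5, 1)) + 0.1,
                        np.full((5, 1), 0.1), by, np.full((5, 3), 0.1))
        C = empirical_outcome_correlation(d)
        # hand computation: r = sum((a-ma)(b-mb)) / sqrt(ssa*ssb)
        for i in range(3):
            for j in range(3):
                a, b = by[:, i], by[:, j]
                num = np.sum((a - a.mean()) * (b - b.mean()))
                den = np.sqrt(np.sum((a - a.mean()) ** 2)
                              * np.sum((b - b.mean()) ** 2))
                assert C[i, j] == pytest.approx(num / den)

    def test_constant_column_rejected(self):
        from mr2.data import SummaryData
        d = SummaryData([f"rs{i}" for i in range(5)], ["X1"], ["Y1", "Y2"],
                        np.zeros((5, 1)) + 0.1, np.full((5, 1), 0.1),
                        np.column_stack([np.ones(5), np.arange(5.0)]),
                        np.full((5, 2), 0.1))
        with pytest.raises(ValueError, match="constant"):
            empirical_outcome_correlation(d)
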