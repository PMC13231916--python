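"""Laplace NLME estimation: likelihood, EBEs, fitting, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voripk.estimate import (FitResult, LaplaceNLME, CovariateDecision,
                             _laplace_subject, _SubjectContext,
                             covariate_step, ebe, eta_shrinkage,
                             fit_population, individual_loglik,
                             laplace_marginal, wald_ci)
from voripk.model_core import DoseEvent, concentration
from voripk.population import (IndividualEffects, PatientCovariates,
                               individual_params)
from voripk.study import StudyDataset, SubjectRecords, simulate_rich_study


def _subject(pop, eta=(0.0, 0.0, 0.0, 0.0), obs_times=(3.0, 7.0, 11.9),
             noise_sd=0.0, seed=0, genotype="NM", n_doses=2):
    """A hand-built subject whose DV equals the model prediction (+noise)."""
    doses = [DoseEvent(12.0 * i, 522.0, 2.0) for i in range(n_doses)]
    cov = PatientCovariates(weight=87.0, genotype_class=genotype)
    params = individual_params(pop, cov, IndividualEffects(*eta))
    times = np.asarray(obs_times, dtype=float)
    dv = concentration(times, doses, params).concentrations
    if noise_sd:
        dv = dv + np.random.default_rng(seed).normal(0, noise_sd, dv.shape)
    return SubjectRecords(1, doses, times, dv, cov)


class TestIndividualLoglik:
    def test_single_observation_at_prediction_closed_form(self, pop):
        quiet = pop.replace(omega_V=0, omega_CL1=0, omega_CL2=0,
                            omega_Tswitch=0)
        sub = _subject(quiet, obs_times=(3.0,))
        f = sub.dv[0]
        v = quiet.sigma_add ** 2 + (quiet.sigma_prop * f) ** 2
        ll = individual_loglik(sub, quiet, IndividualEffects())
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * v), rel=1e-12)

    def test_matches_brute_force_recomposition(self, pop):
        rng = np.random.default_rng(8)
        eta = rng.normal(0, 0.3, 4)
        sub = _subject(pop, obs_times=(2.5, 6.0, 11.5, 23.9), noise_sd=0.3,
                       seed=1, genotype="IM")
        params = individual_params(pop, sub.covariates,
                                   IndividualEffects(*eta))
        f = concentration(sub.obs_times, sub.doses, params).concentrations
        v = pop.sigma_add ** 2 + (pop.sigma_prop * f) ** 2
        expected = (stats.norm.logpdf(sub.dv, f, np.sqrt(v)).sum()
                    + stats.norm.logpdf(eta, 0, pop.omegas).sum())
        assert individual_loglik(sub, pop, eta) == pytest.approx(
            expected, rel=1e-10)

    def test_nonzero_eta_on_zero_omega_rejected(self, pop):
        quiet = pop.replace(omega_V=0.0)
        sub = _subject(quiet)
        with pytest.raises(ValueError, match="omega"):
            individual_loglik(sub, quiet, (0.5, 0.0, 0.0, 0.0))

    def test_zero_residual_variance_rejected(self, pop):
        broken = pop.replace(sigma_add=0.0, sigma_prop=0.0)
        sub = _subject(pop)
        with pytest.raises(ValueError, match="residual"):
            individual_loglik(sub, broken, IndividualEffects())


class TestEBE:
    def test_recovers_generating_eta_with_small_noise(self, pop):
        eta_true = (0.2, -0.4, 0.5, -0.1)
        tight = pop.replace(sigma_add=1e-3, sigma_prop=1e-3,
                            omega_V=1.0, omega_CL1=1.0, omega_CL2=1.0,
                            omega_Tswitch=1.0)
        times = tuple(np.sort(np.concatenate(
            [[s + 3, s + 7, s + 11.9] for s in (0, 48, 144, 312)])))
        sub = _subject(tight, eta=eta_true, obs_times=times, n_doses=28)
        est = ebe(sub, tight)
        np.testing.assert_allclose(est.as_array(), eta_true, atol=1e-2)

    def test_zero_omega_forces_zero_eta(self, pop):
        degenerate = pop.replace(omega_V=0, omega_CL1=0, omega_CL2=0,
                                 omega_Tswitch=0)
        sub = _subject(degenerate, noise_sd=0.5, seed=3)
        assert ebe(sub, degenerate).as_array().tolist() == [0, 0, 0, 0]

    def test_subject_without_observations_returns_prior_mode(self, pop):
        sub = _subject(pop)
        empty = SubjectRecords(2, sub.doses, np.array([]), np.array([]),
                               sub.covariates)
        with pytest.warns(UserWarning, match="no observations"):
            est = ebe(empty, pop)
        assert est.as_array().tolist() == [0, 0, 0, 0]

    def test_widening_prior_moves_mode_toward_data(self, pop):
        # additive-only error keeps the observation variance fixed, so the
        # exact-fit eta is the likelihood mode and the prior only shrinks it
        only_v = pop.replace(omega_CL1=0, omega_CL2=0, omega_Tswitch=0,
                             sigma_prop=0.0, sigma_add=0.1)
        sub = _subject(only_v, eta=(0.4, 0.0, 0.0, 0.0), obs_times=(3.0, 7.0))
        narrow = ebe(sub, only_v.replace(omega_V=0.05)).eta_V
        wide = ebe(sub, only_v.replace(omega_V=2.0)).eta_V
        assert abs(narrow) < abs(wide) <= 0.4 + 1e-4


class TestLaplaceMarginal:
    def test_linear_gaussian_case_matches_analytic_integral(self):
        # prediction linear in a single eta with additive error only:
        # the Laplace approximation is exact
        rng = np.random.default_rng(5)
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([0.5, -1.0, 2.0])
        y = a + rng.normal(0, 0.3, 3)
        omega, sigma = 0.7, 0.25

        ctx = _SubjectContext(y, lambda e: a[None, :] + e @ b[None, :],
                              np.array([omega]), sigma, 0.0)
        m2ll, _, flag = _laplace_subject(ctx)
        cov = sigma ** 2 * np.eye(3) + omega ** 2 * np.outer(b, b)
        closed = -2.0 * stats.multivariate_normal.logpdf(y, a, cov)
        assert flag is None
        assert m2ll == pytest.approx(closed, rel=1e-8)

    def test_duplicating_subjects_doubles_objective(self, pop):
        ds = simulate_rich_study(pop, n_subjects=3, seed=10)
        rec = ds.records
        copy = rec.copy()
        copy["ID"] = copy["ID"] + 100
        doubled = StudyDataset(records=pd.concat([rec, copy],
                                                 ignore_index=True))
        m1 = laplace_marginal(ds, pop)
        m2 = laplace_marginal(doubled, pop)
        assert m2 == pytest.approx(2 * m1, rel=1e-10)

    def test_invariant_to_subject_ordering(self, pop):
        ds = simulate_rich_study(pop, n_subjects=4, seed=11)
        shuffled = ds.records.sort_values(["ID", "TIME"],
                                          ascending=[False, True],
                                          kind="stable", ignore_index=True)
        assert laplace_marginal(StudyDataset(records=shuffled), pop) == \
            pytest.approx(laplace_marginal(ds, pop), rel=1e-12)


class TestWaldCI:
    def test_reproduces_published_volume_interval(self):
        lo, hi = wald_ci(144.79, 8.04)
        assert lo == pytest.approx(123.78, rel=0.005)
        assert hi == pytest.approx(169.37, rel=0.005)

    def test_zero_rse_collapses_to_estimate(self):
        assert wald_ci(10.0, 0.0) == (10.0, 10.0)

    def test_monotone_in_rse_and_log_symmetric(self):
        lo1, hi1 = wald_ci(10.0, 10.0)
        lo2, hi2 = wald_ci(10.0, 30.0)
        assert lo2 < lo1 < 10.0 < hi1 < hi2
        assert lo1 * hi1 == pytest.approx(100.0, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wald_ci(10.0, -5.0)
        with pytest.raises(ValueError):
            wald_ci(-1.0, 10.0)


def _fake_fit(pop, minus2ll, n_params, n_obs=100):
    return FitResult(population=pop, free=("V",) * n_params,
                     minus2ll=minus2ll, n_obs=n_obs, n_params=n_params)


class TestCovariateStep:
    def test_no_improvement_not_included(self, pop):
        d = covariate_step(_fake_fit(pop, 500.0, 3), _fake_fit(pop, 500.0, 4))
        assert d == CovariateDecision(delta_ofv=0.0, include=False,
                                      retain=False, df=1)

    @pytest.mark.parametrize("delta, include, retain", [
        (3.9, True, False), (3.5, False, False), (7.0, True, True)])
    def test_forward_and_backward_thresholds(self, pop, delta, include,
                                             retain):
        d = covariate_step(_fake_fit(pop, 500.0, 3),
                           _fake_fit(pop, 500.0 - delta, 4))
        assert (d.include, d.retain) == (include, retain)

    def test_non_nested_comparisons_rejected(self, pop):
        with pytest.raises(ValueError):
            covariate_step(_fake_fit(pop, 500.0, 4), _fake_fit(pop, 499.0, 3))
        with pytest.raises(ValueError):
            covariate_step(_fake_fit(pop, 500.0, 3, n_obs=100),
                           _fake_fit(pop, 490.0, 4, n_obs=90))

    def test_detects_genotype_effect_of_cohort_magnitude(self, pop):
        """A beta = -0.44 genotype effect passes forward inclusion when
        profiled against the otherwise-known population model."""
        ds = simulate_rich_study(pop, n_subjects=100, seed=31, genotype=None)
        base_pop = pop.replace(beta_geno=0.0)
        base = _fake_fit(base_pop, laplace_marginal(ds, base_pop), 0,
                         n_obs=len(ds.observations()))
        fix = tuple(n for n in
                    ("V", "CL1", "CL2", "Tswitch", "CLseq0", "Thalf_seq",
                     "omega_V", "omega_CL1", "omega_CL2", "omega_Tswitch",
                     "sigma_add", "sigma_prop"))
        ext = fit_population(ds, init=base_pop, fix=fix, n_starts=1,
                             compute_se=False)
        base = FitResult(population=base_pop, free=(), minus2ll=base.minus2ll,
                         n_obs=ext.n_obs, n_params=0)
        decision = covariate_step(base, ext)
        assert ext.population.beta_geno < 0
        assert decision.include

    def test_null_effect_rarely_crosses_threshold(self, pop):
        """With no genotype effect in the data, the profiled improvement
        stays near its chi-square(1) null distribution."""
        null_pop = pop.replace(beta_geno=0.0)
        fix = tuple(n for n in
                    ("V", "CL1", "CL2", "Tswitch", "CLseq0", "Thalf_seq",
                     "omega_V", "omega_CL1", "omega_CL2", "omega_Tswitch",
                     "sigma_add", "sigma_prop"))
        deltas = []
        for seed in (41, 42, 43):
            ds = simulate_rich_study(null_pop, n_subjects=40, seed=seed,
                                     genotype=None)
            base_m2ll = laplace_marginal(ds, null_pop)
            ext = fit_population(ds, init=null_pop, fix=fix, n_starts=1,
                                 compute_se=False)
            deltas.append(base_m2ll - ext.minus2ll)
        deltas = np.array(deltas)
        assert np.all(deltas > -0.1)  # profiling can only improve the fit
        assert np.median(deltas) < 3.84


class TestFitPopulation:
    @pytest.fixture(scope="class")
    def small_fit(self, pop):
        ds = simulate_rich_study(pop, n_subjects=12, seed=23)
        result = fit_population(ds, init=pop, fix=("CLseq0", "Thalf_seq"),
                                n_starts=1, compute_se=True)
        return ds, result

    def test_converges_with_information_criteria(self, small_fit):
        _, res = small_fit
        assert res.converged
        assert res.aic == pytest.approx(res.minus2ll + 2 * res.n_params)
        ds, _ = small_fit
        obs = ds.observations()
        assert res.bic == pytest.approx(
            res.minus2ll + np.log(res.n_obs) * res.n_params)
        assert res.n_obs == len(obs) - int(obs["BLQ"].sum())

    def test_recovers_typical_values_loosely(self, small_fit, pop):
        # 12 subjects is deliberately small; recovery is checked tightly in
        # the acceptance suite at n = 50
        _, res = small_fit
        est = res.estimates()
        assert est["V"] == pytest.approx(pop.theta.V, rel=0.30)
        assert est["CL2"] == pytest.approx(pop.theta.CL2, rel=0.50)

    def test_uncertainty_summaries_present(self, small_fit):
        _, res = small_fit
        for name in res.free:
            assert res.se[name] >= 0
            assert res.rse_percent[name] >= 0
            lo, hi = res.ci95[name]
            assert lo <= res.estimates()[name] <= hi or name == "beta_geno"
        assert "Estimate" in res.summary()

    def test_empirical_bayes_and_shrinkage_outputs(self, small_fit):
        _, res = small_fit
        assert len(res.etas) == 12
        for name, val in res.shrinkage_percent.items():
            assert val < 100.0

    def test_beta_dropped_without_reduced_function_subjects(self, small_fit):
        _, res = small_fit
        assert "beta_geno" not in res.free
        assert "beta_geno_dropped_no_reduced_subjects" in res.flags

    def test_variance_parameters_must_be_positive_to_estimate(self, pop):
        ds = simulate_rich_study(pop, n_subjects=2, seed=1)
        bad = pop.replace(omega_V=0.0)
        with pytest.raises(ValueError, match="omega_V"):
            fit_population(ds, init=bad, n_starts=1, compute_se=False)


class TestEstimatorApi:
    def test_sklearn_style_params_and_predict(self, pop):
        ds = simulate_rich_study(pop, n_subjects=3, seed=33)
        est = LaplaceNLME(init=pop, fix=("CLseq0", "Thalf_seq"), n_starts=1,
                          compute_se=False, maxiter=5, max_cycles=1)
        assert est.get_params()["maxiter"] == 5
        est.set_params(maxiter=8)
        assert est.maxiter == 8
        with pytest.raises(RuntimeError):
            est.predict(ds)
        est.fit(ds)
        assert est.population_.theta.V > 0
        ipred = est.predict(ds, kind="individual")
        ppred = est.predict(ds, kind="population")
        n_used = len(ds.observations()) - int(ds.observations()["BLQ"].sum())
        assert ipred.shape == ppred.shape == (n_used,)
        assert np.all(ipred >= 0) and np.all(ppred >= 0)
        with pytest.raises(ValueError):
            est.predict(ds, kind="bogus")


class TestEtaShrinkage:
    def test_all_etas_zero_gives_full_shrinkage(self, pop):
        etas = pd.DataFrame({"ID": [1, 2, 3],
                             **{f"eta_{n}": [0.0] * 3
                                for n in ("V", "CL1", "CL2", "Tswitch")}})
        fit = FitResult(population=pop, free=(), minus2ll=0.0, n_obs=3,
                        n_params=0, etas=etas)
        assert all(v == pytest.approx(100.0)
                   for v in eta_shrinkage(fit).values())

    def test_zero_omega_reported_as_undefined(self, pop):
        degenerate = pop.replace(omega_V=0.0)
        etas = pd.DataFrame({"ID": [1, 2],
                             **{f"eta_{n}": [0.1, -0.1]
                                for n in ("V", "CL1", "CL2", "Tswitch")}})
        fit = FitResult(population=degenerate, free=(), minus2ll=0.0,
                        n_obs=2, n_params=0, etas=etas)
        assert eta_shrinkage(fit)["V"] is None

    def test_spread_matching_omega_gives_low_shrinkage(self, pop):
        rng = np.random.default_rng(12)
        etas = pd.DataFrame({
            "ID": np.arange(500),
            **{f"eta_{n}": rng.normal(0, o, 500)
               for n, o in zip(("V", "CL1", "CL2", "Tswitch"), pop.omegas)}})
        fit = FitResult(population=pop, free=(), minus2ll=0.0, n_obs=500,
                        n_params=0, etas=etas)
        for val in eta_shrinkage(fit).values():
            assert abs(val) < 12.0
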