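"""FOCE-I estimation: objective, fitting, empirical Bayes estimates."""

import numpy as np
import pytest

import neocefpk as n
from neocefpk.io import DoseEvent, Observation, PKDataset, SubjectData
from neocefpk.model import NEONATAL_EOS_PARAMS as P, PopulationParams

from conftest import gh_marginal_ofv


def _near_deterministic_params():
    return PopulationParams(
        theta1=P.theta1, theta2=P.theta2, theta3=P.theta3, theta4=P.theta4,
        omega2_cl=0.0, omega2_v=0.0, sigma2_prop=1e-8,
    )


class TestConditionalObjective:
    def test_noise_free_data_gives_zero_etas_and_minimal_ofv(self):
        truth = PopulationParams(
            P.theta1, P.theta2, P.theta3, P.theta4, 0.0, 0.0, 0.0
        )
        cohort = n.sample_cohort(n.CohortSpec(n_subjects=12, seed=5))
        data = n.simulate_dataset(cohort, truth, seed=6)
        # small omegas in the evaluator so the etas are free but data are exact
        p_eval = PopulationParams(
            P.theta1, P.theta2, P.theta3, P.theta4, 0.04, 0.04, 1e-6
        )
        ofv0, etas = n.conditional_objective(p_eval, data)
        assert max(abs(e) for pair in etas.values() for e in pair) < 1e-3
        # perturbing theta2 on a coarse grid never improves the objective
        for fac in (0.8, 0.9, 1.1, 1.25):
            p_alt = PopulationParams(
                P.theta1, P.theta2 * fac, P.theta3, P.theta4, 0.04, 0.04, 1e-6
            )
            assert n.conditional_objective(p_alt, data)[0] > ofv0

    def test_subject_relabeling_leaves_ofv_unchanged(self, study_data):
        ofv1, _ = n.conditional_objective(P, study_data)
        shuffled = PKDataset(tuple(reversed(study_data.subjects)))
        ofv2, _ = n.conditional_objective(P, shuffled)
        assert ofv1 == pytest.approx(ofv2, abs=1e-8)

    def test_foce_matches_quadrature_marginal_likelihood(self):
        """FOCE-I approximation within 2 OFV units of exact Gauss-Hermite
        quadrature on a 5-subject sparse toy dataset."""
        cohort = n.sample_cohort(n.CohortSpec(n_subjects=5, seed=7))
        toy = n.simulate_dataset(cohort, P, seed=8)
        ofv_foce, _ = n.conditional_objective(P, toy)
        ofv_exact = gh_marginal_ofv(P, toy)
        assert abs(ofv_foce - ofv_exact) < 2.0

    def test_single_observation_subject_matches_quadrature_closely(self):
        cohort = n.sample_cohort(n.CohortSpec(n_subjects=1, seed=9))
        design = n.DesignSpec(samples_per_subject=1)
        one = n.simulate_dataset(cohort, P, design, seed=10)
        ofv_foce, _ = n.conditional_objective(P, one)
        assert abs(ofv_foce - gh_marginal_ofv(P, one)) < 0.5


class TestFitModel:
    def test_degenerate_noise_free_recovery(self):
        truth = _near_deterministic_params()
        cohort = n.sample_cohort(n.CohortSpec(n_subjects=20, seed=11))
        data = n.simulate_dataset(cohort, truth, seed=12)
        fit = n.fit_model(data, settings=n.FitSettings(compute_rse=False))
        pp = fit.params
        assert pp.theta1 == pytest.approx(P.theta1, rel=2e-3)
        assert pp.theta2 == pytest.approx(P.theta2, rel=2e-3)
        assert pp.theta3 == pytest.approx(P.theta3, rel=0.02)
        assert pp.theta4 == pytest.approx(P.theta4, rel=0.02)

    def test_ofv_at_solution_not_worse_than_start(self, study_data, study_fit):
        start_ofv, _ = n.conditional_objective(P, study_data)
        assert study_fit.ofv <= start_ofv + 1e-6

    def test_doubling_concentrations_halves_cl_and_v(self, study_data, study_fit):
        """Dose/AUC logic: scaling all concentrations by c scales CL and V by 1/c."""
        doubled = PKDataset(tuple(
            SubjectData(
                s.id, s.covariates, s.doses,
                tuple(Observation(o.time, 2 * o.concentration) for o in s.observations),
            )
            for s in study_data.subjects
        ))
        fit2 = n.fit_model(doubled, settings=n.FitSettings(compute_rse=False))
        assert fit2.params.theta2 == pytest.approx(study_fit.params.theta2 / 2, rel=0.01)
        assert fit2.params.theta1 == pytest.approx(study_fit.params.theta1 / 2, rel=0.01)

    def test_parameter_recovery_across_replicates(self):
        """Median relative bias across 20 sparse-design replicates: <10% for
        theta1/theta2, <20% for the covariate exponents."""
        rel = {k: [] for k in ("theta1", "theta2", "theta3", "theta4")}
        for r in range(20):
            cohort = n.sample_cohort(n.CohortSpec(n_subjects=51, seed=100 + r))
            data = n.simulate_dataset(cohort, P, seed=200 + r, n_obs_total=101)
            fit = n.fit_model(
                data, settings=n.FitSettings(compute_rse=False, fatol=1e-3, xatol=1e-3)
            )
            pp = fit.params
            for k in rel:
                truth = getattr(P, k)
                rel[k].append((getattr(pp, k) - truth) / truth)
        assert abs(np.median(rel["theta1"])) < 0.10
        assert abs(np.median(rel["theta2"])) < 0.10
        assert abs(np.median(rel["theta3"])) < 0.20
        assert abs(np.median(rel["theta4"])) < 0.20

    def test_rse_reported_for_all_terms(self, study_fit):
        assert study_fit.rse is not None
        for key in ("theta_v", "theta_cl", "beta_CW->CL", "beta_PNA->CL",
                    "omega2_cl", "omega2_v", "sigma2_prop"):
            assert np.isfinite(study_fit.rse[key]) and study_fit.rse[key] > 0


class TestEmpiricalBayes:
    def test_no_observations_full_shrinkage(self, typical_cov):
        subj = SubjectData("x", typical_cov, (DoseEvent(0.0, 115.5, 0.5),), ())
        assert n.empirical_bayes(P, subj) == (0.0, 0.0)

    def test_rich_data_recovers_true_eta(self, typical_cov):
        rng = np.random.default_rng(3)
        eta_true = (0.25, -0.15)
        ind = n.make_individual(P, typical_cov, *eta_true)
        doses = tuple(DoseEvent(12.0 * k, 115.5, 0.5) for k in range(6))
        t = np.linspace(0.75, 60.0, 20)
        f = n.concentration(ind, doses, t)
        y = f * (1 + 0.05 * rng.standard_normal(20))
        subj = SubjectData(
            "rich", typical_cov, doses,
            tuple(Observation(float(tt), float(yy)) for tt, yy in zip(t, y)),
        )
        # evaluator uses 5% residual error as generated
        p_eval = PopulationParams(P.theta1, P.theta2, P.theta3, P.theta4,
                                  P.omega2_cl, P.omega2_v, 0.05**2)
        eta_hat = n.empirical_bayes(p_eval, subj)
        assert abs(eta_hat[0] - eta_true[0]) < 0.05
        assert abs(eta_hat[1] - eta_true[1]) < 0.05

    def test_vanishing_omega_forces_zero_eta(self, typical_cov):
        rng = np.random.default_rng(4)
        doses = (DoseEvent(0.0, 115.5, 0.5),)
        subj = SubjectData(
            "x", typical_cov, doses,
            (Observation(2.0, 80.0), Observation(9.0, 30.0)),
        )
        p0 = PopulationParams(P.theta1, P.theta2, P.theta3, P.theta4, 0.0, 0.0,
                              P.sigma2_prop)
        assert n.empirical_bayes(p0, subj) == (0.0, 0.0)

    def test_shrinks_toward_zero_as_data_removed(self, typical_cov):
        doses = tuple(DoseEvent(12.0 * k, 115.5, 0.5) for k in range(3))
        ind = n.make_individual(P, typical_cov, 0.35, 0.35)
        t = (2.0, 9.0, 26.0)
        obs = tuple(
            Observation(tt, float(n.concentration(ind, doses, tt))) for tt in t
        )
        full = SubjectData("x", typical_cov, doses, obs)
        one = SubjectData("x", typical_cov, doses, obs[:1])
        e_full = n.empirical_bayes(P, full)
        e_one = n.empirical_bayes(P, one)
        assert np.hypot(*e_one) < np.hypot(*e_full)
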