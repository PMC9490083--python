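"""CWRES, bootstrap, NPDE and pcVPC behaviour."""

import numpy as np
import pytest
import neocefpk as n
from neocefpk.diagnostics import bootstrap, cwres, npde, pcvpc
from neocefpk.estimate import FINAL_MODEL, FitResult, FitSettings
from neocefpk.io import DoseEvent, Observation, PKDataset, SubjectData
from neocefpk.model import NEONATAL_EOS_PARAMS as P, concentration, make_individual


def _fit_at(params, data, ofv=0.0):
    """A FitResult fixed at given parameters (for evaluator-only diagnostics)."""
    return FitResult(
        spec=FINAL_MODEL,
        theta_v=params.theta1,
        theta_cl=params.theta2,
        exponents={"CW->CL": params.theta3, "PNA->CL": params.theta4},
        omega2_cl=params.omega2_cl,
        omega2_v=params.omega2_v,
        sigma2_prop=params.sigma2_prop,
        ofv=ofv,
        ebes=np.zeros((data.n_subjects, 2)),
        ids=tuple(s.id for s in data.subjects),
        converged=True,
        n_obs=data.n_obs,
        n_subjects=data.n_subjects,
    )


class TestCwres:
    def test_noise_free_data_gives_zero_residuals(self, typical_cov):
        doses = tuple(DoseEvent(12.0 * k, 115.5, 0.5) for k in range(3))
        ind = make_individual(P, typical_cov)
        subjects = []
        for i in range(5):
            t = (2.0 + i, 20.0 + i)
            obs = tuple(Observation(tt, float(concentration(ind, doses, tt))) for tt in t)
            subjects.append(SubjectData(f"s{i}", typical_cov, doses, obs))
        data = PKDataset(tuple(subjects))
        # at finite sigma^2 the interaction term shifts the conditional mode
        # by O(sigma^2), so residuals are tiny rather than exactly zero
        res = cwres(_fit_at(P, data), data)
        assert np.allclose(res, 0.0, atol=1e-2)
        small_sigma = n.PopulationParams(
            P.theta1, P.theta2, P.theta3, P.theta4, P.omega2_cl, P.omega2_v, 1e-8
        )
        res2 = cwres(_fit_at(small_sigma, data), data)
        assert np.allclose(res2, 0.0, atol=1e-5)

    def test_single_observation_subjects_match_scalar_formula(self, typical_cov):
        """For n=1 the FOCE residual reduces to a scalar expression that can
        be rebuilt from the public model API with numeric derivatives."""
        doses = (DoseEvent(0.0, 115.5, 0.5),)
        data = PKDataset(tuple(
            SubjectData(f"s{i}", typical_cov, doses, (Observation(t, y),))
            for i, (t, y) in enumerate([(2.0, 95.0), (6.0, 40.0), (10.0, 35.0)])
        ))
        fit = _fit_at(P, data)
        res = cwres(fit, data)
        for i, s in enumerate(data.subjects):
            t, y = s.observations[0].time, s.observations[0].concentration
            eta = n.empirical_bayes(P, s)
            f = concentration(make_individual(P, typical_cov, *eta), doses, t)
            h = 1e-6
            g_cl = (concentration(make_individual(P, typical_cov, eta[0] + h, eta[1]), doses, t) - f) / h
            g_v = (concentration(make_individual(P, typical_cov, eta[0], eta[1] + h), doses, t) - f) / h
            var = g_cl**2 * P.omega2_cl + g_v**2 * P.omega2_v + P.sigma2_prop * f**2
            expect = (y - (f - g_cl * eta[0] - g_v * eta[1])) / np.sqrt(var)
            assert res[i] == pytest.approx(expect, rel=1e-5)

    def test_pooled_moments_near_standard_normal(self, study_data, study_fit):
        res = cwres(study_fit, study_data)
        assert res.size == 101
        assert abs(res.mean()) < 0.1
        assert 0.8 < res.var(ddof=1) < 1.2


class TestBootstrap:
    def test_identity_resample_reproduces_original_fit(self, study_data, study_fit, monkeypatch):
        """With the resampler stubbed to the identity permutation, the single
        replicate refit lands on the original estimates."""
        class _StubRng:
            def integers(self, low, high, size):
                return np.arange(high)

        monkeypatch.setattr(np.random, "default_rng", lambda seed=None: _StubRng())
        b = bootstrap(study_data, FINAL_MODEL, B=1, seed=0, warm_start=study_fit)
        assert b.n_failed == 0
        assert b.median["theta_v"] == pytest.approx(study_fit.theta_v, rel=5e-3)
        assert b.median["theta_cl"] == pytest.approx(study_fit.theta_cl, rel=5e-3)

    def test_deterministic_given_seed(self, study_data, study_fit):
        b1 = bootstrap(study_data, FINAL_MODEL, B=5, seed=9, warm_start=study_fit)
        b2 = bootstrap(study_data, FINAL_MODEL, B=5, seed=9, warm_start=study_fit)
        assert b1.median == b2.median
        assert b1.p5 == b2.p5

    def test_interval_widens_with_generator_noise(self, study_fit):
        """Doubling the IIV and residual SDs in the generator widens the
        bootstrap percentile interval for clearance."""
        import dataclasses

        noisy = n.PopulationParams(
            P.theta1, P.theta2, P.theta3, P.theta4,
            (2 * 0.200) ** 2, (2 * 0.211) ** 2, (2 * 0.142) ** 2,
        )
        widths = {}
        for tag, params in (("base", P), ("noisy", noisy)):
            cohort = n.sample_cohort(n.CohortSpec(n_subjects=51, seed=601))
            data = n.simulate_dataset(cohort, params, seed=602, n_obs_total=101)
            b = bootstrap(data, FINAL_MODEL, B=15, seed=603)
            widths[tag] = b.p95["theta_cl"] - b.p5["theta_cl"]
        assert widths["noisy"] > widths["base"]


class TestNpde:
    def test_self_evaluation_is_standard_normal(self, study_data, study_fit):
        nd = npde(study_fit, study_data, K=500, seed=13)
        assert nd.values.size == 101
        assert abs(nd.mean) < 0.15
        assert abs(nd.variance - 1.0) < 0.15
        # rank-to-normal stage produces a distribution KS-compatible with N(0,1)
        assert nd.ks_pvalue > 0.01

    def test_misspecified_volume_shifts_the_mean(self, study_data, study_fit):
        import dataclasses

        wrong = dataclasses.replace(study_fit, theta_v=2 * study_fit.theta_v)
        nd = npde(wrong, study_data, K=300, seed=14)
        assert abs(nd.mean) > 0.3

    def test_small_k_rejected(self, study_data, study_fit):
        with pytest.raises(ValueError):
            npde(study_fit, study_data, K=50)


class TestPcVpc:
    def _identical_subject_data(self, typical_cov, rng):
        doses = tuple(DoseEvent(12.0 * k, 115.5, 0.5) for k in range(3))
        ind = make_individual(P, typical_cov)
        subjects = []
        for i in range(12):
            obs = []
            for t in (3.0, 20.0):
                f = concentration(ind, doses, t)
                obs.append(Observation(t, float(f * (1 + 0.14 * rng.standard_normal()))))
            subjects.append(SubjectData(f"s{i}", typical_cov, doses, tuple(obs)))
        return PKDataset(tuple(subjects))

    def test_identical_subjects_make_correction_identity(self, typical_cov):
        data = self._identical_subject_data(typical_cov, np.random.default_rng(15))
        fit = _fit_at(P, data)
        v = pcvpc(fit, data, n_sim=100, bins=2, seed=16)
        raw = np.array(
            [[o.concentration for s in data.subjects for o in s.observations
              if o.time == t] for t in (3.0, 20.0)]
        )
        # bins are time-after-dose: t=3 h -> tad 3 (bin 0); t=20 h -> tad 8 (bin 1)
        assert v.observed[1, 0] == pytest.approx(np.median(raw[0]), rel=1e-12)
        assert v.observed[1, 1] == pytest.approx(np.median(raw[1]), rel=1e-12)

    def test_self_simulated_median_inside_envelope(self, study_data, study_fit):
        v = pcvpc(study_fit, study_data, n_sim=300, bins=10, seed=17)
        assert v.median_within_envelope.sum() >= 9

    def test_doubled_observations_escape_envelope(self, study_data, study_fit):
        doubled = PKDataset(tuple(
            SubjectData(
                s.id, s.covariates, s.doses,
                tuple(Observation(o.time, 2 * o.concentration) for o in s.observations),
            )
            for s in study_data.subjects
        ))
        v = pcvpc(study_fit, doubled, n_sim=300, bins=6, seed=18)
        assert (~v.median_within_envelope).sum() >= 4

    def test_all_diagnostics_deterministic(self, study_data, study_fit):
        v1 = pcvpc(study_fit, study_data, n_sim=100, bins=6, seed=19)
        v2 = pcvpc(study_fit, study_data, n_sim=100, bins=6, seed=19)
        assert np.array_equal(v1.observed, v2.observed)
        assert np.array_equal(v1.envelope_lo, v2.envelope_lo)
        n1 = npde(study_fit, study_data, K=200, seed=20)
        n2 = npde(study_fit, study_data, K=200, seed=20)
        assert np.array_equal(n1.values, n2.values)
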