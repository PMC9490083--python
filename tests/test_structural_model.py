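"""Closed-form one-compartment infusion model and covariate functions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neocefpk as n
from neocefpk.io import CovariateRecord, DoseEvent
from neocefpk.model import NEONATAL_EOS_PARAMS as P, RegimenSpec

from conftest import ode_concentration


class TestCovariateFunctions:
    def test_typical_clearance_at_reference(self, typical_cov):
        assert n.individual_clearance(P, typical_cov) == pytest.approx(0.0803, rel=1e-12)

    def test_clearance_smallest_neonate(self):
        cov = CovariateRecord(1220, 1220, 30.0, 1, 30.0 + 1 / 7)
        # 0.0803 * (1220/2310)**1.68, hand-checked power law
        assert n.individual_clearance(P, cov) == pytest.approx(0.02747, rel=5e-4)

    def test_eta_acts_exponentially(self, typical_cov):
        base = n.individual_clearance(P, typical_cov, 0.0)
        assert n.individual_clearance(P, typical_cov, math.log(2)) == pytest.approx(
            2 * base, rel=1e-12
        )

    def test_typical_volume(self):
        assert n.individual_volume(P, 0.0) == pytest.approx(0.873, rel=1e-12)
        assert n.individual_volume(P, math.log(1.5)) / n.individual_volume(P) == pytest.approx(1.5)

    def test_volume_lognormal_under_sampled_eta(self):
        rng = np.random.default_rng(42)
        eta = rng.normal(0, math.sqrt(P.omega2_v), 100_000)
        lnv = np.log([n.individual_volume(P, e) for e in eta[:100]])
        # moments on the full draw, shape on a subsample
        ln_all = math.log(P.theta1) + eta
        assert abs(ln_all.mean() - math.log(P.theta1)) < 0.005
        assert ln_all.std() == pytest.approx(math.sqrt(P.omega2_v), rel=0.02)
        assert np.allclose(lnv, ln_all[:100])

    def test_nonpositive_covariates_rejected(self):
        with pytest.raises(ValueError):
            n.individual_clearance(P, CovariateRecord(-5, 2310, 35.7, 1, 35.84))

    def test_allometric_homogeneity_is_exact(self, typical_cov):
        double = CovariateRecord(2 * 2310, 2310, 35.7, 1, 35.84)
        ratio = n.individual_clearance(P, double) / n.individual_clearance(P, typical_cov)
        assert ratio == pytest.approx(2**P.theta3, rel=1e-12)


class TestConcentration:
    def test_zero_before_and_at_first_dose(self, typical_ind):
        doses = [DoseEvent(0.0, 115.5, 0.5)]
        assert n.concentration(typical_ind, doses, 0.0) == 0.0

    def test_continuous_infusion_limit_is_rate_over_cl(self, typical_ind):
        doses = [DoseEvent(0.0, 1e6, 1e4)]  # effectively never-ending
        c = n.concentration(typical_ind, doses, 500.0)
        assert c == pytest.approx(doses[0].rate / typical_ind.cl, rel=1e-6)

    def test_steady_state_against_ode_oracle(self, typical_ind):
        """Typical neonate, 50 mg/kg q12h, 8.4 h into a steady-state interval."""
        doses = [DoseEvent(12.0 * k, 115.5, 0.5) for k in range(20)]
        t = 14 * 12 + 8.4
        c = n.concentration(typical_ind, doses, t)
        assert c == pytest.approx(93.5, abs=0.1)
        assert c == pytest.approx(ode_concentration(typical_ind.cl, typical_ind.v, doses, t),
                                  rel=1e-6)

    def test_monotone_decay_without_active_infusion(self, typical_ind):
        doses = [DoseEvent(0.0, 115.5, 0.5)]
        t = np.linspace(0.6, 12.0, 50)
        c = n.concentration(typical_ind, doses, t)
        assert np.all(np.diff(c) < 0)

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.1, 10.0),
        cl=st.floats(0.02, 0.3),
        v=st.floats(0.3, 2.0),
        t=st.floats(0.1, 36.0),
    )
    def test_dose_linearity(self, scale, cl, v, t):
        ind = n.IndividualParams(cl=cl, v=v)
        doses = [DoseEvent(0.0, 100.0, 0.5), DoseEvent(12.0, 100.0, 0.5)]
        scaled = [DoseEvent(d.time, d.amount * scale, d.duration) for d in doses]
        c1 = n.concentration(ind, doses, t)
        c2 = n.concentration(ind, scaled, t)
        assert c2 == pytest.approx(scale * c1, rel=1e-9, abs=1e-12)


class TestSteadyState:
    def test_accumulation_factor_value(self, typical_ind):
        # 1 / (1 - exp(-ke * tau)) with ke = 0.0803/0.873
        factor = 1.0 / -np.expm1(-typical_ind.ke * 12.0)
        assert factor == pytest.approx(1.496, abs=2e-3)
        reg = RegimenSpec()
        single = n.concentration(typical_ind, [DoseEvent(0.0, 115.5, 0.5)], 8.4)
        ss = n.steady_state_concentration(typical_ind, reg, 8.4, 2310.0)
        assert ss == pytest.approx(single * factor, rel=1e-9)

    def test_large_ke_tau_reduces_to_single_dose(self):
        ind = n.IndividualParams(cl=5.0, v=0.5)  # ke = 10/h, ke*tau huge
        reg = RegimenSpec()
        single = n.concentration(ind, [DoseEvent(0.0, reg.dose_mg(2310.0), 0.5)], 4.0)
        ss = n.steady_state_concentration(ind, reg, 4.0, 2310.0)
        assert ss == pytest.approx(single, rel=1e-9)

    def test_matches_superposition_at_dose_15(self, typical_ind):
        reg = RegimenSpec()
        doses = [DoseEvent(12.0 * k, reg.dose_mg(2310.0), 0.5) for k in range(15)]
        for t_in in (1.0, 4.0, 8.4, 11.9):
            sup = n.concentration(typical_ind, doses, 14 * 12 + t_in)
            ss = n.steady_state_concentration(typical_ind, reg, t_in, 2310.0)
            assert ss == pytest.approx(sup, rel=1e-3)

    def test_interval_shorter_than_infusion_rejected(self):
        with pytest.raises(ValueError):
            RegimenSpec(dose_per_kg=50, tau=0.4, duration=0.5)


@settings(max_examples=40, deadline=None)
@given(
    cl=st.floats(0.02, 0.3),
    v=st.floats(0.3, 2.0),
    t=st.floats(0.05, 40.0),
)
def test_closed_form_matches_ode_integration(cl, v, t):
    """Superposition solution vs direct integration of dC/dt = R/V - ke C."""
    doses = [DoseEvent(0.0, 100.0, 0.5), DoseEvent(12.0, 120.0, 1.0),
             DoseEvent(24.0, 80.0, 0.25)]
    ind = n.IndividualParams(cl=cl, v=v)
    c = n.concentration(ind, doses, t)
    ref = ode_concentration(cl, v, doses, t)
    assert c == pytest.approx(ref, rel=1e-3, abs=1e-9)
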