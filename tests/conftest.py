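"""Shared fixtures and independent numerical oracles for the test suite.

The oracles re-derive model quantities by routes independent of the package's
closed forms: direct ODE integration of the one-compartment system, and
Gauss-Hermite quadrature of the exact marginal likelihood.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import norm

import neocefpk as n
from neocefpk.io import CovariateRecord


@pytest.fixture(scope="session")
def typical_cov():
    return CovariateRecord(CW=2310.0, BW=2310.0, GA=35.7, PNA=1.0, PMA=35.7 + 1 / 7)


@pytest.fixture(scope="session")
def typical_ind(typical_cov):
    return n.make_individual(n.NEONATAL_EOS_PARAMS, typical_cov)


@pytest.fixture(scope="session")
def study_data():
    """51-subject / 101-observation sparse design under the shipped parameters."""
    return n.make_fixture("study-like", seed=1)


@pytest.fixture(scope="session")
def study_fit(study_data):
    """FOCE-I fit of the final model to the study-like dataset (with RSE)."""
    return n.fit_model(study_data)


# ---------------------------------------------------------------------------
# oracles


def ode_concentration(cl, v, doses, t):
    """Numerically integrate dC/dt = R(t)/V - (CL/V) C up to time ``t``;
    independent of the package's closed-form superposition."""
    ke = cl / v

    def rate_in(tt):
        return sum(d.rate for d in doses if d.time < tt < d.time + d.duration)

    def one(tt):
        if tt <= 0:
            return 0.0
        switch = sorted(
            {s for d in doses for s in (d.time, d.time + d.duration) if 0 < s < tt}
        )
        y, t0 = 0.0, 0.0
        for t1 in switch + [tt]:
            if t1 <= t0:
                continue
            sol = solve_ivp(
                lambda s, yy: [rate_in(s) / v - ke * yy[0]],
                (t0, t1), [y], rtol=1e-10, atol=1e-12,
            )
            y, t0 = float(sol.y[0, -1]), t1
        return y

    arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.array([one(tt) for tt in arr])
    return out if np.ndim(t) else float(out[0])


def gh_marginal_ofv(p, data, nodes=41):
    """-2 log marginal likelihood by dense Gauss-Hermite quadrature over
    (eta_cl, eta_v); exact up to quadrature error, no FOCE linearisation."""
    x, w = np.polynomial.hermite.hermgauss(nodes)
    total = 0.0
    sig = np.sqrt(p.sigma2_prop)
    for s in data.subjects:
        t = np.array([o.time for o in s.observations])
        y = np.array([o.concentration for o in s.observations])
        ll = np.zeros((nodes, nodes))
        for i, xi in enumerate(x):
            eta_cl = np.sqrt(2 * p.omega2_cl) * xi
            for j, xj in enumerate(x):
                eta_v = np.sqrt(2 * p.omega2_v) * xj
                ind = n.make_individual(p, s.covariates, eta_cl, eta_v)
                f = np.maximum(n.concentration(ind, s.doses, t), 1e-300)
                ll[i, j] = norm.logpdf(y, loc=f, scale=sig * f).sum()
        m = ll.max()
        lik = (w[:, None] * w[None, :] * np.exp(ll - m)).sum() / np.pi
        total += -2.0 * (m + np.log(lik))
    return total
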