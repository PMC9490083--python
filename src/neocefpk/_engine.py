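"""Vectorised computation kernel shared by estimation, simulation and diagnostics.

Everything here works on a :class:`PackedDesign` — the ragged per-subject
dose/observation structure padded into rectangular arrays — so that the inner
FOCE problem (one 2-d optimisation per subject) runs as a single batched
Newton iteration across all subjects. The concentration kernel returns
analytic derivatives with respect to the log-scale random effects
(eta_cl, eta_v), which the inner Gauss–Newton solver and the FOCE
linearisation both consume; there is exactly one implementation of the
structural profile used by simulation, estimation, NPDE and the VPC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PKDataset

_F_FLOOR = 1e-12  # floor on model predictions inside logs/divisions


@dataclass(frozen=True)
class PackedDesign:
    """Rectangular (subject x slot) view of a PKDataset.

    Padded observation slots have mask False; padded dose slots have rate 0.
    Covariates are (S,) arrays keyed by name.
    """

    obs_t: np.ndarray  # (S, M) h
    obs_y: np.ndarray  # (S, M) mg/L (zeros where masked)
    obs_mask: np.ndarray  # (S, M) bool
    dose_t0: np.ndarray  # (S, D) h
    dose_rate: np.ndarray  # (S, D) mg/h (0 where padded)
    dose_dur: np.ndarray  # (S, D) h (1 where padded, to avoid 0-division)
    cov: dict[str, np.ndarray]  # each (S,)
    ids: tuple[str, ...]
    weights: np.ndarray | None = None  # subject multiplicities (bootstrap resampling)

    @property
    def n_subjects(self) -> int:
        return self.obs_t.shape[0]

    @property
    def n_obs(self) -> int:
        return int(self.obs_mask.sum())

    @property
    def w(self) -> np.ndarray:
        return self.weights if self.weights is not None else np.ones(self.n_subjects)

    def with_weights(self, weights: np.ndarray) -> "PackedDesign":
        return PackedDesign(
            self.obs_t, self.obs_y, self.obs_mask, self.dose_t0, self.dose_rate,
            self.dose_dur, self.cov, self.ids, np.asarray(weights, dtype=float),
        )

    def subset(self, idx: np.ndarray, weights: np.ndarray | None = None) -> "PackedDesign":
        """Row-subset of subjects, optionally with multiplicity weights."""
        return PackedDesign(
            self.obs_t[idx], self.obs_y[idx], self.obs_mask[idx],
            self.dose_t0[idx], self.dose_rate[idx], self.dose_dur[idx],
            {k: v[idx] for k, v in self.cov.items()},
            tuple(self.ids[i] for i in idx),
            None if weights is None else np.asarray(weights, dtype=float),
        )


def pack(data: PKDataset) -> PackedDesign:
    S = data.n_subjects
    M = max((s.n_obs for s in data.subjects), default=0)
    M = max(M, 1)
    D = max((len(s.doses) for s in data.subjects), default=0)
    D = max(D, 1)
    obs_t = np.zeros((S, M))
    obs_y = np.zeros((S, M))
    obs_mask = np.zeros((S, M), dtype=bool)
    dose_t0 = np.zeros((S, D))
    dose_rate = np.zeros((S, D))
    dose_dur = np.ones((S, D))
    cov = {k: np.zeros(S) for k in ("CW", "BW", "GA", "PNA", "PMA")}
    ids = []
    for i, s in enumerate(data.subjects):
        ids.append(s.id)
        for j, o in enumerate(s.observations):
            obs_t[i, j] = o.time
            obs_y[i, j] = o.concentration
            obs_mask[i, j] = True
        for j, d in enumerate(s.doses):
            dose_t0[i, j] = d.time
            dose_rate[i, j] = d.rate
            dose_dur[i, j] = d.duration
        for k in cov:
            cov[k][i] = getattr(s.covariates, k)
    return PackedDesign(obs_t, obs_y, obs_mask, dose_t0, dose_rate, dose_dur, cov, tuple(ids))


def conc_packed(design: PackedDesign, cl: np.ndarray, v: np.ndarray, with_grad: bool = False):
    """Concentrations f (S, M) at the design's observation times.

    ``cl`` and ``v`` are (S,) individual parameters. With ``with_grad`` also
    returns df/d(eta_cl) and df/d(eta_v), the derivatives with respect to
    additive perturbations of log CL and log V (analytic, not finite
    differences).
    """
    return _conc_arrays(
        design.obs_t, design.dose_t0, design.dose_rate, design.dose_dur, cl, v, with_grad
    )


def _conc_arrays(obs_t, dose_t0, dose_rate, dose_dur, cl, v, with_grad=False):
    ke = (cl / v)[:, None, None]  # (S,1,1)
    scale = dose_rate[:, None, :] / cl[:, None, None]  # (S,1,D)
    dt = obs_t[:, :, None] - dose_t0[:, None, :]  # (S,M,D)
    dur = dose_dur[:, None, :]
    active = dt > 0
    dt_eff = np.clip(dt, 0.0, dur)  # time spent infusing
    s_post = np.clip(dt - dur, 0.0, None)  # time since infusion end
    one_m_e = -np.expm1(-ke * dt_eff)  # 1 - exp(-ke * min(dt, dur))
    decay = np.exp(-ke * s_post)
    contrib = np.where(active, scale * one_m_e * decay, 0.0)
    f = contrib.sum(axis=2)
    if not with_grad:
        return f
    # d log(1 - exp(-x))/dx = exp(-x)/(1-exp(-x)); x = ke*dt_eff
    x = ke * dt_eff
    ex = np.exp(-x)
    # avoid 0/0 where the dose is inactive or x == 0 (contribution is 0 there)
    ratio = np.where(x > 0, x * ex / np.maximum(one_m_e, _F_FLOOR), 1.0)
    # d contrib / d ln ke = contrib * (ratio - ke*s_post); d/d ln(R/CL) = contrib
    dln_ke = contrib * (ratio - ke * s_post)
    # eta_cl: d ln ke = +1, d ln(R/CL) = -1 ; eta_v: d ln ke = -1
    df_cl = (dln_ke - contrib).sum(axis=2)
    df_v = (-dln_ke).sum(axis=2)
    return f, df_cl, df_v


def _h_value(design, f, sigma2, eta, inv_om):
    """Inner FOCE objective per subject (S,): conditional -2 log joint density
    up to constants."""
    fc = np.maximum(f, _F_FLOOR)
    r = design.obs_y - fc
    var = sigma2 * fc * fc
    terms = np.where(design.obs_mask, np.log(var) + r * r / var, 0.0)
    return terms.sum(axis=1) + (eta * eta * inv_om[None, :]).sum(axis=1)


def solve_etas(
    design: PackedDesign,
    cl_typ: np.ndarray,
    v_typ: np.ndarray,
    omega2_cl: float,
    omega2_v: float,
    sigma2: float,
    tol: float = 1e-8,
    max_iter: int = 60,
    eta0: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior modes eta-hat (S, 2) by damped Gauss-Newton, batched over subjects.

    ``eta0`` warm-starts the iteration (the optimum is unique in practice, so
    this only changes the iteration count, not the solution within ``tol``).
    Variance components below ~1e-12 pin the corresponding eta at zero
    (infinitely tight prior).
    """
    S = design.n_subjects
    eta = np.zeros((S, 2)) if eta0 is None else np.array(eta0, dtype=float, copy=True)
    free = np.array([omega2_cl > 1e-12, omega2_v > 1e-12])
    eta *= free[None, :]
    if not free.any() or design.n_obs == 0:
        return np.zeros((S, 2))
    inv_om = np.array(
        [1.0 / omega2_cl if free[0] else 0.0, 1.0 / omega2_v if free[1] else 0.0]
    )
    obs_t, obs_y, obs_mask = design.obs_t, design.obs_y, design.obs_mask
    dose_t0, dose_rate, dose_dur = design.dose_t0, design.dose_rate, design.dose_dur

    def fg(idx, e):
        cl = cl_typ[idx] * np.exp(e[:, 0])
        v = v_typ[idx] * np.exp(e[:, 1])
        return _conc_arrays(
            obs_t[idx], dose_t0[idx], dose_rate[idx], dose_dur[idx], cl, v, True
        )

    def hval(idx, f, e):
        fc = np.maximum(f, _F_FLOOR)
        r = obs_y[idx] - fc
        var = sigma2 * fc * fc
        terms = np.where(obs_mask[idx], np.log(var) + r * r / var, 0.0)
        return terms.sum(axis=1) + (e * e * inv_om[None, :]).sum(axis=1)

    F = np.zeros_like(obs_y)
    Gcl = np.zeros_like(obs_y)
    Gv = np.zeros_like(obs_y)
    active = np.arange(S)
    F[active], Gcl[active], Gv[active] = fg(active, eta[active])
    h = hval(active, F[active], eta[active])
    mu = np.full(S, 1e-8)  # per-subject Levenberg damping
    for _ in range(max_iter):
        a = active
        fc = np.maximum(F[a], _F_FLOOR)
        r = obs_y[a] - fc
        var = sigma2 * fc * fc
        # gradient of h wrt eta: sum_j 2 G_j [1/f - r/var - r^2/(var*f)] + 2 eta/om
        w = np.where(obs_mask[a], 2.0 * (1.0 / fc - r / var - r * r / (var * fc)), 0.0)
        grad = np.stack(
            [(w * Gcl[a]).sum(axis=1), (w * Gv[a]).sum(axis=1)], axis=1
        ) + 2.0 * eta[a] * inv_om[None, :]
        grad *= free[None, :]
        # Gauss-Newton curvature: 2 G G^T / var + 2/om (SPD)
        wj = np.where(obs_mask[a], 2.0 / var, 0.0)
        Hcc = np.where(free[0], (wj * Gcl[a] * Gcl[a]).sum(axis=1) + 2.0 * inv_om[0], 1.0)
        Hvv = np.where(free[1], (wj * Gv[a] * Gv[a]).sum(axis=1) + 2.0 * inv_om[1], 1.0)
        Hcv = (wj * Gcl[a] * Gv[a]).sum(axis=1) * (free[0] & free[1])

        # Levenberg-Marquardt: retry rejected subjects with inflated damping;
        # recomputing a damped step is 2x2 algebra, only candidate evaluation
        # costs a kernel pass, and only over still-rejected subjects.
        rej = np.arange(a.size)
        step_size = np.zeros(a.size)
        for _attempt in range(20):
            d1 = Hcc[rej] * (1.0 + mu[a[rej]])
            d2 = Hvv[rej] * (1.0 + mu[a[rej]])
            dv = Hcv[rej]
            det = d1 * d2 - dv * dv
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            g1, g2 = grad[rej, 0], grad[rej, 1]
            step = np.stack(
                [(-g1 * d2 + g2 * dv) / det, (-g2 * d1 + g1 * dv) / det], axis=1
            )
            cand = eta[a[rej]] + step
            f_c, gcl_c, gv_c = fg(a[rej], cand)
            h_c = hval(a[rej], f_c, cand)
            acc = h_c <= h[a[rej]] + 1e-12
            acc_idx = a[rej[acc]]
            eta[acc_idx] = cand[acc]
            F[acc_idx] = f_c[acc]
            Gcl[acc_idx] = gcl_c[acc]
            Gv[acc_idx] = gv_c[acc]
            h[acc_idx] = h_c[acc]
            mu[acc_idx] = np.maximum(mu[acc_idx] * 0.25, 1e-10)
            step_size[rej[acc]] = np.abs(step[acc]).max(axis=1)
            rej = rej[~acc]
            if rej.size == 0:
                break
            mu[a[rej]] = np.minimum(mu[a[rej]] * 6.0, 1e10)
        # subjects whose last accepted move was tiny (or that could not move
        # at huge damping, i.e. are at a stationary point) are done
        done = step_size < tol
        active = a[~done]
        if active.size == 0:
            break
    return eta


def foce_ofv(
    design: PackedDesign,
    cl_typ: np.ndarray,
    v_typ: np.ndarray,
    omega2_cl: float,
    omega2_v: float,
    sigma2: float,
    eta: np.ndarray | None = None,
    inner_tol: float = 1e-8,
    eta0: np.ndarray | None = None,
):
    """FOCE-with-interaction objective (-2 log approximate marginal likelihood).

    The model function is linearised about each subject's conditional mode
    eta-hat; the residual variance is evaluated at the conditional prediction
    (the "interaction" part). Returns (total OFV including n log 2pi,
    per-subject eta-hat (S,2), per-subject OFV contributions (S,)).
    """
    if eta is None:
        eta = solve_etas(
            design, cl_typ, v_typ, omega2_cl, omega2_v, sigma2, tol=inner_tol, eta0=eta0
        )
    cl = cl_typ * np.exp(eta[:, 0])
    v = v_typ * np.exp(eta[:, 1])
    f, g_cl, g_v = conc_packed(design, cl, v, with_grad=True)
    fc = np.maximum(f, _F_FLOOR)
    mask = design.obs_mask
    S, M = fc.shape
    G = np.stack([np.where(mask, g_cl, 0.0), np.where(mask, g_v, 0.0)], axis=2)  # (S,M,2)
    R = np.where(mask, sigma2 * fc * fc, 1.0)  # padded slots -> unit variance, zero G
    Om = np.array([[omega2_cl, 0.0], [0.0, omega2_v]])
    C = np.einsum("smk,kl,snl->smn", G, Om, G)
    idx = np.arange(M)
    C[:, idx, idx] += R
    e = np.where(mask, design.obs_y - fc, 0.0) + np.einsum("smk,sk->sm", G, eta)
    sign, logdet = np.linalg.slogdet(C)
    sol = np.linalg.solve(C, e[:, :, None])[:, :, 0]
    quad = (e * sol).sum(axis=1)
    n_i = mask.sum(axis=1)
    contrib = logdet + quad + n_i * np.log(2.0 * np.pi)
    return float((contrib * design.w).sum()), eta, contrib


def conditional_pieces(
    design: PackedDesign,
    cl_typ: np.ndarray,
    v_typ: np.ndarray,
    omega2_cl: float,
    omega2_v: float,
    sigma2: float,
    eta: np.ndarray,
):
    """Quantities for residual diagnostics at a given eta-hat.

    Returns dict with the conditional (IPRED) and population (PRED)
    predictions, the FOCE conditional expectation f - G eta, the
    linearised covariance C per subject, and G.
    """
    cl = cl_typ * np.exp(eta[:, 0])
    v = v_typ * np.exp(eta[:, 1])
    f, g_cl, g_v = conc_packed(design, cl, v, with_grad=True)
    fc = np.maximum(f, _F_FLOOR)
    mask = design.obs_mask
    M = fc.shape[1]
    G = np.stack([np.where(mask, g_cl, 0.0), np.where(mask, g_v, 0.0)], axis=2)
    R = np.where(mask, sigma2 * fc * fc, 1.0)
    Om = np.array([[omega2_cl, 0.0], [0.0, omega2_v]])
    C = np.einsum("smk,kl,snl->smn", G, Om, G)
    idx = np.arange(M)
    C[:, idx, idx] += R
    pred = conc_packed(design, cl_typ, v_typ)
    cond_mean = np.where(mask, fc - np.einsum("smk,sk->sm", G, eta), 0.0)
    return {"ipred": fc, "pred": np.maximum(pred, _F_FLOOR), "cond_mean": cond_mean,
            "C": C, "G": G, "R": R}


def simulate_observations(
    design: PackedDesign,
    cl_typ: np.ndarray,
    v_typ: np.ndarray,
    omega2_cl: float,
    omega2_v: float,
    sigma2: float,
    rng: np.random.Generator,
):
    """Draw one replicate of observations at the design: eta ~ N(0, Omega),
    y = f(eta) * (1 + eps), eps ~ N(0, sigma2). Negative draws truncate at 0.

    Returns (y (S,M), eta (S,2), n_truncated).
    """
    S, M = design.obs_t.shape
    eta = rng.standard_normal((S, 2)) * np.sqrt([omega2_cl, omega2_v])
    cl = cl_typ * np.exp(eta[:, 0])
    v = v_typ * np.exp(eta[:, 1])
    f = conc_packed(design, cl, v)
    eps = rng.standard_normal((S, M)) * np.sqrt(sigma2)
    y = f * (1.0 + eps)
    n_trunc = int((y[design.obs_mask] < 0).sum())
    y = np.clip(y, 0.0, None)
    return np.where(design.obs_mask, y, 0.0), eta, n_trunc
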