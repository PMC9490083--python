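"""Population-parameter estimation by FOCE with interaction.

The marginal likelihood of the nonlinear mixed-effects model has no closed
form; FOCE-I approximates each subject's contribution by linearising the
structural model about the subject's conditional mode (empirical Bayes
estimate) of the random effects, with the proportional residual variance
evaluated at the conditional prediction. The resulting objective function
value (OFV) is -2 times the approximate log marginal likelihood, including
the n log(2 pi) constant so it can be compared directly to quadrature.

Estimation minimises the OFV over (theta, omega^2, sigma^2) with positivity
enforced by log transformation of scale and variance parameters; covariate
exponents are unconstrained. Relative standard errors come from the inverse
of the numerical Hessian of the OFV on the natural parameter scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._engine import PackedDesign, foce_ofv, pack, solve_etas
from .io import PKDataset, SubjectData, validate_dataset
from .model import REF_CW, REF_PNA, PopulationParams

__all__ = [
    "CovariateEffect",
    "ModelSpec",
    "ResidualModel",
    "FitSettings",
    "FitResult",
    "BASE_MODEL",
    "FINAL_MODEL",
    "conditional_objective",
    "fit_model",
    "fit_spec",
    "empirical_bayes",
]


@dataclass(frozen=True)
class CovariateEffect:
    """A multiplicative power-function covariate effect on CL or V.

    ``exponent is None`` means the exponent is estimated; a number fixes it
    (e.g. 0.75 for fixed allometry). ``ref`` is the normalisation constant.
    """

    covariate: str  # one of CW, BW, GA, PNA, PMA
    target: str  # "cl" or "v"
    ref: float
    exponent: float | None = None

    @property
    def label(self) -> str:
        return f"{self.covariate}->{self.target.upper()}"


@dataclass(frozen=True)
class ModelSpec:
    effects: tuple[CovariateEffect, ...] = ()

    @property
    def estimated_effects(self) -> tuple[CovariateEffect, ...]:
        return tuple(e for e in self.effects if e.exponent is None)

    def with_effect(self, eff: CovariateEffect) -> "ModelSpec":
        return ModelSpec(self.effects + (eff,))

    def without_effect(self, eff: CovariateEffect) -> "ModelSpec":
        return ModelSpec(tuple(e for e in self.effects if e is not eff))

    @property
    def n_params(self) -> int:
        """Number of estimated parameters (fixed effects + variances)."""
        return 2 + len(self.estimated_effects) + 3


BASE_MODEL = ModelSpec(())
#: Final covariate model: allometric current weight and postnatal-age
#: maturation on clearance, both exponents estimated; no covariates on V.
FINAL_MODEL = ModelSpec(
    (
        CovariateEffect("CW", "cl", REF_CW, None),
        CovariateEffect("PNA", "cl", REF_PNA, None),
    )
)


@dataclass(frozen=True)
class ResidualModel:
    """Proportional residual error: y = f * (1 + eps), eps ~ N(0, sigma2)."""

    kind: str = "proportional"
    sigma2_prop: float = 0.02


@dataclass(frozen=True)
class FitSettings:
    outer_maxiter: int = 4000
    fatol: float = 1e-4  # OFV change at convergence
    xatol: float = 1e-4  # relative parameter change at convergence
    inner_tol: float = 1e-8
    compute_rse: bool = True


@dataclass(frozen=True)
class FitResult:
    spec: ModelSpec
    theta_v: float
    theta_cl: float
    exponents: dict[str, float]  # label -> realised exponent (fixed or estimated)
    omega2_cl: float
    omega2_v: float
    sigma2_prop: float
    ofv: float
    ebes: np.ndarray  # (S, 2) eta-hat (cl, v)
    ids: tuple[str, ...]
    converged: bool
    n_obs: int
    n_subjects: int
    rse: dict[str, float] | None = None

    @property
    def params(self) -> PopulationParams:
        """Map to :class:`PopulationParams`; requires the final covariate shape
        (CW and PNA power terms on CL) or a covariate-free model."""
        labels = {e.label for e in self.spec.effects}
        if labels == {"CW->CL", "PNA->CL"}:
            th3 = self.exponents["CW->CL"]
            th4 = self.exponents["PNA->CL"]
        elif not labels:
            th3 = th4 = 0.0
        else:
            raise ValueError(f"model shape {sorted(labels)} has no PopulationParams mapping")
        return PopulationParams(
            theta1=self.theta_v,
            theta2=self.theta_cl,
            theta3=th3,
            theta4=th4,
            omega2_cl=self.omega2_cl,
            omega2_v=self.omega2_v,
            sigma2_prop=self.sigma2_prop,
        )

    def ebe_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"id": self.ids, "eta_cl": self.ebes[:, 0], "eta_v": self.ebes[:, 1]}
        )


# ---------------------------------------------------------------------------
# parameter vector <-> model quantities


def _typical_cl_v(design: PackedDesign, spec: ModelSpec, theta_v, theta_cl, exps):
    """Per-subject typical CL and V given fixed effects and exponent values."""
    cl = np.full(design.n_subjects, theta_cl)
    v = np.full(design.n_subjects, theta_v)
    it = iter(exps)
    for e in spec.effects:
        expo = e.exponent if e.exponent is not None else next(it)
        factor = (design.cov[e.covariate] / e.ref) ** expo
        if e.target == "cl":
            cl = cl * factor
        else:
            v = v * factor
    return cl, v


# Variance components are floored (1% CV for IIV, 0.1% for residual error):
# a component collapsing toward zero otherwise sends the optimiser down an
# endless flat valley in log-omega space. The floors are far below anything
# estimable from sparse clinical data.
_OM2_FLOOR = 1e-4
_SG2_FLOOR = 1e-6


def _unpack_x(x, spec: ModelSpec):
    k = len(spec.estimated_effects)
    theta_v = np.exp(x[0])
    theta_cl = np.exp(x[1])
    exps = list(x[2 : 2 + k])
    om2_cl = _OM2_FLOOR + np.exp(x[2 + k]) ** 2
    om2_v = _OM2_FLOOR + np.exp(x[3 + k]) ** 2
    sg2 = _SG2_FLOOR + np.exp(x[4 + k]) ** 2
    return theta_v, theta_cl, exps, om2_cl, om2_v, sg2


def _pack_x(theta_v, theta_cl, exps, om2_cl, om2_v, sg2):
    return np.concatenate(
        [
            [np.log(theta_v), np.log(theta_cl)],
            np.asarray(exps, dtype=float),
            [0.5 * np.log(max(om2_cl - _OM2_FLOOR, 1e-10)),
             0.5 * np.log(max(om2_v - _OM2_FLOOR, 1e-10)),
             0.5 * np.log(max(sg2 - _SG2_FLOOR, 1e-10))],
        ]
    )


def _objective(x, design, spec, inner_tol, eta_cache: dict | None = None):
    with np.errstate(all="ignore"):
        theta_v, theta_cl, exps, om2_cl, om2_v, sg2 = _unpack_x(x, spec)
        cl, v = _typical_cl_v(design, spec, theta_v, theta_cl, exps)
        if not np.all(np.isfinite(cl)) or not np.all(np.isfinite(v)):
            return 1e12
        eta0 = eta_cache.get("eta") if eta_cache is not None else None
        try:
            ofv, eta, _ = foce_ofv(
                design, cl, v, om2_cl, om2_v, sg2, inner_tol=inner_tol, eta0=eta0
            )
        except np.linalg.LinAlgError:
            return 1e12
        if not np.isfinite(ofv):
            return 1e12
    if eta_cache is not None:
        eta_cache["eta"] = eta
    return ofv


# ---------------------------------------------------------------------------
# public operations


def conditional_objective(p: PopulationParams, data: PKDataset, inner_tol: float = 1e-8):
    """FOCE-I objective and per-subject conditional modes at fixed parameters.

    Returns (ofv, {subject id: (eta_cl_hat, eta_v_hat)}).
    """
    design = pack(data)
    cl, v = _typical_cl_v(
        design, FINAL_MODEL, p.theta1, p.theta2, [p.theta3, p.theta4]
    )
    ofv, eta, _ = foce_ofv(
        design, cl, v, p.omega2_cl, p.omega2_v, p.sigma2_prop, inner_tol=inner_tol
    )
    return ofv, {sid: (eta[i, 0], eta[i, 1]) for i, sid in enumerate(design.ids)}


def _naive_start(design: PackedDesign, spec: ModelSpec) -> np.ndarray:
    """Reproducible naive-pooled starting values.

    V scale from dose amount over peak concentration; a short pooled
    log-scale least-squares polish of the fixed effects with the random
    effects switched off; 30% IIV and 20% proportional error to start.
    """
    y = design.obs_y[design.obs_mask]
    amt = (design.dose_rate[:, 0] * design.dose_dur[:, 0])
    ymax = np.where(design.obs_mask, design.obs_y, 0.0).max(axis=1)
    ok = ymax > 0
    v0 = float(np.median(amt[ok] / ymax[ok])) if ok.any() else 1.0
    v0 = max(v0, 1e-3)
    cl0 = 0.1 * v0  # half-life ~7 h as a neonatal prior guess
    exps0 = [0.75 if e.covariate in ("CW", "BW") else 0.5 for e in spec.estimated_effects]

    def pooled_sse(z):
        theta_v, theta_cl = np.exp(z[0]), np.exp(z[1])
        cl, v = _typical_cl_v(design, spec, theta_v, theta_cl, list(z[2:]))
        from ._engine import conc_packed

        f = conc_packed(design, cl, v)
        r = np.where(
            design.obs_mask,
            np.log(np.maximum(design.obs_y, 0.1)) - np.log(np.maximum(f, 1e-9)),
            0.0,
        )
        return float((r * r).sum())

    z0 = np.concatenate([[np.log(v0), np.log(cl0)], exps0])
    res = optimize.minimize(
        pooled_sse, z0, method="Nelder-Mead",
        options={"maxiter": 600, "fatol": 1e-6, "xatol": 1e-4},
    )
    z = res.x
    return _pack_x(np.exp(z[0]), np.exp(z[1]), list(z[2:]), 0.30**2, 0.30**2, 0.20**2)


def fit_spec(
    data: PKDataset,
    spec: ModelSpec,
    start: np.ndarray | None = None,
    settings: FitSettings | None = None,
) -> FitResult:
    """Fit an arbitrary covariate model specification; core of :func:`fit_model`."""
    design = pack(data)
    if design.n_obs == 0:
        raise ValueError("cannot fit a dataset with no observations")
    return _fit_design(design, spec, start=start, settings=settings)


def _fit_design(
    design,
    spec: ModelSpec,
    start: np.ndarray | None = None,
    settings: FitSettings | None = None,
) -> FitResult:
    """Fit on a packed (possibly subject-weighted) design.

    The outer Nelder-Mead runs in stages of at most 800 evaluations; between
    stages the simplex is rebuilt at the incumbent. Convergence is declared
    when the optimiser reports success or a restart improves the OFV by less
    than 0.05 (the optimum is then located far inside statistical noise).
    """
    settings = settings or FitSettings()
    x0 = start if start is not None else _naive_start(design, spec)
    eta_cache: dict = {}
    obj = lambda x: _objective(x, design, spec, settings.inner_tol, eta_cache)
    x = np.asarray(x0, dtype=float)
    remaining = settings.outer_maxiter
    converged = False
    last_fun = np.inf
    res = None
    while remaining > 0:
        fev = min(remaining, 800)
        res = optimize.minimize(
            obj,
            x,
            method="Nelder-Mead",
            options={
                "maxiter": fev,
                "maxfev": fev,
                "fatol": settings.fatol,
                "xatol": settings.xatol,
                "adaptive": True,
            },
        )
        x = res.x
        remaining -= res.nfev
        if res.success:
            converged = True
            break
        if last_fun - res.fun < 0.05:
            converged = True
            break
        last_fun = res.fun
    theta_v, theta_cl, exps, om2_cl, om2_v, sg2 = _unpack_x(res.x, spec)
    cl, v = _typical_cl_v(design, spec, theta_v, theta_cl, exps)
    ofv, eta, _ = foce_ofv(design, cl, v, om2_cl, om2_v, sg2, inner_tol=settings.inner_tol)
    exponents: dict[str, float] = {}
    it = iter(exps)
    for e in spec.effects:
        exponents[e.label] = e.exponent if e.exponent is not None else float(next(it))
    rse = None
    if settings.compute_rse:
        rse = _rse_from_hessian(design, spec, theta_v, theta_cl, exps, om2_cl, om2_v, sg2,
                                settings.inner_tol)
    return FitResult(
        spec=spec,
        theta_v=float(theta_v),
        theta_cl=float(theta_cl),
        exponents=exponents,
        omega2_cl=float(om2_cl),
        omega2_v=float(om2_v),
        sigma2_prop=float(sg2),
        ofv=float(ofv),
        ebes=eta,
        ids=design.ids,
        converged=bool(converged),
        n_obs=design.n_obs,
        n_subjects=design.n_subjects,
        rse=rse,
    )


def fit_weighted_design(design, spec, start, settings):
    """Fit with subject multiplicity weights (bootstrap resampling support)."""
    return _fit_design(design, spec, start=start, settings=settings)


def fit_model(
    data: PKDataset,
    start: PopulationParams | None = None,
    settings: FitSettings | None = None,
    spec: ModelSpec = FINAL_MODEL,
) -> FitResult:
    """Maximum-likelihood (FOCE-I) fit of the population model to a dataset.

    ``start`` seeds the optimiser when the spec has the final covariate shape;
    otherwise naive-pooled starting values are derived from the data.
    """
    findings = validate_dataset(data)
    if findings:
        raise ValueError("dataset failed validation: " + "; ".join(map(str, findings[:5])))
    x0 = None
    if start is not None:
        labels = [e.label for e in spec.effects]
        if labels == ["CW->CL", "PNA->CL"]:
            x0 = _pack_x(
                start.theta1, start.theta2, [start.theta3, start.theta4],
                max(start.omega2_cl, 1e-6), max(start.omega2_v, 1e-6),
                max(start.sigma2_prop, 1e-6),
            )
        else:
            raise ValueError("explicit PopulationParams start requires the final model spec")
    return fit_spec(data, spec, start=x0, settings=settings)


def _rse_from_hessian(design, spec, theta_v, theta_cl, exps, om2_cl, om2_v, sg2, inner_tol):
    """RSE (%) per estimated term from the inverse numerical OFV Hessian.

    OFV = -2 log L, so the covariance is 2 * H^{-1}. Central differences on
    the natural parameter scale. Terms with a non-positive variance estimate
    are reported as NaN (singular or indefinite Hessian).
    """
    names = (
        ["theta_v", "theta_cl"]
        + [f"beta_{e.label}" for e in spec.estimated_effects]
        + ["omega2_cl", "omega2_v", "sigma2_prop"]
    )
    p0 = np.array([theta_v, theta_cl, *exps, om2_cl, om2_v, sg2], dtype=float)

    def f(p):
        x = _pack_x(p[0], p[1], p[2 : 2 + len(exps)], p[-3], p[-2], p[-1])
        return _objective(x, design, spec, inner_tol)

    n = len(p0)
    h = 1e-3 * np.maximum(np.abs(p0), 1e-6)
    H = np.zeros((n, n))
    f0 = f(p0)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(p0 + ei); fmm = f(p0 - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            fpj = f(p0 + ei + ej); fpm = f(p0 + ei - ej)
            fmj = f(p0 - ei + ej); fmn = f(p0 - ei - ej)
            H[i, j] = H[j, i] = (fpj - fpm - fmj + fmn) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {k: float("nan") for k in names}
    var = np.diag(cov)
    rse = {}
    for k, name in enumerate(names):
        if var[k] > 0 and p0[k] != 0:
            rse[name] = float(100.0 * np.sqrt(var[k]) / abs(p0[k]))
        else:
            rse[name] = float("nan")
    return rse


def empirical_bayes(
    p: PopulationParams, subject: SubjectData, inner_tol: float = 1e-8
) -> tuple[float, float]:
    """Posterior mode of (eta_cl, eta_v) for one subject under fixed parameters.

    A subject with no observations gets (0, 0) — complete shrinkage to the
    population typical value; shrinkage also follows as omega^2 -> 0.
    """
    if subject.n_obs == 0:
        return (0.0, 0.0)
    design = pack(PKDataset((subject,)))
    cl, v = _typical_cl_v(design, FINAL_MODEL, p.theta1, p.theta2, [p.theta3, p.theta4])
    eta = solve_etas(
        design, cl, v, p.omega2_cl, p.omega2_v, p.sigma2_prop, tol=inner_tol
    )
    return (float(eta[0, 0]), float(eta[0, 1]))
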