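"""Model-evaluation machinery: CWRES, nonparametric bootstrap, NPDE, pcVPC.

All simulation-based diagnostics draw replicate datasets through the same
vectorised kernel the estimator and the synthetic-cohort generator use, so
there is a single implementation of the structural profile, and every
routine is deterministic given its inputs and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla, stats

from ._engine import (
    conditional_pieces,
    pack,
    simulate_observations,
    solve_etas,
)
from .estimate import (
    FitResult,
    FitSettings,
    ModelSpec,
    _pack_x,
    _typical_cl_v,
    fit_spec,
    fit_weighted_design,
)
from .io import PKDataset

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "NpdeResult",
    "VpcResult",
    "cwres",
    "bootstrap",
    "npde",
    "pcvpc",
]


def _fit_cl_v(fit: FitResult, design):
    exps = [fit.exponents[e.label] for e in fit.spec.estimated_effects]
    return _typical_cl_v(design, fit.spec, fit.theta_v, fit.theta_cl, exps)


# ---------------------------------------------------------------------------
# conditional weighted residuals


def cwres(fit: FitResult, data: PKDataset) -> np.ndarray:
    """Conditional weighted residuals, one per observation in dataset order.

    Per subject: L^{-1} (y - y_c) with y_c = f(eta-hat) - G eta-hat (the FOCE
    conditional expectation) and L the Cholesky factor of the linearised
    covariance G Omega G' + R(eta-hat). Under the generating model the pooled
    residuals are approximately standard normal.
    """
    if not fit.converged:
        raise ValueError("cwres requires a converged fit")
    design = pack(data)
    cl, v = _fit_cl_v(fit, design)
    eta = solve_etas(design, cl, v, fit.omega2_cl, fit.omega2_v, fit.sigma2_prop)
    pieces = conditional_pieces(
        design, cl, v, fit.omega2_cl, fit.omega2_v, fit.sigma2_prop, eta
    )
    out = []
    for i in range(design.n_subjects):
        m = design.obs_mask[i]
        n_i = int(m.sum())
        if n_i == 0:
            continue
        C = pieces["C"][i][np.ix_(m, m)]
        resid = design.obs_y[i, m] - pieces["cond_mean"][i, m]
        try:
            L = np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular linearised covariance for subject {design.ids[i]}"
            ) from exc
        out.append(sla.solve_triangular(L, resid, lower=True))
    return np.concatenate(out) if out else np.array([])


# ---------------------------------------------------------------------------
# nonparametric bootstrap


@dataclass(frozen=True)
class BootstrapResult:
    n_replicates: int
    n_failed: int
    estimates: pd.DataFrame  # one row per converged replicate
    median: dict[str, float]
    p5: dict[str, float]
    p95: dict[str, float]


def _fit_param_row(fit: FitResult) -> dict[str, float]:
    row = {"theta_v": fit.theta_v, "theta_cl": fit.theta_cl}
    row.update({f"beta_{k}": v for k, v in fit.exponents.items()})
    row.update(
        {
            "omega2_cl": fit.omega2_cl,
            "omega2_v": fit.omega2_v,
            "sigma2_prop": fit.sigma2_prop,
            "ofv": fit.ofv,
        }
    )
    return row


def bootstrap(
    data: PKDataset,
    spec: ModelSpec,
    B: int = 1000,
    seed: int = 0,
    settings: FitSettings | None = None,
    warm_start: FitResult | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects with replacement, refit.

    Replicates keep the original subject count. Non-converged replicates are
    dropped and counted in ``n_failed``. Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    # replicate-level precision well below bootstrap sampling variability
    settings = settings or FitSettings(
        compute_rse=False, fatol=3e-3, xatol=3e-3, outer_maxiter=1000
    )
    rng = np.random.default_rng(seed)
    if warm_start is None:
        warm_start = fit_spec(data, spec, settings=settings)
    exps = [warm_start.exponents[e.label] for e in spec.estimated_effects]
    x0 = _pack_x(
        warm_start.theta_v, warm_start.theta_cl, exps,
        max(warm_start.omega2_cl, 1e-8), max(warm_start.omega2_v, 1e-8),
        max(warm_start.sigma2_prop, 1e-8),
    )
    base_design = pack(data)
    n = data.n_subjects
    rows = []
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        # duplicated subjects contribute identical likelihood terms, so fit
        # the unique subjects with multiplicity weights (exactly equivalent)
        counts = np.bincount(idx, minlength=n)
        sel = np.nonzero(counts)[0]
        design_b = base_design.subset(sel, weights=counts[sel])
        try:
            fit = fit_weighted_design(design_b, spec, start=x0, settings=settings)
        except Exception as exc:
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            n_failed += 1
            continue
        if not (fit.converged and np.isfinite(fit.ofv)):
            n_failed += 1
            continue
        rows.append(_fit_param_row(fit))
    if not rows:
        raise RuntimeError("all bootstrap replicates failed")
    est = pd.DataFrame(rows)
    cols = [c for c in est.columns if c != "ofv"]
    return BootstrapResult(
        n_replicates=B,
        n_failed=n_failed,
        estimates=est,
        median={c: float(est[c].median()) for c in cols},
        p5={c: float(est[c].quantile(0.05)) for c in cols},
        p95={c: float(est[c].quantile(0.95)) for c in cols},
    )


# ---------------------------------------------------------------------------
# normalized prediction distribution errors


@dataclass(frozen=True)
class NpdeResult:
    values: np.ndarray  # one per observation, dataset order
    mean: float
    variance: float
    ks_stat: float  # Kolmogorov-Smirnov distance to N(0,1)
    ks_pvalue: float


def npde(fit: FitResult, data: PKDataset, K: int = 1000, seed: int = 0) -> NpdeResult:
    """Normalized prediction distribution errors against K model simulations.

    Per subject, the observed vector and each simulated vector are
    decorrelated with the simulation mean and the Cholesky square root of the
    simulation covariance; each decorrelated observation's rank among its
    decorrelated simulations maps through (rank + 0.5)/(K + 1) and the
    inverse normal CDF. Under a correct model the pooled values are ~N(0,1).
    """
    if K < 100:
        raise ValueError("K must be >= 100 for usable rank resolution")
    design = pack(data)
    cl, v = _fit_cl_v(fit, design)
    rng = np.random.default_rng(seed)
    sims = np.empty((K, *design.obs_y.shape))
    for k in range(K):
        sims[k], _, _ = simulate_observations(
            design, cl, v, fit.omega2_cl, fit.omega2_v, fit.sigma2_prop, rng
        )
    values = []
    for i in range(design.n_subjects):
        m = design.obs_mask[i]
        n_i = int(m.sum())
        if n_i == 0:
            continue
        Y = sims[:, i, :][:, m]  # (K, n_i)
        y = design.obs_y[i, m]
        E = Y.mean(axis=0)
        V = np.cov(Y, rowvar=False).reshape(n_i, n_i)
        L = np.linalg.cholesky(V)
        y_star = np.linalg.solve(L, y - E)
        Y_star = np.linalg.solve(L, (Y - E).T).T  # (K, n_i)
        ranks = (Y_star < y_star[None, :]).sum(axis=0)
        p = (ranks + 0.5) / (K + 1.0)
        values.append(stats.norm.ppf(p))
    vals = np.concatenate(values)
    ks = stats.kstest(vals, "norm")
    return NpdeResult(
        values=vals,
        mean=float(vals.mean()),
        variance=float(vals.var(ddof=1)),
        ks_stat=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
    )


# ---------------------------------------------------------------------------
# prediction-corrected visual predictive check


@dataclass(frozen=True)
class VpcResult:
    bin_edges: np.ndarray  # (n_bins + 1,) on time after dose
    bin_mid: np.ndarray
    n_per_bin: np.ndarray
    observed: np.ndarray  # (3, n_bins): pc 5th / 50th / 95th percentiles
    envelope_lo: np.ndarray  # (3, n_bins): 2.5% of each simulated percentile
    envelope_hi: np.ndarray  # (3, n_bins): 97.5%

    @property
    def median_within_envelope(self) -> np.ndarray:
        return (self.observed[1] >= self.envelope_lo[1]) & (
            self.observed[1] <= self.envelope_hi[1]
        )


_PCTS = (5.0, 50.0, 95.0)


def _time_after_dose(design) -> np.ndarray:
    """Time since the most recent dose start, per observation slot (S, M)."""
    dt = design.obs_t[:, :, None] - design.dose_t0[:, None, :]
    dt = np.where((dt > 0) & (design.dose_rate[:, None, :] > 0), dt, np.inf)
    tad = dt.min(axis=2)
    return np.where(np.isfinite(tad), tad, 0.0)


def pcvpc(
    fit: FitResult,
    data: PKDataset,
    n_sim: int = 500,
    bins: int = 6,
    seed: int = 0,
) -> VpcResult:
    """Prediction-corrected VPC with equal-count bins on time after dose.

    Each observed and simulated value is rescaled by (bin median population
    prediction / its own population prediction) before percentiles are taken;
    the simulation envelope is the 2.5-97.5% band of each percentile across
    replicates.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    design = pack(data)
    cl, v = _fit_cl_v(fit, design)
    pieces = conditional_pieces(
        design, cl, v, fit.omega2_cl, fit.omega2_v, fit.sigma2_prop,
        np.zeros((design.n_subjects, 2)),
    )
    mask = design.obs_mask
    pred = pieces["pred"][mask]
    if np.any(pred <= 0):
        raise ValueError("population prediction must be positive for prediction correction")
    tad = _time_after_dose(design)[mask]
    y = design.obs_y[mask]
    edges = np.quantile(tad, np.linspace(0, 1, bins + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    which = np.digitize(tad, edges) - 1
    which = np.clip(which, 0, bins - 1)
    n_per_bin = np.bincount(which, minlength=bins)
    if (n_per_bin == 0).any():
        raise ValueError("empty VPC bin; reduce the number of bins")
    pred_med = np.array([np.median(pred[which == b]) for b in range(bins)])
    correction = pred_med[which] / pred
    y_pc = y * correction

    obs_pct = np.array(
        [[np.percentile(y_pc[which == b], q) for b in range(bins)] for q in _PCTS]
    )
    rng = np.random.default_rng(seed)
    sim_pct = np.empty((n_sim, len(_PCTS), bins))
    for k in range(n_sim):
        yk, _, _ = simulate_observations(
            design, cl, v, fit.omega2_cl, fit.omega2_v, fit.sigma2_prop, rng
        )
        yk_pc = yk[mask] * correction
        for qi, q in enumerate(_PCTS):
            for b in range(bins):
                sim_pct[k, qi, b] = np.percentile(yk_pc[which == b], q)
    return VpcResult(
        bin_edges=edges,
        bin_mid=0.5 * (edges[:-1] + edges[1:]),
        n_per_bin=n_per_bin,
        observed=obs_pct,
        envelope_lo=np.percentile(sim_pct, 2.5, axis=0),
        envelope_hi=np.percentile(sim_pct, 97.5, axis=0),
    )
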