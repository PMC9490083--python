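"""Stepwise covariate selection by likelihood-ratio testing.

Forward inclusion adds, one candidate per fit, the covariate whose inclusion
drops the OFV the most, provided the drop exceeds the chi-square criterion
(3.84 at p < 0.05, 1 df); all significant covariates are then carried
simultaneously into backward elimination, which deletes any covariate whose
removal raises the OFV by no more than 6.635 (p < 0.01). Candidates are
power functions of BW, GA, CW, PNA or PMA normalised to the dataset median,
applied multiplicatively to CL or V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimate import (
    CovariateEffect,
    FitResult,
    FitSettings,
    ModelSpec,
    fit_spec,
)
from .estimate import _pack_x  # shared parameter-vector layout
from .io import PKDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SearchStep",
    "SearchTrace",
    "lrt_threshold",
    "default_candidates",
    "forward_selection",
    "backward_elimination",
    "stepwise_search",
    "compare_allometric_forms",
]

#: Search-time fit settings: no standard errors, slightly looser outer
#: tolerance — only OFV differences matter here.
_SEARCH_SETTINGS = FitSettings(compute_rse=False, fatol=1e-3, xatol=1e-3)


def lrt_threshold(alpha: float, df: int = 1) -> float:
    """Critical OFV change: upper-alpha quantile of chi-square with ``df`` df."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


@dataclass(frozen=True)
class SearchStep:
    """One tested model: enough to re-derive the decision from the numbers."""

    action: str  # "add" or "remove"
    candidate: str  # effect label, e.g. "CW->CL"
    ofv: float  # OFV of the tested model
    ref_ofv: float  # OFV of the reference model at this step
    dofv: float  # signed improvement (ref - tested for add; tested - ref for remove)
    threshold: float
    accepted: bool


@dataclass(frozen=True)
class SearchTrace:
    steps: tuple[SearchStep, ...]
    final_spec: ModelSpec
    final_ofv: float
    base_ofv: float


def default_candidates(data: PKDataset, targets: tuple[str, ...] = ("cl",)):
    """All five covariates as estimated-exponent power terms on each target,
    normalised to the dataset median."""
    cands = []
    for name in ("BW", "GA", "CW", "PNA", "PMA"):
        ref = float(np.median([getattr(s.covariates, name) for s in data.subjects]))
        for tgt in targets:
            cands.append(CovariateEffect(name, tgt, ref, None))
    return cands


def _warm_start(ref: FitResult, new_spec: ModelSpec) -> np.ndarray:
    """Start vector for a spec differing from a fitted reference by one effect."""
    exps = []
    for e in new_spec.estimated_effects:
        if e.label in ref.exponents and any(
            r.label == e.label and r.exponent is None for r in ref.spec.effects
        ):
            exps.append(ref.exponents[e.label])
        else:
            exps.append(0.75 if e.covariate in ("CW", "BW") else 0.5)
    return _pack_x(ref.theta_v, ref.theta_cl, exps,
                   max(ref.omega2_cl, 1e-8), max(ref.omega2_v, 1e-8),
                   max(ref.sigma2_prop, 1e-8))


def _try_fit(data, spec, start, settings) -> FitResult | None:
    try:
        fit = fit_spec(data, spec, start=start, settings=settings)
    except Exception as exc:  # singular / non-finite candidate model
        logger.warning("candidate fit failed (%s): %s", spec, exc)
        return None
    if not np.isfinite(fit.ofv):
        logger.warning("candidate fit non-finite OFV, skipped: %s", spec)
        return None
    return fit


def forward_selection(
    data: PKDataset,
    base: ModelSpec,
    candidates: list[CovariateEffect],
    alpha: float = 0.05,
    settings: FitSettings = _SEARCH_SETTINGS,
) -> SearchTrace:
    """Iteratively add the most significant candidate until none qualifies.

    Ties on ΔOFV break toward fewer added parameters, then lexicographic
    label. Non-convergent candidates are skipped with a logged warning.
    """
    base_fit = fit_spec(data, base, settings=settings)
    current, current_fit = base, base_fit
    remaining = list(candidates)
    steps: list[SearchStep] = []
    thr = lrt_threshold(alpha, 1)
    while remaining:
        trials = []
        for cand in remaining:
            spec = current.with_effect(cand)
            fit = _try_fit(data, spec, _warm_start(current_fit, spec), settings)
            if fit is None:
                continue
            dofv = current_fit.ofv - fit.ofv
            n_added = 1 if cand.exponent is None else 0
            trials.append((dofv, -n_added, cand.label, cand, fit))
            steps.append(SearchStep("add", cand.label, fit.ofv, current_fit.ofv,
                                    dofv, thr, False))
        winners = [t for t in trials if t[0] > thr]
        if not winners:
            break
        winners.sort(key=lambda t: (-t[0], t[1], t[2]))
        _, _, label, cand, fit = winners[0]
        # mark the accepted step (replace the provisional record)
        for i in range(len(steps) - 1, -1, -1):
            if steps[i].candidate == label and steps[i].ref_ofv == current_fit.ofv:
                steps[i] = SearchStep("add", label, fit.ofv, current_fit.ofv,
                                      current_fit.ofv - fit.ofv, thr, True)
                break
        current, current_fit = current.with_effect(cand), fit
        remaining.remove(cand)
    return SearchTrace(tuple(steps), current, current_fit.ofv, base_fit.ofv)


def backward_elimination(
    data: PKDataset,
    full: ModelSpec,
    alpha: float = 0.01,
    settings: FitSettings = _SEARCH_SETTINGS,
    full_fit: FitResult | None = None,
) -> SearchTrace:
    """Delete, one at a time, the covariate whose removal costs the least OFV,
    while that cost does not exceed the chi-square criterion."""
    if full_fit is None:
        full_fit = fit_spec(data, full, settings=settings)
    current, current_fit = full, full_fit
    steps: list[SearchStep] = []
    thr = lrt_threshold(alpha, 1)
    while current.effects:
        trials = []
        for eff in current.effects:
            spec = current.without_effect(eff)
            fit = _try_fit(data, spec, _warm_start(current_fit, spec), settings)
            if fit is None:
                continue
            rise = fit.ofv - current_fit.ofv
            trials.append((rise, eff.label, eff, fit))
            steps.append(SearchStep("remove", eff.label, fit.ofv, current_fit.ofv,
                                    rise, thr, False))
        removable = [t for t in trials if t[0] <= thr]
        if not removable:
            break
        removable.sort(key=lambda t: (t[0], t[1]))
        rise, label, eff, fit = removable[0]
        for i in range(len(steps) - 1, -1, -1):
            if steps[i].candidate == label and steps[i].ref_ofv == current_fit.ofv:
                steps[i] = SearchStep("remove", label, fit.ofv, current_fit.ofv,
                                      rise, thr, True)
                break
        current, current_fit = current.without_effect(eff), fit
    return SearchTrace(tuple(steps), current, current_fit.ofv, full_fit.ofv)


def stepwise_search(
    data: PKDataset,
    base: ModelSpec,
    candidates: list[CovariateEffect],
    alpha_forward: float = 0.05,
    alpha_backward: float = 0.01,
    settings: FitSettings = _SEARCH_SETTINGS,
) -> SearchTrace:
    """Forward inclusion at ``alpha_forward`` then backward elimination at
    ``alpha_backward``; returns the combined trace."""
    fwd = forward_selection(data, base, candidates, alpha_forward, settings)
    bwd = backward_elimination(data, fwd.final_spec, alpha_backward, settings)
    return SearchTrace(fwd.steps + bwd.steps, bwd.final_spec, bwd.final_ofv, fwd.base_ofv)


def compare_allometric_forms(
    data: PKDataset,
    base: ModelSpec = ModelSpec(()),
    settings: FitSettings = _SEARCH_SETTINGS,
) -> tuple[float, float]:
    """ΔOFV of weight-on-CL with the exponent estimated vs fixed at 0.75.

    Returns (dofv_estimated, dofv_fixed), each relative to the base model.
    """
    if data.n_subjects < 2:
        raise ValueError("allometric comparison needs at least 2 subjects")
    ref = float(np.median([s.covariates.CW for s in data.subjects]))
    base_fit = fit_spec(data, base, settings=settings)
    est_spec = base.with_effect(CovariateEffect("CW", "cl", ref, None))
    fix_spec = base.with_effect(CovariateEffect("CW", "cl", ref, 0.75))
    est_fit = _try_fit(data, est_spec, _warm_start(base_fit, est_spec), settings)
    fix_fit = _try_fit(data, fix_spec, _warm_start(base_fit, fix_spec), settings)
    if est_fit is None or fix_fit is None:
        raise RuntimeError("allometric comparison fit failed")
    return (base_fit.ofv - est_fit.ofv, base_fit.ofv - fix_fit.ofv)


def replay_decisions(trace: SearchTrace) -> bool:
    """Audit: every accepted/rejected flag follows from the recorded OFVs and
    thresholds. Returns True when the trace is internally consistent."""
    for s in trace.steps:
        if s.action == "add":
            qualifies = s.dofv > s.threshold
        else:
            qualifies = s.dofv <= s.threshold
        if s.accepted and not qualifies:
            return False
    return True
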