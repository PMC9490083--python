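"""Virtual neonatal cohorts and sparse opportunistic PK datasets.

Emulates the statistical structure of the study population: gestational age
truncated-normal between 30.0 and 41.1 weeks (median 35.7), postnatal age 1-3
days with median 1, current weight log-linearly linked to GA so the cohort
median sits near 2310 g within 1220-3970 g, birth weight equal to current
weight at these ages, and PMA = GA + PNA/7. Dosing is 50 mg/kg every 12 h as
0.5-h infusions; sampling is sparse (about two samples per subject) at
uniform random times over the first three treatment days, mimicking
opportunistic leftover-blood sampling.

Simulated concentrations come from the same closed-form kernel the estimator
uses; only the random effects and proportional noise are added here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import io as dio
from ._engine import pack, simulate_observations
from .io import CovariateRecord, DoseEvent, Observation, PKDataset, SubjectData
from .model import NEONATAL_EOS_PARAMS, PopulationParams

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "DesignSpec",
    "sample_cohort",
    "simulate_dataset",
    "make_fixture",
]


@dataclass(frozen=True)
class CohortSpec:
    """Covariate generator settings; defaults reproduce the study cohort."""

    n_subjects: int = 51
    seed: int = 0
    ga_median: float = 35.7  # weeks
    ga_sd: float = 3.0
    ga_range: tuple[float, float] = (30.0, 41.1)
    cw_median: float = 2310.0  # g at the median GA
    cw_range: tuple[float, float] = (1220.0, 3970.0)
    cw_ga_slope: float = 0.08  # d ln CW / d GA week
    cw_sd_log: float = 0.12
    pna_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # P(PNA = 1, 2, 3 d)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.ga_range[0] < self.ga_median < self.ga_range[1]:
            raise ValueError("GA median must lie inside the GA range")
        if not self.cw_range[0] < self.cw_median < self.cw_range[1]:
            raise ValueError("CW median must lie inside the CW range")
        if abs(sum(self.pna_probs) - 1.0) > 1e-9:
            raise ValueError("PNA probabilities must sum to 1")


@dataclass(frozen=True)
class DesignSpec:
    """Dosing and sampling design of the sparse opportunistic study."""

    dose_per_kg: float = 50.0  # mg/kg
    tau: float = 12.0  # h
    infusion_duration: float = 0.5  # h
    samples_per_subject: int = 2
    sampling_window: tuple[float, float] = (0.5, 72.0)  # h after first dose
    n_doses: int = 7  # covers the sampling window at q12h

    def __post_init__(self) -> None:
        if not self.tau > self.infusion_duration > 0:
            raise ValueError("require tau > infusion duration > 0")
        if self.sampling_window[0] <= 0:
            raise ValueError("samples must be strictly after the first dose")


def sample_cohort(spec: CohortSpec) -> list[CovariateRecord]:
    """Draw a virtual cohort of neonatal covariate records.

    GA ~ truncated normal; CW is log-linear in GA with noise, clipped to the
    study range; BW = CW; PMA = GA + PNA/7. Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ga_range
    a = (lo - spec.ga_median) / spec.ga_sd
    b = (hi - spec.ga_median) / spec.ga_sd
    ga = stats.truncnorm.rvs(
        a, b, loc=spec.ga_median, scale=spec.ga_sd, size=spec.n_subjects, random_state=rng
    )
    log_cw = (
        math.log(spec.cw_median)
        + spec.cw_ga_slope * (ga - spec.ga_median)
        + rng.normal(0.0, spec.cw_sd_log, spec.n_subjects)
    )
    cw = np.clip(np.exp(log_cw), spec.cw_range[0], spec.cw_range[1])
    pna = rng.choice([1.0, 2.0, 3.0], size=spec.n_subjects, p=list(spec.pna_probs))
    records = []
    for i in range(spec.n_subjects):
        records.append(
            CovariateRecord(
                CW=float(cw[i]),
                BW=float(cw[i]),
                GA=float(ga[i]),
                PNA=float(pna[i]),
                PMA=float(ga[i] + pna[i] / 7.0),
            )
        )
    return records


def _dose_schedule(cov: CovariateRecord, design: DesignSpec) -> tuple[DoseEvent, ...]:
    amount = design.dose_per_kg * cov.CW / 1000.0
    return tuple(
        DoseEvent(time=k * design.tau, amount=amount, duration=design.infusion_duration)
        for k in range(design.n_doses)
    )


def simulate_dataset(
    cohort: list[CovariateRecord],
    p: PopulationParams = NEONATAL_EOS_PARAMS,
    design: DesignSpec | None = None,
    seed: int = 0,
    n_obs_total: int | None = None,
) -> PKDataset:
    """Simulate a sparse PK dataset over a cohort under the population model.

    Per subject: eta ~ N(0, Omega); a q12h dose schedule scaled to current
    weight; ``samples_per_subject`` observation times uniform over the
    sampling window; concentrations from the structural model with
    proportional error y = f (1 + eps). If ``n_obs_total`` is given, single
    observations are dropped from randomly chosen subjects until the total
    matches (the study's 101-of-102 design).
    """
    design = design or DesignSpec()
    rng = np.random.default_rng(seed)
    skeleton: list[SubjectData] = []
    for i, cov in enumerate(cohort):
        doses = _dose_schedule(cov, design)
        times = np.sort(
            rng.uniform(design.sampling_window[0], design.sampling_window[1],
                        design.samples_per_subject)
        )
        obs = tuple(Observation(time=float(t), concentration=1.0) for t in times)
        skeleton.append(SubjectData(id=f"S{i + 1:03d}", covariates=cov, doses=doses,
                                    observations=obs))
    if n_obs_total is not None:
        total = sum(s.n_obs for s in skeleton)
        if n_obs_total > total:
            raise ValueError("n_obs_total exceeds the designed observation count")
        while total > n_obs_total:
            k = int(rng.integers(0, len(skeleton)))
            s = skeleton[k]
            if s.n_obs <= 1:
                continue
            skeleton[k] = SubjectData(
                id=s.id, covariates=s.covariates, doses=s.doses,
                observations=s.observations[:-1],
            )
            total -= 1
    base = PKDataset(tuple(skeleton))
    packed = pack(base)
    from .estimate import FINAL_MODEL, _typical_cl_v

    cl_typ, v_typ = _typical_cl_v(
        packed, FINAL_MODEL, p.theta1, p.theta2, [p.theta3, p.theta4]
    )
    y, _, n_trunc = simulate_observations(
        packed, cl_typ, v_typ, p.omega2_cl, p.omega2_v, p.sigma2_prop, rng
    )
    if n_trunc:
        logger.warning("truncated %d negative simulated concentration(s) at 0", n_trunc)
    subjects = []
    for i, s in enumerate(skeleton):
        obs = tuple(
            Observation(time=s.observations[j].time, concentration=float(y[i, j]))
            for j in range(s.n_obs)
        )
        subjects.append(SubjectData(id=s.id, covariates=s.covariates, doses=s.doses,
                                    observations=obs))
    return PKDataset(tuple(subjects))


_PRESETS = {"study-like": dict(n_subjects=51, n_obs_total=101)}


def make_fixture(name: str, seed: int, path: str | None = None) -> PKDataset:
    """Generate a canonical synthetic dataset preset; optionally write it to CSV.

    ``"study-like"`` is the 51-subject / 101-observation sparse design under
    the shipped final-model parameters. Byte-stable for a fixed seed.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    cfg = _PRESETS[name]
    cohort = sample_cohort(CohortSpec(n_subjects=cfg["n_subjects"], seed=seed))
    data = simulate_dataset(
        cohort, NEONATAL_EOS_PARAMS, DesignSpec(), seed=seed + 1,
        n_obs_total=cfg["n_obs_total"],
    )
    if path is not None:
        dio.write_dataset(data, path)
    return data
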