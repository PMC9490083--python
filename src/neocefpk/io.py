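"""Longitudinal PK event data model and NONMEM-flavoured CSV I/O.

The unit of analysis is a :class:`PKDataset`: a collection of subjects, each
carrying intravenous infusion dose events, sparse concentration observations
and a set of neonatal covariates (current weight, birth weight, gestational
age, postnatal age, postmenstrual age).

Internal units are fixed: mg (amount), L (volume), h (time), mg/L
(concentration; µg/ml is accepted as a synonym), g (weight), days (postnatal
age), weeks (gestational / postmenstrual age).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "DoseEvent",
    "Observation",
    "CovariateRecord",
    "SubjectData",
    "PKDataset",
    "Dialect",
    "Finding",
    "SchemaError",
    "UnitError",
    "DataValidationError",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
]

COVARIATE_NAMES = ("CW", "BW", "GA", "PNA", "PMA")

# accepted unit tags, mapped to a multiplicative factor into internal units
_CONC_UNITS = {"mg/L": 1.0, "ug/mL": 1.0, "µg/ml": 1.0, "ug/ml": 1.0, "mg/l": 1.0}
_AMT_UNITS = {"mg": 1.0, "g": 1000.0}
_TIME_UNITS = {"h": 1.0, "hr": 1.0, "min": 1.0 / 60.0}
_WEIGHT_UNITS = {"g": 1.0, "kg": 1000.0}


class SchemaError(ValueError):
    """A required column is missing from the event file."""


class UnitError(ValueError):
    """An unknown unit tag was supplied in the dialect."""


class DataValidationError(ValueError):
    """A row of the event file violates a basic constraint."""


@dataclass(frozen=True)
class DoseEvent:
    """A constant-rate intravenous infusion.

    ``rate`` is derived as ``amount / duration``; the study drug was given as
    0.5 h infusions, so duration is first-class rather than an optional flag.
    """

    time: float  # h since first dose
    amount: float  # mg
    duration: float  # h

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration

    @property
    def end(self) -> float:
        return self.time + self.duration


@dataclass(frozen=True)
class Observation:
    time: float  # h since first dose
    concentration: float  # mg/L


@dataclass(frozen=True)
class CovariateRecord:
    """Neonatal covariates. Weights in g, PNA in days, GA/PMA in weeks."""

    CW: float
    BW: float
    GA: float
    PNA: float
    PMA: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in COVARIATE_NAMES}


@dataclass(frozen=True)
class SubjectData:
    id: str
    covariates: CovariateRecord
    doses: tuple[DoseEvent, ...]
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple(sorted(self.doses, key=lambda d: d.time)))
        object.__setattr__(
            self, "observations", tuple(sorted(self.observations, key=lambda o: o.time))
        )

    @property
    def n_obs(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class PKDataset:
    subjects: tuple[SubjectData, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return sum(s.n_obs for s in self.subjects)

    def subject(self, sid: str) -> SubjectData:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)


@dataclass(frozen=True)
class Dialect:
    """Column mapping and units of a NONMEM-style event CSV.

    One row per event; dose rows carry AMT and RATE with MDV=1, observation
    rows carry DV with MDV=0. Covariate columns repeat per row.
    """

    id_col: str = "ID"
    time_col: str = "TIME"
    amt_col: str = "AMT"
    rate_col: str = "RATE"
    dv_col: str = "DV"
    mdv_col: str = "MDV"
    covariate_cols: dict[str, str] = field(
        default_factory=lambda: {k: k for k in COVARIATE_NAMES}
    )
    conc_unit: str = "mg/L"
    amt_unit: str = "mg"
    time_unit: str = "h"
    weight_unit: str = "g"
    loq: float = 0.5  # mg/L, lower limit of quantification of the assay
    exclude_blq: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "Dialect":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)

    def _factors(self) -> tuple[float, float, float, float]:
        try:
            fc = _CONC_UNITS[self.conc_unit]
        except KeyError:
            raise UnitError(f"unknown concentration unit {self.conc_unit!r}")
        try:
            fa = _AMT_UNITS[self.amt_unit]
        except KeyError:
            raise UnitError(f"unknown amount unit {self.amt_unit!r}")
        try:
            ft = _TIME_UNITS[self.time_unit]
        except KeyError:
            raise UnitError(f"unknown time unit {self.time_unit!r}")
        try:
            fw = _WEIGHT_UNITS[self.weight_unit]
        except KeyError:
            raise UnitError(f"unknown weight unit {self.weight_unit!r}")
        return fc, fa, ft, fw


def read_dataset(path: str, dialect: Dialect | None = None) -> PKDataset:
    """Read a NONMEM-style event CSV into a validated :class:`PKDataset`.

    Dose rows (AMT > 0) become :class:`DoseEvent` with duration AMT/RATE;
    rows with MDV == 0 become :class:`Observation`. Observations below the
    limit of quantification are excluded with a logged warning when the
    dialect says so.
    """
    dialect = dialect or Dialect()
    fc, fa, ft, fw = dialect._factors()
    df = pd.read_csv(path, dtype={dialect.id_col: str}, float_precision="round_trip")

    required = [dialect.id_col, dialect.time_col, dialect.amt_col, dialect.dv_col]
    required += list(dialect.covariate_cols.values())
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    subjects: list[SubjectData] = []
    n_blq = 0
    for sid, grp in df.groupby(dialect.id_col, sort=False):
        doses: list[DoseEvent] = []
        obs: list[Observation] = []
        first = grp.iloc[0]
        cov_kwargs = {}
        for name, col in dialect.covariate_cols.items():
            val = float(first[col])
            if name in ("CW", "BW"):
                val *= fw
            cov_kwargs[name] = val
        cov = CovariateRecord(**cov_kwargs)
        for idx, row in grp.iterrows():
            t = float(row[dialect.time_col]) * ft
            if t < 0:
                raise DataValidationError(f"row {idx}: negative time {t}")
            amt = row[dialect.amt_col]
            if pd.notna(amt) and float(amt) != 0.0:
                amt = float(amt) * fa
                if amt < 0:
                    raise DataValidationError(f"row {idx}: negative dose amount {amt}")
                rate = float(row[dialect.rate_col]) * fa / ft
                if rate <= 0:
                    raise DataValidationError(f"row {idx}: nonpositive infusion rate")
                doses.append(DoseEvent(time=t, amount=amt, duration=amt / rate))
            else:
                mdv = int(row[dialect.mdv_col]) if dialect.mdv_col in grp.columns else 0
                if mdv == 0:
                    conc = float(row[dialect.dv_col]) * fc
                    if dialect.exclude_blq and conc < dialect.loq:
                        n_blq += 1
                        continue
                    obs.append(Observation(time=t, concentration=conc))
        subjects.append(SubjectData(id=str(sid), covariates=cov, doses=tuple(doses), observations=tuple(obs)))
    if n_blq:
        logger.warning(
            "excluded %d observation(s) below the limit of quantification (%.2g mg/L)",
            n_blq,
            dialect.loq,
        )
    data = PKDataset(tuple(subjects))
    findings = validate_dataset(data)
    if findings:
        raise DataValidationError(
            "dataset failed validation: " + "; ".join(str(f) for f in findings[:5])
        )
    return data


def write_dataset(data: PKDataset, path: str, dialect: Dialect | None = None) -> None:
    """Write a dataset as an event CSV readable by :func:`read_dataset`.

    One row per event, chronological within subject (dose before observation
    on ties so a re-read reconstructs the same event order).
    """
    dialect = dialect or Dialect()
    rows: list[dict] = []
    for s in data.subjects:
        events: list[tuple[float, int, dict]] = []
        for d in s.doses:
            events.append(
                (d.time, 0, {dialect.amt_col: d.amount, dialect.rate_col: d.rate,
                             dialect.dv_col: np.nan, dialect.mdv_col: 1})
            )
        for o in s.observations:
            events.append(
                (o.time, 1, {dialect.amt_col: 0.0, dialect.rate_col: 0.0,
                             dialect.dv_col: o.concentration, dialect.mdv_col: 0})
            )
        events.sort(key=lambda e: (e[0], e[1]))
        for t, _, payload in events:
            row = {dialect.id_col: s.id, dialect.time_col: t, **payload}
            for name, col in dialect.covariate_cols.items():
                row[col] = getattr(s.covariates, name)
            rows.append(row)
    cols = [dialect.id_col, dialect.time_col, dialect.amt_col, dialect.rate_col,
            dialect.dv_col, dialect.mdv_col] + list(dialect.covariate_cols.values())
    # %.17g guarantees bit-exact float round-trip through the text file
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class Finding:
    subject: str
    field: str
    message: str

    def __str__(self) -> str:
        return f"[{self.subject}] {self.field}: {self.message}"


def validate_dataset(data: PKDataset) -> list[Finding]:
    """Check all structural invariants; returns findings rather than raising.

    Pure: never mutates its input; a valid dataset yields an empty list.
    """
    findings: list[Finding] = []
    seen: set[str] = set()
    for s in data.subjects:
        if s.id in seen:
            findings.append(Finding(s.id, "id", "duplicate subject id"))
        seen.add(s.id)
        c = s.covariates
        if c.CW <= 0:
            findings.append(Finding(s.id, "CW", f"nonpositive current weight {c.CW}"))
        if c.BW <= 0:
            findings.append(Finding(s.id, "BW", f"nonpositive birth weight {c.BW}"))
        if c.PNA < 0:
            findings.append(Finding(s.id, "PNA", f"negative postnatal age {c.PNA}"))
        expected_pma = c.GA + c.PNA / 7.0
        if abs(c.PMA - expected_pma) > 1.0:
            findings.append(
                Finding(s.id, "PMA",
                        f"PMA {c.PMA:.2f} wk inconsistent with GA+PNA/7 = "
                        f"{expected_pma:.2f} wk (discrepancy {c.PMA - expected_pma:+.2f} wk)")
            )
        if not s.doses:
            findings.append(Finding(s.id, "doses", "subject has no dose events"))
        for i, d in enumerate(s.doses):
            if d.amount <= 0:
                findings.append(Finding(s.id, f"doses[{i}].amount", f"nonpositive amount {d.amount}"))
            if d.duration <= 0:
                findings.append(Finding(s.id, f"doses[{i}].duration", f"nonpositive duration {d.duration}"))
        for i, o in enumerate(s.observations):
            if o.time < 0:
                findings.append(Finding(s.id, f"observations[{i}].time", f"negative time {o.time}"))
            if o.concentration < 0:
                findings.append(
                    Finding(s.id, f"observations[{i}].concentration",
                            f"negative concentration {o.concentration}")
                )
        if s.doses and s.observations:
            if s.observations[0].time < s.doses[0].time:
                findings.append(
                    Finding(s.id, "observations", "observation precedes first dose")
                )
    return findings
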