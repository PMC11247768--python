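"""Cohort persistence and expected-vs-actual validation reports.

Cohorts are written as flat CSV (UTF-8, ISO 8601 dates, empty string for an
absent death date).  Reports compare the generated marginals — total count,
sex and race percentages, deceased count — against what the disease profile
and sampling frame imply, with pass/fail tolerances defaulting to three
binomial standard errors at the cohort's size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import ValidationError

from .demographics import DemographicsTable, strata
from .generator import Cohort, PatientRecord
from .profiles import AGE_GROUPS, RACE_LABELS, DiseaseProfile, age_to_group

__all__ = [
    "FIXED_COLUMNS",
    "SummaryReport",
    "ComparisonRow",
    "ReportError",
    "CohortParseError",
    "write_cohort",
    "read_cohort",
    "summarize",
    "compare_to_expected",
    "age_group_breakdown",
]

FIXED_COLUMNS = (
    "patient_id",
    "state",
    "zip",
    "sex",
    "race",
    "age_years",
    "date_of_birth",
    "date_of_diagnosis",
    "vital_status",
    "date_of_death",
)
_FLAG_COLUMN = "diagnosis_clamped"


class ReportError(ValueError):
    """Raised for inconsistent report requests (e.g. disease mismatch)."""


class CohortParseError(ValueError):
    """Raised when a cohort CSV cannot be parsed; names the offending line."""


def _records_of(cohort: Cohort | Sequence[PatientRecord]) -> Sequence[PatientRecord]:
    return cohort.records if isinstance(cohort, Cohort) else cohort


def write_cohort(cohort: Cohort | Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort to CSV with a fixed column layout.

    Columns: the ten record attributes, one column per clinical parameter,
    then the diagnosis-clamp flag.  The round trip through
    :func:`read_cohort` is lossless.
    """
    records = _records_of(cohort)
    clin_names: list[str] = []
    if isinstance(cohort, Cohort):
        clin_names = [p.name for p in cohort.disease.clinical_params]
    elif records:
        clin_names = list(records[0].clinical)
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "state": r.state_code,
            "zip": r.zip,
            "sex": r.sex,
            "race": r.race,
            "age_years": r.age_years,
            "date_of_birth": r.date_of_birth.isoformat(),
            "date_of_diagnosis": r.date_of_diagnosis.isoformat(),
            "vital_status": r.vital_status,
            "date_of_death": r.date_of_death.isoformat() if r.date_of_death else "",
        }
        for name in clin_names:
            row[name] = repr(r.clinical[name])
        row[_FLAG_COLUMN] = str(r.diagnosis_clamped).lower()
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(FIXED_COLUMNS) + clin_names + [_FLAG_COLUMN])
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV back into validated records."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(FIXED_COLUMNS) - set(df.columns)
    if missing:
        raise CohortParseError(f"{Path(path).name}: missing column(s) {sorted(missing)}")
    extra = [c for c in df.columns if c not in FIXED_COLUMNS and c != _FLAG_COLUMN]
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        r = dict(zip(df.columns, row))
        try:
            records.append(
                PatientRecord(
                    patient_id=r["patient_id"],
                    state_code=r["state"],
                    zip=r["zip"],
                    sex=r["sex"],
                    race=r["race"],
                    age_years=int(r["age_years"]),
                    date_of_birth=date.fromisoformat(r["date_of_birth"]),
                    date_of_diagnosis=date.fromisoformat(r["date_of_diagnosis"]),
                    vital_status=r["vital_status"],
                    date_of_death=(
                        date.fromisoformat(r["date_of_death"]) if r["date_of_death"] else None
                    ),
                    diagnosis_clamped=r.get(_FLAG_COLUMN, "false") == "true",
                    clinical={name: float(r[name]) for name in extra},
                )
            )
        except (ValueError, ValidationError) as exc:
            msg = exc.errors()[0]["msg"] if isinstance(exc, ValidationError) else str(exc)
            raise CohortParseError(f"{Path(path).name}: line {lineno}: {msg}") from exc
    return records


@dataclass(frozen=True)
class SummaryReport:
    """Marginal counts and age-group breakdown of one cohort."""

    disease: str
    n_total: int
    n_male: int
    n_female: int
    n_deceased: int
    race_percent: dict[str, float]
    female_percent: float
    by_age_group: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "disease": self.disease,
            "n_total": self.n_total,
            "n_male": self.n_male,
            "n_female": self.n_female,
            "n_deceased": self.n_deceased,
            "female_percent": round(self.female_percent, 2),
            "race_percent": {k: round(v, 2) for k, v in self.race_percent.items()},
            "by_age_group": self.by_age_group,
        }


@dataclass(frozen=True)
class ComparisonRow:
    """One expected-vs-actual check with its tolerance."""

    metric: str
    result: float
    expected: float
    tolerance: float
    abs_diff: float = field(init=False)
    passed: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "abs_diff", abs(self.result - self.expected))
        object.__setattr__(self, "passed", self.abs_diff <= self.tolerance)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "result": self.result,
            "expected": self.expected,
            "abs_diff": self.abs_diff,
            "tolerance": self.tolerance,
            "pass": self.passed,
        }


def age_group_breakdown(
    cohort: Cohort | Sequence[PatientRecord], table: DemographicsTable
) -> list[dict]:
    """Per age group: frame population, patient count, deceased count.

    Deceased patients are binned by their age at death, matching the stratum
    they were drawn from.
    """
    records = _records_of(cohort)
    pop = {g.label: 0 for g in AGE_GROUPS}
    for s in strata(table):
        pop[s.age_group.label] += s.population
    patients = {g.label: 0 for g in AGE_GROUPS}
    deceased = {g.label: 0 for g in AGE_GROUPS}
    for r in records:
        label = age_to_group(r.age_years).label
        patients[label] += 1
        if r.vital_status == "deceased":
            deceased[label] += 1
    return [
        {
            "age_group": g.label,
            "population": pop[g.label],
            "patients": patients[g.label],
            "deceased": deceased[g.label],
        }
        for g in AGE_GROUPS
    ]


def summarize(
    cohort: Cohort | Sequence[PatientRecord],
    table: DemographicsTable,
    disease: str | None = None,
) -> SummaryReport:
    """Exact marginal counts of a cohort plus its age-group breakdown.

    Percentages are stored at full precision; rounding to two decimals is
    applied only in :meth:`SummaryReport.to_dict` for display.
    """
    records = _records_of(cohort)
    if disease is None:
        disease = cohort.disease.name if isinstance(cohort, Cohort) else ""
    n = len(records)
    n_male = sum(1 for r in records if r.sex == "male")
    n_dec = sum(1 for r in records if r.vital_status == "deceased")
    race_counts = {label: 0 for label in RACE_LABELS}
    for r in records:
        race_counts[r.race] += 1
    race_percent = {k: (100.0 * v / n if n else 0.0) for k, v in race_counts.items()}
    breakdown = {
        row["age_group"]: {
            "population": row["population"],
            "patients": row["patients"],
            "deceased": row["deceased"],
        }
        for row in age_group_breakdown(records, table)
    }
    return SummaryReport(
        disease=disease,
        n_total=n,
        n_male=n_male,
        n_female=n - n_male,
        n_deceased=n_dec,
        race_percent=race_percent,
        female_percent=(100.0 * (n - n_male) / n if n else 0.0),
        by_age_group=breakdown,
    )


def _binomial_percent_tol(p: float, n: int, z: float = 3.0) -> float:
    if n <= 0:
        return float("inf")
    return z * 100.0 * math.sqrt(max(p * (1.0 - p), 0.0) / n)


def compare_to_expected(
    report: SummaryReport,
    profile: DiseaseProfile,
    table: DemographicsTable,
    z: float = 3.0,
) -> list[ComparisonRow]:
    """Expected-vs-actual rows for the cohort marginals.

    Expected totals come from the stratum populations and the profile's
    prevalence; expected percentages are the profile's distributions (the
    blend-1 marginals).  Default tolerances are ``z`` = 3 binomial standard
    errors — the published fidelity claim is "no significant differences"
    without a named test, so a 3-sigma band stands in.
    """
    if report.disease and report.disease != profile.name:
        raise ReportError(
            f"report is for {report.disease!r} but profile is {profile.name!r}"
        )
    denom = profile.prevalence_denominator
    frame = strata(table)
    expected_total = sum(
        int(math.floor(s.population / denom + 0.5)) for s in frame
    )
    n = report.n_total
    rows = [
        ComparisonRow(
            metric="total_patients",
            result=float(n),
            expected=float(expected_total),
            tolerance=z * math.sqrt(max(expected_total, 1.0)),
        )
    ]
    p_female = profile.sex_dist.prob("female")
    rows.append(
        ComparisonRow(
            metric="female_percent",
            result=report.female_percent,
            expected=100.0 * p_female,
            tolerance=_binomial_percent_tol(p_female, n, z),
        )
    )
    for label in RACE_LABELS:
        p = profile.race_dist.prob(label)
        rows.append(
            ComparisonRow(
                metric=f"race_percent[{label}]",
                result=report.race_percent[label],
                expected=100.0 * p,
                tolerance=_binomial_percent_tol(p, n, z),
            )
        )
    # expected deceased: per-group expectation x per-patient death probability.
    # Marginally each frame member is a deceased patient with probability
    # r/denom, so the count is Binomial(pop, r/denom) with variance ~ E[dead].
    exp_dead = 0.0
    var_dead = 0.0
    for s in frame:
        e_patients = s.population / denom
        r = profile.death_rates.rate(s.age_group) / 100_000.0
        exp_dead += e_patients * r
        var_dead += e_patients * r * (1.0 - r / denom)
    rows.append(
        ComparisonRow(
            metric="deceased_patients",
            result=float(report.n_deceased),
            expected=exp_dead,
            tolerance=z * math.sqrt(max(var_dead, 1.0)),
        )
    )
    return rows
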