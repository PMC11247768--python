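"""Hierarchical cohort generation.

Records are generated stratum by stratum: for every (state, age-group) cell
of the sampling frame a patient count is drawn from the disease prevalence
(Binomial(population, 1/N) by default), and each patient is then built
through the chain ZIP -> sex -> age -> race -> clinical values -> vital
status -> dates.  Sex and race are drawn from a mixture of the
disease-specific distribution and the state's census split, controlled by a
blend weight in [0, 1] (1 = pure disease distribution, the default, since
the disease-level ratios dominate the published cohort marginals).

Clinical values and diagnosis lags come from normal distributions truncated
to their published [low, high] ranges.  Mortality is applied as a per-patient
Bernoulli with probability ``rate_per_100k / 100000`` for the patient's age
group.  All randomness flows from one root seed through per-stratum child
streams derived from (seed, state code, age group), so results do not depend
on incidental iteration order and are bit-reproducible.
"""

from __future__ import annotations

import math
from datetime import date, timedelta
from functools import lru_cache
from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .demographics import DemographicsTable, StateDemographics, Stratum, strata
from .profiles import (
    AGE_GROUPS,
    RACE_LABELS,
    SEX_LABELS,
    AgeGroup,
    CategoricalDistribution,
    ClinicalParameterSpec,
    DeathRateTable,
    DiagnosisOffsetSpec,
    DiseaseProfile,
    RangeDistribution,
    group_index,
)

__all__ = [
    "DAYS_PER_UNIT",
    "GenerationSettings",
    "PatientRecord",
    "Cohort",
    "GenerationError",
    "stratum_rng",
    "truncated_normal",
    "draw_stratum_count",
    "apportion_counts",
    "sample_sex",
    "sample_race",
    "sample_age",
    "sample_clinical",
    "sample_diagnosis_offset",
    "assign_vital_status",
    "birth_date_for",
    "diagnosis_date_for",
    "death_date_for",
    "generate_cohort",
]

# fixed calendar conversions for diagnosis offsets
DAYS_PER_UNIT = {"days": 1.0, "months": 30.44, "years": 365.25}

_ONE_DAY = timedelta(days=1)


class GenerationError(ValueError):
    """Raised for invalid generation arguments or impossible date constraints."""


class GenerationSettings(BaseModel):
    """Reproducibility and sampling knobs for one generation run."""

    model_config = ConfigDict(frozen=True)

    seed: int
    reference_date: date = date(2023, 1, 1)
    count_mode: Literal["binomial", "rounded-expectation"] = "binomial"
    race_blend: float = Field(default=1.0, ge=0.0, le=1.0)
    sex_blend: float = Field(default=1.0, ge=0.0, le=1.0)


class PatientRecord(BaseModel):
    """One synthetic patient.

    ``age_years`` is the age at the reference date for living patients and
    the age at death for deceased ones.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    state_code: str
    zip: str
    sex: Literal["male", "female"]
    race: Literal["African-American", "European-American", "Others"]
    age_years: int = Field(ge=0)
    date_of_birth: date
    date_of_diagnosis: date
    vital_status: Literal["alive", "deceased"]
    date_of_death: date | None = None
    diagnosis_clamped: bool = False
    clinical: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "PatientRecord":
        if (self.vital_status == "deceased") != (self.date_of_death is not None):
            raise ValueError("deceased status and presence of death date must agree")
        if self.date_of_birth > self.date_of_diagnosis:
            raise ValueError("diagnosis cannot precede birth")
        if self.date_of_death is not None and self.date_of_diagnosis > self.date_of_death:
            raise ValueError("diagnosis cannot follow death")
        return self


class Cohort(BaseModel):
    """A generated dataset together with the settings that produced it."""

    model_config = ConfigDict(frozen=True)

    disease: DiseaseProfile
    settings: GenerationSettings
    records: tuple[PatientRecord, ...]
    stratum_counts: dict[str, int] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "Cohort":
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids must be unique")
        if self.stratum_counts and sum(self.stratum_counts.values()) != len(self.records):
            raise ValueError("record count must equal the sum of stratum counts")
        return self


def stratum_rng(seed: int, state_code: str, group: AgeGroup | str | int) -> np.random.Generator:
    """Child RNG stream for one (state, age-group) stratum.

    Derived deterministically from the root seed so that per-state iteration
    order cannot change results.
    """
    gi = group if isinstance(group, int) else group_index(group)
    key = int.from_bytes(state_code.encode("ascii"), "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(gi)]))


# ---------------------------------------------------------------------------
# Elementary samplers

def truncated_normal(
    dist: RangeDistribution, rng: np.random.Generator, size: int | None = None
):
    """Draw from Normal(mu, spread) truncated to [low, high].

    ``spread == 0`` degenerates to the point mass at ``mu``.  Returns a float
    when ``size`` is None, else an ndarray of that length.
    """
    if dist.spread == 0:
        return dist.mu if size is None else np.full(size, dist.mu)
    a = (dist.low - dist.mu) / dist.spread
    b = (dist.high - dist.mu) / dist.spread
    out = stats.truncnorm.rvs(a, b, loc=dist.mu, scale=dist.spread, size=size, random_state=rng)
    return float(out) if size is None else out


def sample_clinical(
    spec: ClinicalParameterSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw clinical parameter value(s); always within the spec's [low, high]."""
    return truncated_normal(spec.dist, rng, size)


def sample_diagnosis_offset(
    spec: DiagnosisOffsetSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw diagnosis lag(s) after birth, in the spec's own unit."""
    return truncated_normal(spec.dist, rng, size)


def draw_stratum_count(
    population: int,
    prevalence_denominator: int,
    mode: str,
    rng: np.random.Generator | None = None,
) -> int:
    """Number of patients in a stratum of the given population.

    ``binomial`` draws Binomial(population, 1/denominator); the
    ``rounded-expectation`` mode returns round(population/denominator)
    (half away from zero) and uses no randomness.
    """
    if population < 0:
        raise GenerationError(f"population must be nonnegative, got {population}")
    if population == 0:
        return 0
    if mode == "binomial":
        if rng is None:
            raise GenerationError("binomial mode requires an rng")
        return int(rng.binomial(population, 1.0 / prevalence_denominator))
    if mode == "rounded-expectation":
        return int(math.floor(population / prevalence_denominator + 0.5))
    raise GenerationError(f"unknown count mode {mode!r}")


def apportion_counts(populations: Sequence[int], prevalence_denominator: int) -> list[int]:
    """Split round(total/denominator) patients over strata by largest remainder.

    Independent per-stratum rounding would lose all patients on small frames
    (every cell rounding to zero); apportionment keeps the cohort total equal
    to the rounded total expectation while staying proportional per stratum.
    """
    exact = [p / prevalence_denominator for p in populations]
    total = int(math.floor(sum(exact) + 0.5))
    base = [int(math.floor(e)) for e in exact]
    leftover = total - sum(base)
    order = sorted(range(len(exact)), key=lambda i: (base[i] - exact[i], i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def _mixture_probs(
    profile_dist: CategoricalDistribution,
    state_dist: CategoricalDistribution,
    blend: float,
    labels: Sequence[str],
) -> np.ndarray:
    if not (0.0 <= blend <= 1.0):
        raise GenerationError(f"blend weight must lie in [0, 1], got {blend}")
    p = np.array([blend * profile_dist.prob(l) + (1.0 - blend) * state_dist.prob(l) for l in labels])
    return p / p.sum()


def _sample_categorical(labels, probs, rng, size):
    idx = rng.choice(len(labels), size=size, p=probs)
    if size is None:
        return labels[int(idx)]
    return np.asarray(labels, dtype=object)[idx]


def sample_sex(
    profile_dist: CategoricalDistribution,
    state_dist: CategoricalDistribution,
    blend: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw sex from blend*disease + (1-blend)*census-state mixture."""
    return _sample_categorical(SEX_LABELS, _mixture_probs(profile_dist, state_dist, blend, SEX_LABELS), rng, size)


def sample_race(
    profile_dist: CategoricalDistribution,
    state_dist: CategoricalDistribution,
    blend: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw race from blend*disease + (1-blend)*census-state mixture."""
    return _sample_categorical(RACE_LABELS, _mixture_probs(profile_dist, state_dist, blend, RACE_LABELS), rng, size)


def _group_age_bins(
    group: AgeGroup, pop_by_age: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate single ages and weights for a group; -1 encodes the 85+ pool."""
    if group.upper is None:
        ages = list(range(group.lower, 85)) + [-1]
        keys = [str(a) for a in range(group.lower, 85)] + ["85+"]
    else:
        ages = list(range(group.lower, group.upper + 1))
        keys = [str(a) for a in ages]
    weights = np.array([pop_by_age.get(k, 0) for k in keys], dtype=float)
    return np.array(ages), weights


def sample_age(
    group: AgeGroup,
    pop_by_age: Mapping[str, int],
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw single-year age(s) within a group, weighted by state population.

    The ``85+`` census pool belongs to the ``>60`` group; when it is drawn,
    an age is picked uniformly from 85-99 (the census table gives no upper
    bound).
    """
    ages, weights = _group_age_bins(group, pop_by_age)
    total = weights.sum()
    if total <= 0:
        raise GenerationError(f"age group {group.label!r} has no population")
    idx = rng.choice(len(ages), size=size, p=weights / total)
    drawn = ages[idx]
    if size is None:
        return int(drawn) if drawn != -1 else int(rng.integers(85, 100))
    drawn = np.asarray(drawn).copy()
    mask = drawn == -1
    if mask.any():
        drawn[mask] = rng.integers(85, 100, size=int(mask.sum()))
    return drawn


def assign_vital_status(
    group: AgeGroup | str,
    death_rates: DeathRateTable,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Assign alive/deceased with probability rate_per_100k / 100000."""
    p = death_rates.rate(group) / 100_000.0
    if size is None:
        return "deceased" if rng.random() < p else "alive"
    return np.where(rng.random(size) < p, "deceased", "alive")


# ---------------------------------------------------------------------------
# Dates

def _floor_age(dob: date, on: date) -> int:
    """Completed years between dob and a later date (anniversary counts)."""
    return on.year - dob.year - ((on.month, on.day) < (dob.month, dob.day))


def _shift_years(d: date, years: int) -> date:
    try:
        return d.replace(year=d.year + years)
    except ValueError:  # Feb 29 in a non-leap target year
        return date(d.year + years, 3, 1) if years > 0 else date(d.year + years, 2, 28)


@lru_cache(maxsize=4096)
def _birth_window(age: int, reference_date: date) -> tuple[int, int]:
    """Ordinal range [lo, hi] of birth dates giving floor-age == age at reference."""
    hi = _shift_years(reference_date, -age)
    while _floor_age(hi, reference_date) > age:
        hi -= _ONE_DAY
    while _floor_age(hi + _ONE_DAY, reference_date) == age:
        hi += _ONE_DAY
    lo = _shift_years(reference_date, -(age + 1)) + _ONE_DAY
    while _floor_age(lo, reference_date) < age:
        lo += _ONE_DAY
    while _floor_age(lo - _ONE_DAY, reference_date) == age:
        lo -= _ONE_DAY
    return lo.toordinal(), hi.toordinal()


def birth_date_for(age_years: int, reference_date: date, rng: np.random.Generator) -> date:
    """Uniform birth date such that floor-age at the reference date equals ``age_years``."""
    if age_years < 0:
        raise GenerationError(f"age must be nonnegative, got {age_years}")
    lo, hi = _birth_window(int(age_years), reference_date)
    return date.fromordinal(int(rng.integers(lo, hi + 1)))


def _death_window(dob: date, age_at_death: int, reference_date: date) -> tuple[int, int]:
    lo = _shift_years(dob, age_at_death)
    while _floor_age(dob, lo) < age_at_death:
        lo += _ONE_DAY
    while lo - _ONE_DAY >= dob and _floor_age(dob, lo - _ONE_DAY) == age_at_death:
        lo -= _ONE_DAY
    hi = _shift_years(dob, age_at_death + 1)
    while _floor_age(dob, hi) > age_at_death:
        hi -= _ONE_DAY
    hi = min(hi, reference_date)
    if hi < lo:
        raise GenerationError(
            f"no death date with age {age_at_death} for birth {dob} on or before {reference_date}"
        )
    return lo.toordinal(), hi.toordinal()


def death_date_for(
    date_of_birth: date,
    age_at_death: int,
    reference_date: date,
    rng: np.random.Generator,
) -> date:
    """Uniform death date with floor-age == ``age_at_death``, not after the reference date."""
    if age_at_death < 0:
        raise GenerationError(f"age at death must be nonnegative, got {age_at_death}")
    lo, hi = _death_window(date_of_birth, int(age_at_death), reference_date)
    return date.fromordinal(int(rng.integers(lo, hi + 1)))


def diagnosis_date_for(
    date_of_birth: date,
    spec: DiagnosisOffsetSpec,
    reference_date: date,
    rng: np.random.Generator,
    date_of_death: date | None = None,
) -> tuple[date, bool]:
    """Diagnosis date = birth + drawn offset, clamped into the record's lifespan.

    Returns ``(date, clamped)``; ``clamped`` is True when the drawn offset
    would place the diagnosis after the reference date (or after death) and
    the date was pulled back accordingly.
    """
    offset = truncated_normal(spec.dist, rng)
    days = int(round(offset * DAYS_PER_UNIT[spec.unit]))
    cap = reference_date if date_of_death is None else min(reference_date, date_of_death)
    if cap < date_of_birth:
        raise GenerationError("reference/death date precedes birth; no valid diagnosis date")
    raw = date_of_birth + timedelta(days=days)
    clamped = raw > cap
    return (max(min(raw, cap), date_of_birth), clamped)


# ---------------------------------------------------------------------------
# Cohort assembly

def generate_cohort(
    profile: DiseaseProfile,
    table: DemographicsTable,
    settings: GenerationSettings,
) -> Cohort:
    """Generate a full cohort over every stratum of the sampling frame.

    Deterministic for identical (profile, table, settings): each stratum uses
    its own child RNG stream, whose first draw is the stratum count in
    binomial mode.
    """
    denom = profile.prevalence_denominator
    ref = settings.reference_date
    all_strata = strata(table)
    if settings.count_mode == "rounded-expectation":
        planned = apportion_counts([s.population for s in all_strata], denom)
    else:
        planned = [0] * len(all_strata)  # drawn per stratum below

    states = {s.state_code: s for s in table.states}
    records: list[PatientRecord] = []
    stratum_counts: dict[str, int] = {}
    code = profile.code
    seq = 1

    for si, stratum in enumerate(all_strata):
        state = states[stratum.state_code]
        gi = group_index(stratum.age_group)
        rng = stratum_rng(settings.seed, stratum.state_code, gi)
        if settings.count_mode == "binomial":
            n = draw_stratum_count(stratum.population, denom, "binomial", rng)
        else:
            n = planned[si]
        stratum_counts[f"{stratum.state_code}:{stratum.age_group.label}"] = n
        if n == 0:
            continue

        zip_idx = rng.integers(0, len(state.zip_codes), size=n)
        sexes = sample_sex(profile.sex_dist, state.sex_split, settings.sex_blend, rng, size=n)
        ages = sample_age(stratum.age_group, state.pop_by_age, rng, size=n)
        races = sample_race(profile.race_dist, state.race_split, settings.race_blend, rng, size=n)
        clinical = {
            p.name: np.atleast_1d(sample_clinical(p, rng, size=n)) for p in profile.clinical_params
        }
        dead = np.asarray(assign_vital_status(stratum.age_group, profile.death_rates, rng, size=n)) == "deceased"
        u_birth = rng.random(n)
        u_death = rng.random(n)
        offsets = np.atleast_1d(sample_diagnosis_offset(profile.diagnosis, rng, size=n))
        offset_days = np.rint(offsets * DAYS_PER_UNIT[profile.diagnosis.unit]).astype(int)

        for i in range(n):
            age = int(ages[i])
            lo, hi = _birth_window(age, ref)
            dob = date.fromordinal(lo + int(u_birth[i] * (hi - lo + 1)))
            death: date | None = None
            if dead[i]:
                dlo, dhi = _death_window(dob, age, ref)
                death = date.fromordinal(dlo + int(u_death[i] * (dhi - dlo + 1)))
            cap = ref if death is None else min(ref, death)
            raw_diag = dob + timedelta(days=int(offset_days[i]))
            diag = max(min(raw_diag, cap), dob)
            records.append(
                PatientRecord(
                    patient_id=f"{code}-{seq:07d}",
                    state_code=state.state_code,
                    zip=state.zip_codes[int(zip_idx[i])],
                    sex=str(sexes[i]),
                    race=str(races[i]),
                    age_years=age,
                    date_of_birth=dob,
                    date_of_diagnosis=diag,
                    vital_status="deceased" if dead[i] else "alive",
                    date_of_death=death,
                    diagnosis_clamped=bool(raw_diag > cap),
                    clinical={name: float(vals[i]) for name, vals in clinical.items()},
                )
            )
            seq += 1

    return Cohort(
        disease=profile,
        settings=settings,
        records=tuple(records),
        stratum_counts=stratum_counts,
    )
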