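"""Disease statistics profiles: the generative parameters for one rare disease.

A :class:`DiseaseProfile` bundles everything the cohort generator needs for a
single disease: prevalence (stored as a denominator, 1/N), race and sex
distributions, the initial-diagnosis lag distribution, per-age-group death
rates (per 100,000) and the clinical laboratory-parameter distributions.

Three curated profiles ship with the package — Sickle Cell Disease (SCD,
ORPHA 232), Cystic Fibrosis (CF, ORPHA 586) and Duchenne Muscular Dystrophy
(DMD, ORPHA 98896) — built from published US prevalence, demographic and
mortality statistics.  Profiles are plain JSON files so users can curate
their own diseases with the same schema.

Ages are harmonised into seven groups used throughout the package:
``<5, 5-14, 15-19, 20-24, 25-39, 40-60, >60`` (inclusive integer years,
``>60`` open-ended).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Any, Literal, Mapping

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

__all__ = [
    "RACE_LABELS",
    "SEX_LABELS",
    "AGE_GROUPS",
    "AGE_GROUP_LABELS",
    "AgeGroup",
    "CategoricalDistribution",
    "RangeDistribution",
    "DeathRateTable",
    "DiagnosisOffsetSpec",
    "ClinicalParameterSpec",
    "DiseaseProfile",
    "ProfileError",
    "InvalidDistributionError",
    "ProfileSchemaError",
    "ProfileNormalizationWarning",
    "normalize_categorical",
    "age_to_group",
    "group_index",
    "load_profile",
    "write_profile",
    "builtin_profiles",
]

RACE_LABELS = ("African-American", "European-American", "Others")
SEX_LABELS = ("male", "female")

# Tolerated deviation of a percent column from 100 before a warning is issued.
_PERCENT_SUM_TOL = 0.5


class ProfileError(ValueError):
    """Base class for profile-related errors."""


class InvalidDistributionError(ProfileError):
    """Raised when categorical weights cannot form a probability distribution."""


class ProfileSchemaError(ProfileError):
    """Raised when a profile file is missing fields or contains invalid values."""


class ProfileNormalizationWarning(UserWarning):
    """Issued when printed percentages deviate from a 100% total by more than 0.5."""


@dataclass(frozen=True)
class AgeGroup:
    """One of the seven harmonised age groups.

    ``upper`` is inclusive; ``None`` marks the open-ended ``>60`` group.
    """

    label: str
    lower: int
    upper: int | None

    def contains(self, age: int) -> bool:
        return age >= self.lower and (self.upper is None or age <= self.upper)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


AGE_GROUPS: tuple[AgeGroup, ...] = (
    AgeGroup("<5", 0, 4),
    AgeGroup("5-14", 5, 14),
    AgeGroup("15-19", 15, 19),
    AgeGroup("20-24", 20, 24),
    AgeGroup("25-39", 25, 39),
    AgeGroup("40-60", 40, 60),
    AgeGroup(">60", 61, None),
)
AGE_GROUP_LABELS: tuple[str, ...] = tuple(g.label for g in AGE_GROUPS)
_GROUP_BY_LABEL = {g.label: i for i, g in enumerate(AGE_GROUPS)}


def age_to_group(age: int) -> AgeGroup:
    """Map an integer age in years to its harmonised age group.

    Raises ``ProfileError`` for negative ages.  The seven groups partition
    0..inf, so every nonnegative age maps to exactly one group.
    """
    age = int(age)
    if age < 0:
        raise ProfileError(f"age must be nonnegative, got {age}")
    for group in AGE_GROUPS:
        if group.contains(age):
            return group
    raise AssertionError("unreachable: age groups partition 0..inf")


def group_index(group: AgeGroup | str) -> int:
    """Position of an age group (or its label) in the canonical group order."""
    label = group if isinstance(group, str) else group.label
    try:
        return _GROUP_BY_LABEL[label]
    except KeyError:
        raise ProfileError(f"unknown age-group label {label!r}") from None


class CategoricalDistribution(BaseModel):
    """A discrete probability distribution over named categories."""

    model_config = ConfigDict(frozen=True)

    labels: tuple[str, ...]
    probs: tuple[float, ...]

    @model_validator(mode="after")
    def _check(self) -> "CategoricalDistribution":
        if len(self.labels) != len(self.probs):
            raise ValueError("labels and probs must have the same length")
        if len(self.labels) == 0:
            raise ValueError("distribution must have at least one category")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate category labels")
        if any(p < 0 for p in self.probs):
            raise ValueError("probabilities must be nonnegative")
        total = sum(self.probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1 (got {total!r})")
        return self

    def prob(self, label: str) -> float:
        try:
            return self.probs[self.labels.index(label)]
        except ValueError:
            raise KeyError(label) from None

    def as_mapping(self) -> dict[str, float]:
        return dict(zip(self.labels, self.probs))


def normalize_categorical(weights: Mapping[str, float]) -> CategoricalDistribution:
    """Rescale nonnegative weights to a probability distribution.

    Published percentage columns do not always total exactly 100 (the CF sex
    column totals 101); proportional rescaling is the least-informative fix.

    Raises
    ------
    InvalidDistributionError
        If any weight is negative or all weights are zero.
    """
    if not weights:
        raise InvalidDistributionError("no categories given")
    labels = tuple(weights)
    vals = [float(weights[lab]) for lab in labels]
    if any(v < 0 for v in vals):
        raise InvalidDistributionError(f"negative weight in {dict(weights)!r}")
    total = math.fsum(vals)
    if total <= 0:
        raise InvalidDistributionError("all weights are zero")
    probs = [v / total for v in vals]
    # remove accumulated round-off so the invariant holds exactly
    probs[-1] = 1.0 - math.fsum(probs[:-1])
    return CategoricalDistribution(labels=labels, probs=tuple(probs))


class RangeDistribution(BaseModel):
    """A bounded location/scale spec: Normal(mu, spread) truncated to [low, high].

    ``spread`` is the scale parameter of the underlying normal; for every
    packaged profile the printed ``mu ± spread`` exactly or nearly spans
    ``[low, high]``, so the untruncated normal would escape the printed range.
    ``spread == 0`` denotes the degenerate point mass at ``mu``.
    """

    model_config = ConfigDict(frozen=True)

    low: float
    high: float
    mu: float
    spread: float = Field(ge=0)
    unit: str = ""

    @model_validator(mode="after")
    def _check(self) -> "RangeDistribution":
        if not (self.low <= self.mu <= self.high):
            raise ValueError(f"need low <= mu <= high, got {self.low}, {self.mu}, {self.high}")
        return self

    @property
    def width(self) -> float:
        return self.high - self.low


class DeathRateTable(BaseModel):
    """Death rate per 100,000 for each of the seven age groups."""

    model_config = ConfigDict(frozen=True)

    rate_per_100k: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "DeathRateTable":
        missing = set(AGE_GROUP_LABELS) - set(self.rate_per_100k)
        unknown = set(self.rate_per_100k) - set(AGE_GROUP_LABELS)
        if unknown:
            raise ValueError(f"unknown age-group label(s): {sorted(unknown)}")
        if missing:
            raise ValueError(f"missing age group(s): {sorted(missing)}")
        for label, rate in self.rate_per_100k.items():
            if not (0 <= rate <= 100_000):
                raise ValueError(f"death rate for {label!r} must lie in [0, 100000], got {rate}")
        return self

    def rate(self, group: AgeGroup | str) -> float:
        label = group if isinstance(group, str) else group.label
        return self.rate_per_100k[label]


class DiagnosisOffsetSpec(BaseModel):
    """Distribution of the lag between birth and initial diagnosis."""

    model_config = ConfigDict(frozen=True)

    unit: Literal["days", "months", "years"]
    dist: RangeDistribution


class ClinicalParameterSpec(BaseModel):
    """One clinical laboratory parameter and its value distribution."""

    model_config = ConfigDict(frozen=True)

    name: str = Field(min_length=1)
    dist: RangeDistribution


class DiseaseProfile(BaseModel):
    """All generative statistics for one rare disease."""

    model_config = ConfigDict(frozen=True)

    name: str = Field(min_length=1)
    orpha_code: str
    prevalence_denominator: int = Field(ge=1)
    race_dist: CategoricalDistribution
    sex_dist: CategoricalDistribution
    diagnosis: DiagnosisOffsetSpec
    death_rates: DeathRateTable
    clinical_params: tuple[ClinicalParameterSpec, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "DiseaseProfile":
        if set(self.race_dist.labels) != set(RACE_LABELS):
            raise ValueError(f"race distribution must cover {RACE_LABELS}")
        if set(self.sex_dist.labels) != set(SEX_LABELS):
            raise ValueError(f"sex distribution must cover {SEX_LABELS}")
        names = [p.name for p in self.clinical_params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate clinical parameter names")
        return self

    @property
    def prevalence(self) -> float:
        """Disease prevalence as a fraction (1 / prevalence_denominator)."""
        return 1.0 / self.prevalence_denominator

    @property
    def code(self) -> str:
        """Short disease code: the initials of the name (e.g. 'SCD')."""
        return "".join(w[0] for w in self.name.split()).upper()


def _require(data: Mapping[str, Any], key: str, source: str) -> Any:
    if key not in data:
        raise ProfileSchemaError(f"{source}: missing field {key!r}")
    return data[key]


def _percent_dist(raw: Mapping[str, float], field: str, source: str) -> CategoricalDistribution:
    total = math.fsum(float(v) for v in raw.values())
    if abs(total - 100.0) > _PERCENT_SUM_TOL:
        warnings.warn(
            f"{source}: {field} percentages sum to {total:g}, not 100; "
            "rescaling proportionally",
            ProfileNormalizationWarning,
            stacklevel=3,
        )
    try:
        return normalize_categorical(raw)
    except InvalidDistributionError as exc:
        raise ProfileSchemaError(f"{source}: {field}: {exc}") from exc


def _range_dist(raw: Mapping[str, Any], field: str, source: str) -> RangeDistribution:
    try:
        return RangeDistribution(
            low=_require(raw, "low", f"{source}: {field}"),
            high=_require(raw, "high", f"{source}: {field}"),
            mu=_require(raw, "mu", f"{source}: {field}"),
            spread=_require(raw, "spread", f"{source}: {field}"),
            unit=str(raw.get("unit", "")),
        )
    except ValidationError as exc:
        raise ProfileSchemaError(f"{source}: {field}: {exc.errors()[0]['msg']}") from exc


def profile_from_mapping(data: Mapping[str, Any], source: str = "<profile>") -> DiseaseProfile:
    """Build a validated :class:`DiseaseProfile` from a parsed JSON mapping."""
    race = _percent_dist(_require(data, "race_percent", source), "race_percent", source)
    sex = _percent_dist(_require(data, "sex_percent", source), "sex_percent", source)
    diag_raw = _require(data, "diagnosis", source)
    unit = _require(diag_raw, "unit", f"{source}: diagnosis")
    try:
        diagnosis = DiagnosisOffsetSpec(unit=unit, dist=_range_dist(diag_raw, "diagnosis", source))
    except ValidationError as exc:
        raise ProfileSchemaError(f"{source}: diagnosis: {exc.errors()[0]['msg']}") from exc
    try:
        death = DeathRateTable(rate_per_100k=_require(data, "death_rate_per_100k", source))
    except ValidationError as exc:
        raise ProfileSchemaError(f"{source}: death_rate_per_100k: {exc.errors()[0]['msg']}") from exc
    params = []
    for i, p in enumerate(data.get("clinical_params", [])):
        pname = _require(p, "name", f"{source}: clinical_params[{i}]")
        params.append(
            ClinicalParameterSpec(name=pname, dist=_range_dist(p, f"clinical_params[{i}]", source))
        )
    try:
        return DiseaseProfile(
            name=_require(data, "name", source),
            orpha_code=str(_require(data, "orpha_code", source)),
            prevalence_denominator=_require(data, "prevalence_denominator", source),
            race_dist=race,
            sex_dist=sex,
            diagnosis=diagnosis,
            death_rates=death,
            clinical_params=tuple(params),
        )
    except ValidationError as exc:
        err = exc.errors()[0]
        loc = ".".join(str(x) for x in err["loc"])
        raise ProfileSchemaError(f"{source}: {loc}: {err['msg']}") from exc


def load_profile(path: str | Path) -> DiseaseProfile:
    """Load and validate a disease profile from a JSON file.

    Percent columns are rescaled to probabilities; a
    :class:`ProfileNormalizationWarning` is recorded when a column's total
    deviates from 100 by more than 0.5.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ProfileSchemaError(f"{path.name}: not valid JSON: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ProfileSchemaError(f"{path.name}: top level must be a JSON object")
    return profile_from_mapping(data, source=path.name)


def profile_to_mapping(profile: DiseaseProfile) -> dict[str, Any]:
    """Inverse of :func:`profile_from_mapping` (percent scale, plain types)."""

    def _rd(dist: RangeDistribution) -> dict[str, Any]:
        return {
            "unit": dist.unit,
            "low": dist.low,
            "high": dist.high,
            "mu": dist.mu,
            "spread": dist.spread,
        }

    return {
        "name": profile.name,
        "orpha_code": profile.orpha_code,
        "prevalence_denominator": profile.prevalence_denominator,
        "race_percent": {l: p * 100.0 for l, p in profile.race_dist.as_mapping().items()},
        "sex_percent": {l: p * 100.0 for l, p in profile.sex_dist.as_mapping().items()},
        "diagnosis": _rd(profile.diagnosis.dist) | {"unit": profile.diagnosis.unit},
        "death_rate_per_100k": dict(profile.death_rates.rate_per_100k),
        "clinical_params": [{"name": p.name, **_rd(p.dist)} for p in profile.clinical_params],
    }


def write_profile(profile: DiseaseProfile, path: str | Path) -> None:
    """Serialise a profile back to the JSON schema read by :func:`load_profile`."""
    Path(path).write_text(
        json.dumps(profile_to_mapping(profile), indent=2) + "\n", encoding="utf-8"
    )


_BUILTIN_FILES = {"SCD": "scd.json", "CF": "cf.json", "DMD": "dmd.json"}


@lru_cache(maxsize=1)
def _builtin_cache() -> tuple[tuple[str, DiseaseProfile], ...]:
    out = []
    pkg = resources.files("rarecohort").joinpath("data")
    for code, fname in _BUILTIN_FILES.items():
        data = json.loads(pkg.joinpath(fname).read_text(encoding="utf-8"))
        out.append((code, profile_from_mapping(data, source=fname)))
    return tuple(out)


def builtin_profiles() -> dict[str, DiseaseProfile]:
    """The three packaged disease profiles, keyed by code (SCD, CF, DMD)."""
    return dict(_builtin_cache())
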