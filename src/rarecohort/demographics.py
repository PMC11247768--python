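"""Population sampling frame: state x age x sex x race structure plus ZIP codes.

The generator draws patients from per-state populations resolved to single
years of age (0..84, with everyone 85 and older pooled in an ``"85+"``
bucket, mirroring how US census age tables are published).  Sex and race
splits are held at state level.

Real census retrieval is out of scope; a table is either loaded from a JSON
file the user supplies or synthesised by :func:`make_toy_demographics`, a
seeded generator that emulates the grouped shape of the US age pyramid.
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .profiles import (
    AGE_GROUPS,
    RACE_LABELS,
    SEX_LABELS,
    AgeGroup,
    CategoricalDistribution,
    normalize_categorical,
)

__all__ = [
    "MAX_SINGLE_AGE",
    "OPEN_AGE_KEY",
    "StateDemographics",
    "DemographicsTable",
    "Stratum",
    "DemographicsError",
    "load_demographics",
    "write_demographics",
    "builtin_toy_demographics",
    "make_toy_demographics",
    "strata",
    "zip_for_state",
]

MAX_SINGLE_AGE = 84
OPEN_AGE_KEY = "85+"
_AGE_KEYS = tuple(str(a) for a in range(MAX_SINGLE_AGE + 1)) + (OPEN_AGE_KEY,)

# Grouped age-pyramid shares used by the toy generator, approximating the
# 2020 US population: <5, 5-14, 15-19, 20-24, 25-39, 40-60, >60.
DEFAULT_GROUP_SHARES: dict[str, float] = {
    "<5": 0.059,
    "5-14": 0.125,
    "15-19": 0.066,
    "20-24": 0.066,
    "25-39": 0.205,
    "40-60": 0.256,
    ">60": 0.223,
}


class DemographicsError(ValueError):
    """Raised for invalid demographics files or arguments."""


class StateDemographics(BaseModel):
    """Population structure of one state."""

    model_config = ConfigDict(frozen=True)

    state_code: str = Field(pattern=r"^[A-Z]{2}$")
    zip_codes: tuple[str, ...]
    pop_by_age: dict[str, int]
    sex_split: CategoricalDistribution
    race_split: CategoricalDistribution

    @model_validator(mode="before")
    @classmethod
    def _fill_ages(cls, data: Any) -> Any:
        # missing single-year entries are treated as zero population
        if isinstance(data, dict) and isinstance(data.get("pop_by_age"), Mapping):
            pba = {k: int(v) for k, v in data["pop_by_age"].items()}
            unknown = set(pba) - set(_AGE_KEYS)
            if unknown:
                raise ValueError(f"unknown age key(s): {sorted(unknown)}")
            data = dict(data)
            data["pop_by_age"] = {k: pba.get(k, 0) for k in _AGE_KEYS}
        return data

    @model_validator(mode="after")
    def _check(self) -> "StateDemographics":
        if not self.zip_codes:
            raise ValueError("state must have at least one ZIP code")
        if len(set(self.zip_codes)) != len(self.zip_codes):
            raise ValueError("ZIP codes must be unique within a state")
        for z in self.zip_codes:
            if len(z) != 5 or not z.isdigit():
                raise ValueError(f"ZIP codes must be 5-digit strings, got {z!r}")
        if any(v < 0 for v in self.pop_by_age.values()):
            raise ValueError("population counts must be nonnegative")
        if self.total_population <= 0:
            raise ValueError("total state population must be positive")
        if set(self.sex_split.labels) != set(SEX_LABELS):
            raise ValueError(f"sex split must cover {SEX_LABELS}")
        if set(self.race_split.labels) != set(RACE_LABELS):
            raise ValueError(f"race split must cover {RACE_LABELS}")
        return self

    @property
    def total_population(self) -> int:
        return sum(self.pop_by_age.values())

    def age_keys_in_group(self, group: AgeGroup) -> tuple[str, ...]:
        """Single-age keys belonging to a group; ``85+`` counts in ``>60``."""
        if group.upper is None:
            return tuple(str(a) for a in range(group.lower, MAX_SINGLE_AGE + 1)) + (OPEN_AGE_KEY,)
        return tuple(str(a) for a in range(group.lower, group.upper + 1))

    def pop_in_group(self, group: AgeGroup) -> int:
        return sum(self.pop_by_age[k] for k in self.age_keys_in_group(group))


class DemographicsTable(BaseModel):
    """A set of states forming the sampling frame for one reference year."""

    model_config = ConfigDict(frozen=True)

    states: tuple[StateDemographics, ...]
    reference_year: int = 2020

    @model_validator(mode="after")
    def _check(self) -> "DemographicsTable":
        if not self.states:
            raise ValueError("table must contain at least one state")
        codes = [s.state_code for s in self.states]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate state codes")
        return self

    @property
    def total_population(self) -> int:
        return sum(s.total_population for s in self.states)

    def state(self, code: str) -> StateDemographics:
        for s in self.states:
            if s.state_code == code:
                return s
        raise KeyError(code)


@dataclass(frozen=True)
class Stratum:
    """A (state, age-group) cell of the sampling frame."""

    state_code: str
    age_group: AgeGroup
    population: int


def strata(table: DemographicsTable) -> list[Stratum]:
    """All (state, age-group) strata in deterministic order.

    States are visited in sorted state-code order, groups in canonical age
    order; stratum populations within a state sum exactly to the state total.
    """
    out: list[Stratum] = []
    for state in sorted(table.states, key=lambda s: s.state_code):
        for group in AGE_GROUPS:
            out.append(Stratum(state.state_code, group, state.pop_in_group(group)))
    return out


def zip_for_state(state: StateDemographics, rng: np.random.Generator) -> str:
    """Draw a ZIP code uniformly from the state's list."""
    if not state.zip_codes:
        raise DemographicsError(f"state {state.state_code!r} has no ZIP codes configured")
    return state.zip_codes[int(rng.integers(len(state.zip_codes)))]


# ---------------------------------------------------------------------------
# JSON persistence

def _state_from_mapping(raw: Mapping[str, Any], source: str) -> StateDemographics:
    for key in ("state_code", "zip_codes", "pop_by_age", "sex_percent", "race_percent"):
        if key not in raw:
            raise DemographicsError(f"{source}: state entry missing field {key!r}")
    try:
        return StateDemographics(
            state_code=raw["state_code"],
            zip_codes=tuple(raw["zip_codes"]),
            pop_by_age=raw["pop_by_age"],
            sex_split=normalize_categorical(raw["sex_percent"]),
            race_split=normalize_categorical(raw["race_percent"]),
        )
    except (ValidationError, ValueError) as exc:
        msg = exc.errors()[0]["msg"] if isinstance(exc, ValidationError) else str(exc)
        raise DemographicsError(f"{source}: state {raw.get('state_code')!r}: {msg}") from exc


def load_demographics(path: str | Path) -> DemographicsTable:
    """Load a demographics table from JSON and validate all invariants."""
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DemographicsError(f"{path.name}: not valid JSON: {exc}") from exc
    if "states" not in data:
        raise DemographicsError(f"{path.name}: missing field 'states'")
    states = tuple(_state_from_mapping(s, path.name) for s in data["states"])
    try:
        return DemographicsTable(states=states, reference_year=int(data.get("reference_year", 2020)))
    except ValidationError as exc:
        raise DemographicsError(f"{path.name}: {exc.errors()[0]['msg']}") from exc


def write_demographics(table: DemographicsTable, path: str | Path) -> None:
    """Serialise a table to the JSON schema read by :func:`load_demographics`."""
    data = {
        "reference_year": table.reference_year,
        "states": [
            {
                "state_code": s.state_code,
                "zip_codes": list(s.zip_codes),
                "pop_by_age": dict(s.pop_by_age),
                "sex_percent": {l: p * 100.0 for l, p in s.sex_split.as_mapping().items()},
                "race_percent": {l: p * 100.0 for l, p in s.race_split.as_mapping().items()},
            }
            for s in table.states
        ],
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


def builtin_toy_demographics() -> DemographicsTable:
    """The small packaged sampling frame (3 synthetic states, 1.2M people).

    A convenience fixture for demos and tests; pass a real table to
    :func:`load_demographics` for production-scale runs.
    """
    from importlib import resources

    ref = resources.files("rarecohort").joinpath("data", "toy_demographics.json")
    data = json.loads(ref.read_text(encoding="utf-8"))
    states = tuple(_state_from_mapping(s, "toy_demographics.json") for s in data["states"])
    return DemographicsTable(states=states, reference_year=int(data["reference_year"]))


# ---------------------------------------------------------------------------
# Synthetic fixture generator

def _state_codes(n: int) -> Iterator[str]:
    return itertools.islice(
        ("".join(p) for p in itertools.product(string.ascii_uppercase, repeat=2)), n
    )


def _age_bin_probs(group_shares: Mapping[str, float]) -> np.ndarray:
    """Spread each group's share uniformly over its single-age bins."""
    probs = np.zeros(len(_AGE_KEYS))
    for group in AGE_GROUPS:
        if group.upper is None:
            keys = list(range(group.lower, MAX_SINGLE_AGE + 1)) + [MAX_SINGLE_AGE + 1]
        else:
            keys = list(range(group.lower, group.upper + 1))
        share = group_shares[group.label]
        for k in keys:
            probs[k] = share / len(keys)
    return probs / probs.sum()


def make_toy_demographics(
    n_states: int,
    total_population: int,
    seed: int,
    group_shares: Mapping[str, float] | None = None,
    reference_year: int = 2020,
) -> DemographicsTable:
    """Synthesise a seeded, census-like demographics table.

    The table is bit-reproducible for a fixed seed: populations across states
    sum exactly to ``total_population``, every state receives at least five
    unique ZIP codes, single-year ages follow ``group_shares`` (default: the
    grouped shape of the 2020 US age pyramid), sex splits sit near 50/50 and
    race splits vary around a plausible national mix.
    """
    if n_states < 1:
        raise DemographicsError(f"n_states must be >= 1, got {n_states}")
    if total_population < n_states:
        raise DemographicsError(
            f"total_population ({total_population}) must be >= n_states ({n_states})"
        )
    shares = dict(group_shares) if group_shares is not None else DEFAULT_GROUP_SHARES
    missing = {g.label for g in AGE_GROUPS} - set(shares)
    if missing:
        raise DemographicsError(f"group_shares missing {sorted(missing)}")

    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.full(n_states, 5.0))
    state_totals = rng.multinomial(total_population, weights)
    # every state must have a positive population
    for i in range(n_states):
        if state_totals[i] == 0:
            donor = int(np.argmax(state_totals))
            state_totals[i] += 1
            state_totals[donor] -= 1

    age_probs = _age_bin_probs(shares)
    states = []
    for i, code in enumerate(_state_codes(n_states)):
        counts = rng.multinomial(int(state_totals[i]), age_probs)
        pop_by_age = {k: int(c) for k, c in zip(_AGE_KEYS, counts)}
        n_zip = int(rng.integers(5, 10))
        zips = tuple(f"{i:03d}{j:02d}" for j in range(n_zip))
        male = float(rng.uniform(0.485, 0.515))
        race_w = rng.dirichlet(np.array([12.5, 61.5, 26.0]))
        states.append(
            StateDemographics(
                state_code=code,
                zip_codes=zips,
                pop_by_age=pop_by_age,
                sex_split=normalize_categorical({"male": male, "female": 1.0 - male}),
                race_split=normalize_categorical(dict(zip(RACE_LABELS, race_w.tolist()))),
            )
        )
    return DemographicsTable(states=tuple(states), reference_year=reference_year)
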