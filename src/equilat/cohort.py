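"""Domain types and I/O for race-start and focal-horse lead observations.

A *lead* is the gallop leading foreleg (left or right) chosen by a horse as
it breaks from the starting stalls.  Two table shapes are used throughout:

* race-start tables — one row per horse per race start, with covariates
  (course direction, stall position, age, sex, finish position); and
* focal-horse records — one row per horse carrying an ordered string of
  repeated lead observations (oldest first).

The package ships the published 44-horse repeated-measures table as an
embedded fixture (``load_focal_fixture``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Lead",
    "Sex",
    "RaceStartObservation",
    "FocalHorseRecord",
    "Cohort",
    "LeadSequenceError",
    "SchemaError",
    "IntegrityError",
    "parse_lead_sequence",
    "render_lead_sequence",
    "read_race_starts",
    "write_race_starts",
    "read_focal_records",
    "write_focal_records",
    "deduplicate_horses",
    "load_focal_fixture",
]

START_COLUMNS = (
    "race_id",
    "course_name",
    "direction",
    "horse_id",
    "lead",
    "stall_position",
    "age",
    "sex",
    "finish_position",
)
REQUIRED_START_COLUMNS = (
    "race_id",
    "direction",
    "horse_id",
    "lead",
    "stall_position",
    "age",
    "sex",
    "finish_position",
)


class LeadSequenceError(ValueError):
    """Raised for empty or malformed lead-observation strings."""


class SchemaError(ValueError):
    """Raised when a tabular source is missing required columns."""


class IntegrityError(ValueError):
    """Raised when a table violates a structural invariant (e.g. duplicate
    stall within a race)."""


class Lead(str, enum.Enum):
    """Gallop leading foreleg."""

    LEFT = "L"
    RIGHT = "R"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Sex(str, enum.Enum):
    MARE = "mare"
    GELDING = "gelding"
    STALLION = "stallion"

    @property
    def is_male(self) -> bool:
        """Geldings and stallions together form the study's "male" grouping."""
        return self is not Sex.MARE

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_SEX_ALIASES = {
    "m": Sex.MARE,
    "mare": Sex.MARE,
    "f": Sex.MARE,
    "female": Sex.MARE,
    "g": Sex.GELDING,
    "gelding": Sex.GELDING,
    "s": Sex.STALLION,
    "stallion": Sex.STALLION,
}

_DIRECTION_ALIASES = {
    "c": "C",
    "clockwise": "C",
    "ac": "AC",
    "anticlockwise": "AC",
    "anti-clockwise": "AC",
    "counterclockwise": "AC",
}


def _coerce_sex(value: object) -> Sex:
    key = str(value).strip().lower()
    try:
        return _SEX_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognised sex {value!r}") from None


def _coerce_direction(value: object) -> str:
    key = str(value).strip().lower()
    try:
        return _DIRECTION_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognised course direction {value!r}") from None


@dataclass(frozen=True)
class RaceStartObservation:
    """One horse's lead choice and covariates at a single race start."""

    race_id: str
    direction: str  # "C" (clockwise) or "AC" (anti-clockwise)
    horse_id: str
    lead: Lead
    stall_position: int  # 1 = nearest the inside rail
    age: int
    sex: Sex
    finish_position: int
    course_name: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("C", "AC"):
            raise ValueError(f"direction must be C or AC, got {self.direction!r}")
        if self.stall_position < 1:
            raise ValueError("stall_position must be >= 1")
        if not 2 <= self.age <= 13:
            raise ValueError(f"age {self.age} outside the study range [2, 13]")
        if self.finish_position < 1:
            raise ValueError("finish_position must be >= 1")

    @property
    def is_winner(self) -> bool:
        return self.finish_position == 1


@dataclass(frozen=True)
class FocalHorseRecord:
    """One horse's ordered repeated lead observations plus its sex."""

    horse_id: str
    sex: Sex
    sequence: tuple[Lead, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("focal record needs at least one observation")

    @property
    def n_right(self) -> int:
        return sum(1 for lead in self.sequence if lead is Lead.RIGHT)

    @property
    def n_left(self) -> int:
        return sum(1 for lead in self.sequence if lead is Lead.LEFT)


@dataclass(frozen=True)
class Cohort:
    """A collection of race-start observations with a provenance tag."""

    observations: tuple[RaceStartObservation, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)


def parse_lead_sequence(text: str) -> tuple[Lead, ...]:
    """Parse a string of L/R characters into an ordered lead tuple.

    Whitespace is ignored; letters are case-insensitive.  Any other character
    raises :class:`LeadSequenceError` naming its 1-based position among the
    non-whitespace characters.
    """
    if not isinstance(text, str):
        raise LeadSequenceError("lead sequence must be a string")
    chars = [c for c in text if not c.isspace()]
    if not chars:
        raise LeadSequenceError("empty sequence")
    leads = []
    for pos, c in enumerate(chars, start=1):
        upper = c.upper()
        if upper == "L":
            leads.append(Lead.LEFT)
        elif upper == "R":
            leads.append(Lead.RIGHT)
        else:
            raise LeadSequenceError(
                f"invalid lead symbol {c!r} at position {pos}"
            )
    return tuple(leads)


def render_lead_sequence(leads: Iterable[Lead]) -> str:
    """Inverse of :func:`parse_lead_sequence` on valid sequences."""
    return "".join(lead.value for lead in leads)


def read_race_starts(
    source,
    columns: Mapping[str, str] | None = None,
    lead_values: Mapping[str, str] | None = None,
    provenance: str = "",
) -> Cohort:
    """Read a race-start CSV into a typed :class:`Cohort`.

    Parameters
    ----------
    source:
        Path or open text stream with a header row.
    columns:
        Optional mapping from the file's column names to the canonical names
        (``race_id, direction, horse_id, lead, stall_position, age, sex,
        finish_position`` and optionally ``course_name``).
    lead_values:
        Optional mapping normalising lead codes (e.g. ``{"left": "L"}``)
        before parsing.

    Raises
    ------
    SchemaError
        If a required column is absent.
    IntegrityError
        If a (race_id, stall_position) pair repeats, or a race mixes course
        directions, or any row fails type coercion (all offending line
        numbers are reported together).
    """
    frame = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if columns:
        frame = frame.rename(columns=dict(columns))
    missing = [c for c in REQUIRED_START_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "course_name" not in frame.columns:
        frame["course_name"] = ""

    lead_map = {str(k).strip().lower(): v for k, v in (lead_values or {}).items()}
    observations: list[RaceStartObservation] = []
    problems: list[str] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            raw_lead = str(row["lead"]).strip()
            raw_lead = lead_map.get(raw_lead.lower(), raw_lead)
            (lead,) = parse_lead_sequence(raw_lead)
            observations.append(
                RaceStartObservation(
                    race_id=str(row["race_id"]).strip(),
                    course_name=str(row["course_name"] or "").strip(),
                    direction=_coerce_direction(row["direction"]),
                    horse_id=str(row["horse_id"]).strip(),
                    lead=lead,
                    stall_position=int(row["stall_position"]),
                    age=int(row["age"]),
                    sex=_coerce_sex(row["sex"]),
                    finish_position=int(row["finish_position"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise IntegrityError(
            "rows failed type coercion:\n  " + "\n  ".join(problems)
        )

    seen_stalls: set[tuple[str, int]] = set()
    race_direction: dict[str, str] = {}
    for obs in observations:
        key = (obs.race_id, obs.stall_position)
        if key in seen_stalls:
            raise IntegrityError(
                f"duplicate stall {obs.stall_position} in race {obs.race_id}"
            )
        seen_stalls.add(key)
        prior = race_direction.setdefault(obs.race_id, obs.direction)
        if prior != obs.direction:
            raise IntegrityError(
                f"race {obs.race_id} mixes course directions {prior}/{obs.direction}"
            )
    return Cohort(tuple(observations), provenance=provenance)


def write_race_starts(cohort: Cohort, path) -> None:
    """Write a cohort back to the canonical race-start CSV schema."""
    rows = [
        {
            "race_id": o.race_id,
            "course_name": o.course_name,
            "direction": o.direction,
            "horse_id": o.horse_id,
            "lead": o.lead.value,
            "stall_position": o.stall_position,
            "age": o.age,
            "sex": o.sex.value,
            "finish_position": o.finish_position,
        }
        for o in cohort
    ]
    pd.DataFrame(rows, columns=START_COLUMNS).to_csv(path, index=False)


def read_focal_records(source) -> list[FocalHorseRecord]:
    """Read a focal CSV (columns horse_id, sex, sequence)."""
    frame = pd.read_csv(source, dtype=str, skipinitialspace=True)
    missing = [c for c in ("horse_id", "sex", "sequence") if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return [
        FocalHorseRecord(
            horse_id=str(row.horse_id).strip(),
            sex=_coerce_sex(row.sex),
            sequence=parse_lead_sequence(str(row.sequence)),
        )
        for row in frame.itertuples()
    ]


def write_focal_records(records: Sequence[FocalHorseRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "horse_id": r.horse_id,
                "sex": r.sex.value,
                "sequence": render_lead_sequence(r.sequence),
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def deduplicate_horses(cohort: Cohort) -> Cohort:
    """Keep each horse's first observation (input order breaks ties).

    Idempotent; the output has exactly one observation per distinct horse_id.
    """
    seen: set[str] = set()
    kept = []
    for obs in cohort:
        if obs.horse_id not in seen:
            seen.add(obs.horse_id)
            kept.append(obs)
    return Cohort(tuple(kept), provenance=cohort.provenance)


def load_focal_fixture() -> list[FocalHorseRecord]:
    """The published 44-horse repeated-measures table.

    11 geldings (A-K), 22 mares (L-AG) and 11 stallions (AH-AR); sequence
    lengths range from 5 to 47 observations.
    """
    path = resources.files("equilat").joinpath("data/table2_focal.csv")
    with resources.as_file(path) as p:
        return read_focal_records(p)
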