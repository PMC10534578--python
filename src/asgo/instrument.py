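"""The ASGO and Barthel Index instruments: definitions, scoring, classification.

The ASGO (General Assessment of the Hospitalised Patient) is a checklist of
ten non-medical functions — mental status, movement/ambulation, circulation,
breathing, elimination/sphincter control, feeding, sleep/wake, sensory system,
self-care ability and prevailing mood — each described by up to seven ordered
modalities.  Every variable carries a weight reflecting its priority for
nursing support, and each modality's *ranking value* equals weight × level.
The raw score of an assessment is the sum of the selected ranking values
(minimum 10.0 when every variable sits at its first modality); the
functional-dependence (FD) index is raw score / 10 and maps onto four care
profiles (minimum / medium / high / maximum care required).  Four variables —
circulation, feeding, elimination/sphincter control and sensory system —
permit more than one modality per assessment.

The Barthel Index (BI) is the comparison standard: ten activities-of-daily-
living items scored on the classic 0/5/10/15 point lattice, totalling 0
(total dependence) to 100 (complete independence), dichotomised at 60.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping

__all__ = [
    "ValidationError",
    "ModalityDefinition",
    "VariableDefinition",
    "InstrumentDefinition",
    "AsgoAssessment",
    "AsgoResult",
    "BarthelAssessment",
    "DependenceStatus",
    "ASGO_VARIABLES",
    "BARTHEL_ITEMS",
    "BARTHEL_ALLOWED",
    "load_default_instrument",
    "score_asgo",
    "profile_category",
    "score_barthel",
    "dichotomize_barthel",
    "classify_asgo",
]


class ValidationError(ValueError):
    """An assessment or definition violates the instrument's contract."""


# Canonical variable order (column order of every item matrix downstream).
ASGO_VARIABLES: tuple[str, ...] = (
    "mental_status",
    "movement_ambulation",
    "circulation",
    "breathing",
    "elimination_sphincters",
    "feeding",
    "sleep_wake",
    "sensory_system",
    "self_care",
    "prevailing_mood",
)

EXPECTED_WEIGHTS: Mapping[str, float] = {
    "mental_status": 1.6,
    "movement_ambulation": 1.3,
    "circulation": 0.4,
    "breathing": 0.4,
    "elimination_sphincters": 1.2,
    "feeding": 0.6,
    "sleep_wake": 1.2,
    "sensory_system": 0.6,
    "self_care": 1.3,
    "prevailing_mood": 1.4,
}

MULTI_SELECT_VARIABLES = frozenset(
    {"circulation", "feeding", "elimination_sphincters", "sensory_system"}
)

# Barthel items with their allowed point sets (classic Mahoney–Barthel
# allocation: two 15-point items, six 10-point items, two 5-point items).
BARTHEL_ITEMS: tuple[str, ...] = (
    "feeding",
    "toilet_use",
    "bathing",
    "grooming",
    "dressing",
    "bowel_control",
    "bladder_control",
    "chair_transfer",
    "stair_climbing",
    "walking",
)

BARTHEL_ALLOWED: Mapping[str, tuple[int, ...]] = {
    "feeding": (0, 5, 10),
    "toilet_use": (0, 5, 10),
    "bathing": (0, 5),
    "grooming": (0, 5),
    "dressing": (0, 5, 10),
    "bowel_control": (0, 5, 10),
    "bladder_control": (0, 5, 10),
    "chair_transfer": (0, 5, 10, 15),
    "stair_climbing": (0, 5, 10),
    "walking": (0, 5, 10, 15),
}

BARTHEL_CUTOFF = 60

# FD-index care-profile bands: left-closed, right-open, exhaustive from the
# analytic floor 1.0 upward.
PROFILE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("minimum", 1.0, 2.6),
    ("medium", 2.6, 3.7),
    ("high", 3.7, 4.8),
    ("maximum", 4.8, float("inf")),
)


@dataclass(frozen=True)
class ModalityDefinition:
    """One ordered modality of an ASGO variable.

    ``ranking_value`` is the score contribution when this modality is
    selected and equals (variable weight × level) to one decimal place.
    """

    level: int
    label: str
    ranking_value: float

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 7:
            raise ValidationError(f"modality level {self.level} outside 1..7")
        if self.ranking_value <= 0:
            raise ValidationError("ranking_value must be positive")


@dataclass(frozen=True)
class VariableDefinition:
    """An ASGO variable: a weight and an ordered list of modalities."""

    name: str
    weight: float
    modalities: tuple[ModalityDefinition, ...]
    multi_select: bool = False

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValidationError(f"{self.name}: no modalities")
        values = [m.ranking_value for m in self.modalities]
        if any(b <= a for a, b in zip(values, values[1:])):
            raise ValidationError(
                f"{self.name}: ranking values must strictly increase with level"
            )
        for m in self.modalities:
            expected = round(self.weight * m.level, 1)
            if abs(m.ranking_value - expected) > 1e-9:
                raise ValidationError(
                    f"{self.name} level {m.level}: ranking value "
                    f"{m.ranking_value} != weight x level = {expected}"
                )

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(m.level for m in self.modalities)

    def modality(self, level: int) -> ModalityDefinition:
        for m in self.modalities:
            if m.level == level:
                return m
        raise ValidationError(
            f"{self.name}: level {level} not among printed modalities {self.levels}"
        )

    @property
    def min_value(self) -> float:
        return self.modalities[0].ranking_value

    @property
    def max_value(self) -> float:
        return self.modalities[-1].ranking_value


@dataclass(frozen=True)
class InstrumentDefinition:
    """The full 10-variable ASGO definition (weights, modalities, flags)."""

    variables: tuple[VariableDefinition, ...]
    name: str = "ASGO"
    version: str = "1.0"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(names) != 10 or set(names) != set(ASGO_VARIABLES):
            raise ValidationError(
                f"instrument must define exactly the 10 ASGO variables, got {names}"
            )
        total_weight = sum(v.weight for v in self.variables)
        if abs(total_weight - 10.0) > 1e-9:
            raise ValidationError(f"variable weights must sum to 10.0, got {total_weight}")

    def variable(self, name: str) -> VariableDefinition:
        for v in self.variables:
            if v.name == name:
                return v
        raise ValidationError(f"unknown ASGO variable {name!r}")

    @property
    def min_score(self) -> float:
        """Floor of the raw score: every variable at its first modality."""
        return round(sum(v.min_value for v in self.variables), 10)

    @property
    def max_single_select_score(self) -> float:
        """Ceiling of the raw score under single selections."""
        return round(sum(v.max_value for v in self.variables), 10)


def load_default_instrument() -> InstrumentDefinition:
    """Load the shipped ASGO definition (weights and printed ranking values)."""
    with resources.files("asgo.data").joinpath("asgo_instrument.json").open() as fh:
        payload = json.load(fh)
    return instrument_from_dict(payload)


def instrument_from_dict(payload: Mapping) -> InstrumentDefinition:
    variables = []
    for var in payload["variables"]:
        modalities = tuple(
            ModalityDefinition(m["level"], m["label"], m["ranking_value"])
            for m in var["modalities"]
        )
        variables.append(
            VariableDefinition(
                name=var["name"],
                weight=var["weight"],
                modalities=modalities,
                multi_select=bool(var.get("multi_select", False)),
            )
        )
    return InstrumentDefinition(
        variables=tuple(variables),
        name=payload.get("name", "ASGO"),
        version=str(payload.get("version", "1.0")),
    )


Timepoint = Literal["admission", "discharge"]


@dataclass(frozen=True)
class AsgoAssessment:
    """One patient-timepoint's modality selections, variable → set of levels."""

    selections: Mapping[str, frozenset[int]]
    timepoint: Timepoint = "admission"

    def __post_init__(self) -> None:
        normalised = {k: frozenset(v) for k, v in self.selections.items()}
        object.__setattr__(self, "selections", normalised)

    def validate(self, instrument: InstrumentDefinition) -> None:
        for var in instrument.variables:
            levels = self.selections.get(var.name)
            if not levels:
                raise ValidationError(f"{var.name}: no modality selected")
            if not var.multi_select and len(levels) > 1:
                raise ValidationError(
                    f"{var.name}: {len(levels)} selections on a single-select variable"
                )
            for level in levels:
                var.modality(level)  # raises on unknown level
        extra = set(self.selections) - set(ASGO_VARIABLES)
        if extra:
            raise ValidationError(f"unknown ASGO variables in assessment: {sorted(extra)}")


@dataclass(frozen=True)
class AsgoResult:
    raw_score: float
    fd_index: float
    profile: str
    per_variable: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class BarthelAssessment:
    """Ten BI item scores on the 0/5/10/15 lattice."""

    scores: Mapping[str, int]
    timepoint: Timepoint = "admission"

    def validate(self) -> None:
        for item in BARTHEL_ITEMS:
            if item not in self.scores:
                raise ValidationError(f"Barthel item {item!r} missing")
            value = self.scores[item]
            allowed = BARTHEL_ALLOWED[item]
            if value not in allowed:
                raise ValidationError(
                    f"Barthel item {item!r}: score {value} not in allowed set {allowed}"
                )
        extra = set(self.scores) - set(BARTHEL_ITEMS)
        if extra:
            raise ValidationError(f"unknown Barthel items: {sorted(extra)}")


@dataclass(frozen=True)
class DependenceStatus:
    flag: Literal["dependence", "independence"]
    source: Literal["asgo", "barthel"]
    cutoff_used: float

    @property
    def dependent(self) -> bool:
        return self.flag == "dependence"


def score_asgo(
    assessment: AsgoAssessment,
    instrument: InstrumentDefinition,
    combine: Literal["sum", "max"] = "sum",
) -> AsgoResult:
    """Score an ASGO assessment to raw score, FD index and care profile.

    ``combine`` controls how simultaneous selections on a multi-select
    variable contribute: ``"sum"`` (default — cumulative support needs) adds
    every selected ranking value, ``"max"`` keeps only the highest.
    """
    assessment.validate(instrument)
    if combine not in ("sum", "max"):
        raise ValueError(f"combine must be 'sum' or 'max', got {combine!r}")
    per_variable: dict[str, float] = {}
    for var in instrument.variables:
        values = [var.modality(level).ranking_value for level in assessment.selections[var.name]]
        per_variable[var.name] = sum(values) if combine == "sum" else max(values)
    raw = round(sum(per_variable.values()), 10)
    fd = raw / 10.0
    return AsgoResult(
        raw_score=raw,
        fd_index=fd,
        profile=profile_category(fd),
        per_variable=per_variable,
    )


def profile_category(fd_index: float) -> str:
    """Map an FD index to its care profile (bands left-closed, right-open)."""
    if fd_index < 1.0:
        raise ValidationError(
            f"FD index {fd_index} below the analytic floor 1.0 (all-minimum assessment)"
        )
    for profile, lower, upper in PROFILE_BANDS:
        if lower <= fd_index < upper:
            return profile
    raise AssertionError("profile bands are exhaustive")  # pragma: no cover


def score_barthel(assessment: BarthelAssessment) -> int:
    """Total BI score in [0, 100] (always a multiple of 5)."""
    assessment.validate()
    return int(sum(assessment.scores[item] for item in BARTHEL_ITEMS))


def dichotomize_barthel(total: int) -> DependenceStatus:
    """BI ≥ 60 → independence, < 60 → dependence."""
    if not 0 <= total <= 100:
        raise ValidationError(f"Barthel total {total} outside [0, 100]")
    flag = "independence" if total >= BARTHEL_CUTOFF else "dependence"
    return DependenceStatus(flag=flag, source="barthel", cutoff_used=float(BARTHEL_CUTOFF))


def classify_asgo(raw_score: float, cutoff: float) -> DependenceStatus:
    """ASGO raw score ≥ cutoff → dependence (ties classify as dependent)."""
    if raw_score < 10.0:
        raise ValidationError(f"ASGO raw score {raw_score} below the floor 10.0")
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    flag = "dependence" if raw_score >= cutoff else "independence"
    return DependenceStatus(flag=flag, source="asgo", cutoff_used=float(cutoff))


def all_minimum_assessment(
    instrument: InstrumentDefinition, timepoint: Timepoint = "admission"
) -> AsgoAssessment:
    """The floor assessment: every variable at its first modality."""
    return AsgoAssessment(
        selections={v.name: frozenset({v.modalities[0].level}) for v in instrument.variables},
        timepoint=timepoint,
    )


def all_maximum_assessment(
    instrument: InstrumentDefinition, timepoint: Timepoint = "admission"
) -> AsgoAssessment:
    """Every variable at its highest printed modality, single selection."""
    return AsgoAssessment(
        selections={v.name: frozenset({v.modalities[-1].level}) for v in instrument.variables},
        timepoint=timepoint,
    )
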