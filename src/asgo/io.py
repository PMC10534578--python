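"""Cohort CSV schema and record containers.

One row per patient-timepoint.  ASGO columns hold modality level selections
(multi-select variables as ``;``-separated levels, e.g. ``"1;3"``); Barthel
columns hold item points.  Demographics are optional.  Files are RFC-4180
CSV, UTF-8, header required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .instrument import (
    ASGO_VARIABLES,
    BARTHEL_ITEMS,
    AsgoAssessment,
    BarthelAssessment,
    InstrumentDefinition,
    ValidationError,
    load_default_instrument,
)

logger = logging.getLogger(__name__)

ASGO_COLUMNS = tuple(f"asgo_{v}" for v in ASGO_VARIABLES)
BARTHEL_COLUMNS = tuple(f"bi_{item}" for item in BARTHEL_ITEMS)
REQUIRED_COLUMNS = ("patient_id", "timepoint") + ASGO_COLUMNS + BARTHEL_COLUMNS
DEMOGRAPHIC_COLUMNS = ("age", "gender", "length_of_stay", "admission_reason")
TIMEPOINTS = ("admission", "discharge")
LEVEL_SEPARATOR = ";"


@dataclass
class PairedRecord:
    """Admission + discharge ASGO and Barthel assessments for one patient.

    ``discharge_*`` may be ``None`` when the patient has no discharge row;
    such records are excluded from paired statistics.
    """

    patient_id: str
    admission_asgo: AsgoAssessment
    admission_barthel: BarthelAssessment
    discharge_asgo: AsgoAssessment | None = None
    discharge_barthel: BarthelAssessment | None = None
    demographics: Mapping[str, object] = field(default_factory=dict)

    @property
    def is_paired(self) -> bool:
        return self.discharge_asgo is not None and self.discharge_barthel is not None


@dataclass
class CohortReadResult:
    """Outcome of parsing a cohort CSV."""

    records: list[PairedRecord]
    unpaired: list[str]  # patient ids lacking admission or discharge
    rejected: list[tuple[int, str]]  # (1-based data row number, diagnostic)

    @property
    def paired_records(self) -> list[PairedRecord]:
        return [r for r in self.records if r.is_paired]


def _format_levels(levels: frozenset[int]) -> str:
    return LEVEL_SEPARATOR.join(str(v) for v in sorted(levels))


def _parse_levels(cell: object) -> frozenset[int]:
    text = str(cell).strip()
    if not text or text.lower() == "nan":
        raise ValidationError("empty level selection")
    try:
        return frozenset(int(tok) for tok in text.split(LEVEL_SEPARATOR) if tok.strip())
    except ValueError as exc:
        raise ValidationError(f"unparseable level selection {text!r}") from exc


def record_rows(record: PairedRecord) -> list[dict]:
    """Flatten one record to its CSV row dicts (one per available timepoint)."""
    rows = []
    pairs = [("admission", record.admission_asgo, record.admission_barthel)]
    if record.is_paired:
        pairs.append(("discharge", record.discharge_asgo, record.discharge_barthel))
    for timepoint, asgo, barthel in pairs:
        row: dict[str, object] = {"patient_id": record.patient_id, "timepoint": timepoint}
        for var in ASGO_VARIABLES:
            row[f"asgo_{var}"] = _format_levels(asgo.selections[var])
        for item in BARTHEL_ITEMS:
            row[f"bi_{item}"] = barthel.scores[item]
        for col in DEMOGRAPHIC_COLUMNS:
            if col in record.demographics:
                row[col] = record.demographics[col]
        rows.append(row)
    return rows


def cohort_to_dataframe(records: Sequence[PairedRecord]) -> pd.DataFrame:
    rows = [row for record in records for row in record_rows(record)]
    df = pd.DataFrame(rows)
    ordered = [c for c in REQUIRED_COLUMNS + DEMOGRAPHIC_COLUMNS if c in df.columns]
    return df[ordered]


def write_cohort_csv(records: Sequence[PairedRecord], path) -> None:
    cohort_to_dataframe(records).to_csv(path, index=False)


def _row_to_assessments(
    row: pd.Series, timepoint: str, instrument: InstrumentDefinition
) -> tuple[AsgoAssessment, BarthelAssessment]:
    selections = {var: _parse_levels(row[f"asgo_{var}"]) for var in ASGO_VARIABLES}
    asgo = AsgoAssessment(selections=selections, timepoint=timepoint)
    asgo.validate(instrument)
    scores = {}
    for item in BARTHEL_ITEMS:
        raw = row[f"bi_{item}"]
        try:
            scores[item] = int(raw)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"Barthel item {item!r}: unparseable score {raw!r}") from exc
    barthel = BarthelAssessment(scores=scores, timepoint=timepoint)
    barthel.validate()
    return asgo, barthel


def read_cohort(
    path,
    instrument: InstrumentDefinition | None = None,
    *,
    strict: bool = True,
) -> CohortReadResult:
    """Parse and validate a cohort CSV into paired records.

    Structural problems (missing header columns, duplicate patient-timepoint
    rows) always raise.  Rows failing instrument validation raise a
    row-numbered :class:`ValidationError` when ``strict`` (default), or are
    collected into ``result.rejected`` otherwise.  Patients lacking either
    timepoint land in ``result.unpaired`` and are excluded from paired
    statistics.
    """
    instrument = instrument or load_default_instrument()
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: malformed header, missing columns {missing}")
    bad_tp = df.loc[~df["timepoint"].isin(TIMEPOINTS), "timepoint"].unique().tolist()
    if bad_tp:
        raise ValidationError(f"{path.name}: unknown timepoint values {bad_tp}")
    dup = df.duplicated(subset=["patient_id", "timepoint"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["patient_id", "timepoint"]].drop_duplicates()
        raise ValidationError(
            f"{path.name}: duplicate patient-timepoint rows: "
            + ", ".join(f"{r.patient_id}/{r.timepoint}" for r in offenders.itertuples())
        )

    parsed: dict[str, dict[str, tuple[AsgoAssessment, BarthelAssessment]]] = {}
    demographics: dict[str, dict] = {}
    rejected: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        row_no = int(idx) + 1  # 1-based data row
        try:
            asgo, barthel = _row_to_assessments(row, row["timepoint"], instrument)
        except ValidationError as exc:
            message = f"row {row_no} (patient {row['patient_id']}): {exc}"
            if strict:
                raise ValidationError(message) from exc
            rejected.append((row_no, message))
            continue
        parsed.setdefault(row["patient_id"], {})[row["timepoint"]] = (asgo, barthel)
        demo = {c: row[c] for c in DEMOGRAPHIC_COLUMNS if c in df.columns and pd.notna(row[c])}
        demographics.setdefault(row["patient_id"], {}).update(demo)

    records: list[PairedRecord] = []
    unpaired: list[str] = []
    for pid, by_tp in parsed.items():
        if "admission" not in by_tp:
            unpaired.append(pid)
            continue
        adm_asgo, adm_bi = by_tp["admission"]
        dis = by_tp.get("discharge")
        if dis is None:
            unpaired.append(pid)
        records.append(
            PairedRecord(
                patient_id=pid,
                admission_asgo=adm_asgo,
                admission_barthel=adm_bi,
                discharge_asgo=dis[0] if dis else None,
                discharge_barthel=dis[1] if dis else None,
                demographics=demographics.get(pid, {}),
            )
        )
    if unpaired:
        logger.info("%d patients lack a complete admission/discharge pair", len(unpaired))
    if rejected:
        logger.warning("%d rows rejected by instrument validation", len(rejected))
    return CohortReadResult(records=records, unpaired=sorted(unpaired), rejected=rejected)
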