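"""End-to-end validation pipeline.

From a cohort of paired records: scores both instruments, correlates them
(Spearman), assesses internal consistency (Cronbach's alpha), finds the
Youden-optimal cut-off, builds confusion tables with sensitivity and
specificity at both timepoints, traces ROC curves with AUC, and runs the
factorability diagnostics (KMO, Bartlett) plus PCA-based EFA with varimax
rotation.  Every number in the report is recomputable by calling the
psychometrics operations directly on the raw records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import psychometrics as psy
from .instrument import (
    ASGO_VARIABLES,
    BARTHEL_CUTOFF,
    AsgoAssessment,
    InstrumentDefinition,
    load_default_instrument,
    score_asgo,
    score_barthel,
)
from .io import PairedRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationConfig",
    "TimepointBlock",
    "ValidationReport",
    "run_validation",
    "render_report",
    "asgo_item_matrix",
    "score_cohort_frame",
]


@dataclass
class ValidationConfig:
    """Choices the analysis leaves open, with their defaults.

    ``cutoff=None`` derives the classification cut-off from the Youden index
    on admission scores and applies it at both timepoints; a fixed value
    (e.g. 22.5) overrides it.  ``efa_timepoint`` selects which assessments
    feed the factor analysis; ``item_values`` selects the item matrix
    entries (per-variable summed ranking values, or raw summed levels).
    """

    cutoff: float | None = None
    efa_timepoint: Literal["admission", "discharge", "pooled"] = "admission"
    item_values: Literal["weighted", "levels"] = "weighted"
    multi_combine: Literal["sum", "max"] = "sum"
    roc_midpoint: bool = False

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ValidationConfig":
        return cls(**payload)

    @classmethod
    def from_file(cls, path) -> "ValidationConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text) or {}
        else:
            payload = json.loads(text)
        return cls.from_dict(payload)


@dataclass
class TimepointBlock:
    """All per-timepoint validation results."""

    timepoint: str
    n_all: int
    n_paired: int
    descriptives_all: dict
    descriptives_paired: dict
    spearman_rho: float | None = None
    spearman_p: float | None = None
    cronbach_alpha: float | None = None
    youden_cutoff: float | None = None
    youden_j: float | None = None
    cutoff_used: float | None = None
    confusion: dict | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    auc: float | None = None
    roc_thresholds: list[float] = field(default_factory=list)
    roc_sensitivity: list[float] = field(default_factory=list)
    roc_specificity: list[float] = field(default_factory=list)
    available: bool = True
    note: str = ""


@dataclass
class ValidationReport:
    meta: dict
    admission: TimepointBlock
    discharge: TimepointBlock
    factor: dict

    def to_dict(self) -> dict:
        return {
            "meta": dict(self.meta),
            "admission": asdict(self.admission),
            "discharge": asdict(self.discharge),
            "factor": dict(self.factor),
        }


def _asgo_items(
    assessment: AsgoAssessment,
    instrument: InstrumentDefinition,
    config: ValidationConfig,
) -> np.ndarray:
    if config.item_values == "weighted":
        result = score_asgo(assessment, instrument, combine=config.multi_combine)
        return np.array([result.per_variable[v] for v in ASGO_VARIABLES])
    values = []
    for v in ASGO_VARIABLES:
        levels = assessment.selections[v]
        values.append(sum(levels) if config.multi_combine == "sum" else max(levels))
    return np.array(values, dtype=float)


def asgo_item_matrix(
    records: Sequence[PairedRecord],
    *,
    timepoint: str = "admission",
    instrument: InstrumentDefinition | None = None,
    config: ValidationConfig | None = None,
) -> np.ndarray:
    """Subjects × 10 ASGO item matrix for reliability and factor analysis."""
    instrument = instrument or load_default_instrument()
    config = config or ValidationConfig()
    rows = []
    for record in records:
        if timepoint in ("admission", "pooled"):
            rows.append(_asgo_items(record.admission_asgo, instrument, config))
        if timepoint in ("discharge", "pooled") and record.discharge_asgo is not None:
            rows.append(_asgo_items(record.discharge_asgo, instrument, config))
    return np.vstack(rows)


def _descriptives(asgo_scores: np.ndarray, bi_totals: np.ndarray) -> dict:
    return {
        "asgo_mean": float(asgo_scores.mean()),
        "asgo_sd": float(asgo_scores.std(ddof=1)) if len(asgo_scores) > 1 else 0.0,
        "asgo_min": float(asgo_scores.min()),
        "asgo_max": float(asgo_scores.max()),
        "bi_mean": float(bi_totals.mean()),
        "bi_sd": float(bi_totals.std(ddof=1)) if len(bi_totals) > 1 else 0.0,
    }


def _timepoint_block(
    timepoint: str,
    asgo_all: np.ndarray,
    bi_all: np.ndarray,
    asgo_paired: np.ndarray,
    bi_paired: np.ndarray,
    item_matrix: np.ndarray,
    cutoff: float | None,
    config: ValidationConfig,
) -> TimepointBlock:
    block = TimepointBlock(
        timepoint=timepoint,
        n_all=len(asgo_all),
        n_paired=len(asgo_paired),
        descriptives_all=_descriptives(asgo_all, bi_all),
        descriptives_paired=_descriptives(asgo_paired, bi_paired),
    )
    try:
        block.spearman_rho, block.spearman_p = psy.spearman_rho(asgo_paired, bi_paired)
    except psy.DegenerateDataError as exc:
        block.note = f"correlation unavailable: {exc}"
    try:
        block.cronbach_alpha = psy.cronbach_alpha(item_matrix)
    except psy.DegenerateDataError as exc:
        block.note = (block.note + "; " if block.note else "") + f"alpha unavailable: {exc}"

    truth = bi_paired < BARTHEL_CUTOFF  # Barthel-defined dependence
    if truth.all() or not truth.any():
        block.available = False
        block.note = "single-class timepoint: ROC/cut-off blocks unavailable"
        return block

    curve = psy.roc_curve(asgo_paired, truth, midpoint=config.roc_midpoint)
    block.auc = psy.auc(curve)
    block.roc_thresholds = [float(t) for t in curve.thresholds]
    block.roc_sensitivity = [float(s) for s in curve.sensitivity]
    block.roc_specificity = [float(s) for s in curve.specificity]
    block.youden_cutoff, block.youden_j = psy.youden_optimal_cutoff(curve)

    applied = cutoff if cutoff is not None else block.youden_cutoff
    block.cutoff_used = float(applied)
    table = psy.ConfusionTable.from_predictions(asgo_paired >= applied, truth)
    block.confusion = {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn}
    block.sensitivity, block.specificity = psy.sensitivity_specificity(table)
    return block


def run_validation(
    records: Sequence[PairedRecord],
    config: ValidationConfig | None = None,
    instrument: InstrumentDefinition | None = None,
) -> ValidationReport:
    """Full validation report from paired records.

    Paired statistics use patients with both timepoints (listwise
    exclusion); per-timepoint descriptives are additionally reported on all
    available rows.  When ``config.cutoff`` is unset, the admission Youden
    cut-off is applied at both timepoints.
    """
    config = config or ValidationConfig()
    instrument = instrument or load_default_instrument()
    paired = [r for r in records if r.is_paired]
    if len(paired) < 2:
        raise ValueError("need at least 2 paired records")

    def scores(recs, timepoint):
        asgo = np.array(
            [
                score_asgo(
                    r.admission_asgo if timepoint == "admission" else r.discharge_asgo,
                    instrument,
                    combine=config.multi_combine,
                ).raw_score
                for r in recs
            ]
        )
        bi = np.array(
            [
                score_barthel(
                    r.admission_barthel if timepoint == "admission" else r.discharge_barthel
                )
                for r in recs
            ],
            dtype=float,
        )
        return asgo, bi

    asgo_adm_all, bi_adm_all = scores(records, "admission")
    asgo_adm, bi_adm = scores(paired, "admission")
    asgo_dis, bi_dis = scores(paired, "discharge")

    admission = _timepoint_block(
        "admission",
        asgo_adm_all,
        bi_adm_all,
        asgo_adm,
        bi_adm,
        asgo_item_matrix(records, timepoint="admission", instrument=instrument, config=config),
        config.cutoff,
        config,
    )
    applied_cutoff = config.cutoff if config.cutoff is not None else admission.youden_cutoff
    discharge = _timepoint_block(
        "discharge",
        asgo_dis,
        bi_dis,
        asgo_dis,
        bi_dis,
        asgo_item_matrix(paired, timepoint="discharge", instrument=instrument, config=config),
        applied_cutoff,
        config,
    )

    efa_matrix = asgo_item_matrix(
        paired if config.efa_timepoint != "admission" else records,
        timepoint=config.efa_timepoint,
        instrument=instrument,
        config=config,
    )
    try:
        solution = psy.pca_efa(efa_matrix, item_names=ASGO_VARIABLES)
        R = np.corrcoef(efa_matrix, rowvar=False)
        kmo_value = psy.kmo(R)
        chi2, df, bartlett_p = psy.bartlett_sphericity(R, n=efa_matrix.shape[0])
        dominant = solution.dominant_factor()
        factor = {
            "available": True,
            "efa_timepoint": config.efa_timepoint,
            "n_obs": int(efa_matrix.shape[0]),
            "kmo": kmo_value,
            "bartlett_chi2": chi2,
            "bartlett_df": int(df),
            "bartlett_p": bartlett_p,
            "eigenvalues": [float(v) for v in solution.eigenvalues],
            "variance_pct": [float(v) for v in solution.variance_pct],
            "cumulative_pct": [float(v) for v in solution.cumulative_pct],
            "n_retained": int(solution.n_retained),
            "items": list(ASGO_VARIABLES),
            "loadings_unrotated": solution.loadings.tolist(),
            "loadings_rotated": solution.rotated.tolist(),
            "dominant_factor": [int(d) + 1 for d in dominant],
        }
    except (psy.DegenerateDataError, np.linalg.LinAlgError) as exc:
        logger.warning("factor block unavailable: %s", exc)
        factor = {
            "available": False,
            "efa_timepoint": config.efa_timepoint,
            "n_obs": int(efa_matrix.shape[0]),
            "note": f"factor analysis unavailable: {exc}",
        }

    meta = {
        "n_patients": len(records),
        "n_paired": len(paired),
        "cutoff_mode": "fixed" if config.cutoff is not None else "youden_admission",
        "cutoff_used": float(applied_cutoff) if applied_cutoff is not None else None,
        "efa_timepoint": config.efa_timepoint,
        "item_values": config.item_values,
        "multi_combine": config.multi_combine,
        "roc_midpoint": config.roc_midpoint,
    }
    logger.info(
        "validation: n=%d paired=%d cutoff=%s (%s)",
        meta["n_patients"],
        meta["n_paired"],
        meta["cutoff_used"],
        meta["cutoff_mode"],
    )
    return ValidationReport(meta=meta, admission=admission, discharge=discharge, factor=factor)


# ---------------------------------------------------------------------------
# Rendering


def _round_sig(value, digits: int = 6):
    """Recursively round floats to ``digits`` significant digits for stable,
    byte-identical JSON output."""
    if isinstance(value, float):
        if value != value or value in (float("inf"), float("-inf")):
            return str(value)
        return float(f"{value:.{digits}g}")
    if isinstance(value, dict):
        return {k: _round_sig(v, digits) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_round_sig(v, digits) for v in value]
    return value


def _fmt(value, nd=2) -> str:
    return "unavailable" if value is None else f"{value:.{nd}f}"


def _markdown_report(report: ValidationReport) -> str:
    lines = ["# ASGO validation report", ""]
    meta = report.meta
    lines += [
        f"Patients: {meta['n_patients']} ({meta['n_paired']} paired) — "
        f"cut-off {_fmt(meta['cutoff_used'])} ({meta['cutoff_mode']}), "
        f"EFA on {meta['efa_timepoint']} assessments, {meta['item_values']} item values.",
        "",
        "## Correlation and descriptives",
        "",
        "| Timing | ASGO mean (SD) | BI mean (SD) | Spearman rho | p |",
        "|---|---|---|---|---|",
    ]
    for block in (report.admission, report.discharge):
        d = block.descriptives_paired
        p = "<0.001" if (block.spearman_p is not None and block.spearman_p < 0.001) else _fmt(block.spearman_p, 3)
        lines.append(
            f"| {block.timepoint} | {d['asgo_mean']:.1f} ({d['asgo_sd']:.1f}) | "
            f"{d['bi_mean']:.1f} ({d['bi_sd']:.1f}) | {_fmt(block.spearman_rho)} | {p} |"
        )
    lines += [
        "",
        "## Reliability and score range",
        "",
        "| Timing | Range | Cronbach's alpha |",
        "|---|---|---|",
    ]
    for block in (report.admission, report.discharge):
        d = block.descriptives_paired
        lines.append(
            f"| {block.timepoint} | {d['asgo_min']:.1f}–{d['asgo_max']:.1f} | "
            f"{_fmt(block.cronbach_alpha)} |"
        )
    lines += ["", "## Dependence classification", ""]
    for block in (report.admission, report.discharge):
        lines.append(f"### {block.timepoint.capitalize()}")
        if not block.available or block.confusion is None:
            lines += [f"_{block.note or 'unavailable'}_", ""]
            continue
        c = block.confusion
        lines += [
            "",
            f"Cut-off {block.cutoff_used:.2f}; Youden-optimal {block.youden_cutoff:.2f} "
            f"(J = {block.youden_j:.2f}); AUC = {block.auc:.2f}.",
            "",
            "| | BI dependence | BI independence | Total |",
            "|---|---|---|---|",
            f"| ASGO dependence | {c['tp']} | {c['fp']} | {c['tp'] + c['fp']} |",
            f"| ASGO independence | {c['fn']} | {c['tn']} | {c['fn'] + c['tn']} |",
            f"| Total | {c['tp'] + c['fn']} | {c['fp'] + c['tn']} | "
            f"{c['tp'] + c['fp'] + c['fn'] + c['tn']} |",
            "",
            f"Sensitivity {block.sensitivity:.2f}, specificity {block.specificity:.2f}.",
            "",
        ]
    f = report.factor
    if not f.get("available", True):
        lines += ["## Factor structure", "", f"_{f['note']}_", ""]
        return "\n".join(lines)
    bartlett_p = "<0.001" if f["bartlett_p"] < 0.001 else format(f["bartlett_p"], ".3f")
    lines += [
        "## Factor structure",
        "",
        f"KMO = {f['kmo']:.2f}; Bartlett chi² = {f['bartlett_chi2']:.1f} "
        f"(df {f['bartlett_df']}, p {bartlett_p}); "
        f"{f['n_retained']} factors retained (Kaiser).",
        "",
        "| Component | Eigenvalue | % of variance | Cumulative % |",
        "|---|---|---|---|",
    ]
    for i, (ev, pct, cum) in enumerate(
        zip(f["eigenvalues"], f["variance_pct"], f["cumulative_pct"]), start=1
    ):
        lines.append(f"| {i} | {ev:.2f} | {pct:.2f} | {cum:.2f} |")
    lines += ["", "| Item | " + " | ".join(f"Factor {j + 1}" for j in range(f["n_retained"])) + " |"]
    lines.append("|---|" + "---|" * f["n_retained"])
    for item, row, dom in zip(f["items"], f["loadings_rotated"], f["dominant_factor"]):
        cells = [
            f"**{v:.3f}**" if j + 1 == dom else f"{v:.3f}" for j, v in enumerate(row)
        ]
        lines.append(f"| {item} | " + " | ".join(cells) + " |")
    lines.append("")
    return "\n".join(lines)


def render_report(
    report: ValidationReport,
    out_dir,
    *,
    formats: Sequence[str] = ("json", "md", "csv"),
    plots: bool = False,
) -> list[Path]:
    """Write the report to ``out_dir`` (JSON, Markdown, ROC/loading CSVs).

    JSON is deterministic: keys sorted, floats at 6 significant digits.
    ``plots=True`` additionally writes ROC curve PNGs (requires matplotlib).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    payload = _round_sig(report.to_dict())
    if "json" in formats:
        path = out_dir / "report.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(path)
    if "md" in formats:
        path = out_dir / "report.md"
        path.write_text(_markdown_report(report))
        written.append(path)
    if "csv" in formats:
        for block in (report.admission, report.discharge):
            path = out_dir / f"roc_{block.timepoint}.csv"
            if block.available and block.roc_thresholds:
                pd.DataFrame(
                    {
                        "threshold": block.roc_thresholds,
                        "sensitivity": block.roc_sensitivity,
                        "specificity": block.roc_specificity,
                    }
                ).to_csv(path, index=False)
                written.append(path)
        f = report.factor
        if f.get("available", True):
            path = out_dir / "loadings.csv"
            frame = pd.DataFrame(
                f["loadings_rotated"],
                index=f["items"],
                columns=[f"factor_{j + 1}" for j in range(f["n_retained"])],
            )
            frame["dominant_factor"] = f["dominant_factor"]
            frame.to_csv(path, index_label="item")
            written.append(path)
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for block in (report.admission, report.discharge):
            if not block.available:
                continue
            fig, ax = plt.subplots(figsize=(4.5, 4.5))
            fpr = 1.0 - np.asarray(block.roc_specificity)
            order = np.argsort(fpr)
            ax.plot(fpr[order], np.asarray(block.roc_sensitivity)[order], drawstyle="steps-post")
            ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
            ax.set_xlabel("1 − specificity")
            ax.set_ylabel("Sensitivity")
            ax.set_title(f"ASGO ROC, {block.timepoint} (AUC = {block.auc:.2f})")
            path = out_dir / f"roc_{block.timepoint}.png"
            fig.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(fig)
            written.append(path)
    return written


def score_cohort_frame(
    records: Sequence[PairedRecord],
    cutoff: float = 22.5,
    instrument: InstrumentDefinition | None = None,
    config: ValidationConfig | None = None,
) -> pd.DataFrame:
    """Per patient-timepoint scored table: raw score, FD index, care profile,
    BI total, and both dichotomisations."""
    from .instrument import classify_asgo, dichotomize_barthel

    instrument = instrument or load_default_instrument()
    config = config or ValidationConfig()
    rows = []
    for record in records:
        pairs = [("admission", record.admission_asgo, record.admission_barthel)]
        if record.is_paired:
            pairs.append(("discharge", record.discharge_asgo, record.discharge_barthel))
        for timepoint, asgo, barthel in pairs:
            result = score_asgo(asgo, instrument, combine=config.multi_combine)
            total = score_barthel(barthel)
            rows.append(
                {
                    "patient_id": record.patient_id,
                    "timepoint": timepoint,
                    "asgo_raw_score": result.raw_score,
                    "fd_index": result.fd_index,
                    "care_profile": result.profile,
                    "barthel_total": total,
                    "asgo_status": classify_asgo(result.raw_score, cutoff).flag,
                    "barthel_status": dichotomize_barthel(total).flag,
                }
            )
    return pd.DataFrame(rows)
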