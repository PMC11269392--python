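"""Per-case orchestration and cohort summaries.

``run_case`` drives one specimen end-to-end: parse methylation calls,
binarize and align to the atlas, QC the CpG overlap, score methylation
class and family, apply the diagnostic cutoff, then bin counts,
normalize, subtract the normal reference, segment, call focal events and
fit tumor purity. Stage failures are captured in the report under the
stage name rather than aborting the whole case; a QC failure downgrades
the classification to low confidence but the call is still attempted
(the clinical remediation is an additional sequencing run).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import calibration, classifier, cnv, features
from .genome import DEFAULT_BIN_SIZE, GenomeModel, toy_genome

__all__ = [
    "CaseRecord",
    "CaseReport",
    "CohortSummary",
    "run_case",
    "summarize_cohort",
    "write_report",
    "read_report",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 0.2
LESION_TYPES = ("primary", "secondary")

REPORT_TSV_COLUMNS = [
    "case_id", "age_years", "sex", "location", "reference_diagnosis",
    "lesion_type", "pretreatment", "mc", "score_mc", "mcf", "score_mcf",
    "passes_cutoff", "qc_passed", "observed_cpgs", "purity", "purity_identifiable",
]


@dataclass
class CaseRecord:
    """One cohort row plus the paths to its per-case inputs."""

    case_id: str
    age_years: int
    sex: str
    location: str
    reference_diagnosis: str
    lesion_type: str
    pretreatment: str = "None"
    methylation_path: str = ""
    bin_counts_path: str = ""

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"{self.case_id}: negative age {self.age_years}")
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(
                f"{self.case_id}: lesion_type {self.lesion_type!r} not in {LESION_TYPES}"
            )


@dataclass
class CaseReport:
    """Structured diagnostic report for one case."""

    case_id: str
    record: dict[str, Any] = field(default_factory=dict)
    qc: dict[str, Any] = field(default_factory=dict)
    classification: dict[str, Any] = field(default_factory=dict)
    copy_number: dict[str, Any] = field(default_factory=dict)
    purity: dict[str, Any] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def run_case(
    record: CaseRecord,
    model: classifier.MaskedNetModel,
    atlas: features.ReferenceAtlas,
    cutoff: float = DEFAULT_CUTOFF,
    reference_profile: cnv.BinProfile | None = None,
    genome: GenomeModel | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    min_cpgs: int = features.DEFAULT_MIN_CPGS,
    beta_threshold: float = features.DEFAULT_BETA_THRESHOLD,
    annotations: pd.DataFrame | None = None,
    seg_alpha: float = 0.01,
    seg_min_bins: int = 5,
    seg_permutations: int = 200,
    seed: int = 0,
) -> CaseReport:
    """Run the full diagnostic workflow for one case."""
    genome = genome or toy_genome()
    report = CaseReport(case_id=record.case_id, record=asdict(record))
    report.params = {
        "cutoff": cutoff, "bin_size": bin_size, "min_cpgs": min_cpgs,
        "beta_threshold": beta_threshold, "seg_alpha": seg_alpha,
        "seg_min_bins": seg_min_bins, "seg_permutations": seg_permutations,
        "seed": seed,
    }

    # --- methylation classification ---
    vector = None
    try:
        calls = features.read_methylation_calls(record.methylation_path)
        states = features.binarize(calls, threshold=beta_threshold)
        vector = features.align_to_atlas(states, atlas)
        verdict = features.qc_check(vector, min_cpgs=min_cpgs)
        report.qc = {
            "passed": verdict.passed,
            "observed_cpgs": verdict.observed_count,
            "min_cpgs": verdict.min_cpgs,
            "message": verdict.message,
        }
    except (features.ParseError, OSError) as exc:
        report.errors["methylation_input"] = str(exc)

    if vector is not None:
        try:
            scores = classifier.predict(model, vector)
            fam_scores = classifier.aggregate_families(scores, model.hierarchy)
            mc = classifier.top_call(scores)
            mcf = classifier.top_call(fam_scores)
            report.classification = {
                "mc": mc.label,
                "score_mc": mc.score,
                "mc_tie": mc.tie,
                "mcf": mcf.label,
                "score_mcf": mcf.score,
                "mcf_tie": mcf.tie,
                "passes_cutoff": mc.score > cutoff,
                "cutoff": cutoff,
                "low_confidence": not report.qc.get("passed", False),
            }
        except Exception as exc:  # surfaced with stage name
            report.errors["classification"] = str(exc)

    # --- copy number & purity ---
    try:
        raw = cnv.bin_counts(record.bin_counts_path, genome, bin_size=bin_size)
        norm = cnv.normalize(raw)
        if reference_profile is not None:
            corrected = cnv.subtract_reference(norm, reference_profile)
        else:
            corrected = cnv.BinProfile(
                bins=norm.bins, values=norm.values, stage="corrected", mask=norm.mask
            )
        segments = cnv.segment(
            corrected, alpha=seg_alpha, min_bins=seg_min_bins,
            n_permutations=seg_permutations, seed=seed,
        )
        events = cnv.detect_focal_events(segments, annotations=annotations)
        report.copy_number = {
            "segments": segments.df.to_dict(orient="records"),
            "residual_sd": segments.residual_sd,
            "focal_events": [asdict(e) for e in events],
        }
        fit = cnv.estimate_purity(segments)
        report.purity = {
            "identifiable": fit.identifiable,
            "cellularity": fit.cellularity,
            "ploidy": fit.ploidy,
            "fit_error": fit.fit_error,
            "aneuploid_fraction": fit.aneuploid_fraction,
            "reason": fit.reason,
        }
    except Exception as exc:
        report.errors["copy_number"] = str(exc)

    return report


@dataclass
class CohortSummary:
    """Cohort table statistics plus cutoff calibration metrics."""

    n: int
    median_age: float
    age_range: tuple[int, int]
    sex_counts: dict[str, int]
    diagnosis_counts: dict[str, int]
    lesion_type_counts: dict[str, int]
    cases_passing_cutoff: int
    cutoff: float
    paper_sensitivity: float
    conventional_sensitivity: float | None
    specificity: float | None

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _lower_median(values: list[int]) -> float:
    ordered = sorted(values)
    return float(ordered[(len(ordered) - 1) // 2])


def summarize_cohort(
    records: list[CaseRecord] | pd.DataFrame,
    scored_cases: list[calibration.ScoredCase],
    cutoff: float = DEFAULT_CUTOFF,
) -> CohortSummary:
    """Cohort summary: lower-median age, min/max, categorical counts, and
    the calibration metrics at the given cutoff."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([asdict(r) for r in records])
    if len(df) < 1:
        raise ValueError("empty cohort")
    metrics = calibration.confusion_at_cutoff(scored_cases, cutoff)
    ages = df["age_years"].astype(int).tolist()
    return CohortSummary(
        n=len(df),
        median_age=_lower_median(ages),
        age_range=(min(ages), max(ages)),
        sex_counts=df["sex"].value_counts().to_dict(),
        diagnosis_counts=df["reference_diagnosis"].value_counts().to_dict(),
        lesion_type_counts=df["lesion_type"].value_counts().to_dict(),
        cases_passing_cutoff=metrics.counts.tp + metrics.counts.fp,
        cutoff=cutoff,
        paper_sensitivity=metrics.paper_sensitivity,
        conventional_sensitivity=metrics.conventional_sensitivity,
        specificity=metrics.specificity,
    )


def write_report(
    report: CaseReport, path: str | Path, format: str = "json"
) -> Path:
    """Serialize a case report deterministically (json, tsv or markdown)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        row = {
            "case_id": report.case_id,
            "age_years": report.record.get("age_years"),
            "sex": report.record.get("sex"),
            "location": report.record.get("location"),
            "reference_diagnosis": report.record.get("reference_diagnosis"),
            "lesion_type": report.record.get("lesion_type"),
            "pretreatment": report.record.get("pretreatment"),
            "mc": report.classification.get("mc"),
            "score_mc": report.classification.get("score_mc"),
            "mcf": report.classification.get("mcf"),
            "score_mcf": report.classification.get("score_mcf"),
            "passes_cutoff": report.classification.get("passes_cutoff"),
            "qc_passed": report.qc.get("passed"),
            "observed_cpgs": report.qc.get("observed_cpgs"),
            "purity": report.purity.get("cellularity"),
            "purity_identifiable": report.purity.get("identifiable"),
        }
        pd.DataFrame([row], columns=REPORT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif format == "markdown":
        lines = [f"# Case report: {report.case_id}", ""]
        for section in ("record", "qc", "classification", "copy_number", "purity",
                        "errors", "params"):
            content = getattr(report, section)
            lines.append(f"## {section}")
            lines.append("")
            if not content:
                lines.append("(empty)")
            else:
                for key in sorted(content):
                    lines.append(f"- **{key}**: {content[key]}")
            lines.append("")
        path.write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path: str | Path) -> CaseReport:
    data = json.loads(Path(path).read_text())
    return CaseReport(
        case_id=data["case_id"],
        record=data.get("record", {}),
        qc=data.get("qc", {}),
        classification=data.get("classification", {}),
        copy_number=data.get("copy_number", {}),
        purity=data.get("purity", {}),
        errors=data.get("errors", {}),
        params=data.get("params", {}),
    )
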