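"""Pre- and post-analytical quality control for core-level Ki67 scores.

Post-analytical rule set: a scored core is excluded when its total
nuclei count is below 50 or above 15,000, when its Ki67 score is exactly
100 % (all detected nuclei positive — in practice a staining problem),
or when no tissue was detected at all.  Boundary semantics are literal:
49 is excluded, 50 passes; 15,000 passes, 15,001 is excluded; 100 % is
an exact count condition (no negative nuclei, at least one positive),
never a floating-point comparison.

Pre-analytical control: each TMA carries three control cores (strongly
positive, negative, blank) whose scores must fall inside configurable
bands for the TMA to pass.

Pathologist QC categories: satisfactory invasive / satisfactory DCIS
(more than 500 malignant nuclei, no staining/folding/fixation issues)
versus suboptimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classifier import CoreResult

MIN_NUCLEI = 50
MAX_NUCLEI = 15_000
SATISFACTORY_NUCLEI = 500

CATEGORIES = ("satisfactory_invasive", "satisfactory_dcis", "suboptimal", "unknown")
ISSUE_FLAGS = ("membrane_staining", "cytoplasmic_staining", "background_staining", "folded", "poor_fixation")


@dataclass
class QCDecision:
    core_id: str
    status: str  # "pass" | "excluded"
    reasons: list[str] = field(default_factory=list)
    category: str = "unknown"

    def __post_init__(self) -> None:
        if self.status not in ("pass", "excluded"):
            raise ValueError("status must be 'pass' or 'excluded'")
        if self.status == "excluded" and not self.reasons:
            raise ValueError("an excluded core must carry at least one reason")
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")

    @property
    def stratum(self) -> str:
        """'satisfactory' / 'suboptimal' / 'unknown' for stratified analyses."""
        if self.category in ("satisfactory_invasive", "satisfactory_dcis"):
            return "satisfactory"
        return self.category


@dataclass
class PathologistAnnotation:
    """Visual QC annotation for one core."""

    core_id: str
    tumour_type: str | None = None  # "invasive" | "dcis" | None
    malignant_nuclei: int | None = None
    issues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.issues) - set(ISSUE_FLAGS)
        if bad:
            raise ValueError(f"unknown issue flags: {sorted(bad)}")
        if self.tumour_type not in (None, "invasive", "dcis"):
            raise ValueError("tumour_type must be 'invasive', 'dcis' or None")


def post_analytical_qc(
    result: CoreResult,
    min_nuclei: int = MIN_NUCLEI,
    max_nuclei: int = MAX_NUCLEI,
    category: str = "unknown",
) -> QCDecision:
    """Apply the count/score exclusion rules to one scored core."""
    reasons: list[str] = []
    total = result.total_nuclei
    if total == 0:
        reasons.append("no_tissue")
    elif total < min_nuclei:
        reasons.append("too_few_nuclei")
    if total > max_nuclei:
        reasons.append("too_many_nuclei")
    # exact 100 %: every detected nucleus positive, at least one detected
    if result.n_positive > 0 and result.n_negative == 0:
        reasons.append("score_100")
    status = "excluded" if reasons else "pass"
    return QCDecision(core_id=result.core_id, status=status, reasons=reasons, category=category)


def assign_category(annotation: PathologistAnnotation | None) -> str:
    """Map a pathologist annotation to the QC category.

    More than 500 malignant nuclei with no recorded issues is
    satisfactory (invasive or DCIS per the annotated tumour type);
    any staining/folding/fixation issue or 500 nuclei or fewer is
    suboptimal; no annotation is unknown.
    """
    if annotation is None:
        return "unknown"
    if annotation.malignant_nuclei is None and not annotation.issues:
        return "unknown"
    if annotation.issues:
        return "suboptimal"
    if annotation.malignant_nuclei is not None and annotation.malignant_nuclei <= SATISFACTORY_NUCLEI:
        return "suboptimal"
    if annotation.tumour_type == "dcis":
        return "satisfactory_dcis"
    if annotation.tumour_type == "invasive":
        return "satisfactory_invasive"
    raise ValueError(
        f"core {annotation.core_id}: >500 nuclei and no issues but tumour type missing"
    )


@dataclass
class ControlReport:
    tma_id: str
    passed: bool
    failures: list[str] = field(default_factory=list)
    positive_ki67: float | None = None
    negative_ki67: float | None = None
    blank_total: int | None = None


def check_controls(
    results: list[CoreResult],
    tma_id: str = "",
    min_positive_ki67: float = 50.0,
    max_negative_ki67: float = 5.0,
    max_blank_nuclei: int = MIN_NUCLEI,
) -> ControlReport:
    """TMA-level pre-analytical check on the three control cores.

    Pass requires: strongly positive control scores at least
    ``min_positive_ki67`` %, negative control at most
    ``max_negative_ki67`` %, blank control detects fewer than
    ``max_blank_nuclei`` nuclei.  Controls are exempt from the
    100 %-score exclusion and reported separately.
    """
    controls = {r.control_kind: r for r in results if r.is_control}
    failures: list[str] = []
    report = ControlReport(tma_id=tma_id, passed=True)
    for kind in ("positive", "negative", "blank"):
        if kind not in controls:
            failures.append(f"missing_{kind}_control")
    pos = controls.get("positive")
    if pos is not None:
        report.positive_ki67 = pos.ki67_percent
        if pos.ki67_percent is None or pos.ki67_percent < min_positive_ki67:
            failures.append("positive_control_too_low")
    neg = controls.get("negative")
    if neg is not None:
        report.negative_ki67 = neg.ki67_percent
        if neg.ki67_percent is None or neg.ki67_percent > max_negative_ki67:
            failures.append("negative_control_too_high")
    blank = controls.get("blank")
    if blank is not None:
        report.blank_total = blank.total_nuclei
        if blank.total_nuclei >= max_blank_nuclei:
            failures.append("blank_control_has_tissue")
    report.failures = failures
    report.passed = not failures
    return report
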