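"""Score-cutoff calibration for nanopore-based classification.

A case "passes" when its classification score is strictly greater than
the platform-specific cutoff. The confusion accounting treats a passing
concordant case as a true positive, a failing concordant case as a false
negative, a failing discordant case as a true negative and a passing
discordant case as a false positive.

Two sensitivity conventions coexist here. The operational one used for
reporting is tp / n_total — the fraction of all cases that pass the
cutoff and are correctly classified (this is the convention behind a
"79% sensitivity, 100% specificity" style summary on 19 cases with 15
passing). The conventional tp / (tp + fn) is computed alongside and
reported separately; the two differ whenever concordant cases fall below
the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScoredCase",
    "ConfusionCounts",
    "ConfusionMetrics",
    "RocPoint",
    "CutoffSelection",
    "confusion_at_cutoff",
    "roc_points",
    "roc_auc",
    "select_cutoff",
]


@dataclass(frozen=True)
class ScoredCase:
    """One classified case: score in [0,1] and whether the call matched
    the reference diagnosis."""

    case_id: str
    score: float
    concordant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int  # above cutoff & concordant
    fn: int  # below cutoff & concordant
    tn: int  # below cutoff & discordant
    fp: int  # above cutoff & discordant

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class ConfusionMetrics:
    counts: ConfusionCounts
    cutoff: float
    paper_sensitivity: float  # tp / n_total (operational convention)
    conventional_sensitivity: float | None  # tp / (tp + fn)
    specificity: float | None  # tn / (tn + fp); None when undefined
    specificity_defined: bool


def confusion_at_cutoff(cases: list[ScoredCase], cutoff: float) -> ConfusionMetrics:
    """Confusion counts and metrics at a strict (score > cutoff) cutoff."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    if not cases:
        raise ValueError("no scored cases")
    tp = sum(1 for c in cases if c.score > cutoff and c.concordant)
    fn = sum(1 for c in cases if c.score <= cutoff and c.concordant)
    tn = sum(1 for c in cases if c.score <= cutoff and not c.concordant)
    fp = sum(1 for c in cases if c.score > cutoff and not c.concordant)
    counts = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
    spec_defined = (tn + fp) > 0
    return ConfusionMetrics(
        counts=counts,
        cutoff=cutoff,
        paper_sensitivity=tp / counts.n_total,
        conventional_sensitivity=tp / (tp + fn) if (tp + fn) > 0 else None,
        specificity=tn / (tn + fp) if spec_defined else None,
        specificity_defined=spec_defined,
    )


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    sensitivity: float  # tp / n_total
    specificity: float


def roc_points(cases: list[ScoredCase]) -> list[RocPoint]:
    """One operating point per distinct score plus the all-pass endpoint.

    Requires at least one concordant and one discordant case (specificity
    is undefined otherwise). Points are ordered by increasing cutoff.
    """
    _require_both_outcomes(cases)
    cutoffs = sorted({0.0, 1.0} | {c.score for c in cases})
    points = []
    for cut in cutoffs:
        m = confusion_at_cutoff(cases, cut)
        points.append(
            RocPoint(cutoff=cut, sensitivity=m.paper_sensitivity, specificity=m.specificity)
        )
    return points


def roc_auc(cases: list[ScoredCase]) -> float:
    """Area under the conventional ROC curve (TPR = tp/(tp+fn),
    FPR = fp/(fp+tn)) by trapezoid integration over all distinct scores."""
    _require_both_outcomes(cases)
    scores = np.array([c.score for c in cases])
    pos = np.array([c.concordant for c in cases])
    # decreasing cutoff: TPR and FPR rise monotonically from (0,0) to (1,1)
    cuts = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1], [-np.inf]])
    tpr, fpr = [], []
    n_pos, n_neg = pos.sum(), (~pos).sum()
    for cut in cuts:
        passing = scores > cut
        tpr.append((passing & pos).sum() / n_pos)
        fpr.append((passing & ~pos).sum() / n_neg)
    return float(np.trapezoid(tpr, fpr))


@dataclass(frozen=True)
class CutoffSelection:
    cutoff: float
    interval: tuple[float, float]  # half-open cutoff range with identical confusion
    metrics: ConfusionMetrics
    criterion_met: bool
    note: str = ""


def select_cutoff(
    cases: list[ScoredCase],
    criterion: str = "max-sensitivity-at-full-specificity",
) -> CutoffSelection:
    """Choose a cutoff by sweeping the distinct-score intervals.

    With the strict > rule the confusion is constant for cutoffs within
    [s_i, s_{i+1}) between consecutive distinct scores; the default
    criterion maximizes the operational sensitivity subject to 100%
    specificity and returns the midpoint of the optimal interval, with
    the interval endpoints reported. If full specificity is unattainable
    the best achievable specificity is used and the result is flagged.
    """
    if criterion != "max-sensitivity-at-full-specificity":
        raise ValueError(f"unknown criterion {criterion!r}")
    _require_both_outcomes(cases)
    scores = sorted({c.score for c in cases})
    if len(scores) == 1:
        m = confusion_at_cutoff(cases, scores[0])
        return CutoffSelection(
            cutoff=scores[0], interval=(scores[0], scores[0]), metrics=m,
            criterion_met=False,
            note="degenerate input: all scores equal; no finite optimum",
        )
    candidates = sorted({0.0, *scores})
    edges = candidates + [1.0 if candidates[-1] < 1.0 else candidates[-1]]
    evals = [confusion_at_cutoff(cases, c) for c in candidates]

    full_spec = [
        i for i, m in enumerate(evals)
        if m.specificity_defined and m.specificity == 1.0
    ]
    if full_spec:
        best_sens = max(evals[i].paper_sensitivity for i in full_spec)
        optimal = [i for i in full_spec if evals[i].paper_sensitivity == best_sens]
        met, note = True, ""
    else:
        best_spec = max(
            (m.specificity for m in evals if m.specificity_defined), default=0.0
        )
        optimal = [
            i for i, m in enumerate(evals)
            if m.specificity_defined and m.specificity == best_spec
        ]
        best_sens = max(evals[i].paper_sensitivity for i in optimal)
        optimal = [i for i in optimal if evals[i].paper_sensitivity == best_sens]
        met = False
        note = f"full specificity unattainable; best achievable {best_spec:.3f}"

    # merge the first contiguous run of optimal intervals
    run = [optimal[0]]
    for i in optimal[1:]:
        if i == run[-1] + 1:
            run.append(i)
        else:
            break
    lo = candidates[run[0]]
    hi = edges[run[-1] + 1]
    mid = (lo + hi) / 2.0
    return CutoffSelection(
        cutoff=mid,
        interval=(lo, hi),
        metrics=confusion_at_cutoff(cases, mid),
        criterion_met=met,
        note=note,
    )


def _require_both_outcomes(cases: list[ScoredCase]) -> None:
    if not cases:
        raise ValueError("no scored cases")
    n_conc = sum(c.concordant for c in cases)
    if n_conc == 0 or n_conc == len(cases):
        raise ValueError(
            "ROC analysis requires at least one concordant and one discordant case"
        )
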