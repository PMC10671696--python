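"""Diagnostic-performance statistics.

Confusion matrices and the usual derived metrics (sensitivity,
specificity, PPV, NPV, accuracy, prevalence), two-sided Fisher exact
tests, empirical ROC curves with trapezoidal AUC and Youden-optimal
cutoffs, and an exhaustive integer reconstruction of confusion matrices
from rounded published percentages.

Percentages are rendered half-up to one decimal; the same rounding rule
drives the reconstruction search, so a matrix "matches" a published row
exactly when each of its metrics reproduces the printed value.  Ratios
are carried as exact :class:`fractions.Fraction` values internally so
the rounding is never at the mercy of binary floating point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig, default_config
from .lipids import combined_criterion, intensity_criterion
from .models import Subject

Number = Union[int, float, Fraction]


def round_half_up_percent(value: Number, ndigits: int = 1) -> float:
    """Render a fraction in [0, 1] as a percentage, rounded half-up.

    ``Fraction`` inputs are rounded exactly; floats are first snapped to
    their shortest decimal representation so that e.g. 0.845 -> 84.5.
    """
    if not isinstance(value, Fraction):
        value = Fraction(repr(float(value)))
    scaled = value * 100 * 10**ndigits
    return float(math.floor(scaled + Fraction(1, 2))) / 10**ndigits


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 or c != int(c) for c in counts):
            raise ValueError("confusion-matrix counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("confusion matrix must contain at least one subject")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Exact metric ratios; ``None`` marks an undefined (0-denominator) metric."""

    sensitivity: Optional[Fraction]
    specificity: Optional[Fraction]
    ppv: Optional[Fraction]
    npv: Optional[Fraction]
    accuracy: Fraction
    prevalence: Fraction

    def as_percent(self, ndigits: int = 1) -> Dict[str, Optional[float]]:
        out: Dict[str, Optional[float]] = {}
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "prevalence"):
            value = getattr(self, name)
            out[name] = None if value is None else round_half_up_percent(value, ndigits)
        return out


def confusion(
    truth: Sequence[Optional[bool]], calls: Sequence[Optional[bool]]
) -> Tuple[ConfusionMatrix, int]:
    """Count a 2x2 confusion matrix over paired truth/call flags.

    Pairs where either value is missing (``None``) are excluded; the
    number excluded is returned alongside the matrix.
    """
    if len(truth) != len(calls):
        raise ValueError("truth and calls must have equal length")
    if len(truth) == 0:
        raise ValueError("empty input")
    tp = fp = fn = tn = excluded = 0
    for t, c in zip(truth, calls):
        if t is None or c is None:
            excluded += 1
        elif t and c:
            tp += 1
        elif t and not c:
            fn += 1
        elif not t and c:
            fp += 1
        else:
            tn += 1
    if tp + fp + fn + tn == 0:
        raise ValueError("no complete truth/call pairs")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn), excluded


def _ratio(num: int, den: int) -> Optional[Fraction]:
    return None if den == 0 else Fraction(num, den)


def metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Standard diagnostic metrics as exact fractions."""
    return DiagnosticMetrics(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=Fraction(cm.tp + cm.tn, cm.n),
        prevalence=Fraction(cm.tp + cm.fn, cm.n),
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities
    no greater than the observed table's)."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("Fisher test needs a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve for a 'higher score = more diseased' marker."""

    thresholds: Tuple[float, ...]
    sensitivity: Tuple[float, ...]
    specificity: Tuple[float, ...]
    auc: float
    youden_threshold: float = field(default=float("nan"))
    youden_j: float = field(default=float("nan"))


def roc(scores: Sequence[float], truth: Sequence[bool]) -> ROCCurve:
    """Empirical ROC curve with midpoint thresholds and trapezoidal AUC.

    A subject is called positive when its score is >= the threshold.
    Thresholds are the midpoints between consecutive distinct observed
    scores plus sentinels below the minimum and above the maximum, so
    every achievable (sensitivity, specificity) operating point appears
    exactly once.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-d sequences")
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("truth must contain both classes")

    uniq = np.unique(s)
    cut = np.concatenate(
        ([uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0])
    )
    se = np.array([(s[t] >= c).mean() for c in cut])
    sp = np.array([(s[~t] < c).mean() for c in cut])
    # walking thresholds downward, sensitivity and FPR are both
    # non-decreasing, tracing the ROC polyline in order; trapezoid over
    # it equals the rank (Mann-Whitney) AUC including tie handling
    fpr = 1.0 - sp
    auc = float(np.trapezoid(se[::-1], fpr[::-1]))

    j = se + sp - 1.0
    # argmax over ascending thresholds: first maximum = lowest threshold,
    # i.e. ties break toward the more sensitive operating point
    best = int(np.argmax(j))
    return ROCCurve(
        thresholds=tuple(cut),
        sensitivity=tuple(se),
        specificity=tuple(sp),
        auc=auc,
        youden_threshold=float(cut[best]),
        youden_j=float(j[best]),
    )


def youden_optimal(curve: ROCCurve) -> Tuple[float, float]:
    """The threshold maximising J = sensitivity + specificity - 1."""
    return curve.youden_threshold, curve.youden_j


def reconstruct_confusion(
    rounded_metrics: Dict[str, float], n_max: int = 60, ndigits: int = 1
) -> List[ConfusionMatrix]:
    """Enumerate integer confusion matrices consistent with rounded metrics.

    ``rounded_metrics`` maps metric names (``sensitivity``,
    ``specificity``, ``ppv``, ``npv``, ``accuracy``, ``prevalence``) to
    their published percentages (half-up, ``ndigits`` decimals).  Every
    matrix with n <= ``n_max`` whose metrics reproduce all supplied
    values is returned, ordered by n (then lexicographically), so the
    first element is the smallest consistent study.
    """
    known = {k: float(v) for k, v in rounded_metrics.items()}
    valid = {"sensitivity", "specificity", "ppv", "npv", "accuracy", "prevalence"}
    unknown = set(known) - valid
    if unknown:
        raise ValueError(f"unknown metric names: {sorted(unknown)}")
    if len(known) < 2:
        raise ValueError("need at least two metrics to constrain the matrix")

    def ok(name: str, num: int, den: int) -> bool:
        if name not in known:
            return True
        if den == 0:
            return False
        return round_half_up_percent(Fraction(num, den), ndigits) == known[name]

    solutions: List[ConfusionMatrix] = []
    for pos in range(0, n_max + 1):
        for tp in range(0, pos + 1):
            fn = pos - tp
            if not ok("sensitivity", tp, pos):
                continue
            for neg in range(0, n_max - pos + 1):
                if pos + neg == 0:
                    continue
                for tn in range(0, neg + 1):
                    fp = neg - tn
                    if not ok("specificity", tn, neg):
                        continue
                    if not ok("ppv", tp, tp + fp):
                        continue
                    if not ok("npv", tn, tn + fn):
                        continue
                    n = pos + neg
                    if not ok("accuracy", tp + tn, n):
                        continue
                    if not ok("prevalence", pos, n):
                        continue
                    solutions.append(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
    solutions.sort(key=lambda m: (m.n, m.tp, m.fp, m.fn, m.tn))
    return solutions


# ---------------------------------------------------------------------------
# Cohort-level evaluation

#: Criteria evaluated against the genetic result by default: the five
#: clinical instruments plus the pretreatment-LDL cutoff, the
#: treatment-intensity rule and their conjunction.
DEFAULT_EVAL_CRITERIA = (
    "SimonBroome",
    "MEDPED",
    "JFHMC",
    "HK_panel",
    "ldl_5.5",
    "intensity",
    "combined",
    "DLCNC",
    "modified_DLCNC",
)


def _masked(subject: Subject) -> Subject:
    """Blind a subject's genetic result before clinical scoring (the
    genotype is the truth the criteria are judged against)."""
    if subject.genetic is None:
        return subject
    return subject.model_copy(update={"genetic": None})


def _criterion_call(
    name: str, subject: Subject, config: RunConfig
) -> Optional[bool]:
    from . import criteria as ce  # local import to avoid a cycle

    blind = _masked(subject)
    try:
        if name == "DLCNC":
            return ce.score_dlcnc(blind, config).binary_call
        if name == "modified_DLCNC":
            return ce.score_modified_dlcnc(blind, config).binary_call
        if name == "SimonBroome":
            return ce.classify_simon_broome(blind, config).binary_call
        if name == "MEDPED":
            return ce.classify_medped(blind, config).binary_call
        if name == "JFHMC":
            return ce.classify_jfhmc(blind, config).binary_call
        if name == "HK_panel":
            return ce.classify_hk_panel(blind, config).binary_call
        if name == "ldl_5.5":
            ldl, _ = ce.select_ldl_for_scoring(blind, config)
            return ldl >= config.intensity.combined_ldl_cutoff
        if name == "intensity":
            return intensity_criterion(subject, config.intensity)
        if name == "combined":
            return combined_criterion(subject, config.intensity)
    except Exception:
        return None
    raise ValueError(f"unknown criterion {name!r}")


def evaluate_criteria_on_cohort(
    subjects: Iterable[Subject],
    criteria: Sequence[str] = DEFAULT_EVAL_CRITERIA,
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Per-criterion diagnostic performance against the genetic result.

    Subjects without a genetic result are dropped; subjects missing a
    criterion's inputs are excluded from that row only, so each row
    reports its own effective n and prevalence.  The Fisher p is on the
    criterion-call x genotype 2x2 table.
    """
    cfg = config if config is not None else default_config()
    cohort = [s for s in subjects if s.genetic_positive is not None]
    if not cohort:
        raise ValueError("no genetically tested subjects to evaluate")
    truth = [s.genetic_positive for s in cohort]
    rows = []
    for name in criteria:
        calls = [_criterion_call(name, s, cfg) for s in cohort]
        cm, excluded = confusion(truth, calls)
        m = metrics(cm).as_percent()
        p = fisher_exact([[cm.tp, cm.fn], [cm.fp, cm.tn]])
        rows.append(
            {
                "criterion": name,
                "n": cm.n,
                "excluded": excluded,
                "tp": cm.tp,
                "fp": cm.fp,
                "fn": cm.fn,
                "tn": cm.tn,
                **m,
                "fisher_p": round(p, 3),
            }
        )
    return pd.DataFrame(rows)
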