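"""Diagnostic-accuracy measures with confidence intervals.

The positive class throughout is beta-thalassemia trait (BTT): a confusion
matrix counts tp = true BTT called BTT, fp = IDA called BTT, etc.  Thirteen
measures are derived: sensitivity, specificity, FPR, FNR, PPV, NPV, Youden's
J (sens + spec - 1), accuracy, F-measure, the likelihood ratios
PLR = sens/(1-spec) and NLR = (1-sens)/spec, the diagnostic odds ratio
DOR = PLR/NLR = (tp*tn)/(fp*fn) (+inf when a classifier makes no false
negatives or no false positives), and AUC.  For a hard binary classifier the
empirical AUC collapses to (sensitivity + specificity)/2 = (J + 1)/2.

Confidence intervals: Clopper-Pearson exact intervals for proportions, the
standard log-method for PLR/NLR/DOR, and a stratified binomial bootstrap for
Youden/accuracy/F (no closed-form convention exists for those).

``recover_confusion_from_summary`` inverts published (Youden, accuracy)
pairs back to the integer confusion matrix when the class sizes are known
and unequal — with sizes in the hundreds the 2-decimal summary determines
the matrix uniquely, which is what makes published accuracy tables
re-derivable without patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import BTT, IDA

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "RocCurve",
    "confusion",
    "metric_set",
    "metric_cis",
    "empirical_auc",
    "compare_auc",
    "recover_confusion_from_summary",
    "recover_confusion_best",
    "ReconstructionError",
]

_Z = {0.95: 1.959963984540054}


def _zvalue(level: float) -> float:
    return _Z.get(level) or float(stats.norm.ppf(0.5 + level / 2))


class ReconstructionError(ValueError):
    """Published summary values admit no consistent integer confusion matrix."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionMatrix:
    """2x2 counts with BTT as the positive class."""
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    tp = fp = fn = tn = 0
    for t, p in zip(truth, predicted):
        if t not in (IDA, BTT) or p not in (IDA, BTT):
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        if t == BTT:
            tp += p == BTT
            fn += p == IDA
        else:
            fp += p == BTT
            tn += p == IDA
    return ConfusionMatrix(tp, fp, fn, tn)


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    fpr: float
    fnr: float
    ppv: float
    npv: float
    youden: float
    accuracy: float
    f_measure: float
    plr: float
    nlr: float
    dor: float
    auc: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in MEASURES}


MEASURES = (
    "sensitivity", "specificity", "fpr", "fnr", "ppv", "npv",
    "youden", "accuracy", "plr", "nlr", "dor", "f_measure", "auc",
)


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    """All thirteen measures from a confusion matrix (proportions in [0,1]).

    Requires both classes present.  PPV/NPV are NaN-flagged (never silently
    wrong) when no prediction of the corresponding kind was made; DOR is
    +inf when fn = 0 or fp = 0 with a non-zero numerator.
    """
    if cm.n_pos == 0 or cm.n_neg == 0:
        raise ValueError("both classes must be present (tp+fn > 0 and tn+fp > 0)")
    sens = cm.tp / cm.n_pos
    spec = cm.tn / cm.n_neg
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    plr = _ratio(sens, 1 - spec)
    nlr = _ratio(1 - sens, spec)
    dor = _ratio(cm.tp * cm.tn, cm.fp * cm.fn)
    f = _ratio(2 * ppv * sens, ppv + sens) if math.isfinite(ppv) else math.nan
    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        fpr=1 - spec,
        fnr=1 - sens,
        ppv=ppv,
        npv=npv,
        youden=sens + spec - 1,
        accuracy=(cm.tp + cm.tn) / cm.n,
        f_measure=f,
        plr=plr,
        nlr=nlr,
        dor=dor,
        auc=(sens + spec) / 2,  # hard binary classifier
    )


# ---------------------------------------------------------------------------
# Confidence intervals

def _clopper_pearson(x: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def _log_ratio_ci(value: float, cells: tuple[float, ...], level: float,
                  se_terms: tuple[float, ...]) -> tuple[float, float]:
    if not math.isfinite(value) or value <= 0 or any(c == 0 for c in cells):
        return (math.nan, math.nan)
    se = math.sqrt(sum(se_terms))
    z = _zvalue(level)
    return (value * math.exp(-z * se), value * math.exp(z * se))


def metric_cis(
    cm: ConfusionMatrix,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """95% (by default) confidence intervals for every measure.

    Degenerate counts yield one-sided Clopper-Pearson bounds naturally; ratio
    CIs with an empty cell are returned as (nan, nan) rather than silently
    fabricated.
    """
    m = metric_set(cm)
    out: dict[str, tuple[float, float]] = {}
    out["sensitivity"] = _clopper_pearson(cm.tp, cm.n_pos, level)
    out["specificity"] = _clopper_pearson(cm.tn, cm.n_neg, level)
    out["fnr"] = tuple(1 - b for b in reversed(out["sensitivity"]))
    out["fpr"] = tuple(1 - b for b in reversed(out["specificity"]))
    out["ppv"] = (
        _clopper_pearson(cm.tp, cm.tp + cm.fp, level)
        if cm.tp + cm.fp else (math.nan, math.nan)
    )
    out["npv"] = (
        _clopper_pearson(cm.tn, cm.tn + cm.fn, level)
        if cm.tn + cm.fn else (math.nan, math.nan)
    )
    out["plr"] = _log_ratio_ci(
        m.plr, (cm.tp, cm.fp), level,
        (1 / cm.tp - 1 / cm.n_pos, 1 / cm.fp - 1 / cm.n_neg)
        if cm.tp and cm.fp else (math.nan,),
    )
    out["nlr"] = _log_ratio_ci(
        m.nlr, (cm.fn, cm.tn), level,
        (1 / cm.fn - 1 / cm.n_pos, 1 / cm.tn - 1 / cm.n_neg)
        if cm.fn and cm.tn else (math.nan,),
    )
    out["dor"] = _log_ratio_ci(
        m.dor, (cm.tp, cm.fp, cm.fn, cm.tn), level,
        (1 / cm.tp, 1 / cm.fp, 1 / cm.fn, 1 / cm.tn)
        if all((cm.tp, cm.fp, cm.fn, cm.tn)) else (math.nan,),
    )
    # stratified binomial bootstrap for the composite measures
    rng = np.random.default_rng(seed)
    sens_b = rng.binomial(cm.n_pos, m.sensitivity, size=n_boot) / cm.n_pos
    spec_b = rng.binomial(cm.n_neg, m.specificity, size=n_boot) / cm.n_neg
    p = cm.n_pos / cm.n
    youden_b = sens_b + spec_b - 1
    acc_b = p * sens_b + (1 - p) * spec_b
    tp_b = sens_b * cm.n_pos
    fp_b = (1 - spec_b) * cm.n_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv_b = tp_b / (tp_b + fp_b)
        f_b = 2 * ppv_b * sens_b / (ppv_b + sens_b)
    qs = (100 * (1 - level) / 2, 100 * (1 + level) / 2)
    out["youden"] = tuple(np.percentile(youden_b, qs))
    out["accuracy"] = tuple(np.percentile(acc_b, qs))
    out["f_measure"] = (
        tuple(np.nanpercentile(f_b, qs))
        if np.isfinite(f_b).any() else (math.nan, math.nan)
    )
    out["auc"] = tuple(np.percentile((youden_b + 1) / 2, qs))
    return out


# ---------------------------------------------------------------------------
# ROC / AUC

HIGHER_IS_BTT = "higher-is-BTT"
LOWER_IS_BTT = "lower-is-BTT"


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    se: float
    scores: np.ndarray  # oriented so higher predicts BTT (kept for pairing)
    truth: np.ndarray   # boolean, True = BTT


def empirical_auc(
    scores: Sequence[float],
    truth: Sequence[str],
    direction: str = HIGHER_IS_BTT,
) -> RocCurve:
    """Empirical ROC curve by threshold sweep; AUC is the Mann-Whitney
    concordance probability (ties counted 1/2), with Hanley-McNeil SE."""
    from sklearn.metrics import roc_curve as _sk_roc

    scores = np.asarray(scores, dtype=float)
    y = np.asarray([t == BTT for t in truth])
    if not any(t in (IDA, BTT) for t in truth) or len(set(truth)) < 2:
        raise ValueError("both classes must be present in truth")
    if direction == LOWER_IS_BTT:
        scores = -scores
    elif direction != HIGHER_IS_BTT:
        raise ValueError(f"unknown direction {direction!r}")
    fpr, tpr, thr = _sk_roc(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    n1 = int(y.sum())
    n2 = len(y) - n1
    q1 = auc / (2 - auc)
    q2 = 2 * auc * auc / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n2 - 1) * (q2 - auc**2))
    se = math.sqrt(max(var, 0.0) / (n1 * n2))
    return RocCurve(fpr, tpr, thr, auc, se, scores, y)


def _delong_structural_components(y: np.ndarray, scores: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[y]
    neg = scores[~y]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (ranks[m:] - neg_ranks) / m
    auc = v10.mean()
    return auc, v10, v01


def compare_auc(curve_a: RocCurve, curve_b: RocCurve) -> tuple[float, float]:
    """Paired DeLong test of AUC difference; returns (z, two-sided p).

    Both curves must come from the same patients in the same order (identical
    truth vectors).  Swapping the arguments negates z.
    """
    if len(curve_a.truth) != len(curve_b.truth) or not np.array_equal(
        curve_a.truth, curve_b.truth
    ):
        raise ValueError("curves are not paired on the same truth vector")
    y = curve_a.truth
    auc_a, v10a, v01a = _delong_structural_components(y, curve_a.scores)
    auc_b, v10b, v01b = _delong_structural_components(y, curve_b.scores)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0 or math.isclose(var, 0.0):
        return (0.0, 1.0) if math.isclose(diff, 0.0) else (math.copysign(math.inf, diff), 0.0)
    z = diff / math.sqrt(var)
    p = 2 * float(stats.norm.sf(abs(z)))
    return z, p


# ---------------------------------------------------------------------------
# Summary -> confusion matrix reconstruction

def _solve_sens_spec(youden: float, accuracy: float, n_pos: int, n_neg: int):
    p = n_pos / (n_pos + n_neg)
    j, a = youden / 100.0, accuracy / 100.0
    sens = (a - (1 - p) * (1 + j)) / (2 * p - 1)
    spec = (1 + j) - sens
    return sens, spec


def _summary(tp: int, tn: int, n_pos: int, n_neg: int) -> tuple[float, float]:
    j = 100 * (tp / n_pos + tn / n_neg - 1)
    a = 100 * (tp + tn) / (n_pos + n_neg)
    return j, a


def recover_confusion_best(
    youden: float, accuracy: float, n_pos: int, n_neg: int
) -> tuple[ConfusionMatrix, float, float]:
    """Nearest integer confusion matrix to published (Youden %, accuracy %).

    Returns (matrix, Youden residual, accuracy residual) where the residuals
    are published-minus-rederived in percentage points.  Searches the 3x3
    integer neighbourhood of the closed-form solution and minimises the
    worst residual.
    """
    if n_pos == n_neg:
        raise ReconstructionError("class sizes must differ (system is singular)")
    sens, spec = _solve_sens_spec(youden, accuracy, n_pos, n_neg)
    # inputs are rounded to 2 decimals, which can push the implied rates
    # marginally past the unit interval; tolerate that and clamp
    slack = 0.01 / abs(2 * n_pos / (n_pos + n_neg) - 1) / 100
    if not (-slack <= sens <= 1 + slack and -slack <= spec <= 1 + slack):
        raise ReconstructionError(
            f"implied sensitivity {sens:.4f} / specificity {spec:.4f} "
            "outside [0, 1]: inconsistent inputs"
        )
    tp0 = int(round(min(max(sens, 0.0), 1.0) * n_pos))
    tn0 = int(round(min(max(spec, 0.0), 1.0) * n_neg))
    best = None
    for tp in range(max(tp0 - 1, 0), min(tp0 + 1, n_pos) + 1):
        for tn in range(max(tn0 - 1, 0), min(tn0 + 1, n_neg) + 1):
            j, a = _summary(tp, tn, n_pos, n_neg)
            score = max(abs(j - youden), abs(a - accuracy))
            if best is None or score < best[0]:
                best = (score, tp, tn, youden - j, accuracy - a)
    _, tp, tn, dj, da = best
    return ConfusionMatrix(tp, n_neg - tn, n_pos - tp, tn), dj, da


def recover_confusion_from_summary(
    youden: float, accuracy: float, n_pos: int, n_neg: int, tol: float = 0.005
) -> ConfusionMatrix:
    """Invert (Youden %, accuracy %) to the integer confusion matrix.

    Verifies that the re-derived summary reproduces the inputs to 2 decimals
    (|residual| <= ``tol`` percentage points) and raises
    :class:`ReconstructionError` otherwise.
    """
    cm, dj, da = recover_confusion_best(youden, accuracy, n_pos, n_neg)
    if abs(dj) > tol + 1e-9 or abs(da) > tol + 1e-9:
        raise ReconstructionError(
            f"no integer matrix reproduces Youden={youden} and accuracy="
            f"{accuracy} with sizes {n_pos}/{n_neg} "
            f"(best residuals {dj:+.3f}, {da:+.3f})"
        )
    return cm
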