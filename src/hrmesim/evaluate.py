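"""Diagnostic-agreement and image-quality statistics.

Everything needed to evaluate a binary device call against a clinical
comparator with a histopathology gold standard: the stratified 2x2x3
agreement table, sensitivity/specificity with Wilson score intervals,
exact McNemar on paired discordants, Cohen's kappa, ROC/PR analysis
with sensitivity-matched operating points, a two-proportion chi-square,
QC accounting, Weber contrast and blank-target noise floor.

Proportion statistics delegate to statsmodels/sklearn/scipy where those
provide the standard routine; the table bookkeeping and the operating
point logic are local.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AgreementTable",
    "printed_agreement_fixture",
    "DiagnosticSummary",
    "ROCResult",
    "diagnostics_from_table",
    "wilson_interval",
    "mcnemar_exact",
    "cohens_kappa",
    "roc_analysis",
    "matched_operating_point",
    "two_proportion_chisq",
    "qc_failure_fraction",
    "weber_fraction",
    "noise_floor",
    "UndefinedStatisticError",
]

SEVERITY_ORDER = ("benign", "AIN1", "AIN2+")


class UndefinedStatisticError(ZeroDivisionError):
    """A statistic's denominator is zero; the message names the statistic."""


@dataclass(frozen=True)
class AgreementTable:
    """Counts indexed by (device call, comparator call, severity class).

    ``counts[d, h, c]`` with d, h in {0: negative, 1: positive} and
    c indexing (benign, AIN1, AIN2+).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (2, 2, 3):
            raise ValueError("counts must have shape (2, 2, 3)")
        if (c < 0).any():
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def class_totals(self) -> np.ndarray:
        """Per-severity-class site counts (benign, AIN1, AIN2+)."""
        return self.counts.sum(axis=(0, 1))

    def collapsed(self) -> np.ndarray:
        """2x2 device x comparator table summed over severity classes."""
        return self.counts.sum(axis=2)

    def device_positive(self) -> np.ndarray:
        """Device-positive count per class."""
        return self.counts[1].sum(axis=0)

    def hra_positive(self) -> np.ndarray:
        return self.counts[:, 1, :].sum(axis=0)


def printed_agreement_fixture() -> AgreementTable:
    """The published 2x2x3 agreement counts of the 104-site analysis set.

    Rows are (device call, comparator call); columns are the severity
    classes (benign n=11, AIN1 n=71, AIN2+ n=22); grand total 104.
    """
    counts = np.zeros((2, 2, 3), dtype=int)
    counts[0, 0] = (7, 34, 0)   # device -, HRA -
    counts[0, 1] = (2, 28, 2)   # device -, HRA +
    counts[1, 0] = (0, 2, 2)    # device +, HRA -
    counts[1, 1] = (2, 7, 18)   # device +, HRA +
    return AgreementTable(counts=counts)


@dataclass
class DiagnosticSummary:
    """Headline agreement diagnostics for one stratified table."""

    n_sites: int
    device_sensitivity: float
    device_specificity: float
    hra_sensitivity: float
    hra_specificity: float
    device_sensitivity_ci: tuple[float, float]
    device_specificity_ci: tuple[float, float]
    agreement_count: int
    agreement_fraction: float
    kappa: float
    prevalence: float
    discordant_count: int
    discordant_ain1_fraction: float
    fractions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Point statistics rounded the way clinical tables print them."""
        return {
            "device_sensitivity": round(self.device_sensitivity, ndigits),
            "device_specificity": round(self.device_specificity, ndigits),
            "hra_sensitivity": round(self.hra_sensitivity, ndigits),
            "hra_specificity": round(self.hra_specificity, ndigits),
            "kappa": round(self.kappa, ndigits),
            "agreement_fraction": round(self.agreement_fraction, ndigits),
            "prevalence": round(self.prevalence, ndigits),
        }


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    # closed-form boundaries are exact; remove round-off from the solver
    lo = 0.0 if k == 0 else float(np.clip(lo, 0.0, 1.0))
    hi = 1.0 if k == n else float(np.clip(hi, 0.0, 1.0))
    return lo, hi


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value from the two discordant counts.

    p = min(1, 2 P(X <= min(b, c))) for X ~ Binomial(b + c, 1/2);
    p = 1 when there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return 1.0
    p = 2.0 * stats.binom.cdf(min(b, c), n, 0.5)
    return float(min(1.0, p))


def cohens_kappa(cross_table: np.ndarray) -> float:
    """Cohen's kappa for a 2x2 (or KxK) rater agreement table."""
    t = np.asarray(cross_table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("cross_table must be square")
    total = t.sum()
    if total == 0:
        raise ValueError("cross_table has no observations")
    po = np.trace(t) / total
    pe = float((t.sum(axis=1) / total) @ (t.sum(axis=0) / total))
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def diagnostics_from_table(table: AgreementTable,
                           ci_level: float = 0.95) -> DiagnosticSummary:
    """Compute every headline diagnostic from the stratified table.

    The positive class is AIN2+ (last severity column); negatives pool
    benign and AIN1.  Device sensitivity = device-positive AIN2+ sites /
    all AIN2+ sites, specificity = device-negative negatives / all
    negatives, and likewise for the comparator.
    """
    c = table.counts
    if table.total == 0:
        raise UndefinedStatisticError("diagnostics: empty table")
    n_pos = int(c[:, :, 2].sum())
    n_neg = int(c[:, :, :2].sum())
    if n_pos == 0:
        raise UndefinedStatisticError("sensitivity: no positive-class sites")
    if n_neg == 0:
        raise UndefinedStatisticError("specificity: no negative-class sites")

    dev_tp = int(c[1, :, 2].sum())
    dev_tn = int(c[0, :, :2].sum())
    hra_tp = int(c[:, 1, 2].sum())
    hra_tn = int(c[:, 0, :2].sum())

    agree = int(c[0, 0].sum() + c[1, 1].sum())
    discord = table.total - agree
    # AIN1 sites called negative by the device but positive by the
    # comparator: the dominant discordance mode (over-calling of
    # low-grade disease by visual impression)
    discord_ain1 = int(c[0, 1, 1])

    return DiagnosticSummary(
        n_sites=table.total,
        device_sensitivity=dev_tp / n_pos,
        device_specificity=dev_tn / n_neg,
        hra_sensitivity=hra_tp / n_pos,
        hra_specificity=hra_tn / n_neg,
        device_sensitivity_ci=wilson_interval(dev_tp, n_pos, ci_level),
        device_specificity_ci=wilson_interval(dev_tn, n_neg, ci_level),
        agreement_count=agree,
        agreement_fraction=agree / table.total,
        kappa=cohens_kappa(table.collapsed()),
        prevalence=n_pos / table.total,
        discordant_count=discord,
        discordant_ain1_fraction=discord_ain1 / discord if discord else 0.0,
        fractions={
            "device_sensitivity": (dev_tp, n_pos),
            "device_specificity": (dev_tn, n_neg),
            "hra_sensitivity": (hra_tp, n_pos),
            "hra_specificity": (hra_tn, n_neg),
            "agreement": (agree, table.total),
            "prevalence": (n_pos, table.total),
            "discordant_ain1": (discord_ain1, discord),
        },
    )


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    pr_auc: float


def roc_analysis(scores, labels) -> ROCResult:
    """ROC and precision-recall analysis with score >= threshold positivity.

    AUC equals the Mann-Whitney statistic (ties get half credit); PR-AUC
    is the step integral of the precision-recall curve.  Thresholds are
    the unique score values plus a sentinel above the maximum (the
    all-negative operating point).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    uniq = np.unique(scores)
    thresholds = np.concatenate([uniq, [uniq[-1] + 1.0]])[::-1]
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    sens = np.array([(scores[labels] >= t).sum() / n_pos for t in thresholds])
    spec = np.array([(scores[~labels] < t).sum() / n_neg for t in thresholds])
    auc = float(roc_auc_score(labels, scores))
    pr_auc = float(average_precision_score(labels, scores))
    return ROCResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        pr_auc=pr_auc,
    )


def matched_operating_point(roc: ROCResult, target_sensitivity: float
                            ) -> tuple[float, float, float, bool]:
    """Threshold matching a comparator's sensitivity.

    Among thresholds whose sensitivity is at least the target, returns
    the one with maximal specificity (ties broken toward the higher
    threshold).  Returns (threshold, sensitivity, specificity, matched);
    ``matched`` is False when no threshold attains the target, in which
    case the maximum-sensitivity point is reported.
    """
    if not 0 <= target_sensitivity <= 1:
        raise ValueError("target sensitivity must be in [0, 1]")
    ok = roc.sensitivities >= target_sensitivity
    if not ok.any():
        i = int(np.argmax(roc.sensitivities))
        return (float(roc.thresholds[i]), float(roc.sensitivities[i]),
                float(roc.specificities[i]), False)
    cand = np.flatnonzero(ok)
    best_spec = roc.specificities[cand].max()
    # ties toward higher threshold: thresholds are sorted descending
    i = int(cand[np.flatnonzero(roc.specificities[cand] == best_spec)[0]])
    return (float(roc.thresholds[i]), float(roc.sensitivities[i]),
            float(roc.specificities[i]), True)


def two_proportion_chisq(k1: int, n1: int, k2: int, n2: int,
                         correction: bool = False) -> float:
    """Pearson chi-square p-value comparing two binomial proportions."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n with n > 0")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise UndefinedStatisticError("chi-square: degenerate pooled proportion")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.pvalue)


def qc_failure_fraction(n_imaged: int, n_passed: int) -> float:
    """Fraction of imaged sites failing quality control, as a percentage
    rounded to one decimal (e.g. 109 imaged / 104 passed -> 4.6)."""
    if n_imaged <= 0:
        raise ValueError("n_imaged must be positive")
    if not 0 <= n_passed <= n_imaged:
        raise ValueError("need 0 <= n_passed <= n_imaged")
    return round(100.0 * (n_imaged - n_passed) / n_imaged, 1)


def weber_fraction(image, fg_mask, bg_mask) -> float:
    """Weber contrast (mean foreground - mean background) / mean background."""
    px = np.asarray(getattr(image, "pixels", image), dtype=float)
    fg = np.asarray(fg_mask, dtype=bool)
    bg = np.asarray(bg_mask, dtype=bool)
    if not fg.any() or not bg.any():
        raise ValueError("masks must be nonempty")
    if (fg & bg).any():
        raise ValueError("masks must be disjoint")
    mb = px[bg].mean()
    if mb == 0:
        raise UndefinedStatisticError("weber fraction: zero background mean")
    return float((px[fg].mean() - mb) / mb)


def noise_floor(blank) -> float:
    """Standard deviation of a blank-target image's pixel intensities."""
    px = np.asarray(getattr(blank, "pixels", blank), dtype=float)
    if px.size == 0:
        raise ValueError("empty frame")
    return float(px.std())
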