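"""Synthetic site cohorts: per-site clinical records with programmed
class structure, device-score distributions and rater confusion.

A "site" is one biopsied location with a histopathology grade, the
anoscopy (HRA) impression, a device probability score, and a quality
flag.  Severity tiers collapse the six histopathology grades into the
three used by the analysis: benign, AIN1 (low grade, including
condyloma), and AIN2+ (grade 2 or worse, the positive class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import AgreementTable, printed_agreement_fixture  # noqa: F401

__all__ = [
    "HISTOPATHOLOGY_GRADES",
    "SEVERITY_CLASSES",
    "severity_from_histopathology",
    "SiteRecord",
    "ClassScoreSpec",
    "CohortSpec",
    "generate_site_cohort",
    "cohort_to_dataframe",
    "write_cohort_csv",
    "read_cohort_csv",
    "agreement_table_from_cohort",
]

HISTOPATHOLOGY_GRADES = ("benign", "AIN1", "condyloma", "AIN2", "AIN3", "cancer")
SEVERITY_CLASSES = ("benign", "AIN1", "AIN2+")

_SEVERITY_MAP = {
    "benign": "benign",
    "AIN1": "AIN1",
    "condyloma": "AIN1",  # low-grade tier; flagged in record metadata
    "AIN2": "AIN2+",
    "AIN3": "AIN2+",
    "cancer": "AIN2+",
}


def severity_from_histopathology(grade: str) -> str:
    """Collapse a histopathology grade into its severity tier.

    AIN2, AIN3 and cancer map to AIN2+; condyloma acuminatum is grouped
    with the low-grade (AIN1) tier.
    """
    try:
        return _SEVERITY_MAP[grade]
    except KeyError:
        raise ValueError(f"unknown histopathology grade: {grade!r}") from None


@dataclass
class SiteRecord:
    site_id: str
    patient_id: str
    histopathology: str
    hra_impression: str  # "HSIL" or "non-HSIL"
    device_score: float
    qc_pass: bool = True
    severity_class: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if self.histopathology not in HISTOPATHOLOGY_GRADES:
            raise ValueError(f"unknown grade {self.histopathology!r}")
        if self.hra_impression not in ("HSIL", "non-HSIL"):
            raise ValueError(f"bad HRA impression {self.hra_impression!r}")
        if not 0.0 <= self.device_score <= 1.0:
            raise ValueError("device_score must be in [0, 1]")
        expected = severity_from_histopathology(self.histopathology)
        if not self.severity_class:
            self.severity_class = expected
        elif self.severity_class != expected:
            raise ValueError("severity_class inconsistent with histopathology")


@dataclass(frozen=True)
class ClassScoreSpec:
    """Device-score distribution for one severity class.

    Beta(alpha, beta) on [0, 1]; a degenerate spec (``point`` not None)
    pins every score to that value, useful for exact parameter-recovery
    checks.
    """

    alpha: float = 2.0
    beta: float = 2.0
    point: float | None = None

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.point is not None:
            if not 0 <= self.point <= 1:
                raise ValueError("degenerate point must be in [0, 1]")
            return np.full(n, float(self.point))
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")
        return rng.beta(self.alpha, self.beta, n)


#: Default per-class score distributions; means ordered benign < AIN1 < AIN2+.
DEFAULT_SCORE_SPECS = {
    "benign": ClassScoreSpec(alpha=1.5, beta=8.0),   # mean ~0.16
    "AIN1": ClassScoreSpec(alpha=2.0, beta=6.0),     # mean 0.25
    "AIN2+": ClassScoreSpec(alpha=6.0, beta=2.5),    # mean ~0.71
}

#: Default per-class probability that HRA calls HSIL, loosely mirroring the
#: over-calling of low-grade sites seen in the printed agreement structure.
DEFAULT_HRA_CONFUSION = {"benign": 0.35, "AIN1": 0.49, "AIN2+": 0.91}


@dataclass
class CohortSpec:
    """Programmed structure of a synthetic site cohort.

    ``class_counts`` are exact (the cohort honors them without sampling);
    scores come from per-class distributions on [0, 1]; HRA impressions
    are Bernoulli draws with per-class HSIL probability.
    """

    class_counts: dict[str, int] = field(
        default_factory=lambda: {"benign": 11, "AIN1": 71, "AIN2+": 22})
    score_distributions: dict[str, ClassScoreSpec] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_SPECS))
    hra_confusion: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HRA_CONFUSION))
    qc_fail_probability: float = 0.046

    def __post_init__(self) -> None:
        for c, n in self.class_counts.items():
            if c not in SEVERITY_CLASSES:
                raise ValueError(f"unknown severity class {c!r}")
            if n < 0:
                raise ValueError("class counts must be >= 0")
        if sum(self.class_counts.values()) == 0:
            raise ValueError("at least one class count must be positive")
        for c, p in self.hra_confusion.items():
            if not 0 <= p <= 1:
                raise ValueError(f"hra_confusion[{c!r}] must be in [0, 1]")
        if not 0 <= self.qc_fail_probability <= 1:
            raise ValueError("qc_fail_probability must be in [0, 1]")


_CLASS_GRADE = {"benign": "benign", "AIN1": "AIN1", "AIN2+": "AIN2"}


def generate_site_cohort(spec: CohortSpec, seed: int = 0) -> list[SiteRecord]:
    """Draw a reproducible cohort honoring the spec's exact class counts."""
    rng = np.random.default_rng(seed)
    records: list[SiteRecord] = []
    idx = 0
    for cls in SEVERITY_CLASSES:
        n = spec.class_counts.get(cls, 0)
        if n == 0:
            continue
        dist = spec.score_distributions.get(cls, ClassScoreSpec())
        scores = np.clip(dist.draw(rng, n), 0.0, 1.0)
        p_hsil = spec.hra_confusion.get(cls, 0.5)
        hsil = rng.random(n) < p_hsil
        qc = rng.random(n) >= spec.qc_fail_probability
        for j in range(n):
            records.append(SiteRecord(
                site_id=f"S{idx:04d}",
                patient_id=f"P{idx // 3:03d}",  # ~3 sites per patient
                histopathology=_CLASS_GRADE[cls],
                hra_impression="HSIL" if hsil[j] else "non-HSIL",
                device_score=float(scores[j]),
                qc_pass=bool(qc[j]),
            ))
            idx += 1
    return records


def cohort_to_dataframe(records: list[SiteRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "site_id": r.site_id,
            "patient_id": r.patient_id,
            "histopathology": r.histopathology,
            "severity_class": r.severity_class,
            "hra_impression": r.hra_impression,
            "device_score": r.device_score,
            "qc_pass": r.qc_pass,
        }
        for r in records
    ])


def write_cohort_csv(records: list[SiteRecord], path) -> None:
    cohort_to_dataframe(records).to_csv(path, index=False)


def read_cohort_csv(path) -> list[SiteRecord]:
    df = pd.read_csv(path)
    return [
        SiteRecord(
            site_id=str(row.site_id),
            patient_id=str(row.patient_id),
            histopathology=row.histopathology,
            hra_impression=row.hra_impression,
            device_score=float(row.device_score),
            qc_pass=bool(row.qc_pass),
        )
        for row in df.itertuples()
    ]


def agreement_table_from_cohort(records: list[SiteRecord],
                                cutoff: float = 0.4) -> AgreementTable:
    """Cross-tabulate device calls (score >= cutoff) against HRA by severity."""
    counts = np.zeros((2, 2, 3), dtype=int)
    cls_idx = {c: i for i, c in enumerate(SEVERITY_CLASSES)}
    for r in records:
        if not r.qc_pass:
            continue
        dev = int(r.device_score >= cutoff)
        hra = int(r.hra_impression == "HSIL")
        counts[dev, hra, cls_idx[r.severity_class]] += 1
    return AgreementTable(counts=counts)
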