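"""Rater-agreement analytics and the toolkit's inferential statistics.

A resident's final diagnosis can be checked post hoc by an independent
expert who re-diagnoses the case from the records and rates their own
confidence on the same 9-point scale.  This module quantifies that
comparison (concordance rate, confidence agreement, under/over-
confidence) and provides the effect-size and correlation tests used in
cohort analyses.

Cohen's d uses the pooled standard deviation without small-sample
(Hedges) correction.  Its 95% confidence interval uses the large-sample
normal approximation with
``SE = sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2-2)))``.

Correlation p-values use the exact-under-normality t transformation
``t = r * sqrt((n-2)/(1-r^2))`` on ``n-2`` degrees of freedom; for
Spearman's coefficient (Pearson on mid-ranks) the same transform is an
approximation that is adequate for n above ~20.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass
from math import sqrt
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from .core import ConfidenceLevel, DomainError


@dataclass(frozen=True)
class RaterPair:
    """Final-diagnosis confidence of resident and expert for one case."""

    case_id: str
    resident_final_confidence: ConfidenceLevel
    expert_final_confidence: ConfidenceLevel
    diagnosis_concordant: bool


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    p: float
    n: int
    method: str  # "pearson" | "spearman"
    approximate: bool = False


@dataclass(frozen=True)
class AgreementSummary:
    """Confidence agreement between raters, in percent of pairs."""

    perfect_match_pct: float
    within_one_pct: float
    farther_pct: float
    max_discrepancy: int
    expert_underconfident_pct: float
    expert_overconfident_pct: float
    n: int


def read_pairs_csv(path) -> list:
    """Load rater pairs from a CSV with columns
    ``case_id,resident_level,expert_level,concordant``."""
    pairs = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in _csv.DictReader(fh):
            pairs.append(
                RaterPair(
                    case_id=row["case_id"],
                    resident_final_confidence=ConfidenceLevel(int(row["resident_level"])),
                    expert_final_confidence=ConfidenceLevel(int(row["expert_level"])),
                    diagnosis_concordant=row["concordant"].strip().lower() in {"1", "true", "yes"},
                )
            )
    return pairs


def concordance_rate(pairs: Sequence[RaterPair]) -> float:
    """Fraction of cases where expert and resident agree on the diagnosis."""
    if not pairs:
        raise DomainError("concordance_rate of an empty pair list")
    return sum(p.diagnosis_concordant for p in pairs) / len(pairs)


def confidence_agreement(pairs: Sequence[RaterPair]) -> AgreementSummary:
    """How closely the two raters' confidence in the final diagnosis agrees.

    *Underconfident* means the expert rated lower than the resident.
    Discrepancy is the absolute difference in scale steps, so
    perfect + within-one + farther = 100%.
    """
    if not pairs:
        raise DomainError("confidence_agreement of an empty pair list")
    n = len(pairs)
    diffs = [
        p.expert_final_confidence.value - p.resident_final_confidence.value for p in pairs
    ]
    perfect = sum(d == 0 for d in diffs)
    within_one = sum(abs(d) == 1 for d in diffs)
    farther = n - perfect - within_one
    return AgreementSummary(
        perfect_match_pct=100.0 * perfect / n,
        within_one_pct=100.0 * within_one / n,
        farther_pct=100.0 * farther / n,
        max_discrepancy=max(abs(d) for d in diffs),
        expert_underconfident_pct=100.0 * sum(d < 0 for d in diffs) / n,
        expert_overconfident_pct=100.0 * sum(d > 0 for d in diffs) / n,
        n=n,
    )


def cohens_d(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> EffectSize:
    """Standardized mean difference ``(m1 - m2) / pooled SD`` with 95% CI.

    ``pooled SD = sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))``.
    """
    if s1 < 0 or s2 < 0:
        raise DomainError("standard deviations must be non-negative")
    if n1 < 2 or n2 < 2:
        raise DomainError("cohens_d needs n >= 2 per group")
    pooled = sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0.0:
        if m1 != m2:
            raise DomainError("zero pooled SD with unequal means: d undefined")
        d = 0.0
    else:
        d = (m1 - m2) / pooled
    se = sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2 - 2)))
    z = _sps.norm.ppf(0.975)
    return EffectSize(d=d, ci_low=d - z * se, ci_high=d + z * se)


def cohens_d_from_data(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohens_d(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))


def pearson_test(r: float, n: int) -> CorrelationResult:
    """Two-sided significance of a Pearson coefficient from its summary value.

    ``t = r*sqrt((n-2)/(1-r^2))`` referred to a t distribution with
    ``n-2`` degrees of freedom.
    """
    if n < 3:
        raise DomainError("pearson_test needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise DomainError(f"correlation coefficient out of range: {r}")
    if abs(r) == 1.0:
        return CorrelationResult(coefficient=r, p=0.0, n=n, method="pearson", approximate=True)
    t = r * sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * _sps.t.sf(abs(t), n - 2)
    return CorrelationResult(coefficient=r, p=p, n=n, method="pearson")


def pearson_test_from_data(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DomainError("paired data must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise DomainError("constant vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    return pearson_test(r, len(x))


def spearman_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rank correlation (Pearson on mid-ranks) with the
    t-transform p-value, flagged as an approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DomainError("paired data must have equal length")
    if len(x) < 3:
        raise DomainError("spearman_test needs n >= 3")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise DomainError("constant vector: rank correlation undefined")
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rs) >= 1.0 - 1e-12:
        rs = float(np.sign(rs))
        return CorrelationResult(coefficient=rs, p=0.0, n=len(x), method="spearman", approximate=True)
    base = pearson_test(rs, len(x))
    return CorrelationResult(coefficient=rs, p=base.p, n=len(x), method="spearman", approximate=True)


def spearman_test_from_summary(rs: float, n: int) -> CorrelationResult:
    base = pearson_test(rs, n)
    return CorrelationResult(coefficient=rs, p=base.p, n=n, method="spearman", approximate=True)
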