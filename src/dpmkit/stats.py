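"""Per-case metrics and cohort descriptive statistics for DPM data.

The quantities of interest in a cohort of traced cases are counts
(options, cues, units, per-phase composition), confidence endpoints
(initial rating of each option, terminal rating split by outcome) and
the structural proportions of the three-phase pattern (final diagnosis
already present in phase 1, late option additions, ratings at the scale
extremes).  Standard deviations are sample SDs (``n-1`` denominator).

The mean number of options added during the verification phase is
reported under both defensible denominators — over all cases, and over
only the cases with at least one addition — because summary statistics
in the field appear under either convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import concordance as _concordance
from .core import (
    DecisionProcessMatrix,
    DomainError,
    Outcome,
    TriState,
    UnitKind,
    classify_outcome,
    ratings_for,
    require_valid,
    unit_counts,
)
from .segmentation import PhaseComposition, phase_composition, segment

MAX_LEVEL_VALUE = 4
MIN_LEVEL_VALUE = -4


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def trajectory(dpm: DecisionProcessMatrix, option_id: str) -> list:
    """Ordered series ``[(order_index, level), ...]`` of one option's ratings.

    Empty if the option was never rated (a place-marker option).
    """
    return [(u.order_index, u.level) for u in ratings_for(dpm, option_id)]


def net_change(series: Sequence[tuple]) -> int:
    """Last rating minus first rating of a trajectory."""
    if not series:
        raise DomainError("net_change of an empty trajectory")
    return series[-1][1] - series[0][1]


# ---------------------------------------------------------------------------
# Case summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseSummary:
    case_id: str
    n_units: int
    n_cues: int
    n_options: int
    n_confidences: int
    composition: PhaseComposition
    conforming: bool
    final_in_phase1: bool
    initial_confidence: Dict[str, int]
    terminal_confidence: Dict[str, int]
    outcome: Dict[str, Outcome]
    final_terminal_levels: tuple
    excluded_terminal_levels: tuple
    phase1_initial_levels: tuple
    time_pressure: TriState = TriState.UNKNOWN
    stress: TriState = TriState.UNKNOWN
    case_experience: TriState = TriState.UNKNOWN
    similarity: Optional[int] = None
    experience_months: Optional[int] = None

    @property
    def options_added_phase2(self) -> int:
        return self.composition.phase2_options_added

    @property
    def mean_final_terminal(self) -> Optional[float]:
        if not self.final_terminal_levels:
            return None
        return float(np.mean(self.final_terminal_levels))


def case_summary(dpm: DecisionProcessMatrix) -> CaseSummary:
    """Condense one valid case into the metrics used at cohort level."""
    require_valid(dpm)
    counts = unit_counts(dpm)
    part = segment(dpm)
    comp = phase_composition(dpm, part)

    intro_opt = {u.ref_id: u.order_index for u in dpm.units if u.kind is UnitKind.OPTION}
    initial: Dict[str, int] = {}
    terminal: Dict[str, int] = {}
    outcome: Dict[str, Outcome] = {}
    for o in dpm.options:
        ratings = ratings_for(dpm, o.option_id)
        if ratings:
            initial[o.option_id] = ratings[0].level
            terminal[o.option_id] = ratings[-1].level
        outcome[o.option_id] = classify_outcome(dpm, o.option_id)

    final_ids = [oid for oid, oc in outcome.items() if oc is Outcome.FINAL]
    final_in_phase1 = bool(final_ids) and all(
        intro_opt.get(oid, 10**9) <= part.phase1_end for oid in final_ids
    )
    final_terminal = tuple(terminal[oid] for oid in final_ids if oid in terminal)
    excluded_terminal = tuple(
        terminal[oid] for oid, oc in outcome.items() if oc is Outcome.EXCLUDED and oid in terminal
    )
    phase1_initial = tuple(
        initial[oid]
        for oid, idx in intro_opt.items()
        if idx <= part.phase1_end and oid in initial
    )

    md = dpm.metadata
    return CaseSummary(
        case_id=md.case_id,
        n_units=counts["total"],
        n_cues=counts["CUE"],
        n_options=counts["OPTION"],
        n_confidences=counts["CONFIDENCE"],
        composition=comp,
        conforming=part.conforming,
        final_in_phase1=final_in_phase1,
        initial_confidence=initial,
        terminal_confidence=terminal,
        outcome=outcome,
        final_terminal_levels=final_terminal,
        excluded_terminal_levels=excluded_terminal,
        phase1_initial_levels=phase1_initial,
        time_pressure=md.time_pressure,
        stress=md.stress,
        case_experience=md.case_experience,
        similarity=md.similarity,
        experience_months=md.experience_months,
    )


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sd: Optional[float]  # None when n < 2
    min: float
    max: float
    n: int

    @staticmethod
    def of(values: Sequence[float]) -> "MetricSummary":
        arr = np.asarray(values, dtype=float)
        return MetricSummary(
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if len(arr) >= 2 else None,
            min=float(arr.min()),
            max=float(arr.max()),
            n=len(arr),
        )


@dataclass(frozen=True)
class CohortSummary:
    n_cases: int
    metrics: Dict[str, MetricSummary]
    prop_conforming: float
    prop_final_in_phase1: float
    prop_any_phase2_addition: float
    prop_final_rated_max: float  # over final diagnoses
    prop_excluded_rated_min: float  # over excluded options

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": name,
                "mean": m.mean,
                "sd": m.sd,
                "min": m.min,
                "max": m.max,
                "n": m.n,
            }
            for name, m in self.metrics.items()
        ]
        for name, value in [
            ("prop_conforming", self.prop_conforming),
            ("prop_final_in_phase1", self.prop_final_in_phase1),
            ("prop_any_phase2_addition", self.prop_any_phase2_addition),
            ("prop_final_rated_max", self.prop_final_rated_max),
            ("prop_excluded_rated_min", self.prop_excluded_rated_min),
        ]:
            rows.append({"metric": name, "mean": value, "sd": None, "min": None, "max": None, "n": self.n_cases})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def cohort_summary(cases: Sequence[CaseSummary]) -> CohortSummary:
    """Descriptive statistics over a cohort of case summaries."""
    if not cases:
        raise DomainError("cohort_summary of an empty cohort")
    metrics: Dict[str, MetricSummary] = {}
    metrics["n_options"] = MetricSummary.of([c.n_options for c in cases])
    metrics["n_cues"] = MetricSummary.of([c.n_cues for c in cases])
    metrics["n_units"] = MetricSummary.of([c.n_units for c in cases])
    metrics["phase1_options"] = MetricSummary.of([c.composition.phase1_options for c in cases])
    metrics["phase1_cues"] = MetricSummary.of([c.composition.phase1_cues for c in cases])
    metrics["phase2_cues"] = MetricSummary.of([c.composition.phase2_cues for c in cases])

    additions = [c.options_added_phase2 for c in cases]
    metrics["options_added_all_cases"] = MetricSummary.of(additions)
    with_any = [a for a in additions if a > 0]
    if with_any:
        metrics["options_added_given_any"] = MetricSummary.of(with_any)

    initial = [lvl for c in cases for lvl in c.phase1_initial_levels]
    if initial:
        metrics["initial_confidence"] = MetricSummary.of(initial)
    final_terminal = [lvl for c in cases for lvl in c.final_terminal_levels]
    if final_terminal:
        metrics["final_terminal_confidence"] = MetricSummary.of(final_terminal)
    excluded_terminal = [lvl for c in cases for lvl in c.excluded_terminal_levels]
    if excluded_terminal:
        metrics["excluded_terminal_confidence"] = MetricSummary.of(excluded_terminal)

    n = len(cases)
    return CohortSummary(
        n_cases=n,
        metrics=metrics,
        prop_conforming=sum(c.conforming for c in cases) / n,
        prop_final_in_phase1=sum(c.final_in_phase1 for c in cases) / n,
        prop_any_phase2_addition=sum(a > 0 for a in additions) / n,
        prop_final_rated_max=(
            sum(lvl == MAX_LEVEL_VALUE for lvl in final_terminal) / len(final_terminal)
            if final_terminal
            else float("nan")
        ),
        prop_excluded_rated_min=(
            sum(lvl == MIN_LEVEL_VALUE for lvl in excluded_terminal) / len(excluded_terminal)
            if excluded_terminal
            else float("nan")
        ),
    )


def cases_to_frame(cases: Sequence[CaseSummary]) -> pd.DataFrame:
    """One row per case with the scalar metrics (for export / modeling)."""
    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "n_units": [c.n_units for c in cases],
            "n_cues": [c.n_cues for c in cases],
            "n_options": [c.n_options for c in cases],
            "phase1_cues": [c.composition.phase1_cues for c in cases],
            "phase1_options": [c.composition.phase1_options for c in cases],
            "phase2_cues": [c.composition.phase2_cues for c in cases],
            "options_added_phase2": [c.options_added_phase2 for c in cases],
            "conforming": [c.conforming for c in cases],
            "final_in_phase1": [c.final_in_phase1 for c in cases],
            "final_terminal": [c.mean_final_terminal for c in cases],
            "time_pressure": [c.time_pressure.value for c in cases],
            "stress": [c.stress.value for c in cases],
            "case_experience": [c.case_experience.value for c in cases],
            "similarity": [c.similarity for c in cases],
            "experience_months": [c.experience_months for c in cases],
        }
    )


# ---------------------------------------------------------------------------
# Group comparisons on contextual flags
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_yes: float
    sd_yes: Optional[float]
    n_yes: int
    mean_no: float
    sd_no: Optional[float]
    n_no: int
    effect_size: Optional[_concordance.EffectSize]  # None when an SD is undefined


_DEFAULT_GROUP_METRICS = ("n_cues", "n_options", "final_terminal")


def compare_groups(
    cases: Sequence[CaseSummary],
    flag: str,
    metrics: Sequence[str] = _DEFAULT_GROUP_METRICS,
) -> Dict[str, GroupComparison]:
    """Compare yes/no groups of a contextual flag on the given metrics.

    ``flag`` is one of ``time_pressure``, ``stress``, ``case_experience``.
    Cases answering "don't know" are dropped.  Cohen's d is computed via
    :func:`dpmkit.concordance.cohens_d`; with fewer than two cases in a
    group the SD (and hence d) is reported as undefined.
    """
    if flag not in {"time_pressure", "stress", "case_experience"}:
        raise DomainError(f"unknown contextual flag {flag!r}")
    frame = cases_to_frame(cases)
    yes = frame[frame[flag] == TriState.YES.value]
    no = frame[frame[flag] == TriState.NO.value]
    if len(yes) < 1 or len(no) < 1:
        raise DomainError(f"flag {flag!r} needs at least one case per level")
    out: Dict[str, GroupComparison] = {}
    for metric in metrics:
        a = yes[metric].dropna().to_numpy(dtype=float)
        b = no[metric].dropna().to_numpy(dtype=float)
        sd_a = float(a.std(ddof=1)) if len(a) >= 2 else None
        sd_b = float(b.std(ddof=1)) if len(b) >= 2 else None
        effect = None
        if sd_a is not None and sd_b is not None:
            try:
                effect = _concordance.cohens_d(a.mean(), sd_a, len(a), b.mean(), sd_b, len(b))
            except DomainError:
                effect = None
        out[metric] = GroupComparison(
            metric=metric,
            mean_yes=float(a.mean()),
            sd_yes=sd_a,
            n_yes=len(a),
            mean_no=float(b.mean()),
            sd_no=sd_b,
            n_no=len(b),
            effect_size=effect,
        )
    return out
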