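"""Domain model for Decision Process Matrices (DPM).

A DPM records one diagnostic episode as a numbered event log: *cues*
(meaningful units of clinical information), *options* (suspected
diagnoses), *confidence ratings* (the physician's certainty for or
against one option at one moment, on an anchored 9-point scale from
-4 "practically impossible" to +4 "practically certain") and a single
*final determination* closing the case.  Every occurrence carries a
consecutive 1-based order index, so the matrix doubles as a process
trace.

This module holds the in-memory types and a structural validator; file
formats live in :mod:`dpmkit.io`, phase analysis in
:mod:`dpmkit.segmentation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Union


class DpmError(Exception):
    """Base class for all dpmkit errors."""


class DomainError(DpmError, ValueError):
    """A value outside its admissible domain (e.g. confidence +5)."""


class UnknownIdError(DpmError, KeyError):
    """Lookup of a cue/option identifier that does not exist."""


class InconsistentCaseError(DpmError):
    """A case whose internal references contradict each other."""


class PreconditionError(DpmError):
    """An operation was applied to a case violating its preconditions."""


# ---------------------------------------------------------------------------
# Confidence scale
# ---------------------------------------------------------------------------

#: Verbal anchors of the 9-point confidence scale.  The scale is fixed:
#: every rating in a DPM is one of these nine integers.
CONFIDENCE_LABELS: dict[int, str] = {
    -4: "practically impossible",
    -3: "improbable",
    -2: "doubtful",
    -1: "thinkable",
    0: "possible",
    +1: "probable",
    +2: "quite probable",
    +3: "very probable",
    +4: "practically certain",
}

_LABEL_TO_LEVEL = {label: value for value, label in CONFIDENCE_LABELS.items()}

MIN_LEVEL = -4
MAX_LEVEL = 4


def label_for(value: int) -> str:
    """Verbal anchor for a confidence level.

    >>> label_for(4)
    'practically certain'
    """
    try:
        return CONFIDENCE_LABELS[int(value)]
    except (KeyError, TypeError) as exc:
        raise DomainError(f"confidence level out of scale: {value!r}") from exc


def level_for(label: str) -> int:
    """Inverse of :func:`label_for`."""
    try:
        return _LABEL_TO_LEVEL[label]
    except KeyError as exc:
        raise DomainError(f"unknown confidence label: {label!r}") from exc


@dataclass(frozen=True, order=True)
class ConfidenceLevel:
    """One point on the anchored scale; value and label are bijective."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in CONFIDENCE_LABELS:
            raise DomainError(f"confidence level out of scale: {self.value!r}")

    @property
    def label(self) -> str:
        return CONFIDENCE_LABELS[self.value]

    @classmethod
    def from_label(cls, label: str) -> "ConfidenceLevel":
        return cls(level_for(label))


# ---------------------------------------------------------------------------
# Entities
# ---------------------------------------------------------------------------


class CueSource(str, Enum):
    """Where a cue came from in the emergency-department workflow."""

    MHT = "MHT"  # medical history-taking
    PE = "PE"  # physical examination
    ILT = "ILT"  # imaging & laboratory tests
    LITERATURE = "LITERATURE"
    OTHER = "OTHER"


class Outcome(str, Enum):
    FINAL = "FINAL"
    EXCLUDED = "EXCLUDED"
    UNDETERMINED = "UNDETERMINED"


class UnitKind(str, Enum):
    CUE = "CUE"
    OPTION = "OPTION"
    CONFIDENCE = "CONFIDENCE"
    FINAL = "FINAL"


class TriState(str, Enum):
    """Answer categories of the contextual questionnaire items."""

    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Cue:
    cue_id: str
    text: str
    source: CueSource = CueSource.MHT


@dataclass(frozen=True)
class OptionTrack:
    """One suspected diagnosis and how it ended."""

    option_id: str
    text: str
    outcome: Outcome = Outcome.UNDETERMINED


@dataclass(frozen=True)
class Unit:
    """One numbered occurrence in the event log.

    Field usage depends on ``kind``:

    * ``CUE`` / ``OPTION`` — ``ref_id`` names the cue/option introduced.
    * ``CONFIDENCE`` — ``option_ref`` names the rated option,
      ``cue_ref`` (optional) the cue the rating responds to, ``level``
      the scale value, ``is_exclusion`` whether the rating rules the
      option out.
    * ``FINAL`` — ``option_ref`` is a tuple of one or more option ids
      (a final diagnosis, or differential diagnoses).
    """

    order_index: int
    kind: UnitKind
    ref_id: Optional[str] = None
    option_ref: Union[str, tuple, None] = None
    cue_ref: Optional[str] = None
    level: Optional[int] = None
    is_exclusion: bool = False


@dataclass(frozen=True)
class CaseMetadata:
    case_id: str
    resident_id: str = ""
    patient_age: Optional[int] = None
    patient_sex: Optional[str] = None
    time_pressure: TriState = TriState.UNKNOWN
    stress: TriState = TriState.UNKNOWN
    case_experience: TriState = TriState.UNKNOWN
    similarity: Optional[int] = None  # 1..6, only if case_experience = yes
    experience_months: Optional[int] = None


@dataclass(frozen=True)
class DecisionProcessMatrix:
    """A complete traced case: metadata, event log, cue and option tracks."""

    metadata: CaseMetadata
    units: tuple = ()
    cues: tuple = ()
    options: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        object.__setattr__(self, "cues", tuple(self.cues))
        object.__setattr__(self, "options", tuple(self.options))

    # convenience lookups ---------------------------------------------------
    def cue(self, cue_id: str) -> Cue:
        for c in self.cues:
            if c.cue_id == cue_id:
                return c
        raise UnknownIdError(cue_id)

    def option(self, option_id: str) -> OptionTrack:
        for o in self.options:
            if o.option_id == option_id:
                return o
        raise UnknownIdError(option_id)

    def units_of_kind(self, kind: UnitKind) -> list:
        return [u for u in self.units if u.kind is kind]

    @property
    def final_unit(self) -> Optional[Unit]:
        finals = self.units_of_kind(UnitKind.FINAL)
        return finals[0] if len(finals) == 1 else None

    def final_option_ids(self) -> tuple:
        f = self.final_unit
        if f is None or f.option_ref is None:
            return ()
        return tuple(f.option_ref)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    rule: str
    message: str
    order_index: Optional[int] = None


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple = ()
    warnings: tuple = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def _confidence_units(dpm: DecisionProcessMatrix) -> list:
    return dpm.units_of_kind(UnitKind.CONFIDENCE)


def validate(dpm: DecisionProcessMatrix) -> ValidationReport:
    """Check every structural invariant of the DPM representation.

    Violations are data, not exceptions: the report lists each broken
    rule with the offending unit index.  Unrated ("place marker")
    options are tolerated and reported as warnings only.
    """
    if not isinstance(dpm, DecisionProcessMatrix):
        raise DomainError("expected a DecisionProcessMatrix")
    v: list[Violation] = []
    w: list[Violation] = []
    units = dpm.units
    n = len(units)

    # consecutive 1..n numbering
    indices = sorted(u.order_index for u in units)
    if indices != list(range(1, n + 1)):
        v.append(Violation("numbering", "numbering not consecutive 1..n"))

    by_index = {u.order_index: u for u in units}

    # id registries
    cue_ids = [c.cue_id for c in dpm.cues]
    opt_ids = [o.option_id for o in dpm.options]
    if len(set(cue_ids)) != len(cue_ids):
        v.append(Violation("cue-ids", "duplicate cue_id in cue list"))
    if len(set(opt_ids)) != len(opt_ids):
        v.append(Violation("option-ids", "duplicate option_id in option list"))
    cue_set, opt_set = set(cue_ids), set(opt_ids)

    for c in dpm.cues:
        if not c.text:
            v.append(Violation("cue-text", f"cue {c.cue_id!r} has empty text"))
        if not isinstance(c.source, CueSource):
            v.append(Violation("cue-source", f"cue {c.cue_id!r} source not in closed set"))

    # exactly one FINAL, carrying the maximal order index
    finals = dpm.units_of_kind(UnitKind.FINAL)
    if len(finals) != 1:
        v.append(Violation("final-count", f"expected exactly one FINAL unit, found {len(finals)}"))
    else:
        f = finals[0]
        if n and f.order_index != max(indices):
            v.append(Violation("final-last", "FINAL unit is not the last unit", f.order_index))
        refs = f.option_ref if isinstance(f.option_ref, (tuple, list)) else None
        if not refs:
            v.append(Violation("final-refs", "FINAL must reference >= 1 option", f.order_index))
        else:
            for oid in refs:
                if oid not in opt_set:
                    v.append(Violation("final-refs", f"FINAL references unknown option {oid!r}", f.order_index))

    # per-kind field discipline and backward references
    intro_cue: dict[str, int] = {}
    intro_opt: dict[str, int] = {}
    for u in units:
        if u.kind is UnitKind.CUE:
            if u.ref_id is None or u.ref_id not in cue_set:
                v.append(Violation("cue-ref", "CUE unit does not introduce a listed cue", u.order_index))
            elif u.ref_id in intro_cue:
                v.append(Violation("cue-ref", f"cue {u.ref_id!r} introduced twice", u.order_index))
            else:
                intro_cue[u.ref_id] = u.order_index
        elif u.kind is UnitKind.OPTION:
            if u.ref_id is None or u.ref_id not in opt_set:
                v.append(Violation("option-ref", "OPTION unit does not introduce a listed option", u.order_index))
            elif u.ref_id in intro_opt:
                v.append(Violation("option-ref", f"option {u.ref_id!r} introduced twice", u.order_index))
            else:
                intro_opt[u.ref_id] = u.order_index
        elif u.kind is UnitKind.CONFIDENCE:
            if u.level is None or u.level not in CONFIDENCE_LABELS:
                v.append(Violation("level", "CONFIDENCE level missing or out of scale", u.order_index))
            if not isinstance(u.option_ref, str) or u.option_ref not in opt_set:
                v.append(Violation("conf-option", "CONFIDENCE must rate one known option", u.order_index))
            if u.cue_ref is not None and u.cue_ref not in cue_set:
                v.append(Violation("conf-cue", f"CONFIDENCE cites unknown cue {u.cue_ref!r}", u.order_index))

    # every listed cue/option must be introduced by exactly one unit
    for cid in cue_set - set(intro_cue):
        v.append(Violation("cue-intro", f"cue {cid!r} never introduced by a CUE unit"))
    for oid in opt_set - set(intro_opt):
        v.append(Violation("option-intro", f"option {oid!r} never introduced by an OPTION unit"))

    # confidence units must point backwards
    for u in _confidence_units(dpm):
        if isinstance(u.option_ref, str) and u.option_ref in intro_opt:
            if intro_opt[u.option_ref] >= u.order_index:
                v.append(Violation("conf-order", "CONFIDENCE precedes the option it rates", u.order_index))
        if u.cue_ref is not None and u.cue_ref in intro_cue:
            if intro_cue[u.cue_ref] >= u.order_index:
                v.append(Violation("conf-order", "CONFIDENCE precedes the cue it cites", u.order_index))

    # unit conservation
    counts = {k: len(dpm.units_of_kind(k)) for k in UnitKind}
    if counts[UnitKind.FINAL] == 1 and n != (
        counts[UnitKind.CUE] + counts[UnitKind.OPTION] + counts[UnitKind.CONFIDENCE] + 1
    ):
        v.append(Violation("conservation", "unit total does not decompose into kinds"))

    # outcome bookkeeping
    final_ids = set(dpm.final_option_ids())
    excluded_ids = {
        u.option_ref for u in _confidence_units(dpm) if u.is_exclusion and isinstance(u.option_ref, str)
    }
    for o in dpm.options:
        if o.option_id in final_ids and o.option_id in excluded_ids:
            v.append(Violation("outcome", f"option {o.option_id!r} both final and excluded"))
        expected = (
            Outcome.FINAL
            if o.option_id in final_ids
            else Outcome.EXCLUDED
            if o.option_id in excluded_ids
            else Outcome.UNDETERMINED
        )
        if o.outcome is not expected:
            v.append(
                Violation(
                    "outcome",
                    f"option {o.option_id!r} recorded as {o.outcome.value}, units imply {expected.value}",
                )
            )
        if expected is Outcome.UNDETERMINED:
            w.append(Violation("unrated-option", f"option {o.option_id!r} neither final nor excluded"))

    # metadata constraints
    md = dpm.metadata
    if md.similarity is not None:
        if md.case_experience is not TriState.YES:
            v.append(Violation("metadata", "similarity given without case_experience = yes"))
        if not 1 <= md.similarity <= 6:
            v.append(Violation("metadata", f"similarity {md.similarity} outside 1..6"))

    return ValidationReport(tuple(v), tuple(w))


def require_valid(dpm: DecisionProcessMatrix) -> None:
    """Raise :class:`PreconditionError` unless *dpm* validates cleanly."""
    report = validate(dpm)
    if not report.ok:
        first = report.violations[0]
        raise PreconditionError(
            f"invalid DPM ({len(report.violations)} violations; first: {first.rule}: {first.message})"
        )


# ---------------------------------------------------------------------------
# Basic queries
# ---------------------------------------------------------------------------


def unit_counts(dpm: DecisionProcessMatrix) -> dict:
    """Counts of units by kind plus ``total``; total equals max order index."""
    require_valid(dpm)
    counts = {k.value: len(dpm.units_of_kind(k)) for k in UnitKind}
    counts["total"] = len(dpm.units)
    return counts


def ratings_for(dpm: DecisionProcessMatrix, option_id: str) -> list:
    """All CONFIDENCE units targeting *option_id*, in order of occurrence."""
    dpm.option(option_id)  # raises UnknownIdError
    out = [u for u in _confidence_units(dpm) if u.option_ref == option_id]
    out.sort(key=lambda u: u.order_index)
    return out


def terminal_confidence(dpm: DecisionProcessMatrix, option_id: str) -> Optional[ConfidenceLevel]:
    """The last rating an option received, or ``None`` if never rated."""
    ratings = ratings_for(dpm, option_id)
    if not ratings:
        return None
    return ConfidenceLevel(ratings[-1].level)


def initial_confidence(dpm: DecisionProcessMatrix, option_id: str) -> Optional[ConfidenceLevel]:
    """The first rating an option received, or ``None`` if never rated."""
    ratings = ratings_for(dpm, option_id)
    if not ratings:
        return None
    return ConfidenceLevel(ratings[0].level)


def classify_outcome(dpm: DecisionProcessMatrix, option_id: str) -> Outcome:
    """FINAL if the final determination names the option; else EXCLUDED if
    any exclusion-flagged rating targets it; else UNDETERMINED."""
    dpm.option(option_id)
    is_final = option_id in dpm.final_option_ids()
    is_excluded = any(u.is_exclusion for u in ratings_for(dpm, option_id))
    if is_final and is_excluded:
        raise InconsistentCaseError(f"option {option_id!r} referenced both by FINAL and an exclusion flag")
    if is_final:
        return Outcome.FINAL
    if is_excluded:
        return Outcome.EXCLUDED
    return Outcome.UNDETERMINED
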