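"""Three-phase segmentation of a DPM event log.

Traced diagnostic episodes show a recurring structure: an *option
generation* phase in which a few initial cues prompt the first
suspected diagnoses, an *option verification* phase in which further
cues are gathered and confidence in each hypothesis is updated, and a
closing *final determination*.

The boundary rule operationalizing this pattern: phase 3 is the final
determination unit; phase 2 begins at the first cue whose order index
exceeds that of the first option; phase 1 is everything before it.
Options mentioned during phase 2 stay phase-2 members — late hypothesis
generation does not reopen phase 1.

Cases that do not fit (no option before the final unit, or no cue after
the first option) are reported as non-conforming with explanatory
notes, never rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import DecisionProcessMatrix, UnitKind, require_valid


@dataclass(frozen=True)
class PhasePartition:
    """Indices splitting the unit sequence into the three phases.

    Units ``1..phase1_end`` form phase 1, ``phase1_end+1..phase2_end``
    phase 2, and the remaining unit(s) the final determination.
    """

    phase1_end: int
    phase2_end: int
    conforming: bool = True
    notes: tuple = ()


@dataclass(frozen=True)
class PhaseComposition:
    phase1_cues: int
    phase1_options: int
    phase1_confidences: int
    phase2_cues: int
    phase2_options_added: int
    phase2_confidences: int
    conforming: bool = True

    @property
    def total_non_final(self) -> int:
        return (
            self.phase1_cues
            + self.phase1_options
            + self.phase1_confidences
            + self.phase2_cues
            + self.phase2_options_added
            + self.phase2_confidences
        )


def segment(dpm: DecisionProcessMatrix) -> PhasePartition:
    """Partition a valid case into the three phases (pure, idempotent)."""
    require_valid(dpm)
    n = len(dpm.units)
    option_indices = [u.order_index for u in dpm.units if u.kind is UnitKind.OPTION]
    if not option_indices:
        return PhasePartition(n - 1, n - 1, conforming=False, notes=("no-option-before-final",))
    first_option = min(option_indices)
    later_cues = [
        u.order_index for u in dpm.units if u.kind is UnitKind.CUE and u.order_index > first_option
    ]
    if not later_cues:
        # everything before the final unit is generation; verification is empty
        return PhasePartition(n - 1, n - 1, conforming=False, notes=("empty-phase-2",))
    phase2_start = min(later_cues)
    return PhasePartition(phase2_start - 1, n - 1, conforming=True, notes=())


def phase_composition(dpm: DecisionProcessMatrix, partition: PhasePartition) -> PhaseComposition:
    """Per-phase unit counts; sums to the unit total minus the FINAL unit."""
    counts = {"p1": {k: 0 for k in UnitKind}, "p2": {k: 0 for k in UnitKind}}
    for u in dpm.units:
        if u.order_index <= partition.phase1_end:
            counts["p1"][u.kind] += 1
        elif u.order_index <= partition.phase2_end:
            counts["p2"][u.kind] += 1
    return PhaseComposition(
        phase1_cues=counts["p1"][UnitKind.CUE],
        phase1_options=counts["p1"][UnitKind.OPTION],
        phase1_confidences=counts["p1"][UnitKind.CONFIDENCE],
        phase2_cues=counts["p2"][UnitKind.CUE],
        phase2_options_added=counts["p2"][UnitKind.OPTION],
        phase2_confidences=counts["p2"][UnitKind.CONFIDENCE],
        conforming=partition.conforming,
    )
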