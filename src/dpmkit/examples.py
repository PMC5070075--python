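"""The bundled worked example: one complete traced diagnostic episode.

An 18-year-old male with four days of fever and abdominal pain; 46
numbered units.  Three initial cues prompt two suspected diagnoses
("Viral Gastroenteritis" rated *quite probable*, "Lung infection"
rated *probable*), each rated against every generation-phase cue.  The
verification phase opens at unit 12 with "cold extremities a couple of
days ago", which raises a third hypothesis ("Vascular problem",
*thinkable*); 15 further cues — including two physical examinations
(units 40, 42) and a laboratory analysis (unit 44) — drive the
confidence in the gastroenteritis up, exclude the vascular problem at
unit 37 and the lung infection at unit 45.  Unit 46 fixes the final
diagnosis.

The same case ships as ``data/example_case.json``; the builder here is
the source of truth for that file.
"""

from __future__ import annotations

from importlib import resources

from .core import (
    CaseMetadata,
    Cue,
    CueSource,
    DecisionProcessMatrix,
    OptionTrack,
    Outcome,
    Unit,
    UnitKind,
)

_MHT = CueSource.MHT
_PE = CueSource.PE
_ILT = CueSource.ILT

_CUES = [
    ("c01", "adolescent patient", _MHT),
    ("c02", "abdominal pain", _MHT),
    ("c03", "flu-like symptoms", _MHT),
    ("c04", "cold extremities a couple of days ago", _MHT),
    ("c05", "no diarrhea at symptom onset", _MHT),
    ("c06", "fever up to 38.9 C", _MHT),
    ("c07", "no cough or sputum", _MHT),
    ("c08", "crampy abdominal pain after meals", _MHT),
    ("c09", "nausea without vomiting", _MHT),
    ("c10", "sick contact with similar symptoms at home", _MHT),
    ("c11", "no chest pain", _MHT),
    ("c12", "no calf or leg swelling", _MHT),
    ("c13", "normal skin colour of the limbs", _MHT),
    ("c14", "extremities warm again for days", _MHT),
    ("c15", "no pain or pallor in the limbs", _MHT),
    ("c16", "reports diffuse muscle aches", _MHT),
    ("c17", "abdomen soft, diffuse tenderness, no guarding", _PE),
    ("c18", "lungs clear on auscultation", _PE),
    ("c19", "leukocytes normal, CRP mildly elevated", _ILT),
]

_OPTIONS = [
    ("o1", "Viral Gastroenteritis", Outcome.FINAL),
    ("o2", "Lung infection", Outcome.EXCLUDED),
    ("o3", "Vascular problem", Outcome.EXCLUDED),
]

# (order_index, kind, ref/option, cue_ref, level, is_exclusion)
_UNITS = [
    (1, "CUE", "c01"),
    (2, "CUE", "c02"),
    (3, "CUE", "c03"),
    (4, "OPT", "o1"),
    (5, "CONF", "o1", "c01", +2),
    (6, "CONF", "o1", "c02", +2),
    (7, "CONF", "o1", "c03", +2),
    (8, "OPT", "o2"),
    (9, "CONF", "o2", "c01", +1),
    (10, "CONF", "o2", "c02", +1),
    (11, "CONF", "o2", "c03", +1),
    (12, "CUE", "c04"),
    (13, "OPT", "o3"),
    (14, "CONF", "o3", "c04", -1),
    (15, "CUE", "c05"),
    (16, "CONF", "o1", "c05", +2),
    (17, "CUE", "c06"),
    (18, "CONF", "o1", "c06", +2),
    (19, "CONF", "o2", "c06", +1),
    (20, "CUE", "c07"),
    (21, "CONF", "o2", "c07", 0),
    (22, "CUE", "c08"),
    (23, "CONF", "o1", "c08", +3),
    (24, "CUE", "c09"),
    (25, "CONF", "o1", "c09", +3),
    (26, "CUE", "c10"),
    (27, "CONF", "o1", "c10", +3),
    (28, "CUE", "c11"),
    (29, "CONF", "o3", "c11", -2),
    (30, "CUE", "c12"),
    (31, "CONF", "o3", "c12", -3),
    (32, "CUE", "c13"),
    (33, "CONF", "o3", "c13", -3),
    (34, "CUE", "c14"),
    (35, "CONF", "o3", "c14", -3),
    (36, "CUE", "c15"),
    (37, "CONF", "o3", "c15", -4, True),
    (38, "CUE", "c16"),
    (39, "CONF", "o1", "c16", +3),
    (40, "CUE", "c17"),
    (41, "CONF", "o1", "c17", +3),
    (42, "CUE", "c18"),
    (43, "CONF", "o2", "c18", -2),
    (44, "CUE", "c19"),
    (45, "CONF", "o2", "c19", -4, True),
    (46, "FINAL", ("o1",)),
]


def worked_example() -> DecisionProcessMatrix:
    """Build the 46-unit worked example in memory."""
    units = []
    for row in _UNITS:
        idx, kind = row[0], row[1]
        if kind == "CUE":
            units.append(Unit(idx, UnitKind.CUE, ref_id=row[2]))
        elif kind == "OPT":
            units.append(Unit(idx, UnitKind.OPTION, ref_id=row[2]))
        elif kind == "CONF":
            excl = bool(row[5]) if len(row) > 5 else False
            units.append(
                Unit(idx, UnitKind.CONFIDENCE, option_ref=row[2], cue_ref=row[3], level=row[4], is_exclusion=excl)
            )
        else:
            units.append(Unit(idx, UnitKind.FINAL, option_ref=row[2]))
    return DecisionProcessMatrix(
        metadata=CaseMetadata(case_id="example-01", resident_id="R01", patient_age=18, patient_sex="M"),
        units=tuple(units),
        cues=tuple(Cue(*c) for c in _CUES),
        options=tuple(OptionTrack(*o) for o in _OPTIONS),
    )


def example_case_path():
    """Path to the packaged JSON encoding of the worked example."""
    return resources.files("dpmkit") / "data" / "example_case.json"
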