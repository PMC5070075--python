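"""Readers, writers and a plain-text renderer for DPM case files.

Two equivalent single-file dialects are defined here (the elicitation
protocol itself has no machine format, so both dialects are defined by
this package):

* **JSON** (``dpm-1``): a versioned document with ``metadata``,
  ``cues``, ``options`` and ``units`` arrays.  Unknown fields are
  rejected, not ignored, so fixtures stay canonical; writing is
  deterministic (fixed key order, two-space indent, trailing newline),
  which makes round trips byte-stable.
* **CSV**: one row per unit with header
  ``order_index,kind,ref_id,text,option_ref,cue_ref,level,is_exclusion,source``
  and case metadata as leading ``#key=value`` comment lines.  Cue and
  option texts/sources travel on the rows that introduce them, so the
  two dialects interconvert losslessly.
"""

from __future__ import annotations

import csv as _csv
import io as _stdio
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .core import (
    CaseMetadata,
    Cue,
    CueSource,
    DecisionProcessMatrix,
    DpmError,
    OptionTrack,
    Outcome,
    TriState,
    Unit,
    UnitKind,
)

FORMAT_VERSION = "dpm-1"

PathLike = Union[str, Path]


class DpmFormatError(DpmError):
    """A file does not conform to one of the dpm dialects.

    ``where`` is a JSON pointer (JSON dialect) or a row number
    (CSV dialect)."""

    def __init__(self, message: str, where: str = ""):
        self.where = where
        super().__init__(f"{message}" + (f" (at {where})" if where else ""))


@dataclass(frozen=True)
class DpmDocument:
    format_version: str
    case: DecisionProcessMatrix


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

_METADATA_KEYS = {
    "case_id",
    "resident_id",
    "patient_age",
    "patient_sex",
    "time_pressure",
    "stress",
    "case_experience",
    "similarity",
    "experience_months",
}
_UNIT_KEYS = {"order_index", "kind", "ref_id", "option_ref", "cue_ref", "level", "is_exclusion"}
_CUE_KEYS = {"cue_id", "text", "source"}
_OPTION_KEYS = {"option_id", "text", "outcome"}
_TOP_KEYS = {"format_version", "metadata", "cues", "options", "units"}


def _check_keys(obj: dict, allowed: set, required: set, pointer: str) -> None:
    if not isinstance(obj, dict):
        raise DpmFormatError("expected an object", pointer)
    unknown = set(obj) - allowed
    if unknown:
        raise DpmFormatError(f"unknown field(s) {sorted(unknown)}", pointer)
    missing = required - set(obj)
    if missing:
        raise DpmFormatError(f"missing required field(s) {sorted(missing)}", pointer)


def _metadata_from_obj(obj: dict, pointer: str) -> CaseMetadata:
    _check_keys(obj, _METADATA_KEYS, {"case_id"}, pointer)
    try:
        return CaseMetadata(
            case_id=str(obj["case_id"]),
            resident_id=str(obj.get("resident_id", "")),
            patient_age=obj.get("patient_age"),
            patient_sex=obj.get("patient_sex"),
            time_pressure=TriState(obj.get("time_pressure", "unknown")),
            stress=TriState(obj.get("stress", "unknown")),
            case_experience=TriState(obj.get("case_experience", "unknown")),
            similarity=obj.get("similarity"),
            experience_months=obj.get("experience_months"),
        )
    except ValueError as exc:
        raise DpmFormatError(str(exc), pointer) from exc


def _unit_from_obj(obj: dict, pointer: str) -> Unit:
    _check_keys(obj, _UNIT_KEYS, {"order_index", "kind"}, pointer)
    try:
        kind = UnitKind(obj["kind"])
    except ValueError as exc:
        raise DpmFormatError(f"unknown unit kind {obj['kind']!r}", pointer) from exc
    option_ref = obj.get("option_ref")
    if kind is UnitKind.FINAL:
        if not isinstance(option_ref, list):
            raise DpmFormatError("FINAL option_ref must be a list", pointer)
        option_ref = tuple(option_ref)
    elif option_ref is not None and not isinstance(option_ref, str):
        raise DpmFormatError("option_ref must be a string", pointer)
    if not isinstance(obj["order_index"], int):
        raise DpmFormatError("order_index must be an integer", pointer)
    return Unit(
        order_index=obj["order_index"],
        kind=kind,
        ref_id=obj.get("ref_id"),
        option_ref=option_ref,
        cue_ref=obj.get("cue_ref"),
        level=obj.get("level"),
        is_exclusion=bool(obj.get("is_exclusion", False)),
    )


def case_from_obj(doc: dict) -> DecisionProcessMatrix:
    """Build a case from a parsed ``dpm-1`` document, rejecting unknown fields."""
    _check_keys(doc, _TOP_KEYS, _TOP_KEYS, "/")
    if doc["format_version"] != FORMAT_VERSION:
        raise DpmFormatError(
            f"unsupported format_version {doc['format_version']!r}, expected {FORMAT_VERSION!r}",
            "/format_version",
        )
    metadata = _metadata_from_obj(doc["metadata"], "/metadata")
    cues = []
    for i, c in enumerate(doc["cues"]):
        ptr = f"/cues/{i}"
        _check_keys(c, _CUE_KEYS, _CUE_KEYS, ptr)
        try:
            cues.append(Cue(cue_id=str(c["cue_id"]), text=str(c["text"]), source=CueSource(c["source"])))
        except ValueError as exc:
            raise DpmFormatError(str(exc), ptr) from exc
    options = []
    for i, o in enumerate(doc["options"]):
        ptr = f"/options/{i}"
        _check_keys(o, _OPTION_KEYS, _OPTION_KEYS, ptr)
        try:
            options.append(
                OptionTrack(option_id=str(o["option_id"]), text=str(o["text"]), outcome=Outcome(o["outcome"]))
            )
        except ValueError as exc:
            raise DpmFormatError(str(exc), ptr) from exc
    units = [_unit_from_obj(u, f"/units/{i}") for i, u in enumerate(doc["units"])]
    return DecisionProcessMatrix(metadata=metadata, units=tuple(units), cues=tuple(cues), options=tuple(options))


def case_to_obj(dpm: DecisionProcessMatrix) -> dict:
    """Serialize to the canonical ``dpm-1`` object (optional fields omitted)."""
    md = dpm.metadata
    meta: dict = {"case_id": md.case_id, "resident_id": md.resident_id}
    if md.patient_age is not None:
        meta["patient_age"] = md.patient_age
    if md.patient_sex is not None:
        meta["patient_sex"] = md.patient_sex
    meta["time_pressure"] = md.time_pressure.value
    meta["stress"] = md.stress.value
    meta["case_experience"] = md.case_experience.value
    if md.similarity is not None:
        meta["similarity"] = md.similarity
    if md.experience_months is not None:
        meta["experience_months"] = md.experience_months

    units = []
    for u in dpm.units:
        obj: dict = {"order_index": u.order_index, "kind": u.kind.value}
        if u.ref_id is not None:
            obj["ref_id"] = u.ref_id
        if u.kind is UnitKind.FINAL:
            obj["option_ref"] = list(u.option_ref or ())
        elif u.option_ref is not None:
            obj["option_ref"] = u.option_ref
        if u.cue_ref is not None:
            obj["cue_ref"] = u.cue_ref
        if u.level is not None:
            obj["level"] = u.level
        if u.kind is UnitKind.CONFIDENCE:
            obj["is_exclusion"] = u.is_exclusion
        units.append(obj)

    return {
        "format_version": FORMAT_VERSION,
        "metadata": meta,
        "cues": [{"cue_id": c.cue_id, "text": c.text, "source": c.source.value} for c in dpm.cues],
        "options": [{"option_id": o.option_id, "text": o.text, "outcome": o.outcome.value} for o in dpm.options],
        "units": units,
    }


def dumps_json(dpm: DecisionProcessMatrix) -> str:
    return json.dumps(case_to_obj(dpm), indent=2, ensure_ascii=False) + "\n"


def loads_json(text: str) -> DecisionProcessMatrix:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DpmFormatError(f"not valid JSON: {exc}") from exc
    return case_from_obj(doc)


def read_json(path: PathLike) -> DecisionProcessMatrix:
    return loads_json(Path(path).read_text(encoding="utf-8"))


def write_json(dpm: DecisionProcessMatrix, path: PathLike) -> None:
    Path(path).write_text(dumps_json(dpm), encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

CSV_HEADER = ["order_index", "kind", "ref_id", "text", "option_ref", "cue_ref", "level", "is_exclusion", "source"]


def dumps_csv(dpm: DecisionProcessMatrix) -> str:
    cue_by_id = {c.cue_id: c for c in dpm.cues}
    opt_by_id = {o.option_id: o for o in dpm.options}
    buf = _stdio.StringIO()
    md = dpm.metadata
    meta_items = [
        ("case_id", md.case_id),
        ("resident_id", md.resident_id),
        ("patient_age", md.patient_age),
        ("patient_sex", md.patient_sex),
        ("time_pressure", md.time_pressure.value),
        ("stress", md.stress.value),
        ("case_experience", md.case_experience.value),
        ("similarity", md.similarity),
        ("experience_months", md.experience_months),
    ]
    for key, value in meta_items:
        if value is not None and value != "":
            buf.write(f"#{key}={value}\n")
    writer = _csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for u in dpm.units:
        text = source = ""
        ref_id = u.ref_id or ""
        option_ref = ""
        if u.kind is UnitKind.CUE:
            cue = cue_by_id.get(ref_id)
            if cue is not None:
                text, source = cue.text, cue.source.value
        elif u.kind is UnitKind.OPTION:
            opt = opt_by_id.get(ref_id)
            if opt is not None:
                text = opt.text
        elif u.kind is UnitKind.CONFIDENCE:
            option_ref = u.option_ref or ""
        elif u.kind is UnitKind.FINAL:
            option_ref = ";".join(u.option_ref or ())
        writer.writerow(
            [
                u.order_index,
                u.kind.value,
                ref_id,
                text,
                option_ref,
                u.cue_ref or "",
                "" if u.level is None else u.level,
                ("true" if u.is_exclusion else "false") if u.kind is UnitKind.CONFIDENCE else "",
                source,
            ]
        )
    return buf.getvalue()


_META_INT_KEYS = {"patient_age", "similarity", "experience_months"}
_META_TRISTATE_KEYS = {"time_pressure", "stress", "case_experience"}


def loads_csv(text: str) -> DecisionProcessMatrix:
    meta_kv: dict = {}
    lines = text.splitlines()
    row_no = 0
    while row_no < len(lines) and lines[row_no].startswith("#"):
        line = lines[row_no][1:]
        if "=" not in line:
            raise DpmFormatError("malformed metadata comment, expected #key=value", f"line {row_no + 1}")
        key, _, value = line.partition("=")
        meta_kv[key.strip()] = value
        row_no += 1
    reader = _csv.reader(lines[row_no:])
    try:
        header = next(reader)
    except StopIteration:
        raise DpmFormatError("empty CSV, missing header row") from None
    if header != CSV_HEADER:
        raise DpmFormatError(f"bad header row, expected {','.join(CSV_HEADER)}", f"line {row_no + 1}")

    meta_obj: dict = {"case_id": meta_kv.get("case_id", "")}
    for key, value in meta_kv.items():
        if key == "case_id":
            continue
        if key not in _METADATA_KEYS:
            raise DpmFormatError(f"unknown metadata key {key!r}")
        meta_obj[key] = int(value) if key in _META_INT_KEYS else value
    metadata = _metadata_from_obj(meta_obj, "metadata block")

    units: list[Unit] = []
    cues: list[Cue] = []
    options: list[OptionTrack] = []
    expected = 1
    for i, row in enumerate(reader):
        where = f"row {i + 1}"
        if len(row) != len(CSV_HEADER):
            raise DpmFormatError(f"expected {len(CSV_HEADER)} columns, got {len(row)}", where)
        raw_index, raw_kind, ref_id, text, option_ref, cue_ref, raw_level, raw_excl, source = row
        try:
            order_index = int(raw_index)
        except ValueError:
            raise DpmFormatError(f"order_index not an integer: {raw_index!r}", where) from None
        if order_index != expected:
            raise DpmFormatError(f"order_index {order_index} not consecutive (expected {expected})", where)
        expected += 1
        try:
            kind = UnitKind(raw_kind)
        except ValueError:
            raise DpmFormatError(f"unknown kind {raw_kind!r}", where) from None
        if kind is UnitKind.CUE:
            try:
                cues.append(Cue(cue_id=ref_id, text=text, source=CueSource(source)))
            except ValueError:
                raise DpmFormatError(f"unknown cue source {source!r}", where) from None
            units.append(Unit(order_index, kind, ref_id=ref_id))
        elif kind is UnitKind.OPTION:
            options.append(OptionTrack(option_id=ref_id, text=text))
            units.append(Unit(order_index, kind, ref_id=ref_id))
        elif kind is UnitKind.CONFIDENCE:
            if not option_ref:
                raise DpmFormatError("CONFIDENCE row with empty option_ref", where)
            if raw_level == "":
                raise DpmFormatError("CONFIDENCE row with empty level", where)
            units.append(
                Unit(
                    order_index,
                    kind,
                    option_ref=option_ref,
                    cue_ref=cue_ref or None,
                    level=int(raw_level),
                    is_exclusion=raw_excl == "true",
                )
            )
        else:  # FINAL
            refs = tuple(r for r in option_ref.split(";") if r)
            if not refs:
                raise DpmFormatError("FINAL row with empty option_ref", where)
            units.append(Unit(order_index, kind, option_ref=refs))

    # outcomes are derivable from the event log; reconstruct them
    final_ids = set()
    for u in units:
        if u.kind is UnitKind.FINAL:
            final_ids.update(u.option_ref)
    excluded_ids = {u.option_ref for u in units if u.kind is UnitKind.CONFIDENCE and u.is_exclusion}
    options = [
        OptionTrack(
            o.option_id,
            o.text,
            Outcome.FINAL
            if o.option_id in final_ids
            else Outcome.EXCLUDED
            if o.option_id in excluded_ids
            else Outcome.UNDETERMINED,
        )
        for o in options
    ]
    return DecisionProcessMatrix(metadata=metadata, units=tuple(units), cues=tuple(cues), options=tuple(options))


def read_csv(path: PathLike) -> DecisionProcessMatrix:
    return loads_csv(Path(path).read_text(encoding="utf-8"))


def write_csv(dpm: DecisionProcessMatrix, path: PathLike) -> None:
    Path(path).write_text(dumps_csv(dpm), encoding="utf-8")


# ---------------------------------------------------------------------------
# Plain-text matrix rendering
# ---------------------------------------------------------------------------


def render_matrix(dpm: DecisionProcessMatrix, partition=None) -> str:
    """Render the case as a text grid: cues as rows (in order of
    appearance), options as columns, cells ``index:level`` for each
    rating citing that cue/option pair.  Rows are prefixed with their
    phase when a partition is given.  Output is a pure function of the
    inputs.
    """
    intro_cue = {u.ref_id: u.order_index for u in dpm.units if u.kind is UnitKind.CUE}
    intro_opt = {u.ref_id: u.order_index for u in dpm.units if u.kind is UnitKind.OPTION}
    cue_order = sorted(dpm.cues, key=lambda c: intro_cue.get(c.cue_id, 0))
    opt_order = sorted(dpm.options, key=lambda o: intro_opt.get(o.option_id, 0))

    cells: dict = {}
    orphans = []  # ratings citing no cue
    for u in dpm.units:
        if u.kind is not UnitKind.CONFIDENCE:
            continue
        marker = f"{u.order_index:02d}:{u.level:+d}" + ("!" if u.is_exclusion else "")
        if u.cue_ref is None:
            orphans.append((u.option_ref, marker))
        else:
            cells.setdefault((u.cue_ref, u.option_ref), []).append(marker)

    def phase_of(idx: int) -> str:
        if partition is None:
            return ""
        if idx <= partition.phase1_end:
            return "P1"
        if idx <= partition.phase2_end:
            return "P2"
        return "P3"

    headers = [f"{intro_opt.get(o.option_id, 0):02d} {o.text}" for o in opt_order]
    rows = []
    for c in cue_order:
        label = f"{intro_cue.get(c.cue_id, 0):02d} {c.text} [{c.source.value}]"
        row = [phase_of(intro_cue.get(c.cue_id, 0)), label]
        for o in opt_order:
            row.append(" ".join(cells.get((c.cue_id, o.option_id), [])))
        rows.append(row)
    if orphans:
        row = ["", "(no cue)"]
        for o in opt_order:
            row.append(" ".join(m for oid, m in orphans if oid == o.option_id))
        rows.append(row)

    table = [["", f"case {dpm.metadata.case_id}"] + headers] + rows
    widths = [max(len(r[i]) for r in table) for i in range(len(table[0]))]
    lines = [" | ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in table]
    f = dpm.final_unit
    if f is not None:
        names = ", ".join(dpm.option(oid).text for oid in (f.option_ref or ()))
        lines.append(f"{phase_of(f.order_index)} {f.order_index:02d} final -> {names}".strip())
    return "\n".join(lines) + "\n"
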