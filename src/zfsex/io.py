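"""Plate-level qPCR data structures and text dialects.

Two input dialects are supported:

* **trace** — long-format amplification curves: ``well,dye,cycle,rfu``, one
  row per measured cycle;
* **endpoint** — instrument-style endpoint export: ``well,dye,cq,end_rfu``,
  where an empty ``cq`` field means "never crossed the threshold" (absent),
  never zero.

Both round-trip bit-exactly through their writers.  All files are UTF-8
delimited text, comma by default with tab accepted.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "WellRecord", "SampleSheetRow", "RunBundle", "PlateGeometry",
    "read_trace_table", "write_trace_table",
    "read_endpoint_table", "write_endpoint_table",
    "read_sample_sheet", "write_sample_sheet",
    "write_well_results", "write_specimen_results",
    "render_risk", "SchemaError", "ParseError",
]


class SchemaError(ValueError):
    """Input file does not match the expected header/schema."""


class ParseError(ValueError):
    """A data row could not be parsed; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass(frozen=True)
class PlateGeometry:
    """Well coordinate validator; 96-well (A–H × 1–12) by default."""

    rows: str = "ABCDEFGH"
    columns: int = 12

    @classmethod
    def plate384(cls) -> "PlateGeometry":
        return cls(rows="ABCDEFGHIJKLMNOP", columns=24)

    def validate(self, well: str) -> str:
        well = well.strip().upper()
        if len(well) < 2 or well[0] not in self.rows:
            raise ValueError(f"bad well coordinate {well!r}")
        try:
            col = int(well[1:])
        except ValueError:
            raise ValueError(f"bad well coordinate {well!r}") from None
        if not 1 <= col <= self.columns:
            raise ValueError(f"well column out of range: {well!r}")
        return f"{well[0]}{col}"

    def all_wells(self) -> list[str]:
        return [f"{r}{c}" for r in self.rows for c in range(1, self.columns + 1)]


@dataclass
class WellRecord:
    """One well × one dye: a trace and/or an endpoint (Cq, final RFU)."""

    well: str
    dye: str
    trace: Optional[list[tuple[int, float]]] = None
    cq: Optional[float] = None
    end_rfu: Optional[float] = None

    def __post_init__(self) -> None:
        if self.trace is None and (self.cq is None and self.end_rfu is None):
            raise ValueError(f"{self.well}/{self.dye}: neither trace nor endpoint data")
        if self.cq is not None and self.cq < 0:
            raise ValueError(f"{self.well}/{self.dye}: negative Cq")
        if self.trace is not None:
            cycles = [c for c, _ in self.trace]
            if cycles != list(range(1, len(cycles) + 1)):
                raise ValueError(
                    f"{self.well}/{self.dye}: trace cycles must be 1..C with no gaps"
                )
            if self.end_rfu is not None and not math.isclose(
                self.end_rfu, self.trace[-1][1], rel_tol=0, abs_tol=1e-9
            ):
                raise ValueError(
                    f"{self.well}/{self.dye}: end_rfu disagrees with final trace value"
                )

    @property
    def final_rfu(self) -> Optional[float]:
        if self.end_rfu is not None:
            return self.end_rfu
        if self.trace:
            return self.trace[-1][1]
        return None

    def fluorescence(self) -> list[float]:
        if self.trace is None:
            raise ValueError(f"{self.well}/{self.dye}: no trace")
        return [f for _, f in self.trace]


ROLES = ("unknown", "standard", "ntc", "extraction_blank")


@dataclass(frozen=True)
class SampleSheetRow:
    well: str
    specimen_id: str
    replicate_index: int = 1
    role: str = "unknown"
    standard_copies: Optional[float] = None
    known_sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        if (self.standard_copies is not None) != (self.role == "standard"):
            raise ValueError("standard_copies present exactly when role=standard")
        if self.standard_copies is not None and self.standard_copies <= 0:
            raise ValueError("standard_copies must be > 0")
        if self.known_sex is not None and self.known_sex not in ("male", "female"):
            raise ValueError(f"known_sex must be male/female, got {self.known_sex!r}")


@dataclass
class RunBundle:
    """A full run: well records + sample sheet + run-level metadata."""

    records: list[WellRecord] = field(default_factory=list)
    sheet: list[SampleSheetRow] = field(default_factory=list)
    cycles: int = 40
    metadata: dict = field(default_factory=dict)

    def validate(self, dyes: Sequence[str] = ("FAM", "VIC")) -> None:
        seen: dict[str, set[str]] = {}
        for rec in self.records:
            seen.setdefault(rec.well, set()).add(rec.dye)
            if rec.trace is not None and len(rec.trace) != self.cycles:
                raise ValueError(
                    f"{rec.well}/{rec.dye}: trace length {len(rec.trace)} != "
                    f"run cycles {self.cycles}"
                )
            if rec.cq is not None and rec.cq > self.cycles:
                raise ValueError(f"{rec.well}/{rec.dye}: Cq beyond cycle count")
        sheet_wells = {row.well for row in self.sheet}
        for well, have in seen.items():
            if well not in sheet_wells:
                raise ValueError(f"orphan well record {well} not on sample sheet")
        for row in self.sheet:
            missing = set(dyes) - seen.get(row.well, set())
            if missing:
                raise ValueError(
                    f"sheet well {row.well} missing records for dyes {sorted(missing)}"
                )
        unknowns = [(r.specimen_id, r.replicate_index)
                    for r in self.sheet if r.role == "unknown"]
        if len(unknowns) != len(set(unknowns)):
            raise ValueError("duplicate (specimen_id, replicate_index) among unknowns")

    def record(self, well: str, dye: str) -> WellRecord:
        for rec in self.records:
            if rec.well == well and rec.dye == dye:
                return rec
        raise KeyError(f"no record for {well}/{dye}")


def _sniff_reader(stream: TextIO) -> csv.reader:
    first = stream.readline()
    delim = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    rest = stream.read()
    return csv.reader((first + rest).splitlines(), delimiter=delim)


def _check_header(header: list[str], required: Sequence[str]) -> None:
    cols = [h.strip().lower() for h in header]
    for col in required:
        if col not in cols:
            raise SchemaError(f"missing required column {col!r} (header: {cols})")


def _index(header: list[str]) -> dict[str, int]:
    return {h.strip().lower(): i for i, h in enumerate(header)}


def read_trace_table(stream: TextIO, geometry: PlateGeometry = PlateGeometry()) -> list[WellRecord]:
    """Read long-format traces (``well,dye,cycle,rfu``) into WellRecords.

    Records come back in deterministic order: row-major wells, then dye
    lexicographic.  Duplicate (well, dye, cycle) rows and non-numeric
    fluorescence are hard errors carrying the offending line number.
    """
    reader = _sniff_reader(stream)
    rows = list(reader)
    if not rows:
        logger.warning("empty trace table")
        return []
    _check_header(rows[0], ("well", "dye", "cycle", "rfu"))
    idx = _index(rows[0])
    data: dict[tuple[str, str], dict[int, float]] = {}
    for ln, row in enumerate(rows[1:], start=2):
        if not row or not any(cell.strip() for cell in row):
            continue
        try:
            well = geometry.validate(row[idx["well"]])
        except ValueError as exc:
            raise ParseError(str(exc), ln) from None
        dye = row[idx["dye"]].strip()
        try:
            cycle = int(row[idx["cycle"]])
        except ValueError:
            raise ParseError(f"non-integer cycle {row[idx['cycle']]!r}", ln) from None
        if cycle < 1:
            raise ParseError(f"cycle must be >= 1, got {cycle}", ln)
        try:
            rfu = float(row[idx["rfu"]])
        except ValueError:
            raise ParseError(f"non-numeric fluorescence {row[idx['rfu']]!r}", ln) from None
        if math.isnan(rfu):
            raise ParseError("NaN fluorescence", ln)
        key = (well, dye)
        if cycle in data.setdefault(key, {}):
            raise ParseError(f"duplicate (well,dye,cycle) = {key + (cycle,)}", ln)
        data[key][cycle] = rfu

    def well_key(item):
        (well, dye), _ = item
        return (well[0], int(well[1:]), dye)

    records = []
    for (well, dye), points in sorted(data.items(), key=well_key):
        trace = sorted(points.items())
        records.append(WellRecord(well=well, dye=dye, trace=[(c, f) for c, f in trace]))
    return records


def write_trace_table(records: Iterable[WellRecord], stream: TextIO, delimiter: str = ",") -> None:
    w = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
    w.writerow(["well", "dye", "cycle", "rfu"])
    for rec in records:
        if rec.trace is None:
            raise ValueError(f"{rec.well}/{rec.dye} has no trace")
        for cycle, rfu in rec.trace:
            w.writerow([rec.well, rec.dye, cycle, repr(rfu)])


def read_endpoint_table(
    stream: TextIO,
    geometry: PlateGeometry = PlateGeometry(),
    cycles: int = 40,
) -> list[WellRecord]:
    """Read endpoint rows (``well,dye,cq,end_rfu``); empty cq = no Cq."""
    reader = _sniff_reader(stream)
    rows = list(reader)
    if not rows:
        logger.warning("empty endpoint table")
        return []
    _check_header(rows[0], ("well", "dye", "cq", "end_rfu"))
    idx = _index(rows[0])
    records = []
    for ln, row in enumerate(rows[1:], start=2):
        if not row or not any(cell.strip() for cell in row):
            continue
        try:
            well = geometry.validate(row[idx["well"]])
        except ValueError as exc:
            raise ParseError(str(exc), ln) from None
        dye = row[idx["dye"]].strip()
        raw_cq = row[idx["cq"]].strip()
        cq: Optional[float] = None
        if raw_cq:
            try:
                cq = float(raw_cq)
            except ValueError:
                raise ParseError(f"non-numeric cq {raw_cq!r}", ln) from None
            if math.isnan(cq):
                raise ParseError("NaN cq", ln)
            if not 0 <= cq <= cycles:
                raise ParseError(f"cq {cq} outside [0, {cycles}]", ln)
        try:
            end_rfu = float(row[idx["end_rfu"]])
        except ValueError:
            raise ParseError(f"non-numeric end_rfu {row[idx['end_rfu']]!r}", ln) from None
        if math.isnan(end_rfu):
            raise ParseError("NaN end_rfu", ln)
        records.append(WellRecord(well=well, dye=dye, cq=cq, end_rfu=end_rfu))
    return records


def write_endpoint_table(records: Iterable[WellRecord], stream: TextIO, delimiter: str = ",") -> None:
    w = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
    w.writerow(["well", "dye", "cq", "end_rfu"])
    for rec in records:
        cq = "" if rec.cq is None else repr(rec.cq)
        end = rec.final_rfu
        if end is None:
            raise ValueError(f"{rec.well}/{rec.dye} has no endpoint fluorescence")
        w.writerow([rec.well, rec.dye, cq, repr(end)])


def read_sample_sheet(stream: TextIO, geometry: PlateGeometry = PlateGeometry()) -> list[SampleSheetRow]:
    reader = _sniff_reader(stream)
    rows = list(reader)
    if not rows:
        logger.warning("empty sample sheet")
        return []
    _check_header(rows[0], ("well", "specimen_id", "replicate_index", "role"))
    idx = _index(rows[0])
    out = []
    for ln, row in enumerate(rows[1:], start=2):
        if not row or not any(cell.strip() for cell in row):
            continue
        try:
            well = geometry.validate(row[idx["well"]])
            copies_raw = row[idx["standard_copies"]].strip() if "standard_copies" in idx else ""
            sex_raw = row[idx["known_sex"]].strip() if "known_sex" in idx else ""
            out.append(SampleSheetRow(
                well=well,
                specimen_id=row[idx["specimen_id"]].strip(),
                replicate_index=int(row[idx["replicate_index"]]),
                role=row[idx["role"]].strip().lower(),
                standard_copies=float(copies_raw) if copies_raw else None,
                known_sex=sex_raw.lower() or None,
            ))
        except ValueError as exc:
            raise ParseError(str(exc), ln) from None
    return out


def write_sample_sheet(sheet: Iterable[SampleSheetRow], stream: TextIO, delimiter: str = ",") -> None:
    w = csv.writer(stream, delimiter=delimiter, lineterminator="\n")
    w.writerow(["well", "specimen_id", "replicate_index", "role", "standard_copies", "known_sex"])
    for row in sheet:
        w.writerow([
            row.well, row.specimen_id, row.replicate_index, row.role,
            "" if row.standard_copies is None else repr(row.standard_copies),
            row.known_sex or "",
        ])


# --- results rendering -----------------------------------------------------

def render_risk(risk: Optional[float], n: int) -> str:
    """Render a false-homozygote risk the way the specimen table prints it:
    one-decimal percent, floored at "<0.1%", "na" when no discriminant
    replicate exists."""
    if n == 0 or risk is None:
        return "na"
    if risk < 0.001:
        return "<0.1%"
    return f"{risk * 100:.1f}%"


def _fmt(value: Optional[float], decimals: int) -> str:
    if value is None:
        return ""
    text = f"{value:.{decimals}f}"
    # avoid "-0" / "-0.0" for values that round to zero
    if float(text) == 0:
        text = text.lstrip("-")
    return text


def write_well_results(rows: Iterable[dict], stream: TextIO) -> None:
    """Per-well call table, tab-separated, fixed column order.

    Cq at 2 decimals, copy numbers at 1 decimal.
    """
    cols = ["well", "specimen_id", "replicate_index", "call",
            "cq_x", "cq_y", "end_rfu_x", "end_rfu_y", "copies_x", "copies_y"]
    stream.write("\t".join(cols) + "\n")
    for row in rows:
        out = [
            str(row["well"]), str(row["specimen_id"]), str(row["replicate_index"]),
            str(row["call"]),
            _fmt(row.get("cq_x"), 2), _fmt(row.get("cq_y"), 2),
            _fmt(row.get("end_rfu_x"), 1), _fmt(row.get("end_rfu_y"), 1),
            _fmt(row.get("copies_x"), 1), _fmt(row.get("copies_y"), 1),
        ]
        stream.write("\t".join(out) + "\n")


def write_specimen_results(rows: Iterable[dict], stream: TextIO) -> None:
    """Per-specimen consensus table mirroring the published cohort layout:
    replicate breakdown, mean RFU and copy number per allele, inferred sex
    with status, and the rendered (P_XX)^n dropout risk."""
    cols = ["specimen_id", "pcr_positive", "n_xx", "n_xy", "n_yy", "n_inconclusive",
            "mean_rfu_y", "mean_rfu_x", "mean_cn_y", "mean_cn_x", "mean_cn_total",
            "sex", "status", "risk", "flags"]
    stream.write("\t".join(cols) + "\n")
    for row in rows:
        out = [
            str(row["specimen_id"]),
            str(row["pcr_positive"]), str(row["n_xx"]), str(row["n_xy"]),
            str(row["n_yy"]), str(row["n_inconclusive"]),
            _fmt(row.get("mean_rfu_y"), 0), _fmt(row.get("mean_rfu_x"), 0),
            _fmt(row.get("mean_cn_y"), 1), _fmt(row.get("mean_cn_x"), 1),
            _fmt(row.get("mean_cn_total"), 1),
            str(row["sex"]), str(row["status"]), str(row["risk"]),
            ";".join(row.get("flags", [])),
        ]
        stream.write("\t".join(out) + "\n")
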