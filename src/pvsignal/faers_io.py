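"""Reading and writing FAERS-dialect quarterly ASCII tables.

The FDA Adverse Event Reporting System publishes each quarter as seven
``$``-delimited text tables (DEMO, DRUG, REAC, THER, INDI, OUTC, RPSR), one
header line followed by one row per record fragment, all joined on
``PRIMARYID``.  This module parses that dialect into typed case records and
writes pipeline outputs.  Partial dates (FAERS date tokens are 4, 6 or
8 digits) are retained with an explicit precision instead of being imputed;
downstream consumers decide how to handle them.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

TABLE_NAMES = ("demo", "drug", "reac", "ther", "indi", "outc", "rpsr")

#: FAERS outcome codes (OUTC_COD). DE death, LT life-threatening,
#: HO hospitalization, DS disability, CA congenital anomaly,
#: RI required intervention, OT other.
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})


class FaersFormatError(ValueError):
    """A table-level format violation (e.g. a mandatory column is absent)."""


class DateParseError(ValueError):
    """A date token that is not a valid 4/6/8-digit FAERS date."""


@dataclass(frozen=True, slots=True)
class CalendarDate:
    """A possibly partial calendar date.

    FAERS emits dates as YYYY, YYYYMM or YYYYMMDD tokens; precision records
    which form was seen.  Ordering places missing parts earliest (a
    year-precision date sorts before any fully specified date in that year).
    """

    year: int
    month: int | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day requires month")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    @property
    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> _dt.date:
        """Exact date; requires day precision."""
        if self.precision != "day":
            raise ValueError(f"not day-precise: {self}")
        return _dt.date(self.year, self.month, self.day)

    def token(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_date(token: str) -> CalendarDate | None:
    """Parse a FAERS date token into a :class:`CalendarDate`.

    Empty tokens mean missing and return ``None``.  8 digits give day
    precision, 6 month, 4 year; anything else, or an impossible calendar
    part, raises :class:`DateParseError`.
    """
    token = token.strip()
    if not token:
        return None
    if not token.isdigit() or len(token) not in (4, 6, 8):
        raise DateParseError(f"bad date token {token!r}")
    year = int(token[:4])
    if len(token) == 4:
        return CalendarDate(year)
    month = int(token[4:6])
    if not 1 <= month <= 12:
        raise DateParseError(f"bad date token {token!r}")
    if len(token) == 6:
        return CalendarDate(year, month)
    day = int(token[6:8])
    try:
        _dt.date(year, month, day)
    except ValueError as exc:
        raise DateParseError(f"bad date token {token!r}") from exc
    return CalendarDate(year, month, day)


@dataclass(frozen=True, slots=True)
class DrugEntry:
    """One drug mention on a report: verbatim name, canonical target name
    (``None`` when the name is not a study drug), FAERS role code and the
    therapy start date from THER, when linkable."""

    verbatim: str
    canonical: str | None
    role: str
    start_dt: CalendarDate | None = None


@dataclass(slots=True)
class CaseRecord:
    """One assembled safety report (one PRIMARYID)."""

    primaryid: str
    caseid: str
    fda_dt: CalendarDate
    sex: str = "unknown"  # female | male | unknown
    age_years: float | None = None
    weight_kg: float | None = None
    country: str = "unknown"
    event_dt: CalendarDate | None = None
    drugs: list[DrugEntry] = field(default_factory=list)
    events: set[str] = field(default_factory=set)
    outcomes: set[str] = field(default_factory=set)

    def has_role(self, canonical: str, role: str) -> bool:
        return any(d.canonical == canonical and d.role == role for d in self.drugs)


@dataclass(slots=True)
class RejectedRow:
    table: str
    line_number: int
    reason: str


@dataclass(slots=True)
class RawQuarter:
    """The seven tables of one quarter, parsed into field-maps."""

    quarter_label: str
    demo_rows: list[dict[str, str]] = field(default_factory=list)
    drug_rows: list[dict[str, str]] = field(default_factory=list)
    reac_rows: list[dict[str, str]] = field(default_factory=list)
    ther_rows: list[dict[str, str]] = field(default_factory=list)
    indi_rows: list[dict[str, str]] = field(default_factory=list)
    outc_rows: list[dict[str, str]] = field(default_factory=list)
    rpsr_rows: list[dict[str, str]] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)

    def rows(self, table: str) -> list[dict[str, str]]:
        return getattr(self, f"{table}_rows")


def _parse_table(path: Path, table: str, delimiter: str,
                 rejects: list[RejectedRow]) -> list[dict[str, str]]:
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise FaersFormatError(f"{table}: empty file, no header")
        header = [h.strip().upper() for h in header_line.split(delimiter)]
        if "PRIMARYID" not in header:
            raise FaersFormatError(f"{table}: mandatory column PRIMARYID missing")
        n_cols = len(header)
        rows: list[dict[str, str]] = []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            tokens = line.split(delimiter)
            if len(tokens) != n_cols:
                rejects.append(RejectedRow(
                    table, line_no,
                    f"expected {n_cols} fields, got {len(tokens)}"))
                continue
            rows.append({col: tok.strip() for col, tok in zip(header, tokens)})
        return rows


def parse_quarter(paths: Mapping[str, str | Path], quarter_label: str = "",
                  delimiter: str = "$") -> RawQuarter:
    """Parse one quarter's tables.

    ``paths`` maps lower-case table names (subset of :data:`TABLE_NAMES`) to
    file paths.  Ragged rows are collected into ``quarter.rejects`` and
    skipped; a table missing PRIMARYID raises :class:`FaersFormatError`.
    """
    quarter = RawQuarter(quarter_label=quarter_label)
    for table, path in paths.items():
        if table not in TABLE_NAMES:
            raise FaersFormatError(f"unknown table {table!r}")
        rows = _parse_table(Path(path), table, delimiter, quarter.rejects)
        getattr(quarter, f"{table}_rows").extend(rows)
    return quarter


def write_table(path: str | Path, header: Sequence[str],
                rows: Iterable[Mapping[str, str]], delimiter: str = "$") -> None:
    """Write rows in the FAERS dialect (header line + delimited rows)."""
    header = [h.upper() for h in header]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(header) + "\n")
        for row in rows:
            fh.write(delimiter.join(str(row.get(col, "")) for col in header) + "\n")


def write_quarter(quarter: RawQuarter, out_dir: str | Path,
                  headers: Mapping[str, Sequence[str]],
                  delimiter: str = "$") -> dict[str, Path]:
    """Write all seven tables of a quarter; returns table -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = quarter.quarter_label.upper()
    paths: dict[str, Path] = {}
    for table in TABLE_NAMES:
        path = out_dir / f"{table.upper()}{suffix}.txt"
        write_table(path, headers[table], quarter.rows(table), delimiter)
        paths[table] = path
    return paths


def write_rejects(rejects: Sequence[RejectedRow], path: str | Path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["table", "line_number", "reason"])
        for r in rejects:
            writer.writerow([r.table, r.line_number, r.reason])


_AGE_FACTORS = {"": 1.0, "YR": 1.0, "DEC": 10.0, "MON": 1 / 12,
                "WK": 1 / 52.1775, "DY": 1 / 365.25, "HR": 1 / 8766.0}
_WT_FACTORS = {"": 1.0, "KG": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}


def _to_years(age: str, code: str) -> float | None:
    try:
        value = float(age)
    except ValueError:
        return None
    factor = _AGE_FACTORS.get(code.upper())
    return value * factor if factor is not None else None


def _to_kg(weight: str, code: str) -> float | None:
    try:
        value = float(weight)
    except ValueError:
        return None
    factor = _WT_FACTORS.get(code.upper())
    return value * factor if factor is not None else None


_SEX_MAP = {"F": "female", "M": "male"}


@dataclass(slots=True)
class AssemblyStats:
    """Bookkeeping from record assembly."""

    dropped_no_demo: int = 0
    primaryid_collisions: int = 0


def assemble_records(quarters: Sequence[RawQuarter], synonyms=None,
                     ) -> tuple[list[CaseRecord], AssemblyStats]:
    """Join the per-table rows into one :class:`CaseRecord` per PRIMARYID.

    DRUG/REAC/THER/OUTC fragments lacking a DEMO row are dropped and counted.
    A PRIMARYID seen in several quarters keeps the later-parsed DEMO row
    (collision counted).  PTs are deduplicated within a record; drug names
    are normalized through ``synonyms`` (a
    :class:`~pvsignal.dedup_normalize.SynonymDictionary` or ``None``).
    """
    stats = AssemblyStats()
    records: dict[str, CaseRecord] = {}

    for quarter in quarters:
        for row in quarter.demo_rows:
            pid = row.get("PRIMARYID", "")
            caseid = row.get("CASEID", "")
            fda_dt = parse_date(row.get("FDA_DT", "")) or CalendarDate(1900)
            if pid in records:
                stats.primaryid_collisions += 1
            records[pid] = CaseRecord(
                primaryid=pid,
                caseid=caseid,
                fda_dt=fda_dt,
                sex=_SEX_MAP.get(row.get("SEX", "").upper(), "unknown"),
                age_years=_to_years(row.get("AGE", ""), row.get("AGE_COD", "")),
                weight_kg=_to_kg(row.get("WT", ""), row.get("WT_COD", "")),
                country=row.get("OCCR_COUNTRY", "") or "unknown",
                event_dt=parse_date(row.get("EVENT_DT", "")),
            )

    # THER start dates keyed by (primaryid, drug sequence number)
    starts: dict[tuple[str, str], CalendarDate] = {}
    for quarter in quarters:
        for row in quarter.ther_rows:
            key = (row.get("PRIMARYID", ""), row.get("DSG_DRUG_SEQ", ""))
            try:
                start = parse_date(row.get("START_DT", ""))
            except DateParseError:
                start = None
            if start is not None:
                starts[key] = start

    for quarter in quarters:
        for row in quarter.drug_rows:
            pid = row.get("PRIMARYID", "")
            record = records.get(pid)
            if record is None:
                stats.dropped_no_demo += 1
                continue
            verbatim = row.get("DRUGNAME", "")
            role = row.get("ROLE_COD", "").upper()
            if role not in ROLE_CODES:
                role = "C"
            canonical = synonyms.lookup(verbatim) if synonyms is not None else None
            start = starts.get((pid, row.get("DRUG_SEQ", "")))
            record.drugs.append(DrugEntry(verbatim, canonical, role, start))

        for row in quarter.reac_rows:
            record = records.get(row.get("PRIMARYID", ""))
            if record is None:
                stats.dropped_no_demo += 1
                continue
            pt = row.get("PT", "").strip()
            if pt:
                record.events.add(pt)

        for row in quarter.outc_rows:
            record = records.get(row.get("PRIMARYID", ""))
            if record is None:
                stats.dropped_no_demo += 1
                continue
            code = row.get("OUTC_COD", "").upper()
            record.outcomes.add(code if code in OUTCOME_CODES else "unknown")

    return list(records.values()), stats
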