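"""Reading and writing FAERS-style "$"-delimited ASCII tables.

The dialect is the one used by modern FAERS quarterly extracts: a header
line, "$" as the field separator, no quoting (fields must not contain "$"),
UTF-8, one record per line, missing values rendered as the empty string.

Dates in spontaneous reports are often partial (``YYYYMM`` or ``YYYY``);
they are kept as :class:`PartialDate` pairs of (date, precision) so that
downstream exclusion rules can distinguish *missing* from *inaccurate*.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, fields as _dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Optional

DELIMITER = "$"

#: canonical file names for the six table kinds
FILE_NAMES = {
    "DEMO": "DEMO.txt",
    "DRUG": "DRUG.txt",
    "REAC": "REAC.txt",
    "INDI": "INDI.txt",
    "THER": "THER.txt",
    "RPSR": "RPSR.txt",
}

AGE_UNIT_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})


class SchemaError(ValueError):
    """A table file does not match the expected schema."""


@dataclass(frozen=True)
class PartialDate:
    """A date token of day, month or year precision (or invalid)."""

    date: Optional[_dt.date]
    precision: str  # 'day' | 'month' | 'year' | 'invalid'

    @property
    def is_day(self) -> bool:
        return self.precision == "day"


def parse_partial_date(token: Optional[str]) -> PartialDate:
    """Parse a FAERS date token.

    ``YYYYMMDD`` -> day precision, ``YYYYMM`` -> month (day set to 1),
    ``YYYY`` -> year (Jan 1); anything else, including empty/None, is
    invalid.  Total function: never raises.
    """
    if not token:
        return PartialDate(None, "invalid")
    token = token.strip()
    if not token.isdigit():
        return PartialDate(None, "invalid")
    try:
        if len(token) == 8:
            return PartialDate(
                _dt.date(int(token[:4]), int(token[4:6]), int(token[6:8])), "day"
            )
        if len(token) == 6:
            return PartialDate(_dt.date(int(token[:4]), int(token[4:6]), 1), "month")
        if len(token) == 4:
            year = int(token)
            if year < 1900 or year > 2100:
                return PartialDate(None, "invalid")
            return PartialDate(_dt.date(year, 1, 1), "year")
    except ValueError:
        return PartialDate(None, "invalid")
    return PartialDate(None, "invalid")


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class DemographicRecord:
    primary_id: str
    case_id: str
    fda_dt: Optional[str] = None  # raw token; YYYYMMDD sorts chronologically
    event_dt: Optional[str] = None
    age: Optional[float] = None
    age_unit: Optional[str] = None
    sex: Optional[str] = None
    weight_kg: Optional[float] = None
    reporter_country: Optional[str] = None
    occupation: Optional[str] = None


@dataclass(frozen=True)
class DrugRecord:
    primary_id: str
    drug_name: str
    role: str


@dataclass(frozen=True)
class ReactionRecord:
    primary_id: str
    pt: str


@dataclass(frozen=True)
class IndicationRecord:
    primary_id: str
    indication_pt: str


@dataclass(frozen=True)
class TherapyRecord:
    primary_id: str
    start_dt: Optional[str] = None
    end_dt: Optional[str] = None


@dataclass(frozen=True)
class ReportSourceRecord:
    primary_id: str
    source_code: Optional[str] = None


# ---------------------------------------------------------------------------
# schema registry: column name -> (field, parser, formatter)


def _opt_str(tok: str) -> Optional[str]:
    return tok if tok != "" else None


def _req_str(tok: str) -> str:
    return tok


def _opt_float(tok: str) -> Optional[float]:
    if tok == "":
        return None
    try:
        return float(tok)
    except ValueError:
        return None  # unparseable numerics become missing, not errors


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


_SCHEMAS = {
    "DEMO": (
        DemographicRecord,
        [
            ("PRIMARYID", "primary_id", _req_str),
            ("CASEID", "case_id", _req_str),
            ("FDA_DT", "fda_dt", _opt_str),
            ("EVENT_DT", "event_dt", _opt_str),
            ("AGE", "age", _opt_float),
            ("AGE_COD", "age_unit", _opt_str),
            ("SEX", "sex", _opt_str),
            ("WT", "weight_kg", _opt_float),
            ("REPORTER_COUNTRY", "reporter_country", _opt_str),
            ("OCCP_COD", "occupation", _opt_str),
        ],
    ),
    "DRUG": (
        DrugRecord,
        [
            ("PRIMARYID", "primary_id", _req_str),
            ("DRUGNAME", "drug_name", _req_str),
            ("ROLE_COD", "role", _req_str),
        ],
    ),
    "REAC": (
        ReactionRecord,
        [("PRIMARYID", "primary_id", _req_str), ("PT", "pt", _req_str)],
    ),
    "INDI": (
        IndicationRecord,
        [("PRIMARYID", "primary_id", _req_str), ("INDI_PT", "indication_pt", _req_str)],
    ),
    "THER": (
        TherapyRecord,
        [
            ("PRIMARYID", "primary_id", _req_str),
            ("START_DT", "start_dt", _opt_str),
            ("END_DT", "end_dt", _opt_str),
        ],
    ),
    "RPSR": (
        ReportSourceRecord,
        [("PRIMARYID", "primary_id", _req_str), ("RPSR_COD", "source_code", _opt_str)],
    ),
}

TABLE_KINDS = tuple(_SCHEMAS)


def read_table(path: str | Path, kind: str) -> Iterator:
    """Yield typed records from a "$"-delimited table.

    Column order is resolved by header name, case-insensitively; extra
    columns are ignored.  Unparseable numeric fields become missing.
    Raises :class:`SchemaError` on an empty file or missing columns.
    """
    record_type, columns = _SCHEMAS[kind]
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if header_line == "":
            raise SchemaError(f"{path}: empty file (no header)")
        header = [h.strip().upper() for h in header_line.rstrip("\n").split(DELIMITER)]
        index = {name: i for i, name in enumerate(header)}
        missing = [col for col, _, _ in columns if col not in index]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
        positions = [(index[col], field, parser) for col, field, parser in columns]
        for line in fh:
            parts = line.rstrip("\n").split(DELIMITER)
            kwargs = {}
            for pos, field, parser in positions:
                tok = parts[pos] if pos < len(parts) else ""
                kwargs[field] = parser(tok)
            yield record_type(**kwargs)


def write_table(records: Iterable, path: str | Path, kind: str) -> int:
    """Write records of one kind; returns the row count.

    Missing fields are rendered as empty strings.  Mixed record kinds
    raise ``ValueError``.
    """
    record_type, columns = _SCHEMAS[kind]
    field_order = [field for _, field, _ in columns]
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(DELIMITER.join(col for col, _, _ in columns) + "\n")
        for rec in records:
            if not isinstance(rec, record_type):
                raise ValueError(
                    f"expected {record_type.__name__}, got {type(rec).__name__}"
                )
            values = [_fmt(getattr(rec, f)) for f in field_order]
            for v in values:
                if DELIMITER in v:
                    raise ValueError(f"field value contains the delimiter: {v!r}")
            fh.write(DELIMITER.join(values) + "\n")
            n += 1
    return n


def record_fields(kind: str) -> tuple:
    """Field names of the record type for a table kind (schema order)."""
    return tuple(f.name for f in _dc_fields(_SCHEMAS[kind][0]))
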