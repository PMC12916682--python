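"""Reading and writing FAERS-dialect quarterly ASCII tables.

FAERS quarterly extracts ship one ``$``-delimited text file per table
(DEMO, DRUG, REAC, OUTC, RPSR, THER, INDI) per quarter, with a single
header row and no quoting or escaping.  Tables are held in memory as
:class:`pandas.DataFrame` with all-string columns; empty fields become
:data:`pandas.NA`.  Partial dates (YYYY / YYYYMM / YYYYMMDD) are kept
verbatim so downstream stages decide usability.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import pandas as pd

DELIMITER = "$"

#: mandatory columns per table kind (modern, post-2014 schema only)
TABLE_SCHEMAS: Mapping[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
    "rpsr": ("primaryid", "rpsr_cod"),
}

#: known optional columns we retain when present
OPTIONAL_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "demo": ("event_dt", "age", "age_cod", "sex", "reporter_country", "occp_cod"),
    "drug": ("prod_ai",),
    "reac": (),
    "outc": (),
    "ther": ("end_dt",),
    "indi": (),
    "rpsr": (),
}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
AGE_UNIT_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})


class FaersSchemaError(ValueError):
    """A table is missing a mandatory column for its kind."""


class FaersParseError(ValueError):
    """A data line could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _check_kind(table_kind: str) -> str:
    kind = table_kind.lower()
    if kind not in TABLE_SCHEMAS:
        raise ValueError(
            f"unknown table kind {table_kind!r}; expected one of {sorted(TABLE_SCHEMAS)}"
        )
    return kind


def parse_faers_table(text_stream, table_kind: str) -> pd.DataFrame:
    """Parse one ``$``-delimited FAERS table into a string DataFrame.

    Parameters
    ----------
    text_stream
        Open text stream, path, or raw string containing the table.
    table_kind
        One of ``demo, drug, reac, outc, ther, indi, rpsr``
        (case-insensitive); decides which columns are mandatory.

    Returns
    -------
    DataFrame with lower-cased column names, string dtype, empty fields
    as ``pd.NA``; row count equals the number of data lines.  Unknown
    columns are dropped.
    """
    kind = _check_kind(table_kind)
    if isinstance(text_stream, str) and "\n" not in text_stream and "$" not in text_stream:
        # path-like string
        with open(text_stream, "r", encoding="utf-8", errors="replace") as fh:
            text = fh.read()
    elif isinstance(text_stream, str):
        text = text_stream
    elif isinstance(text_stream, (bytes, bytearray)):
        text = bytes(text_stream).decode("utf-8", errors="replace")
    else:
        text = text_stream.read()
        if isinstance(text, bytes):
            text = text.decode("utf-8", errors="replace")

    lines = text.splitlines()
    if not lines:
        raise FaersSchemaError(f"{kind}: empty input (no header line)")
    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in header]
    if missing:
        raise FaersSchemaError(
            f"{kind}: missing mandatory column(s) {', '.join(missing)}"
        )

    ncol = len(header)
    rows: list[list[str]] = []
    for i, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        fields = line.split(DELIMITER)
        if len(fields) != ncol:
            raise FaersParseError(
                f"expected {ncol} fields, found {len(fields)}", line_number=i
            )
        rows.append(fields)

    keep = [c for c in header if c in TABLE_SCHEMAS[kind] + OPTIONAL_COLUMNS[kind]]
    df = pd.DataFrame(rows, columns=header, dtype="string")
    df = df[keep]
    df = df.apply(lambda s: s.str.strip())
    return df.mask(df == "", pd.NA)


def concat_quarters(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Vertically concatenate per-quarter tables of the same kind.

    Input order is preserved quarter-by-quarter; duplicate primaryids
    across quarters are retained (deduplication is a later stage).
    """
    tables = list(tables)
    nonempty = [t for t in tables if len(t.columns)]
    if not nonempty:
        return pd.DataFrame()
    cols = set(map(tuple, (t.columns for t in nonempty)))
    if len(cols) > 1:
        raise ValueError(f"mixed table kinds: differing column sets {sorted(cols)}")
    return pd.concat(nonempty, ignore_index=True)


def write_faers_table(records: pd.DataFrame, table_kind: str) -> str:
    """Serialize records back to the ``$``-delimited dialect.

    Missing values become empty strings.  Because the dialect has no
    quoting, any field containing the delimiter is rejected.
    """
    kind = _check_kind(table_kind)
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in records.columns]
    if missing:
        raise FaersSchemaError(
            f"{kind}: records lack mandatory column(s) {', '.join(missing)}"
        )
    df = records.astype("string").fillna("")
    for col in df.columns:
        bad = df[col].str.contains(DELIMITER, regex=False)
        if bad.any():
            idx = int(bad.idxmax())
            raise ValueError(
                f"{kind}: field {col!r} at row {idx} contains the {DELIMITER!r} "
                "delimiter; the FAERS dialect has no escaping"
            )
    buf = io.StringIO()
    buf.write(DELIMITER.join(df.columns) + "\n")
    for row in df.itertuples(index=False):
        buf.write(DELIMITER.join(row) + "\n")
    return buf.getvalue()


def date_length(value) -> int:
    """Length tag of a verbatim FAERS date: 8 (full), 6, 4, or 0 (unusable)."""
    if value is None or value is pd.NA:
        return 0
    s = str(value).strip()
    if s.isdigit() and len(s) in (4, 6, 8):
        return len(s)
    return 0


def is_full_date(value) -> bool:
    return date_length(value) == 8
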