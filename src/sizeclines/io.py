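"""CSV interchange in Darwin-Core-flavoured column names.

The internal record table uses snake_case columns and split year/month/
day; on disk records carry the aggregator-style headers
(decimalLatitude, eventDate, institutionCode, massInGrams, ...) with
eventDate in ISO form, truncated when month or day is unknown.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_records", "write_records"]

_DWC = {
    "record_id": "occurrenceID",
    "source": "institutionCode",
    "decimal_latitude": "decimalLatitude",
    "decimal_longitude": "decimalLongitude",
    "sex": "sex",
    "life_stage": "lifeStage",
    "body_mass": "massInGrams",
    "total_length": "totalLengthInMM",
    "tail_length": "tailLengthInMM",
}


def _event_date(row) -> str:
    y, m, d = row
    if pd.isna(y):
        return ""
    if pd.isna(m):
        return f"{int(y):04d}"
    if pd.isna(d):
        return f"{int(y):04d}-{int(m):02d}"
    return f"{int(y):04d}-{int(m):02d}-{int(d):02d}"


def write_records(records: pd.DataFrame, path: str | Path) -> Path:
    out = pd.DataFrame({dwc: records[col] for col, dwc in _DWC.items()
                        if col in records.columns})
    out["eventDate"] = [
        _event_date(r) for r in records[["year", "month", "day"]].itertuples(index=False)
    ]
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_records(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype={"eventDate": "string"})
    out = pd.DataFrame({col: raw[dwc] for col, dwc in _DWC.items() if dwc in raw})
    parts = raw["eventDate"].fillna("").str.split("-", expand=True)
    parts = parts.reindex(columns=range(3))
    for i, col in enumerate(("year", "month", "day")):
        out[col] = pd.to_numeric(parts[i], errors="coerce").astype("Int64")
    return out
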