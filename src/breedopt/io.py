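"""Delimited-text persistence for simulation records and surfaces.

Records round-trip at full double precision.  A file lacking the
composite ``m`` column is accepted: ``m`` is recomputed from ``g``,
``f`` and the configured inbreeding weight on load.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import RECORD_COLUMNS, TargetSpec

__all__ = ["read_records", "write_records", "RecordFormatError"]

_REQUIRED = [c for c in RECORD_COLUMNS if c != "m"]
_INT_COLUMNS = ["replicate_id", "seed", "x1", "x2", "x3"]


class RecordFormatError(ValueError):
    """Malformed record file (header or row level)."""


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write simulation records as CSV with the canonical column order."""
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise RecordFormatError(f"records are missing columns: {missing}")
    cols = [c for c in RECORD_COLUMNS if c in records.columns]
    # pandas' default float formatting is shortest-round-trip repr
    records[cols].to_csv(path, index=False)


def read_records(path: str | Path, target: TargetSpec | None = None) -> pd.DataFrame:
    """Read simulation records, validating header and rows.

    Raises :class:`RecordFormatError` naming expected columns on header
    mismatch, and listing 1-based line numbers for unparseable rows.
    """
    target = target or TargetSpec()
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if [c for c in cols if c in RECORD_COLUMNS] != cols or any(
        c not in cols for c in _REQUIRED
    ):
        raise RecordFormatError(
            f"header mismatch in {path}: expected columns {RECORD_COLUMNS} "
            f"(m optional), found {cols}"
        )
    out = {}
    bad_lines: set[int] = set()
    for c in cols:
        values = df[c].to_numpy()
        try:
            # numpy's parser is exact to the last ulp
            parsed = values.astype(np.float64)
        except ValueError:
            parsed = np.empty(len(values))
            for i, v in enumerate(values):
                try:
                    parsed[i] = float(v)
                except ValueError:
                    parsed[i] = np.nan
                    # header is line 1, data starts at line 2
                    bad_lines.add(i + 2)
        out[c] = parsed
    if bad_lines:
        raise RecordFormatError(
            f"malformed rows in {path} at lines {sorted(bad_lines)}"
        )
    res = pd.DataFrame(out)
    for c in _INT_COLUMNS:
        res[c] = res[c].astype("int64")
    if "m" not in res.columns:
        res["m"] = res["g"] - target.inbreeding_weight * res["f"]
    return res[RECORD_COLUMNS]
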