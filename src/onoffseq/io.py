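"""Reading and writing count-series files.

The on-disk format is tidy CSV with a header row and columns ``series_id``
(string), ``time_index`` (0-based integer) and ``count`` (non-negative
integer).  The observation lag Delta is an experiment constant and lives in
the configuration, not in the file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ObservationSet, TimeSeries

__all__ = ["CountsFileError", "read_counts", "write_counts"]

COLUMNS = ("series_id", "time_index", "count")


class CountsFileError(ValueError):
    """A counts file fails validation; the message names series and row."""


def read_counts(path, delta: float = 1.0) -> ObservationSet:
    """Parse and validate a counts CSV into an ObservationSet.

    Series appear in the output in order of first appearance.  Within a
    series the time indices must be exactly 0..n with no gaps or
    duplicates, and counts must be non-negative integers.
    """
    df = pd.read_csv(path, dtype={"series_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CountsFileError(f"{path}: missing column(s) {missing}; header must be {COLUMNS}")
    for col in ("time_index", "count"):
        values = df[col]
        bad = values.isna() | (np.asarray(values, dtype=float) != np.floor(values))
        if bad.any():
            row = int(bad.idxmax())
            raise CountsFileError(
                f"{path}: non-integer {col} in series "
                f"{df['series_id'].iloc[row]!r} (file row {row + 2})"
            )
    if (df["count"] < 0).any():
        row = int((df["count"] < 0).idxmax())
        raise CountsFileError(
            f"{path}: negative count in series {df['series_id'].iloc[row]!r} "
            f"(file row {row + 2})"
        )
    series = []
    for sid in df["series_id"].unique():
        sub = df[df["series_id"] == sid].sort_values("time_index")
        idx = sub["time_index"].to_numpy(dtype=int)
        expected = np.arange(len(idx))
        if not np.array_equal(idx, expected):
            gap = int(np.argmax(idx != expected))
            raise CountsFileError(
                f"{path}: series {sid!r} has a gap or duplicate at time_index "
                f"{idx[gap]} (expected {expected[gap]})"
            )
        series.append(
            TimeSeries(counts=sub["count"].to_numpy(dtype=int), delta=delta, series_id=sid)
        )
    if not series:
        raise CountsFileError(f"{path}: file contains no series")
    return ObservationSet(series=tuple(series), delta=delta)


def write_counts(data: ObservationSet, path) -> None:
    """Write an ObservationSet as tidy CSV (sorted by series, then time)."""
    rows = {
        "series_id": [], "time_index": [], "count": [],
    }
    for s in data.series:
        rows["series_id"] += [s.series_id] * len(s.counts)
        rows["time_index"] += list(range(len(s.counts)))
        rows["count"] += [int(c) for c in s.counts]
    pd.DataFrame(rows).to_csv(Path(path), index=False)
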