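"""CSV readers/writers for chamber tables and results.

Conventions: comma-separated, UTF-8, "." decimal, one header row.
Timestamps are accepted either as epoch seconds or ISO-8601 strings and
normalised internally to seconds since episode start.  Results columns
carry their units in the header as ``name [unit]`` so the files stay
self-describing and round-trip losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import DataError, FormatError
from .flux import ChamberSeries

_REQUIRED = ("timestamp", "chamber_id", "n2o_ppb")
_OPTIONAL = ("co2_ppm", "d15n_raw")


def _timestamps_to_seconds(col: pd.Series) -> np.ndarray:
    """Epoch seconds from either numeric or ISO-8601 timestamps."""
    try:
        return col.astype(float).to_numpy()
    except (TypeError, ValueError):
        pass
    try:
        dt = pd.to_datetime(col, format="ISO8601")
    except (TypeError, ValueError) as exc:
        raise FormatError(f"timestamps are neither numeric nor ISO-8601: {exc}") from exc
    return dt.astype("int64").to_numpy() / 1e9


def split_episodes(time_s: np.ndarray, gap_s: float) -> list[np.ndarray]:
    """Index blocks separated wherever the time gap exceeds ``gap_s``."""
    idx = np.arange(time_s.size)
    if time_s.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(time_s) > gap_s) + 1
    return np.split(idx, breaks)


def read_chamber_table(path, config: RunConfig) -> list[ChamberSeries]:
    """Parse a chamber concentration table into per-closure series.

    One :class:`ChamberSeries` per (chamber_id, closure episode); closures
    are split wherever consecutive timestamps of the same chamber are more
    than ``config.flux_window.episode_gap_s`` apart.  Rows are taken in
    file order — a backwards timestamp inside an episode is a data error
    (with its row index), not something to silently re-sort.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"chamber table is missing mandatory column {col!r}")
    t_all = _timestamps_to_seconds(df["timestamp"])
    gap = config.flux_window.episode_gap_s
    out = []
    for chamber_id, grp in df.groupby("chamber_id", sort=False):
        rows = grp.index.to_numpy()
        t = t_all[rows]
        bad = np.flatnonzero(np.diff(t) <= 0)
        # a gap <= 0 can never be an episode break, so check before splitting
        if bad.size:
            raise DataError(
                f"chamber {chamber_id}: non-monotonic timestamp at input row {int(rows[bad[0] + 1])}"
            )
        for ep in split_episodes(t, gap):
            sub = grp.iloc[ep]
            te = t[ep]
            out.append(
                ChamberSeries(
                    chamber_id=str(chamber_id),
                    time_s=te - te[0],
                    n2o_ppb=sub["n2o_ppb"].to_numpy(dtype=float),
                    co2_ppm=(sub["co2_ppm"].to_numpy(dtype=float)
                             if "co2_ppm" in sub.columns else None),
                    d15n=(sub["d15n_raw"].to_numpy(dtype=float)
                          if "d15n_raw" in sub.columns else None),
                    geometry=config.chamber_geometry,
                    start_time_s=float(te[0]),
                )
            )
    return out


@dataclass
class ResultsTable:
    """Long-format results with per-column units.

    ``units`` maps column name -> unit string ("-" for dimensionless/keys).
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.data.empty:
            raise DataError("results table is empty")


_HEADER_RE = re.compile(r"^(?P<name>.*?)\s*\[(?P<unit>[^\]]*)\]$")


def write_results(table: ResultsTable, path) -> None:
    """Write a results CSV whose header carries units as ``name [unit]``.

    Floats are written at full repr precision so a read-back equals the
    written values exactly.  An empty table raises before any file is
    created.
    """
    table.validate()
    renamed = {
        col: f"{col} [{table.units.get(col, '-')}]" for col in table.data.columns
    }
    try:
        table.data.rename(columns=renamed).to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path) -> ResultsTable:
    """Inverse of :func:`write_results`."""
    df = pd.read_csv(path)
    names, units = [], {}
    for col in df.columns:
        m = _HEADER_RE.match(col)
        if not m:
            raise FormatError(f"results column {col!r} has no unit bracket")
        names.append(m.group("name"))
        units[m.group("name")] = m.group("unit")
    df.columns = names
    return ResultsTable(data=df, units=units)
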