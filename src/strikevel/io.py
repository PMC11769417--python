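"""Reading and writing accelerometer CSV files (PhyPhox export dialect).

PhyPhox exports a one-line header followed by four numeric columns: time
in seconds and x/y/z acceleration in m/s².  Depending on the phone's
locale the file is either comma-delimited with ``.`` decimals or
semicolon-delimited with ``,`` decimals; both are accepted.  Columns are
matched by header keywords, not position.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """The file does not look like a PhyPhox accelerometer export."""


class TraceValidationError(ValueError):
    """Parsed data violate the acceleration-trace invariants."""


@dataclass
class AccelerationTrace:
    """A timestamped triaxial acceleration recording.

    Attributes
    ----------
    timestamps : np.ndarray
        Seconds from recording start; strictly increasing, possibly
        non-uniformly spaced.
    ax, ay, az : np.ndarray
        Per-axis acceleration in m/s² (gravity-free linear acceleration
        expected).
    nominal_rate : float, optional
        Nominal sampling rate in Hz (metadata only; computations use the
        actual timestamps).
    label : str
        Free-text source identifier.
    """

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    nominal_rate: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.timestamps)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise TraceValidationError(
                "timestamps, ax, ay, az must have identical length"
            )
        if n < 2:
            raise TraceValidationError(f"trace needs at least 2 samples, got {n}")
        for name, arr in (("timestamps", self.timestamps), ("ax", self.ax),
                          ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise TraceValidationError(f"non-finite value in {name} at row {bad}")
        diffs = np.diff(self.timestamps)
        if np.any(diffs <= 0):
            bad = int(np.flatnonzero(diffs <= 0)[0]) + 1
            raise TraceValidationError(
                f"timestamps not strictly increasing at row {bad}"
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AccelerationTrace):
            return NotImplemented
        return (
            np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.ax, other.ax)
            and np.array_equal(self.ay, other.ay)
            and np.array_equal(self.az, other.az)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Time (s)": self.timestamps,
                "Acceleration x (m/s^2)": self.ax,
                "Acceleration y (m/s^2)": self.ay,
                "Acceleration z (m/s^2)": self.az,
            }
        )


_AXIS_PATTERNS = {axis: re.compile(rf"(^|[^a-z]){axis}([^a-z]|$)") for axis in "xyz"}


def _sniff_dialect(header_line: str) -> tuple[str, str]:
    """Return (delimiter, decimal mark) from the header line."""
    if ";" in header_line:
        return ";", ","
    return ",", "."


def _match_columns(columns: list[str]) -> dict[str, str]:
    """Map roles {time, x, y, z} to header names by keyword."""
    mapping: dict[str, str] = {}
    lowered = {c: c.strip().strip('"').lower() for c in columns}
    for col, low in lowered.items():
        if "time" in low and "time" not in mapping:
            mapping["time"] = col
    for axis in "xyz":
        pat = _AXIS_PATTERNS[axis]
        for col, low in lowered.items():
            if col == mapping.get("time"):
                continue
            if pat.search(low) and axis not in mapping:
                mapping[axis] = col
                break
    missing = [role for role in ("time", "x", "y", "z") if role not in mapping]
    if missing:
        raise FormatError(
            f"could not identify column(s) {missing} in header {columns}"
        )
    return mapping


def read_phyphox_csv(path: str | Path) -> AccelerationTrace:
    """Read a PhyPhox accelerometer CSV export.

    Accepts comma-delimited files with ``.`` decimals and
    semicolon-delimited files with ``,`` decimals.  Columns are matched
    by header keywords (a column containing "time", and columns whose
    name contains a standalone x / y / z), so column order is irrelevant.

    Raises
    ------
    FormatError
        If a required column cannot be identified.
    TraceValidationError
        If timestamps are not strictly increasing, values are
        non-finite, or the file has fewer than 2 data rows.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise FormatError(f"{path}: empty file")
    sep, decimal = _sniff_dialect(header_line)
    df = pd.read_csv(path, sep=sep, decimal=decimal)
    if df.shape[0] < 2:
        raise TraceValidationError(f"{path}: fewer than 2 data rows")
    mapping = _match_columns(list(df.columns))
    cols = {}
    for role in ("time", "x", "y", "z"):
        series = pd.to_numeric(df[mapping[role]], errors="coerce")
        cols[role] = series.to_numpy(dtype=float)
    return AccelerationTrace(
        timestamps=cols["time"], ax=cols["x"], ay=cols["y"], az=cols["z"],
        label=path.name,
    )


def write_trace_csv(
    trace: AccelerationTrace,
    path: str | Path,
    sep: str = ",",
    decimal: str = ".",
) -> None:
    """Write a trace as a PhyPhox-dialect CSV readable by read_phyphox_csv."""
    trace.to_frame().to_csv(path, index=False, sep=sep, decimal=decimal)


def write_results_csv(results, path: str | Path) -> None:
    """Write a session result (one row per strike) or a reliability
    report (one row per metric) as a flat CSV.

    Session velocities are rounded to 2 decimals in the file; report
    values are written at full precision so that a written report
    re-reads to within 1e-9.
    """
    path = Path(path)
    if hasattr(results, "strike_velocities"):  # SessionResult
        rows = []
        for i, (v, valid, reason) in enumerate(results.strike_velocities, start=1):
            rows.append(
                {
                    "strike": i,
                    "impact_velocity_m_s": round(v, 2) if np.isfinite(v) else "",
                    "valid": valid,
                    "quality_flag": reason or "",
                }
            )
        if results.n_valid == 0:
            logger.warning("writing session result with no valid strikes to %s", path)
        pd.DataFrame(
            rows,
            columns=["strike", "impact_velocity_m_s", "valid", "quality_flag"],
        ).to_csv(path, index=False)
    elif hasattr(results, "to_frame"):  # ReliabilityReport
        results.to_frame().to_csv(path, index=False)
    else:
        raise TypeError(f"cannot serialize results of type {type(results).__name__}")
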