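"""Flat-punch indentation loading programs and force-record handling.

The two standard programs differ only in loading speed: P1 rams to the
1 mm target depth at 1.0 mm/s, P2 at 1.6 mm/s; both hold for 90 s, unload
at 1 mm/s to a -0.1 mm stand-off above the surface and recover there, for a
per-cycle duration of ramp + 90 + 1 + 120 s.  Displacement is the
indentation depth (positive into the sample).

Force records are delimited text with header ``t_s,u_mm,F_mN``, '.' decimal
separator and '#' comment lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import ConfigError

log = logging.getLogger(__name__)

HOLD_S = 90.0
UNLOAD_SPEED = 1.0  # mm/s
RECOVERY_S = 120.0  # includes the 1 s nominal unload bookkeeping
STANDOFF_MM = -0.1
DEPTH_MM = 1.0
SPEEDS = {"P1": 1.0, "P2": 1.6}  # mm/s


class FormatError(ValueError):
    """Raised for malformed force-record files."""


class AlignmentError(ValueError):
    """Raised when a record cannot be aligned to a protocol."""


@dataclass(frozen=True)
class IndentationProtocol:
    """Piecewise-linear time-displacement program.

    ``breakpoints`` is an (n, 2) array of (t [s], depth [mm]) vertices;
    depth is linear in between.
    """

    name: str
    speed: float  # loading speed [mm/s]
    depth: float
    cycles: int
    breakpoints: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.breakpoints[-1, 0])

    @property
    def cycle_duration(self) -> float:
        """ramp + hold + 1 s unload + recovery."""
        return self.depth / self.speed + HOLD_S + 1.0 + RECOVERY_S

    def displacement(self, t) -> np.ndarray:
        """Depth at time(s) t [mm], linear interpolation."""
        return np.interp(t, self.breakpoints[:, 0], self.breakpoints[:, 1])

    def cycle_window(self, cycle: int) -> tuple[float, float, float]:
        """(start, end of hold, end) times of a 1-based cycle."""
        if not 1 <= cycle <= self.cycles:
            raise ValueError(f"cycle {cycle} out of range")
        ramp1 = self.depth / self.speed
        ramp = ramp1 if cycle == 1 else (self.depth - STANDOFF_MM) / self.speed
        start = (cycle - 1) * self.cycle_duration
        return start, start + ramp + HOLD_S, start + self.cycle_duration

    def segments(self):
        """Yield (t0, t1, kind) with kind in {ramp, hold, unload, recovery}."""
        kinds = []
        for c in range(1, self.cycles + 1):
            start, hold_end, end = self.cycle_window(c)
            ramp = self.depth / self.speed if c == 1 \
                else (self.depth - STANDOFF_MM) / self.speed
            unload = (self.depth - STANDOFF_MM) / UNLOAD_SPEED
            kinds += [
                (start, start + ramp, "ramp"),
                (start + ramp, hold_end, "hold"),
                (hold_end, hold_end + unload, "unload"),
                (hold_end + unload, end, "recovery"),
            ]
        return kinds


def build_protocol(name: str, cycles: int = 1) -> IndentationProtocol:
    """Construct P1 or P2 with the given number of trapezoidal cycles."""
    if name not in SPEEDS:
        raise ConfigError(f"unknown protocol {name!r}; expected P1 or P2")
    if cycles < 1:
        raise ConfigError("cycles must be >= 1")
    v = SPEEDS[name]
    cycle_len = DEPTH_MM / v + HOLD_S + 1.0 + RECOVERY_S
    pts = [(0.0, 0.0)]
    pos = 0.0
    for c in range(cycles):
        start = c * cycle_len
        # ramp of later cycles starts from the -0.1 mm stand-off; the extra
        # travel is absorbed by shortening the recovery of that cycle
        t = start + (DEPTH_MM - pos) / v
        pts.append((t, DEPTH_MM))
        t += HOLD_S
        pts.append((t, DEPTH_MM))
        t += (DEPTH_MM - STANDOFF_MM) / UNLOAD_SPEED
        pts.append((t, STANDOFF_MM))
        pts.append(((c + 1) * cycle_len, STANDOFF_MM))
        pos = STANDOFF_MM
    return IndentationProtocol(
        name=name, speed=v, depth=DEPTH_MM, cycles=cycles,
        breakpoints=np.asarray(pts, dtype=float),
    )


# ---------------------------------------------------------------------------
# force records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceRecord:
    """One replicate's sampled (t, u, F) history."""

    replicate_id: str
    protocol_id: str
    t: np.ndarray  # s, strictly increasing
    u: np.ndarray  # mm (depth)
    F: np.ndarray  # mN

    def __post_init__(self) -> None:
        for arr in (self.t, self.u, self.F):
            if not np.all(np.isfinite(arr)):
                raise FormatError("force record contains non-finite values")
        if len(self.t) < 2 or np.any(np.diff(self.t) <= 0):
            raise FormatError("time must be strictly increasing")


def write_force_record(record: ForceRecord, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# replicate={record.replicate_id}\n")
        fh.write(f"# protocol={record.protocol_id}\n")
        fh.write("t_s,u_mm,F_mN\n")
        for t, u, F in zip(record.t, record.u, record.F):
            fh.write(f"{t:.17g},{u:.17g},{F:.17g}\n")


def write_force_records(records: list[ForceRecord], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_force_record(rec, directory / f"{rec.replicate_id}.csv")


def read_force_record(path: str | Path) -> ForceRecord:
    path = Path(path)
    meta = {"replicate": path.stem, "protocol": ""}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line.lstrip("#").strip().split("=", 1)
                meta[k.strip()] = v.strip()
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: {exc}") from exc
    required = ["t_s", "u_mm", "F_mN"]
    if list(df.columns[:3]) != required:
        raise FormatError(f"{path}: expected header {','.join(required)}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        rows = ", ".join(str(i + 2) for i in df.index[bad][:5])
        raise FormatError(f"{path}: malformed rows at lines {rows}")
    t = df["t_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        k = int(np.argmax(np.diff(t) <= 0))
        raise FormatError(f"{path}: non-monotone time at line {k + 3}")
    return ForceRecord(
        replicate_id=meta["replicate"], protocol_id=meta["protocol"],
        t=t, u=df["u_mm"].to_numpy(float), F=df["F_mN"].to_numpy(float),
    )


def read_force_records(path: str | Path) -> list[ForceRecord]:
    """Read one record (file) or all ``*.csv`` records in a directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            log.warning("no force records found in %s", path)
            return []
        return [read_force_record(f) for f in files]
    if path.stat().st_size == 0:
        log.warning("empty force-record file %s", path)
        return []
    return [read_force_record(path)]


# ---------------------------------------------------------------------------
# alignment and summary statistics
# ---------------------------------------------------------------------------

def _onset_time(record: ForceRecord, protocol: IndentationProtocol) -> float:
    """First crossing of 5% of the record's cycle-1 peak force."""
    t_end = protocol.cycle_window(1)[1] + 1.0
    mask = record.t <= record.t[0] + t_end
    peak = float(np.max(record.F[mask]))
    thresh = 0.05 * peak
    above = np.nonzero(record.F >= thresh)[0]
    if peak <= 0 or len(above) == 0:
        raise AlignmentError(
            f"record {record.replicate_id}: no 5%-of-peak onset found")
    k = above[0]
    if k == 0:
        return float(record.t[0])
    # linear interpolation of the crossing
    t0, t1 = record.t[k - 1], record.t[k]
    f0, f1 = record.F[k - 1], record.F[k]
    return float(t0 + (thresh - f0) / (f1 - f0) * (t1 - t0))


def align_records(records: list[ForceRecord],
                  protocol: IndentationProtocol,
                  grid_dt: float | None = None) -> list[ForceRecord]:
    """Shift each record so its loading onset maps to t = 0 (the protocol's
    ramp start) and resample all onto a common grid."""
    if not records:
        return []
    if grid_dt is None:
        grid_dt = float(np.median(np.concatenate(
            [np.diff(r.t) for r in records])))
    grid = np.arange(0.0, protocol.duration + 0.5 * grid_dt, grid_dt)
    out = []
    for rec in records:
        shift = _onset_time(rec, protocol)
        t = rec.t - shift
        if t[0] > grid[0] + grid_dt or t[-1] < grid[-1] - grid_dt:
            raise AlignmentError(
                f"record {rec.replicate_id} does not cover the protocol "
                f"duration after alignment (spans {t[0]:.3g}..{t[-1]:.3g} s)")
        out.append(ForceRecord(
            replicate_id=rec.replicate_id, protocol_id=rec.protocol_id,
            t=grid.copy(),
            u=np.interp(grid, t, rec.u),
            F=np.interp(grid, t, rec.F),
        ))
    return out


@dataclass(frozen=True)
class CurveSummary:
    """Pointwise median/IQR across replicates plus per-cycle scalars."""

    t: np.ndarray
    median: np.ndarray
    iqr: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    peak_force: np.ndarray  # per cycle [mN]
    relaxation: np.ndarray  # per cycle, (peak - end-of-hold)/peak [-]


def summarize(records: list[ForceRecord],
              protocol: IndentationProtocol) -> CurveSummary:
    """Median and IQR pointwise in time (quartiles by the linear-
    interpolation convention of numpy); per-cycle peak force and
    force-relaxation fraction evaluated on the median curve."""
    if not records:
        raise ValueError("at least one replicate is required")
    t = records[0].t
    for r in records[1:]:
        if len(r.t) != len(t) or not np.allclose(r.t, t):
            raise ValueError("records must share a common grid; align first")
    F = np.vstack([r.F for r in records])
    med = np.median(F, axis=0)
    q25, q75 = np.percentile(F, [25, 75], axis=0)
    peaks, relax = [], []
    for c in range(1, protocol.cycles + 1):
        start, hold_end, _ = protocol.cycle_window(c)
        win = (t >= start) & (t <= hold_end)
        peak = float(np.max(med[win]))
        # last sample inside the hold: robust against the unload
        # discontinuity right after hold_end
        f_end = float(med[win][-1])
        peaks.append(peak)
        relax.append((peak - f_end) / peak if peak != 0 else np.nan)
    return CurveSummary(t=t, median=med, iqr=q75 - q25, q25=q25, q75=q75,
                        peak_force=np.asarray(peaks),
                        relaxation=np.asarray(relax))
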