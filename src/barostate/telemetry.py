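"""Waveform I/O, cardiac-cycle detection, and analysis-window selection.

A recording is a uniformly sampled arterial pressure trace (mmHg).  Samples
that are non-finite or outside the physiologically plausible 0-300 mmHg
range are flagged corrupt; cardiac cycles overlapping corrupt samples are
excluded rather than repaired.  Per-cycle quantities follow the field's
conventions: SP and DP are the local extrema of the pulse signal, RR is the
inter-systolic-peak interval, and MAP is the time average of pressure over
the cycle (with ``DP + PP/3`` available as a fallback when only extrema
exist).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import h5py
import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .exceptions import (
    EmptyInputError,
    EmptyWindowsError,
    FormatError,
    InvalidInputError,
    NoBeatsError,
)

__all__ = [
    "PressureWaveform",
    "BEAT_COLUMNS",
    "read_waveform",
    "write_waveform",
    "read_beats_csv",
    "write_beats_csv",
    "detect_beats",
    "compute_map",
    "MapResult",
    "Window",
    "WindowSet",
    "select_windows",
    "window_beats",
]

#: canonical beat-table columns, in on-disk order
BEAT_COLUMNS = ["t_s", "rr_s", "sp_mmHg", "dp_mmHg", "pp_mmHg", "map_mmHg"]

_PRESSURE_RANGE = (0.0, 300.0)  # mmHg; outside is treated as a telemetry glitch


@dataclass
class PressureWaveform:
    """Uniformly sampled arterial pressure trace.

    Attributes
    ----------
    samples : numpy.ndarray
        Pressure in mmHg.
    fs : float
        Sampling rate in samples/s.
    t0 : float
        Time of the first sample, seconds from record start.
    quality_mask : numpy.ndarray of bool
        True where the sample is valid.  Computed on construction when not
        supplied: finite and within 0-300 mmHg.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    quality_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not (self.fs > 0) or not math.isfinite(self.fs):
            raise InvalidInputError(f"fs must be positive, got {self.fs}")
        if self.quality_mask is None:
            with np.errstate(invalid="ignore"):
                self.quality_mask = (
                    np.isfinite(self.samples)
                    & (self.samples >= _PRESSURE_RANGE[0])
                    & (self.samples <= _PRESSURE_RANGE[1])
                )
        else:
            self.quality_mask = np.asarray(self.quality_mask, dtype=bool)
            if self.quality_mask.shape != self.samples.shape:
                raise InvalidInputError("quality_mask must match samples in shape")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def write_waveform(waveform: PressureWaveform, path: str | Path) -> None:
    """Write a waveform as CSV (``time_s,pressure_mmHg``) or HDF5.

    The format is chosen by suffix: ``.h5``/``.hdf5`` writes dataset
    ``/pressure`` with attributes ``fs`` and ``t0``; anything else writes the
    two-column CSV with full round-trip float precision.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("pressure", data=waveform.samples)
            ds.attrs["fs"] = waveform.fs
            ds.attrs["t0"] = waveform.t0
    else:
        buf = io.StringIO()
        buf.write("time_s,pressure_mmHg\n")
        t = waveform.times
        for ti, pi in zip(t.tolist(), waveform.samples.tolist()):
            buf.write(f"{ti!r},{pi!r}\n")
        path.write_text(buf.getvalue())


def read_waveform(path: str | Path, format: str | None = None) -> PressureWaveform:
    """Read a waveform written by :func:`write_waveform`.

    CSV requires the exact header ``time_s,pressure_mmHg``; the sampling
    rate is recovered from the median time step.  HDF5 requires dataset
    ``/pressure`` with an ``fs`` attribute.  Non-finite samples are flagged
    corrupt, not dropped.
    """
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "pressure" not in f:
                raise FormatError(f"{path}: missing dataset 'pressure'")
            ds = f["pressure"]
            if "fs" not in ds.attrs:
                raise FormatError(f"{path}: dataset 'pressure' lacks 'fs' attribute")
            samples = ds[...]
            fs = float(ds.attrs["fs"])
            t0 = float(ds.attrs.get("t0", 0.0))
        if samples.size == 0:
            raise EmptyInputError(f"{path}: empty pressure dataset")
        return PressureWaveform(samples=samples, fs=fs, t0=t0)
    if fmt != "csv":
        raise FormatError(f"unknown waveform format {fmt!r}")
    with open(path) as f:
        header = f.readline().strip()
        if header != "time_s,pressure_mmHg":
            raise FormatError(
                f"{path}: expected header 'time_s,pressure_mmHg', got {header!r}"
            )
        table = pd.read_csv(
            f,
            header=None,
            names=["time_s", "pressure_mmHg"],
            float_precision="round_trip",
        )
    if len(table) == 0:
        raise EmptyInputError(f"{path}: no samples")
    t = table["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples to infer fs")
    dt = np.median(np.diff(t))
    if not (dt > 0):
        raise FormatError(f"{path}: time column is not increasing")
    return PressureWaveform(
        samples=table["pressure_mmHg"].to_numpy(dtype=float), fs=1.0 / dt, t0=float(t[0])
    )


def repr_float(value) -> str:
    """Full round-trip precision float formatting for CSV output."""
    return repr(float(value))


def write_beats_csv(beats: pd.DataFrame, path: str | Path, extra_columns=()) -> None:
    """Beat table CSV with a 1-based ``beat_index`` column, full precision."""
    cols = BEAT_COLUMNS + [c for c in extra_columns if c in beats.columns]
    out = beats[cols].copy()
    out.insert(0, "beat_index", np.arange(1, len(out) + 1))
    out.to_csv(path, index=False, float_format=repr_float)


def read_beats_csv(path: str | Path) -> pd.DataFrame:
    beats = pd.read_csv(path, float_precision="round_trip")
    missing = set(BEAT_COLUMNS) - set(beats.columns)
    if missing:
        raise FormatError(f"{path}: beat table missing columns {sorted(missing)}")
    return beats.reset_index(drop=True)


class MapResult(NamedTuple):
    value: float
    mode: str  # "waveform" (time average) or "extrema" (DP + PP/3)


def compute_map(samples=None, *, sp: float | None = None, dp: float | None = None) -> MapResult:
    """Mean arterial pressure for one cardiac cycle.

    Preferred mode passes the cycle's samples (half-open, onset to next
    onset) and returns their time average.  The fallback mode passes the
    cycle extrema and returns the classic ``DP + PP/3`` approximation.
    """
    if samples is not None:
        seg = np.asarray(samples, dtype=float)
        if seg.size == 0:
            raise InvalidInputError("empty cycle segment")
        if not np.all(np.isfinite(seg)):
            raise InvalidInputError("cycle segment contains non-finite samples")
        return MapResult(float(seg.mean()), "waveform")
    if sp is None or dp is None:
        raise InvalidInputError("provide either cycle samples or both sp and dp")
    if sp <= dp:
        raise InvalidInputError(f"sp must exceed dp, got sp={sp}, dp={dp}")
    return MapResult(float(dp + (sp - dp) / 3.0), "extrema")


def _edge_boundaries(p, minima, fs, median_cycle_samples):
    """Accept record edges as cycle boundaries when they sit at diastole."""
    out = list(minima)
    if minima.size == 0:
        return np.asarray(out, dtype=int)
    lead = int(0.7 * median_cycle_samples)
    if minima[0] >= lead and p[0] <= p[minima[0]] + 0.5:
        out.insert(0, 0)
    last = p.size - 1
    if last - minima[-1] >= lead and p[last] <= p[minima[-1]] + 0.5:
        out.append(last)
    return np.asarray(out, dtype=int)


def detect_beats(
    waveform: PressureWaveform,
    refractory_s: float = 0.05,
    min_amplitude: float = 5.0,
    prominence: float = 2.5,
) -> pd.DataFrame:
    """Detect cardiac cycles and per-cycle pressures from a pressure trace.

    Alternating local maxima (systole) and minima (diastole) are found with a
    refractory period (default 50 ms, below the shortest plausible rat cycle)
    to avoid double-counting the dicrotic notch.  A cycle spans one diastolic
    onset to the next; RR is the inter-systolic-peak interval and the cycle
    duration column equals it.  Cycles overlapping corrupt samples are
    dropped.  MAP is the time average of the cycle's samples.

    Raises
    ------
    NoBeatsError
        If the record has < 2 s of valid samples or its valid peak-to-trough
        range is below ``min_amplitude`` mmHg (no pulsatility).
    """
    p = waveform.samples
    valid = waveform.quality_mask
    if valid.sum() < 2 * waveform.fs:
        raise NoBeatsError("fewer than 2 s of valid samples")
    pv = p[valid]
    if pv.max() - pv.min() < min_amplitude:
        raise NoBeatsError(
            f"peak-to-trough range {pv.max() - pv.min():.2f} mmHg "
            f"< {min_amplitude} mmHg: no pulsatility"
        )
    # fill corrupt samples by interpolation so peak finding is well defined;
    # any cycle touching a filled sample is discarded below
    p_work = p.copy()
    if not valid.all():
        idx = np.arange(p.size)
        p_work[~valid] = np.interp(idx[~valid], idx[valid], p[valid])

    distance = max(1, int(round(refractory_s * waveform.fs)))
    maxima, _ = find_peaks(p_work, distance=distance, prominence=prominence)
    minima, _ = find_peaks(-p_work, distance=distance, prominence=prominence)
    if maxima.size == 0 or minima.size < 1:
        raise NoBeatsError("no alternating pressure extrema found")
    median_cycle = np.median(np.diff(maxima)) if maxima.size > 1 else distance * 2
    bounds = _edge_boundaries(p_work, minima, waveform.fs, median_cycle)
    if bounds.size < 2:
        raise NoBeatsError("fewer than one full cardiac cycle detected")

    rows = []
    sp_idx_prev = None
    for j in range(bounds.size - 1):
        a, b = bounds[j], bounds[j + 1]
        if not valid[a:b].all():
            sp_idx_prev = None
            rows.append(None)
            continue
        seg = p[a:b]
        sp_idx = a + int(np.argmax(seg))
        rows.append(
            {
                "onset": a,
                "sp_idx": sp_idx,
                "sp": float(seg.max()),
                "dp": float(seg.min()),
                "map": float(seg.mean()),
                "dur": (b - a) / waveform.fs,
            }
        )
        sp_idx_prev = sp_idx
    # RR from systolic-peak spacing where the next cycle exists; duration otherwise
    beats = []
    for j, row in enumerate(rows):
        if row is None:
            continue
        nxt = rows[j + 1] if j + 1 < len(rows) else None
        if nxt is not None:
            rr = (nxt["sp_idx"] - row["sp_idx"]) / waveform.fs
        else:
            rr = row["dur"]
        beats.append(
            {
                "t_s": waveform.t0 + row["onset"] / waveform.fs,
                "rr_s": rr,
                "sp_mmHg": row["sp"],
                "dp_mmHg": row["dp"],
                "pp_mmHg": row["sp"] - row["dp"],
                "map_mmHg": row["map"],
            }
        )
    if not beats:
        raise NoBeatsError("all detected cycles overlap corrupt samples")
    return pd.DataFrame(beats)


@dataclass(frozen=True)
class Window:
    """One selected analysis window inside an hour block."""

    block: int        # 1-based hour index
    t_start_s: float
    t_end_s: float


@dataclass
class WindowSet:
    """Up to one uncorrupted fixed-length window per hour block."""

    windows: list[Window]
    missing_blocks: list[int]
    window_s: float
    block_s: float
    source_id: str = ""

    def to_records(self) -> list[dict]:
        return [
            {"block": w.block, "t_start_s": w.t_start_s, "t_end_s": w.t_end_s}
            for w in self.windows
        ]


def _clean_spans(t: np.ndarray, rr: np.ndarray, max_gap_s: float):
    """Maximal intervals continuously covered by beats (gaps <= max_gap_s)."""
    breaks = np.flatnonzero(np.diff(t) > max_gap_s)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))
    return [(t[i], t[j] + rr[j]) for i, j in zip(starts, ends)]


def select_windows(
    beats: pd.DataFrame,
    span: tuple[float, float] | None = None,
    block_s: float = 3600.0,
    window_s: float = 300.0,
    n_blocks: int = 12,
    max_gap_s: float = 1.0,
    source_id: str = "",
) -> WindowSet:
    """Pick one fixed-length uncorrupted window per hour block.

    For each block the window is the ``window_s`` stretch of continuous beat
    coverage (inter-beat gaps <= ``max_gap_s``) lying inside the block whose
    center is nearest the block midpoint; on an exact tie the earlier window
    is taken.  Blocks with no such stretch are reported in
    ``missing_blocks``.
    """
    if len(beats) == 0:
        raise EmptyWindowsError("empty beat table")
    t = beats["t_s"].to_numpy(dtype=float)
    rr = beats["rr_s"].to_numpy(dtype=float)
    if span is None:
        span = (float(t[0]), float(t[0]) + block_s * n_blocks)
    spans = _clean_spans(t, rr, max_gap_s)
    windows: list[Window] = []
    missing: list[int] = []
    for b in range(n_blocks):
        b0 = span[0] + b * block_s
        b1 = min(b0 + block_s, span[1])
        mid = 0.5 * (b0 + b1)
        best = None
        for s0, s1 in spans:
            a, z = max(s0, b0), min(s1, b1)
            if z - a < window_s:
                continue
            w = min(max(mid - window_s / 2.0, a), z - window_s)
            dist = abs(w + window_s / 2.0 - mid)
            if best is None or dist < best[0] - 1e-12:
                best = (dist, w)
        if best is None:
            missing.append(b + 1)
        else:
            windows.append(Window(b + 1, best[1], best[1] + window_s))
    if not windows:
        raise EmptyWindowsError("no hour block contains an uncorrupted window")
    return WindowSet(
        windows=windows,
        missing_blocks=missing,
        window_s=window_s,
        block_s=block_s,
        source_id=source_id,
    )


def window_beats(beats: pd.DataFrame, window: Window) -> pd.DataFrame:
    """Beats whose onset lies in the half-open window [t_start, t_end)."""
    t = beats["t_s"]
    return beats[(t >= window.t_start_s) & (t < window.t_end_s)].reset_index(drop=True)
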