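"""State-conditioned pressure statistics and cohort-level summaries.

Everything downstream of the on/off labels lives here: MAP means and kernel
density estimates conditioned on baroreflex state, MAP trends aligned to
state-transition onsets, the on-fraction-versus-MAP cohort correlation,
heart-rate variability, arterial-wall elasticity from paired
pressure/wall-thickness measurements, and day-by-day dark-cycle MAP
summaries for denervation experiments.  Outputs are plain tables and
scalars ready for external statistics software; no figure styling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError

__all__ = [
    "MAP_GRID_MMHG",
    "state_conditioned_map",
    "StateSummary",
    "transition_trends",
    "TransitionTrend",
    "cohort_correlation",
    "compute_elasticity",
    "daily_map_summary",
    "densities_frame",
    "hr_std_bpm",
    "paired_t",
    "sem",
]

#: fixed evaluation grid for MAP densities (mmHg)
MAP_GRID_MMHG = np.arange(40.0, 200.0 + 1e-9, 0.5)


def sem(x) -> float:
    """Standard error of the mean, std(ddof=1)/sqrt(n)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def hr_std_bpm(rr_series) -> float:
    """Standard deviation of heart rate (beats/min) over a recording."""
    rr = np.asarray(rr_series, dtype=float)
    if rr.size < 2:
        raise InvalidInputError("need at least 2 beats")
    if np.any(rr <= 0):
        raise InvalidInputError("RR intervals must be positive")
    return float(np.std(60.0 / rr, ddof=1))


@dataclass
class StateSummary:
    """MAP statistics conditioned on baroreflex state for one recording."""

    map_mean_on: float | None          # beat-weighted
    map_mean_off: float | None
    map_mean_on_tw: float | None       # time-weighted (beat durations)
    map_mean_off_tw: float | None
    density_grid: np.ndarray
    density_on: np.ndarray | None
    density_off: np.ndarray | None
    density_all: np.ndarray
    n_on: int
    n_off: int
    flags: list[str]


def _kde(values: np.ndarray, grid: np.ndarray) -> np.ndarray | None:
    if values.size < 2 or np.std(values) == 0:
        return None
    # normal-reference (Silverman) bandwidth
    return stats.gaussian_kde(values, bw_method="silverman")(grid)


def state_conditioned_map(
    beats: pd.DataFrame, final_labels, grid: np.ndarray = MAP_GRID_MMHG
) -> StateSummary:
    """Partition per-beat MAP by state; report means and densities.

    Means are given both beat-weighted (each cycle counts once) and
    time-weighted (each cycle weighted by its duration).  Densities are
    Gaussian KDEs on the fixed grid; a state with too few beats is omitted
    and flagged.
    """
    labels = np.asarray(final_labels)
    mp = beats["map_mmHg"].to_numpy(dtype=float)
    dt = beats["rr_s"].to_numpy(dtype=float)
    if labels.shape != mp.shape:
        raise InvalidInputError("labels must align with the beat table")
    flags: list[str] = []
    out = {}
    for name, sel in (("on", labels == 1), ("off", labels == 0)):
        if sel.sum() == 0:
            out[name] = (None, None, None)
            flags.append(f"no {name} beats")
            continue
        mean_bw = float(mp[sel].mean())
        mean_tw = float(np.average(mp[sel], weights=dt[sel]))
        dens = _kde(mp[sel], grid)
        if dens is None:
            flags.append(f"{name} density omitted (too few beats or zero spread)")
        out[name] = (mean_bw, mean_tw, dens)
    return StateSummary(
        map_mean_on=out["on"][0],
        map_mean_off=out["off"][0],
        map_mean_on_tw=out["on"][1],
        map_mean_off_tw=out["off"][1],
        density_grid=grid,
        density_on=out["on"][2],
        density_off=out["off"][2],
        density_all=_kde(mp, grid),
        n_on=int((labels == 1).sum()),
        n_off=int((labels == 0).sum()),
        flags=flags,
    )


@dataclass
class TransitionTrend:
    """MAP trajectories aligned to episode onsets for one state."""

    state: int
    grid_s: np.ndarray                 # 0 .. horizon, fixed step
    trajectories: np.ndarray           # (n_episodes, len(grid))
    mean: np.ndarray | None
    sem: np.ndarray | None
    delta: float | None                # mean(MAP at horizon) - mean(MAP at onset)
    n_episodes: int


def transition_trends(
    beats: pd.DataFrame,
    episodes: pd.DataFrame,
    horizon_s: float = 20.0,
    step_s: float = 0.5,
) -> dict[int, TransitionTrend]:
    """MAP trends over the first ``horizon_s`` seconds of each episode.

    Episodes longer than the horizon qualify.  Per-beat MAP (a step
    function, each beat holding its value for its duration) is resampled by
    previous-value hold onto the common grid ``0, step_s, ..., horizon_s``
    measured from episode onset; the mean trajectory +- SEM across episodes
    and the onset-to-horizon change are reported per state.  States with no
    qualifying episode yield an empty result.
    """
    t = beats["t_s"].to_numpy(dtype=float)
    mp = beats["map_mmHg"].to_numpy(dtype=float)
    grid = np.arange(0.0, horizon_s + step_s / 2.0, step_s)
    out: dict[int, TransitionTrend] = {}
    for state in (1, 0):
        eps = episodes[
            (episodes["state"] == state) & (episodes["duration_s"] > horizon_s)
        ]
        trajs = []
        for _, ep in eps.iterrows():
            sample_t = ep["t_start_s"] + grid
            idx = np.searchsorted(t, sample_t, side="right") - 1
            if idx[0] < 0:
                continue  # onset precedes the first beat; cannot resample
            trajs.append(mp[idx])
        if trajs:
            arr = np.vstack(trajs)
            mean = arr.mean(axis=0)
            se = arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0]) if arr.shape[0] > 1 else None
            delta = float(mean[-1] - mean[0])
        else:
            arr = np.empty((0, grid.size))
            mean = se = delta = None
        out[state] = TransitionTrend(
            state=state,
            grid_s=grid,
            trajectories=arr,
            mean=mean,
            sem=se,
            delta=delta,
            n_episodes=arr.shape[0],
        )
    return out


def paired_t(before, after):
    """Paired two-sided t test, e.g. MAP at episode onset vs at the horizon
    across animals.  Returns ``{"t", "p", "n", "mean_diff"}``."""
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("paired observations required")
    if x.size < 2:
        raise InvalidInputError("need at least 2 pairs")
    t_stat, p = stats.ttest_rel(y, x)
    return {
        "t": float(t_stat),
        "p": float(p),
        "n": int(x.size),
        "mean_diff": float((y - x).mean()),
    }


def densities_frame(summary: "StateSummary") -> pd.DataFrame:
    """State-conditioned MAP densities as a tidy table
    (``map_mmHg, density_on, density_off, density_all``)."""
    n = summary.density_grid.size
    empty = np.full(n, np.nan)
    return pd.DataFrame(
        {
            "map_mmHg": summary.density_grid,
            "density_on": summary.density_on if summary.density_on is not None else empty,
            "density_off": summary.density_off if summary.density_off is not None else empty,
            "density_all": summary.density_all if summary.density_all is not None else empty,
        }
    )


def cohort_correlation(on_fractions, map_means):
    """Pearson correlation between on fraction and mean MAP across animals.

    Returns a dict with ``r``, the t statistic, the two-sided ``p`` value,
    ``n``, and the least-squares line (``slope``, ``intercept``) for
    plotting.
    """
    x = np.asarray(on_fractions, dtype=float)
    y = np.asarray(map_means, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("paired observations required")
    n = x.size
    if n < 3:
        raise InvalidInputError(f"need >= 3 pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidInputError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    t_stat = r * math.sqrt((n - 2) / (1.0 - r * r)) if abs(r) < 1 else math.inf * np.sign(r)
    slope, intercept = np.polyfit(x, y, 1)
    return {
        "r": float(r),
        "t": float(t_stat),
        "p": float(p),
        "n": int(n),
        "slope": float(slope),
        "intercept": float(intercept),
    }


def compute_elasticity(
    P_sys: float, P_dia: float, T_sys: float, T_dia: float, literal: bool = False
) -> float:
    """Arterial elasticity from pressures and wall thicknesses (mmHg).

    Default reading: ``E = (P_sys - P_dia) * T_dia / (T_sys - T_dia)`` —
    pulse pressure divided by the relative systolic-diastolic wall-thickness
    strain, the elastic-modulus analogue.  ``literal=True`` instead
    evaluates ``(P_sys - P_dia) * (T_dia / T_sys - T_dia)``, the
    alternative parenthesization; it is dimensionally incoherent as a
    strain and provided only for comparison.
    """
    if not (P_sys > P_dia):
        raise InvalidInputError("P_sys must exceed P_dia")
    if T_sys == T_dia:
        raise InvalidInputError("T_sys equals T_dia: elasticity undefined (division by zero)")
    if literal:
        return float((P_sys - P_dia) * (T_dia / T_sys - T_dia))
    return float((P_sys - P_dia) * T_dia / (T_sys - T_dia))


def daily_map_summary(beats_by_day: dict, baseline_days) -> pd.DataFrame:
    """Per-day dark-cycle MAP summary with change from the pre-surgery baseline.

    ``beats_by_day`` maps day number to that day's beat table (or any frame
    with a ``map_mmHg`` column).  The day-0 reference is the mean over
    ``baseline_days`` of the daily means; ``delta_mmHg`` is each day's mean
    relative to it.  Empty days are omitted and flagged in the ``flag``
    column of the returned frame.
    """
    baseline_days = list(baseline_days)
    if not beats_by_day:
        raise InvalidInputError("no days supplied")
    missing = [d for d in baseline_days if d not in beats_by_day]
    if missing:
        raise InvalidInputError(f"baseline days absent from data: {missing}")
    rows = []
    for day in sorted(beats_by_day):
        frame = beats_by_day[day]
        mp = np.asarray(frame["map_mmHg"], dtype=float)
        if mp.size == 0:
            rows.append({"day": day, "map_mean_mmHg": np.nan, "map_std_mmHg": np.nan,
                         "n_beats": 0, "flag": "empty"})
            continue
        rows.append(
            {
                "day": day,
                "map_mean_mmHg": float(mp.mean()),
                "map_std_mmHg": float(np.std(mp, ddof=1)) if mp.size > 1 else np.nan,
                "n_beats": int(mp.size),
                "flag": "",
            }
        )
    table = pd.DataFrame(rows)
    base = table[table["day"].isin(baseline_days) & (table["flag"] == "")]
    if len(base) == 0:
        raise InvalidInputError("all baseline days are empty")
    day0 = float(base["map_mean_mmHg"].mean())
    table["baseline_mmHg"] = day0
    table["delta_mmHg"] = table["map_mean_mmHg"] - day0
    return table
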