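"""On/off labelling of baroreflex engagement from slope pairs.

Each cardiac cycle contributes a point ``(mu_d, mu_m)``: the observed and
model-predicted local rates of change of the RR interval.  When the
baroreflex drives heart rate the two agree and the point falls near the
diagonal ``y = x``; when heart-rate fluctuations are decoupled from
pressure the point scatters away from it.  The on region is the closed set
between the two branches of a hyperbola symmetric about ``y = x`` with axis
intercepts at ``+-r``; in rotated coordinates

    u = (mu_d + mu_m)/sqrt(2),   v = (mu_m - mu_d)/sqrt(2),

a point is on iff

    v**2  <=  r**2 * (a**2 - 1) / (2 * a**2)  +  u**2 / a**2 ,

a band around the diagonal whose branches have vertices at
``|v| = r * sqrt((a**2 - 1) / 2) / a``, cross the axes exactly at ``+-r``,
and open with asymptote slope ``1/a``: the unitless curvature parameter
``a`` (> 1) sets how slowly the tolerated model/data disagreement grows
with the magnitude of the slopes.  Off states are therefore flagged when
the observed rate of change of RR departs from the predicted one by more
than the band allows — whether or not the two happen to share a sign.
``r`` absorbs the noise floor of the slope estimates: it is set to half the
pooled data-slope standard deviation (0.0004 for baroreceptor-intact rats,
0.00015 after sinoaortic denervation).

Raw labels are then denoised by iterating a 10-second moving-window average
of the 0/1 sequence until the thresholded labels stop changing (>= 0.5 is
on), and maximal runs of constant label become episodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "Boundary",
    "DEFAULT_R_NORMAL",
    "DEFAULT_R_DENERVATED",
    "DEFAULT_A_CURV",
    "classify_points",
    "smooth_labels",
    "compute_on_fraction",
    "extract_episodes",
    "calibrate_r",
    "StateTrack",
    "classify_beats",
]

DEFAULT_R_NORMAL = 0.0004
DEFAULT_R_DENERVATED = 0.00015
DEFAULT_A_CURV = 3.5
DEFAULT_SMOOTHING_WINDOW_S = 10.0


@dataclass(frozen=True)
class Boundary:
    """Hyperbolic on/off boundary in (mu_d, mu_m) space."""

    r: float = DEFAULT_R_NORMAL
    a_curv: float = DEFAULT_A_CURV

    def __post_init__(self) -> None:
        if not (self.r > 0):
            raise InvalidInputError(f"r must be positive, got {self.r}")
        if not (self.a_curv > 1):
            raise InvalidInputError(
                f"a_curv must exceed 1 for a real hyperbola, got {self.a_curv}"
            )

    def contains(self, mu_d, mu_m):
        """True where (mu_d, mu_m) lies in the closed on region."""
        mu_d = np.asarray(mu_d, dtype=float)
        mu_m = np.asarray(mu_m, dtype=float)
        u2 = 0.5 * (mu_d + mu_m) ** 2
        v2 = 0.5 * (mu_m - mu_d) ** 2
        a2 = self.a_curv**2
        return a2 * v2 - u2 <= self.r**2 * (a2 - 1.0) / 2.0


def calibrate_r(mu_d_pooled) -> float:
    """Boundary intercept from a cohort: half the pooled data-slope sd.

    Pools every animal's ``mu_d`` values (NaNs from truncated edge windows
    ignored) and returns ``std/2``.  This is the derivation rule behind the
    published constants; it is exposed separately rather than applied
    silently, so analyses of new cohorts can recompute it deliberately.
    """
    mu = np.asarray(mu_d_pooled, dtype=float)
    mu = mu[np.isfinite(mu)]
    if mu.size < 2:
        raise InvalidInputError("need at least 2 finite slopes to calibrate r")
    return float(0.5 * np.std(mu, ddof=1))


def classify_points(mu_d, mu_m, boundary: Boundary = Boundary()):
    """Raw per-beat labels (1=on, 0=off) from slope pairs.

    Beats with undefined slopes (NaN from edge-truncated windows) inherit
    the nearest defined beat's label and are reported in the returned
    ``imputed`` mask; they should be excluded from variability statistics
    but keep the episode sequence contiguous.

    Returns ``(labels, imputed)``.
    """
    mu_d = np.asarray(mu_d, dtype=float)
    mu_m = np.asarray(mu_m, dtype=float)
    if mu_d.shape != mu_m.shape or mu_d.ndim != 1:
        raise InvalidInputError("mu_d and mu_m must be 1-D and aligned")
    defined = np.isfinite(mu_d) & np.isfinite(mu_m)
    if not defined.any():
        raise InvalidInputError("no beat has defined slopes")
    labels = np.zeros(mu_d.size, dtype=int)
    labels[defined] = boundary.contains(mu_d[defined], mu_m[defined]).astype(int)
    imputed = ~defined
    if imputed.any():
        idx = np.arange(mu_d.size)
        # nearest defined beat by index; undefined slopes cluster at segment
        # edges, so this is a handful of comparisons in practice
        nearest = idx[defined][
            np.abs(idx[defined][None, :] - idx[imputed][:, None]).argmin(axis=1)
        ]
        labels[imputed] = labels[nearest]
    return labels, imputed


def _moving_time_average(values: np.ndarray, t: np.ndarray, window_s: float) -> np.ndarray:
    lo = np.searchsorted(t, t - window_s / 2.0, side="left")
    hi = np.searchsorted(t, t + window_s / 2.0, side="right")
    P = np.concatenate(([0.0], np.cumsum(values)))
    return (P[hi] - P[lo]) / (hi - lo)


def smooth_labels(
    raw_labels,
    t_series,
    window_s: float = DEFAULT_SMOOTHING_WINDOW_S,
    max_iter: int = 100,
):
    """Iterated moving-window average of the 0/1 label sequence.

    Each pass replaces the 0/1 series by its time-centered moving average
    over ``|t_i - t_j| <= window_s / 2`` and re-thresholds at 0.5 (>= 0.5
    is on); passes repeat until the labels stop changing between
    iterations, or ``max_iter`` is reached (flagged via ``converged``).
    Re-thresholding between passes makes the procedure an iterated
    majority filter: label runs shorter than about half the window are
    absorbed by their surroundings, longer runs are stable, and the
    converged output is a fixed point (re-applying the procedure changes
    nothing).  Averaging the real-valued series instead would drain to a
    global constant and erase every minority episode.

    Returns ``(smoothed_values, final_labels, n_iter, converged)`` where
    ``smoothed_values`` is the last computed moving average.
    """
    labels = np.asarray(raw_labels)
    t = np.asarray(t_series, dtype=float)
    if labels.shape != t.shape or labels.ndim != 1:
        raise InvalidInputError("labels and t must be 1-D and aligned")
    if not np.isin(labels, (0, 1)).all():
        raise InvalidInputError("raw labels must be 0 or 1")
    if not (window_s > 0):
        raise InvalidInputError(f"window_s must be positive, got {window_s}")
    if labels.size == 1:
        return labels.astype(float), labels.astype(int), 0, True
    final = labels.astype(int)
    for it in range(1, max_iter + 1):
        values = _moving_time_average(final.astype(float), t, window_s)
        new = (values >= 0.5).astype(int)
        if np.array_equal(new, final):
            return values, new, it, True
        final = new
    return values, final, max_iter, False


def compute_on_fraction(final_labels, dt_series) -> float:
    """Time-weighted fraction of the record spent in the on state."""
    labels = np.asarray(final_labels)
    dt = np.asarray(dt_series, dtype=float)
    if labels.shape != dt.shape:
        raise InvalidInputError("labels and dt must be aligned")
    total = dt.sum()
    if not (total > 0):
        raise InvalidInputError("total time is zero")
    return float(dt[labels == 1].sum() / total)


def extract_episodes(
    final_labels, t_series, dt_series, min_duration_s: float | None = None
) -> pd.DataFrame:
    """Maximal constant-label runs as episodes tiling the record.

    Episode j starts at its first beat's onset and ends at the next
    episode's start (the last ends at the final beat's offset), so episode
    durations always sum to the record duration.  With ``min_duration_s``
    only episodes strictly longer than the threshold are kept.
    """
    labels = np.asarray(final_labels)
    t = np.asarray(t_series, dtype=float)
    dt = np.asarray(dt_series, dtype=float)
    if not (labels.shape == t.shape == dt.shape) or labels.ndim != 1:
        raise InvalidInputError("labels, t and dt must be 1-D and aligned")
    if labels.size == 0:
        return pd.DataFrame(columns=["state", "t_start_s", "t_end_s", "duration_s"])
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate(([0], change + 1))
    bounds = np.concatenate((t[starts], [t[-1] + dt[-1]]))
    rows = pd.DataFrame(
        {
            "state": labels[starts].astype(int),
            "t_start_s": bounds[:-1],
            "t_end_s": bounds[1:],
        }
    )
    rows["duration_s"] = rows["t_end_s"] - rows["t_start_s"]
    if min_duration_s is not None:
        rows = rows[rows["duration_s"] > min_duration_s].reset_index(drop=True)
    return rows


@dataclass
class StateTrack:
    """Per-beat state labels, their smoothing trace, and summary quantities."""

    raw_labels: np.ndarray
    smoothed_values: np.ndarray
    final_labels: np.ndarray
    imputed: np.ndarray
    on_fraction: float
    episodes: pd.DataFrame
    smoothing_window_s: float = DEFAULT_SMOOTHING_WINDOW_S
    smoothing_converged: bool = True
    boundary: Boundary = field(default_factory=Boundary)


def classify_beats(
    mu_d,
    mu_m,
    t_series,
    dt_series,
    boundary: Boundary = Boundary(),
    smoothing_window_s: float = DEFAULT_SMOOTHING_WINDOW_S,
) -> StateTrack:
    """Label, smooth, and summarize one contiguous segment of beats."""
    raw, imputed = classify_points(mu_d, mu_m, boundary)
    values, final, _, converged = smooth_labels(
        raw, t_series, window_s=smoothing_window_s
    )
    return StateTrack(
        raw_labels=raw,
        smoothed_values=values,
        final_labels=final,
        imputed=imputed,
        on_fraction=compute_on_fraction(final, dt_series),
        episodes=extract_episodes(final, t_series, dt_series),
        smoothing_window_s=smoothing_window_s,
        smoothing_converged=converged,
        boundary=boundary,
    )
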