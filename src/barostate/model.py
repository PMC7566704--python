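"""First-order linear baroreflex filter relating MAP to the RR interval.

The model treats the RR interval as the output of a first-order low-pass
filter driven by mean arterial pressure,

    dRR/dt = (alpha * MAP(t) + R0 - RR) / tau,

where ``alpha`` (s/mmHg) is the baroreflex sensitivity (change in RR interval
per unit change in pressure), ``tau`` (s) sets how quickly pressure changes
propagate into heart-rate changes (1/tau is the response rate), and ``R0``
(s) is the offset RR interval.  Holding MAP constant over each cardiac cycle
of duration dt_j (zero-order hold) gives the exact per-beat update

    RR_{j+1} = RR_ss_j + (RR_j - RR_ss_j) * exp(-dt_j / tau),
    RR_ss_j  = alpha * MAP_j + R0.

``R0`` is tied to the operating point of each 5-minute record through
``R0 = <RR> - alpha * <MAP>`` so that the filter's steady state matches the
record mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["BaroParams", "compute_R0", "simulate_rr", "steady_state_rr"]

try:  # hot loop used inside the fitting objective; fall back to pure Python
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class BaroParams:
    """Parameters of the baroreflex filter.

    Attributes
    ----------
    alpha : float
        Baroreflex sensitivity in s/mmHg (non-negative: higher pressure
        lengthens the RR interval).
    tau : float
        Response time constant in seconds, strictly positive.
    R0 : float or None
        Offset RR interval in seconds.  ``None`` when the offset is to be
        recomputed per analysis window via :func:`compute_R0`.
    """

    alpha: float
    tau: float
    R0: float | None = None

    def __post_init__(self) -> None:
        if not (self.tau > 0) or not math.isfinite(self.tau):
            raise InvalidInputError(f"tau must be positive and finite, got {self.tau}")
        if self.alpha < 0 or not math.isfinite(self.alpha):
            raise InvalidInputError(
                f"alpha must be non-negative and finite, got {self.alpha}"
            )
        if self.R0 is not None and not math.isfinite(self.R0):
            raise InvalidInputError(f"R0 must be finite, got {self.R0}")

    def with_R0(self, R0: float) -> "BaroParams":
        return BaroParams(alpha=self.alpha, tau=self.tau, R0=R0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha_s_per_mmHg": self.alpha,
            "tau_s": self.tau,
            "R0_s": self.R0,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BaroParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            alpha=payload["alpha_s_per_mmHg"],
            tau=payload["tau_s"],
            R0=payload.get("R0_s"),
        )


def compute_R0(rr_series, map_series, alpha: float) -> float:
    """Offset RR interval tying the filter to a record's operating point.

    ``R0 = <RR> - alpha * <MAP>`` with ``<.>`` the mean over the supplied
    (typically 5-minute) record.
    """
    rr = np.asarray(rr_series, dtype=float)
    mp = np.asarray(map_series, dtype=float)
    if rr.size == 0 or mp.size == 0:
        raise InvalidInputError("compute_R0 requires non-empty series")
    if rr.shape != mp.shape:
        raise InvalidInputError(
            f"rr and map series must have the same length, got {rr.size} and {mp.size}"
        )
    return float(rr.mean() - alpha * mp.mean())


def steady_state_rr(map_value, params: BaroParams):
    """RR interval the filter settles to at a fixed pressure."""
    if params.R0 is None:
        raise InvalidInputError("params.R0 is unset; call compute_R0 first")
    return params.alpha * np.asarray(map_value, dtype=float) + params.R0


def _simulate_rr_py(mp, dt, alpha, tau, R0, rr_init):
    n = mp.shape[0]
    out = np.empty(n)
    rr = rr_init
    out[0] = rr
    for j in range(n - 1):
        rss = alpha * mp[j] + R0
        rr = rss + (rr - rss) * math.exp(-dt[j] / tau)
        out[j + 1] = rr
    return out


if _HAVE_NUMBA:
    _simulate_rr_fast = _njit(cache=True)(_simulate_rr_py)
else:  # pragma: no cover
    _simulate_rr_fast = _simulate_rr_py


def simulate_rr(map_series, dt_series, params: BaroParams, rr_init: float | None = None):
    """Run the per-beat zero-order-hold solution of the filter.

    Parameters
    ----------
    map_series : array-like
        Per-beat MAP in mmHg; MAP_j is held constant over beat j.
    dt_series : array-like
        Per-beat durations in seconds (dt_j > 0), same length as MAP.
    params : BaroParams
        Filter parameters; ``R0`` must be set.
    rr_init : float, optional
        RR_1.  Callers analysing data pass the first observed RR; defaults to
        the steady state at the first MAP value.

    Returns
    -------
    numpy.ndarray
        Model RR series, same length as the inputs.
    """
    mp = np.ascontiguousarray(map_series, dtype=float)
    dt = np.ascontiguousarray(dt_series, dtype=float)
    if mp.shape != dt.shape or mp.ndim != 1:
        raise InvalidInputError("map_series and dt_series must be 1-D and equal length")
    if mp.size == 0:
        raise InvalidInputError("empty input series")
    if np.any(dt <= 0) or not np.all(np.isfinite(dt)):
        raise InvalidInputError("beat durations must be positive and finite")
    if params.R0 is None:
        raise InvalidInputError("params.R0 is unset; call compute_R0 first")
    if rr_init is None:
        rr_init = float(params.alpha * mp[0] + params.R0)
    return _simulate_rr_fast(mp, dt, params.alpha, params.tau, params.R0, float(rr_init))
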