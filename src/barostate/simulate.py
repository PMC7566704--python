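"""Synthetic telemetry generator with known ground truth.

Emulates conscious rodent blood-pressure telemetry at the beat level and, on
request, as a rendered 500 Hz pulsatile waveform:

* per-beat MAP follows a discretized Ornstein-Uhlenbeck (OU) process — a
  mean-reverting Gaussian process standing in for slow physiological
  pressure fluctuations;
* a two-state continuous-time Markov chain switches the baroreflex between
  engaged ("on") and disengaged ("off") episodes lasting seconds to minutes;
* during on episodes the RR interval follows the first-order baroreflex
  filter driven by MAP (see :mod:`barostate.model`); during off episodes it
  follows an independent OU process around the mean RR, ignoring pressure;
* each beat is rendered as a smooth single-pulse template (raised-cosine
  upstroke, exponential diastolic decay) whose extrema equal the beat's
  systolic and diastolic pressures.

Every stage is reproducible bit-for-bit under a fixed seed, and the true
state sequence and filter parameters are returned alongside the data, so the
whole downstream analysis can be validated against ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import ConfigError, InvalidInputError
from .model import BaroParams
from .telemetry import PressureWaveform, write_beats_csv

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gen_state_sequence",
    "states_at",
    "gen_map_track",
    "gen_rr_track",
    "render_waveform",
    "simulate",
    "write_ground_truth",
]

#: fraction of the cycle occupied by the systolic upstroke
_UPSTROKE_FRAC = 0.3
#: decay rate of the diastolic run-off (per unit normalized phase)
_DECAY_RATE = 5.0


@dataclass
class SimConfig:
    """Study conditions for one synthetic telemetry recording.

    Defaults reproduce the operating point of a normotensive adult rat on
    dark-cycle telemetry: HR near 360 beats/min, MAP near 120 mmHg with
    slow few-mmHg fluctuations, baroreflex gain 0.001 s/mmHg with a 2 s
    response time, and on/off dwell times of 120 s and 60 s.
    """

    seed: int = 0
    duration_s: float = 3600.0
    fs: float = 500.0
    hr_baseline: float = 360.0          # beats/min
    map_mean: float = 120.0             # mmHg
    map_sd: float = 4.0                 # mmHg
    map_corr_time_s: float = 8.0        # OU relaxation time of MAP
    true_alpha: float = 0.001           # s/mmHg
    true_tau: float = 2.0               # s
    true_R0: float = 0.04666666666666667  # s; 60/360 - 0.001*120
    rr_obs_noise_sd: float = 0.001      # s, additive observation noise on RR
    off_rr_sd: float = 0.008            # s, sd of decoupled RR fluctuations
    off_rr_corr_time_s: float = 5.0     # s, relaxation time of off-state RR OU
    mean_dwell_on_s: float = 120.0
    mean_dwell_off_s: float = 60.0
    pp_mean: float = 40.0               # mmHg, pulse pressure of rendered beats

    def validate(self) -> None:
        positive = {
            "duration_s": self.duration_s,
            "fs": self.fs,
            "hr_baseline": self.hr_baseline,
            "map_mean": self.map_mean,
            "map_corr_time_s": self.map_corr_time_s,
            "true_tau": self.true_tau,
            "off_rr_corr_time_s": self.off_rr_corr_time_s,
            "mean_dwell_on_s": self.mean_dwell_on_s,
            "mean_dwell_off_s": self.mean_dwell_off_s,
            "pp_mean": self.pp_mean,
        }
        for name, value in positive.items():
            if not (value > 0) or not math.isfinite(value):
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        for name, value in (
            ("map_sd", self.map_sd),
            ("rr_obs_noise_sd", self.rr_obs_noise_sd),
            ("off_rr_sd", self.off_rr_sd),
            ("true_alpha", self.true_alpha),
        ):
            if value < 0 or not math.isfinite(value):
                raise ConfigError(f"{name} must be non-negative, got {value}")
        # the filter's operating point must match the rendered rate
        rr_ss = self.true_R0 + self.true_alpha * self.map_mean
        rr_nom = 60.0 / self.hr_baseline
        if not (rr_ss > 0):
            raise ConfigError("true_R0 + true_alpha*map_mean must be positive")
        if abs(rr_nom - rr_ss) > 0.2 * rr_ss:
            raise ConfigError(
                "hr_baseline inconsistent with filter operating point: "
                f"60/hr = {rr_nom:.4f} s vs alpha*MAP + R0 = {rr_ss:.4f} s"
            )

    @property
    def rr_nominal(self) -> float:
        """Steady-state RR interval (s) at the mean pressure."""
        return self.true_R0 + self.true_alpha * self.map_mean

    def true_params(self) -> BaroParams:
        return BaroParams(alpha=self.true_alpha, tau=self.true_tau, R0=self.true_R0)


@dataclass
class GroundTruth:
    """Simulation output bundling data and its generating truth."""

    beats: pd.DataFrame          # t_s, rr_s, sp_mmHg, dp_mmHg, pp_mmHg, map_mmHg, state
    episodes: pd.DataFrame       # state, t_start_s, t_end_s, duration_s
    params: BaroParams
    config: SimConfig = field(repr=False)

    @property
    def state_sequence(self) -> np.ndarray:
        return self.beats["state"].to_numpy()

    @property
    def on_fraction_time(self) -> float:
        """Time-weighted on fraction of the episode list over [0, duration]."""
        on = self.episodes["state"] == 1
        return float(
            self.episodes.loc[on, "duration_s"].sum()
            / self.episodes["duration_s"].sum()
        )

    @property
    def on_fraction_beats(self) -> float:
        """Beat-duration-weighted on fraction of the generated beat table."""
        dt = self.beats["rr_s"].to_numpy()
        on = self.beats["state"].to_numpy() == 1
        return float(dt[on].sum() / dt.sum())


def gen_state_sequence(
    mean_dwell_on_s: float,
    mean_dwell_off_s: float,
    duration_s: float,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Alternating on/off episodes with exponential (memoryless) dwell times.

    The initial state is drawn from the stationary occupancy
    ``p_on = mean_on / (mean_on + mean_off)``; together with the memoryless
    dwell law this makes the process time-stationary, so the expected
    time-weighted on fraction equals ``p_on`` for any record length.

    Returns a DataFrame with columns ``state`` (1=on, 0=off), ``t_start_s``,
    ``t_end_s`` and ``duration_s`` whose episodes tile ``[0, duration_s]``.
    """
    if not (mean_dwell_on_s > 0 and mean_dwell_off_s > 0):
        raise ConfigError("mean dwell times must be strictly positive")
    if not (duration_s > 0):
        raise ConfigError(f"duration_s must be positive, got {duration_s}")
    rng = np.random.default_rng(seed)
    p_on = mean_dwell_on_s / (mean_dwell_on_s + mean_dwell_off_s)
    state = 1 if rng.random() < p_on else 0
    rows = []
    t = 0.0
    while t < duration_s:
        mean = mean_dwell_on_s if state == 1 else mean_dwell_off_s
        t_end = min(t + rng.exponential(mean), duration_s)
        if t_end > t:
            rows.append((state, t, t_end, t_end - t))
        state = 1 - state
        t = t_end
    return pd.DataFrame(rows, columns=["state", "t_start_s", "t_end_s", "duration_s"])


def states_at(times, episodes: pd.DataFrame) -> np.ndarray:
    """State labels at the given times (state changes at episode boundaries)."""
    t = np.asarray(times, dtype=float)
    starts = episodes["t_start_s"].to_numpy()
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(episodes) - 1)
    return episodes["state"].to_numpy()[idx]


def gen_map_track(
    config: SimConfig, n_beats: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Per-beat MAP series: exact discretization of a stationary OU process.

    Beats are spaced at the nominal interval ``60/hr_baseline``; the series
    has stationary mean ``map_mean``, stationary sd ``map_sd`` and lag-one
    autocorrelation ``exp(-dt/map_corr_time_s)``, and is initialized at
    stationarity.
    """
    config.validate()
    if n_beats < 2:
        raise InvalidInputError(f"n_beats must be >= 2, got {n_beats}")
    if config.map_sd == 0:
        return np.full(n_beats, config.map_mean)
    rng = np.random.default_rng(seed)
    dt = 60.0 / config.hr_baseline
    rho = math.exp(-dt / config.map_corr_time_s)
    x0 = rng.normal(0.0, config.map_sd)
    innov = config.map_sd * math.sqrt(1.0 - rho * rho) * rng.standard_normal(n_beats - 1)
    x = np.empty(n_beats)
    x[0] = x0
    x[1:], _ = lfilter([1.0], [1.0, -rho], innov, zi=np.array([rho * x0]))
    return config.map_mean + x


def gen_rr_track(
    map_series,
    state_sequence,
    config: SimConfig,
    seed: int | np.random.Generator,
    return_latent: bool = False,
):
    """Per-beat RR intervals: baroreflex filter when on, decoupled OU when off.

    During on beats the latent RR follows the zero-order-hold solution of the
    baroreflex filter driven by MAP, stepped with the latent beat duration.
    During off beats it follows an independent OU process around the nominal
    mean RR with sd ``off_rr_sd`` and relaxation time ``off_rr_corr_time_s``,
    ignoring MAP.  Observed RR adds white Gaussian noise ``rr_obs_noise_sd``
    on top of the latent dynamics (observation noise does not feed back).
    """
    config.validate()
    mp = np.asarray(map_series, dtype=float)
    st = np.asarray(state_sequence)
    if mp.shape != st.shape or mp.ndim != 1:
        raise InvalidInputError("map_series and state_sequence must be 1-D, equal length")
    rng = np.random.default_rng(seed)
    n = mp.size
    rr_bar = config.rr_nominal
    alpha, tau, R0 = config.true_alpha, config.true_tau, config.true_R0
    tau_off = config.off_rr_corr_time_s
    eps_off = rng.standard_normal(n)
    eps_obs = rng.standard_normal(n)
    latent = np.empty(n)
    rr = rr_bar
    for j in range(n):
        latent[j] = rr
        dt = rr  # state advances beat by beat; the current RR is the step
        if st[j] == 1:
            rss = alpha * mp[j] + R0
            rr = rss + (rr - rss) * math.exp(-dt / tau)
        else:
            rho = math.exp(-dt / tau_off)
            rr = rr_bar + (rr - rr_bar) * rho + config.off_rr_sd * math.sqrt(
                1.0 - rho * rho
            ) * eps_off[j]
        if rr <= 0:
            raise ConfigError(
                "latent RR became non-positive; off_rr_sd is too large for the "
                "configured mean RR"
            )
    observed = latent + config.rr_obs_noise_sd * eps_obs
    if np.any(observed <= 0):
        raise ConfigError(
            "observed RR became non-positive; rr_obs_noise_sd is too large"
        )
    if return_latent:
        return observed, latent
    return observed


def _pulse_template(phi: np.ndarray) -> np.ndarray:
    """Normalized single-pulse shape on phase [0, 1): 0 at onset, 1 at peak."""
    g = np.empty_like(phi)
    up = phi <= _UPSTROKE_FRAC
    g[up] = 0.5 * (1.0 - np.cos(np.pi * phi[up] / _UPSTROKE_FRAC))
    s = (phi[~up] - _UPSTROKE_FRAC) / (1.0 - _UPSTROKE_FRAC)
    k = _DECAY_RATE
    g[~up] = (np.exp(-k * s) - math.exp(-k)) / (1.0 - math.exp(-k))
    return g


def template_mean_fraction() -> float:
    """Cycle-average of the normalized pulse, i.e. (MAP - DP) / PP.

    Closed form from the raised-cosine upstroke (mean 1/2 over its span) and
    the exponential decay segment.
    """
    k = _DECAY_RATE
    decay_mean = ((1.0 - math.exp(-k)) / k - math.exp(-k)) / (1.0 - math.exp(-k))
    return _UPSTROKE_FRAC * 0.5 + (1.0 - _UPSTROKE_FRAC) * decay_mean


def render_waveform(beat_table: pd.DataFrame, fs: float, t0: float = 0.0) -> PressureWaveform:
    """Render a beat table as a continuous pulsatile pressure waveform.

    Each beat occupies ``[t_j, t_j + rr_j)`` and is drawn with the smooth
    single-pulse template scaled so the per-sample minimum equals DP (at the
    cycle onset) and the maximum equals SP; consecutive beats join
    continuously at diastolic pressure.
    """
    required = {"t_s", "rr_s", "sp_mmHg", "dp_mmHg"}
    missing = required - set(beat_table.columns)
    if missing:
        raise InvalidInputError(f"beat table missing columns: {sorted(missing)}")
    t_on = beat_table["t_s"].to_numpy(dtype=float)
    rr = beat_table["rr_s"].to_numpy(dtype=float)
    sp = beat_table["sp_mmHg"].to_numpy(dtype=float)
    dp = beat_table["dp_mmHg"].to_numpy(dtype=float)
    if len(t_on) == 0:
        raise InvalidInputError("beat table is empty")
    if np.any(rr <= 0):
        raise InvalidInputError("all beats must have positive RR")
    if np.any(sp <= dp):
        raise InvalidInputError("systolic pressure must exceed diastolic for every beat")
    total = t_on[-1] - t_on[0] + rr[-1]
    n = int(round(total * fs))
    t = t_on[0] + np.arange(n) / fs
    idx = np.clip(np.searchsorted(t_on, t, side="right") - 1, 0, len(t_on) - 1)
    phi = np.clip((t - t_on[idx]) / rr[idx], 0.0, 1.0 - 1e-12)
    samples = dp[idx] + (sp[idx] - dp[idx]) * _pulse_template(phi)
    return PressureWaveform(samples=samples, fs=fs, t0=t0 + float(t_on[0]))


def simulate(config: SimConfig, render: bool = False):
    """Generate a full synthetic recording with ground truth.

    Returns ``GroundTruth`` (beat table, episode list, true parameters), plus
    the rendered :class:`PressureWaveform` when ``render=True``.

    Sub-seeds for the switching process, the MAP track, and the RR track are
    spawned deterministically from ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seed_state, seed_map, seed_rr = ss.spawn(3)

    episodes = gen_state_sequence(
        config.mean_dwell_on_s,
        config.mean_dwell_off_s,
        config.duration_s,
        np.random.default_rng(seed_state),
    )
    dt_nom = 60.0 / config.hr_baseline
    n_est = int(math.ceil(config.duration_s / dt_nom * 1.3)) + 16
    map_track = gen_map_track(config, n_est, np.random.default_rng(seed_map))

    # beat onsets are defined by the generated RR itself: lay out beats on the
    # nominal grid for the per-beat processes, then accumulate onset times
    starts = episodes["t_start_s"].to_numpy()
    ep_state = episodes["state"].to_numpy()
    rng_rr = np.random.default_rng(seed_rr)
    t_nom = np.arange(n_est) * dt_nom
    state_nom = ep_state[
        np.clip(np.searchsorted(starts, t_nom, side="right") - 1, 0, len(starts) - 1)
    ]
    rr_obs, rr_lat = gen_rr_track(
        map_track, state_nom, config, rng_rr, return_latent=True
    )
    t_beats = np.concatenate(([0.0], np.cumsum(rr_obs[:-1])))
    keep = t_beats < config.duration_s
    t_beats, rr_obs = t_beats[keep], rr_obs[keep]
    map_track, = (map_track[keep],)
    state = states_at(t_beats, episodes)

    c = template_mean_fraction()
    dp = map_track - c * config.pp_mean
    sp = dp + config.pp_mean
    beats = pd.DataFrame(
        {
            "t_s": t_beats,
            "rr_s": rr_obs,
            "sp_mmHg": sp,
            "dp_mmHg": dp,
            "pp_mmHg": sp - dp,
            "map_mmHg": map_track,
            "state": state.astype(int),
        }
    )
    truth = GroundTruth(
        beats=beats, episodes=episodes, params=config.true_params(), config=config
    )
    if render:
        waveform = render_waveform(beats, fs=config.fs)
        return truth, waveform
    return truth


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> dict:
    """Write the beat table (CSV) and truth file (JSON); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beats_path = out / "truth_beats.csv"
    write_beats_csv(truth.beats, beats_path, extra_columns=["state"])
    truth_path = out / "truth.json"
    payload = {
        "true_params": {
            "alpha_s_per_mmHg": truth.params.alpha,
            "tau_s": truth.params.tau,
            "R0_s": truth.params.R0,
        },
        "on_fraction_time": truth.on_fraction_time,
        "episodes": truth.episodes.to_dict(orient="records"),
        "config": asdict(truth.config),
    }
    truth_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {"beats": str(beats_path), "truth": str(truth_path)}
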