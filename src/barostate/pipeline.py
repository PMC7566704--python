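"""End-to-end orchestration: simulate/read -> beats -> windows -> fit ->
classify -> summarize, with one config, per-stage seeds, and a manifest.

The pipeline is deterministic: rerunning with an identical config and seed
reproduces every output byte-for-byte (timings go to the log, not the
manifest).  Each stage writes its artifact before the next starts, and a
stage failure halts the run with the stage name and offending input in the
error message.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import Boundary, classify_beats, compute_on_fraction
from .estimation import (
    DEFAULT_ALPHA_BOUNDS,
    DEFAULT_TAU_BOUNDS,
    FitProblem,
    fit_parameters,
    grid_landscape,
    window_slopes,
)
from .exceptions import ConfigError, PipelineError
from .model import compute_R0, simulate_rr
from .simulate import SimConfig, simulate, write_ground_truth
from .summary import hr_std_bpm, state_conditioned_map, transition_trends
from .telemetry import (
    detect_beats,
    read_waveform,
    repr_float,
    select_windows,
    window_beats,
    write_beats_csv,
    write_waveform,
)

__all__ = ["RunConfig", "load_config", "run_pipeline"]

log = logging.getLogger("barostate")


@dataclass
class WindowsConfig:
    block_s: float = 3600.0
    window_s: float = 300.0
    n_blocks: int = 12
    max_gap_s: float = 1.0


@dataclass
class SlopesConfig:
    T_s: float = 10.0


@dataclass
class BoundaryConfig:
    r: float = 0.0004          # 0.00015 for denervated animals
    a_curv: float = 3.5


@dataclass
class SmoothingConfig:
    window_s: float = 10.0


@dataclass
class TransitionsConfig:
    horizon_s: float = 20.0
    step_s: float = 0.5


@dataclass
class FitConfig:
    tau_bounds: tuple[float, float] = DEFAULT_TAU_BOUNDS
    alpha_bounds: tuple[float, float] = DEFAULT_ALPHA_BOUNDS
    n_grid: tuple[int, int] = (5, 5)
    landscape: bool = False
    landscape_n: int = 15


@dataclass
class RunConfig:
    """Single-document configuration for one pipeline run.

    Either ``simulate`` holds overrides for :class:`SimConfig` (synthetic
    input) or ``input_waveform`` names a waveform file; exactly one must be
    set.  Defaults of the analysis blocks match the published settings:
    10 s slope and smoothing windows, boundary r = 0.0004 with curvature
    3.5, a 0.5 on-threshold, and twelve 5-minute windows per dark cycle.
    """

    seed: int = 0
    out_dir: str = "barostate_run"
    input_waveform: str | None = None
    simulate: dict | None = None
    windows: WindowsConfig = field(default_factory=WindowsConfig)
    slopes: SlopesConfig = field(default_factory=SlopesConfig)
    boundary: BoundaryConfig = field(default_factory=BoundaryConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    transitions: TransitionsConfig = field(default_factory=TransitionsConfig)
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if (self.input_waveform is None) == (self.simulate is None):
            raise ConfigError("set exactly one of 'input_waveform' and 'simulate'")
        if self.simulate is not None:
            unknown = set(self.simulate) - {
                f.name for f in dataclasses.fields(SimConfig)
            } - {"render"}
            if unknown:
                raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
            if "seed" in self.simulate:
                raise ConfigError(
                    "simulate.seed is derived from the master seed; do not set it"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for name, sub_cls in (
            ("windows", WindowsConfig),
            ("slopes", SlopesConfig),
            ("boundary", BoundaryConfig),
            ("smoothing", SmoothingConfig),
            ("transitions", TransitionsConfig),
            ("fit", FitConfig),
        ):
            if name in data and isinstance(data[name], dict):
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                sub_unknown = set(data[name]) - sub_known
                if sub_unknown:
                    raise ConfigError(
                        f"unknown keys in '{name}' block: {sorted(sub_unknown)}"
                    )
                block = sub_cls(**data[name])
                for tup_field in ("tau_bounds", "alpha_bounds", "n_grid"):
                    if hasattr(block, tup_field):
                        setattr(block, tup_field, tuple(getattr(block, tup_field)))
                data[name] = block
        return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return RunConfig.from_dict(raw)


def stage_seed(master_seed: int, stage_index: int) -> int:
    """Per-stage seed derived from the master seed via a counter (< 2**31)."""
    ss = np.random.SeedSequence([int(master_seed), int(stage_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns a result bundle.

    The bundle contains the in-memory stage outputs plus ``manifest`` with
    the config, seed, package version, and sha256 of every written file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    bundle: dict = {"out_dir": str(out)}
    stage = "setup"
    try:
        # -- simulate ----------------------------------------------------
        if config.simulate is not None:
            stage = "simulate"
            log.info("stage simulate: generating synthetic telemetry")
            sim_kwargs = dict(config.simulate)
            sim_kwargs.pop("render", None)
            sim_cfg = SimConfig(seed=stage_seed(config.seed, 0), **sim_kwargs)
            truth, waveform = simulate(sim_cfg, render=True)
            outputs["waveform"] = out / "waveform.h5"
            write_waveform(waveform, outputs["waveform"])
            truth_paths = write_ground_truth(truth, out)
            outputs.update({k: Path(v) for k, v in truth_paths.items()})
            bundle["truth"] = truth
            waveform_path = outputs["waveform"]
        else:
            waveform_path = Path(config.input_waveform)

        # -- beats -------------------------------------------------------
        stage = "beats"
        log.info("stage beats: reading %s", waveform_path)
        if not waveform_path.exists():
            raise FileNotFoundError(f"waveform file not found: {waveform_path}")
        waveform = read_waveform(waveform_path)
        beats = detect_beats(waveform)
        outputs["beats"] = out / "beats.csv"
        write_beats_csv(beats, outputs["beats"])
        bundle["beats"] = beats
        log.info("stage beats: %d cycles detected", len(beats))

        # -- windows -----------------------------------------------------
        stage = "windows"
        wcfg = config.windows
        window_set = select_windows(
            beats,
            block_s=wcfg.block_s,
            window_s=wcfg.window_s,
            n_blocks=wcfg.n_blocks,
            max_gap_s=wcfg.max_gap_s,
        )
        outputs["windows"] = out / "windows.json"
        _write_json(
            outputs["windows"],
            {
                "windows": window_set.to_records(),
                "missing_blocks": window_set.missing_blocks,
                "window_s": window_set.window_s,
                "block_s": window_set.block_s,
            },
        )
        segments = [window_beats(beats, w) for w in window_set.windows]
        bundle["window_set"] = window_set
        log.info(
            "stage windows: %d/%d blocks usable",
            len(window_set.windows),
            wcfg.n_blocks,
        )

        # -- fit ---------------------------------------------------------
        stage = "fit"
        problem = FitProblem(segments, T=config.slopes.T_s)
        fit = fit_parameters(
            problem,
            tau_bounds=config.fit.tau_bounds,
            alpha_bounds=config.fit.alpha_bounds,
            n_grid=config.fit.n_grid,
        )
        outputs["params"] = out / "params.json"
        _write_json(
            outputs["params"],
            {
                "alpha_s_per_mmHg": fit.params.alpha,
                "tau_s": fit.params.tau,
                "R0_s_per_window": fit.R0_per_window,
                "J": fit.J,
                "sigma_d": fit.sigma_d,
                "sigma_m": fit.sigma_m,
                "converged": fit.converged,
            },
        )
        if config.fit.landscape:
            outputs["landscape"] = out / "landscape.csv"
            grid_landscape(
                problem,
                tau_bounds=config.fit.tau_bounds,
                alpha_bounds=config.fit.alpha_bounds,
                n=config.fit.landscape_n,
            ).to_csv(outputs["landscape"], index=False, float_format=repr_float)
        bundle["fit"] = fit
        log.info(
            "stage fit: alpha=%.3g s/mmHg tau=%.3g s J=%.3g",
            fit.params.alpha,
            fit.params.tau,
            fit.J,
        )

        # -- classify ----------------------------------------------------
        stage = "classify"
        boundary = Boundary(r=config.boundary.r, a_curv=config.boundary.a_curv)
        state_rows = []
        episode_frames = []
        tracks = []
        for seg, mu_d in zip(segments, problem.mu_d):
            t = seg["t_s"].to_numpy()
            rr = seg["rr_s"].to_numpy()
            mp = seg["map_mmHg"].to_numpy()
            R0 = compute_R0(rr, mp, fit.params.alpha)
            rr_model = simulate_rr(mp, rr, fit.params.with_R0(R0), rr_init=rr[0])
            mu_m = window_slopes(rr_model, t, config.slopes.T_s)
            track = classify_beats(
                mu_d, mu_m, t, rr, boundary, config.smoothing.window_s
            )
            tracks.append(track)
            episode_frames.append(track.episodes)
            state_rows.append(
                pd.DataFrame(
                    {
                        "t_s": t,
                        "mu_d": mu_d,
                        "mu_m": mu_m,
                        "raw_label": track.raw_labels,
                        "smoothed_value": track.smoothed_values,
                        "final_label": track.final_labels,
                    }
                )
            )
        states = pd.concat(state_rows, ignore_index=True)
        states.insert(0, "beat_index", np.arange(1, len(states) + 1))
        episodes = pd.concat(episode_frames, ignore_index=True)
        outputs["states"] = out / "states.csv"
        states.to_csv(outputs["states"], index=False, float_format=repr_float)
        outputs["episodes"] = out / "episodes.csv"
        episodes.rename(
            columns={"t_start_s": "t_start_s", "t_end_s": "t_end_s"}
        ).to_csv(outputs["episodes"], index=False, float_format=repr_float)
        all_beats = pd.concat(segments, ignore_index=True)
        final_labels = np.concatenate([tr.final_labels for tr in tracks])
        on_fraction = compute_on_fraction(final_labels, all_beats["rr_s"].to_numpy())
        bundle.update(
            tracks=tracks,
            episodes=episodes,
            states=states,
            on_fraction=on_fraction,
            window_segments=segments,
            final_labels=final_labels,
        )
        log.info("stage classify: on fraction %.3f", on_fraction)

        # -- summarize ---------------------------------------------------
        stage = "summarize"
        summary = state_conditioned_map(all_beats, final_labels)
        trends = transition_trends(
            all_beats,
            episodes,
            horizon_s=config.transitions.horizon_s,
            step_s=config.transitions.step_s,
        )
        payload = {
            "on_fraction": on_fraction,
            "map_mean_on_mmHg": summary.map_mean_on,
            "map_mean_off_mmHg": summary.map_mean_off,
            "map_mean_on_tw_mmHg": summary.map_mean_on_tw,
            "map_mean_off_tw_mmHg": summary.map_mean_off_tw,
            "delta_map_20s_on_mmHg": trends[1].delta,
            "delta_map_20s_off_mmHg": trends[0].delta,
            "n_episodes_on_gt_horizon": trends[1].n_episodes,
            "n_episodes_off_gt_horizon": trends[0].n_episodes,
            "hr_std_bpm": hr_std_bpm(all_beats["rr_s"]),
            "n_windows": len(segments),
            "n_beats": int(len(all_beats)),
            "alpha_s_per_mmHg": fit.params.alpha,
            "tau_s": fit.params.tau,
            "sigma_d": fit.sigma_d,
        }
        outputs["summary"] = out / "summary.json"
        _write_json(outputs["summary"], payload)
        bundle["summary"] = payload
        bundle["trends"] = trends
    except Exception as exc:
        raise PipelineError(f"stage '{stage}': {exc}") from exc

    # the hash covers the scientific settings, not the output location
    hashed_config = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(hashed_config, sort_keys=True, default=float).encode()
        ).hexdigest(),
        "outputs": {k: {"file": p.name, "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    _write_json(out / "manifest.json", manifest)
    bundle["manifest"] = manifest
    return bundle
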