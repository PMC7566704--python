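"""Waveform I/O round trips, beat detection, per-cycle MAP, window selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import trapezoid

from barostate import (
    PressureWaveform,
    SimConfig,
    compute_map,
    detect_beats,
    read_waveform,
    render_waveform,
    select_windows,
    simulate,
    window_beats,
    write_waveform,
)
from barostate.exceptions import (
    EmptyInputError,
    EmptyWindowsError,
    FormatError,
    InvalidInputError,
    NoBeatsError,
)
from barostate.telemetry import read_beats_csv, write_beats_csv


@pytest.fixture(scope="module")
def rendered():
    """60 s of rendered waveform with its generating beat table."""
    cfg = SimConfig(seed=3, duration_s=60.0)
    truth, wf = simulate(cfg, render=True)
    return truth, wf


class TestWaveformIO:
    def test_hdf5_round_trip_is_bit_exact(self, tmp_path, rendered):
        _, wf = rendered
        write_waveform(wf, tmp_path / "w.h5")
        back = read_waveform(tmp_path / "w.h5")
        assert np.array_equal(back.samples, wf.samples)
        assert back.fs == wf.fs and back.t0 == wf.t0

    def test_csv_round_trip_and_fs_inference(self, tmp_path):
        wf = PressureWaveform(samples=np.linspace(80, 120, 500), fs=500.0, t0=1.5)
        write_waveform(wf, tmp_path / "w.csv")
        back = read_waveform(tmp_path / "w.csv")
        np.testing.assert_allclose(back.samples, wf.samples, rtol=0, atol=0)
        assert back.fs == pytest.approx(500.0, rel=1e-9)
        assert back.t0 == pytest.approx(1.5)

    def test_nan_samples_flagged_corrupt_not_dropped(self, tmp_path):
        samples = np.full(1000, 100.0)
        samples[100:150] = np.nan
        wf = PressureWaveform(samples=samples, fs=500.0)
        write_waveform(wf, tmp_path / "w.csv")
        back = read_waveform(tmp_path / "w.csv")
        assert back.samples.size == 1000
        assert not back.quality_mask[100:150].any()
        assert back.quality_mask[:100].all() and back.quality_mask[150:].all()

    def test_missing_header_is_format_error(self, tmp_path):
        (tmp_path / "bad.csv").write_text("0.0,100.0\n0.002,101.0\n")
        with pytest.raises(FormatError):
            read_waveform(tmp_path / "bad.csv")

    def test_empty_file_is_empty_input_error(self, tmp_path):
        (tmp_path / "empty.csv").write_text("time_s,pressure_mmHg\n")
        with pytest.raises(EmptyInputError):
            read_waveform(tmp_path / "empty.csv")

    def test_h5_missing_fs_attribute_is_format_error(self, tmp_path):
        import h5py

        with h5py.File(tmp_path / "no_fs.h5", "w") as f:
            f.create_dataset("pressure", data=np.full(100, 100.0))
        with pytest.raises(FormatError):
            read_waveform(tmp_path / "no_fs.h5")

    def test_beats_csv_round_trip(self, tmp_path, rendered):
        truth, _ = rendered
        write_beats_csv(truth.beats, tmp_path / "b.csv")
        back = read_beats_csv(tmp_path / "b.csv")
        np.testing.assert_allclose(back["rr_s"], truth.beats["rr_s"], rtol=0)
        assert back["beat_index"].iloc[0] == 1


class TestDetectBeats:
    def test_constant_trace_has_no_beats(self):
        wf = PressureWaveform(samples=np.full(5000, 100.0), fs=500.0)
        with pytest.raises(NoBeatsError):
            detect_beats(wf)

    def test_round_trip_recovers_beat_count_and_pressures(self):
        # 360 beats/min for 60 s rendered and re-detected
        t = np.arange(360) * (1.0 / 6.0)
        beats = pd.DataFrame(
            {
                "t_s": t,
                "rr_s": np.full(360, 1.0 / 6.0),
                "sp_mmHg": np.full(360, 130.0),
                "dp_mmHg": np.full(360, 85.0),
            }
        )
        wf = render_waveform(beats, fs=500.0)
        found = detect_beats(wf)
        assert abs(len(found) - 360) <= 1
        assert np.abs(found["sp_mmHg"] - 130.0).max() < 0.5
        assert np.abs(found["dp_mmHg"] - 85.0).max() < 0.5
        # RR is quantized to the 2 ms sample grid
        assert found["rr_s"].median() == pytest.approx(1.0 / 6.0, abs=1.0 / 500.0)

    def test_simulator_round_trip_matches_truth(self, rendered):
        truth, wf = rendered
        found = detect_beats(wf)
        assert abs(len(found) - len(truth.beats)) <= 1
        n = min(len(found), len(truth.beats))
        assert np.abs(
            found["sp_mmHg"].to_numpy()[:n] - truth.beats["sp_mmHg"].to_numpy()[:n]
        ).max() < 0.5
        assert np.abs(
            found["map_mmHg"].to_numpy()[:n] - truth.beats["map_mmHg"].to_numpy()[:n]
        ).max() < 0.5

    def test_corrupt_gap_drops_only_overlapping_beats(self, rendered):
        truth, wf = rendered
        clean = detect_beats(wf)
        corrupted = PressureWaveform(samples=wf.samples.copy(), fs=wf.fs, t0=wf.t0)
        gap = slice(int(20 * wf.fs), int(22 * wf.fs))  # 2 s gap at t = 20 s
        corrupted.samples[gap] = np.nan
        corrupted.quality_mask[gap] = False
        found = detect_beats(corrupted)
        assert not (
            (found["t_s"] + found["rr_s"] > 20.0) & (found["t_s"] < 22.0)
        ).any()
        expected_dropped = (
            (clean["t_s"] + clean["rr_s"] > 20.0) & (clean["t_s"] < 22.0)
        ).sum()
        assert len(clean) - len(found) == pytest.approx(expected_dropped, abs=1)
        # beats far from the gap are unchanged
        before = found[found["t_s"] < 19.0]
        np.testing.assert_allclose(
            before["sp_mmHg"], clean.iloc[: len(before)]["sp_mmHg"], atol=1e-12
        )

    def test_offset_invariance(self, rendered):
        _, wf = rendered
        base = detect_beats(wf)
        shifted = detect_beats(
            PressureWaveform(samples=wf.samples + 20.0, fs=wf.fs, t0=wf.t0)
        )
        assert len(base) == len(shifted)
        np.testing.assert_allclose(shifted["rr_s"], base["rr_s"], atol=1e-12)
        np.testing.assert_allclose(shifted["sp_mmHg"], base["sp_mmHg"] + 20.0, atol=1e-9)

    def test_beat_table_invariants_on_simulator_output(self, rendered):
        _, wf = rendered
        b = detect_beats(wf)
        assert (b["sp_mmHg"] > b["dp_mmHg"]).all()
        np.testing.assert_allclose(b["pp_mmHg"], b["sp_mmHg"] - b["dp_mmHg"])
        assert (b["dp_mmHg"] <= b["map_mmHg"]).all()
        assert (b["map_mmHg"] <= b["sp_mmHg"]).all()
        assert (b["rr_s"] > 0).all()
        assert b["t_s"].is_monotonic_increasing


class TestComputeMap:
    def test_constant_cycle(self):
        assert compute_map(np.full(100, 100.0)).value == pytest.approx(100.0)

    def test_sinusoid_over_whole_periods(self):
        t = np.arange(1000) / 1000.0
        seg = 100.0 + 20.0 * np.sin(2 * np.pi * 5 * t)
        assert compute_map(seg).value == pytest.approx(100.0, abs=1e-9)

    def test_matches_trapezoid_oracle_on_pulse_template(self):
        beats = pd.DataFrame(
            {"t_s": [0.0], "rr_s": [0.2], "sp_mmHg": [120.0], "dp_mmHg": [80.0]}
        )
        wf = render_waveform(beats, fs=5000.0)
        est = compute_map(wf.samples).value
        # periodic cycle: close the contour with the first sample repeated
        closed = np.concatenate((wf.samples, wf.samples[:1]))
        oracle = trapezoid(closed, dx=1.0 / 5000.0) / 0.2
        assert est == pytest.approx(oracle, rel=1e-6)

    def test_extrema_fallback_mode(self):
        res = compute_map(None, sp=120.0, dp=80.0)
        assert res.value == pytest.approx(80.0 + 40.0 / 3.0)
        assert res.mode == "extrema"

    def test_empty_segment_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_map(np.array([]))


def _uniform_beats(duration_s, rr=0.2, t0=0.0):
    t = t0 + np.arange(int(duration_s / rr)) * rr
    return pd.DataFrame(
        {
            "t_s": t,
            "rr_s": np.full(t.size, rr),
            "sp_mmHg": 120.0,
            "dp_mmHg": 80.0,
            "pp_mmHg": 40.0,
            "map_mmHg": 100.0,
        }
    )


class TestSelectWindows:
    def test_clean_record_centers_every_window(self):
        beats = _uniform_beats(12 * 3600.0)
        ws = select_windows(beats)
        assert len(ws.windows) == 12 and not ws.missing_blocks
        for w in ws.windows:
            mid = (w.block - 1) * 3600.0 + 1800.0
            assert abs((w.t_start_s + w.t_end_s) / 2.0 - mid) <= 0.2  # one beat
            assert w.t_end_s - w.t_start_s == pytest.approx(300.0)

    def test_corruption_shifts_window_to_nearest_clean_span(self):
        beats = _uniform_beats(2 * 3600.0)
        # kill minutes 25-35 of hour 2
        bad = (beats["t_s"] >= 3600 + 25 * 60) & (beats["t_s"] < 3600 + 35 * 60)
        beats = beats[~bad].reset_index(drop=True)
        ws = select_windows(beats, n_blocks=2)
        w2 = [w for w in ws.windows if w.block == 2][0]
        # oracle: enumerate every feasible 300 s start on a fine grid
        gaps = [(3600 + 25 * 60, 3600 + 35 * 60)]
        starts = np.arange(3600.0, 2 * 3600.0 - 300.0, 1.0)
        feasible = [
            s for s in starts if not any(s < g1 and s + 300 > g0 for g0, g1 in gaps)
        ]
        best = min(feasible, key=lambda s: abs(s + 150.0 - (3600 + 1800)))
        assert abs(w2.t_start_s - best) <= 1.0

    def test_fully_corrupt_hour_is_flagged(self):
        beats = _uniform_beats(3 * 3600.0)
        bad = (beats["t_s"] >= 3600.0) & (beats["t_s"] < 2 * 3600.0)
        beats = beats[~bad].reset_index(drop=True)
        ws = select_windows(beats, n_blocks=3)
        assert ws.missing_blocks == [2]
        assert sorted(w.block for w in ws.windows) == [1, 3]

    def test_no_usable_hour_raises(self):
        beats = _uniform_beats(60.0)  # far less than one window
        with pytest.raises(EmptyWindowsError):
            select_windows(beats)

    def test_window_beats_slice_is_half_open(self):
        beats = _uniform_beats(3600.0)
        ws = select_windows(beats, n_blocks=1)
        seg = window_beats(beats, ws.windows[0])
        assert seg["t_s"].iloc[0] >= ws.windows[0].t_start_s
        assert seg["t_s"].iloc[-1] < ws.windows[0].t_end_s
        assert len(seg) == pytest.approx(1500, abs=1)
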