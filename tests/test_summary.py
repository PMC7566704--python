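"""State-conditioned MAP statistics, transition trends, cohort correlation,
elasticity, and daily summaries."""

import numpy as np
import pandas as pd
import pytest

from barostate import (
    SimConfig,
    cohort_correlation,
    compute_elasticity,
    daily_map_summary,
    simulate,
    state_conditioned_map,
    transition_trends,
)
from barostate.classify import extract_episodes
from barostate.exceptions import InvalidInputError
from barostate.summary import hr_std_bpm, sem


def beats_frame(mp, rr=0.2):
    mp = np.asarray(mp, dtype=float)
    if mp.size == 0:
        return pd.DataFrame({"t_s": [], "rr_s": [], "map_mmHg": []})
    rr = np.broadcast_to(rr, mp.shape).astype(float)
    t = np.concatenate(([0.0], np.cumsum(rr[:-1])))
    return pd.DataFrame({"t_s": t, "rr_s": rr, "map_mmHg": mp})


class TestStateConditionedMap:
    def test_all_on_flags_missing_off_state(self, rng):
        beats = beats_frame(rng.normal(120, 5, 500))
        s = state_conditioned_map(beats, np.ones(500, dtype=int))
        assert s.map_mean_on == pytest.approx(beats["map_mmHg"].mean())
        assert s.map_mean_off is None and s.density_off is None
        assert any("off" in f for f in s.flags)

    def test_recovers_injected_state_offset(self, rng):
        # off beats drawn 2 mmHg higher than on beats
        labels = (rng.random(20_000) < 0.6).astype(int)
        mp = rng.normal(120, 4, 20_000) + 2.0 * (labels == 0)
        s = state_conditioned_map(beats_frame(mp), labels)
        assert s.map_mean_off - s.map_mean_on == pytest.approx(2.0, abs=0.3)

    def test_densities_normalize_on_grid(self, rng):
        labels = (rng.random(3000) < 0.5).astype(int)
        s = state_conditioned_map(beats_frame(rng.normal(120, 6, 3000)), labels)
        step = s.density_grid[1] - s.density_grid[0]
        for dens in (s.density_on, s.density_off, s.density_all):
            assert dens.sum() * step == pytest.approx(1.0, abs=1e-3)

    def test_time_weighted_decomposition_identity(self, rng):
        # overall time-weighted <MAP> = f*<MAP>_on + (1-f)*<MAP>_off exactly
        n = 4000
        labels = (rng.random(n) < 0.55).astype(int)
        beats = beats_frame(rng.normal(125, 5, n), rr=rng.uniform(0.15, 0.25, n))
        s = state_conditioned_map(beats, labels)
        dt = beats["rr_s"].to_numpy()
        f = dt[labels == 1].sum() / dt.sum()
        overall = np.average(beats["map_mmHg"], weights=dt)
        assert f * s.map_mean_on_tw + (1 - f) * s.map_mean_off_tw == pytest.approx(
            overall, rel=1e-12
        )


class TestTransitionTrends:
    def test_constant_map_has_zero_delta(self):
        n = 3000
        beats = beats_frame(np.full(n, 120.0))
        labels = (np.arange(n) // 300) % 2
        eps = extract_episodes(labels, beats["t_s"].to_numpy(), beats["rr_s"].to_numpy())
        trends = transition_trends(beats, eps)
        assert trends[1].delta == 0.0 and trends[0].delta == 0.0

    def test_recovers_injected_drift(self, rng):
        # MAP drifts +0.1 mmHg/s during off episodes -> delta_off ~ 2 mmHg
        rr = 0.2
        per = 300  # beats per 60 s episode
        n = 100 * 2 * per
        pos = np.arange(n) % (2 * per)
        labels = (pos < per).astype(int)  # alternating 60 s on / 60 s off
        elapsed_off = np.where(pos >= per, (pos - per) * rr, 0.0)
        mp = 120.0 + rng.normal(0, 0.5, n) + 0.1 * elapsed_off
        beats = beats_frame(mp, rr=rr)
        eps = extract_episodes(
            labels, beats["t_s"].to_numpy(), beats["rr_s"].to_numpy()
        )
        trends = transition_trends(beats, eps)
        assert trends[0].delta == pytest.approx(2.0, abs=0.4)
        assert trends[1].delta == pytest.approx(0.0, abs=0.4)

    def test_grid_and_shapes_contract(self):
        n = 2000
        beats = beats_frame(np.full(n, 110.0))
        labels = (np.arange(n) // 250) % 2
        eps = extract_episodes(labels, beats["t_s"].to_numpy(), beats["rr_s"].to_numpy())
        trends = transition_trends(beats, eps, horizon_s=20.0, step_s=0.5)
        for tr in trends.values():
            assert tr.grid_s.size == 41  # horizon/step + 1
            if tr.n_episodes:
                assert tr.trajectories.shape == (tr.n_episodes, 41)

    def test_no_qualifying_episode_is_flagged_empty(self):
        beats = beats_frame(np.full(100, 120.0))
        eps = extract_episodes(
            np.ones(100, dtype=int),
            beats["t_s"].to_numpy(),
            beats["rr_s"].to_numpy(),
        )
        trends = transition_trends(beats, eps, horizon_s=100.0)
        assert trends[0].n_episodes == 0 and trends[0].delta is None


class TestCohortCorrelation:
    def test_collinear_decreasing_gives_minus_one(self):
        res = cohort_correlation([0.8, 0.6, 0.4], [100.0, 120.0, 140.0])
        assert res["r"] == pytest.approx(-1.0)

    def test_matches_textbook_sum_formula(self):
        x = np.array([0.45, 0.52, 0.61, 0.70, 0.83])
        y = np.array([148.0, 139.0, 141.0, 128.0, 122.0])
        n = 5
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x * x).sum() - x.sum() ** 2) * np.sqrt(
            n * (y * y).sum() - y.sum() ** 2
        )
        res = cohort_correlation(x, y)
        assert res["r"] == pytest.approx(num / den, rel=1e-12)
        assert res["n"] == 5 and res["p"] < 0.05

    def test_joint_permutation_invariance(self, rng):
        x = rng.random(10)
        y = rng.random(10)
        perm = rng.permutation(10)
        assert cohort_correlation(x, y)["r"] == pytest.approx(
            cohort_correlation(x[perm], y[perm])["r"], rel=1e-12
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            cohort_correlation([0.5, 0.5, 0.5], [100.0, 110.0, 120.0])
        with pytest.raises(InvalidInputError):
            cohort_correlation([0.4, 0.6], [100.0, 110.0])


class TestElasticity:
    def test_worked_example_default_reading(self):
        assert compute_elasticity(120.0, 80.0, 1.1, 1.0) == pytest.approx(400.0)

    def test_literal_reading_exposed(self):
        assert compute_elasticity(120.0, 80.0, 1.1, 1.0, literal=True) == pytest.approx(
            40.0 * (1.0 / 1.1 - 1.0)
        )

    def test_linear_in_pulse_pressure(self):
        base = compute_elasticity(120.0, 80.0, 1.1, 1.0)
        assert compute_elasticity(160.0, 80.0, 1.1, 1.0) == pytest.approx(2 * base)

    def test_diverges_as_thickness_difference_vanishes(self):
        e1 = compute_elasticity(120.0, 80.0, 1.01, 1.0)
        e2 = compute_elasticity(120.0, 80.0, 1.001, 1.0)
        assert e2 > e1 > 0
        with pytest.raises(InvalidInputError):
            compute_elasticity(120.0, 80.0, 1.0, 1.0)


class TestDailySummary:
    def test_identical_days_have_zero_delta(self, rng):
        day = beats_frame(rng.normal(110, 5, 1000))
        table = daily_map_summary({d: day for d in range(-4, 4)}, range(-4, 1))
        np.testing.assert_allclose(table["delta_mmHg"], 0.0, atol=1e-12)

    def test_injected_shift_recovered(self, rng):
        days = {d: beats_frame(rng.normal(110, 5, 2000)) for d in range(-2, 5)}
        days[3] = beats_frame(rng.normal(120, 5, 2000))
        table = daily_map_summary(days, [-2, -1, 0])
        d3 = table.loc[table["day"] == 3, "delta_mmHg"].iloc[0]
        assert d3 == pytest.approx(10.0, abs=0.5)

    def test_higher_variance_raises_daily_std(self):
        # paired comparison: same seeds, only the spread differs
        quiet = beats_frame(np.random.default_rng(5).normal(110, 3, 3000))
        labile = beats_frame(np.random.default_rng(5).normal(110, 9, 3000))
        t_q = daily_map_summary({0: quiet}, [0])
        t_l = daily_map_summary({0: labile}, [0])
        assert t_l["map_std_mmHg"].iloc[0] > t_q["map_std_mmHg"].iloc[0]

    def test_empty_day_flagged(self, rng):
        days = {0: beats_frame(rng.normal(110, 5, 100)), 1: beats_frame(np.array([]))}
        table = daily_map_summary(days, [0])
        assert table.loc[table["day"] == 1, "flag"].iloc[0] == "empty"


class TestSmallHelpers:
    def test_paired_t_matches_one_sample_formula(self, rng):
        from barostate.summary import paired_t

        before = rng.normal(120, 5, 12)
        after = before + rng.normal(2, 1, 12)
        res = paired_t(before, after)
        d = after - before
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res["t"] == pytest.approx(t_manual, rel=1e-10)
        assert res["mean_diff"] == pytest.approx(d.mean())
        assert res["n"] == 12

    def test_densities_frame_columns_align_with_grid(self, rng):
        from barostate.summary import densities_frame

        labels = (rng.random(2000) < 0.5).astype(int)
        s = state_conditioned_map(beats_frame(rng.normal(120, 6, 2000)), labels)
        frame = densities_frame(s)
        assert list(frame.columns) == [
            "map_mmHg", "density_on", "density_off", "density_all",
        ]
        np.testing.assert_array_equal(frame["map_mmHg"], s.density_grid)
        step = s.density_grid[1] - s.density_grid[0]
        assert frame["density_on"].sum() * step == pytest.approx(1.0, abs=1e-3)

    def test_sem_matches_brute_force(self, rng):
        x = rng.random(37)
        assert sem(x) == pytest.approx(x.std(ddof=1) / np.sqrt(37), rel=1e-12)

    def test_hr_std_on_simulated_record(self):
        truth = simulate(SimConfig(seed=2, duration_s=300.0))
        rr = truth.beats["rr_s"].to_numpy()
        assert hr_std_bpm(rr) == pytest.approx(np.std(60.0 / rr, ddof=1))
        assert 0.0 < hr_std_bpm(rr) < 60.0
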