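# Methods

`barostate` detects intermittent engagement ("on") and disengagement
("off") of baroreflex-mediated heart-rate control in continuous arterial
pressure recordings, and quantifies it with the *on fraction* — the share
of recording time spent in the on state.  This note documents the model,
the algorithmic choices, the synthetic-data generator, and the limits of
what the test suite demonstrates.

## The baroreflex filter

When the reflex arc is engaged, a rise in mean arterial pressure (MAP)
lengthens the interval between heartbeats (RR).  The package models this
with a first-order linear filter,

    dRR/dt = (alpha · MAP(t) + R0 − RR) / tau,

with three parameters:

| parameter | units  | meaning                                            | default handling |
|-----------|--------|----------------------------------------------------|------------------|
| alpha     | s/mmHg | baroreflex sensitivity: RR change per unit MAP     | fitted, bounds [1e-5, 1e-2] |
| tau       | s      | response time constant (1/tau = response rate)     | fitted, bounds [0.1, 30] |
| R0        | s      | offset RR interval                                 | `⟨RR⟩ − alpha·⟨MAP⟩` per 5-minute window |

Holding MAP constant over each cardiac cycle of duration `dt_j`
(zero-order hold) makes the per-beat update exact:

    RR_{j+1} = RR_ss,j + (RR_j − RR_ss,j) · exp(−dt_j/tau),
    RR_ss,j  = alpha · MAP_j + R0.

Each 5-minute window is simulated independently with `RR_1` set to the
first observed RR; any initialization transient decays within ~5 tau,
far shorter than the window.  For time-varying MAP the left-endpoint
zero-order hold is first-order accurate in `dt`; the test suite asserts
the observed convergence under grid refinement rather than a nominal
order.

## Per-beat quantities

Cardiac cycles are detected from the pressure waveform as alternating
local maxima (systole) and minima (diastole) with a 50 ms refractory
period (rat heart rate stays below ~600 beats/min; the refractory period
suppresses dicrotic-notch double counts).  A cycle runs from one
diastolic onset to the next; RR is the inter-systolic-peak interval, and
MAP is the time average of pressure over the cycle (`DP + PP/3` is
available as a fallback when only extrema exist).  Samples that are
non-finite or outside 0–300 mmHg are flagged corrupt and any cycle
touching them is dropped, not repaired.  From each hour of a 12-hour
dark-cycle recording, the analysis takes the one 5-minute window of
continuous clean coverage whose center lies nearest the hour's midpoint
(ties resolve to the earlier window).

## Slope variability and the fit

Local heart-rate variability is summarized by `mu_d` and `mu_m`: the
ordinary-least-squares slope of RR versus time inside a `T = 10 s` window
centered at each beat, computed for the observed and the model-predicted
RR.  Windows never cross analysis-window boundaries; edge windows use the
available beats and need at least three, otherwise the slope is undefined
(NaN) and excluded from variability statistics.  Slopes are computed with
per-segment centering and extended-precision prefix sums, which agrees
with a direct per-beat normal-equations solve to ~1e-14.

Pooling slopes over all windows gives `sigma_d = std(mu_d)` and
`sigma_m = std(mu_m)`, and the parameters minimize

    J(tau, alpha) = ((sigma_m − sigma_d) / sigma_d)²

by Nelder-Mead in log10 space, multi-started from a 5×5 log-spaced grid
over the bounds.

**Identifiability.**  Because the model RR is affine in `alpha`, for
every `tau` there is an `alpha` that matches `sigma_m` to `sigma_d`
exactly: the minimum of J is a one-dimensional ridge, and a plain argmin
returns an arbitrary ridge point.  The fit therefore applies a
deterministic tie-break: among starts whose final J lies within `j_tol`
(default 1e-6) of the best, it keeps the one maximizing the Pearson
correlation between pooled model and data slopes.  The correlation is
invariant to rescaling `alpha`, so the tie-break only disambiguates
response *timing*; on synthetic always-on data it pins `tau` near the
generating value and recovers `alpha` to within a few percent.  The full
J landscape can be exported (`grid_landscape`) for inspection.

## On/off classification

Each beat contributes a point `(mu_d, mu_m)`.  Engagement means the model
tracks the data, i.e. the point lies near the diagonal `y = x`;
disengagement scatters it away.  The boundary between the regimes is a
hyperbola symmetric about the diagonal with axis intercepts `±r`. In
rotated coordinates `u = (mu_d+mu_m)/√2`, `v = (mu_m−mu_d)/√2` a beat is
**on** iff

    v² ≤ r²(a²−1)/(2a²) + u²/a²,

a band around the diagonal with vertex height `r·sqrt((a²−1)/2)/a` and
asymptote slope `1/a`.  The curvature parameter `a = 3.5` controls how
the tolerated model/data disagreement grows with slope magnitude; the
geometry requires `a > 1`.  Among the hyperbolae satisfying the intercept
and symmetry constraints, this is the one whose off region actually
captures decoupled beats: the alternative branch orientation (asymptotes
at slope ~0.93) algebraically reduces to a sign-agreement test whose
off-state detection rate is capped near 50% regardless of parameters —
measured directly during development — and cannot segment switching data.

The intercept `r` absorbs the noise floor of the slope estimates.  It is
fixed at 0.0004 for baroreceptor-intact animals and 0.00015 after
sinoaortic denervation; the underlying calibration rule — half the pooled
`sigma_d` of the cohort — is exposed as `calibrate_r` and never applied
silently.  Membership is closed (boundary points are on).  Beats with
undefined slopes inherit the nearest defined beat's label, flagged, and
are excluded from variability statistics.

Raw labels are denoised by an iterated majority filter: average the 0/1
series over a 10 s time-centered window, re-threshold at 0.5 (≥ 0.5 is
on), and repeat until the labels stop changing (cap 100 iterations,
flagged).  Re-thresholding between passes matters: iterating the plain
moving average on real values converges toward a global constant and
erases every minority episode, while the majority filter terminates at a
true fixed point and preserves episodes longer than about half the
window.  Maximal runs of constant label become episodes; the on fraction
is time-weighted (`sum of on-beat durations / total duration`).

## Synthetic telemetry generator

The generator emulates dark-cycle rodent telemetry with every stage's
ground truth retained:

- **Switching**: a two-state continuous-time Markov chain (exponential
  dwell times, default means 120 s on / 60 s off) started from its
  stationary occupancy, so the expected time-weighted on fraction is
  `120/180` at any record length.  States change at beat boundaries.
- **MAP**: a discretized Ornstein-Uhlenbeck process, mean 120 mmHg, sd
  4 mmHg, relaxation time 8 s, initialized at stationarity.
- **RR**: during on beats, the filter recursion (alpha = 0.001 s/mmHg,
  tau = 2 s) driven by the MAP track; during off beats an independent OU
  process around the mean RR (sd 8 ms, relaxation 5 s) that ignores MAP —
  decoupled but comparably variable heart rate, as during behavioral
  override of the reflex.  White observation noise (sd 1 ms) is added on
  top without feeding back into the dynamics.
- **Waveform**: each beat is a raised-cosine upstroke (30% of the cycle)
  followed by an exponential diastolic decay, scaled so the sample
  extrema equal SP and DP and joined continuously at diastole.

The noise scales were calibrated *a priori* so that the pooled
`sigma_d` of intact synthetic recordings is ≈ 0.0008 — the operating
point implied by the published intercept `r = sigma_d/2 = 0.0004` — with
on- and off-state slope variability in roughly 1:2 ratio.  HR baseline
(360 beats/min), MAP level, and pulse pressure (40 mmHg) are standard
adult-rat telemetry values.  The config validator requires the rendered
rate to match the filter operating point `R0 + alpha·MAP` within 20%.

What the generator does **not** emulate: respiratory and circadian
modulation, sigmoidal (saturating) baroreflex curves, pressure-dependent
dwell times (except where a test injects them), state-dependent MAP
levels, and telemetry artifacts other than the corrupt-sample mask.
Passing recovery tests therefore demonstrates internal consistency of
the pipeline under the stated stochastic model, not performance on real
recordings.

## Numerical choices and degenerate inputs

- Sample standard deviations use `ddof=1` throughout.
- `sigma_d` below 1e-12 (flat data) raises a degenerate-data error; a
  zero denominator in a slope window yields NaN for that beat.
- Windows, episodes, and blocks are half-open `[start, end)`; beat
  indices are 0-based internally and 1-based in written tables.
- Ties in window selection and fit starts resolve to the earlier
  candidate; all stages are deterministic given the seed, and per-stage
  seeds derive from the master seed via `SeedSequence([seed, counter])`.
- The elasticity formula reads `(P_sys − P_dia) · T_dia/(T_sys − T_dia)`
  by default — pulse pressure over relative wall-thickness strain, the
  dimensionally coherent reading — with the literal alternative
  parenthesization available via `literal=True`.
- Recovery studies in the tests and the acceptance script use scaled
  problem sizes chosen as representative: a two-hour rendered recording
  (twelve 5-minute windows cut from 10-minute blocks) and ten one-hour
  beat-level recordings; window selection itself is exercised at the full
  12 × 1-hour layout on constructed beat tables.

## Known limitations

- The (tau, alpha) ridge means the fitted pair is identified only through
  the timing tie-break; recordings whose slope autocorrelation is flat in
  tau (for example, heavily smoothed or very short windows) can still
  return poorly determined parameters.  Inspect the exported landscape.
- On-fraction estimates are biased toward the majority state for episodes
  shorter than about half the smoothing window (~5 s), which the 10 s
  filter cannot resolve.
- The boundary constants are cohort-level calibrations; analyses of data
  with different noise floors should recompute `r` via `calibrate_r`.
- Beat detection assumes a pulsatile signal with at least 5 mmHg
  peak-to-trough range and clean diastolic minima; severe damping or
  catheter ringing will degrade cycle segmentation before anything
  downstream fails loudly.
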