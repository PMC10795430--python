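# Methods

This note records the models behind `gateqa`, the defaults and why they
were chosen, the numerical choices, and what the synthetic-data layer can
and cannot say about real hardware.

## Breathing waveforms

The ground-truth waveform is `x(t) = baseline + A·cos⁴(π t/T)`:
peak-to-peak amplitude `A` (mm), period `T` (s), end-exhale at the
baseline and the inhale peak at `baseline + A`. The cos⁴ shape spends
most of the cycle near end-exhale, which is what makes end-exhale gating
attractive in the first place. Its maximum speed, used for latency
back-calculation, is closed-form:

    V_max = A·(4π/T)·(3√3/16) = (3√3π/4)·A/T,

attained where tan²(πt/T) = 1/3 (20.405 mm/s for A = 20 mm, T = 4 s).

Volunteer-like traces are built per cycle: amplitudes and periods are
drawn from truncated normals (±3 SD, floored at 0.1 mm and 0.5 s so every
cycle stays physical) and one cos⁴ template is rescaled per cycle. Cycles
are concatenated at the end-exhale minima — both endpoints of a min-to-min
cycle are exactly zero, so the trace is value-continuous for any amplitude
sequence; slope continuity is *not* enforced, which resembles real
breath-to-breath irregularity. A leading descending half-cycle makes the
degenerate case (all SDs zero) reduce exactly to the cos⁴ formula. Only
the published per-pattern means and SDs are available for the volunteer
recordings, so the generator is moment-matched, not trace-matched: the
distribution family (truncated normal) and the absence of serial
correlation between cycles are modelling choices.

Ground truth is sampled at 100 Hz by default — more than 4× the camera
rate — so that interpolation error in downstream comparisons is dominated
by the camera grid, not the truth grid.

## Camera emulation

Optical surface trackers do not sample on a fixed clock. Successive
sample intervals are reciprocals of truncated-normal instantaneous rates
(defaults 22.7 ± 0.5 Hz, truncated to [5, 100] Hz); values are linearly
interpolated from the truth at `t − lag` and perturbed with i.i.d.
Gaussian noise. The position-noise magnitude of a real tracker is not
separable from phantom reproducibility in published data, so `noise_sd`
is a free parameter (0 by default). Thermal drift, camera geometry,
occlusions and skin-tone effects are out of scope.

## Trace comparison

Cycles are detected as prominent extrema (default prominence 10 % of the
signal range; default separation half the median peak spacing from a
first pass). Peak times are refined by a quadratic fit over ±5 % of the
cycle around the raw argmax: breathing peaks are locally parabolic, and
the fit removes both the sampling-grid quantisation and most of the
noise-induced argmax jitter. Period is the spacing of successive refined
peaks; amplitude is the peak value minus the mean of the adjacent valley
values; summary SDs use the n−1 convention.

Truth and measurement are synchronized on an anchor peak — the fourth
detected peak (a stable point after the tracker's learning phase) or the
maximum-amplitude peak — and compared on the truth grid over the overlap
region (the measured signal is linearly interpolated; computing on the
denser grid was a choice, the alternative being the measured grid). MAD
is the mean absolute difference; PCC the standard Pearson r. Without the
sub-sample anchor refinement the alignment is quantised to the ~44 ms
camera sampling grid and the noise-free MAD floor would be ~0.2 mm; with
it, the noise-free chain achieves MAD < 0.01 mm and PCC > 0.9999.

## Gating

Two phase conventions describe the same breathing curve: the CT scanner
splits it into inhale 0–100 % and exhale 0–100 % branches, while the
gating software puts the inhale peak at 100 % and the end-exhale trough at
50 %. The mapping is proportional: branch-relative tracker % = CT %/2;
absolute tracker % = CT %/2 on the exhale branch and 50 + CT %/2 on the
inhale branch. A 30 % exhale – 30 % inhale window is therefore 15–65 % on
the tracker scale.

The default gating convention is `amplitude_threshold`: after a learning
period (default 3 cycles; the baseline is the mean learning-cycle valley
value and the working amplitude the mean learning-cycle peak-to-peak),
the gate opens when the *descending* signal crosses `exhale%·A` above
baseline and closes when the *ascending* signal crosses `inhale%·A`.
This convention is the default because it uniquely reproduces the
measured reference triple for cos⁴(A = 20 mm, T = 4 s) with the 30–30
window: gate-on 2.12 s, 53 % of the period (the on-fraction is the root of
cos⁴u = 0.3: 1 − 2·arccos(0.3^¼)/π = 0.5304), and 6 mm residual motion. A
linear-in-time phase window 15–65 % would give 2.0 s / 50 % / 12.6 mm and
is inconsistent with those numbers; it is nevertheless implemented as
`time_phase` for comparison. Whether a real tracker's internal "phase" is
amplitude-proportional cannot be decided from published behaviour alone;
both conventions are first-class.

Crossing times are linearly interpolated between samples, so gate
boundaries are far more accurate than the sampling grid. Intervals
shorter than `min_gate_duration` (default 0.1 s) are discarded as noise
chatter; a 0 % exhale bound can never open the gate (the threshold sits on
the signal's own minimum). Latency shifts every on-transition by the
beam-on delay and every off-transition by the beam-off delay, dropping
collapsed intervals and merging overlaps; equal delays preserve interval
durations exactly. Duty-cycle and residual-motion statistics use only
*steady* intervals (opened and closed by genuine crossings); residual
motion includes the interpolated threshold values at the interval
endpoints, so a noise-free symmetric window yields the threshold exactly.

## Delivery

Spots are delivered in plan order at a constant particle rate; the clock
advances continuously, weight is deposited only while the beam signal is
on, and delivery resumes after gate-off, so the full plan weight always
arrives (conservation is exact by construction and asserted to 0.1 %).
Each deposited sub-weight (1 ms sub-steps) adds a Gaussian of the plan's
spot FWHM (default 10 mm) centred at `s − x(t)` on the target-frame grid
(default 0.17 mm ≈ 150 dpi film resolution; linear binning followed by a
single kernel convolution). There is no range/depth model: energy layers
differ only in delivery time, which is exactly what creates interplay
along the scan axis. No dose-rate transients, no synchrotron spill
structure — the constant-rate model is a documented simplification.

Default timing: the heaviest layer takes 1.5 s of beam-on time, 2 ms
settle between spots, 2 s between layers, so a 9-layer plan spans many
breathing cycles. One subtlety matters: with perfectly periodic breathing
and rigid timing, every layer start can phase-lock to the gate-open
transition, and if each lateral position is visited once per layer the
scan position correlates perfectly with breathing phase — the gated edge
then smears by several mm, which contradicts measured behaviour. Real 2-D
raster scanning traverses the scan line once per row of the orthogonal
axis, i.e. many passes per layer at different phases. `make_uniform_plan`
models this with `n_rows` (scan line serialised per layer, weight split
per pass): the scenario default of 8 rows decorrelates scan position from
phase, and the simulated gated-vs-static low-edge shift lands at about
−1 mm, matching film measurements. With `n_rows=1` the pathological
interplay case remains available for study.

The gated profile is shifted relative to the static (end-exhale) reference
even at zero latency: the window admits dose over the whole 0–6 mm
residual range, whose occupancy-weighted mean lies ~1.4 mm from the static
position. Injected beam delays modulate this shift; the back-calculated
`T_d = ΔL/V_max` uses the waveform's *maximum* speed because that is the
only velocity that converts the published beam-on and beam-off shifts
(1.04 and 1.12 mm) into the published delays (50.98 and 54.91 ms)
consistently. Since the true edge-crossing speed is below `V_max`, the
back-calculated delay is a lower bound on an injected delay, which the
property suite asserts. The beam-off delay only leaves a signature when
deposits actually run into gate-off transitions; the latency property
test therefore uses layers longer than one gate interval.

## Profile metrics

All relative levels are fractions of the *plateau* — the mean dose over
the central 50 % of the above-half-maximum region — so isolated noise
spikes do not distort widths; for a profile without a flat top (a single
spot) the plateau is ~6 % below the peak, and shape checks against
closed-form Gaussian widths pass the peak explicitly as the normalisation.
Widths use the outermost linearly-interpolated crossings (robust for
noisy multi-crossing profiles). Edge shifts compare per-edge crossing
positions of test and reference, each normalised to its own plateau.

## Dosimetry

`M_corr = M·k_TP·k_s·k_pol` with
`k_TP = ((273.15+T)/(273.15+T_ref))·(P_ref/P)`; reference conditions
default to 20 °C / 1013.25 hPa (standard protocol values, configurable).
`D_w = M_corr·N_D,w,Co-60·k_Q`; both calibration constants are config
inputs with placeholder defaults of 1 — real values are chamber-specific
and not published. The deviation convention is
`100·(D_ref − D_meas)/D_ref` (positive = measurement low). Recombination
from the two-voltage method, humidity and perturbation factors are out of
scope; the "effective point of measurement" is a label, not a positional
correction.

## Scenario runner and problem sizes

`run_scenario` executes generate → sample → gate → deliver → analyze from
one config; every stochastic stage draws an independent sub-seed from the
master seed (`numpy` `SeedSequence`), so runs are bit-reproducible. The
default scenario uses a 120 s trace (long enough for a gated 9-layer
delivery including learning and dead times), a 40 mm field at 2 mm spot
spacing, 8 rows per layer and a ±60 mm scoring grid. The test suite and
acceptance script use these sizes or smaller (60–80 s traces, 2–4
layers where the full plan adds nothing), which keeps any single
simulation under a few seconds.

## What passing tests do and do not show

The synthetic layer reproduces the *published summary statistics* of the
hardware chain: waveform moments, camera rate, gating geometry, profile
metrics and their tolerances. It does not contain hysteresis (3-D target
trajectories are independently scaled copies of one 1-D signal), baseline
drift, serial correlation of breathing cycles, camera occlusion, spill
structure, depth dose or film-calibration nonlinearity. Passing tests
therefore validate the analysis pipeline and the gating/delivery logic,
not the hardware itself; quantities that depend on unmodelled physics
(e.g. absolute chamber doses against a TPS) are exercised only through
their formalism.
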