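# Methods

## Scope

`apneasim` is a software reconstruction of a mechatronic validation
bench for neonatal-apnea motion sensors. The physical bench moves a
platform to mimic abdominal breathing, disturbs it with a servo-driven
hammer, and records three accelerometers (abdomen, bed, ceiling) plus an
IR proximity sensor. Everything here is the software analogue: commanded
motion, noise, and sensor acquisition are all synthesised, so the
detection rule, the fusion logic, the statistics, and the monitoring
logic can be exercised reproducibly without hardware.

## Motion model

A breath cycle is a symmetric triangle, 0 → A → 0, with peak amplitude
A (µm) and period 60/rate: the stepper runs at constant speed per
half-cycle, which is the simplest motion consistent with a linear-motion
drive. Displacement samples are quantized to the stepper quantum
(default 0.11 µm/step). Apnea events are intervals of frozen motion
scheduled in recording time; breathing phase accumulates only outside
them, so a pause beginning mid-cycle holds the displacement wherever it
was, like a stopped motor. The standard protocol commands 100 breaths at
40 breaths/min (a typical resting neonatal rate, inside the platform's
0–120 band) with three randomly placed 20 s apneas.

Body acceleration is the second derivative of displacement (central
differences), low-pass filtered by a 2nd-order Butterworth applied
forward–backward (zero phase; effective 4th-order magnitude). The filter
stands in for the mechanical compliance of clothing and mattress, whose
only documented property is that it damps sharp transients; 10 Hz is the
default cutoff and is freely configurable. The filtered acceleration is
projected onto the sensor axes by the unit vector (cos θ, 0, sin θ);
θ = 90° is the supine analogue (all motion on z), 45°/135° are the
inclined postures that split energy across two axes. Gravity, when
enabled, adds a static 1 g projection on the same axes — it serves only
to give channels a realistic DC operating point; amplitude metrics
detrend it away.

## Noise model

The hammer is modelled as a marked Poisson process: strikes arrive at
`strike_rate_hz`, each contributing a damped sinusoid
`a·exp(−t/τ)·sin(2πft)` with log-normal peak `a` (median
`amplitude_scale_g`, log-SD `amplitude_sigma`). The ceiling channel sees
the source directly; bed and body channels receive linearly attenuated
copies (gains ≤ 1, so ceiling ≥ bed ≥ body additive). The waveform
family is a modelling choice — an impact exciting a lightly damped
structural mode — because only the source's adjustability (speed,
displacement, energy) is documented, not its spectrum.

Defaults were calibrated once against the reference study's qualitative
outcome and then frozen: strike rate 0.16 Hz, median peak 6.8 mg,
σ = 0.95, ring 45 Hz, decay 0.12 s, couplings 0.55 (bed) and 0.06
(body). With clean body-episode amplitudes of ≈5.8/11.7/19.0 mg at
500/1000/1500 µm, these place the bed-channel amplitude distribution
across the three displacement levels, giving mean unusable fractions of
roughly 17/10/6 % — the same ordering and magnitude as the reference
counts. The per-condition hammer energies of the original bench are
unknown, so exact counts are explicitly not a reproduction target; only
the zero-noise limit (100 % detection) and the monotone displacement
trend are asserted.

## Sensors

The accelerometer chain is a uniform mid-tread quantizer: code =
round(a/LSB) + 2^(bits−1), clipped to [0, 2^bits − 1], with LSB =
2·range/2^bits. For the default 12-bit ±3 g chain the sensitivity is
682 LSB/g and the scale factor 1.46 mg/LSB; both figures are truncated,
not rounded, matching how datasheets print them (e.g. the 10-bit ±2 g
part gives 256 LSB/g and 3.9 mg/LSB). Decoding is exact to within half
an LSB (≈0.73 mg) away from the rails.

The IR proximity sensor uses the classic inverse-distance approximation
V = k/(d + d₀) with k = 12 V·cm and d₀ = 0.42 cm — representative of
short-range analogue IR rangers, not fitted to a specific unit — plus
additive Gaussian noise (default SD 4 mV) and a 4 cm standoff. The
sampling default is 4 kHz for six channels (1 kHz or 500 Hz are used in
tests and the acceptance study; all rates are far above the 10 Hz motion
band, so episode amplitudes are rate-insensitive).

## Detection and IR fusion

Episodes are one commanded breath cycle each, cut from the truth
timeline; apnea intervals are flagged windows, scored by the monitor,
never tallied as breaths. The episode metric is the peak-to-peak value
after linear detrending — for the body signal, the maximum over the
three axes, which is what makes the inclined postures easier. An episode
is **unusable** when the bed-channel amplitude is ≥ the body amplitude
(ties unusable: when in doubt, distrust the data). The bed channel is
the comparator because it is the noise sensor physically adjacent to the
body sensor; the ceiling channel is kept for diagnostics.

IR rescue re-examines unusable episodes only: the IR window is smoothed
(50 ms moving average), linearized around its mean operating point
(slope (d+d₀)²/k), and reduced to a detrended peak-to-peak displacement
estimate. If that estimate reaches 50 % of the commanded displacement
the episode is reclassified as detected. Both the fraction and the
smoothing are configurable. Note a generator limitation: the simulated
IR channel is mechanically decoupled from the hammer, so under default
noise the rescue succeeds almost always and with-IR unusable counts sit
near zero — the real bench retains a few, presumably through
vibration paths this model does not include. Passing tests therefore
demonstrate the direction of the IR effect, not its exact size on real
hardware.

## Statistics

Per condition, the error odds are 100·unusable/detected (undefined if
nothing was detected). Displacement-level summaries are the mean ±
sample SD (n−1) over the three angles; the overall summary is the mean ±
sample SD of the three level means — computed from unrounded level
means, with rounding (half-up, 2 dp) applied only at reporting. The
pooled 2×2 table sums counts over the nine conditions per mode; the
association test is Pearson's χ² without continuity correction (the
closed form n(ad−bc)²/(r₁r₂c₁c₂), 1 df), and the effect size is the
odds ratio (b/a)/(d/c) of an unusable outcome without IR versus with.
No confidence interval is attached to the odds ratio and no
multiple-testing correction is applied (a single test). p-values below
0.001 are reported as a bound. All of these choices are verified
in-suite: the χ² closed form is property-tested against the
Σ(O−E)²/E definition and cross-checked against an independent library
implementation, and every aggregate of the packaged reference grid is an
exact 2-dp function of its counts.

## Monitoring state machine

Frames (default 0.25 s; all thresholds are in seconds and independent of
frame length) carry detrended peak-to-peak summaries g_body and g_bed in
g, using the same metric as detection. A frame is *clear* when
g_body > g_bed and a *breath* when additionally g_body ≥ g_th. The timer
T accumulates whenever no breath is confirmed; unclear frames never
reset it. Contracts:

* T entering [10, 20) s emits exactly one apnea alert per pause and
  requests the caregiver survey.
* A confirmed breath always resets T and the pause. (The narrative
  description of the flow resets T only below 10 s, but that would force
  a 15 s pause followed by resumed breathing into rescue at 20 s; the
  implemented semantics keeps the single-alert behaviour and is the
  safety-consistent reading.)
* T ≥ 20 s escalates to rescue even while a survey is pending — a 20 s
  motionless pause is the defining apnea condition — and > 20 s of
  continuously unclear signal does the same. The rescue trigger records
  which of the two it was, judged by the signal state at firing time.
* Rescue is absorbing: only an explicit operator reset resumes
  monitoring. The bed-motion actuator is represented as an emitted
  event.

Survey triage: critical iff both SAT and BPM are strictly below 90
("below" read strictly; configurable thresholds). Missing vitals are not
evaluable and escalate to rescue — the fail-safe default. Risk colors:
red for any rescue trigger or critical survey, yellow for an apnea alert
otherwise, green for routine records. The 8Ws record auto-fills the
computable fields (what = trigger, when = timestamp, where = configured
location, what-to-do = the color legend) and leaves the rest to the
operator.

## Numerical and design notes

* One root seed drives everything; per-condition streams are derived as
  seed + condition index, and the hammer and IR noise generators within
  a recording use independent spawned substreams. Identical seeds give
  bit-identical recordings.
* The detrended peak-to-peak of a sinusoid only approaches twice its
  amplitude as the cycle count per window grows (the linear-regression
  cross term decays as 1/k); tests use many-cycle windows for that
  identity.
* Episode windows are cut by rounding boundary times to sample indices;
  a breath starting exactly at an apnea onset is shifted past the pause,
  one ending there is not.
* The error odds (unusable/detected) are odds, not a proportion of
  episodes; with 100 episodes per condition the two differ in the
  denominator (detected, not total).
* Problem sizes: the default protocol is 100 breaths/condition at 4 kHz;
  the test suite and the acceptance study use 500 Hz–1 kHz and 20–100
  breaths, chosen so the whole suite runs in seconds while remaining far
  above the motion band.

## Known limitations

The generator omits: mechanical coupling of the hammer into the IR
path (see above), sensor drift and temperature effects (metadata
placeholders only), breath-to-breath variability of rate and amplitude
(cycles are identical by design — this matches a commanded platform, not
a newborn), and obstructive apnea (motion present without airflow),
which motion sensing alone cannot represent. Statistical reproduction is
exact for the packaged reference grid; simulated error rates reproduce
trends, not the reference's exact counts.
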