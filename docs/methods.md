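# Methods

## Measurement model

A smartphone accelerometer rides on the striking limb (distal wrist for
punches, distal calf for kicks). The recording starts with ~5 s of
stationary guard position — a noise-only baseline — followed by a
series of maximal strikes at a heavy bag, each separated by ≥10 s of
rest. The analysis makes three assumptions:

1. **Orientation-free norm.** Strikes are fast, roughly linear limb
   movements, so the Euclidean norm A = √(Ax²+Ay²+Az²) of the local
   acceleration captures the movement without pose estimation or sensor
   fusion. The resulting velocity is expressed in the sensor's local
   frame, not a global frame.
2. **Impact at peak norm.** The largest norm sample of a strike
   (A_peak) is the instant of bag contact: the impact deceleration
   dominates everything the limb does beforehand.
3. **Stationary onset.** Scanning backwards from A_peak, the first
   sample strictly below a noise threshold (A_initial) is the strike
   onset, and the limb's velocity there is zero. Integrating the norm
   over [A_initial, A_peak] with the trapezoidal rule (on actual
   per-interval Δt; no resampling) therefore yields the impact
   velocity. Because the integrand is non-negative, the velocity
   profile is monotone and the impact velocity is also the segment's
   maximum — unlike component-wise integration, where cancellation can
   occur. Nothing after the peak is integrated.

## Pipeline parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `threshold.value` | 2.0 | m/s² | separates strike onset from stationary-guard sensor noise on a gravity-free export |
| `threshold.k` (adaptive) | 3.0 | — | mean + 3 SD of the baseline norm when a per-recording threshold is wanted |
| `baseline_seconds` | 5.0 | s | length of the recorded noise window |
| `n_strikes` | 5 | — | strikes per test series (fatigue vs sample-size compromise) |
| `min_separation_s` | 1.0 | s | peak masking radius; conservative given ≥10 s rest between strikes |
| `max_lookback_s` | 0.6 | s | bound on the backward onset scan; a strike fits well inside a 600 ms window around its peak |
| `validity.min_samples` | 3 | — | a 2-sample segment cannot support a meaningful trapezoid |
| `validity.min/max_duration_s` | 0.04 / 0.6 | s | plausible strike durations; outside this, execution or sensor errors are assumed |

All validity bounds are config-overridable; they operationalize the
otherwise unspecified notion of an "abnormal" repetition. Multi-strike
files are handled by iterative max-and-mask peak picking: repeatedly
take the global maximum of the unmasked post-baseline region, mask
±`min_separation_s` around it, stop when `n_strikes` peaks are found or
nothing exceeds the threshold. Partial detection logs a warning and
proceeds; it never raises.

**Gravity guard.** A 2 m/s² threshold is meaningful only for
gravity-free linear acceleration. If the median baseline norm lies in
[8.5, 11] m/s² the trace almost certainly includes gravity; the package
warns prominently and only subtracts the median baseline norm (floored
at 0) when `subtract_gravity` is explicitly set. Data are never altered
silently.

## Reliability statistics

All statistics operate on a complete-case subjects × sessions matrix
(subjects missing a session are dropped with a logged count; fewer than
3 completers is an error).

* **CV%** = 100·SD/M with the sample SD (n−1). Within-day CVs use the
  valid strikes of one session; between-day CVs use each subject's two
  session values, summarized as min/mean/max across subjects.
* **Two-way ANOVA.** One subjects × sessions decomposition (no
  replication) supplies MS_subjects, MS_sessions, MS_error. ICC and SEM
  both use this decomposition, so they are mutually consistent.
* **ICC(3,1)** = (MS_B − MS_E)/(MS_B + (k−1)·MS_E): two-way mixed,
  single-measure, consistency form — session main effects cancel, so a
  constant learning/fatigue offset between sessions does not lower it.
  The 95% CI uses F = MS_B/MS_E on (n−1, (n−1)(k−1)) df:
  FL = F/F₀.₉₇₅(df1,df2), FU = F·F₀.₉₇₅(df2,df1), mapped through
  (F* − 1)/(F* + k − 1). Verified in the tests against a brute-force
  loop-computed ANOVA and against pingouin's ICC(C,1).
* **SEM** = √MS_error, **SEM%** = 100·SEM/grand mean.
* **Bland–Altman**: differences d = session2 − session1; MD = mean(d);
  LOA = MD ± 1.96·SD(d), hence LOA_upper + LOA_lower = 2·MD identically.
* **Paired t**: scipy's paired test (df = n−1, two-sided), with
  zero-variance differences handled explicitly (t = 0, p = 1 when
  MD = 0; ±∞, p = 0 for a constant non-zero shift).

The sign convention (session2 − session1) affects only the signs of MD
and t, never magnitudes, LOA width, ICC or SEM.

## Synthetic data

**Trace generator.** Each strike is a half-sine pulse
a(t) = A·sin(π(t−t₀)/T) projected on a per-strike unit direction, with
i.i.d. Gaussian noise per axis. The half-sine was chosen because it has
a closed-form velocity: A·T/π from onset to the pulse's own peak at
t₀ + T/2 (the quantity the pipeline estimates) and 2·A·T/π over the
full pulse (reported for sampling-rate studies). Defaults state the
emulated protocol: 5 s baseline, 5 strikes 10 s apart, 50 Hz sampling;
A = 80 m/s² and T = 0.1 s give jab-scale velocities (~2.5 m/s onset to
peak), and 0.3 m/s² per-axis noise keeps the baseline norm comfortably
below the 2 m/s² threshold.

Strike onsets are snapped to the sampling grid. This removes onset
phase as a confounder when measuring integration accuracy versus
sampling rate, at the cost of making pulse-edge samples land exactly on
zeros of the pulse — detection studies at marginal rates are therefore
conservative (a pulse of width T is missed once fs ≤ 1/T). The
generator does not model drift or bias (segments are short), sensor
saturation, asymmetric rise/fall of real strikes, or bag/limb rebound;
green pipeline tests establish correctness of segmentation and
integration on the stated pulse model, not biomechanical realism.

**Cohort generator.** Session scores x_is = μ_i + δ_is with
μ_i ~ N(μ_pop, σ_b) and δ_is ~ N(0, σ_w), so ICC_true =
σ_b²/(σ_b²+σ_w²) and E[MS_error] = σ_w². Defaults (38 subjects,
μ_pop = 6.11 m/s, σ_b = 1.06 m/s) emulate a jab-average cohort;
σ_w = 0.5 m/s puts the SEM at the ~0.5 m/s scale such systems exhibit.
The model has no session main effect, learning trend, or
heteroscedasticity.

## Numerical choices

* Trapezoidal cumulative integration via scipy; exact for integrands
  piecewise linear on the sample grid.
* Onset comparison is *strictly below* the threshold; a tie at exactly
  the threshold does not end the backward scan.
* Duration validity bounds carry a 1e-6 relative epsilon so that
  floating-point timestamp differences cannot flip a boundary decision
  (e.g. a nominal 0.04 s segment evaluating to 0.039999…).
* The residual sum of squares is floored at 0 before division to guard
  against negative rounding residue when sessions are identical.
* Indices are 0-based; segments include both endpoints. Velocities are
  rounded to 2 decimals only in output files; aggregation happens at
  full precision. Report CSVs are written at full precision and
  round-trip to 1e-9.
* All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical traces and cohorts.

## Known limitations

* Velocity is in the sensor's local frame; no drift correction is
  applied (segments are ≤0.6 s, so drift is second-order).
* The peak-norm impact criterion fails for movements whose largest
  acceleration is not the impact (e.g. heavy wind-up with no contact).
* At 50 Hz the trapezoid underestimates a 0.1 s half-sine by ~3%; the
  error falls monotonically with sampling rate (measured in the tests).
* Detection of very short impacts is sampling-limited: a pulse of width
  w needs at least ⌈1/w⌉ Hz for a guaranteed in-pulse sample (67 Hz for
  15 ms), and 2× that by the Nyquist criterion for reconstruction —
  and even an in-pulse sample may fall below the threshold near the
  pulse edges.
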