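# Methods

## The recording model

A session is modeled as an interleaved stream of frames alternating between
an isosbestic channel (Ca²⁺-insensitive; bleach and motion only) and a
Ca²⁺-dependent channel, at a combined 60 frames/s (30/s per channel). The
interleaving order is fixed as (isosbestic, calcium) and recorded explicitly
in the frame table, so no reader ever has to infer it.

The synthetic generator composes, per channel:

* **Photobleaching** — a single exponential with constant offset,
  *b₀ e^(−t/τ) + b₁*, the same parameters for both channels evaluated at
  each channel's own sample times. A single term keeps the nonlinear fit
  identifiable at the data sizes used here; real rigs sometimes need a
  double exponential, which this generator deliberately does not emulate.
* **Transients** (Ca²⁺ channel only) — kernels
  *A (1 − e^(−t/τᵣ)) e^(−t/τ_d)* with analytic peak at
  *τᵣ ln(1 + τ_d/τᵣ)*, modeling shock- or bout-locked responses.
* **Steps** (Ca²⁺ channel only) — rectangular sustained changes. A dunk
  trial (rapid rise, sustained through a 30-s swim, return at platform
  raise) is a positive step; feeding-type suppression is a negative step
  persisting to the session end. The biexponential kernel cannot hold a
  30-s plateau, which is why sustained events are modeled as steps.
* **Motion artifacts** — brief biexponential deflections (rise 0.02 s,
  decay 0.2 s) at Poisson times, amplitudes drawn Normal(0, σ_art). Motion
  is slow relative to the 16.7 ms between the two frames of an interleaved
  pair, so each artifact sample is evaluated once per pair and added to both
  frames — the calcium channel receives it with gain 1, the isosbestic with
  gain *g* (`artifact_channel_gain`). This makes the two channels exactly
  proportional at artifact samples, an invariant the tests exploit.
* **Sensor noise** — independent Gaussian noise per channel per frame.

Defaults (bleach 30 units, τ = 600 s over an offset of 50; artifacts at
0.1 Hz with σ = 5; noise σ = 2 per channel; gain 0.5) describe a plausible
rig at session lengths of 10–20 minutes. The generator does not model
photon statistics, hemodynamics, wavelength-dependent bleaching, or
multi-site recording; passing tests show the *analysis chain* is correct
and calibrated under these assumptions, not that any particular biological
effect exists.

All randomness flows through one `numpy` generator seeded per call;
identical seeds give bit-identical frame tables.

## The signal chain

Order: deinterleave → smooth → detrend → standardize → scale → subtract.

* **Smoothing** — centered moving average, default 9 samples (~0.3 s at
  30/s; the width is a convention, chosen to suppress frame noise without
  blunting second-scale transients). Edges use shrinking (truncated)
  windows so no samples are invented. Whether standardization should
  precede smoothing is genuinely open; the chain is
  smooth-first by default and config-overridable (`smooth_first`).
* **Baseline detrend** — nonlinear least squares on *b₀ e^(−t/τ) + b₁*
  (scipy `curve_fit`, analytic Jacobian, log-linear-style initialization
  from head/tail means, τ bounded positive). A constant series is treated
  as the degenerate b₀ = 0 case. The fit reports R².
* **Fallback rule** — if the optimizer fails or either channel's R² falls
  below 0.5, the chain switches to `reference_z` mode: both channels are
  z-scored against the mean/SD of a baseline reference window only
  (default: the first quarter of the recording) and no dF/F is formed.
  This mirrors how sessions with a sustained step drop must be analyzed —
  the step's nature and duration preclude an exponential baseline. The R²
  gate is crude: a strongly bleaching session with a late sustained step
  can evade it (the exponential chases the step), and a short, nearly
  bleach-free session can trigger it even though nothing is wrong. Callers
  can always force a mode and disable the fallback.
* **Standardization** — population (n) SD convention throughout, over the
  full series in baseline mode or over the reference window in reference
  mode. Zero variance raises rather than returning NaNs.
* **Isosbestic scaling** — Huber-loss linear regression (tuning constant
  1.345, MAD scale) of ca_z on iso_z, implemented as an IRLS with a
  closed-form two-parameter weighted solve (each iteration is O(n); the
  tests pin agreement with statsmodels RLM to 1e−6). If the unconstrained
  slope is negative it is clamped to zero and the intercept refit as the
  Huber location of ca_z; the two procedures agree whenever the constraint
  is inactive.
* **dF/F** — `ca_z − iso_fitted`: subtraction in standardized space, i.e.
  the Ca²⁺ channel minus the scaled isosbestic prediction of shared
  bleach/motion structure. A division form is available
  (`dff_method="divide"`) but off by default, since in standardized space
  the denominator can pass near zero.

## Amplitude conventions

Standardizing over the full trace makes the z-value of a sustained event
depend on the event's own duty cycle: a 30-s plateau recurring every 120 s
mathematically cannot exceed (1−p)/√(p(1−p)) ≈ 1.7 full-trace SDs
regardless of its physical size. Event amplitudes are therefore expressed
in units of the *smoothed baseline SD* — the variability of the event-free
corrected trace — which is how a rise is naturally read off a standardized
trace against its baseline. The generator computes this analytically:
noise contributes σ_noise/√w through a w-sample moving average, and
artifact shot noise contributes via Campbell's theorem (rate · σ_art² ·
∫k_smoothed²). `dunk_protocol(amplitude_z=5)` injects a raw step of
5 × that SD; the acceptance test then checks both that the pipeline's
peri-event rise, mapped back through the stored standardization SD,
recovers the raw step within 15%, and that the rise measured against the
pooled pre-event baseline SD recovers 5 within 15%.

## Statistics

* **Windowed CI test** — per-trial means over a pre-window (default the
  10 s ending at onset) and a post-window (the event duration, else 10 s),
  paired differences, and two-sided t intervals at 95/99/99.9%. Intervals
  nest by construction, so significance is monotone in level; the 95%
  decision coincides with a paired t-test at α = 0.05. The replication
  unit is the trial within a recording (use per-subject window means
  across recordings to make subjects the unit). Direction is read from the
  mean trace, not the test. Under a matched null (no events injected,
  everything else identical) the measured rejection rate at the 95% level
  is 5.05% over 2,000 simulated sessions.
* **Rank-sum helper** — Wilcoxon rank-sum (Mann-Whitney) on window means:
  exact null distribution for n ≤ 10 per group without ties, tie-corrected
  normal approximation otherwise, no continuity correction (so identical
  samples give p = 1). All-tied input raises with guidance instead of
  fabricating a p-value.
* **Random-epoch control** — epochs centered at uniformly sampled times
  whose windows avoid both the recording edges and any excluded event
  spans, deterministic under a seed.

## Operant scoring

The schedule logic replays an event log: during stimulation an active-port
poke earns a 10-s pause (FR1) or advances the progressive-ratio counter;
pokes during a pause are inert for the schedule but still counted, since
total port activations are themselves an outcome; the inactive port never
affects state. Progressive-ratio requirements round half away from zero —
no index in the behaviorally relevant range lands on .5, so the rule is
fixed purely for determinism. A reward requires its full pause to fit
before the session end: stimulation terminates at the session close, so a
pause that cannot fit earns nothing. This keeps rewards ≤
floor(session/pause) for every possible event stream (the alternative —
crediting truncated pauses — breaks that bound for session lengths that are
not multiples of the pause length).

## Behavior scoring

Category sets are data, not constants: the swim assay uses four categories
with the 4/3/2/1 active-to-passive encoding; the photostimulation assay
uses nine. Ethogram bins (default 10 s) take the predominant (modal)
category; ties are broken by earliest onset within the bin (a human
scorer's natural rule; a lexicographic rule is available for strict
reproducibility across label renamings). Treading and digging are merged
into a single bedding-movement category at scoring time, conservatively,
since the two are hard to separate and jointly constitute defensive
burying. Transition events require the new bout to last ≥ 0.5 s by
default, suppressing classifier flicker. Per-period category durations sum
exactly to the period length whenever period boundaries align with frames.

## Numerical and size choices

Tolerances: baseline-fit recovery on noise-free input is tested at 1e−6
relative; `reference_z` with a full-length window matches plain
standardization to 1e−9; cross-correlation at lag 0 matches a plain
Pearson r to 1e−12. The calibration and oracle tests use 2,000 simulated
sessions, 1,000 random tracks per oracle comparison, and 10,000 draws for
the type-I check — sizes chosen so Monte-Carlo error is a fraction of each
acceptance band while the whole suite stays in the minutes range.

## Known limitations

* The artifact and noise parameters are conventions, not estimates from
  any real rig; the generator's realism claims end there.
* The R² fallback gate is a blunt instrument (see above).
* Division-based dF/F in raw-fluorescence space is not implemented; the
  division option operates on the standardized/scaled traces.
* Cross-correlation treats autocorrelated series naively: the null band
  3/√n assumes white noise, and lag-resolved inference should use a
  block or phase-randomized null if it matters.
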