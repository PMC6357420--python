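# Methods

This note records the model, the numerical choices, and what the synthetic
data do and do not establish. It documents decisions; every empirical number
cited here is computed by the test suite or `scripts/acceptance.py`, not
asserted independently.

## Signal model and processing chain

Raw surface EMG is converted to a linear envelope by: 4th-order Butterworth
high-pass at 20 Hz, demean, full-wave rectification, 4th-order Butterworth
low-pass at 25 Hz. "Zero lag" is realized as forward–backward filtering
(`scipy.signal.sosfiltfilt`) with reflected-signal padding, so the envelope
carries no group delay; the zero-phase property is asserted in tests (a
synthetic burst's envelope peak stays within ±2 samples of the burst center).
The demean step is retained after the high-pass even though the high-pass
already removes DC — the processing order is part of the contract, and the
step is numerically harmless. Negative excursions left by low-pass ringing
are clipped to zero so integrated amplitudes are nonnegative.

Amplitude normalization divides each channel by the mean over strides of the
per-stride envelope maximum ("averaged peak activation across steps"). Peaks
are taken per stride and averaged — not one global maximum — so a single
spiking stride does not set the scale. MVC normalization is deliberately not
offered: populations with impaired voluntary drive cannot produce reliable
maximal contractions. A channel whose averaged stride peak is ~0 is reported
as degenerate rather than silently normalized.

## Gait events and the six regions

Heel strike / toe off are threshold crossings of each belt's vertical GRF
(default 20 N, a common force-plate convention; configurable) sustained for
at least 50 ms, with sub-sample linear interpolation of the crossing time.
Shorter contact/flight runs are treated as bounce noise and merged; partial
edge contacts are dropped so each leg's sequence starts with a heel strike.

Each stride is tiled by six half-open regions: DS1 = [ipsilateral HS,
contralateral TO); SS1/SS2 = single support split at its temporal midpoint;
DS2 = [contralateral HS, ipsilateral TO); SW1/SW2 = swing split at its
temporal midpoint. "First and second halves" are read as equal *time* halves
(the natural reading; no kinematic mid-swing event is available from GRF).
Because the partition is event-anchored, it tiles every stride exactly no
matter how asymmetric the timing — the property that makes scores comparable
across asymmetric gaits — and the tiling is asserted property-style over
arbitrary event configurations.

All internal time is seconds, never sample indices; a sample covers the
half-open interval [t, t+dt). EMG and GRF may therefore be sampled at
different rates with no resampling, and a trial analyzed at 500 vs 1000 Hz
yields timing components differing by well under 1 percentage point (tested).

## On/off detection

Every envelope sample of a muscle (whole trial pooled, matching the plain
reading of "each point of the linear envelope of each muscle") is assigned
to one of k = 5 amplitude clusters; the lowest-mean cluster is "off", all
others "on". Five clusters let a raised baseline occupy the bottom cluster
while bursts of unequal height fill the rest.

In one dimension the k-means optimum is a contiguous partition of the sorted
values, so we solve it **exactly** with a monotone divide-and-conquer dynamic
program (O(k n log n)). This removes initialization and seed dependence
entirely: identical input gives an identical mask, and reruns are bit-exact.
The DP is verified against full enumeration of contiguous partitions at tiny
n and against a plain O(k n²) exhaustive-split dynamic program at n = 200;
a fixed-seed Lloyd solver (scikit-learn) is kept as a cross-check and is
never better than the exact solution. Ties between equal cluster means break
toward the lowest index. No minimum-burst-duration or gap-filling
post-processing is applied by default (none is part of the method); both are
available as explicit options.

Known behavior worth stating: if a channel's value distribution is a set of
extremely tight groups, forcing five clusters will split a group, and the
upper part of a split baseline counts as "on". Real envelopes (and the
generator's signal-proportional noise) do not occupy that regime.

## Components, profiles, scores

Components are computed per stride and then averaged (the stride count is
recorded); per stride, timing is the on-time share of each region and
amplitude the share of the cycle's integrated on-envelope falling in each
region, so amplitude rows sum to 100 whenever the muscle is on at all. A
stride with zero on-time for a muscle contributes zero amplitude everywhere
and triggers a structured warning; averaging then effectively weights the
active strides.

Normative profiles store cell-wise mean and SD (n−1 denominator; the data
are a sample of the healthy population) per speed band. Both legs of a
healthy subject enter as separate observations — an acknowledged
independence approximation that follows how such cohorts are used in
practice. A zero-SD cell rejects the profile by name rather than producing
infinite scores.

Scoring is the plain z-score per cell; negative means reduced timing or
amplitude relative to normal. The default window half-width 2.57 is a
configuration value, not a branch; the narrower 2.05 window is the same
parameter set differently. Note the exact two-sided normal critical values
are 2.5758 (99%) and 2.0537 (96%); the conventional two-decimal figures 2.57
and 2.05 correspond to central coverages of 98.98% and 96.0%, and the
two-sided tail mass outside ±2.57 is 1.017%. Per-muscle totals are the mean
of the six *absolute* region scores (without the absolute value the total
would reward compensating deviations).

Healthy self-assessment scores cohort members against the leave-in profile
by default (leave-one-out is a flag); with a leave-in profile of n
observations, |z| is mathematically bounded by (n−1)/√n, which the tests
assert. Speed-band assignment uses strict outer strata: < 0.4 m/s → 0.3
band, 0.4–0.8 m/s inclusive → 0.6 band, > 0.8 m/s → 0.9 band.

Cohort summaries count a subject as altered for a muscle/component when any
of its six region scores leaves the window; cell-level summaries count
cells. Correlations of per-subject totals with covariates (paretic
propulsion, walking speed) are Pearson r with the two-sided p from the t
distribution on n−2 df.

## Synthetic data: what it emulates and what it does not

The generator produces periodic gait: per-leg stance fractions, a
contralateral phase lag, per-muscle activation bursts in gait-phase
coordinates, a double-bump vertical GRF (`sin(πu) + 0.3 sin(3πu)` over
stance), and a braking/propulsion anterior GRF (`−b sin(2πu)` then
`−p sin(2πu)`), giving a closed-form positive anterior impulse of
`p·stance_s/π` per stride. Bursts are plateaus with raised-cosine ramps; the
true on/off support is the half-amplitude support, an analytic property of
the shape, so ground truth never depends on the detector. Envelope noise is
truncated-Gaussian and **signal-proportional** (SD = `noise_sd` × the local
noiseless envelope): EMG envelope variability scales with activation level,
and a real envelope's baseline is tight because everything has passed the
same 25 Hz smoothing. Ground-truth components are closed-form integrals of
the burst shapes over the analytic region boundaries, verified against
numerical quadrature.

Preset placements follow textbook phasing (plantarflexors through single
support into DS2, TA through swing into loading, quadriceps at loading
response, hamstrings in terminal swing, GM in early stance); the hemiparetic
preset encodes early plantarflexor activity in DS1 wrapping into terminal
swing with reduced SS2 activity, TA co-activation in DS2 with an
early-terminating swing burst, GM shifted into DS2/swing, asymmetric stance
fractions, and a push-off scaled to 0.4, i.e. an analytic paretic propulsion
of 27.3%. These are package constants documented as presets, not cohort
estimates.

Cohorts draw per-subject parameters around a base model (burst centers ±2
percentage points, amplitudes ×(1 ± 0.15), stride duration ±5%, stance
fraction ±0.015 by default). Per-subject noise seeds are a deterministic
hash of the master seed and the subject's parameters, so identical
parameters give bit-identical trials and any parameter spread gives
independent noise. A separate component-space sampler draws timing and
amplitude cells directly from Gaussian normative cells (timing SD 6 pp,
amplitude SD 3 pp around the healthy preset's analytic components, clipped
to their domains with amplitude rows renormalized to 100); it is the basis
for normative-profile tests and for the healthy self-consistency figure.

What passing these tests shows: the pipeline recovers known burst timing,
amplitude shares, events and impulses from clean periodic gait with
realistic envelope noise, and the scoring machinery is calibrated. What it
does not show: performance on real EMG with motion artifact, ECG
contamination, electrode lift-off, non-periodic gait, turning, or crosstalk
between belts — none of which the generator emulates.

## Problem sizes and numerical choices

End-to-end tests and examples run 12–20 s trials at 500–1000 Hz with 1 s
strides (≈10–18 analyzable strides); the exact k-means is the dominant cost
and handles a full 40 s × 2000 Hz channel in ~2 s. Healthy normative cohorts
use 20 subjects × both legs = 40 observations, matching the scale such
control cohorts typically have. Event detection defaults: 20 N threshold,
50 ms debounce. Timing components are clipped at 100 against sample-quantization
overshoot; amplitude rows are renormalized to remove accumulated float dust
(the per-stride construction makes them sum to 100 analytically). Degenerate
inputs (flat channels, constant envelopes, missing contralateral events,
zero propulsion on both legs, zero-variance covariates) raise typed errors
rather than propagating NaNs; strides with unusable event patterns are
skipped with a logged warning rather than failing the trial.

## Known limitations

Amplitude scores are shares of the cycle's integrated on-envelope, so they
are coupled to total on-time: a muscle that is on longer dilutes each
region's share. Interpret amplitude scores together with timing scores.
The normalization is relative to walking itself (averaged stride peak), so
the method cannot distinguish an appropriately active muscle from a globally
under- or over-active one. Region definitions need bilateral force data;
overground walking without instrumented force measurement is out of scope,
as are kinematic event detection and belt-crosstalk handling.
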