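# Methods

This note documents the models, conventions and numerical choices behind
`wakeosc`, in enough detail to reproduce or audit any stage.

## Preprocessing cascade

Raw multichannel EEG (µV, ≥500 Hz) passes, in order: per-channel mean
removal; 40 Hz FIR low-pass; zero-phase 2-Hz-wide notches at the line
frequency and every harmonic below Nyquist; resampling to 250 Hz; and a
zero-phase Kaiser-design FIR high-pass with 0.5 Hz passband edge, 0.25 Hz
stopband edge, 60 dB stopband attenuation and 0.05 passband ripple.

Artifact detection runs on an internal 1–40 Hz copy, on a non-overlapping
3-s segment grid (half-open `[3k, 3k+3)` s windows; a trailing partial
window is dropped). A (channel, segment) cell is **major** when any sample
exceeds 500 µV, otherwise **minor** when the cell's best Pearson
correlation with its 6 nearest channels (3-D electrode distance) is below
0.3; undefined correlations (flat channels) count as minor. Choices the
upstream description leaves open, fixed here:

- *Neighborhood*: k-nearest by electrode distance, k = 6 — standard
  practice for high-density nets and directly testable.
- *Major resolution*: each major cell is cleared by dropping whichever of
  its whole channel or whole segment discards fewer clean cells; ties
  prefer the segment, preserving topography.
- *Minor thinning*: repeatedly drop the channel or segment with the most
  minor cells (larger count wins, ties to the segment) until every channel
  and every segment has at most 30% minor cells. Fractions use the
  **original** grid as denominator; a shrinking denominator makes the loop
  self-amplifying on moderately dirty data and can cascade to full removal.
  Majors are not counted in the 30%.
- *Second pass*: after the removal plan and average referencing, any
  remaining (channel, 3-s window) above 140 µV is resolved by the same
  least-loss rule. The vendor cleaning routines this emulates are not
  reproduced bit-for-bit; the stated thresholds are.

A recording is excluded (typed `RecordingExcluded` carrying the QC report)
when more than 25 channels were removed or less than 60 s of data remains.
Otherwise the zero-filled reference channel Cz is added, removed channels
**and Cz** are reconstructed by spherical-spline interpolation (a Cz left
at `0 − mean` anticorrelates with its neighbors and would be re-flagged on
a second run; interpolating it makes the cascade idempotent), the montage
is reduced to the 123 analysis channels (the 129-position geodesic net
minus external electrodes E49, E56, E107, E113 and face electrodes E126,
E127), and the average reference is set so each sample's channel mean is 0.

Independent-component screening consumes component time courses or spectra
produced by any standard ICA (the decomposition itself is out of scope): a
component is rejected when labeled muscle/eye/heart, or when the aperiodic
exponent of its 5-Hz-smoothed Welch spectrum fit over 8–30 Hz is below 0.5
— near-flat or rising component spectra mark non-neural sources.

## Cycle-by-cycle burst detection

Signals are narrow-bandpass filtered in six overlapping bands — 4 Hz wide,
2 Hz steps, 2–16 Hz: (2,6), (4,8), (6,10), (8,12), (10,14), (12,16).
Zero-crossings of the narrowband signal bracket half-cycles; the extrema
between crossings are located in the broadband (0.5–40 Hz) signal; a cycle
runs from positive peak to positive peak with one negative peak inside.
Cycle amplitude is the mean of the two positive peaks minus the negative
peak. Parse-level validity guards (they matter only for degenerate inputs
such as exact silence): a peak must be a genuine local extremum (plateaus
longer than 2 equal samples are not peaks), cycles need positive amplitude,
and a cycle's period must lie within an octave of its band
(`[1/(2·f_hi), 2/f_lo]`) — spans violating this arise from filter ringing
in signal-free stretches, not from oscillations the band can represent.

Seven scores per cycle, all in [0, 1]; consistency scores compare only
*temporally contiguous* neighbor cycles (a neighbor across a gap is not an
adjacent cycle of the same oscillation; edge cycles use the neighbor they
have):

| score | definition |
|---|---|
| period consistency | worst of min/max ratios of adjacent periods |
| amplitude consistency | same ratio on adjacent peak-to-peak amplitudes |
| flank consistency | min/max ratio of descending vs ascending flank durations |
| shape consistency | 1 − mean abs. difference between the cycle's amplitude-normalized waveform (32-point resample) and the mean of its neighbors' |
| monotonicity in time | fraction of flank samples moving in the flank's direction |
| monotonicity in amplitude | net amplitude change ÷ total absolute change along both flanks |
| reversal ratio | 1 − direction reversals ÷ flank samples |

These are conventional cycle-by-cycle definitions; the published criteria
name the scores without printing formulas, so bit-exact agreement with the
original MATLAB implementation is not claimed — the criteria thresholds
below are reproduced exactly.

A burst is a run of at least MinCycles consecutive (contiguous) cycles
passing every threshold of a criteria set. Three sets apply, their union is
taken, and overlapping same-channel bursts merge (frequency recomputed from
the pooled negative peaks; merging happens after the union):

- **Set 1** (permissive, many criteria): in-band frequency; period 0.5,
  amplitude 0.4, flank 0.5, shape 0.2 consistency; monotonicity in time
  0.4, in amplitude 0.4; reversal ratio 0.6; MinCycles 4.
- **Set 2**: period 0.6, amplitude 0.6, flank 0.6 consistency; monotonicity
  in amplitude 0.6; MinCycles 5.
- **Set 3** (strict monotonicity): in-band frequency; period 0.7, flank 0.3
  consistency; monotonicity in amplitude 0.9; MinCycles 3.

No amplitude threshold appears anywhere, so the detected burst set is
invariant under positive scaling of the signal. Burst frequency is the
inverse mean spacing of negative peaks; only 2–16 Hz bursts are kept, so
the shortest possible burst is 3 cycles at 16 Hz = 187.5 ms. Indices are
0-based, intervals half-open.

Peak-to-peak cycle parsing yields n−1 cycles from an n-cycle sinusoid (the
first positive peak opens the first cycle), so a detected burst's span
understates a planted burst's duration by about one cycle — the round-trip
tests and recovery analyses use sustained planted bursts (≥12 cycles),
where this edge loss stays within their tolerance bands.

## Burst measures and clustering

**Density** = 100 × Σ burst durations ÷ recording duration. Pooled over
channels it can exceed 100%. Pooling across bands sums durations of all
bursts of any analysis frequency (≥4 Hz). **Amplitude** = mean
peak-to-peak difference over all cycles of all bursts (cycle-weighted).

Bursts on different channels link when the temporal overlap is at least
50% of the shorter burst and their frequencies differ by ≤1 Hz; clusters
are connected components of this link graph (transitive closure — the
pairwise rule alone is order-dependent). A cluster's frequency is the
duration-weighted mean of its members'; cluster-level density counts each
cluster's global span once, removing the effect of cross-scalp burst
spread. Channel-level bursts are used for topographies, clusters for
channel-averaged measures.

Analysis bands: theta 4–7 Hz, alpha 8–11 Hz, low beta 12–16 Hz, edges
inclusive, with open 1 Hz gaps (7–8, 11–12) absorbing developmental drift
in peak frequency; bursts under 4 Hz are excluded from analysis (fixed
bands with gaps are used deliberately instead of individual alpha
frequency).

## Spectral parameterization

Welch spectra: 4-s Hanning windows, 50% overlap, 0.25 Hz resolution;
smoothing is a tricube-weighted moving average spanning 2 Hz (5 Hz for
component screening), which leaves flat spectra unchanged. The aperiodic
model is a line in log10-power vs log10-frequency: `offset` is log power
at 1 Hz, `exponent` the x in 1/f^x (positive = descending). Fitting (2–35
Hz, fixed mode, i.e. no knee):

1. robust initial line — ordinary fit, then refit excluding the top 2.5%
   of positive residuals (points sitting on oscillation peaks);
2. iterative Gaussian extraction from the flattened spectrum: take the
   maximum, estimate width from its half-height crossings (FWHM clamped to
   0.5–12 Hz), subtract, repeat while the maximum exceeds 2 SD of the
   current residual (iteration cap 12 — configurable and unreachable for
   realistic spectra, a guard for pathological synthetic input);
3. joint least-squares refinement of all Gaussians on the flattened
   spectrum, then aperiodic refit on the peak-subtracted spectrum;
4. steps 2–3 repeat (up to 4 rounds) because the initial line sits above
   the true aperiodic wherever peaks exist, biasing first-round peak
   heights low;
5. a final bounded polish refits line and Gaussians simultaneously, seeding
   extra Gaussians from any residual structure. On spectra that are
   exactly a power law plus Gaussians this makes recovery exact; on noisy
   spectra the width bounds and peak cap keep it stable. The model's MAE
   never exceeds the plain straight-line fit's.

Fit quality is reported as MAE and R² in log10 space. Band measures over
4–16 Hz: `power` = mean log10 power; `periodic power` = mean of (log10
power − aperiodic model). Channel averages of spectral measures use the 98
non-edge analysis channels; the 25 edge channels are the most inferior (by
z-coordinate) of the 123 — the source description fixes only the count, so
the membership rule is this package's choice.

## Statistics

The central model, fit by maximum likelihood via `statsmodels` MixedLM:

```
Measure ~ Task + Time*Age + Group + Sex + (1|Participant) + (1|Participant:Session)
```

Coding: Time evening=0/morning=1; Group control=0/ADHD=1; Sex
female=0/male=1; Task treatment-coded with oddball as reference; Age in
years, uncentered. Session enters as a variance component nested in
Participant. Reported per fixed effect: β, Wald t, two-sided p on a t
distribution with residual df = rows − fixed parameters (for 1,243 rows
and 9 parameters, df = 1,234). When the random-effects covariance is
singular (variances at zero, e.g. tiny noise-free cohorts) the degenerate
model's OLS estimates are reported rather than dropped. One independent
cross-check test fits the same simulated cohort in R with lme4 and
compares coefficients.

Per-channel models are the same fit per channel with Benjamini–Hochberg
FDR (step-up, q = 0.05) across channels within each term. Overnight
change: measures are averaged within participant × time point (across
sessions and tasks), morning − evening differences are correlated with age
(Pearson), FDR-corrected across measures; participants missing a time
point are excluded, and constant differences yield an explicit undefined
(NaN) correlation rather than a number.

Steiger's Z1* for two dependent correlations sharing one variable:
Fisher-transform r12 and r13; with r̄ = (r12+r13)/2,

```
ψ = r23(1 − 2r̄²) − ½ r̄²(1 − 2r̄² − r23²),   s = ψ / (1 − r̄²)²
Z = (z12 − z13) · sqrt((n − 3) / (2(1 − s)))
```

two-sided p from the normal distribution; inputs failing positive
semidefiniteness of the 3×3 correlation matrix are rejected.

## Synthetic data: what it emulates and what it does not

`generate_aperiodic` synthesizes the 1/f^x background in the frequency
domain: the one-sided PSD is set to `10^offset / f^x` µV²/Hz (clamped
below 0.5 Hz), phases are randomized, and the signal is the inverse FFT —
so the Welch spectrum matches the target law exactly in expectation,
giving analytic ground truth. Channels are unit-norm Gaussian-kernel
(σ = 6 cm) mixtures of independent sources across electrode positions:
neighboring channels correlate like real EEG while every channel's PSD
stays exactly on the target law.

`insert_bursts` superposes sinusoidal bursts (optional waveform asymmetry
via phase warping) with raised-cosine on/off ramps spanning the first and
last **quarter**-cycle: short enough that every peak-to-peak cycle keeps
the planted amplitude (making manifest amplitudes exact), long enough to
avoid onset ringing. Ground-truth densities and amplitudes in the manifest
are computed from the burst specifications, never from the signal.
Artifacts are statistical stand-ins, not physiological waveforms: a >500 µV
3-Hz-carrier spike (inside the detection band), replacement of a channel
segment by independent noise, or zeroing.

`simulate_cohort` emits measure tables directly from the generative twin of
the mixed model (defaults emulate oscillation amplitude: intercept 40 µV,
β_age −0.8 µV/yr, β_time −4 µV, β_age×time 0.14, participant/session/
residual SDs 4/1/2 µV, 100 participants aged 3.5–24.7, two sessions; a
single task coefficient is shared by all non-oddball levels). This is what
the statistics layer is validated on: 100 replicates give ≥95% 2-SE
coverage. `simulate_cohort_recordings` additionally emits small raw-EEG
cohorts (6 participants, 16 channels, 66 s) for end-to-end smoke tests of
plumbing, not power.

What passing these tests does **not** show about real data: synthetic
bursts are near-sinusoidal and well separated, real oscillations overlap,
wax and wane and have non-sinusoidal shape; artifacts here are statistical
caricatures of movement, blink and electrode failures; no volume
conduction or head-model forward projection is simulated; and cohort
tables assume the mixed model is exactly true. Recovery tolerances
(density ±3 percentage points, amplitude ±5%, aperiodic parameters ±0.1)
are therefore lower bounds on real-data uncertainty.

## Problem sizes used in validation

Chosen as the package's standard validation battery: 10 minutes of
synthetic EEG for the burst-duration scan; 90-s, 128-channel recordings
for the preprocessing and artifact checks; 4-minute single-channel signals
for aperiodic recovery at exponents 0.5–2.0; 120-s recordings with
~28 sustained bursts for measure recovery; 100 cohort replicates (n = 100,
2 sessions) for mixed-effects coverage; 5,000 trivariate-normal draws
(n = 100) for Steiger calibration; 300 global-null batteries of 123
p-values for FDR; 20 analytic spectra for the fitter.

## Known limitations

- The burst-score formulas are reconstructions of named criteria;
  thresholds transfer, exact scores may not.
- Burst spans systematically miss ~1 edge cycle per burst (cycle-parsing
  definition); density is correspondingly conservative for short bursts.
- No knee-mode aperiodic fitting; spectra with a bend inside 2–35 Hz will
  bias the exponent.
- ICA decomposition and component classification are consumed, not
  produced; only the spectral-exponent screening rule is implemented.
- The EDF writer is minimal (16-bit, 1-s records, integer sampling rates);
  it round-trips through standard readers but implements no EDF+
  annotations.
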