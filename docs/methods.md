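# Methods

`earoddball` re-implements, as a tested pipeline over synthetic sessions, the
analysis of auditory attention during a workday recorded with around-the-ear
EEG (cEEGrid): oddball paradigm generation, continuous-EEG cleaning, P3
extraction, gyroscope-based movement quantification, and mixed-model
behavioral/ERP statistics.  No recordings of this kind are publicly
available, so the package ships a first-class synthetic-session generator
whose defaults are the published fitted estimates; the pipeline's validity is
established by closed-form checks, planted-artifact oracles, and parameter
recovery.

## Paradigm

Each block presents 160 double tones (700 ms tone, 100 ms gap, 500 ms tone;
1300 ms total): 112 standards (70%) and 48 targets (30%), the first four
always standards, never more than two targets in succession.  Role orders
are drawn by rejection sampling from uniform shuffles, so every admissible
order is equally likely.  Inter-trial intervals (offset to onset) are
uniform on 0.5–0.9 s in the *rapid* variant and 56.2–61.2 s in the
*sporadic* variant, giving the closed-form rates 60·0.3/(1.3+0.7) = 9
targets/min (rapid) and (1.3+58.7)/60/0.3 ≈ 3.3 min/target (sporadic).
Sporadic blocks additionally carry ten unscored rapid-paced familiarization
trials (alternating standard/target) at each end and a one-minute rest
marker after 80 scored trials.  The 160 scored trials are generated in
addition to the familiarization trials, preserving the 112/48 scored
composition.  Double tones are synthesized as fixed harmonic series (all
harmonics 1/k for the oboe-like standard timbre, odd harmonics for the
clarinet-like target) with 5-ms linear ramps and equal RMS across roles;
exact timbre never enters the analysis, only event times and roles do.

## Synthetic sessions

**Behavior.**  Per scored target, a miss is drawn from a binomial-logit
model and, if hit, a reaction time from an inverse-Gaussian model with
inverse link (response-scale mean = 1/linear predictor).  Defaults are the
published link-scale estimates: RT intercept 0.91, condition slope −0.39
(rapid mean 1.10 s, sporadic increase 0.82 s); miss intercept −3.31, slope
1.15 (3.5% rising to 10.4%).  Per-participant random intercepts and slopes
are independent normal draws; the behavioral covariance structure is not
published, so independence — the structure stated for the ERP model — is
the default, with a correlated option in the fitting code.  The
inverse-Gaussian shape defaults to 7, making the RT SD ≈ 0.4·mean (no
dispersion estimate is published; this is a typical RT coefficient of
variation).  Random-effect SDs default to (0.06, 0.05) for RT — the scale
of the published standard errors — and (0.4, 0.3) for the logit model.

**EEG.**  Each stimulus adds a stereotyped response on the vertical bipolar
cEEGrid derivation, mean(R2,R3) − mean(R6,R7): a Gaussian negativity at
150 ms (σ 25 ms, −1 µV) and a P3-like Gaussian positivity (σ 70 ms) peaking
at 312 ms (rapid) or 384 ms (sporadic), scaled so that the mean over the
extraction window (peak ± 100 ms on the 250-Hz grid) equals exactly
1.07 µV for standards and 1.07+1.75 µV for targets (1.63 and 1.63+1.20 µV
sporadic) in the absence of noise.  Channel loadings follow a linear
vertical gradient normalized so the bipolar derivation sees the source at
unit gain; only the bipolar contrast is published, so per-channel
amplitudes are free parameters.  Background noise is 3 µV RMS of 1/f noise
plus 0.5 µV white sensor noise per channel; 70% of the 1/f variance is
shared across channels through four common sources, because ongoing EEG
over a compact ear grid is spatially smooth — with channel-independent
noise the union of per-channel epoch-rejection criteria would reject an
unrealistic ~60% of clean epochs.  Every block opens with a 60-s
artifact-free calibration segment; event onsets are snapped to the sample
grid.  Electrode geometry is idealized (each grid a 240° arc of 15°
angular radius around the ear); no measured cEEGrid coordinates are
published, and both interpolation and the amplitude gradient depend on
positions only through smooth functions of inter-electrode angles.

**Artifacts.**  An artifact plan injects (a) high-variance bursts,
optionally time-locked to high-displacement periods, (b) ≥60-s flatline
segments, (c) drift-heavy (1/f) noisy channels spanning the whole
recording — a high-impedance channel is bad during calibration too — and
(d) sparse ±500 µV transients.  Every insertion is logged, and the tests
use the log as ground truth.

**Gyroscope.**  Three-axis angular-rate traces (deg/s, 250 Hz, shared
clock with the EEG) follow a three-state semi-Markov activity model —
still (σ 0.5), fidgeting (σ 1.5), ambulatory (σ 7.5 per axis) — with
exponential dwell times and state fractions 0.95/0.05/0 in rapid and
0.70/0.15/0.15 in sporadic blocks, plus one contiguous 20-min ambulatory
"lunch" bout per full-length sporadic block.  These fractions were chosen
analytically (chi-distribution tail arithmetic) so that ~95% of rapid and
~75% of sporadic samples fall below the individual movement-free
threshold, the published field result.  The true sampling rate and units
of the original amplifier's gyroscope are not published; units cancel in
all thresholding.

## Cleaning

Fixed order: 10-Hz low-pass (order 330) and 0.1-Hz high-pass (order 8250),
both zero-phase Hamming-windowed sinc FIR (high-pass by spectral inversion
of the unit-DC-gain low-pass, so DC gain is exactly zero); flatline channel
rejection (flat ≥ 60 s, strict); ASR burst correction; ±500 µV amplitude
and 2-SD spectral channel rejection; block discard when at least half the
channels are bad, otherwise spherical interpolation.  Flatlines are
detected on the raw signal: the 8250-tap high-pass smears ~16.5 s of edge
transients into each end of a flat segment and would hide a just-over-60-s
flatline.  The amplitude criterion flags a channel when |x| > 500 µV in
more than 0.1% of samples (the aggregation is not published; the fraction
is configurable).  Spectral rejection z-scores band-averaged log-power
over 1–10 Hz (the data are low-passed at 10 Hz, so wider default bands
would be mostly empty); a degenerate all-equal case yields z = 0.

ASR calibrates on each block's one-minute still segment, high-passed at
0.5 Hz (0.25–0.75 Hz transition band): principal axes of the mean
covariance, per-component sliding-window (0.5 s) RMS thresholds at
mean + 20·SD.  Application eigendecomposes each half-overlapping window
and rebuilds directions whose RMS exceeds the threshold rescaled into the
window's eigenbasis, via the calibration square-root covariance; windows
with no flagged direction pass through bit-identically.  Mean (not
geometric-median) covariance and no spectral weighting are used; channel,
line-noise and window criteria are disabled.  Correctness is asserted by
near-identity on clean data (< 5% RMS change) and ≥ 50% RMS suppression of
planted 20× bursts, not by numerical equality with any particular plugin.
Spherical interpolation is the classical spline on the sphere (stiffness
m = 4, 50 Legendre terms, zero-sum constraint plus constant term, so
constants are reproduced exactly).

## ERP extraction

Epochs span [−0.2, 0.8) s around the first-tone onset (250 samples at
250 Hz; the endpoint convention is not published) and are corrected to the
[−0.2, 0) s baseline mean.  Excluded: familiarization trials, the first
two epochs per block, missed targets (only the missed targets' epochs, not
neighboring standards).  Joint-probability rejection estimates each
channel's value distribution with a 100-bin histogram over the pooled
range of kept epochs, sums log densities per epoch, and rejects — in a
single pass — epochs whose improbability z-score exceeds 2 on any channel
(local) or on the channel mean (global).  The criterion is one-sided on
improbability, the semantics of the standard tool: unusually *typical*
epochs are not artifacts.  The per-trial amplitude is the bipolar mean
within peak ± 100 ms, the peak being the maximum (the P3 is a positivity;
ties break early) of the per-condition grand average within 200–600 ms.
Grand averages weight participants equally regardless of trial counts.

Epoch-rejection percentages are reported but never asserted against the
field study's ~30%: they depend on the real recordings' artifact
structure.  On the synthetic defaults the rate happens to land near 28%.

## Movement

Displacement is the per-sample norm √(yaw²+pitch²+roll²).  The individual
movement-free threshold is median + 4·IQR over the participant's
concatenated rapid blocks (linear-interpolation/type-7 quantiles; the
convention is not published).  Percentile profiles compute percentiles
1–99 per participant and block, then average across participants.  The
categorized time course bins each sample by how many rapid-block SDs it
sits above the rapid-block mean (0, 1, 2, 3+), smooths with a centered
10-s moving median (edge-truncated), resamples to 1 Hz by block averaging,
and grand-averages over the span covered by at least half the
participants.

## Statistics

The three mixed models (RT: inverse-Gaussian/inverse; accuracy:
binomial/logit; P3 amplitude per condition: Gaussian/identity) share one
estimator: Laplace-approximate maximum likelihood with a two-level fixed
factor and by-participant random intercepts and slopes (independent by
default).  The Laplace approximation is exact for the Gaussian LMM and for
the inverse-Gaussian/inverse pair, whose joint log-likelihood is quadratic
in the linear predictor; the inner mode is found by Newton iterations with
step halving, the outer problem by Nelder–Mead over fixed effects,
log-SDs, and the log dispersion parameter.  Wald standard errors come from
the fixed-effect block of the observed information with variance
parameters held at their estimates (the usual mixed-model Wald
convention); single-coefficient tests are (β/SE)² on one χ² df.  Boundary
(singular) variance estimates are flagged, never silently refit.  Model
comparison ranks by log-likelihood, with likelihood-ratio statistics and
χ² p-values for nested pairs (same family and link, fewer parameters) and
a non-nested flag otherwise.  The candidate RT set is {inverse Gaussian,
gamma, Gaussian} × {inverse, log, identity}.  The repeated-measures ANOVA
with generalized eta squared and Bonferroni paired post hocs wraps
pingouin and is verified against hand-computed sums of squares.

## Parameter recovery and problem sizes

Recovery simulations use 8 participants under the study design (three
rapid and two sporadic blocks, 48 targets each).  Behavioral and
model-level ERP recoveries refit the generating model on 100 replicates
and recover every fixed effect within 3 Monte-Carlo SEs.  The
full-pipeline ERP recoveries (simulate EEG → epoch → reject → window →
LMM) use one block per participant per replicate and time-compressed
pacing for the sporadic condition: epoch content is pacing-independent
once epochs cannot overlap, and a 160-minute block adds only runtime.
The full pipeline carries a small (~3–6%) downward bias on the
target−standard contrast because joint-probability rejection at 2 SDs
preferentially truncates large-amplitude target epochs; the estimator
chain is unbiased with rejection disabled.  This is a property of the
procedure, not of the implementation, and on real data it is part of what
the published estimates already reflect.

The analysis drivers use the same compressed pacing for EEG stages and
full-length blocks for the gyroscope stage (movement structure lives on
the real clock).  The Wald test's null rejection rate, measured over 500
null replicates at these sizes, is ≈ 0.05.

## What the synthetic data do not show

The generator makes no attempt at realistic ocular/cardiac artifact
morphology, room acoustics, transport (Bluetooth) effects, real cEEGrid
electrode coordinates, or the day's uncontrolled covariates (soundscape,
task engagement).  Passing tests therefore demonstrate that the pipeline
computes the intended quantities and recovers known generative structure —
not that it would reproduce any particular field recording's rejection
rates or effect sizes, which depend on real artifact structure the
synthetic sessions only caricature.
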