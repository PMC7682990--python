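# Methods

`pfitag` analyzes multi-target perceptual filling-in (PFI) experiments with
frequency-tagged EEG, and ships a synthetic-data generator that produces
behavior and EEG with the statistical structure those analyses assume. This
note documents the models, the estimators, the numerical choices, and what
the synthetic data can and cannot show.

## The experimental structure being modeled

Four peripheral targets flicker at f1 = 15 Hz over a surround texture
flickering at f2 = 20 Hz. Participants hold a button per target while that
target is perceptually filled in (invisible). Each 60 s trial embeds one
catch event (phenomenally matched disappearance, PMD): 1–4 targets are
physically removed for a uniform 3.5–5 s interval starting no earlier than
10 s into the trial. Steady-state visually evoked potentials (SSVEPs) at
f1, f2 and the intermodulation frequency f2 − f1 = 5 Hz, plus the 8–12 Hz
alpha rhythm, are analyzed time-locked to button reports.

## Synthetic behavior

- Filling-in onsets are a Poisson process per target (default 0.05
  events/s/target) with log-normal durations (mean 4 s, SD 1 s). These are
  free parameters of the paradigm — no published numeric distributions
  exist — chosen so that targets are reported invisible ~28% of the time
  ("appearing and disappearing often, for a few seconds at a time") and so
  that successive transitions are typically farther apart than the ±1.75 s
  span of the SNR analysis windows.
- Grouping: with probability `coupling` (default 0.35) each other target
  joins an onset (shared onset, independent duration), producing the
  observed excess of simultaneous disappearances over the independence
  prediction.
- Reports lag true transitions by a Gaussian delay truncated at zero
  (mean 0.7 s, SD 0.2 s — the published mean PMD reaction time is 0.68 s);
  responders report physical removals through the same lag model.
- A filling-in event that would overlap the PMD window at a removed target
  is truncated at PMD onset, so presses inside PMD windows are attributable
  to the removal.
- Between-participant heterogeneity: onset rate and duration mean are
  scaled per participant by log-normal factors (SD 0.4 and 0.3), mirroring
  the large individual differences in the amount of PFI that real cohorts
  show.

## Synthetic EEG

Each channel is a topography-weighted sum of:

- f1 and f2 sinusoids at exactly 15 and 20 Hz (random phase per trial);
- an intermodulation signal produced by half-wave rectification of the
  summed f1 + f2 drives (gain 0.4). A static nonlinearity provably creates
  energy at f2 − f1; no 5 Hz sinusoid is injected;
- a 10 Hz alpha rhythm (amplitude 2, the dominant rhythm as in real EEG);
- a shared 1/f noise source plus independent 1/f sensor noise (exponent 1,
  scale 1.0). The scale is calibrated so moving-window log10-SNR baselines
  sit near 1.5–2 and the SNR neighborhoods are noise-dominated — at lower
  noise the tags' own modulation sidebands dominate the neighborhoods,
  which no spatial filter can improve and which real EEG does not show.

Event-locked modulation is transient: every press adds, and every release
subtracts, a raised-cosine bump (rise 0.3 s, plateau 1.0 s) in a
component's gain, starting `latency` seconds relative to the report.
Default depths and latencies encode the empirical pattern the analyses are
designed to detect: during PFI the surround response rises ~1.22 s and the
target response ~0.43 s before the disappearance report; during PMD the
target response falls (~0.52 s before the report) and the surround rises
late (~0.10 s); alpha is suppressed (20% during PFI, 10% during PMD,
saturating across targets). A sustained model (gain elevated for the whole
invisibility interval) was considered and rejected: it makes
disappearance- and reappearance-aligned epochs differ across the entire
window, contradicting the bounded significance intervals observed
empirically. Per-participant jitter (latency SD 0.15 s, depth SD 20%)
matches the between-participant spread of onset estimates.

Topographies are Gaussian bumps on a deterministic sunflower-spiral
montage (posterior for the visual tags, centro-parietal for alpha); no
real electrode geometry or head-model forward projection is attempted.

## Analysis estimators

**log-SNR.** Slepian-tapered sliding-window power (k tapers, NW =
(k+1)/2; default k = 1, 2.5 s window, 250 ms step), log10 power at the
tag bin minus mean log10 power over flanking neighborhoods ([f±0.5,
f±2.5] Hz moving-window; [f±0.06, f±0.12] Hz whole-trial), always
excluding the half-bandwidth (k+1)/(2T) around the tag. Windows are
zero-padded to 3 s by default so the 5/15/20 Hz tags fall exactly on the
1/3 Hz bin grid: an off-grid tag straddles two 0.4 Hz bins and the
straddled peak bin of an amplitude-modulated tag fluctuates by ±0.3–0.4
log10 units around transitions (verified on noiseless sinusoids). Padding
is configurable (`pad_to=None` disables it); the whole-trial variant is
unpadded since 60 s windows put the tags on-grid. At 250 Hz a 250 ms step
is 62.5 samples; start indices are `round(i·step·fs)` so the mean step is
exact. The nearest bin is used for the tag (ties to the lower bin), and
per-epoch log-SNR is averaged across epochs (not SNR of averaged power).

**RESS.** One spatial filter per tag frequency per participant: largest
generalized eigenvector of (narrowband covariance, broadband covariance),
where the narrowband signal is a frequency-domain Gaussian (FWHM 0.5 Hz on
the amplitude spectrum: gain 0.5 at ±FWHM/2) and the reference is the
unfiltered epochs. Training epochs are [−3, −0.1] and [0.1, 3] s around
every press/release, avoiding PMD periods and pooled without condition
labels. The reference covariance is shrunk by 1% toward its scaled
identity (mean eigenvalue) against ill-conditioning. Weights are
unit-norm with the largest-|w| channel forced positive.

**Alpha.** Gaussian bandpass (center 10 Hz, FWHM 2 Hz) then the
analytic-signal magnitude, per electrode; normalized by each participant's
mean envelope over −2.5..−1.5 s before the press (one baseline per
electrode, pooled over the participant's epochs). The outer 0.25 s of each
epoch is excluded from statistics against edge effects.

**Cluster permutation.** Pointwise paired t (two-tailed, p < 0.05
uncorrected) thresholding; contiguous clusters summarized by summed t;
null = maximum |summed t| per permutation over both polarities, permuting
condition averages within participant (sign flips — vectorized because
the per-point second moment is sign-invariant). Add-one p-values
(r+1)/(n+1); `n_perm="all"` enumerates all 2^N flips and then reports the
exact fraction. The electrode-time variant additionally requires at least
3 spatially adjacent suprathreshold electrodes per point (neighbor-count
reading of the minimum-cluster-size rule) and grows clusters over a
symmetrized k-nearest-neighbor (k = 4) adjacency of the synthetic montage.
Degenerate zero-variance points map to t = ±inf, p = 0 (or t = 0, p = 1
when the mean is also zero).

**Onset latency.** Participants' SNR time courses are linearly
interpolated from the 250 ms grid to 1 ms individually, then running
paired t-tests; the onset is the first point of a contiguous significant
run of ≥ 500 ms (pointwise uncorrected 0.05 — threshold-plus-duration,
not cluster permutation). Leave-one-out jackknifing reports all subsample
onsets, their median, raw SD, and the (N−1)/N-inflated jackknife SE
(published "SD"s are ambiguous between the two, so both are emitted);
undefined subsamples are excluded from the median and their fraction is a
first-class output. Distributions are compared by paired t and Wilcoxon
over matched subsamples, dropping undefined pairs with a reported count.

**Behavioral nulls.** The PMD bootstrap null epochs [S−2, S+4] s of button
data at removed-target locations from a random trial T′ per PMD (T′ = T
allowed), 1000 sets by default; CI = ±1.96 z on logit-transformed set
means (values clipped to [ε, 1−ε], ε = 1/(2·n_events)), back-transformed.
Samples falling outside a trial are dropped from averages. The reaction
time is the first post-onset time where the observed median press course
exceeds the upper CI; participants without one within 2 s (inclusive) are
excluded, and trials with any removed-target button pressed < 50%
(inclusive) of the PMD window are rejected. The location-shuffling null
rebuilds trials per location from random trials (with replacement); the
quadratic coefficient of value vs nPFI (centered OLS polynomial fit — the
quadratic coefficient is shift-invariant) is compared to the shuffled
betas' 95th percentile, with add-one p-values. nPFI = 0 is included in
the fit (5 levels). The amount of PFI is the frame-grid mean of the
pressed-button count over [0, +3] s after presses / [−3, 0] s before
releases; events are sorted by descending amount and linearly resampled
along the event index to 100 rows per participant.

**Mixed model.** Event-level log-SNR ~ amount with a participant random
intercept, ML fit, likelihood-ratio χ²(1) against the no-slope model;
with a single participant the comparison degenerates to the OLS LRT.
Observations are event-level with trial nesting ignored.

## Controlled recovery scenarios (`pfitag.validation`)

Recovery checks run where the injected quantity is well defined:

- *Latency lead*: sparse long events (0.02 /s/target, 8 ± 1 s, no
  coupling), IM/alpha modulation silenced (their rectified 15/20 Hz
  content otherwise shifts both onsets), homogeneous cohort (with
  per-participant latency jitter a single true lead does not exist), ±4 s
  epochs, 8 participants × 10 trials. The onset detector fires early by a
  fixed amount — any 2.5 s window "sees" a transition up to ~1.25 s before
  its center reaches it — but the advance is common to f1 and f2 and
  cancels in the lead difference.
- *Alpha suppression*: sparse isolated events keep the baseline window
  clean; depth measured on the modulation plateau (0.3–1.2 s) of the
  normalized envelope at the alpha-dominant channel.
- *Screening*: one responder and one non-responder at 0.02 /s/target.
  At heavy filling-in rates a non-responder's spontaneous presses are
  genuinely indistinguishable from removal reports (the quantized median
  press course crosses the CI by chance), so separation is tested where
  the procedure has full power.

## Problem sizes

The default pipeline scale is 8 participants × 24 trials; the test suite
and the acceptance script run the end-to-end signature at 16 participants
× 24 × 60 s trials with 16 channels, 200 bootstrap sets and 500
permutations, and the calibration suites at 100–200 simulations with
reduced trial counts. These sizes were chosen so a complete run finishes
in minutes on a single core while every statistic retains enough power
for its check; the full published scale (16 × 48, 64 channels, 1000–2000
permutations) is available through the configuration objects.

## What passing tests do and do not show

The generator produces stationary sinusoidal tags, a single shared 1/f
source, transient raised-cosine gain bumps, and exact report-locked
modulation. Real EEG adds non-stationary broadband artifacts, eye
movements, volume-conduction structure, imperfect time-locking, and
unknown true modulation shapes. Passing recovery tests therefore shows the
estimators are correctly implemented and calibrated under the assumed
statistical structure — not that the pipeline would recover the same
numbers from arbitrary real recordings. Published headline statistics that
depend on the real 16-participant dataset are reproduced only as
qualitative signatures (directions and orderings), not as numeric targets.

## Known limitations

- The IM component's rectified signal also contains f1/f2/harmonic energy,
  so IM modulation leaks weakly into the tag channels (silenced in the
  latency recovery scenario for this reason).
- The spectrogram time grid jitters by ±2 ms around the nominal 250 ms
  step (integer sample starts).
- Bad-channel handling, re-referencing, surface Laplacian, and real-time
  calibration are out of scope; readers for BrainVision/EDF are provided
  but real-data preprocessing is not.
- `statsmodels` MixedLM occasionally reports boundary/convergence warnings
  on null-variance datasets; the LRT is mildly conservative there (null
  χ² mean ≈ 0.88 in calibration).
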