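# Methods

`gonogo-erp` simulates trial-level EEG from a cued go/nogo experiment and
re-implements the full analysis chain that such studies apply: average-
mastoid referencing, band-pass filtering, epoching, baselining, amplitude
artifact rejection, component quantification (CNV, P300, target- and
response-locked LRP), repeated-measures/mixed ANOVA, and default-prior
(JZS) Bayes-factor model selection. This note documents the generative
model, the measurement conventions, the statistical machinery, the
numerical choices, and what the synthetic data can and cannot show.

## The task

An S1–S2 paradigm. Each trial: fixation cross (500 ms), cue (1500 ms — the
cue–target interval), imperative target (visible 1000 ms), then a jittered
inter-trial gap (uniform; mean 2000 ms, 1500–2500 ms in the young-adult
profile, mean 3000 ms, 2500–3500 ms in the older-adult profile). Cues are
blocked: *directional* cues validly announce the response hand but 30% of
their targets are nogo stimuli (exact count per block, floor of the
proportion, positions randomized); *non-directional* cues announce only
target timing and are always followed by a go target whose direction is
random. The default session is five 80-trial blocks (three directional,
two non-directional); desk-scale runs use 40-trial blocks.

## Generative model

Each session is a sum of deterministic component templates plus noise, on
a configurable montage (64 scalp sites + 2 mastoids by default; an
8-channel compact montage carries identical signal at the measurement
sites and is used for fast runs).

**CNV** — a negative half-cosine ramp at Cz starting `cnv_onset` (500 ms)
after the cue, peaking 200 ms before the target (the start of the CNV
measurement window), holding its plateau through the target-locked
measurement windows and decaying 800–1300 ms after the target, i.e.
outside every window. The ramp is scaled so that the sample mean over the
1300–1500 ms post-cue window equals `cnv_amp` exactly. The template
spreads to neighbouring scalp sites by a Gaussian falloff (σ = 0.35 head
units on a schematic 10-10 layout); because the spread is hand-symmetric
it cancels exactly in the LRP double subtraction, and because the plateau
is constant over the pre-target baselines it vanishes from all
target-locked measures.

**P300** — a positive Gaussian bump (σ = 45 ms) at Pz on go trials, peak
`p300_amp` at `p300_lat` ms post-target, spread by the same falloff.

**Lateralized motor potential** — deposited only on the central electrode
contralateral to the responding hand (no spatial spread: any symmetric
spread would cancel in the LRP anyway, while asymmetric leakage into Pz
would bias the P300). It has three phases: a slow *preparation* build-up
under directional cues (the cued hand is known during the cue–target
interval), rising over the 650 ms before the response and resolving
shortly after it; a broad (200 ms) target-locked *selection* bump; and a
sharp (40 ms), six-fold deeper response-locked *execution* bump. The
preparation drift gives the directional response-locked window the
sustained negativity real directional LRPs show, which deepens and
stabilizes the fractional-area threshold.

The nominal onsets `tlrp_onset` and `rlrp_onset` are defined
*operationally*: as what the standard 25% fractional-area measurement
reads out on noiseless data. Because target-locked averages smear the
response-locked bumps across the session's RT distribution (and vice
versa), the two readouts are coupled through the actually drawn response
times; the generator therefore calibrates the two bump onsets per cue and
session by root-finding against the package's own measurement chain
(double subtraction averaged over the session's RT multiset, baselining,
30 Hz zero-phase low-pass, 25% fractional area with the window mean as
threshold). A deterministic placement cannot satisfy the printed onset
pairs — e.g. a target-locked onset of 271 ms with a mean RT near 390 ms
and a response-locked onset of −109 ms — precisely because those pairs
arise from RT-distribution smearing in real target-locked averages; the
empirical-multiset calibration reproduces that mechanism. Calibration
residuals are typically < 0.1 ms for the printed parameter sets;
residuals above 1 ms are logged (between-subject parameter draws
occasionally land a few ms outside the template family's reachable set,
in which case the templates are placed best-effort), and beyond 40 ms
the onset pair is reported unreachable (response-locked onsets must lie
inside the −300…−100 ms window by definition of the measurement). With
`lrp_amp = 0` the motor stage is skipped entirely.

**Behaviour** — response times are ex-Gaussian per cue × hand cell
(mean = μ + τ). The study reports only cell means, so σ = 40 ms and
τ = 60 ms are free conventions documented as such. Go omissions occur at
`miss_rate` (default 1.61%) and nogo false alarms at `false_alarm_rate`
(default 0.1%), the rates the study prints. Responses are snapped to the
sample grid so the synthesized deflection and the calibration see
identical timing.

**Noise** — independent 1/f^α Gaussian noise per channel (α = 1), scaled
to `noise_rms` (default 10 µV), plus a 50 Hz line sinusoid
(`line_amp`, default 2 µV, random phase per channel). No spatial
correlation, no ocular artifacts (an amplitude-outlier injector exists for
testing the rejection stage).

**Cohorts** — per-subject parameters are drawn around the profile
defaults. One offset per parameter family shifts all condition values
jointly, so within-subject condition differences stay at their configured
values. A subject's overall slowness (the RT offset, SD 40 ms) also
shifts the target-locked LRP onset — later response selection delays the
response by the same amount — while the response-relative onset is
unaffected; this keeps every subject's (tLRP, rLRP, RT) triple on the
manifold the calibration can realize. Response-locked onsets are clipped
to −280…−112 ms: onsets within a few ms of the −100 ms window edge put
three quarters of the suprathreshold area into the last few milliseconds
of the window, where the estimator is unstable under noise. Session order
(active/sham) is counterbalanced across subjects. All randomness flows
from one seed through `numpy.random.SeedSequence` spawning (per subject,
then per session), so cohorts are bit-reproducible.

Null construction: with `stim_effect = 0` (the default) the active and
sham generative processes are identical, so any detected stimulation
effect is a false positive. `StimEffect` adds configurable shifts to
RT, CNV amplitude and the LRP onsets under active stimulation.

## Preprocessing and measurement conventions

* Reference: average of the two mastoids; re-referencing twice is an
  error.
* Filter: zero-phase forward–backward 4th-order Butterworth band-pass
  0.02–30 Hz (SOS) plus a 50 Hz notch (Q = 30). A 0.02 Hz corner has a
  ~50 s time constant, so recordings spanning fewer than ten corner
  periods are linearly detrended and low-pass filtered instead (logged);
  on the true band-pass path the filtfilt padding is scaled to three
  corner periods.
* Epochs: half-open [t_start, t_end) in ms relative to the named zero
  event (fixation, cue, target or response), sample 0 at the event's
  onset sample (index = round(onset·fs/1000)). Cue-locked epochs span
  −800…+2300 ms (i.e. 300 ms before fixation to 800 ms after the target;
  the full span is 3100 ms at this trial timing). Response-locked epochs
  span −800…+200 ms.
* Baselines: CNV, 200 ms preceding fixation; P300 and tLRP, 200 ms
  pre-target; rLRP, −700…−500 ms before the response.
* Artifact rejection: any scalp channel exceeding ±100 µV within an epoch
  masks the trial; sessions with > 40% rejected are flagged for
  exclusion. Both numbers are field conventions (the study states
  neither); per-trial rejection and whole-subject flagging are both
  available.
* CNV: mean amplitude at Cz over 1300–1500 ms post-cue. P300: absolute
  extremum at Pz (no local-maximum requirement, endpoints eligible, ties
  to the earliest) over 200–500 ms (young profile) or 250–650 ms (older
  profile) post-target. LRP: pointwise
  ½[(C4−C3)_left-hand + (C3−C4)_right-hand] from condition averages
  (equivalently, by linearity, the average of per-trial differences),
  low-passed at 30 Hz zero-phase after derivation, onset = 25%
  fractional-area latency over 100–600 ms (target-locked) or −300…−100 ms
  (response-locked).
* Fractional-area latency: the threshold is the mean amplitude across the
  window; area accumulates only where the waveform exceeds the threshold
  in the component's polarity direction; the latency is the linearly
  interpolated time at which the cumulative trapezoidal area first
  reaches the requested fraction of the total. Zero suprathreshold area
  raises a distinct `UndefinedLatencyError`. Whether the original
  software accumulated area beyond the mean or relative to zero cannot be
  determined from the text; both conventions are implemented
  (`area_reference='window_mean'` default, `'zero'` alternative).

## Statistics

**ANOVA** — classical balanced sums-of-squares decomposition with subject
as an additive random block (nested in the between-subject group when one
exists). Each within effect is tested against its own effect-by-subject
interaction; the between effect against subjects-within-groups. Terms are
computed by inclusion–exclusion on marginal cell means with cells
weighted by their observation counts, which is exact for balanced and
proportional (unequal-group) designs. All design factors here are
two-level, so every numerator df is 1 and sphericity correction is moot;
for any two-level within factor F equals the squared paired t on subject
cell means (a tested invariant). No multiplicity correction is applied
across ANOVA families, mirroring the original analyses.

**Bayes factors** — the default-prior linear-model family: zero-centred
g-priors on standardized effects through orthonormal sum-to-zero contrast
projections, one g per effect term, g ~ InverseGamma(½, r²/2), with
Jeffreys priors on the intercept and error variance. Fixed effects use
r = 0.5 (the conventional "medium" default); the subject block is a
nuisance random factor with its own scale r = 1.0. Conditional on g the
marginal likelihood is closed-form (determinant/Woodbury identities on
the stacked effect columns); the g-integral is evaluated by fixed-seed
Monte Carlo over the priors (default 10 000 draws; 2 000 at desk scale),
vectorized over draws with the log-sum-exp trick, reporting a relative
Monte-Carlo standard error and a convergence flag. The model space is
every hierarchical model respecting full marginality (an interaction
requires all its constituents), always including the subject block; 1, 2
and 3 factors give 2, 5 and 19 models. One-factor two-level tables carry
no information separating the subject term from the residual beyond the
per-subject differences, so they collapse to difference scores and the
one-sample JZS Bayes factor, evaluated by adaptive quadrature (the
Monte-Carlo path over the same one-dimensional integral is retained for
cross-checks). Bayes factors are scale-invariant by construction.

The reported "null versus strongest stimulation model" ratio compares the
strongest model *without* any stimulation term against the strongest
model containing one. When no other factor carries evidence the former is
the subject-only null; when, as here, the cue effect is overwhelming, the
matched comparison isolates the stimulation question — this is the only
reading under which a null-favouring ratio of order 2–11 can coexist with
cue F-statistics in the hundreds, as in the study this package models.

## Problem sizes and runtime

Full-size sessions (five 80-trial blocks, 64 + 2 channels) at 256 Hz are
the package defaults for the command-line `run`. The test-suite and
acceptance-script conditions use the documented desk-scale profile —
23 subjects × 2 sessions, five 40-trial blocks, 128 Hz, the compact
montage, 2 000 Monte-Carlo draws — under which one full
simulate–measure–analyse replicate takes roughly half a minute and the
noiseless recovery checks run in seconds. The original recordings were
sampled at 2048 Hz; all windows are specified in milliseconds, so the
sampling rate only sets the quantization of latency estimates (one sample
is 3.9 ms at 256 Hz, 7.8 ms at 128 Hz, both finer than the
between-condition differences of interest).

## What passing tests do and do not show

The generator reproduces the *structure* of the study — event timing,
nogo proportions, printed condition means, error rates, a null
stimulation contrast — with stylized template shapes, stationary 1/f
noise, and no ocular or movement artifacts, no volume conduction, and no
drifts in vigilance. Passing the parameter-recovery and null-behaviour
tests therefore shows that the measurement and inference machinery is
correct and well calibrated on data whose ground truth is known, and that
the Bayesian machinery penalizes a truly absent stimulation effect while
detecting an injected one. It does not validate the physiological realism
of the templates, and measured onset latencies under noise carry a small
condition-dependent bias intrinsic to threshold-based fractional-area
estimation near window edges (a few ms here; present in any application
of the estimator).

## Known limitations

* The ANOVA and Bayes engines require balanced (or proportional)
  complete tables; subjects with empty cells must be dropped upstream.
* Calibration defines LRP onsets through the default measurement
  convention; switching `area_reference` to `'zero'` changes what the
  generator's nominal onsets mean.
* EDF output is 16-bit; round-trips are exact only to the per-channel
  quantization step (~0.002% of the data range).
* The 0.02 Hz high-pass is honoured only on recordings long enough to
  support it; shorter recordings are detrended instead (logged).
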