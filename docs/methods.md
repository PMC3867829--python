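# Methods

This note documents the models, operational definitions, and numerical
choices behind `qeeg`. The package analyses two-channel EEG recorded after
resuscitation from cardiac arrest, quantifies its staged recovery, and links
the EEG metrics to neurological outcome and survival in a two-arm
(hypothermia vs. normothermia) rodent experiment. Because animal-level raw
data for such experiments are generally unavailable, a synthetic generator
with fully known ground truth drives all end-to-end validation.

## EEG conditioning

Recordings are two bipolar channels sampled at a nominal 300 Hz in
microvolts, with the time axis anchored at ROSC (return of spontaneous
circulation). Digital conditioning reproduces the analog acquisition
passband: a 4th-order Butterworth band-pass, 0.3–70 Hz, applied forward and
backward (`sosfiltfilt`) so that it is zero-phase. Zero-phase filtering
matters here because burst *onset times* are an endpoint; a causal filter
would delay every onset by the group delay. If the sample rate cannot
represent the 70 Hz corner, the corner is clamped just below Nyquist and a
warning is raised.

## Burst detection and epoch classification

The field's verbal definitions are: bursts are deflections exceeding 10 µV
on **both** left and right channels; interburst (suppression) intervals are
at least 0.5 s of absent or sub-10 µV activity; and each nonoverlapping 60 s
epoch is classified as isoelectric, burst suppression, or continuous
background. These leave several quantities unspecified, which we fix as
follows:

- **Amplitude measure** — rectified (absolute) amplitude of the conditioned
  signal, compared against the 10 µV threshold. A supra-threshold excursion
  must persist ≥ 10 ms (debounce) to count; this rejects isolated spikes at
  the sample level. The same rectified measure defines "visible activity"
  for the isoelectric rule, so one threshold governs both decisions. With
  the default 2 µV RMS suppression background, a 60 s epoch's peak rectified
  amplitude stays below 10 µV with probability > 0.99 (Gaussian extreme-value
  bound at 18 000 samples), making isoelectric labels unambiguous by
  construction.
- **Within-burst gaps** — sub-threshold gaps shorter than 0.5 s are absorbed
  into the burst (only the ≥ 0.5 s rule defines a true interburst interval);
  bursts shorter than 50 ms after merging are discarded as artifacts.
- **Both-channel rule** — a burst requires overlapping supra-threshold
  candidate intervals on the two channels; the event interval is the union
  of the overlapping pair. Burst *counting* therefore uses the two-channel
  conjunction, consistent with the amplitude rule.
- **Epoch classification** — isoelectric if no debounced activity occurs on
  either channel; burst suppression if at least one detected burst overlaps
  the epoch and the epoch contains a ≥ 0.5 s suppression segment; continuous
  otherwise. Trailing partial epochs are dropped, not padded.
- **Recovery of continuous background** — the start of the first continuous
  epoch after which every remaining labeled epoch is continuous. Recovery is
  reported as a single time point, and without the persistence requirement a
  momentary relapse would make it ill-defined.
- **Burst frequency** — burst-onset counts per time bin (default 10 min)
  divided by the bin width, restricted to the burst-suppression period.
  Once continuous background is durably restored, its unbroken
  supra-threshold activity is excluded from the burst list (it would
  otherwise register as one giant event).

## Spectral entropy

For each 60 s epoch the power spectral density is estimated by the Welch
averaged periodogram: 10 s Hann-windowed segments with 50 % overlap, linear
detrend per segment. 10 s segments give 0.1 Hz resolution, which cleanly
resolves the 0.5 Hz lower band edge; segment length and overlap are
configurable, and a single 60 s periodogram (segment = epoch) is supported.
Band powers `X_i` are the PSD integrated over delta (0.5–4 Hz), theta
(4–8 Hz), alpha (8–13 Hz), and beta (13–30 Hz), with half-open bins
`[low, high)` so shared edges are counted exactly once. The band
probabilities are `p_i = X_i / Σ X_j` and the spectral entropy is the
normalized Shannon entropy `SE = −Σ p_i log2 p_i / log2 4 ∈ [0, 1]`, with
`0·log2 0 = 0`. SE is computed per channel and reported with the
left/right mean. A flat epoch (`Σ X = 0`) has no defined distribution;
its SE is a missing value, not 0 — the normalization requires a positive
denominator, and isoelectric epochs are excluded from entropy summaries
anyway since SE characterizes continuous background activity.

Useful anchors: uniform band power gives SE = 1; a single dominant band
gives SE → 0; `p = (1/2, 1/4, 1/8, 1/8)` gives exactly 0.875; white noise
spreads power in proportion to bandwidth, `p = (3.5, 4, 5, 17)/29.5`,
giving SE ≈ 0.824.

## Synthetic EEG generator

The generator emulates the canonical three-stage post-resuscitation
recovery: isoelectric → burst suppression → continuous background.

- **Suppression background**: independent Gaussian noise per channel,
  default σ = 2 µV, chosen (see above) so isoelectric epochs never cross
  the 10 µV activity threshold in practice.
- **Burst process**: an inhomogeneous Poisson process with a
  piecewise-linear bursts-per-minute profile over the burst-suppression
  stage, realized by thinning. Placed bursts keep a ≥ 0.6 s gap from the
  previous burst (just above the 0.5 s merge rule) so generated events are
  unambiguous to the detector. That hard core imposes a dead time of about
  (mean duration + 0.6 s) per event; the candidate intensity is dead-time
  compensated, µ(t) = λ(t)/(1 − λ(t)·d̄), so placed counts remain unbiased
  for the nominal Poisson mean λT. Every placed burst is written to the
  record's event log, which downstream tests use as the exact oracle.
- **Burst waveform**: 2–20 Hz band-limited noise under a Tukey (α = 0.5)
  envelope, peak-normalized (default 50 µV). Real bursts have richer and
  more variable morphology; only amplitude, duration, and timing matter to
  the detector under test. The same waveform is added to both channels
  (the both-channel rule needs co-occurring bursts) over independent
  background noise.
- **Continuous stage**: per channel, an independent sum of four
  band-limited Gaussian noises with configured band-power fractions and
  total RMS (default 20 µV), ramped on over 0.5 s at the stage boundary.
  Band-limited noise is synthesized in the Fourier domain with exact
  mean-square normalization.

### Cohort model

A two-arm cohort draws per-animal stage boundaries from group-specific
normal distributions. Defaults are the published group summaries: burst
onset 15.1 ± 1.9 vs 21.5 ± 6.0 min and continuous-background recovery
171.2 ± 15.2 vs 239.5 ± 38.4 min (hypothermia vs normothermia). Burst-rate
ramps default to 2→12 vs 2→8 bursts/min over the burst-suppression stage —
rising profiles of realistic magnitude; treated band fractions
(0.65, 0.15, 0.10, 0.10) and control fractions (0.75, 0.11, 0.07, 0.07)
were chosen so the analytic entropy of each mixture (≈ 0.739 and ≈ 0.599)
matches the reported late-recovery group means.

The NDS link maps each animal's generating recovery time to a latent
severity `z = (recovery − center)/scale` (center: midpoint of the group
means; scale: half the group-mean gap, floored by the within-group SD), a
per-day drift (improving in the treated arm, worsening in the control arm),
and per-category Gaussian noise; a logistic squash and tertile cut select
each category's score from its allowed set. Survival is day-resolution:
each day an animal dies with probability `expit(k·(NDS − center))`
(defaults k = 0.015, center = 420), and a total of 500 — brain death — is
always fatal. Dead animals are carried forward at 500, matching how such
scales treat death.

**Timescale** — the default cohort uses `time_scale = 1/6`: stage-boundary
parameters (not burst rates, not the 60 s epoch grid) are compressed so a
six-hour protocol becomes one hour per animal and a 2 × 10 cohort runs in
about a minute. The full timeline (`time_scale = 1`) is supported
unchanged. Compression was chosen so boundaries stay resolvable on the
epoch grid (the shortest isoelectric periods remain > 2 epochs).

**Seeding** — one master seed; animal *i* uses `default_rng([seed, i, k])`
with k = 0 (parameter draws), 1 (signal synthesis), 2 (outcome draws).
Fixed seed ⇒ bit-identical cohorts, and any animal can be regenerated
alone.

### What the generator does *not* emulate

No biophysical cortical model, no artifacts or electrode noise, no
epileptiform patterns, no drifting amplitudes within a stage, and abrupt
(single-boundary) stage transitions rather than gradual evolution. Passing
parameter-recovery tests therefore demonstrates the correctness of the
detection/classification/entropy machinery under the stated definitions,
not robustness of those definitions to real-world recording pathology.

## Statistics

- **Welch t-test** (raw or from mean/SD/n) with Satterthwaite df is the
  default two-sample test; the published p-values for this design are
  reproduced by the unequal-variance form, not the pooled form. When one
  group has zero variance the df reduces to n − 1 of the other group; two
  zero-variance groups give p = 1 (equal means) or p = 0 with a warning.
  The raw-sample form computes its own summaries and defers to the summary
  form, so the two are identical by construction.
- **Fisher's exact test** is two-sided by the sum-of-smaller-probabilities
  rule (all tables with the observed margins whose probability does not
  exceed the observed table's). A brute-force enumeration oracle verifies
  it over every 2×2 table with total ≤ 20.
- **Kaplan–Meier / log-rank** (via lifelines) with censoring at 96 h;
  day-resolution ties use the standard tied-risk-set formulation. No events
  at all ⇒ the log-rank statistic is reported missing.
- **Spearman correlation** uses mid-ranks for ties with the t-approximation
  p-value; constant input yields a missing value.
- **Logistic regression** is single-predictor maximum likelihood
  (statsmodels); the Wald test on the slope is the reported p-value, and
  complete separation is detected and flagged rather than returning a
  silently divergent estimate.
- **Two-way ANOVA** (group × time, type-II SS via statsmodels OLS) with
  per-time unadjusted Welch tests as post hoc comparisons. No
  multiple-testing adjustment is applied by default, matching the source
  analysis; Holm adjustment is available separately.

### Calibration study design

Type-I error of the Welch t and Fisher tests is checked over 1000 null
replicates at α = 0.05 (acceptance band 0.05 ± 0.02). The t null uses two
n = 10 normal samples — the experiment's group size. The Fisher null uses
two binomial(100, 0.5) groups: at n = 10 the hypergeometric support is so
coarse that the achievable size is ≈ 0.015, below the nominal level by
construction, so a calibration statement at the nominal level is only
meaningful at a size where the support is fine-grained.

## Problem sizes in the shipped tests

The default test suite exercises: single records of 5–15 min at 300 Hz for
unit tests; a 2 × 10 compressed-timeline cohort (one hour per animal) for
parameter recovery; 1000-replicate nulls for calibration; and exhaustive
Fisher enumeration to table total 20. These sizes were chosen so the whole
suite runs in a few minutes on one core while keeping every statistical
band (3σ Poisson, L1 ≤ 0.1 band recovery, ±0.02 calibration) meaningful.

## Known limitations

- The isoelectric/burst-suppression boundary is observable only through the
  first burst, so "onset of identifiable bursting" is the first detected
  burst event, not the latent stage boundary.
- Epoch classification at stage boundaries is ambiguous within one epoch by
  construction; all boundary-recovery guarantees are stated to ± 1 epoch.
- SE is slightly biased upward on mixtures with a strongly dominant band
  (spectral leakage spreads power into neighbouring bands); the effect is
  within the ± 0.05 validation band at the default settings.
- The NDS/survival link is a phenomenological logistic model chosen to
  reproduce the qualitative outcome pattern (low, improving scores and
  survival in the treated arm; escalation to 500 and death in the control
  arm); its coefficients are not estimates of any biological quantity.
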