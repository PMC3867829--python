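# qeeg — quantitative early-postresuscitation EEG analysis

After resuscitation from cardiac arrest the EEG recovers through a
stereotyped sequence — an isoelectric (flat) period, then *burst
suppression* (high-amplitude bursts separated by suppression intervals),
then continuous background activity — and the speed and quality of that
recovery carries prognostic information about neurological outcome.
`qeeg` implements the quantitative analysis of this recovery for
two-channel rodent EEG, together with the outcome-statistics layer used to
relate EEG metrics to neurological deficit and survival in a two-arm
(therapeutic hypothermia vs. normothermia) experiment, and a synthetic
EEG + cohort generator with fully known ground truth so that every stage
of the pipeline is testable without animal data.

It is aimed at researchers in experimental resuscitation / neurocritical
care and at anyone who needs a transparent, tested reference
implementation of burst-suppression metrics and band-power spectral
entropy.

## What it computes

**EEG layer** (300 Hz, µV, two bipolar channels, time anchored at return
of spontaneous circulation, ROSC):

- zero-phase 0.3–70 Hz conditioning;
- burst detection: rectified amplitude > 10 µV required on *both*
  channels, interburst suppression ≥ 0.5 s, sub-threshold gaps < 0.5 s
  absorbed;
- per-60 s-epoch classification into isoelectric / burst suppression /
  continuous background;
- recovery metrics: onset time of identifiable bursting, burst frequency
  per time bin during the burst-suppression period, and the time of
  durable recovery of continuous background activity;
- spectral entropy per epoch, from the Welch averaged periodogram
  (10 s Hann segments, 50 % overlap, linear detrend). With band powers
  X_i over delta (0.5–4 Hz), theta (4–8 Hz), alpha (8–13 Hz) and beta
  (13–30 Hz):

      p_i = X_i / Σ_j X_j ,      SE = − Σ_i p_i log2 p_i / log2 N ,  N = 4

  so SE = 1 when power is uniform across bands and SE = 0 when one band
  dominates.

**Outcome layer**: neurological deficit score (NDS, seven categories,
total 0 = intact … 500 = brain death) with validation; Welch t-tests from
raw samples or printed mean/SD/n; Fisher's exact test; Spearman
correlation; single-predictor logistic regression with separation
detection; Kaplan–Meier + log-rank with censoring at 96 h; two-way
(group × time) ANOVA with per-time post hoc tests.

**Synthetic generator**: three-stage recordings with an inhomogeneous
Poisson burst process (piecewise-linear rate, dead-time compensated),
band-limited tapered bursts shared across channels, a continuous stage
with configured band-power fractions, and a two-arm cohort whose stage
boundaries, NDS trajectories and survival follow group-dependent
distributions. Every generated event is logged, so detection and
classification can be validated by exact parameter recovery. See
`docs/methods.md` for the model and all operational definitions.

## Worked example

```python
from qeeg.synth import StageProfile, ContinuousSpec, generate_recording
from qeeg.bursts import compute_recovery_metrics
from qeeg.entropy import entropy_timecourse

# 2 min isoelectric, 10 min burst suppression ramping 2 -> 12 bursts/min,
# then continuous background with a delta-dominant band mixture
profile = StageProfile(isoelectric_end=120, bs_end=720,
                       burst_rate=((0.0, 2.0), (1.0, 12.0)))
continuous = ContinuousSpec(band_fractions=(0.65, 0.15, 0.10, 0.10))
rec = generate_recording(profile, continuous, fs=300, duration=900, seed=1)

metrics, bursts, labels = compute_recovery_metrics(rec)
print(f"bursts detected: {len(bursts)} (generated: {rec.log.n_bursts})")
print(f"burst onset:     {metrics.burst_onset_min:.2f} min")
print(f"recovery:        {metrics.recovery_min:.1f} min (truth {rec.log.bs_end/60:.1f})")

se = entropy_timecourse(rec)
cont = se[se.t_start_s >= rec.log.bs_end]
print(f"continuous-stage SE: {cont.SE_mean.mean():.3f}")
```

prints

```
bursts detected: 70 (generated: 70)
burst onset:     2.12 min
recovery:        12.0 min (truth 12.0)
continuous-stage SE: 0.753
```

Every burst placed by the generator is recovered by the detector; the
first burst appears right after the 2 min isoelectric period; continuous
background is recovered at the true 12 min stage boundary; and the
delta-dominant mixture yields a spectral entropy near its analytic value
(≈ 0.74 for these fractions, small upward bias from spectral leakage).

The full pipeline — simulate a 2 × 10 cohort, classify, compute entropy,
run the group statistics, and emit a two-arm outcome report — is one
command:

```sh
qeeg run --seed 1 --out demo_run
cat demo_run/report.txt
```

The report shows group mean ± SD and Welch p-values for burst onset,
recovery time, mean burst frequency and late spectral entropy, the NDS
totals per day, and the survival comparison (Fisher exact and log-rank).
Individual stages are also available as `qeeg simulate`, `qeeg classify`,
`qeeg entropy`, and `qeeg stats`.

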