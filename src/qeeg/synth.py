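"""Synthetic two-channel EEG and cohort generator.

Emulates the three-stage EEG recovery seen after resuscitation from cardiac
arrest — an isoelectric period, a burst-suppression period with a rising
burst rate, then continuous background activity — together with a matching
synthetic cohort (neurological deficit scores and survival) whose generating
parameters are all known, so every downstream stage can be validated by
parameter recovery.

The burst process is an inhomogeneous Poisson process with a piecewise-linear
rate; bursts are band-limited noise packets with a Tukey taper, shared across
the two channels (independent background noise per channel) so the
both-channel detection rule is satisfiable by construction.

Seeding: a single master seed; the stream for animal ``i`` is derived as
``default_rng([seed, i, k])`` with ``k`` = 0 (parameter draws), 1 (signal
synthesis), 2 (outcome draws), so cohorts are reproducible animal-by-animal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import tukey
from scipy.special import expit

from .records import BURST_THRESHOLD_UV, EEGRecord, RecordingLog

__all__ = [
    "StageProfile",
    "ContinuousSpec",
    "GroupParams",
    "CohortSpec",
    "AnimalOutcome",
    "generate_burst",
    "generate_bandlimited_noise",
    "generate_recording",
    "draw_cohort_params",
    "generate_cohort",
]

#: Default band edges (Hz) for the continuous-background mixture:
#: delta, theta, alpha, beta.
DEFAULT_BANDS = ((0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0))


@dataclass
class StageProfile:
    """Stage boundaries and burst-process parameters for one recording.

    ``burst_rate`` is a piecewise-linear bursts-per-minute profile over the
    burst-suppression stage, given as ``((frac, rate), ...)`` with ``frac``
    the fractional position within the stage (0 = stage start, 1 = stage
    end); rates in between are linearly interpolated.
    """

    isoelectric_end: float  # s from ROSC
    bs_end: float  # s from ROSC; start of continuous stage
    suppression_sigma: float = 2.0  # µV RMS of sub-threshold background
    burst_rate: tuple[tuple[float, float], ...] = ((0.0, 2.0), (1.0, 12.0))
    burst_amp: float = 50.0  # µV peak
    burst_dur_range: tuple[float, float] = (0.2, 0.8)  # s

    def __post_init__(self) -> None:
        if not 0 <= self.isoelectric_end < self.bs_end:
            raise ValueError("need 0 <= isoelectric_end < bs_end")
        if self.burst_amp <= BURST_THRESHOLD_UV:
            raise ValueError(
                f"burst_amp must exceed the {BURST_THRESHOLD_UV} µV threshold"
            )
        if self.suppression_sigma < 0:
            raise ValueError("suppression_sigma must be nonnegative")
        lo, hi = self.burst_dur_range
        if not 0 < lo <= hi:
            raise ValueError("invalid burst duration range")
        fracs = [f for f, _ in self.burst_rate]
        if any(r < 0 for _, r in self.burst_rate) or fracs != sorted(fracs):
            raise ValueError("burst_rate must be sorted with nonnegative rates")

    def rate_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Burst rate (bursts/min) at absolute time ``t`` (s from ROSC)."""
        frac = (np.asarray(t) - self.isoelectric_end) / (
            self.bs_end - self.isoelectric_end
        )
        xs = np.array([f for f, _ in self.burst_rate])
        ys = np.array([r for _, r in self.burst_rate])
        return np.interp(frac, xs, ys)

    def expected_burst_count(self) -> float:
        """Integral of the rate profile over the burst-suppression stage."""
        xs = np.array([f for f, _ in self.burst_rate])
        ys = np.array([r for _, r in self.burst_rate])
        stage_min = (self.bs_end - self.isoelectric_end) / 60.0
        return float(np.trapezoid(ys, xs) * stage_min)


@dataclass
class ContinuousSpec:
    """Band-power composition of the continuous background stage."""

    band_fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    total_rms: float = 20.0  # µV
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        fr = np.asarray(self.band_fractions, dtype=float)
        if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("band_fractions must be nonnegative and sum to 1")
        if len(fr) != len(self.bands):
            raise ValueError("one fraction per band required")


def generate_bandlimited_noise(
    band: tuple[float, float],
    target_power: float,
    fs: float,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Gaussian noise whose spectral support lies inside ``band``.

    Synthesized in the Fourier domain: white Gaussian noise is projected onto
    the rFFT bins inside ``[low, high)`` and rescaled so the mean-square power
    equals ``target_power`` (µV²) exactly.
    """
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} must satisfy 0 < low < high < fs/2")
    if target_power < 0:
        raise ValueError("target_power must be nonnegative")
    if target_power == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < low) | (freqs >= high)] = 0.0
    x = np.fft.irfft(spec, n=n)
    ms = np.mean(x**2)
    if ms == 0:  # band narrower than one FFT bin
        raise ValueError("band contains no FFT bin for this n and fs")
    return x * math.sqrt(target_power / ms)


def generate_burst(
    duration: float,
    peak_amp: float,
    fs: float,
    seed: int | np.random.Generator,
    band: tuple[float, float] = (2.0, 20.0),
) -> np.ndarray:
    """One burst waveform: tapered band-limited noise at a set peak amplitude.

    The Tukey envelope brings both ends to ~0 so bursts can be added into a
    record without discontinuities; the absolute peak is normalized to
    ``peak_amp`` µV.
    """
    if duration <= 0:
        raise ValueError("burst duration must be positive")
    if peak_amp <= 0:
        raise ValueError("peak_amp must be positive")
    n = max(int(round(duration * fs)), 8)
    x = generate_bandlimited_noise(band, 1.0, fs, n, seed)
    x *= tukey(n, alpha=0.5)
    return x * (peak_amp / np.max(np.abs(x)))


def _draw_burst_times(
    profile: StageProfile, rng: np.random.Generator, min_gap: float = 0.6
) -> tuple[np.ndarray, np.ndarray]:
    """Inhomogeneous Poisson burst onsets by thinning.

    Bursts are kept only if they start ``min_gap`` after the previous burst
    ends and finish before the continuous stage, so generated events are
    unambiguous under the ≥0.5 s interburst rule. That hard core imposes a
    dead time of roughly (mean duration + gap) per event, which would thin
    the realized rate below the nominal profile; the candidate intensity is
    therefore dead-time compensated, µ(t) = λ(t)/(1 − λ(t)·d̄), so placed
    counts stay unbiased for the nominal Poisson mean.
    """
    dead = float(np.mean(profile.burst_dur_range)) + min_gap

    def mu(t: float) -> float:
        lam = float(profile.rate_at(t)) / 60.0  # per second
        return lam / max(1.0 - min(lam * dead, 0.9), 0.1)

    rate_max = max(r for _, r in profile.burst_rate) / 60.0
    mu_max = rate_max / max(1.0 - min(rate_max * dead, 0.9), 0.1)
    onsets, durations = [], []
    t = profile.isoelectric_end
    prev_end = -np.inf
    while mu_max > 0:
        t += rng.exponential(1.0 / mu_max)
        if t >= profile.bs_end:
            break
        if rng.random() > mu(t) / mu_max:
            continue
        dur = rng.uniform(*profile.burst_dur_range)
        if t < prev_end + min_gap or t + dur > profile.bs_end:
            continue
        onsets.append(t)
        durations.append(dur)
        prev_end = t + dur
    return np.asarray(onsets), np.asarray(durations)


def generate_recording(
    profile: StageProfile,
    continuous: ContinuousSpec,
    fs: float,
    duration: float,
    seed: int | np.random.Generator,
    t0: float = 0.0,
) -> EEGRecord:
    """Synthesize a two-channel recording with the three-stage structure.

    Both channels share the burst waveforms and timing (the both-channel
    detection rule requires co-occurring bursts) over independent Gaussian
    suppression noise; the continuous stage is an independent band-limited
    mixture per channel with the configured band-power fractions.

    Returns an :class:`EEGRecord` whose ``log`` holds the exact stage
    boundaries and burst placements.
    """
    if fs < 100:
        raise ValueError("sample rate must be at least 100 Hz")
    if duration < profile.bs_end:
        raise ValueError(
            f"duration {duration} s is shorter than bs_end {profile.bs_end} s"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    data = rng.normal(0.0, profile.suppression_sigma, size=(2, n))

    # continuous background from bs_end onward, ramped on over 0.5 s
    i_cont = int(round(profile.bs_end * fs))
    n_cont = n - i_cont
    if n_cont > 0:
        powers = np.asarray(continuous.band_fractions) * continuous.total_rms**2
        ramp = np.ones(n_cont)
        n_ramp = min(int(0.5 * fs), n_cont)
        ramp[:n_ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        for ch in range(2):
            mix = np.zeros(n_cont)
            for band, power in zip(continuous.bands, powers):
                if power > 0:
                    mix += generate_bandlimited_noise(band, power, fs, n_cont, rng)
            data[ch, i_cont:] += mix * ramp

    onsets, durations = _draw_burst_times(profile, rng)
    for t, dur in zip(onsets, durations):
        w = generate_burst(dur, profile.burst_amp, fs, rng)
        i0 = int(round(t * fs))
        data[:, i0 : i0 + len(w)] += w[: n - i0]

    log = RecordingLog(
        isoelectric_end=profile.isoelectric_end,
        bs_end=profile.bs_end,
        burst_onsets=onsets,
        burst_durations=durations,
    )
    return EEGRecord(data=data, fs=fs, t0=t0, log=log)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class GroupParams:
    """Generating distributions for one experimental arm.

    Stage-boundary distributions are in minutes from ROSC at full (uncompressed)
    timescale; defaults mirror a hypothermia-treated arm with faster EEG
    recovery. ``nds_day_slope`` shifts the latent neuro-injury severity per
    postresuscitation day (negative = improving).
    """

    name: str = "hypothermia"
    burst_onset_min: tuple[float, float] = (15.1, 1.9)  # (mean, sd) minutes
    recovery_min: tuple[float, float] = (171.2, 15.2)  # (mean, sd) minutes
    burst_rate: tuple[tuple[float, float], ...] = ((0.0, 2.0), (1.0, 12.0))
    band_fractions: tuple[float, float, float, float] = (0.65, 0.15, 0.10, 0.10)
    nds_day_slope: float = -0.4


NORMOTHERMIA_DEFAULTS = GroupParams(
    name="normothermia",
    burst_onset_min=(21.5, 6.0),
    recovery_min=(239.5, 38.4),
    burst_rate=((0.0, 2.0), (1.0, 8.0)),
    band_fractions=(0.75, 0.11, 0.07, 0.07),
    nds_day_slope=1.2,
)


@dataclass
class CohortSpec:
    """Full description of a synthetic two-arm cohort.

    ``time_scale`` compresses stage boundaries (not burst rates or the 60 s
    epoch grid) so a six-hour protocol can be exercised at desk scale; 1.0
    reproduces the full timeline. The NDS link maps each animal's generating
    recovery time onto a latent severity via a logistic; per-day death
    probability is a logistic in the day's total NDS, and a total of 500
    (brain death) is always fatal.
    """

    n_per_group: int = 10
    groups: tuple[GroupParams, GroupParams] = (
        GroupParams(),
        NORMOTHERMIA_DEFAULTS,
    )
    fs: float = 300.0
    time_scale: float = 1.0 / 6.0
    duration_s: float | None = None  # default: 6 h × time_scale
    suppression_sigma: float = 2.0
    burst_amp: float = 50.0
    burst_dur_range: tuple[float, float] = (0.2, 0.8)
    continuous_rms: float = 20.0
    # NDS link: z = (recovery_min − center)/scale (+ day slope + noise)
    nds_center_min: float | None = None  # default: midpoint of group means
    nds_scale_min: float | None = None  # default: half the group-mean gap
    nds_noise_sd: float = 0.4
    # survival: P(death on day d) = expit(k·(NDS_d − center))
    death_nds_center: float = 420.0
    death_logit_k: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        for g in self.groups:
            if g.burst_onset_min[1] < 0 or g.recovery_min[1] < 0:
                raise ValueError("group SDs must be nonnegative")
        if not 0 < self.time_scale <= 1:
            raise ValueError("time_scale must be in (0, 1]")

    @property
    def record_duration(self) -> float:
        return (
            self.duration_s
            if self.duration_s is not None
            else 6 * 3600 * self.time_scale
        )


@dataclass
class AnimalOutcome:
    """Outcome row for one synthetic animal."""

    animal_id: str
    group: str
    true_isoelectric_end: float  # s, scaled timeline
    true_bs_end: float  # s, scaled timeline
    band_fractions: tuple[float, ...]
    nds_by_day: dict[int, "object"] = field(default_factory=dict)  # day → NDSRecord
    survival_hr: float = 96.0
    event: int = 0

    def nds_total_by_day(self) -> dict[int, int]:
        from .stats import nds_total

        return {d: nds_total(r) for d, r in self.nds_by_day.items()}


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float
) -> float:
    """Normal draw resampled to stay above ``low`` (keeps orderings valid)."""
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > low:
            return x
    return low + abs(rng.normal(0.0, sd)) + 1e-6


def draw_cohort_params(spec: CohortSpec) -> list[dict]:
    """Draw per-animal generating parameters (no signal synthesis).

    Separated from :func:`generate_cohort` so distribution-level studies
    (e.g. null calibration over many replicate cohorts) do not pay for EEG
    synthesis.
    """
    out = []
    idx = 0
    for group in spec.groups:
        for _ in range(spec.n_per_group):
            rng = np.random.default_rng([spec.seed, idx, 0])
            onset_min = _truncated_normal(rng, *group.burst_onset_min, low=1.0)
            rec_min = _truncated_normal(
                rng, *group.recovery_min, low=onset_min * 1.5
            )
            out.append(
                {
                    "animal_id": f"A{idx:03d}",
                    "group": group.name,
                    "group_params": group,
                    "index": idx,
                    # scaled-timeline boundaries used for synthesis
                    "isoelectric_end": onset_min * 60 * spec.time_scale,
                    "bs_end": rec_min * 60 * spec.time_scale,
                    # unscaled draws retained for the NDS link
                    "recovery_min_full": rec_min,
                    "onset_min_full": onset_min,
                }
            )
            idx += 1
    return out


def _simulate_outcome(
    spec: CohortSpec, params: dict, rng: np.random.Generator
) -> AnimalOutcome:
    from .stats import NDS_CATEGORIES, NDSRecord, nds_total

    means = [g.recovery_min[0] for g in spec.groups]
    sds = [g.recovery_min[1] for g in spec.groups]
    center = (
        spec.nds_center_min if spec.nds_center_min is not None else np.mean(means)
    )
    # severity scale: half the group-mean gap, floored by the within-group
    # spread so identical arms still yield a finite latent score
    scale = (
        spec.nds_scale_min
        if spec.nds_scale_min is not None
        else max(abs(means[1] - means[0]) / 2.0, float(np.mean(sds)), 1e-6)
    )
    z_base = (params["recovery_min_full"] - center) / scale
    day_slope = params["group_params"].nds_day_slope

    outcome = AnimalOutcome(
        animal_id=params["animal_id"],
        group=params["group"],
        true_isoelectric_end=params["isoelectric_end"],
        true_bs_end=params["bs_end"],
        band_fractions=params["group_params"].band_fractions,
    )
    dead = False
    for day in (1, 2, 3, 4):
        if dead:
            # carried forward as brain death, matching how a dead animal
            # scores at the ceiling of the deficit scale
            scores = {c: levels[-1] for c, levels in NDS_CATEGORIES.items()}
        else:
            z_day = z_base + day_slope * (day - 1)
            scores = {}
            for cat, levels in NDS_CATEGORIES.items():
                z_cat = z_day + rng.normal(0.0, spec.nds_noise_sd)
                sev = float(expit(1.5 * z_cat))
                level = min(int(sev * 3), 2)
                scores[cat] = levels[level]
        rec = NDSRecord(day=day, **scores)
        outcome.nds_by_day[day] = rec
        if not dead:
            total = nds_total(rec)
            p_death = float(
                expit(spec.death_logit_k * (total - spec.death_nds_center))
            )
            if total >= 500 or rng.random() < p_death:
                dead = True
                outcome.survival_hr = 24.0 * day
                outcome.event = 1
    return outcome


def generate_cohort(
    spec: CohortSpec, synthesize_eeg: bool = True
) -> tuple[list[EEGRecord | None], list[AnimalOutcome]]:
    """Generate the cohort: one recording and one outcome per animal.

    With ``synthesize_eeg=False`` the records list holds ``None`` per animal
    (outcomes only), which is cheap enough for replicate studies.
    """
    records: list[EEGRecord | None] = []
    outcomes: list[AnimalOutcome] = []
    for params in draw_cohort_params(spec):
        idx = params["index"]
        if synthesize_eeg:
            profile = StageProfile(
                isoelectric_end=params["isoelectric_end"],
                bs_end=params["bs_end"],
                suppression_sigma=spec.suppression_sigma,
                burst_rate=params["group_params"].burst_rate,
                burst_amp=spec.burst_amp,
                burst_dur_range=spec.burst_dur_range,
            )
            cont = ContinuousSpec(
                band_fractions=params["group_params"].band_fractions,
                total_rms=spec.continuous_rms,
            )
            rec = generate_recording(
                profile,
                cont,
                fs=spec.fs,
                duration=max(spec.record_duration, params["bs_end"] + 120.0),
                seed=np.random.default_rng([spec.seed, idx, 1]),
            )
        else:
            rec = None
        records.append(rec)
        outcomes.append(
            _simulate_outcome(spec, params, np.random.default_rng([spec.seed, idx, 2]))
        )
    return records, outcomes
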