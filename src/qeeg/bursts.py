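"""EEG conditioning, burst detection, epoch classification, recovery metrics.

The burst-suppression analysis follows the standard operational definitions
for early postresuscitation EEG: a burst is a supra-threshold (>10 µV on both
channels) deflection, separated from its neighbours by at least 0.5 s of
sub-threshold signal; each nonoverlapping 60 s epoch is classified as
isoelectric, burst suppression, or continuous background; and per-animal
recovery is summarized by the first-burst onset time, the burst-frequency
time course, and the time at which continuous background activity is
durably restored.

Operational choices where the field's verbal definitions leave latitude:

* Amplitude is measured on the rectified conditioned signal; an excursion
  must persist ≥10 ms (debounce) to count as activity. The same rectified
  measure defines "visible activity" for the isoelectric rule, so a record
  whose background stays below 10 µV peak is isoelectric by construction.
* Sub-threshold gaps shorter than 0.5 s inside a burst are absorbed; bursts
  shorter than 50 ms after merging are discarded.
* The both-channel rule requires overlapping supra-threshold intervals on
  both channels; the event interval is the union of the overlapping pair.
* Continuous-background recovery is the start of the first epoch from which
  every subsequent labeled epoch is continuous (momentary relapses would
  otherwise make a single recovery time ill-defined).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .records import (
    BURST_THRESHOLD_UV,
    EPOCH_S,
    MIN_INTERBURST_S,
    BurstEvent,
    EEGRecord,
    EpochClass,
    EpochLabel,
    RecoveryMetrics,
)

__all__ = [
    "condition",
    "detect_bursts",
    "classify_epochs",
    "burst_onset_time",
    "recovery_time",
    "burst_frequency",
    "compute_recovery_metrics",
]

DEBOUNCE_S = 0.010
MIN_BURST_S = 0.050
BANDPASS_HZ = (0.3, 70.0)


def condition(record: EEGRecord, band: tuple[float, float] = BANDPASS_HZ) -> EEGRecord:
    """Zero-phase band-pass (default 0.3–70 Hz, the analog passband).

    Zero-phase filtering (forward-backward Butterworth) keeps burst onsets
    free of group delay. If the upper corner is not below Nyquist it is
    clamped with a warning.
    """
    low, high = band
    nyq = record.fs / 2.0
    if high >= nyq:
        warnings.warn(
            f"low-pass corner {high} Hz unreachable at fs={record.fs} Hz; "
            "clamping below Nyquist",
            stacklevel=2,
        )
        high = 0.95 * nyq
    sos = signal.butter(4, [low, high], btype="bandpass", fs=record.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, record.data, axis=1)
    return EEGRecord(
        data=filtered, fs=record.fs, t0=record.t0, labels=record.labels,
        log=record.log,
    )


def _runs(mask: np.ndarray) -> np.ndarray:
    """(start, end) sample index pairs of True runs; end is exclusive."""
    if mask.size == 0:
        return np.empty((0, 2), dtype=int)
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return np.column_stack([starts, ends])


def _drop_short(runs: np.ndarray, min_len: int) -> np.ndarray:
    if len(runs) == 0:
        return runs
    return runs[(runs[:, 1] - runs[:, 0]) >= min_len]


def _merge_gaps(runs: np.ndarray, max_gap: int) -> np.ndarray:
    """Merge runs separated by gaps shorter than ``max_gap`` samples."""
    if len(runs) < 2:
        return runs
    merged = [runs[0].tolist()]
    for s, e in runs[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=int)


def _activity_runs(x: np.ndarray, fs: float, threshold: float) -> np.ndarray:
    """Debounced supra-threshold runs of one channel's rectified signal."""
    runs = _runs(np.abs(x) > threshold)
    return _drop_short(runs, max(int(round(DEBOUNCE_S * fs)), 1))


def detect_bursts(
    record: EEGRecord,
    threshold: float = BURST_THRESHOLD_UV,
    min_gap: float = MIN_INTERBURST_S,
) -> list[BurstEvent]:
    """Detect bursts requiring supra-threshold amplitude on both channels.

    Per channel: rectified amplitude > ``threshold`` with a 10 ms debounce,
    sub-threshold gaps < ``min_gap`` absorbed. A burst requires overlapping
    candidate intervals on both channels (event = union of the pair); final
    events closer than ``min_gap`` are merged and events shorter than 50 ms
    dropped. Events are returned sorted by onset, in seconds from ROSC.
    """
    fs = record.fs
    gap_n = int(round(min_gap * fs))
    cand = []
    for ch in range(2):
        runs = _activity_runs(record.data[ch], fs, threshold)
        cand.append(_merge_gaps(runs, gap_n))
    left, right = cand
    if len(left) == 0 or len(right) == 0:
        return []

    # sweep the two sorted interval lists for overlaps; union overlapping pairs
    events: list[list[int]] = []
    i = j = 0
    while i < len(left) and j < len(right):
        ls, le = left[i]
        rs, re = right[j]
        if ls < re and rs < le:  # overlap
            s, e = min(ls, rs), max(le, re)
            if events and s - events[-1][1] < gap_n:
                events[-1][1] = max(events[-1][1], e)
            else:
                events.append([s, e])
        if le <= re:
            i += 1
        else:
            j += 1

    out = []
    min_n = int(round(MIN_BURST_S * fs))
    for s, e in events:
        if e - s < min_n:
            continue
        peaks = tuple(float(np.max(np.abs(record.data[ch, s:e]))) for ch in range(2))
        out.append(
            BurstEvent(
                onset=record.t0 + s / fs,
                offset=record.t0 + e / fs,
                peak_amp=peaks,
            )
        )
    return out


def _epoch_slices(record: EEGRecord, epoch_s: float) -> list[tuple[int, int]]:
    n_epoch = int(round(epoch_s * record.fs))
    n_full = record.n_samples // n_epoch
    return [(k * n_epoch, (k + 1) * n_epoch) for k in range(n_full)]


def classify_epochs(
    record: EEGRecord,
    bursts: list[BurstEvent] | None = None,
    epoch_s: float = EPOCH_S,
    threshold: float = BURST_THRESHOLD_UV,
    min_suppression: float = MIN_INTERBURST_S,
) -> list[EpochLabel]:
    """Label each full nonoverlapping epoch isoelectric / BS / continuous.

    * isoelectric — no debounced supra-threshold activity on either channel;
    * burst suppression — at least one detected burst overlaps the epoch and
      the epoch contains a suppression segment (both channels sub-threshold)
      of at least ``min_suppression`` seconds;
    * continuous — otherwise.

    A trailing partial epoch is excluded from labeling.
    """
    if bursts is None:
        bursts = detect_bursts(record, threshold=threshold)
    fs = record.fs
    active = np.zeros(record.n_samples, dtype=bool)
    for ch in range(2):
        for s, e in _activity_runs(record.data[ch], fs, threshold):
            active[s:e] = True

    burst_iv = np.array(
        [[(b.onset - record.t0) * fs, (b.offset - record.t0) * fs] for b in bursts]
    ).reshape(-1, 2)

    labels = []
    min_sup_n = int(round(min_suppression * fs))
    for k, (s, e) in enumerate(_epoch_slices(record, epoch_s)):
        seg_active = active[s:e]
        if not seg_active.any():
            cls = EpochClass.ISOELECTRIC
        else:
            has_burst = bool(
                len(burst_iv) and np.any((burst_iv[:, 0] < e) & (burst_iv[:, 1] > s))
            )
            sup_runs = _drop_short(_runs(~seg_active), min_sup_n)
            if has_burst and len(sup_runs):
                cls = EpochClass.BURST_SUPPRESSION
            else:
                cls = EpochClass.CONTINUOUS
        labels.append(
            EpochLabel(epoch_index=k, t_start=record.t0 + s / fs, label=cls)
        )
    return labels


def burst_onset_time(bursts: list[BurstEvent]) -> float:
    """Onset of the first burst, minutes from ROSC; NaN if no bursts."""
    if not bursts:
        return float("nan")
    return min(b.onset for b in bursts) / 60.0


def recovery_time(labels: list[EpochLabel]) -> float:
    """Start of durable continuous background, minutes from ROSC.

    The first continuous epoch after which every remaining labeled epoch is
    continuous; NaN if the record never reaches that state.
    """
    idx = None
    for lab in labels:
        if lab.label is EpochClass.CONTINUOUS:
            if idx is None:
                idx = lab
        else:
            idx = None
    return float("nan") if idx is None else idx.t_start / 60.0


def burst_frequency(
    bursts: list[BurstEvent],
    bin_width: float = 10.0,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Burst-onset counts per time bin, as bursts/min.

    Parameters are in minutes from ROSC; ``window`` defaults to the first
    two hours. Returns ``(bin_starts_min, rate_per_min)``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if window is None:
        window = (0.0, 120.0)
    start, end = window
    edges = np.arange(start, end + 1e-9, bin_width)
    if edges[-1] < end:
        edges = np.r_[edges, end]
    onsets_min = np.array([b.onset / 60.0 for b in bursts])
    counts, _ = np.histogram(onsets_min, bins=edges)
    widths = np.diff(edges)
    return edges[:-1], counts / widths


def compute_recovery_metrics(
    record: EEGRecord,
    bin_width: float = 10.0,
    freq_window: tuple[float, float] | None = None,
) -> tuple[RecoveryMetrics, list[BurstEvent], list[EpochLabel]]:
    """Condition → detect → classify → summarize one record.

    The returned burst list is restricted to the burst-suppression period:
    once continuous background is durably restored its unbroken
    supra-threshold activity would otherwise register as one giant event.
    """
    rec = condition(record)
    bursts = detect_bursts(rec)
    labels = classify_epochs(rec, bursts)
    onset = burst_onset_time(bursts)
    recov = recovery_time(labels)
    if np.isfinite(recov):
        bursts = [b for b in bursts if b.onset < recov * 60.0]
    if freq_window is None:
        end = recov if np.isfinite(recov) else rec.t0 / 60.0 + rec.duration / 60.0
        freq_window = (onset if np.isfinite(onset) else 0.0, max(end, 1e-6))
    bins, freq = burst_frequency(bursts, bin_width=bin_width, window=freq_window)
    return (
        RecoveryMetrics(
            burst_onset_min=onset,
            recovery_min=recov,
            burst_freq=freq,
            burst_freq_bins=bins,
        ),
        bursts,
        labels,
    )
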