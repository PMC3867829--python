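"""Core containers for two-channel EEG recordings and derived annotations.

All times are seconds relative to ROSC (return of spontaneous circulation)
unless a field name says otherwise; ``EEGRecord.t0`` anchors the first sample
on that axis so recordings that start mid-way remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: Amplitude (µV) a deflection must exceed to count as EEG activity / a burst.
BURST_THRESHOLD_UV = 10.0
#: Minimum suppression (interburst) interval, seconds.
MIN_INTERBURST_S = 0.5
#: Epoch length used for pattern classification and spectral entropy, seconds.
EPOCH_S = 60.0


class EpochClass(str, Enum):
    """Three-way EEG background pattern taxonomy."""

    ISOELECTRIC = "isoelectric"
    BURST_SUPPRESSION = "burst_suppression"
    CONTINUOUS = "continuous"


@dataclass
class RecordingLog:
    """Ground-truth event log written by the synthetic generator.

    Serves as the oracle for parameter-recovery tests: stage boundaries and
    every placed burst are recorded exactly as generated.
    """

    isoelectric_end: float  # s from ROSC; start of burst-suppression stage
    bs_end: float  # s from ROSC; start of continuous background stage
    burst_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    burst_durations: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_bursts(self) -> int:
        return len(self.burst_onsets)


@dataclass
class EEGRecord:
    """Two-channel EEG in microvolts at a fixed sample rate.

    Parameters
    ----------
    data : ndarray, shape (2, n_samples)
        Left and right channel samples, µV.
    fs : float
        Sample rate, Hz (nominally 300).
    t0 : float
        Time of the first sample, seconds from ROSC.
    labels : tuple of str
        Channel labels, default ``("EEG-L", "EEG-R")``.
    log : RecordingLog, optional
        Generator ground truth when the record is synthetic.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    labels: tuple[str, str] = ("EEG-L", "EEG-R")
    log: RecordingLog | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != 2:
            raise ValueError(
                f"expected 2 channels, got {self.data.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds from ROSC."""
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class BurstEvent:
    """A detected burst: supra-threshold activity on both channels."""

    onset: float  # s from ROSC
    offset: float  # s from ROSC
    peak_amp: tuple[float, float]  # µV, (left, right)

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("burst offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class EpochLabel:
    """Pattern class of one nonoverlapping 60 s epoch."""

    epoch_index: int
    t_start: float  # s from ROSC
    label: EpochClass


@dataclass
class RecoveryMetrics:
    """Per-animal EEG recovery summary.

    ``burst_onset_min`` and ``recovery_min`` are minutes from ROSC; either is
    NaN when the corresponding event never occurs in the record.
    ``burst_freq`` is bursts/min per time bin over the burst-suppression
    period, with ``burst_freq_bins`` giving the bin start times in minutes.
    """

    burst_onset_min: float
    recovery_min: float
    burst_freq: np.ndarray
    burst_freq_bins: np.ndarray

    def __post_init__(self) -> None:
        ok = np.isnan(self.burst_onset_min) or np.isnan(self.recovery_min)
        if not ok and self.burst_onset_min > self.recovery_min:
            raise ValueError("burst onset cannot follow continuous recovery")
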