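"""File formats and configuration.

Signals travel as EDF (two signals ``EEG-L``/``EEG-R``, physical dimension
µV) or as a plain CSV dialect with columns ``time_s, ch_left_uV,
ch_right_uV``. Cohort tables, per-animal metrics, epoch labels and entropy
series are CSV; statistics and the run manifest are JSON; pipeline
configuration is YAML or JSON.

EDF reading goes through MNE's EDF reader. Writing uses a minimal 16-bit
EDF writer (header + int16 data records, symmetric physical range over the
recorded extremes), sufficient for round-tripping two-channel µV signals at
a fixed rate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import EEGRecord
from .stats import NDS_CATEGORIES, NDSRecord
from .synth import AnimalOutcome

__all__ = [
    "read_eeg",
    "write_eeg",
    "write_cohort_csv",
    "read_cohort_csv",
    "PipelineConfig",
    "load_config",
    "save_config",
    "RunManifest",
]

_EDF_DIGITAL = (-32768, 32767)


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(path: Path, record: EEGRecord) -> None:
    fs = record.fs
    rec_dur = 1.0
    spr = int(round(fs * rec_dur))
    if abs(spr - fs * rec_dur) > 1e-9:
        raise ValueError("EDF writer requires an integer number of samples/s")
    n = record.n_samples
    n_rec = int(np.ceil(n / spr))
    n_ch = 2
    pmax = float(max(1.0, np.abs(record.data).max()) * 1.0001)
    pmin = -pmax
    dmin, dmax = _EDF_DIGITAL

    hdr = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field(f"Startdate X X X X t0={record.t0:g}s", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (n_ch + 1), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field(f"{rec_dur:g}", 8),
            _edf_field(n_ch, 4),
        ]
        + [_edf_field(lbl, 16) for lbl in record.labels]
        + [_edf_field("AgAgCl electrode", 80)] * n_ch
        + [_edf_field("uV", 8)] * n_ch
        + [_edf_field(f"{pmin:.7g}", 8)] * n_ch
        + [_edf_field(f"{pmax:.7g}", 8)] * n_ch
        + [_edf_field(dmin, 8)] * n_ch
        + [_edf_field(dmax, 8)] * n_ch
        + [_edf_field("", 80)] * n_ch
        + [_edf_field(spr, 8)] * n_ch
        + [_edf_field("", 32)] * n_ch
    )
    gain = (dmax - dmin) / (pmax - pmin)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for ch in range(n_ch):
                seg = record.data[ch, r * spr : (r + 1) * spr]
                if len(seg) < spr:
                    seg = np.pad(seg, (0, spr - len(seg)))
                digital = np.round((seg - pmin) * gain + dmin).astype("<i2")
                fh.write(digital.tobytes())


def _read_edf(path: Path) -> EEGRecord:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if len(raw.ch_names) < 2:
        raise ValueError(
            f"EDF file {path} has {len(raw.ch_names)} channel(s); two EEG "
            "channels required"
        )
    data_uv = raw.get_data()[:2] * 1e6  # MNE loads EEG in volts
    # time origin is stashed in the header's 80-byte recording-id field,
    # which MNE does not surface — grab the token straight from the header
    t0 = 0.0
    with open(path, "rb") as fh:
        fh.seek(88)
        rec_id = fh.read(80).decode("ascii", errors="replace")
    for token in rec_id.split():
        if token.startswith("t0=") and token.endswith("s"):
            t0 = float(token[3:-1])
    labels = tuple(name.removeprefix("EEG ").strip() for name in raw.ch_names[:2])
    return EEGRecord(
        data=data_uv, fs=float(raw.info["sfreq"]), t0=t0, labels=labels
    )


def write_eeg(path: str | Path, record: EEGRecord, format: str | None = None) -> Path:
    """Write a two-channel record as EDF or CSV (inferred from the suffix)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        _write_edf(path, record)
    elif fmt == "csv":
        pd.DataFrame(
            {
                "time_s": record.times,
                "ch_left_uV": record.data[0],
                "ch_right_uV": record.data[1],
            }
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported signal format {fmt!r}")
    return path


def read_eeg(path: str | Path, format: str | None = None) -> EEGRecord:
    """Read a two-channel EEG record from EDF or CSV.

    For CSV, the sample rate is inferred from the median spacing of the
    ``time_s`` column and the time origin from its first value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        df = pd.read_csv(path)
        required = {"time_s", "ch_left_uV", "ch_right_uV"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"signal CSV must have columns {sorted(required)}; "
                f"got {list(df.columns)}"
            )
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        return EEGRecord(
            data=np.vstack([df["ch_left_uV"], df["ch_right_uV"]]),
            fs=1.0 / dt,
            t0=float(df["time_s"].iloc[0]),
        )
    raise ValueError(f"unsupported signal format {fmt!r}")


def write_cohort_csv(path: str | Path, outcomes: list[AnimalOutcome]) -> Path:
    """Cohort table: one row per animal, NDS per category per day, survival."""
    rows = []
    for o in outcomes:
        row: dict = {
            "animal_id": o.animal_id,
            "group": o.group,
            "true_isoelectric_end_s": o.true_isoelectric_end,
            "true_bs_end_s": o.true_bs_end,
            "survival_hr": o.survival_hr,
            "event": o.event,
        }
        for i, frac in enumerate(o.band_fractions):
            row[f"band_fraction_{i}"] = frac
        for day, rec in o.nds_by_day.items():
            for cat in NDS_CATEGORIES:
                row[f"nds_day{day}_{cat}"] = getattr(rec, cat)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_cohort_csv(path: str | Path) -> list[AnimalOutcome]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        nds = {}
        for day in (1, 2, 3, 4):
            cols = {cat: f"nds_day{day}_{cat}" for cat in NDS_CATEGORIES}
            if all(c in row and pd.notna(row[c]) for c in cols.values()):
                nds[day] = NDSRecord(
                    day=day, **{cat: int(row[c]) for cat, c in cols.items()}
                )
        fracs = tuple(
            row[c] for c in df.columns if c.startswith("band_fraction_")
        )
        out.append(
            AnimalOutcome(
                animal_id=str(row["animal_id"]),
                group=str(row["group"]),
                true_isoelectric_end=float(row["true_isoelectric_end_s"]),
                true_bs_end=float(row["true_bs_end_s"]),
                band_fractions=fracs,
                nds_by_day=nds,
                survival_hr=float(row["survival_hr"]),
                event=int(row["event"]),
            )
        )
    return out


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (mirrors the module-level defaults)."""

    outdir: str = "qeeg_out"
    seed: int = 0
    n_per_group: int = 10
    fs: float = 300.0
    time_scale: float = 1.0 / 6.0
    epoch_s: float = 60.0
    burst_threshold_uv: float = 10.0
    interburst_gap_s: float = 0.5
    welch_segment_s: float = 10.0
    welch_overlap: float = 0.5
    band_edges: tuple[float, ...] = (0.5, 4.0, 8.0, 13.0, 30.0)
    freq_bin_min: float = 10.0
    write_edf: bool = False

    def __post_init__(self) -> None:
        if self.epoch_s <= 0 or self.fs < 100:
            raise ValueError("invalid epoch length or sample rate")
        if self.burst_threshold_uv <= 0 or self.interburst_gap_s <= 0:
            raise ValueError("threshold and gap must be positive")
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("welch_overlap must be in [0, 1)")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    payload = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "band_edges" in payload:
        payload["band_edges"] = tuple(payload["band_edges"])
    return PipelineConfig(**payload)


def save_config(path: str | Path, config: PipelineConfig) -> Path:
    payload = dataclasses.asdict(config)
    payload["band_edges"] = list(payload["band_edges"])
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
    return Path(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written once per pipeline run."""

    config: dict
    software_version: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.input_checksums[p.name] = _sha256(p)

    def write(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return Path(path)
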