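"""EEG and tabular I/O: recordings, analysis segments, clinical and course tables.

Recordings are multichannel resting EEG from an eight-electrode 10-20
montage (F3, F4, C3, C4, P3, P4, O1, O2) sampled at 500 Hz.  Analysis works
on 30 s artifact-free eyes-closed segments (15,000 samples), two per
session.  The acquisition bandpass (1.5-120 Hz) is treated as a property of
the hardware: readers never filter, resample or re-reference, since such
processing can distort the non-linear structure the entropy analysis
measures.

Conventions: 0-based sample indices, half-open time windows
[start, start + duration) in seconds, amplitudes in microvolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONTAGE_8",
    "CONDITIONS",
    "Recording",
    "TimeSeriesSegment",
    "SessionRecord",
    "read_recording",
    "write_matrix_csv",
    "extract_segments",
    "flag_artifacts",
    "read_clinical_table",
    "read_course_table",
    "validate_course_table",
]

#: The eight-electrode montage used throughout.
MONTAGE_8 = ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")

#: Treatment-condition vocabulary for a session.
CONDITIONS = ("pre_ect", "during_ect", "after_ect", "lorazepam")

#: Required columns of an ECT course table (one row per stimulation).
COURSE_COLUMNS = ("session", "stimulation", "percent_energy", "charge_mC", "seizure_duration_s")


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    data is channels x samples; channel_labels are unique 10-20 names.
    """

    channel_labels: list[str]
    data: np.ndarray
    sampling_rate_hz: float
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass
class TimeSeriesSegment:
    """One channel's artifact-free analysis segment.

    The canonical protocol uses 30 s at 500 Hz = 15,000 samples; shorter
    segments are allowed for testing and scaled-down runs.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channel: str = ""
    segment_index: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("segment samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n / self.sampling_rate_hz


@dataclass
class SessionRecord:
    """One EEG session: two segments per channel plus clinical context."""

    session_id: str
    condition: str
    segments: dict[str, tuple[TimeSeriesSegment, TimeSeriesSegment]]
    bfcrs: int | None = None
    bdnf_ng_ml: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        for ch, pair in self.segments.items():
            if len(pair) != 2:
                raise ValueError(f"channel {ch}: exactly 2 segments required")
        if self.bfcrs is not None and self.bfcrs < 0:
            raise ValueError("BFCRS score cannot be negative")
        if self.bdnf_ng_ml is not None and not self.bdnf_ng_ml > 0:
            raise ValueError("BDNF concentration must be positive")


def _normalize_label(raw: str) -> str:
    """Map an EDF channel label onto a bare 10-20 name (EEG F3-A2 -> F3)."""
    s = raw.strip()
    if s.upper().startswith("EEG"):
        s = s[3:].lstrip(" :")
    s = s.split("-")[0].strip()
    return s.upper()


def read_recording(
    path: str | Path,
    format: Literal["edf", "matrix_csv"] | None = None,
    session_id: str | None = None,
    require_montage: bool = True,
) -> Recording:
    """Read an EEG recording from an EDF/EDF+ file or a matrix CSV.

    Matrix CSV: header row of channel labels, one row per sample, values in
    microvolts; the sampling rate is taken from a ``# sampling_rate_hz=``
    comment on the first line (default 500).  EDF: physical units are
    normalized to microvolts; channel labels are case-normalized and
    reference suffixes stripped before matching the montage.

    With ``require_montage`` the eight montage channels must all be present
    and the result is restricted to them, in montage order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix_csv"
    if format == "edf":
        labels, data, rate = _read_edf(path)
    elif format == "matrix_csv":
        labels, data, rate = _read_matrix_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    if require_montage:
        norm = {_normalize_label(l): i for i, l in enumerate(labels)}
        missing = [ch for ch in MONTAGE_8 if ch not in norm]
        if missing:
            raise ValueError(f"missing required channels: {', '.join(missing)}")
        idx = [norm[ch] for ch in MONTAGE_8]
        labels = list(MONTAGE_8)
        data = data[idx]
    return Recording(
        channel_labels=list(labels),
        data=data,
        sampling_rate_hz=rate,
        session_id=session_id or path.stem,
    )


def _read_edf(path: Path) -> tuple[list[str], np.ndarray, float]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    rates = {raw.info["sfreq"]}
    if len(rates) != 1:
        raise ValueError("non-uniform sampling rate across channels")
    data = raw.get_data() * 1e6  # mne returns volts; normalize to microvolts
    return list(raw.ch_names), data, float(raw.info["sfreq"])


def _read_matrix_csv(path: Path) -> tuple[list[str], np.ndarray, float]:
    rate = 500.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].replace(",", " ").split():
                if token.startswith("sampling_rate_hz="):
                    rate = float(token.split("=", 1)[1])
            header_row = 1
        else:
            header_row = 0
    df = pd.read_csv(path, skiprows=header_row)
    if df.empty:
        raise ValueError(f"empty matrix file: {path}")
    return [str(c) for c in df.columns], df.to_numpy(dtype=float).T, rate


def write_matrix_csv(
    rec: Recording, path: str | Path, float_format: str = "%.6f"
) -> None:
    """Write a recording as a matrix CSV readable by :func:`read_recording`."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={rec.sampling_rate_hz:g}\n")
        df.to_csv(fh, index=False, float_format=float_format)


def extract_segments(
    rec: Recording,
    markers: Sequence[tuple[float, float]],
    channels: Sequence[str] | None = None,
) -> dict[str, list[TimeSeriesSegment]]:
    """Cut analysis segments out of a recording at the given markers.

    Each marker is (start_s, duration_s); the window is half-open, sample
    exact and never resampled.  duration * rate must be integral.  Returns a
    per-channel list of segments in marker order, segment_index starting at 1.
    Overlapping markers are allowed with a warning.
    """
    rate = rec.sampling_rate_hz
    windows: list[tuple[int, int]] = []
    for start_s, dur_s in markers:
        n = dur_s * rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"duration {dur_s}s is not a whole number of samples at {rate} Hz")
        i0 = int(round(start_s * rate))
        i1 = i0 + int(round(n))
        if i0 < 0 or i1 > rec.n_samples:
            raise ValueError(
                f"window [{start_s}, {start_s + dur_s})s out of bounds for "
                f"{rec.n_samples / rate:g}s recording"
            )
        windows.append((i0, i1))
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            warnings.warn("segment windows overlap", stacklevel=2)
    channels = list(channels) if channels is not None else list(rec.channel_labels)
    out: dict[str, list[TimeSeriesSegment]] = {}
    for ch in channels:
        sig = rec.channel(ch)
        out[ch] = [
            TimeSeriesSegment(
                samples=sig[i0:i1].copy(),
                sampling_rate_hz=rate,
                channel=ch,
                segment_index=k + 1,
            )
            for k, (i0, i1) in enumerate(windows)
        ]
    return out


def flag_artifacts(
    seg: TimeSeriesSegment, amp_limit_uv: float = 100.0, grad_limit_uv: float = 50.0
) -> bool:
    """Automated stand-in for visual artifact rejection.

    Returns True (clean) unless any sample exceeds ``amp_limit_uv`` in
    magnitude or any successive-sample step exceeds ``grad_limit_uv``.
    Defaults approximate conventional clinical rejection thresholds.
    """
    if amp_limit_uv <= 0 or grad_limit_uv <= 0:
        raise ValueError("artifact limits must be positive")
    x = seg.samples
    if np.any(np.abs(x) > amp_limit_uv):
        return False
    if x.size > 1 and np.any(np.abs(np.diff(x)) > grad_limit_uv):
        return False
    return True


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the per-session clinical table.

    CSV columns: session (id), condition (four-level vocabulary), bfcrs
    (non-negative integer, may be blank), bdnf_ng_ml (positive, usually
    blank: serum BDNF is sampled sparsely).  Returns a DataFrame indexed by
    session id with NaN for missing values.
    """
    df = pd.read_csv(path, dtype={"session": str})
    if df.empty:
        raise ValueError(f"empty clinical table: {path}")
    required = {"session", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"clinical table must have columns {sorted(required)}")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    for col in ("bfcrs", "bdnf_ng_ml"):
        if col not in df.columns:
            df[col] = np.nan
    if (df["bfcrs"].dropna() < 0).any():
        raise ValueError("negative BFCRS score")
    if (df["bdnf_ng_ml"].dropna() <= 0).any():
        raise ValueError("non-positive BDNF concentration")
    return df.set_index("session")


def validate_course_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an ECT course table (one row per stimulation)."""
    missing = set(COURSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"course table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("empty course table")
    if (df["charge_mC"] <= 0).any():
        raise ValueError("charge must be positive")
    if (df["seizure_duration_s"] < 0).any():
        raise ValueError("seizure duration cannot be negative")
    sessions = sorted(df["session"].unique())
    if sessions != list(range(1, len(sessions) + 1)):
        raise ValueError("session numbers must be contiguous from 1")
    return df


def read_course_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an ECT course table CSV."""
    return validate_course_table(pd.read_csv(path))
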