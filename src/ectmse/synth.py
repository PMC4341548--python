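"""Synthetic surrogate study: multichannel EEG, clinical course, ECT table.

The recorded patient EEG behind the treatment-course analysis is not
publicly deposited, so this module generates a complete surrogate study
with the same design: 24 sessions (3 pre-ECT, 7 during ECT, 8 after ECT, 6
under lorazepam), two 30 s eyes-closed segments per session, eight 10-20
channels at 500 Hz.

Each channel signal is built mechanistically rather than by targeting
entropy values, so that entropy estimation remains an honest test:

* a 1/f^beta Gaussian background (spectral synthesis, beta = 1 by default),
* a 10 Hz alpha oscillation with a slowly drifting envelope, strongest
  occipitally (the posterior dominant rhythm),
* fine-scale regularity injection: a fraction ``lam_f`` of the background is
  replaced by a short-window moving average of itself, which makes
  neighbouring samples predictable and lowers SampEn at small scale factors,
* coarse-scale variability injection: band-limited (0.5-6 Hz) Gaussian slow
  activity added with weight ``lam_c``, which survives coarse-graining and
  raises SampEn at large scale factors.

Condition effect maps set ``lam_f`` frontocentrally and ``lam_c``
occipitally so that ECT lowers fine-scale complexity over F3/F4/C3/C4 and
raises coarse-scale complexity over O1/O2, while lorazepam improves the
clinical score without moving either.  The clinical model gives a high
pre-ECT catatonia score that falls during ECT, partially relapses after,
and falls again under lorazepam; serum BDNF rises with ECT and is observed
at only a few sessions, as in sparse serum sampling.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    CONDITIONS,
    MONTAGE_8,
    Recording,
    SessionRecord,
    TimeSeriesSegment,
    validate_course_table,
    write_matrix_csv,
)

__all__ = [
    "GeneratorConfig",
    "ChannelEffect",
    "generate_channel_signal",
    "generate_study",
    "table1_fixture",
    "write_study",
]

_GROUPS = {
    "frontocentral": ("F3", "F4", "C3", "C4"),
    "parietal": ("P3", "P4"),
    "occipital": ("O1", "O2"),
}

#: Relative alpha amplitude per channel: posterior-dominant gradient.
DEFAULT_ALPHA_AMP = {
    "F3": 0.25, "F4": 0.25, "C3": 0.4, "C4": 0.4,
    "P3": 0.8, "P4": 0.8, "O1": 1.2, "O2": 1.2,
}

#: Fine-scale regularity mixing fraction per group and condition.
DEFAULT_LAM_F = {
    "frontocentral": {"pre_ect": 0.0, "during_ect": 0.65, "after_ect": 0.45, "lorazepam": 0.45},
    "parietal": {"pre_ect": 0.0, "during_ect": 0.3, "after_ect": 0.2, "lorazepam": 0.2},
    "occipital": {"pre_ect": 0.0, "during_ect": 0.0, "after_ect": 0.0, "lorazepam": 0.0},
}

#: Coarse-scale slow-variability weight per group and condition.
DEFAULT_LAM_C = {
    "frontocentral": {"pre_ect": 0.0, "during_ect": 0.0, "after_ect": 0.0, "lorazepam": 0.0},
    "parietal": {"pre_ect": 0.05, "during_ect": 0.4, "after_ect": 0.3, "lorazepam": 0.3},
    "occipital": {"pre_ect": 0.1, "during_ect": 0.9, "after_ect": 0.6, "lorazepam": 0.6},
}


@dataclass(frozen=True)
class ChannelEffect:
    """Signal-composition parameters for one channel in one condition."""

    background_exponent: float = 1.0
    alpha_amp: float = 0.0
    fine_scale_regularity: float = 0.0  # lam_f in [0, 1]
    coarse_scale_variability: float = 0.0  # lam_c >= 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fine_scale_regularity <= 1.0:
            raise ValueError("fine_scale_regularity must be in [0, 1]")
        if self.coarse_scale_variability < 0:
            raise ValueError("coarse_scale_variability must be >= 0")
        if self.background_exponent < 0:
            raise ValueError("background exponent must be >= 0")


@dataclass
class GeneratorConfig:
    """Configuration of the surrogate study.

    Defaults reproduce the study design: 24 sessions split 3/7/8/6 across
    pre-ECT, during-ECT, after-ECT and lorazepam, 30 s segments at 500 Hz,
    signal SD 20 microvolts.
    """

    seed: int = 0
    n_sessions_per_condition: dict[str, int] = field(
        default_factory=lambda: {
            "pre_ect": 3, "during_ect": 7, "after_ect": 8, "lorazepam": 6
        }
    )
    sampling_rate_hz: float = 500.0
    segment_s: float = 30.0
    n_segments: int = 2
    sd_uv: float = 20.0
    background_exponent: float = 1.0
    alpha_amp: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHA_AMP))
    lam_f: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_LAM_F)
    )
    lam_c: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_LAM_C)
    )
    # clinical model (BFCRS points, BDNF ng/ml)
    bfcrs_pre: float = 35.0
    bfcrs_during: tuple[float, float] = (30.0, 10.0)  # start -> end of ECT course
    bfcrs_after: tuple[float, float] = (14.0, 22.0)  # partial relapse
    bfcrs_lorazepam: tuple[float, float] = (8.0, 3.0)
    bfcrs_noise_sd: float = 1.5
    bdnf_pre: float = 5.0
    bdnf_peak: float = 14.0
    bdnf_noise_sd: float = 0.5
    #: session positions (1-based, chronological) with a serum BDNF draw
    bdnf_sessions: tuple[int, ...] = (2, 7, 13, 21)

    def __post_init__(self) -> None:
        for cond, n in self.n_sessions_per_condition.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if n < 1:
                raise ValueError("session counts must be >= 1")
        if self.segment_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("segment length and sampling rate must be positive")

    def effect(self, channel: str, condition: str) -> ChannelEffect:
        group = next(g for g, chs in _GROUPS.items() if channel in chs)
        return ChannelEffect(
            background_exponent=self.background_exponent,
            alpha_amp=self.alpha_amp[channel],
            fine_scale_regularity=self.lam_f[group][condition],
            coarse_scale_variability=self.lam_c[group][condition],
        )


def _spectral_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    beta: float,
    f_lo: float | None = None,
    f_hi: float | None = None,
) -> np.ndarray:
    """Unit-SD Gaussian noise with a 1/f^beta (optionally band-limited) spectrum."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-beta / 2.0)
    if f_lo is not None:
        amp[freqs < f_lo] = 0.0
    if f_hi is not None:
        amp[freqs > f_hi] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, len(freqs))
    x = np.fft.irfft(amp * np.exp(1j * phases), n)
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate spectral band")
    return x / sd


_SMOOTH_WINDOW = 5  # samples (10 ms at 500 Hz); sets the regularity scale


def generate_channel_signal(
    cfg: GeneratorConfig,
    channel: str,
    condition: str,
    rng: np.random.Generator,
    segment_index: int = 1,
) -> TimeSeriesSegment:
    """One channel's synthetic eyes-closed segment for one condition."""
    eff = cfg.effect(channel, condition)
    n = int(round(cfg.segment_s * cfg.sampling_rate_hz))
    fs = cfg.sampling_rate_hz

    bg = _spectral_noise(rng, n, fs, eff.background_exponent)
    lam_f = eff.fine_scale_regularity
    if lam_f > 0:
        kernel = np.ones(_SMOOTH_WINDOW) / _SMOOTH_WINDOW
        smooth = np.convolve(bg, kernel, mode="same")
        smooth /= smooth.std()
        bg = (1.0 - lam_f) * bg + lam_f * smooth
        bg /= bg.std()

    sig = bg
    if eff.alpha_amp > 0:
        t = np.arange(n) / fs
        envelope = np.clip(1.0 + 0.5 * _spectral_noise(rng, n, fs, 0.0, 0.1, 1.0), 0.0, None)
        sig = sig + eff.alpha_amp * envelope * np.sin(
            2.0 * np.pi * 10.0 * t + rng.uniform(0.0, 2.0 * np.pi)
        )
    if eff.coarse_scale_variability > 0:
        sig = sig + eff.coarse_scale_variability * _spectral_noise(rng, n, fs, 0.0, 0.5, 6.0)

    sig = cfg.sd_uv * sig / sig.std()
    return TimeSeriesSegment(
        samples=sig, sampling_rate_hz=fs, channel=channel, segment_index=segment_index
    )


def _clinical_trajectory(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    order = ["pre_ect", "during_ect", "after_ect", "lorazepam"]
    pos = 0
    for cond in order:
        n = cfg.n_sessions_per_condition[cond]
        if cond == "pre_ect":
            targets = np.full(n, cfg.bfcrs_pre)
        elif cond == "during_ect":
            targets = np.linspace(*cfg.bfcrs_during, n)
        elif cond == "after_ect":
            targets = np.linspace(*cfg.bfcrs_after, n)
        else:
            targets = np.linspace(*cfg.bfcrs_lorazepam, n)
        for k in range(n):
            pos += 1
            score = targets[k] + rng.normal(0.0, cfg.bfcrs_noise_sd)
            rows.append(
                {
                    "session": f"S{pos:02d}",
                    "position": pos,
                    "condition": cond,
                    "bfcrs": int(max(0, round(score))),
                    "bdnf_ng_ml": np.nan,
                }
            )
    df = pd.DataFrame(rows)
    # BDNF: low pre-ECT, rising through the ECT course, sustained after
    n_total = len(df)
    n_pre = cfg.n_sessions_per_condition["pre_ect"]
    n_during = cfg.n_sessions_per_condition["during_ect"]
    ect_end = n_pre + n_during
    for sess_pos in cfg.bdnf_sessions:
        if not 1 <= sess_pos <= n_total:
            continue
        if sess_pos <= n_pre:
            level = cfg.bdnf_pre
        elif sess_pos <= ect_end:
            frac = (sess_pos - n_pre) / n_during
            level = cfg.bdnf_pre + frac * (cfg.bdnf_peak - cfg.bdnf_pre)
        else:
            level = cfg.bdnf_peak - 0.1 * (sess_pos - ect_end)
        val = max(0.1, level + rng.normal(0.0, cfg.bdnf_noise_sd))
        df.loc[df["position"] == sess_pos, "bdnf_ng_ml"] = round(val, 2)
    return df


def generate_study(
    cfg: GeneratorConfig, channels: tuple[str, ...] = MONTAGE_8
) -> tuple[list[SessionRecord], pd.DataFrame]:
    """Generate the full surrogate study.

    Returns the chronologically ordered session records (24 by default, two
    segments per channel each) and the ECT course table, which defaults to
    the in-course stimulation log (:func:`table1_fixture`).  Identical seed
    and config reproduce the study exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    clinical = _clinical_trajectory(cfg, rng)
    sessions: list[SessionRecord] = []
    for _, row in clinical.iterrows():
        segs: dict[str, tuple[TimeSeriesSegment, TimeSeriesSegment]] = {}
        for ch in channels:
            pair = tuple(
                generate_channel_signal(cfg, ch, row["condition"], rng, segment_index=k + 1)
                for k in range(cfg.n_segments)
            )
            segs[ch] = pair  # type: ignore[assignment]
        sessions.append(
            SessionRecord(
                session_id=row["session"],
                condition=row["condition"],
                segments=segs,
                bfcrs=int(row["bfcrs"]),
                bdnf_ng_ml=None if pd.isna(row["bdnf_ng_ml"]) else float(row["bdnf_ng_ml"]),
            )
        )
    return sessions, table1_fixture()


def table1_fixture() -> pd.DataFrame:
    """The recorded ECT stimulation log: eight stimulations over seven sessions.

    Charges follow a titration from the 30% energy seizure threshold; the
    seventh session's first stimulation (5% energy) failed to induce a
    seizure (duration 0) and was followed by a second, effective one.
    """
    df = pd.DataFrame(
        {
            "session": [1, 2, 3, 4, 5, 6, 7, 7],
            "stimulation": [1, 1, 1, 1, 1, 1, 1, 2],
            "percent_energy": [30, 25, 20, 15, 10, 10, 5, 10],
            "charge_mC": [151.1, 125.2, 100.1, 74.7, 49.8, 49.8, 49.8, 49.8],
            "seizure_duration_s": [54, 69, 55, 57, 60, 70, 0, 78],
        }
    )
    return validate_course_table(df)


def write_study(
    cfg: GeneratorConfig, out_dir: str | Path, channels: tuple[str, ...] = MONTAGE_8
) -> Path:
    """Write a generated study to disk in the formats the readers consume.

    Per session a matrix CSV with both segments concatenated, plus
    clinical.csv, course.csv and manifest.yaml with per-session file paths
    and segment markers.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions, course = generate_study(cfg, channels)
    manifest: dict = {"sampling_rate_hz": cfg.sampling_rate_hz, "sessions": []}
    clin_rows = []
    for rec in sessions:
        data = np.vstack(
            [
                np.concatenate([seg.samples for seg in rec.segments[ch]])
                for ch in channels
            ]
        )
        fname = f"{rec.session_id}.csv"
        write_matrix_csv(
            Recording(
                channel_labels=list(channels),
                data=data,
                sampling_rate_hz=cfg.sampling_rate_hz,
                session_id=rec.session_id,
            ),
            out_dir / fname,
        )
        markers = [
            [round(k * cfg.segment_s, 6), cfg.segment_s] for k in range(cfg.n_segments)
        ]
        manifest["sessions"].append(
            {"session": rec.session_id, "file": fname, "markers": markers}
        )
        clin_rows.append(
            {
                "session": rec.session_id,
                "condition": rec.condition,
                "bfcrs": rec.bfcrs,
                "bdnf_ng_ml": rec.bdnf_ng_ml if rec.bdnf_ng_ml is not None else "",
            }
        )
    pd.DataFrame(clin_rows).to_csv(out_dir / "clinical.csv", index=False)
    course.to_csv(out_dir / "course.csv", index=False)
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
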