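"""End-to-end orchestration: files in, tidy tables and a report bundle out.

Stages compose through tidy long-format CSVs (one row per session x channel
x segment x scale factor for MSE; per frequency bin for spectra), so the
file-driven CLI chain produces exactly what the in-process pipeline does.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import course as course_mod
from .course import (
    ComplexitySummary,
    clinical_association,
    condition_average,
    ect_course_summary,
    reproducibility_correlation,
    summarize_session,
)
from .entropy import EntropyParams, MSECurve, average_segments, mse_curve
from .io import (
    CONDITIONS,
    MONTAGE_8,
    SessionRecord,
    extract_segments,
    flag_artifacts,
    read_clinical_table,
    read_course_table,
    read_recording,
)
from .spectral import alpha_dominance_check, power_spectrum

logger = logging.getLogger("ectmse")

__all__ = [
    "PipelineConfig",
    "load_study",
    "mse_table",
    "spectra_table",
    "curves_by_session",
    "summaries_from_curves",
    "run_pipeline",
]

MSE_SCHEMA = ["session", "condition", "channel", "segment", "sf", "sampen"]
SPECTRA_SCHEMA = ["session", "condition", "channel", "freq_hz", "log_power"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; YAML-loadable."""

    manifest: str = ""
    clinical: str = ""
    course: str = ""
    out_dir: str = "results"
    entropy: EntropyParams = field(default_factory=EntropyParams)
    epoch_s: float = 2.0
    log_base: float = 10.0
    amp_limit_uv: float = 100.0
    grad_limit_uv: float = 50.0
    alpha_ratio_threshold: float = 1.0
    scale_factors: tuple[int, ...] | None = None  # None = all 1..max_sf

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        entropy = EntropyParams(**raw.pop("entropy", {}))
        return cls(entropy=entropy, **raw)


def load_study(
    manifest_path: str | Path, clinical_path: str | Path
) -> list[SessionRecord]:
    """Assemble session records from a manifest, per-session files and the clinical table."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not manifest or not manifest.get("sessions"):
        raise ValueError(f"empty manifest: {manifest_path}")
    clinical = read_clinical_table(clinical_path)
    sessions: list[SessionRecord] = []
    for entry in manifest["sessions"]:
        sid = str(entry["session"])
        rec = read_recording(manifest_path.parent / entry["file"], session_id=sid)
        segs = extract_segments(rec, [tuple(m) for m in entry["markers"]])
        crow = clinical.loc[sid]
        sessions.append(
            SessionRecord(
                session_id=sid,
                condition=str(crow["condition"]),
                segments={ch: tuple(lst) for ch, lst in segs.items()},  # type: ignore[arg-type]
                bfcrs=None if pd.isna(crow["bfcrs"]) else int(crow["bfcrs"]),
                bdnf_ng_ml=None if pd.isna(crow["bdnf_ng_ml"]) else float(crow["bdnf_ng_ml"]),
            )
        )
    return sessions


def mse_table(
    sessions: Sequence[SessionRecord],
    params: EntropyParams = EntropyParams(),
    scale_factors: Sequence[int] | None = None,
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy MSE table: one row per session x channel x segment x scale factor."""
    rows = []
    for rec in sessions:
        use = channels if channels is not None else list(rec.segments)
        for ch in use:
            for seg in rec.segments[ch]:
                curve = mse_curve(seg, params, scale_factors=scale_factors)
                sfs = (
                    range(1, params.max_sf + 1)
                    if scale_factors is None
                    else scale_factors
                )
                for sf in sfs:
                    rows.append(
                        {
                            "session": rec.session_id,
                            "condition": rec.condition,
                            "channel": ch,
                            "segment": seg.segment_index,
                            "sf": sf,
                            "sampen": curve.sampen_by_sf[sf - 1],
                        }
                    )
    return pd.DataFrame(rows, columns=MSE_SCHEMA)


def spectra_table(
    sessions: Sequence[SessionRecord],
    epoch_s: float = 2.0,
    log_base: float = 10.0,
    channels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy spectra: per channel, power averaged across both segments' epochs, then logged."""
    rows = []
    for rec in sessions:
        use = channels if channels is not None else list(rec.segments)
        for ch in use:
            specs = [power_spectrum(seg, epoch_s, log_base) for seg in rec.segments[ch]]
            power = np.mean([ps.power for ps in specs], axis=0)
            with np.errstate(divide="ignore"):
                log_power = np.log(power) / np.log(log_base)
            for f, lp in zip(specs[0].freqs_hz, log_power):
                rows.append(
                    {
                        "session": rec.session_id,
                        "condition": rec.condition,
                        "channel": ch,
                        "freq_hz": f,
                        "log_power": lp,
                    }
                )
    return pd.DataFrame(rows, columns=SPECTRA_SCHEMA)


def curves_by_session(
    df: pd.DataFrame, params: EntropyParams = EntropyParams()
) -> dict[str, dict[str, tuple[MSECurve, MSECurve]]]:
    """Rebuild per-session, per-channel segment curve pairs from a tidy MSE table."""
    out: dict[str, dict[str, tuple[MSECurve, MSECurve]]] = {}
    for (session, channel), grp in df.groupby(["session", "channel"], sort=False):
        curves = []
        for seg_idx in (1, 2):
            sub = grp[grp["segment"] == seg_idx]
            arr = np.full(params.max_sf, np.nan)
            arr[sub["sf"].to_numpy(dtype=int) - 1] = sub["sampen"].to_numpy()
            curves.append(
                MSECurve(
                    sampen_by_sf=arr,
                    channel=str(channel),
                    segment_index=seg_idx,
                    params=params,
                )
            )
        out.setdefault(str(session), {})[str(channel)] = (curves[0], curves[1])
    return out


def summaries_from_curves(
    by_session: dict[str, dict[str, tuple[MSECurve, MSECurve]]],
    conditions: dict[str, str],
) -> list[ComplexitySummary]:
    """Segment-average each channel's curves, then summarize each session."""
    out = []
    for session, by_ch in by_session.items():
        averaged = {ch: average_segments(c1, c2) for ch, (c1, c2) in by_ch.items()}
        out.append(
            summarize_session(averaged, session_id=session, condition=conditions[session])
        )
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Writes mse.csv, spectra.csv, summaries.csv and report.json under
    ``cfg.out_dir``; returns the report dict.  Deterministic given inputs.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions = load_study(cfg.manifest, cfg.clinical)
    logger.info("loaded %d sessions", len(sessions))

    # artifact screen and wakefulness check (advisory: flagged, not dropped)
    artifact_flags = {}
    alpha_flags = {}
    for rec in sessions:
        clean = all(
            flag_artifacts(seg, cfg.amp_limit_uv, cfg.grad_limit_uv)
            for pair in rec.segments.values()
            for seg in pair
        )
        artifact_flags[rec.session_id] = bool(clean)
        if "O1" in rec.segments and "O2" in rec.segments:
            alpha_flags[rec.session_id] = bool(
                alpha_dominance_check(
                    power_spectrum(rec.segments["O1"][0], cfg.epoch_s, cfg.log_base),
                    power_spectrum(rec.segments["O2"][0], cfg.epoch_s, cfg.log_base),
                    cfg.alpha_ratio_threshold,
                )
            )

    df_mse = mse_table(sessions, cfg.entropy, scale_factors=cfg.scale_factors)
    df_mse.to_csv(out_dir / "mse.csv", index=False)
    df_spec = spectra_table(sessions, cfg.epoch_s, cfg.log_base)
    df_spec.to_csv(out_dir / "spectra.csv", index=False)

    conditions = {rec.session_id: rec.condition for rec in sessions}
    by_session = curves_by_session(df_mse, cfg.entropy)
    summaries = summaries_from_curves(by_session, conditions)
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out_dir / "summaries.csv", index=False
    )

    cond_means = {
        cond: condition_average(summaries, cond)
        for cond in CONDITIONS
        if any(s.condition == cond for s in summaries)
    }
    repro = (
        reproducibility_correlation(by_session)
        if cfg.scale_factors is None and len(by_session) >= 3
        else None
    )
    clinical = read_clinical_table(cfg.clinical)
    assoc_all = clinical_association(summaries, clinical, on_insufficient="skip")
    assoc_no_lzp = clinical_association(
        summaries, clinical, exclude=("lorazepam",), on_insufficient="skip"
    )

    report = {
        "n_sessions": len(sessions),
        "sessions_per_condition": {
            cond: sum(1 for s in sessions if s.condition == cond) for cond in CONDITIONS
        },
        "artifact_clean": artifact_flags,
        "alpha_dominant": alpha_flags,
        "condition_means": cond_means,
        "reproducibility_r": repro,
        "associations": {
            "all_conditions": _assoc_dict(assoc_all),
            "lorazepam_excluded": _assoc_dict(assoc_no_lzp),
        },
    }
    if cfg.course:
        report["ect_course"] = ect_course_summary(read_course_table(cfg.course))
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("report written to %s", out_dir / "report.json")
    return report


def _assoc_dict(results) -> dict:
    return {
        f"{r.complexity_var}__vs__{r.clinical_var}": {
            "pearson_r": r.pearson_r,
            "n_points": r.n_points,
        }
        for r in results
    }
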