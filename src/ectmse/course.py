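"""Treatment-course aggregation: scale-band summaries, reproducibility, associations.

The per-session complexity read-outs condense each session's
segment-averaged MSE curves into two scalars: the mean SampEn over scale
factors 1-5 across the frontocentral channels (F3, F4, C3, C4), which falls
with ECT, and the mean over scale factors 31-40 across the occipital
channels (O1, O2), which rises.  These are averaged per treatment condition,
checked for two-segment reproducibility via Pearson correlation, and
associated with the clinical course (BFCRS catatonia score, serum BDNF) —
descriptively, as correlation coefficients with their n; no hypothesis
testing is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import MSECurve

__all__ = [
    "FRONTOCENTRAL",
    "OCCIPITAL",
    "REGIONS",
    "FINE_SF_BAND",
    "COARSE_SF_BAND",
    "ComplexitySummary",
    "AssociationResult",
    "summarize_session",
    "condition_average",
    "reproducibility_correlation",
    "clinical_association",
    "ect_course_summary",
]

FRONTOCENTRAL = ("F3", "F4", "C3", "C4")
OCCIPITAL = ("O1", "O2")
#: Electrode pairs for the two-segment reproducibility check.
REGIONS = {"frontal": ("F3", "F4"), "central": ("C3", "C4"), "occipital": ("O1", "O2")}
#: Scale-factor bands (inclusive) for the two summary read-outs.
FINE_SF_BAND = (1, 5)
COARSE_SF_BAND = (31, 40)


@dataclass
class ComplexitySummary:
    """Scale-band x region complexity scalars for one session."""

    session_id: str
    condition: str
    frontocentral_low_sf: float
    occipital_high_sf: float
    n_missing: int = 0


@dataclass
class AssociationResult:
    """Pearson association between a complexity summary and a clinical variable."""

    complexity_var: str
    clinical_var: str
    pearson_r: float
    n_points: int
    excluded_conditions: tuple[str, ...] = ()
    points: pd.DataFrame | None = field(default=None, repr=False)


def _band_values(
    curves: Mapping[str, MSECurve], channels: Sequence[str], band: tuple[int, int]
) -> np.ndarray:
    lo, hi = band
    vals = [np.asarray(curves[ch].sampen_by_sf[lo - 1 : hi]) for ch in channels]
    return np.concatenate(vals)


def summarize_session(
    curves: Mapping[str, MSECurve],
    session_id: str = "",
    condition: str = "",
    fine_band: tuple[int, int] = FINE_SF_BAND,
    coarse_band: tuple[int, int] = COARSE_SF_BAND,
) -> ComplexitySummary:
    """Condense one session's segment-averaged curves into the two band scalars.

    ``curves`` maps channel name to that channel's segment-averaged MSECurve;
    F3, F4, C3, C4, O1 and O2 are required.  Undefined (NaN) entries are
    skipped and counted; a band with no defined entries is an error.
    """
    required = set(FRONTOCENTRAL) | set(OCCIPITAL)
    missing = required - set(curves)
    if missing:
        raise ValueError(f"missing channels for summary: {sorted(missing)}")
    fc = _band_values(curves, FRONTOCENTRAL, fine_band)
    oc = _band_values(curves, OCCIPITAL, coarse_band)
    n_missing = int(np.isnan(fc).sum() + np.isnan(oc).sum())
    if np.all(np.isnan(fc)):
        raise ValueError("all frontocentral fine-scale entries undefined")
    if np.all(np.isnan(oc)):
        raise ValueError("all occipital coarse-scale entries undefined")
    return ComplexitySummary(
        session_id=session_id,
        condition=condition,
        frontocentral_low_sf=float(np.nanmean(fc)),
        occipital_high_sf=float(np.nanmean(oc)),
        n_missing=n_missing,
    )


def condition_average(
    summaries: Sequence[ComplexitySummary], condition: str
) -> dict[str, float]:
    """Arithmetic mean of each band scalar across a condition's sessions."""
    sel = [s for s in summaries if s.condition == condition]
    if not sel:
        raise ValueError(f"no sessions in condition {condition!r}")
    return {
        "condition": condition,
        "n_sessions": len(sel),
        "frontocentral_low_sf": float(np.mean([s.frontocentral_low_sf for s in sel])),
        "occipital_high_sf": float(np.mean([s.occipital_high_sf for s in sel])),
    }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    return float(stats.pearsonr(x, y).statistic)


def reproducibility_correlation(
    curves_by_segment: Mapping[str, Mapping[str, tuple[MSECurve, MSECurve]]],
    regions: Mapping[str, Sequence[str]] = REGIONS,
) -> dict[str, float]:
    """Two-segment reproducibility of MSE per region, across sessions.

    ``curves_by_segment`` maps session id -> channel -> (segment-1 curve,
    segment-2 curve).  For each region, each session and each segment, the
    region scalar is the mean SampEn over the region's channels and all
    scale factors; the returned value is the Pearson correlation between the
    segment-1 and segment-2 scalars across sessions (>= 3 required).
    """
    out: dict[str, float] = {}
    for region, channels in regions.items():
        s1, s2 = [], []
        for session, by_ch in curves_by_segment.items():
            vals1 = [np.nanmean(by_ch[ch][0].sampen_by_sf) for ch in channels]
            vals2 = [np.nanmean(by_ch[ch][1].sampen_by_sf) for ch in channels]
            s1.append(np.mean(vals1))
            s2.append(np.mean(vals2))
        if len(s1) < 3:
            raise ValueError("need >= 3 sessions with both segments")
        out[region] = _pearson(np.asarray(s1), np.asarray(s2))
    return out


def clinical_association(
    summaries: Sequence[ComplexitySummary],
    clinical: pd.DataFrame,
    exclude: Sequence[str] = (),
    on_insufficient: str = "raise",
) -> list[AssociationResult]:
    """Pearson associations of the band scalars with BFCRS and BDNF.

    ``clinical`` is indexed by session id with columns bfcrs and bdnf_ng_ml
    (NaN = not measured; BDNF is sparse by design and only measured sessions
    enter).  ``exclude`` drops whole conditions — the lorazepam-excluded
    variant isolates the ECT-linked association, since lorazepam improves
    the clinical score without moving EEG complexity.  Each result carries
    the paired scatter points for plotting.
    """
    rows = []
    for s in summaries:
        if s.condition in exclude:
            continue
        if s.session_id not in clinical.index:
            continue
        crow = clinical.loc[s.session_id]
        rows.append(
            {
                "session": s.session_id,
                "condition": s.condition,
                "frontocentral_low_sf": s.frontocentral_low_sf,
                "occipital_high_sf": s.occipital_high_sf,
                "bfcrs": crow.get("bfcrs", np.nan),
                "bdnf_ng_ml": crow.get("bdnf_ng_ml", np.nan),
            }
        )
    df = pd.DataFrame(rows)
    results: list[AssociationResult] = []
    for cvar in ("frontocentral_low_sf", "occipital_high_sf"):
        for clin in ("bfcrs", "bdnf_ng_ml"):
            sub = df.dropna(subset=[cvar, clin]) if not df.empty else df
            if len(sub) < 3:
                if on_insufficient == "skip":
                    continue
                raise ValueError(
                    f"insufficient overlap for {cvar} vs {clin}: {len(sub)} points"
                )
            r = _pearson(sub[cvar].to_numpy(), sub[clin].to_numpy())
            results.append(
                AssociationResult(
                    complexity_var=cvar,
                    clinical_var=clin,
                    pearson_r=r,
                    n_points=len(sub),
                    excluded_conditions=tuple(exclude),
                    points=sub[["session", "condition", cvar, clin]].copy(),
                )
            )
    return results


def ect_course_summary(table: pd.DataFrame) -> dict[str, float]:
    """Course statistics from the per-stimulation ECT table.

    Means are taken over seizure-producing stimulations only (duration > 0);
    a zero duration marks a failed induction.  The first treatment's charge
    is the titrated seizure threshold.
    """
    if table.empty:
        raise ValueError("empty course table")
    first = table.sort_values(["session", "stimulation"]).iloc[0]
    effective = table[table["seizure_duration_s"] > 0]
    return {
        "threshold_first_mC": float(first["charge_mC"]),
        "mean_charge_mC": float(effective["charge_mC"].mean()),
        "mean_seizure_s": float(effective["seizure_duration_s"].mean()),
        "n_failed": int((table["seizure_duration_s"] == 0).sum()),
        "n_stimulations": int(len(table)),
    }
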