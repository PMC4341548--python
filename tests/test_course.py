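"""Session summaries, condition averages, reproducibility and associations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ectmse.course import (
    AssociationResult,
    ComplexitySummary,
    clinical_association,
    condition_average,
    ect_course_summary,
    reproducibility_correlation,
    summarize_session,
)
from ectmse.entropy import EntropyParams, MSECurve
from ectmse.synth import table1_fixture

PARAMS = EntropyParams(max_sf=40)
CHANNELS = ("F3", "F4", "C3", "C4", "O1", "O2")


def curve(values, channel="F3", segment_index=0):
    return MSECurve(
        sampen_by_sf=np.asarray(values, float),
        channel=channel,
        segment_index=segment_index,
        params=PARAMS,
    )


def flat_curves(value):
    return {ch: curve(np.full(40, value), channel=ch) for ch in CHANNELS}


class TestSummarizeSession:
    def test_constant_curves_give_constant_summaries(self):
        s = summarize_session(flat_curves(1.3), session_id="S01", condition="pre_ect")
        assert s.frontocentral_low_sf == pytest.approx(1.3)
        assert s.occipital_high_sf == pytest.approx(1.3)
        assert s.n_missing == 0

    def test_hand_built_arithmetic(self):
        curves = flat_curves(0.0)
        # F3 contributes 1..5 at SF 1-5, others zero: mean over 20 values
        arr = np.zeros(40)
        arr[:5] = [1, 2, 3, 4, 5]
        curves["F3"] = curve(arr, channel="F3")
        # O1 contributes 2.0 at SF 31-40, O2 stays 0: mean over 20 values
        arr2 = np.zeros(40)
        arr2[30:40] = 2.0
        curves["O1"] = curve(arr2, channel="O1")
        s = summarize_session(curves)
        assert s.frontocentral_low_sf == pytest.approx(15.0 / 20.0)
        assert s.occipital_high_sf == pytest.approx(20.0 / 20.0)

    def test_missing_channel_rejected(self):
        curves = flat_curves(1.0)
        del curves["O2"]
        with pytest.raises(ValueError, match="missing channels"):
            summarize_session(curves)

    def test_missing_entries_skipped_and_counted(self):
        curves = flat_curves(1.0)
        arr = np.full(40, 1.0)
        arr[39] = np.nan
        curves["O1"] = curve(arr, channel="O1")
        s = summarize_session(curves)
        assert s.n_missing == 1
        assert s.occipital_high_sf == pytest.approx(1.0)

    def test_all_band_entries_missing_rejected(self):
        curves = flat_curves(1.0)
        nan_arr = np.full(40, 1.0)
        nan_arr[30:] = np.nan
        curves["O1"] = curve(nan_arr, channel="O1")
        curves["O2"] = curve(nan_arr, channel="O2")
        with pytest.raises(ValueError, match="occipital"):
            summarize_session(curves)

    def test_permutation_invariance_over_channels_and_sfs(self, rng):
        vals = rng.uniform(0.5, 2.5, size=(6, 40))
        curves = {ch: curve(vals[i], channel=ch) for i, ch in enumerate(CHANNELS)}
        s1 = summarize_session(curves)
        # swap channels within regions and shuffle SFs within the fine band
        swapped = dict(curves)
        swapped["F3"], swapped["F4"] = (
            curve(vals[1], channel="F3"),
            curve(vals[0], channel="F4"),
        )
        perm = np.arange(40)
        perm[:5] = [4, 2, 0, 3, 1]
        swapped["C3"] = curve(vals[2][perm], channel="C3")
        s2 = summarize_session(swapped)
        assert s2.frontocentral_low_sf == pytest.approx(s1.frontocentral_low_sf)


class TestConditionAverage:
    def _summary(self, sid, cond, fc, oc):
        return ComplexitySummary(sid, cond, fc, oc)

    def test_single_session_is_itself(self):
        s = self._summary("S01", "pre_ect", 1.4, 0.6)
        out = condition_average([s], "pre_ect")
        assert out["frontocentral_low_sf"] == 1.4
        assert out["n_sessions"] == 1

    def test_two_sessions_midpoint(self):
        ss = [
            self._summary("S01", "pre_ect", 1.0, 0.4),
            self._summary("S02", "pre_ect", 2.0, 0.8),
        ]
        out = condition_average(ss, "pre_ect")
        assert out["frontocentral_low_sf"] == pytest.approx(1.5)
        assert out["occipital_high_sf"] == pytest.approx(0.6)

    def test_idempotent_on_identical_sessions(self):
        ss = [self._summary(f"S{i}", "after_ect", 1.1, 0.9) for i in range(5)]
        out = condition_average(ss, "after_ect")
        assert out["frontocentral_low_sf"] == pytest.approx(1.1)

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            condition_average([self._summary("S01", "pre_ect", 1, 1)], "lorazepam")


class TestReproducibility:
    def _study(self, seg2_from_seg1, n_sessions=8, seed=3):
        rng = np.random.default_rng(seed)
        out = {}
        for k in range(n_sessions):
            by_ch = {}
            for ch in CHANNELS:
                v1 = rng.uniform(0.5, 2.0, 40)
                v2 = seg2_from_seg1(v1, rng)
                by_ch[ch] = (
                    curve(v1, channel=ch, segment_index=1),
                    curve(v2, channel=ch, segment_index=2),
                )
            out[f"S{k:02d}"] = by_ch
        return out

    def test_identical_segments_give_r_1(self):
        study = self._study(lambda v, rng: v.copy())
        r = reproducibility_correlation(study)
        assert all(val == pytest.approx(1.0) for val in r.values())

    def test_sign_flipped_deviations_give_r_minus_1(self):
        # segment-2 session scalars mirror segment-1 deviations about the mean;
        # channels share one curve per session so all region scalars coincide
        rng = np.random.default_rng(5)
        study = {}
        for k in range(8):
            v = rng.uniform(0.5, 2.0, 40)
            study[f"S{k:02d}"] = {
                ch: (curve(v, channel=ch, segment_index=1), None) for ch in CHANNELS
            }
        scalars = {
            sid: np.mean([np.nanmean(c1.sampen_by_sf) for c1, _ in by_ch.values()])
            for sid, by_ch in study.items()
        }
        grand = np.mean(list(scalars.values()))
        for sid, by_ch in study.items():
            target = 2 * grand - scalars[sid]
            for ch, (c1, _) in by_ch.items():
                by_ch[ch] = (c1, curve(np.full(40, target), channel=ch, segment_index=2))
        r = reproducibility_correlation(study)
        assert all(val == pytest.approx(-1.0) for val in r.values())

    def test_attenuation_matches_variance_ratio_oracle(self):
        # shared session effect + independent segment noise: Pearson r across
        # sessions estimates var_session / (var_session + var_noise)
        rng = np.random.default_rng(11)
        sd_s, sd_e = 0.5, 0.25
        expected = sd_s**2 / (sd_s**2 + sd_e**2)
        n = 400
        study = {}
        for k in range(n):
            base = 1.5 + rng.normal(0, sd_s)
            by_ch = {}
            for ch in CHANNELS:
                v1 = np.full(40, base + rng.normal(0, sd_e) if ch == "F3" else base)
                v2 = np.full(40, base + rng.normal(0, sd_e) if ch == "F3" else base)
                by_ch[ch] = (
                    curve(v1, channel=ch, segment_index=1),
                    curve(v2, channel=ch, segment_index=2),
                )
            study[f"S{k:03d}"] = by_ch
        # with only F3 noisy, the frontal region scalar has noise sd sd_e/2
        r = reproducibility_correlation(study)
        expected_frontal = sd_s**2 / (sd_s**2 + (sd_e / 2) ** 2)
        assert r["frontal"] == pytest.approx(expected_frontal, abs=0.06)
        assert r["occipital"] == pytest.approx(1.0)

    def test_requires_three_sessions(self):
        study = self._study(lambda v, rng: v.copy(), n_sessions=2)
        with pytest.raises(ValueError, match=">= 3"):
            reproducibility_correlation(study)


class TestClinicalAssociation:
    def _inputs(self, fc_vals, bfcrs_vals, conditions=None):
        n = len(fc_vals)
        conditions = conditions or ["pre_ect"] * n
        summaries = [
            ComplexitySummary(f"S{i:02d}", conditions[i], fc_vals[i], 1.0 + 0.1 * i)
            for i in range(n)
        ]
        clinical = pd.DataFrame(
            {
                "session": [f"S{i:02d}" for i in range(n)],
                "condition": conditions,
                "bfcrs": bfcrs_vals,
                "bdnf_ng_ml": [5.0 + i for i in range(n)],
            }
        ).set_index("session")
        return summaries, clinical

    def test_exactly_linear_gives_r_1(self):
        summaries, clinical = self._inputs([1.0, 2.0, 3.0, 4.0], [10, 20, 30, 40])
        results = clinical_association(summaries, clinical)
        r = {(x.complexity_var, x.clinical_var): x.pearson_r for x in results}
        assert r[("frontocentral_low_sf", "bfcrs")] == pytest.approx(1.0)

    def test_negative_linear_gives_r_minus_1(self):
        summaries, clinical = self._inputs([4.0, 3.0, 2.0, 1.0], [10, 20, 30, 40])
        results = clinical_association(summaries, clinical)
        r = {(x.complexity_var, x.clinical_var): x.pearson_r for x in results}
        assert r[("frontocentral_low_sf", "bfcrs")] == pytest.approx(-1.0)

    def test_constant_clinical_rejected(self):
        summaries, clinical = self._inputs([1.0, 2.0, 3.0], [10, 10, 10])
        with pytest.raises(ValueError, match="zero variance"):
            clinical_association(summaries, clinical)

    def test_exclusion_drops_condition(self):
        conds = ["pre_ect", "pre_ect", "during_ect", "lorazepam", "lorazepam"]
        summaries, clinical = self._inputs(
            [1.0, 2.0, 3.0, 4.0, 5.0], [10, 20, 30, 40, 50], conds
        )
        results = clinical_association(summaries, clinical, exclude=("lorazepam",))
        assert all(x.n_points == 3 for x in results)
        assert all(x.excluded_conditions == ("lorazepam",) for x in results)

    def test_insufficient_overlap_rejected(self):
        summaries, clinical = self._inputs([1.0, 2.0], [10, 20])
        with pytest.raises(ValueError, match="insufficient overlap"):
            clinical_association(summaries, clinical)

    def test_pearson_matches_covariance_formula(self, rng):
        x = rng.uniform(0, 1, 12)
        y = 0.3 * x + rng.uniform(0, 1, 12)
        summaries, clinical = self._inputs(list(x), list(np.round(100 * y)))
        results = clinical_association(summaries, clinical)
        got = {(a.complexity_var, a.clinical_var): a.pearson_r for a in results}[
            ("frontocentral_low_sf", "bfcrs")
        ]
        yv = np.round(100 * y)
        manual = np.sum((x - x.mean()) * (yv - yv.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((yv - yv.mean()) ** 2))
        )
        assert got == pytest.approx(manual, abs=1e-12)


class TestCourseSummary:
    def test_recorded_course_statistics(self):
        out = ect_course_summary(table1_fixture())
        assert out["mean_seizure_s"] == pytest.approx(63.29, abs=0.005)
        assert out["mean_charge_mC"] == pytest.approx(85.8, abs=0.05)
        assert out["threshold_first_mC"] == 151.1
        assert out["n_failed"] == 1
        assert out["n_stimulations"] == 8

    def test_single_stimulation(self):
        df = pd.DataFrame(
            {
                "session": [1],
                "stimulation": [1],
                "percent_energy": [30],
                "charge_mC": [100.0],
                "seizure_duration_s": [50.0],
            }
        )
        out = ect_course_summary(df)
        assert out["mean_charge_mC"] == 100.0
        assert out["mean_seizure_s"] == 50.0
        assert out["n_failed"] == 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ect_course_summary(pd.DataFrame())
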