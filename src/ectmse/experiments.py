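"""Validation experiments for the entropy pipeline.

Each function runs a self-contained computational experiment — oracle
equivalence, analytic limits, the entropy-vs-scale signatures of white and
1/f noise, and recovery of the injected treatment-course effects from the
surrogate study — and returns plain numbers.  They are used by the test
suite and the reproduction script alike.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .course import clinical_association, condition_average, summarize_session
from .entropy import EntropyParams, average_segments, mse_curve, sample_entropy, template_match_counts
from .io import TimeSeriesSegment
from .synth import GeneratorConfig, generate_study

__all__ = [
    "brute_force_match_counts",
    "analytic_iid_sampen",
    "sampen_oracle_comparison",
    "iid_gaussian_limit",
    "costa_signature",
    "effect_recovery",
]

FINE_CHANNELS = ("F3", "F4", "C3", "C4")
COARSE_CHANNELS = ("O1", "O2")


def brute_force_match_counts(x: np.ndarray, m: int, r_abs: float) -> tuple[int, int]:
    """Reference O(N^2) template matcher (full pairwise distance matrices).

    Counts ordered pairs (i, j), i != j, over the N - m extensible
    templates whose length-m (B) and length-(m+1) (A) windows match within
    Chebyshev distance < r_abs.  Deliberately dense and loop-free so it
    shares no code path with the sorted counter it checks.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m
    emb = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    d_full = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
    d_m = np.max(np.abs(emb[:, None, :m] - emb[None, :, :m]), axis=2)
    off = ~np.eye(nt, dtype=bool)
    b = int(np.sum((d_m < r_abs) & off))
    a = int(np.sum((d_full < r_abs) & off))
    return a, b


def analytic_iid_sampen(r_frac: float = 0.2) -> float:
    """SampEn limit for iid Gaussian noise.

    For an iid series, matches at each embedding coordinate are independent,
    so the conditional probability of one further match is the probability
    that two independent N(0, sd^2) draws differ by less than r = r_frac*sd,
    i.e. 2*Phi(r_frac/sqrt(2)) - 1; SampEn converges to its negative log
    regardless of m.
    """
    return -math.log(2.0 * stats.norm.cdf(r_frac / math.sqrt(2.0)) - 1.0)


def _random_test_series(rng: np.random.Generator, n: int) -> np.ndarray:
    """A mixed bag of short series: noise, AR(1), noisy periodic, random walk."""
    kind = rng.integers(4)
    if kind == 0:
        return rng.standard_normal(n)
    if kind == 1:
        phi = rng.uniform(0.3, 0.95)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.standard_normal()
        return x
    if kind == 2:
        t = np.arange(n)
        period = rng.integers(3, 20)
        return np.sin(2 * np.pi * t / period) + 0.3 * rng.standard_normal(n)
    return np.cumsum(rng.standard_normal(n))


def sampen_oracle_comparison(
    seed: int = 0, n_series: int = 50, max_n: int = 200, m: int = 2, r_frac: float = 0.2
) -> dict[str, float]:
    """Compare the counter against the dense reference on random short series.

    Returns the largest count discrepancy (should be exactly 0) and the
    largest absolute SampEn difference (should be at floating-point level)
    over ``n_series`` random series of length 20..max_n.
    """
    rng = np.random.default_rng(seed)
    max_count_diff = 0
    max_abs_diff = 0.0
    n_defined = 0
    for _ in range(n_series):
        n = int(rng.integers(20, max_n + 1))
        x = _random_test_series(rng, n)
        sd = x.std()
        if sd == 0:
            continue
        r = r_frac * sd
        a1, b1 = template_match_counts(x, m, r)
        a2, b2 = brute_force_match_counts(x, m, r)
        max_count_diff = max(max_count_diff, abs(a1 - a2), abs(b1 - b2))
        if a2 > 0 and b2 > 0:
            n_defined += 1
            diff = abs(-math.log(a1 / b1) - -math.log(a2 / b2))
            max_abs_diff = max(max_abs_diff, diff)
    return {
        "n_series": n_series,
        "n_defined": n_defined,
        "max_count_diff": max_count_diff,
        "max_abs_entropy_diff": max_abs_diff,
    }


def iid_gaussian_limit(
    seed: int = 0, n_seeds: int = 10, n: int = 15000, m: int = 2, r_frac: float = 0.2
) -> dict[str, float]:
    """Mean SampEn of iid Gaussian noise vs the analytic value."""
    rng = np.random.default_rng(seed)
    params = EntropyParams(m=m, r_frac=r_frac)
    vals = [sample_entropy(rng.standard_normal(n), params) for _ in range(n_seeds)]
    analytic = analytic_iid_sampen(r_frac)
    return {
        "mean_sampen": float(np.mean(vals)),
        "analytic": analytic,
        "abs_error": float(abs(np.mean(vals) - analytic)),
        "n": n,
        "n_seeds": n_seeds,
    }


def _one_over_f_noise(rng: np.random.Generator, n: int, beta: float = 1.0) -> np.ndarray:
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(amp * np.exp(1j * rng.uniform(0, 2 * np.pi, len(freqs))), n)
    return x / x.std()


def costa_signature(
    seed: int = 0, n_seeds: int = 20, n: int = 5000, max_sf: int = 40
) -> dict[str, float]:
    """Entropy-vs-scale signatures of white vs 1/f noise.

    Per seed: the white-noise MSE curve should fall with scale factor
    (negative fitted slope), and at scale factors >= 10 its slope magnitude
    should exceed that of the 1/f curve, whose entropy stays near-constant.
    Returns the fraction of seeds showing each signature.
    """
    rng = np.random.default_rng(seed)
    params = EntropyParams(max_sf=max_sf)
    sfs = np.arange(1, max_sf + 1)
    tail = sfs >= 10
    n_decreasing = 0
    n_flatter = 0
    for _ in range(n_seeds):
        white = mse_curve(
            TimeSeriesSegment(rng.standard_normal(n), 500.0, "sim"), params
        ).sampen_by_sf
        pink = mse_curve(
            TimeSeriesSegment(_one_over_f_noise(rng, n), 500.0, "sim"), params
        ).sampen_by_sf
        slope_white = stats.linregress(sfs, white).slope
        if slope_white < 0:
            n_decreasing += 1
        sw = stats.linregress(sfs[tail], white[tail]).slope
        sp = stats.linregress(sfs[tail], pink[tail]).slope
        if abs(sp) < abs(sw):
            n_flatter += 1
    return {
        "n_seeds": n_seeds,
        "n": n,
        "frac_white_decreasing": n_decreasing / n_seeds,
        "frac_pink_flatter_tail": n_flatter / n_seeds,
    }


def _study_summaries(cfg: GeneratorConfig, params: EntropyParams):
    """Run the banded entropy pipeline over one surrogate study."""
    channels = FINE_CHANNELS + COARSE_CHANNELS
    sessions, _ = generate_study(cfg, channels=channels)
    fine_sfs = list(range(1, 6))
    coarse_sfs = list(range(31, 41))
    summaries = []
    clinical_rows = []
    for rec in sessions:
        curves = {}
        for ch in channels:
            sfs = fine_sfs if ch in FINE_CHANNELS else coarse_sfs
            pair = [mse_curve(seg, params, scale_factors=sfs) for seg in rec.segments[ch]]
            curves[ch] = average_segments(pair[0], pair[1])
        summaries.append(
            summarize_session(curves, session_id=rec.session_id, condition=rec.condition)
        )
        clinical_rows.append(
            {
                "session": rec.session_id,
                "condition": rec.condition,
                "bfcrs": rec.bfcrs,
                "bdnf_ng_ml": rec.bdnf_ng_ml,
            }
        )
    import pandas as pd

    clinical = pd.DataFrame(clinical_rows).set_index("session")
    return summaries, clinical


def effect_recovery(
    seed: int = 0, n_seeds: int = 20, segment_s: float = 10.0
) -> dict[str, float]:
    """Recovery of the injected treatment effects from full surrogate courses.

    For each seed the complete default-schedule study is generated (at the
    stated segment length), the banded entropy pipeline is run, and three
    findings are scored: mean frontocentral fine-scale entropy lower during
    ECT than pre-ECT; mean occipital coarse-scale entropy higher during ECT
    than pre-ECT; and the catatonia-score association stronger (larger
    absolute Pearson r for the frontocentral summary) once lorazepam
    sessions — which improve the score without moving complexity — are
    excluded.  Returns the fraction of seeds recovering each.
    """
    params = EntropyParams()
    n_fine_lower = 0
    n_coarse_higher = 0
    n_assoc_sharper = 0
    for k in range(n_seeds):
        cfg = GeneratorConfig(seed=seed + k, segment_s=segment_s)
        summaries, clinical = _study_summaries(cfg, params)
        pre = condition_average(summaries, "pre_ect")
        dur = condition_average(summaries, "during_ect")
        if dur["frontocentral_low_sf"] < pre["frontocentral_low_sf"]:
            n_fine_lower += 1
        if dur["occipital_high_sf"] > pre["occipital_high_sf"]:
            n_coarse_higher += 1
        r_all = _assoc_r(summaries, clinical, exclude=())
        r_noz = _assoc_r(summaries, clinical, exclude=("lorazepam",))
        if abs(r_noz) > abs(r_all):
            n_assoc_sharper += 1
    return {
        "n_seeds": n_seeds,
        "segment_s": segment_s,
        "frac_fine_scale_lower_during_ect": n_fine_lower / n_seeds,
        "frac_coarse_scale_higher_during_ect": n_coarse_higher / n_seeds,
        "frac_bfcrs_assoc_sharper_without_lorazepam": n_assoc_sharper / n_seeds,
    }


def _assoc_r(summaries, clinical, exclude) -> float:
    results = clinical_association(summaries, clinical, exclude=exclude)
    for r in results:
        if r.complexity_var == "frontocentral_low_sf" and r.clinical_var == "bfcrs":
            return r.pearson_r
    raise RuntimeError("association result missing")
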