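"""Multiscale entropy: coarse-graining, sample entropy, and entropy-vs-scale curves.

Sample entropy (SampEn) quantifies the irregularity of a time series as the
negative natural logarithm of the conditional probability that two runs of
``m`` consecutive points that match within a tolerance ``r`` (Chebyshev
distance, self-matches excluded) still match when extended to ``m + 1``
points.  Multiscale entropy (MSE) evaluates SampEn on successively
coarse-grained copies of the signal: at scale factor tau the series is
replaced by the means of non-overlapping windows of tau samples, so small
scale factors probe fast temporal structure and large ones slow structure.

The tolerance is expressed as a fraction of the standard deviation of the
*original* (scale 1) series and, by default, held fixed across scale
factors, so that entropy changes across scales reflect the coarse-grained
dynamics rather than a rescaled similarity criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numba import njit

from .io import TimeSeriesSegment

__all__ = [
    "EntropyParams",
    "CoarseGrainedSeries",
    "MSECurve",
    "coarse_grain",
    "sample_entropy",
    "template_match_counts",
    "mse_curve",
    "average_segments",
]


@dataclass(frozen=True)
class EntropyParams:
    """Parameters of the sample-entropy estimator.

    m
        Embedding dimension (template length), >= 1.
    r_frac
        Tolerance as a fraction of the standard deviation of the scale-1
        series, in (0, 1).
    max_sf
        Largest coarse-graining scale factor of an MSE curve.
    tolerance_mode
        ``"fixed"``: r is derived once from the scale-1 series and reused at
        every scale (the conventional MSE choice, default).  ``"per_scale"``:
        r is recomputed from each coarse-grained series.
    """

    m: int = 2
    r_frac: float = 0.2
    max_sf: int = 40
    tolerance_mode: Literal["fixed", "per_scale"] = "fixed"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not 0.0 < self.r_frac < 1.0:
            raise ValueError(f"r_frac must be in (0, 1), got {self.r_frac}")
        if self.max_sf < 1:
            raise ValueError(f"max_sf must be >= 1, got {self.max_sf}")
        if self.tolerance_mode not in ("fixed", "per_scale"):
            raise ValueError(f"unknown tolerance_mode {self.tolerance_mode!r}")


@dataclass(frozen=True)
class CoarseGrainedSeries:
    """A coarse-grained series: window means at scale factor ``sf``."""

    values: np.ndarray
    sf: int
    source_n: int

    def __post_init__(self) -> None:
        if len(self.values) != self.source_n // self.sf:
            raise ValueError("coarse-grained length must be floor(source_n / sf)")


@dataclass
class MSECurve:
    """SampEn per scale factor for one segment (or a segment average).

    ``sampen_by_sf[tau - 1]`` is the SampEn at scale factor ``tau``; entries
    where the estimator is undefined (no template matches) are NaN and are
    propagated, never silently dropped.
    """

    sampen_by_sf: np.ndarray
    channel: str
    segment_index: int
    params: EntropyParams

    def __post_init__(self) -> None:
        self.sampen_by_sf = np.asarray(self.sampen_by_sf, dtype=float)
        if len(self.sampen_by_sf) != self.params.max_sf:
            raise ValueError("curve length must equal params.max_sf")

    def sf_band_mean(self, lo: int, hi: int) -> float:
        """Mean SampEn over scale factors lo..hi inclusive (NaN-skipping)."""
        band = self.sampen_by_sf[lo - 1 : hi]
        if np.all(np.isnan(band)):
            return float("nan")
        return float(np.nanmean(band))


def coarse_grain(x: Sequence[float] | np.ndarray, sf: int) -> CoarseGrainedSeries:
    """Coarse-grain ``x`` at scale factor ``sf``.

    y_j = mean(x[(j-1)*sf : j*sf]) for j = 1..floor(N/sf); trailing samples
    that do not fill a window are discarded.  ``sf == 1`` returns the series
    unchanged.
    """
    x = np.asarray(x, dtype=float)
    if sf < 1:
        raise ValueError(f"scale factor must be >= 1, got {sf}")
    n = len(x)
    if sf > n:
        raise ValueError(f"scale factor {sf} exceeds series length {n}")
    n_cg = n // sf
    values = x[: n_cg * sf].reshape(n_cg, sf).mean(axis=1)
    return CoarseGrainedSeries(values=values, sf=sf, source_n=n)


@njit(cache=True)
def _match_counts_sorted(x: np.ndarray, m: int, r: float):  # pragma: no cover
    # Exact ordered-pair template matching, strict Chebyshev "< r".
    # Templates i = 0..n-m-1 (the n-m templates that extend to length m+1),
    # sorted by first coordinate so only candidates with |x_i - x_j| < r in
    # the first coordinate are compared. Equivalent to the O(N^2) scan.
    n = x.shape[0]
    nt = n - m
    order = np.argsort(x[:nt])
    a_count = 0
    b_count = 0
    for a in range(nt):
        i = order[a]
        xi = x[i]
        for b in range(a + 1, nt):
            j = order[b]
            if x[j] - xi >= r:
                break
            ok = True
            for k in range(1, m):
                d = x[i + k] - x[j + k]
                if d >= r or -d >= r:
                    ok = False
                    break
            if ok:
                b_count += 1
                d = x[i + m] - x[j + m]
                if d < r and -d < r:
                    a_count += 1
    return 2 * a_count, 2 * b_count


def template_match_counts(
    x: Sequence[float] | np.ndarray, m: int, r_abs: float
) -> tuple[int, int]:
    """Ordered-pair template match counts (A, B) for SampEn.

    Both counts run over the N - m templates that can be extended by one
    point: B is the number of ordered pairs (i, j), i != j, whose length-m
    templates lie within Chebyshev distance < r_abs; A the same for the
    length-(m+1) extensions.  SampEn = -ln(A / B).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if len(x) < m + 2:
        raise ValueError(f"series of length {len(x)} too short for m={m}")
    if r_abs <= 0:
        raise ValueError("tolerance must be positive")
    a, b = _match_counts_sorted(x, m, float(r_abs))
    return int(a), int(b)


def sample_entropy(
    x: Sequence[float] | np.ndarray,
    params: EntropyParams = EntropyParams(),
    r_abs: float | None = None,
) -> float:
    """Sample entropy of ``x``.

    If ``r_abs`` is None the tolerance is ``params.r_frac`` times the
    standard deviation of ``x`` itself.  Returns NaN when no template pair
    matches at length m or at length m + 1 (the conditional probability is
    then undefined).

    Raises on zero-variance input when the tolerance must be derived from it.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if r_abs is None:
        sd = float(np.std(x))
        if sd == 0.0:
            raise ValueError("zero-variance series: tolerance r would be degenerate")
        r_abs = params.r_frac * sd
    a, b = template_match_counts(x, params.m, r_abs)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def mse_curve(
    seg: TimeSeriesSegment,
    params: EntropyParams = EntropyParams(),
    scale_factors: Sequence[int] | None = None,
) -> MSECurve:
    """Multiscale entropy curve of one segment.

    For each scale factor tau in 1..params.max_sf, SampEn of the
    coarse-grained series; with the default fixed-tolerance mode the
    tolerance is r_frac * SD of the scale-1 segment at every scale.
    Undefined entries are NaN.  ``scale_factors`` restricts computation to a
    subset of scales (others NaN) for banded summaries.
    """
    x = np.asarray(seg.samples, dtype=float)
    if len(x) // params.max_sf < params.m + 2:
        raise ValueError(
            f"segment of {len(x)} samples too short for max_sf={params.max_sf} "
            f"(coarse series would have < m + 2 points)"
        )
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("zero-variance segment")
    r_fixed = params.r_frac * sd
    sfs = range(1, params.max_sf + 1) if scale_factors is None else scale_factors
    out = np.full(params.max_sf, np.nan)
    for tau in sfs:
        y = coarse_grain(x, tau).values
        if params.tolerance_mode == "per_scale":
            sd_tau = float(np.std(y))
            if sd_tau == 0.0:
                continue
            r = params.r_frac * sd_tau
        else:
            r = r_fixed
        out[tau - 1] = sample_entropy(y, params, r_abs=r)
    return MSECurve(
        sampen_by_sf=out,
        channel=seg.channel,
        segment_index=seg.segment_index,
        params=params,
    )


def average_segments(curve1: MSECurve, curve2: MSECurve) -> MSECurve:
    """Element-wise mean of the two per-segment curves of one session/channel.

    NaN (undefined) entries propagate: the mean is NaN wherever either curve
    is NaN.
    """
    if curve1.params != curve2.params:
        raise ValueError("cannot average curves with different entropy parameters")
    if curve1.channel != curve2.channel:
        raise ValueError(
            f"cannot average curves from different channels "
            f"({curve1.channel} vs {curve2.channel})"
        )
    mean = (curve1.sampen_by_sf + curve2.sampen_by_sf) / 2.0
    return MSECurve(
        sampen_by_sf=mean, channel=curve1.channel, segment_index=0, params=curve1.params
    )
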