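# Methods

## Sample entropy and the multiscale curve

Sample entropy of a series {x₁…x_N} with embedding dimension m and tolerance
r is −ln(A/B): B is the number of ordered pairs (i, j), i ≠ j, of m-point
templates whose Chebyshev distance is strictly below r, A the number still
matching when the templates are extended to m + 1 points. Both counts run
over the N − m templates that can be extended, so A/B is exactly the
conditional probability that an m-match remains a match one point later;
normalising denominators cancel in the ratio. Matching is strict (`< r`) and
self-pairs are excluded. When A or B is zero the estimator is undefined; the
package returns NaN, propagates it through segment averaging, and band
summaries skip NaNs with a reported count, so a sparse undefined tail never
aborts a course-level analysis.

The counter sorts templates by their first coordinate and only compares
candidates within r in that coordinate (numba-compiled), which is
algebraically identical to the exhaustive O(N²) scan; the test suite checks
exact count equality against an independent dense-matrix oracle, and the iid
Gaussian limit −ln(2Φ(r/√2)−1) ≈ 2.185 for r = 0.2 is reproduced within
Monte-Carlo error at N = 15,000.

Coarse-graining at scale factor τ replaces non-overlapping τ-sample windows
by their means (trailing remainder discarded), τ = 1 … 40. The tolerance is
r = 0.2 × SD of the *original* (τ = 1) segment and is held fixed across
scale factors — the convention under which white noise shows falling entropy
with scale while long-range-correlated 1/f noise stays near-constant. A
`per_scale` switch recomputes r from each coarse-grained series for
sensitivity analyses. Defaults m = 2, r = 0.2, maximum scale factor 40
(covering the 31–40 reporting band).

## Spectral analysis

Each segment is split into consecutive non-overlapping 2 s epochs (15 per
30 s segment). Per epoch a Hann taper is applied and the one-sided squared
FFT magnitude is normalised by the window power Σw² so that white noise of
variance σ² gives a flat spectrum at σ²-level; bins except DC/Nyquist are
doubled. Powers are averaged across epochs (and across the session's two
segments) before the log10 transform, giving 0.5 Hz resolution. Band edges
default to theta 4–8, alpha 8–13, beta 13–30, gamma 30–60 Hz; the
directional band-power results are not sensitive to these edges within
conventional choices. The wakefulness check requires occipital alpha power
to exceed the mean of the flanking theta and beta powers in both O1 and O2
(ratio threshold 1.0, configurable). Against a flat (white) background this
margin is near-chance by construction; against the realistic 1/f background
it discriminates sharply, which is the regime the generator produces.

## Analysis segments and artifact handling

Segments are cut sample-exactly with 0-based indices and half-open time
windows; readers never filter, resample or re-reference — the acquisition
bandpass is treated as a hardware property, and any further processing could
distort the non-linear structure the entropy analysis measures. Visual
artifact rejection is replaced by an automated screen: a segment is flagged
unless all samples are within ±100 µV and successive-sample steps within
50 µV (both configurable). Segment positions within a recording are an
input (manifest markers), not inferred.

## The surrogate study

The patient EEG behind the original course is not deposited, so the
generator emulates the design: 24 sessions (3 pre-ECT, 7 during, 8 after, 6
lorazepam, chronological), two 30 s segments × 8 channels at 500 Hz, target
SD 20 µV. Each signal is a 1/f^β Gaussian background (β = 1, spectral
synthesis with random phases) plus a 10 Hz alpha rhythm with a slowly
drifting envelope, amplitude graded posteriorly (O1/O2 1.2, P3/P4 0.8,
C3/C4 0.4, F3/F4 0.25 relative to background SD).

Treatment effects are injected mechanistically rather than by targeting
entropy values, so the estimator is honestly tested:

* **Fine-scale regularity** (λ_f): a fraction λ_f of the background is
  replaced by its 5-sample moving average, making neighbouring samples
  predictable and lowering SampEn at scale factors 1–5. Frontocentral λ_f:
  0 pre, 0.65 during, 0.45 after and under lorazepam.
* **Coarse-scale variability** (λ_c): additive band-limited (0.5–6 Hz)
  Gaussian slow activity with weight λ_c, which survives coarse-graining and
  raises SampEn at scale factors 31–40. Occipital λ_c: 0.1 pre, 0.9 during,
  0.6 after and under lorazepam. An amplitude-modulation route was
  prototyped first but is confounded by the fixed-tolerance normalisation
  (the envelope inflates the τ = 1 SD, hence r, roughly in proportion);
  the additive slow component produces the coarse-scale effect robustly.

Parietal channels receive attenuated effects and are computed but not
summarised. The clinical model sets BFCRS ≈ 35 pre-ECT, falling to ≈ 10
through the ECT course, relapsing partially to ≈ 20, and dropping to ≈ 5
under lorazepam (Gaussian noise SD 1.5, integer-rounded, floored at 0);
BDNF starts at 5 ng/ml, rises to ≈ 14 with ECT, and is observed at only 4
sessions to emulate sparse serum sampling. Lorazepam sessions improve the
score while leaving both complexity read-outs at their after-ECT level —
which is why excluding them sharpens the complexity–BFCRS correlation, the
pattern the association analysis is designed to expose.

What the surrogate does **not** emulate: volume-conduction correlations
between channels (channels are independent draws), eye-blink/EMG artifacts,
drowsiness drift within a session, or any biophysical seizure mechanism.
Passing tests therefore demonstrate that the estimators recover known
injected structure of realistic amplitude and spectrum — not that the
clinical effect sizes themselves are reproduced, which the source figures do
not quantify numerically.

## Aggregation choices

The two-segment reproducibility check correlates, across sessions, a
per-segment region scalar defined as the mean SampEn over the region's two
channels and all 40 scale factors (frontal F3/F4, central C3/C4, occipital
O1/O2) — the interpretive choice of "what was correlated", recorded as such.
Because the treatment effect lives in narrow scale bands, this all-scale
scalar has modest between-session variance in the surrogate and its r values
are reported descriptively, validated instead by the identical-segment
limit (r = 1) and a variance-ratio attenuation oracle. Associations are
plain Pearson coefficients with their n; BDNF uses only measured sessions,
no interpolation, and no hypothesis tests are attached.

## Problem sizes and runtime

Single-study demonstrations use the canonical 30 s segments. The repeated
Monte-Carlo experiments (Costa-signature and the 20-seed effect-recovery
runs in the tests and the reproduction script) use 10 s segments
(N = 5,000) and the six summarised channels — at these sizes each experiment
completes in minutes while every tested contrast retains a wide margin over
its estimation noise. The analysis drivers default to 10 s segments for the
same reason and accept `--segment-s 30`.

## Degenerate inputs and numerical notes

Zero-variance series make the relative tolerance degenerate and are
rejected; series shorter than m + 2 are rejected; a scale-factor range
requiring coarse series shorter than m + 2 is rejected at curve level.
Flagged-undefined entropies are NaN end to end. Pearson correlations with a
zero-variance input raise. All entropy logarithms are natural; spectral
logs are base 10 (switchable). Matrix CSVs round-trip integer-representable
microvolt data bitwise; EDF physical values are converted to µV on read.
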