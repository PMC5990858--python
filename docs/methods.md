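# Methods

## Signal model and scope

The object of analysis is an hourly relative-search-volume (RSV) series:
integers 0–100 on a uniform hourly grid, one series per query term, at
least two complete days long. The working assumption is additive
structure

    RSV(t) = slow trend (period > 32 h)
           + diurnal component (period ≈ 24 h)
           + fast noise (period < 4 h)
           + white observation noise,

and the pipeline's job is to isolate the middle term and quantify it.
The timestamp grid is treated as abstract and uniform: no time-zone or
DST arithmetic is performed. (A March series in a country that switches
to summer time mid-month still arrives from Google Trends as 31 × 24
labelled hours; whether those are UTC or a 23-hour local day is not
recoverable from the export, so the package does not guess.)

## Reading and stitching exports

Google Trends hourly exports cover at most about a week per file, each
file carrying its own 0–100 normalization. `stitch_weekly` chains
consecutive segments onto a common relative scale using the **ratio of
means over each overlap** — robust to the integer quantization of the
export, unlike per-hour ratios — with the earlier segment's value kept on
overlapping hours, then renormalizes the stitched series so its maximum
is exactly 100. Because RSV is relative, the result is invariant to
scaling any input segment by a positive constant (property-tested).
Segments that abut exactly carry no cross-scale information; they are
each max-normalized with a recorded warning. Gaps between segments are
an error; gaps *inside* a series of up to `max_gap` hours (default 2)
are linearly interpolated by `validate_series`, larger ones raise.
`<1` cells map to 0, preserving integrality.

## Wavelet band-pass

The continuous wavelet transform uses the Morlet mother wavelet with
centre frequency ω₀ = 6, computed in the frequency domain with
zero-padding to the next power of two. Scales form the dyadic grid
sⱼ = s₀·2^(j·δj) with s₀ = 2δt, δj = 0.125, extended until the Fourier
period λⱼ = 4πsⱼ/(ω₀ + √(2 + ω₀²)) ≈ 1.033·sⱼ reaches 128 h. This is
the standard published convention for rhythm analysis in geophysical and
biological series, and the only one with a fully published inverse:

    x̂(t) = (δj √δt)/(C_δ ψ₀(0)) · Σ_{j ∈ band} Re(Wⱼ(t))/√sⱼ,
    C_δ = 0.776, ψ₀(0) = π^(−1/4).

Band membership is inclusive on both edges, default 4 ≤ λ ≤ 32 h: slow
trends are *strictly longer* than 32 h, fast noise strictly shorter than
4 h. The series mean is removed before the transform and stored; diurnal
profiles are computed on the mean-restored reconstruction so peak–trough
differences live on the 0–100 RSV scale (percentage points). The cone of
influence uses the √2·s e-folding rule mapped to period units
(λ_coi(t) = 1.033·d/√2 for distance d from the nearer edge); acceptance
checks evaluate only interior points (coi ≥ 32 h), because amplitude near
the edges is attenuated by construction. With δj = 0.125 the empirical
C_δ gives ≈ 1% amplitude error for mid-band sinusoids; the 15% tolerance
used in tests leaves room for band-edge leakage.

Measured selectivity (recomputed by `scripts/acceptance.py`): a 24 h
cosine passes with correlation > 0.999 and ≈ 1% amplitude error; 72 h and
2 h cosines are attenuated below 1% RMS.

## Diurnal profiles

`fold_days` trims leading/trailing partial days so the first retained
sample falls at hour 0, then reshapes losslessly into days × 24.
`mean_profile` takes column means; peak and trough are argmax/argmin with
ties broken to the earliest hour (determinism), and hour *h* labels the
clock window [h:00, h+1:00). The summary statistic is
pp = mean[peak] − mean[trough], invariant to adding a constant and
linear under scaling (property-tested).

## Hourly significance matrix

Each clock hour is a group with the days as replicates (n = days per
group after trimming). A one-way ANOVA tests the omnibus hypothesis; the
Tukey–Kramer procedure then compares all pairs via

    q_ij = |m_i − m_j| / sqrt(s²/2 · (1/n_i + 1/n_j)),   s² = SSW/(N−k),

referred to the studentized range with k = 24 groups. With complete days
all n_i are equal and the Kramer form reduces exactly to Tukey HSD. The
reported matrix is directional — (i, j) marked when the adjusted p is
below α *and* m_i > m_j — while the adjusted p itself is two-sided and
symmetric. By default the test runs on the band-passed, mean-restored
series (the analysis object of the pipeline); a raw mode is available.

Numerical choice: significance decisions compare q against the exact
critical value (`studentized_range.ppf`, cached per (k, df, α));
reported p-values come from a cached monotone PCHIP interpolant of
`studentized_range.sf` on a dense q grid, accurate to < 1e-5, because
direct evaluation of the survival function is ~10 ms per point — far too
slow for Monte-Carlo calibration at 276 pairs per matrix. The interpolant
is verified against direct evaluation, and the whole procedure against
statsmodels' `pairwise_tukeyhsd` and a permutation max-T null, in the
test suite.

Normality and equal-variance diagnostics do not block execution; the
procedure is applied unconditionally, and day-to-day autocorrelation is
not modelled (a known limitation of plain ANOVA on folded days).

## Time-block trichotomy

Hours partition into night (0–7), work (8–15) and evening (16–23) —
nighttime, structured office time, unstructured leisure time. Block
analysis runs on **raw** RSV, not the reconstruction: blocks summarize
observed search volume. One-way ANOVA over the three blocks is followed
by the three pairwise two-sided t-tests on the ANOVA-pooled MSE
(df = N − 3, the SPSS-style post hoc), each p multiplied by 3 and capped
at 1 (Bonferroni). Default observations are hourly values (n = 8 × days
per block); `unit="day"` aggregates to daily block means first as a
sensitivity analysis, since hourly values within a day are not
independent — this choice of observational unit is genuinely open and
both are exposed.

## Synthetic generator

`generate_series` produces, per term,

    baseline + A·cos(2π(t − acrophase)/24)
             + trend_amplitude·cos(2πt/trend_period)
             + noise_hf_amplitude·cos(2πt/noise_hf_period + φ_term)
             + N(0, white_sd²),

with optional renormalization to max 100 and integer quantization
(clipping applied after renormalization; ground truth is computed
pre-clipping, and tests use configurations where clipping is inactive).
Defaults — 31 days, 6 terms, baseline 50, A = 15 peaking at 2 AM, trend
20 @ 72 h, fast component 3 @ 2 h, white SD 5 — emulate a month of
night-peaking health-query volume at realistic noise levels. The trend
and fast periods deliberately straddle the 4–32 h band edges, and the
fast component is a fixed-period cosine with random phase rather than
broadband noise, so band rejection has an exact analytic target. The
ground truth records the cosine sampled at integer hours (peak–trough
exactly 2A for integer acrophase) and per-term renormalization factors.

What the generator does *not* emulate: Google's sampling noise and
privacy thresholding, day-of-week (168 h) structure, and non-sinusoidal
diurnal shapes. Passing tests therefore demonstrate that the machinery
recovers a known additive sinusoidal rhythm under realistic noise — not
that any particular real-world series contains one.

## Problem sizes and calibration checks

Parameter recovery uses 20 independent seeds of the standard 31-day
configuration (median pp error ≈ 1.5% of the true 30 pp; modal peak hour
equals the acrophase). Type-I-error calibration uses 500 null
simulations of 14 days of pure white noise: hourly-ANOVA rejection at
α = .05 lands near 5%, and the fraction of null runs with any
Tukey-significant pair (familywise error) stays below 7%. Permutation
oracles in the test suite run at 2 000–10 000 resamples on reduced
instances.

## Known limitations

- Plain ANOVA treats days as independent replicates; persistent
  autocorrelation across days inflates significance on real data.
- The 24×24 matrix is computed per term; no cross-term pooling or
  multiplicity control across terms.
- Exact numeric parity with analyses performed in other CWT
  implementations (different mother wavelets or scale grids) is not a
  goal; the conventions above are fixed and published.
- Stitching resolves overlap by "earlier segment wins"; averaging is a
  defensible alternative and would differ in the conflict count, not the
  scale.
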