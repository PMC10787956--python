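# Methods

This note records the modelling choices, parameter conventions and numerical
decisions behind `remband`, and what the bundled synthetic experiments can
and cannot demonstrate.

## Analysis chain

**Epoching.** Sleep stages arrive as `(stage, onset, duration)` annotations
in seconds from recording start, half-open intervals, stages
W/S1–S4/REM/MT. Every REM annotation is tiled into consecutive 30-s epochs
starting at its onset; a trailing remainder shorter than 30 s is discarded,
and no epoch ever crosses an annotation boundary. Whether segments should
instead be concatenated before tiling is not determined by the source
conventions we follow; per-annotation tiling is this package's choice.
Signals are never resampled and artifact handling is purely
frequency-selective (next paragraph) — there is no amplitude-based epoch
rejection.

**Band decomposition.** Each epoch is decomposed by a multilevel DWT with
the `db5` wavelet, symmetric boundary extension, to depth log2(fs/2) — 8
levels at 512 Hz. Rhythms map to detail levels by their dyadic ranges: at
512 Hz beta ← D4 (16–32 Hz), alpha ← D5 (8–16), theta ← D6 (4–8),
delta ← D7∪D8 (1–4). The approximation A8 (<1 Hz: electrode drift, slow
head/ocular movement) and D1–D3 (>32 Hz: EMG contamination, line noise) are
discarded — this is the only artifact filter, and it restricts the analysis
to 1–30 Hz. Bands are *reconstructed signals* (inverse DWT with all other
levels zeroed), not coefficient sets, so time-domain statistics and sample
entropy are computed on series with the epoch's own length and sampling
rate. Only rates of the form 32·2^j Hz (64, 128, 256, 512, …) admit a
dyadic mapping whose edges land on the clinical band boundaries; other
rates are rejected rather than approximated.

The dyadic edges do not coincide with the nominal alpha/beta boundaries
(8–16 vs 8–13 Hz, 16–32 vs 13–30 Hz). We therefore never report dyadic band
power directly: spectra are integrated over the *nominal* ranges, and the
dyadic mismatch contributes only residual leakage.

**Spectral estimation.** Welch's method with a 128-sample Hamming window,
50% overlap, 256-point DFT, per-segment mean removal, one-sided density
scaling. On a 30-s epoch at 512 Hz this yields 239 segments and a 2-Hz
grid. Note the resolution bandwidth of this configuration is ≈4 Hz — wider
than the delta band itself — which smears narrow-band power into
neighbouring bands; this is treated as part of the measurement operator
(see *Generator calibration*). Absolute band power (APSD) is the
trapezoidal integral of the band-reconstructed signal's density over the
band's nominal range, with linear interpolation where an edge (13 Hz) falls
between grid points, so adjacent bands abut without double counting.
The integral (rather than the mean) of the density is used so APSD obeys
Parseval-style scaling: doubling the signal quadruples APSD. Relative band
power (RPSD) normalizes the four APSDs to percentages; the four values sum
to 100 by construction. A configuration switch (`psd_on="raw"`) computes
all band integrals from a single PSD of the unsplit epoch instead, for
sensitivity analysis.

**Features (28 per epoch).** Per band: mean, SD, RMS (mV; population SD —
at N = 15 360 the ddof distinction is immaterial, and RMS² = SD² + mean²
holds exactly); RPSD (%) and APSD; the ratios (θ+α)/β, α/δ, α/θ, α/β
computed from RPSD percentages (identical to computing them from APSD,
since the common denominator cancels); and sample entropy. An epoch with
zero total band power is excluded with a logged reason, never emitted as a
NaN row.

**Sample entropy.** SampEn(m, r) follows Richman–Moorman counting: with
templates of length m = 5 and tolerance r = 0.2 × the band signal's own SD,
B counts template pairs at Chebyshev distance ≤ r, A counts the same pairs
extended one sample, self-matches excluded, both lengths drawing from the
same N − m template starts; SampEn = −ln(A/B). The parameter reading
"maximum template length 5" is taken as *compute at m = 5*; the kernel
accepts any m ≥ 1. Degenerate conventions, each logged: constant series
→ 0; B = 0 → 0; A = 0 → ln(B) (the standard cap, −ln with A set to 1).
The kernel is exact — a box-assisted scan (templates sorted by first
sample; only first-coordinate-compatible pairs examined) that performs
identical comparisons to the naive O(N²) loop, verified count-for-count
against a brute-force oracle in the test suite.

**Screening.** Features are compared between groups over pooled epochs.
The default policy applies the Mann–Whitney rank-sum test to every feature
(the appropriate choice when per-feature normality is mixed); an `auto`
policy gates on Shapiro–Wilk per group at α = 0.05 and uses the Welch
(unequal-variance) two-sample t-test when both groups pass. The exact
Mann–Whitney null is used for pooled samples of ≤ 16 without ties,
otherwise the normal approximation with tie and continuity corrections.
Raw p-values are starred (`*` p ≤ 0.05, `**` p ≤ 0.001) with no
multiple-testing correction by default, mirroring the per-feature reporting
convention of this literature; Benjamini–Hochberg adjustment is available
but off by default. **Caveat (pseudo-replication):** epochs from one
subject are not independent, yet the tests treat pooled epochs as
exchangeable. With few subjects per group the p-values are
anti-conservative under between-subject heterogeneity. The package
reproduces this convention and documents it rather than resolving it.

**Classifier.** A from-scratch CART: Gini impurity, midpoint thresholds,
best-first growth (the frontier node with the largest weighted impurity
decrease is split next), at most 100 splits, minimum leaf size 1 — the
"fine tree" preset of commercial toolboxes. Ties between candidate splits
break to the lowest feature index, then the lowest threshold; impure nodes
admit zero-gain splits (classic CART behaviour, required for XOR-like
layouts). Routing: value < threshold → left, = threshold → right.
Cross-validation is stratified by class with a seeded shuffle;
**epoch-level** CV is the default (epochs from one subject can appear in
both training and test folds, matching the pooled-epoch design above),
which inflates accuracy relative to leave-subject-out CV — the
methodologically safer subject-level split is a one-line change on the fold
labels. Metrics (sensitivity, specificity, accuracy, PPV; bruxism
positive) come from the confusion matrix pooled over folds
(micro-averaging); per-fold values are also emitted. The CV seed is a
required, logged configuration item.

## Synthetic cohorts

**What is emulated.** Each channel is a sum of four independent Gaussian
noise components, band-pass filtered (zero-phase Butterworth, order 6) at
the nominal band edges and rescaled to per-band target SDs in mV, plus an
optional sub-1-Hz sinusoidal drift and a >30 Hz sinusoid that exercise the
frequency-selective artifact filtering. Hypnograms interleave REM blocks
with W/S1–S4 filler stages so extraction faces distractor annotations.
Fixtures are written as EDF (16-bit, 1-s records, quantization range ±8 ×
the largest band SD plus artifact amplitudes, keeping quantization error
well below 0.1% of signal SD) plus plain-text hypnograms and a JSON
manifest. Components are synthesized with 8 s of padding beyond each end,
trimmed before use, so IIR startup transients (seconds long at the 1-Hz
delta edge) never reach the emitted signal. Generation is deterministic:
each (subject, channel) stream derives from (cohort seed, subject index,
channel index).

**Generator calibration.** Measured RPSD is a biased functional of the
component variances: the 4-Hz Welch resolution bandwidth and the dyadic
DWT both leak power across neighbouring bands. Because the components are
independent, measured band power is *exactly linear* in component
variances, so the generator estimates the 4×4 leakage matrix of the
analysis chain once (Monte-Carlo over a fixed internal seed, 20
realizations per band) and solves a non-negative least-squares system for
component variances whose measured RPSD hits the requested targets
(`profile_from_rpsd`). Without calibration, a variance-proportional profile
misses delta-dominant targets by tens of percentage points. When a target
is at or below the leakage floor from neighbouring bands the NNLS solution
clips that component to zero and the residual spreads over the other bands
— still within the recovery tolerance used in the tests.

**Default study conditions.** The two canned group profiles target the
published group-mean relative band powers (δ/θ/α/β healthy
65.26/20.619/8.424/5.696%, bruxism 65.302/17.480/9.931/7.287%) with total
signal SDs of 10.0 mV (healthy) and 11.5 mV (bruxism) and 2 mV drift plus
0.5 mV high-frequency contamination in both groups. The higher bruxism
total power makes the theta, alpha and beta band SDs larger in the bruxism
group, matching the directions of the published amplitude features. The
published amplitude and relative-power tables are not jointly realizable
by any stationary generator (equal relative delta at higher total power
forces a higher, not lower, delta SD), so the relative-power targets take
precedence — they drive both the screening directions and the classifier.
Rehearsal experiments default to 100 epochs/group for recovery and 3 × 60
epochs for the null, on one channel: sizes chosen so group means are
stable (SE of a group-mean RPSD ≈ 0.2 points at 100 epochs) while the
whole suite runs in minutes on one CPU.

**What is *not* emulated — and what passing therefore shows.** The
generator produces stationary Gaussian band noise: no 1/f spectral slope
within bands, no sleep micro-architecture (spindles, K-complexes, CAP
A-phases), no real artifact taxonomy, no between-subject variability
within a group, and no non-stationarity across the night. Passing the
recovery experiment demonstrates that the *pipeline* — extraction, band
split, spectral normalization, screening, classifier — is correct and
unbiased as a measurement chain; it does not demonstrate that real
bruxism EEG is this separable. In particular the near-perfect CV metrics
on synthetic cohorts reflect the absence of within-group heterogeneity,
and epoch-level CV on real data would additionally leak subject identity.

## Numerical conventions

* Band-edge bins: integration intervals abut at 4, 8, 13 Hz with linear
  interpolation, so the four band integrals of one PSD sum exactly to the
  1–30 Hz integral.
* Welch: density scaling, one-sided, per-segment mean detrend; segment
  count is floor((N − 128)/64) + 1.
* Exact Mann–Whitney p-values are two-sided as 2·min(P(U ≤ u), P(U ≥ u))
  clipped to 1; the asymptotic branch deviates from the exact null by at
  most ≈0.011 at n = 8 + 8 (measured over all achievable U).
* Tree ties: lowest feature index, then lowest threshold; frontier ties by
  insertion order (deterministic given row order).
* EDF physical ranges are stored in 8-char ASCII; the encoder quantizes
  against the stored (rounded) value so a write–read round trip is exact to
  one quantization step.
* Degenerate inputs: zero-power epochs and zero-denominator ratios raise a
  dedicated exclusion error; all-identical feature columns are flagged
  `degenerate` in the significance table rather than tested.

## Known limitations

* Pooled-epoch testing and epoch-level CV (above) are faithful to the
  reporting conventions of this literature but statistically optimistic;
  subject-level alternatives exist in the API.
* The CAP scoring-file dialects of public sleep databases vary by subject;
  the package defines its own plain hypnogram dialect and does not parse
  EDF+ embedded annotations.
* `shapiro_wilk` is limited to 3 ≤ n ≤ 5000 by the underlying
  approximation.
* Supported sampling rates for the dyadic band map are 32·2^j Hz; arbitrary
  rates would require wavelet-packet or filter-bank decompositions, which
  are out of scope.
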