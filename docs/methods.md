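# Methods

This note documents the models, conventions and numerical choices behind
`hrvfatigue`, and what its synthetic experiments do and do not demonstrate.

## Synthetic cohort model

RR intervals are generated directly in the interval domain:

    RR_i = mean_rr + amp_lf · sin(2π·0.1·t_i) + amp_hf · sin(2π·0.25·t_i) + e_i,
    e_i ~ N(0, sd_noise²),  RR_i floored at 300 ms,

with one parameter set per mental state (and optionally per sex). A sinusoid
of amplitude *a* contributes ≈ a²/2 ms² to its spectral band, so the default
parameters are solved from the target group statistics: `mean_rr` from the
group mean RR, `amp_lf/amp_hf` from the LF/HF band powers, and `sd_noise`
so the total interval variance matches the group SDNN². Defaults (ms):

| state, sex | mean_rr | sd_noise | amp_lf | amp_hf |
|---|---|---|---|---|
| alert, pooled | 801.4 | 28.3 | 38.2 | 32.2 |
| fatigued, pooled | 869.9 | 44.1 | 53.1 | 38.7 |
| alert, male | 815.9 | 29.6 | 43.6 | 34.7 |
| fatigued, male | 907.0 | 52.0 | 62.6 | 41.3 |
| alert, female | 788.2 | 27.6 | 32.4 | 29.8 |
| fatigued, female | 835.3 | 37.6 | 42.4 | 36.2 |

The fatigued state therefore shifts every calibrated quantity in the
physiologically expected direction: longer mean RR, larger variability,
higher band powers.

Two deliberate simplifications:

* **Phase clock.** The modulation phase advances on the nominal beat clock
  (`i · mean_rr`) rather than realised cumulative time. Sampling a sinusoid
  at realised beat times oversamples its short-interval phases and biases
  the beat-averaged mean RR low by ≈ (amp_lf² + amp_hf²)/(2·mean_rr) —
  about 2.5 ms at fatigued defaults — which would make the generator's
  realised mean disagree with its own parameter. On the nominal clock the
  per-series mean RR is an unbiased estimate of `mean_rr` while the
  realised spectral peaks stay at ≈ 0.1 / 0.25 Hz.
* **White interval noise.** The residual noise is white in the beat domain,
  so part of it falls into the LF and especially the HF band after
  resampling. Extracted HF power on default cohorts is therefore larger
  than the calibration target (the LF target is matched closely), and the
  LF/HF ratio runs lower than in real drivers. Only the *directions* of the
  state shifts and the band-power orders of magnitude are treated as
  calibration targets, and those hold.

Each subject has a single alert→fatigued changepoint, drawn uniformly from
minutes 15–30 of a 60-minute drive by default, so every subject contributes
both states with more fatigued than alert windows. Per minute, each of 5
simulated raters reports the true (pooled) state with probability
1 − `error_rate` (default 0.1); a correct rating during fatigued truth is
*very fatigued* with probability 0.3, and an erroneous rating comes from the
opposite pooled state. Optional ECG synthesis places a five-wave Gaussian
template (P, Q, R, S, T; R strictly dominant) at each beat time with a
0.4 s lead-in so no QRS is truncated; white noise can be added at a chosen
SNR. The generator does not model respiration, baseline wander, ectopy, or
pathological morphology.

**Crucially, the generator has no between-subject baseline heterogeneity:**
all subjects of a sex share identical state parameters. Real drivers differ
substantially in resting RR and variability, which is the main obstacle to
real-world fatigue classification. Synthetic classification accuracies
(often 100 % at full cohort size) therefore demonstrate that the pipeline
detects the encoded effect, not that real 2-minute fatigue detection is this
easy.

## Windowing and labeling

Windows start at 0, step, 2·step, … with the last window ending at or before
the recording end: `count = floor((duration − window)/step) + 1`, giving 59
two-minute windows at 50 % overlap for 60 minutes. An interval belongs to
the window containing its onset timestamp, half-open `[start, end)`, so a
boundary beat is never double-counted within one window (overlapping
neighbours legitimately share beats). A window is labeled *alert* /
*fatigued* only when every covered minute reaches the same ≥ 3-of-5
consensus (fatigued and very-fatigued votes pooled); anything else is
*discordant* and removed before analysis.

## Feature conventions

* **Time domain.** DRR is the sample (n−1) standard deviation. MHR is the
  mean of instantaneous rates 60000/RR_i, not 60000/MRR. pNN15 divides
  NNN15 by the total number of intervals (not the number of successive
  pairs), read literally from the feature definition.
* **Spectrum.** The tachogram (RR anchored at the terminating beat) is
  cubic-spline resampled to 4 Hz, linearly detrended, and Welch-averaged
  (Hann, 64 s windows, 50 % overlap — two windows per 2-minute segment).
  Bands: VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.40 Hz. Two-minute records
  cannot support VLF interpretation, so VLF enters only the total power;
  normalised units are band/(LF+HF)·100, making PLF_nu + PHF_nu = 100 by
  construction whenever LF+HF > 0.
* **Poincaré.** Population-variance convention: SD1² = var(ΔRR)/2,
  SD2² = 2·var(RR) − SD1² (clamped at 0). SD1 equals RMSSD/√2 up to the
  sample/population correction and the (mean ΔRR)² term. The SD2/SD1 ratio
  of a zero-variability series is NaN, not an exception.
* **Entropies.** m = 2 and r = 0.2 × segment SD by default. ApEn is the
  Pincus definition with self-matches (so a constant series gives exactly
  0); SampEn excludes self-matches and counts pairs over the first N − m
  templates, returning NaN with a warning when no pairs match. Both use the
  Chebyshev distance and are validated to 1e-12 against literal double-loop
  oracles.
* **DFA.** Integrated mean-centred series, non-overlapping boxes, per-box
  linear detrend, α = least-squares slope of log F(n) vs log n over box
  sizes 4–16 (α1) and 16–64 (α2). The classic estimator carries a small
  positive bias at small boxes (white noise reads ≈ 0.58 rather than 0.50);
  the conventional normalisation is kept and the validation bands
  (0.5 ± 0.1 white, 1.5 ± 0.15 integrated, n = 5000) account for it.
* **Correlation dimension.** Delay embedding m = 10, τ = 1, Euclidean
  distances with a Theiler window of τ. The scaling region is chosen
  automatically as the radii at log-spaced quantiles (0.5 %–32 %) of the
  pairwise-distance distribution — the pre-saturation flank of the
  correlation integral — and D2 is the least-squares slope of log C(ρ)
  there. On ~150-beat segments a 10-dimensional embedding is data-starved;
  D2 is reported anyway (as in the table layout the pipeline mirrors) and
  should be read comparatively, not as an absolute dimension.

Degenerate inputs follow one rule: quantities that are mathematically
undefined (ratios with zero denominators, entropies with no matches,
exponents without enough boxes) become NaN with a warning where useful;
contract violations (too few beats, invalid parameters) raise with the
offending segment named.

## Statistics

Group tables report mean, sample SD and quartiles (linear interpolation
between order statistics — no convention is universal, this one is the
common spreadsheet default). The Mann–Whitney U uses midranks; for
n1 + n2 ≤ 12 the exact two-sided p is computed by enumerating all
C(n1+n2, n1) group assignments, otherwise a tie-corrected normal
approximation with continuity correction (verified to agree with the exact
path within 0.02 on tie-free 6+6 samples, and with an independent
asymptotic implementation to 1e-10). The significance threshold is 0.01
with **no multiple-testing correction across the 20 features** — the
comparison tables mirror a design that applies none, and the raw p-values
are reported so any correction can be applied downstream.

Overlapping windows make neighbouring segments statistically dependent; the
tests are nevertheless applied segment-wise (the design the pipeline
replicates) and this caveat is the reason the *null-calibration* experiment
in the acceptance suite uses non-overlapping windows (step = window) with
the changepoint on a window boundary: there the segments are genuinely
independent draws and the binomial reference for the empirical test level
is exact. Measured on 100 null cohorts, per-feature rejection counts at
α = 0.01 were 0–3 (nominal 1).

## Classifier

CART with Gini impurity 1 − Σp², candidate thresholds at midpoints between
consecutive distinct sorted values, and sample-weighted child impurity.
A node becomes a leaf when pure, smaller than `min_samples` (default 5;
the stopping threshold is otherwise unconstrained by the replicated
design), or when no split strictly reduces impurity. Leaves predict the
majority class, ties going to *fatigued* (the majority class of the study
design). No pruning. All tie-breaks are deterministic: features in the
canonical 20-feature order, thresholds ascending, strict improvement only —
reproducibility requires fixing these even though impurity ties between
different features are common on small nodes (a reference implementation
with randomized tie-breaking produces different but equally optimal trees).

Two engines share this exact specification: a recursive `TreeNode` builder
for inspection and a flat-array engine compiled with numba that makes the
exhaustive subset search fast (~0.3 ms per tree at n ≈ 100); tests assert
their predictions are identical on random fixtures. Each search uses one
stratified 8:2 train/test split shared across all subsets so accuracies are
comparable; ranking is by test ACC, then SEN, then subset order. Because
overlapping windows of one subject can land on both sides of a
segment-level split, test accuracy is optimistic; a subject-wise split mode
(whole subjects held out) is provided for leakage-free evaluation.

## Problem sizes in the test suite

Replicate-based experiments are run at reduced cohort sizes chosen as the
package's own test design: null calibration and shift-direction checks use
3+3 subjects × 20 minutes (100 and 50 replicates), the classifier-power
check 2+2 subjects × 20 minutes with the full 4845-subset k=4 search per
replicate (50 replicates; measured median margin of the best tree over the
majority baseline ≈ 36 percentage points (range 29–47)). `scripts/acceptance.py` runs
the full 18-subject, 60-minute study once.

## Known limitations

* No between-subject heterogeneity, respiration, or circadian structure in
  the generator; synthetic classification difficulty is far below real data.
* Broadband interval noise inflates extracted HF power relative to the
  calibration target (LF is matched closely).
* Spectral details (detrending, windowing) follow common open conventions,
  not any specific commercial HRV package; absolute band powers from other
  software will differ.
* D2 and α2 on 2-minute segments are at or below the lengths where these
  estimators stabilise; they are computed for table parity, flagged here.
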