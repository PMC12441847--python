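# Methods

## Problem and approach

Nanomotion-based drug susceptibility testing (DST) records the deflection of
a micro-cantilever carrying living cells as a single sampled channel, in
three phases: a short *blank* phase (bare functionalized sensor), a
*medium* phase (cells attached, no drug) and a *drug* phase after drug
addition. Susceptible cells change their micromechanical activity after
drug exposure; resistant or untreated cells do not. `nanodst` turns such
recordings into quantile-spectral features and classifies them with a small
logistic model.

Deflection amplitudes are uncalibrated (arbitrary units). Every statistic
downstream is therefore either scale-invariant (spikiness, Jensen–Shannon
distance, quantile ratios, classification after z-scoring) or explicitly
scale-sensitive and documented as such (band power, variance trace).

### Recording clock

All window and interval times are measured from the start of the medium
phase (t = 0). The blank phase has no standardized duration, lives at
negative clock times, and is excluded from every feature interval. Slicing
a recording to one phase (`phase_segment`) preserves this clock, so a
drug-only sub-recording still knows that the drug phase starts at, say,
minute 120.

## Quantile spectrograms

The core transform replaces the averaging step of Welch's PSD estimator
with per-frequency empirical quantiles. A time window of the recording is
cut into tapered, detrended segments; each segment's one-sided PSD-scaled
periodogram is one draw from the local power distribution; the quantile
spectrum at level q is the per-frequency q-quantile over those draws
(linear interpolation between order statistics, hence monotone in q by
construction). Stacked over successive windows this gives the 3-D quantile
spectrogram (level × frequency × window).

Two identities pin the estimator:

* **Welch consistency** — the mean over segment periodograms equals the
  textbook Welch estimate exactly (verified against `scipy.signal.welch` at
  1e-10 relative).
* **Chi-squared law** — for Gaussian white noise with boxcar taper and no
  overlap, periodogram ordinates at interior bins are exponential
  (chi-squared, 2 df), so quantile curves have the closed form
  −μ·ln(1−q) and the median/mean ratio is ln 2 ≈ 0.693 per bin.

Defaults: 1 s segments, 50% overlap, Hann taper, constant detrend. Nothing
forces these choices; 1 s gives 1 Hz resolution — ample for the 0–10 Hz
band — and several hundred segments per 5-minute window, which stabilizes
decile estimates. With overlapping segments the periodogram draws are
correlated; quantiles are still taken over the raw segment set. The
resulting mild bias is accepted rather than inventing a decorrelation step;
the boxcar/no-overlap configuration is the one compared against closed
forms. The DC bin is dropped from the spectrogram: after constant
detrending it is numerical residue.

Windows tile each contiguous run of included phases, non-overlapping,
trailing partial windows dropped (determinism over data retention at these
sample counts). Two window profiles are used: 5-minute windows over
medium+drug (low-frequency, colon-cell style analysis) and 15-minute
windows over the drug phase only (ovarian-style analysis, where the medium
phase is kept solely for cell recovery and excluded from features).

## Features

A feature is a fully parameterized descriptor evaluated on the spectrogram;
its canonical name alone reproduces its value (total provenance, tested by
a parse/format round-trip). Conventions are half-open everywhere: bands
[f_lo, f_hi) Hz, intervals [t_lo, t_hi) minutes, windows identified by
start time.

Per window and band at one quantile level:

* **band_power** — mean PSD over the band's bins.
* **spikiness** — max/median over the band's bins. The literature leaves
  "spikiness" undefined; max/median is scale-free, robust to the bulk of
  the band, and captures peakedness. The definition is isolated behind the
  descriptor kind so a crest factor could replace it as a one-point change.
* **js_chi2** — Jensen–Shannon distance between the band's values and a
  chi-squared reference scaled to the empirical mean: the positive axis is
  split into K = 16 equal-probability bins of the scaled reference, and the
  base-2 JS distance (square root of the divergence; a metric in [0, 1])
  between empirical bin frequencies and the uniform 1/K mass is returned.
  df = 2 is the raw-periodogram law for Gaussian noise; quantile-spectrum
  values are order statistics of that law, so df stays configurable.
* **quantile_ratio / quantile_difference** — ratio or difference of band
  mean power between two quantile levels.

Per-window values are pooled over all windows whose start lies in the
interval, and the descriptor's summary percentile of the pool is the
feature value. The percentile-over-windows reading (rather than over bins
or levels) is a declared convention. A difference/ratio combinator applies
between the summaries of two intervals; the grammar generates such pairs
for every unordered pair of its intervals. The full Cartesian grammar
reaches hundreds of thousands of columns at fine grids; defaults are
desk-scale (tens of columns). Non-finite feature values raise — there is no
imputation.

## Classification protocol

* **Split** — stratified 4:1:1: per stratum of size n, train = ⌊4n/6⌋,
  validation = ⌊n/6⌋, test = remainder; membership randomized by seed,
  counts deterministic. This floor/remainder rule is the unique simple
  rounding reproducing the study's printed tables (34 → 22/5/7, 24 →
  16/4/4, 38 → 25/6/7, 36 → 24/6/6). Strata may combine label and dose.
* **Selection** — greedy forward selection capped at two features: each
  step fits candidate logistic models on training rows and scores accuracy
  on the pooled train+validation predictions, stopping when no addition
  improves accuracy. Ties break on the lowest canonical descriptor name;
  zero-variance training columns are skipped with a log entry. A
  validation-only scoring pool is available behind a flag.
* **Fit** — z-scoring (training rows only) then logistic regression with a
  weak L2 penalty (C = 1000). The penalty is always on: a separable 1-D
  feature makes the unpenalized likelihood diverge while the decision
  boundary — the only thing used — is unaffected.
* **Decision rule** — class = positive iff the linear score ≥ 0; the
  boundary itself counts as positive (susceptible).
* **Metrics** — accuracy as the proportion of correctly classified samples,
  per-class recall, average precision by the step-interpolation definition,
  and the random-classifier AP baseline = positive prevalence of the
  evaluated subset.
* **Isolation** — test rows never touch standardization, selection or
  fitting; a test perturbs test-row values and asserts identical models.
* **Exposure sweep** — for each exposure duration, features are rebuilt
  from drug-phase windows ending within it and accuracy is estimated by
  stratified k-fold cross-validation (default 6 folds, echoing the 4:1:1
  granularity) on the train+validation rows; the plateau is the first grid
  point no later point beats by more than the tolerance.

## Synthetic recordings

No raw nanomotion recordings are publicly deposited, so a seeded generator
stands in. A recording is

    white noise (σ) + 1/f^α noise (FFT spectral shaping, α default 1)
    + optional resonance noise (biquad peak filter, emulating the
      cantilever resonance near 8.5 kHz)
    + Poisson spike train (exponential amplitudes, half-cosine pulse).

For positive labels only, the power in a configured band [f_lo, f_hi)
relaxes multiplicatively from baseline toward baseline × power_ratio with
an exponential time constant τ after drug onset (implemented as amplitude
modulation of the FFT-extracted band component, leaving out-of-band power
untouched — a tested invariant). The spike rate can be modulated likewise.
The generator deliberately models no cell biophysics; its contract is only
that classes differ through band-limited spectral statistics, and tests
hold for power_ratio below or above 1 since the sign of the real effect is
not established.

Defaults follow the study's phase structure (2 h medium, 2–6 h drug; blank
duration unstated, default 5 min) at a desk-scale 4 kHz sampling rate —
full-rate 60 kHz × 8 h would be ~1.7 G samples and adds nothing to the
method. The 4 kHz default disables the resonance (above Nyquist); an
18 kHz `ovarian_profile` enables it together with the 7–8 kHz effect band.

What the generator does *not* emulate: nonstationary drift, temperature
transients, attachment/detachment events, multi-cell interference, or any
realistic cell spectrum. Passing tests therefore demonstrate that the
pipeline recovers band-localized spectral effects under its own stated
noise model — not performance on real recordings.

## Recovery study (the package's integration benchmark)

`nanodst.pipeline.run_recovery_study` simulates 20 positive + 20 negative
recordings (4 kHz; 1 min blank, 30 min medium, 30 min drug; 0.5–10 Hz power
quartered with τ = 10 min), computes 5-min quantile spectrograms, evaluates
a six-feature grammar (band power and spikiness of the median spectrum in
three bands over minutes 45–60), splits 4:1:1, forward-selects and fits.
The held-out accuracy is expected ≥ 0.9 and the greedy first pick must
equal an exhaustive single-feature oracle. The 30-minute phases are a
deliberate scale-down that preserves segment counts per window; they are
the study conditions of this benchmark, not tuning knobs.

## Viability and IC50

Relative viability = 100 × (A_exp − A_bg)/(A_ctrl − A_bg), not clipped.
Dose–response uses the four-parameter logistic ("variable slope") model
v(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill), fit by bounded
nonlinear least squares in linear parameter space (IC50 through its log for
positivity; bottom ≥ −10%, top ≤ 150%, hill free-sign). Zero-concentration
wells enter through the asymptote rather than being dropped by a log
transform. Initialization takes top/bottom from the data extremes, the
IC50 guess from the log-midpoint of the half-maximal crossing, and the hill
sign from the trend. Non-convergence is flagged on the result, not raised.
The reference IC50 values reported for the ovarian pair (0.602 μM
sensitive, 6.189 μM resistant) are context only — the underlying absorbance
points are not machine-readable — so recovery is validated on simulated
curves: noiseless round-trips within 1%, and mean bias below 5% under 5%
Gaussian noise at 8 concentrations × 3 replicates over 200 seeds.

## Numerical conventions

* Population (n-denominator) variance in the variance trace; at ~10⁵
  samples per 8 s window the n vs n−1 distinction is far below noise.
* Trailing partial windows are dropped everywhere.
* Quantiles/percentiles use the linear-interpolation estimator throughout.
* Degenerate inputs raise: non-finite samples, non-positive PSD values in
  spikiness/js_chi2, empty bands/intervals, single-class training sets.
  The one warning-not-error case is a single-segment quantile spectrum
  (all levels collapse) and sub-3-sample strata (test subset may be empty).

## Known limitations

* The exact segmentation parameters of the original "modified Welch"
  analysis are unpublished; defaults here are declared conventions, and all
  are configurable.
* Overlapping-segment quantiles carry a small correlation-induced bias.
* The printed real-data accuracies (100%/90.9% colon; 84.6% ovarian; 84%
  plateau) are not reproduction targets: without the raw recordings they
  document context, not benchmarks.
* The amplitude-modulation effect model slightly smears the band edge at
  very short τ; with the default τ of minutes this is negligible.
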