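# Methods

This note documents the models implemented in `striakit`, the defaults and
why they were chosen, the numerical decisions taken where a published
description is silent or ambiguous, and the limits of what the synthetic
data can establish.

## Photometry processing chain

A recording holds a 465 nm sensor channel and a 405 nm isosbestic control
channel sampled at a common rate, plus one autofluorescence scalar per
channel (fluorescence measured with the patch cord disconnected from the
animal). Processing stages, in order, each logged in the trace's provenance
record:

1. **Downsampling** by mean binning to a target rate (default 120 Hz).
   Acquisition systems record at kS/s rates after an anti-alias low-pass;
   mean binning is itself a box filter, and an optional zero-phase
   Butterworth low-pass (`lowpass_hz`) can emulate a hardware filter before
   binning. 120 Hz retains the 1–2 s transient kinetics of ACh biosensors
   with a wide margin.
2. **Autofluorescence subtraction** of the per-channel scalar.
3. **Photobleaching detrend**: least-squares fit of `a·e^(−t/τ) + c` per
   channel; the fit is subtracted and the pre-detrend channel mean restored
   as an offset. If the fit does not converge the channel falls back to a
   linear detrend and the provenance records it.
4. **ΔF/F** = (F − F₀)/F₀ with F₀ = fitted asymptote `c` plus the restored
   offset. There is no universal F₀ convention; this one makes F₀ the
   fitted steady-state fluorescence of the channel, is invariant under
   positive affine rescaling of the raw data (jointly with the
   autofluorescence scalar), and errors out when non-positive.
5. **Control subtraction**: signal ΔF/F minus control ΔF/F, plain
   subtraction (a least-squares scaling of the control onto the signal is
   available but off by default — with a true isosbestic channel the
   shared artifacts already enter both ΔF/F traces at unit gain).
6. **z-scoring**. A zero-variance trace (e.g. identical channels) is an
   error, not a silent NaN.

Numerical notes on the exponential fit: τ is initialized at a third of the
recording span; `a` is bounded to ±10× the data range and the asymptote `c`
to the data range ± one range. The bound on `c` matters: for recordings
much shorter than the bleach time constant the (a, τ, c) likelihood surface
is nearly flat along a trade-off direction and an unconstrained `c` can run
away to large negative values, which would poison F₀. Within the bound the
fitted curve is unchanged for practical purposes (verified against a
grid-search fit in the tests).

## Transient detection

Detection uses a two-stage unscaled-MAD rule on the z-scored trace `z`:

* residual `r = z − rollmed(z)` with a centered 10 s rolling median
  (window rounded up to an odd sample count; edge windows shrink);
* `MAD₁ = median(|r − median(r)|)` over all samples, with no 1.4826
  normal-consistency factor — thresholds are in raw MAD units;
* the *filtered trace* keeps samples with `r ≤ 2·MAD₁` (one-sided: only
  high-amplitude excursions are excluded), in a single pass;
* with `m_f` and `MAD₂` the median and MAD of the filtered trace, events
  are strict local maxima of `z` above `m_f + 3·MAD₂`. A flat plateau
  higher than its surroundings counts once, at its first sample; endpoints
  never count. Peaks closer than `min_sep_s` (default 0.5 s) are resolved
  keeping the larger peak, the earlier one on an exact tie. Amplitudes are
  reported as `z − m_f` at the peak.

Which MAD backs the peak threshold is configurable (`peak_mad="filtered"`
default, `"residual"` for sensitivity analyses); anchoring the threshold to
the filtered trace keeps both the location (`m_f`) and the scale (`MAD₂`)
estimates on the same event-purged sample. Per-recording diagnostics
(`m_f`, both MADs, the threshold) are exported on the event train so that
group-level comparability of medians and thresholds can be checked.

Summaries: frequency = count/duration·60 (events/min); inter-event
intervals are successive peak-time differences; IEI distributions are
compared with the two-sample two-sided Kolmogorov–Smirnov test (asymptotic
p, via scipy).

### False-positive behavior on noise-dominated traces — a known limitation

The 3-MAD rule places the peak threshold at `≈ 3 × 0.674 ≈ 2` robust
standard deviations above the baseline. For any Gaussian-dominated trace
the rate of local maxima exceeding u·σ is approximately
`bandwidth × exp(−u²/2)`, so at u ≈ 2 the detector fires on noise at
roughly 13% of the noise-maxima rate: ~75 events/min for white noise
sampled at 120 Hz, ~50/min for 12 Hz-band noise, still ~2/min for noise
smoothed to 0.3 Hz. Pushing the false-positive rate to ≤ 0.1/min would
require an effective noise bandwidth near 0.01 Hz — fluctuations on the
scale of minutes — which is incompatible with resolving 1–2 s transients.
Consequently, on synthetic traces whose between-event variance is honest
instrument noise, detector output is noise-peak-dominated: the
false-positive rate is orders of magnitude above 0.1/min, the detected
frequency does not track the true event rate (it can even *decrease* as
true events crowd out noise peaks under the minimum-separation rule), and a
two-fold difference in true rate between groups is not recovered as a
two-fold frequency ratio. The corresponding acceptance tests are left
failing by design rather than weakened; they document the recipe's
behavior. On real recordings the rule behaves better to the extent that
the between-event trace is dominated by slow sensor/physiological
fluctuations rather than broadband noise — but the sensitivity is then set
by that slow component, not by instrument noise. Detection of *large*
events is unaffected: transients of ≥ 5 z-units are recovered with > 95%
hit rate (±2 s) in the tests, and detected event *times* are reliable even
when the count is not.

## Spot-field co-localization

For each channel-A spot the Euclidean distance to the nearest channel-B
spot (directional A→B; a 2-D analysis, as the images are projections) is
computed with a k-d tree and binned into a 10 nm-wide histogram over
[0, 500] nm plus an open overflow bin, so counts always conserve spots.
Spots with NND ≤ 95 nm are classified co-expressing — ties count as
co-expressing, since "below the threshold" does not resolve equality and
the threshold itself carries measurement uncertainty far larger than a tie.
Group fractions are compared by Pearson χ² (1 df, no continuity correction
by default); NND distributions by KS.

No edge correction is applied for spots near the field border; their NNDs
are biased upward, which at the default geometry (10 × 10 µm field, 95 nm
threshold) affects < 4% of spots and shifts the co-expressing fraction by
well under a percentage point. The chance co-expression fraction under
complete spatial randomness, `1 − exp(−ρπr²)`, bounds the opposite bias
from accidental neighbors (≈ 2.8% at ρ = 10⁻⁶ spots/nm², r = 95 nm).

## Uptake arithmetic

Cells are keyed by genotype × condition; SEM uses the sample sd (n−1
denominator) and is flagged undefined for n < 2. Percent changes and
transporter contributions take an explicit rounding mode because published
percent summaries mix conventions — from the same printed means,
100·(25.3 − 11.9)/11.9 = 112.6 prints as +113 (nearest) while
100·(16.21 − 9.27)/9.27 = 74.9 prints as +74 (truncation); the library
defaults to unrounded values and lets the caller choose the rendering.
Group comparisons implement exactly the two named designs: one-way ANOVA
with Tukey's HSD, and two-way ANOVA (type-II, via statsmodels OLS) with
Bonferroni-corrected pairwise t-tests; all-constant groups are flagged
`degenerate_variance` instead of producing an undefined F.

## Addiction-like criteria and cohort arithmetic

The phrase "75th percentile of the normal distribution of the control
group" is read as the *empirical* 75th percentile (linear interpolation
between order statistics); a Gaussian-quantile mode (mean + 0.6745·sd)
is provided behind a flag because the wording also admits that reading.
Criterion positivity is strict (score > threshold, so threshold-equal
scores are negative), the addicted label requires ≥ 2 of 3 criteria, and
thresholds must come from the control group of the same experiment and
epoch. The classification is invariant under any strictly monotone
transform applied consistently to a criterion (property-tested), which is
why the empirical-percentile reading is the safer default. With continuous
scores and a large control group each criterion marks ≈ 25% of controls
positive by construction.

Carrier prevalence renders to one decimal as percentages are printed
(9/793 → 1.1%). Allele frequency is risk/(risk + reference); note that
counts of 9 risk vs 1595 reference alleles give 0.56%, not the 0.8%
sometimes quoted alongside them — the arithmetic is reported as computed
and the discrepancy left to the caller. Fisher's exact test returns the
sample odds ratio and the conditional two-sided p (sum of hypergeometric
tables with probability ≤ observed), verified against full enumeration for
all margins ≤ 12.

## Synthetic data

All generators draw from an explicit per-call seed; no global RNG state.
Randomness is split into component substreams (events, artifact, per-channel
noise) so that sweeping one parameter at a fixed seed keeps the other
realizations identical — a variance-reduction device for parameter sweeps,
not a statistical assumption.

**Photometry** (defaults: 20 min at 600 Hz): signal = autofluorescence
(10 a.u.) + baseline (100 a.u.) + bleach (30 a.u., τ = 600 s) + transients
+ shared artifact + white noise (sd 1 a.u.); control = the same minus
transients, with its own noise draw and autofluorescence (8 a.u.).
Transients: homogeneous Poisson onsets (default 2/min), peak-normalized
difference-of-exponentials kernel `(1 − e^(−t/0.3 s))·e^(−t/1.5 s)` scaled
to 5 a.u. (≈ 5% ΔF/F — typical ACh-sensor kinetics and amplitude),
overlaps summing linearly. The artifact is Gaussian noise smoothed to
≈ 0.5 Hz, sd 1 a.u., shared across channels to emulate motion. The
generator does *not* emulate hemodynamic spectra, sensor nonlinearity,
wavelength-dependent artifact gain, or slow physiological ACh fluctuations
between events; in particular its between-event variance is honest
broadband noise, which is exactly the regime where the MAD detector's
false-positive limitation (above) is maximal. Recovery results on these
traces therefore characterize the recipe under a noise-dominated baseline,
not under every real-data regime.

**Spot fields** (defaults: 10 × 10 µm, 200 A spots, 40% paired,
Rayleigh σ = 40 nm displacement at uniform angle, 20 unpaired B spots):
emulates a two-transporter vesicle preparation with ~40% co-expression and
an NND peak near 50 nm (the Rayleigh mode equals σ). Ground-truth pair ids
are retained. Localization error beyond the pairing displacement, spot
intensity, and clustering of singletons are not modeled. At these defaults
the 95 nm classifier's expected fraction is
0.4·(1 − e^(−95²/(2·40²))) + chance ≈ 39.3%, slightly below the generative
40% (Rayleigh tail beyond 95 nm, partly offset by chance neighbors) —
within the ±3-point recovery tolerance used in the tests.

**Uptake replicates**: zero-truncated normal per cell; the default cells
encode the printed wild-type/mutant ACh-uptake group summaries
(mean ± SEM with n = 7–8), converting SEM to sd by √n. **Behavior
scores**: multivariate normal per genotype (floored at 0), defaults with
identical distributions across genotypes (persistence 30 ± 10, motivation
35 ± 12, compulsivity 10 ± 4, mild positive correlations), n = 14 per
genotype matching typical cohort sizes; the scale is plausible for a long
fixed-ratio schedule rather than calibrated to any dataset.

## Problem sizes in the test and acceptance runs

The test suite and `scripts/acceptance.py` use 20-min recordings for
detector error-rate and ratio measurements (50 event-free traces; 7 + 7
per-group recordings), 20 spot fields per co-expression estimate, 10⁴
paired spots for the Rayleigh CDF check, and 4–5 × 10³ animals for
classifier-calibration checks — sizes at which the Monte-Carlo standard
errors are several times smaller than the tolerances being asserted, while
a full run stays in the minutes range on one CPU.

## Known limitations

* The MAD detector's false-positive rate on noise-dominated traces (see
  above) — the dominant caveat for any frequency readout.
* No edge correction in NND analysis; 2-D projections only.
* The two-way ANOVA post hoc uses pooled-variance pairwise t-tests with
  Bonferroni correction across all cell pairs, the most common reading of
  "Bonferroni post hoc"; marginal-mean contrasts are not implemented.
* Behavioral score simulation is Gaussian; real operant counts are
  discrete, skewed and occasionally zero-inflated, so classifier
  calibration at small n should be checked against the empirical data at
  hand.
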