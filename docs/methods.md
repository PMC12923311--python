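# Methods

`nbceus` quantifies nanobubble contrast-enhanced ultrasound (CEUS) cine
loops of the kidney: per-pixel time–intensity-curve (TIC) kinetics,
echo decorrelation-time (DT) mapping, co-occurrence texture of the
parametric maps, and two-group / correlation statistics. A seeded
synthetic cine simulator provides ground-truth data so every stage can
be verified at desk scale. This note records the models, the defaults
and why they were chosen, and what the synthetic validation does and
does not demonstrate.

## Acquisition model

An acquisition series is a sequence of continuous imaging windows
("acquisitions", Aq 1..n), each a stack of 2-D frames at a fixed frame
interval, with start offsets measured from contrast injection. The
reference protocol is six contiguous 200-s windows of 1000 frames at 5
frames per second (~20 min total). All intensities are linear,
non-negative, arbitrary units; analyses assume linear scale, so
dB-compressed exports must be converted (10^(dB/20)) before use.

The **desk-scale protocol** used by the tests and validation studies
keeps the six 200-s windows and the 20-min timeline but samples at
0.8 s (250 frames per window) on a 64×64 grid. Window *duration* is
preserved deliberately: z-scoring each pixel's within-window series
removes its mean, which caps the largest observable decorrelation lag
at roughly one sixth of the window length regardless of the underlying
process. A 10-s retention threshold is therefore only meaningful when
one window spans a few minutes — shortening windows to 50 s would make
the threshold unreachable for any signal. Reducing the frame rate
instead preserves the whole temporal structure of the protocol at a
quarter of the data volume.

## TIC parametrics

For a pixel's (or the whole organ's) concatenated TIC, features are:

* **TTP** — time from the first sample to the first maximum of the
  smoothed curve (centered moving average, edge-truncated; default
  window 5 frames; ties broken by earliest occurrence);
* **PI** — the smoothed maximum;
* **AUC / AUrC / AUfC** — trapezoidal areas on the *unsmoothed*
  samples: total, start→peak (inflow), peak→end (washout + retention).
  The peak sample belongs to both limbs, so AUrC + AUfC = AUC exactly
  (machine precision), and smoothing never changes the integrals.

Trapezoids are not drawn across inter-acquisition gaps (an interval
longer than twice the median spacing). No baseline subtraction happens
by default — synthetic data start at zero — but a
`baseline_frames` option subtracts the mean of the first N frames,
floored at zero.

Map histograms report the n−1 sample variance, moment-based skewness
g1 (undefined for constant maps), and fixed percentiles.

## Decorrelation-time mapping

Within one acquisition, each masked pixel's series is z-scored (sample
SD) and its autocorrelation estimated with the biased estimator
normalized by the lag-0 sum, which guarantees r(0)=1 and |r(k)|≤1 and
is stable at long lags. The DT is the first lag where r(k) falls to
the threshold (default 0.5), linearly interpolated between adjacent
lags for sub-frame resolution. Searching extends to
`max_lag_fraction` (default 0.5) of the window; pixels that never
cross are *censored* and, under the default `assign_cap` policy, enter
summaries at the cap value, making mean DT a conservative lower bound
(`exclude` drops them instead). Zero-variance pixels are missing and
excluded everywhere. No detrending is applied beyond z-scoring.

For an AR(1) fluctuation with coefficient ρ the theoretical ACF is
ρ^k, so DT → ln(0.5)/ln(ρ)·Δt; this analytic oracle anchors the
estimator tests (ρ = 0.5, 0.8, 0.95 → 0.20, 0.62, 2.70 s at 5 fps,
recovered within 10% over 100 seeds). A z-scored sinusoid of period P
has ACF ≈ cos(2πk/P), crossing 0.5 at P/6 — the second, independent
oracle.

Summaries per acquisition: mean DT (overall retention), spatial n−1
variance of DT (patchiness of retention within a kidney), and the
count of pixels above `dt_threshold_s` (default 10 s, the extravasated
area), plus the censored fraction.

## Texture

Parametric maps are min–max quantized to `levels` gray bins (default
32) inside the mask (maximum maps to the top bin; constant maps to bin
0). Co-occurrence counts accumulate over the four distance-1
directions into a single symmetric matrix; pairs touching the mask
boundary or a missing value are dropped, not zero-padded, so organ
edges contribute no artificial texture. Features: contrast
Σp(i,j)(i−j)², energy Σp², homogeneity Σp/(1+|i−j|), correlation
Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) (missing when a marginal is degenerate). Note
the homogeneity kernel is 1+|i−j|; scikit-image's `graycoprops` uses
1+(i−j)², so only contrast/energy/correlation are directly comparable
across the two implementations (the tests do exactly that comparison,
plus an exact naive-enumeration oracle for all four).

## Group statistics

Two-group comparisons use Welch's unequal-variance t-test
(Welch–Satterthwaite df, two-sided p) and Glass's Δ — the mean
difference in units of the *control* (sham) group's n−1 SD, injury
always the treated group. Δ ≥ 0.8 is read as a large effect. In batch
comparisons a zero control SD yields Δ = ±∞ (its limit) rather than an
abort; the scalar function raises.

Correlations are product–moment Pearson r, by default on
log10-transformed values (density-like quantities spanning decades;
non-positive values are dropped pairwise with a logged warning), with
p from the exact t transform; Spearman is available as
`method="spearman"`. Phase averaging takes each animal's mean over
the acquisitions it has within the early (Aq 1–3) and late (Aq 4–6)
phases, so animals lost mid-experiment contribute up to their last
acquisition. No multiple-testing correction is applied by default.

## Synthetic cine model

Per pixel, the noise-free mean is a vascular bolus plus a retention
term:

    s(t) = A · (t/t_p)^α · exp(α(1 − t/t_p))
         + B · (1 − exp(−t/τ_in)) · w(aq)

The gamma-variate kernel peaks at exactly (t_p, A), making TTP/PI
recovery testable in closed form; α defaults to 2, τ_in to 120 s. The
acquisition weight w(aq) is 0 through Aq 1–3 and climbs linearly to 1
at Aq 6 (`retention_ramp_start=4`; setting 1 gives a plain linear
0→1 ramp). The late-start default emulates extravasation that has not
yet accumulated during the early phase; with an early-starting ramp
the retained-agent fluctuation already separates the groups at Aq 2–3,
because per-animal summaries average thousands of pixels and amplify
any systematic early residue into an enormous effect size.

Temporal fluctuations are multiplicative AR(1) processes with states
carried across acquisition boundaries: the vascular component carries
a fast coefficient (ρ_fast = 0.3) everywhere, the retention component
the per-pixel coefficient (ρ_slow = 0.995 on retention pixels). This
two-component form is what makes retention pixels decorrelate fast
early (vascular signal dominates) and slowly late (retained signal
dominates), mirroring agents that extravasate over minutes. Additive
Gaussian noise (σ_add = 3 vs. vascular amplitude 40) models the
electronic floor; the multiplicative scale σ_mult = 1.5 is a
speckle-like stand-in — full Rayleigh speckle physics, attenuation,
shadowing and motion are deliberately out of scope. Intensities are
clipped at zero; frames are float32.

Geometry: a seeded ellipse (~50–70% of the frame) with an inner
medulla whose amplitude is scaled by 0.6, reproducing the medulla
enhancing less than the cortex. Patchy structures (retention,
hypoperfusion) are thresholded Gaussian-smoothed random fields
(smoothness 8 px) cut at the within-mask quantile, so requested area
fractions are met to one-pixel granularity.

Cohorts: controls draw a retention fraction near 0.02, injury animals
near 0.25 (per-animal jitter SD 0.005 / 0.06); injury kidneys
additionally get hypoperfused patches (20% of the organ at amplitude
×0.5) and a delayed, more heterogeneous wash-in (t_p 12.5 ± 2.5 s
between animals vs 10 ± 3.0 s for controls; spatial SD 2.0 vs 1.5 s).
A per-animal lognormal gain (SD 0.3 of log) on A and B jointly mimics
dose/attenuation/system-gain variability. The between-animal spreads
matter: they set the within-group variance against which Welch's test
judges the (wanted) late-phase difference and the (unwanted)
early-phase residuals, and they give the histology correlations a
severity range to work with. With these defaults, 100-replicate
studies show all three late-phase DT metrics significant with Δ ≥ 0.8
in every replicate and early-phase comparisons non-significant in
~85–93% — the early/late pattern the analysis is designed to detect.

Synthetic histology couples three read-outs (ordinal tubular-injury
score 1–5, neutrophil density, extravascular fluorescence density) to
each animal's latent severity — its true retention fraction. Densities
are proportional to severity with lognormal noise whose SD is derived
from the cohort's log-severity spread so that the expected Pearson r
(log scale) equals `target_correlation` (default 0.8);
`target_correlation=1` is exactly noiseless. The injury score is
1 + 9·severity, clipped to [1, 5], so zero severity sits exactly at
the floor.

What passing on synthetic data does **not** show: robustness to
motion, attenuation/shadowing, nonlinear-propagation artifacts, real
speckle statistics, segmentation error (masks are inputs here), or any
particular in vivo effect size. The studies demonstrate that the
estimators recover known truth and that the pipeline detects the
qualitative injury pattern it targets, at the configured noise levels.

## Numerical choices and degenerate inputs

* ACF via FFT (padded to the next power of two), identical to the
  direct sum to ~1e-15.
* Threshold crossings interpolate linearly; the first-crossing rule
  plus r(0)=1 make the interpolation denominator strictly positive.
* Peak ties → earliest time; constant TICs → TTP 0, AUrC 0.
* Constant maps quantize to level 0; their GLCM has all mass at (0,0),
  energy 1, correlation missing.
* Welch with both groups degenerate and equal means → t=0, p=1.
* Per-animal seeds spawn from one master `SeedSequence`; identical
  seeds and configs give bit-identical outputs (CSV bytes compared in
  the tests).
* Missing values: NaN in float maps/TIFFs, empty fields in CSVs.

## Validation study sizes

The replicated studies run at desk scale: 100 cohorts (4+6 animals,
64×64, 6×250 frames) for the group-separation rates, 50 cohorts for
correlation recovery, 100 seeds × 5000 frames for the AR(1) oracle,
10,000 random curves for the TIC decomposition sweep, 1000 replicates
for the Welch null calibration. The full 128×128 × 1000-frame protocol
is available through `PipelineConfig` / `AcquisitionSchedule`.

## Known limitations

* DT is estimated within windows without detrending; strong wash-in
  trends early in an acquisition register as genuinely slow signal
  (they are), which inflates Aq-1 DT for both groups.
* The censoring cap makes mean DT conservative but
  threshold-count-friendly; under `exclude` the mean refers to the
  crossing pixels only.
* Quantization is per-map min–max, so texture features are invariant
  to affine intensity changes but sensitive to single extreme pixels
  stretching the range.
* The simulator's two tissue fluctuation components are an idealized
  stand-in for bubble kinetics; its parameters are calibrated for the
  qualitative injury pattern, not fitted to any animal dataset.
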