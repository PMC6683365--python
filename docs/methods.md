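# Methods

This note documents the models and numerical choices behind `surfmsi`,
what the synthetic-data generator does and does not emulate, and the
known limitations. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Ion-image extraction

A pixel's value for a target ion is the **sum** of the intensities of
all centroided peaks with |m/z − target| ≤ tolerance; the window is
closed on both sides and the default tolerance of 1 Da is a half-width
(total window 2 Da). Sum rather than maximum was chosen because TOF
peaks can split across neighbouring centroids; the choice is pinned by
an oracle test against a naive double loop. Raster positions without a
recorded spectrum are NaN, distinct from a recorded zero.

imzML I/O delegates to pyimzML; intensities are stored as float32 and
m/z as float64 (a common imzML dialect), so round trips preserve
intensities to float32 precision only. In-memory coordinates are
0-based (x = column, y = row); the format's 1-based indices are
converted at the boundary.

## Normalization chain

1. **Log transform**: log10(intensity + 1). The pseudocount of one raw
   unit is negligible against baselines of ~100 counts and keeps
   recorded zeros finite.
2. **Tissue segmentation**: Otsu threshold on log10 total ion current,
   morphological closing (radius 1), largest 8-connected component.
   Two degenerate cases return the whole slide: no real TIC bimodality
   (between-class separation < 0.15 log10 units), and a high-TIC class
   covering < 10% of pixels — the signature of a homogenate-covered
   calibration slide where the only bright pixels are the standard
   spots themselves, not tissue on glass.
3. **Background/signal classification**: a deterministic 1D
   two-component Gaussian mixture on the log intensities (EM; means
   initialized at the 10th/90th percentiles, equal initial weights and
   variances; posterior assignment). The lower-mean component is the
   background. Model-based clustering matters here: the background is a
   tight, dominant population while the signal spans several decades,
   and a plain two-means rule places its midpoint boundary so high that
   low-dose signal pixels contaminate the background cluster — observed
   to bias the subtracted background mean by ~+0.15 log10 units and the
   recovered calibration intercept from 0.2 to ~0.0. Posterior
   assignment keeps the boundary at the background's upper tail.
   Constant input degenerates to a single all-background cluster with a
   warning.
4. **Batch correction**: subtract, per sample and per ion, the mode of
   the Gaussian KDE (Silverman bandwidth, 512-point grid over the data
   range) of the log intensities — equivalently, set the background
   mean to zero. The mode is computed over all recorded pixels by
   default, relying on background dominance; a background-cluster-only
   variant is available (`mode_on="background"`). The correction is a
   per-sample constant shift, so within-sample pixel ranking is
   untouched; its resolution is one KDE grid step, and tests assert the
   post-correction background mode is within one step of zero.
5. **Noise threshold**: the empirical 99.5% quantile of the pooled
   corrected intensities of untreated control sections only. Pixels
   strictly above the threshold (ties count as background) and on
   tissue form the above-noise mask.

Each ion (SP-C analog, m/z 3618; SP-B analog, m/z 3886) gets its own
independent background model and threshold.

## Calibration model

Slide preprocessing follows four steps: (1) classify background on the
analyte channel and subtract the background cluster mean (absorbs
slide-to-slide analytical offsets); (2) detect spotted pixels on the
melittin marker channel (same mixture split, upper component,
8-connected components ranked by size, ordered left-to-right by the
stamp layout — assignment to amounts is positional, never by
intensity); (3) allocate each spot's nominal nanograms uniformly over
its detected pixels, c_pixel = ng / pixel count; (4) fit

  mean adjusted log10 signal ~ slope · c_pixel + intercept,
  random intercept per experiment, REML (statsmodels MixedLM).

The response is the per-spot mean of per-pixel log signals; replicate
slides within an experiment share the experiment's random effect and
are pooled. A per-pixel-response variant was considered and not
implemented; the spot mean matches the granularity at which amounts are
known.

**Confidence intervals.** Fixed-effect 95% CIs use containment-style t
quantiles: between-experiment degrees of freedom (m − 1) for the
intercept, within degrees of freedom (N − m − 1) for the slope. With
only three experiments the usual large-sample normal intervals
undercover badly for the intercept (0.82 observed vs 0.95 nominal in a
300-run pre-study simulation); the containment choice restores ~0.95
for both coefficients, which the test suite re-checks over 200
simulated designs. A REML fit whose between-experiment variance hits
the zero boundary is refit as pooled OLS with a warning (at that
boundary the fixed effects coincide anyway).

**Inverse prediction.** amount = (signal − intercept)/slope for each
above-noise pixel; signals below the intercept clamp to 0 ng and are
flagged. The 95% bounds take the extreme amounts over the four corners
of the fixed-effect confidence rectangle. Random-effect uncertainty is
deliberately excluded from the envelope — a simplification that makes
the bounds slightly anti-conservative for extrapolation to new
experiments.

## Spatial statistics

Border distance is the Euclidean distance (in pixel units) from each
tissue pixel to the nearest off-tissue pixel center, computed with a
distance transform on a zero-padded mask so the grid edge always counts
as border; an exhaustive nearest-neighbour search is the test oracle.
Profiles use equal-width bins (default 15) over 0.7–35.5 px — the
endpoints are conventions carried as configurable defaults — with the
per-bin **median** of the corrected signal.

`Sum_log10_I` is the sum of corrected log10 intensities over above-noise
pixels (not the log of the raw sum), consistent with performing all
statistics on the log scale; `Avg_log10_I` averages over tissue pixels
only.

## Physiology

PaO2 and PaCO2 are log10-transformed before any summary (series carry a
transform flag and refuse double transformation); other parameters stay
on their natural scale. AUC is the trapezoidal rule over observed
timepoints with no extrapolation; the endpoint requires the exact final
time (no interpolation). Group comparisons run Levene's test with
median centering (Brown–Forsythe) at α = 0.05 to route between pooled
and Welch t-tests. Associations are Spearman correlations (average
ranks for ties) between treated animals' AUC summaries and the MSI
section summaries; no multiplicity correction is applied by default,
mirroring the exploratory character of the association analysis
(`statsmodels` Benjamini–Hochberg can be applied downstream).

## Synthetic-data generator

The generator's defaults encode the study conditions: six calibration
amounts (1, 2.5, 5, 10, 25, 50 ng per 0.5 µl spot of each peptide),
6.25 ng melittin marker, three experiments × two replicate slides,
calibration law slope 3.1 log10-units per ng with intercept 0.2 above
background; cohorts of 7 treated + 5 control animals sampled at 0, 5,
30, 60, 90, 120 minutes; SP-C:SP-B abundance ratio 7.5 (their 1.5% vs
0.2% share of the surfactant mass).

Choices the study conditions do not pin down, made once on realism
grounds:

- **Spectra** are sparse centroided peak lists (processed-mode style):
  a lognormal background peak inside every monitored channel, six decoy
  matrix peaks, and five endogenous peaks on tissue pixels only. The
  endogenous peaks raise tissue TIC ~16-fold over bare glass, which is
  what makes TIC segmentation work even on control sections whose
  analyte channels are pure background.
- **Background levels**: log10 mean 1.0 (≈10 counts) for glass/matrix
  on sections, 2.0 (≈100 counts) for homogenate-covered calibration
  slides, SD 0.15; normal on the log scale (the raw-intensity noise
  distribution is not otherwise constrained, and lognormal raw
  intensity is the standard assumption).
- **Deposition field**: per-pixel amount = abundance ×
  exp(−0.03 · distance from section center) × hotspot boosts (three
  Gaussian foci, ×1.8, width 2.5 px, placed in the central half of the
  tissue), emulating a gradient-driven spread from central airways with
  local accumulation. Pure radial-decay phantoms (no hotspots) are the
  condition under which distance profiles are provably monotone.
- **Peptide signal** rides on the slide background: log10 intensity =
  background level + intercept + slope × amount + N(0, 0.12).
  Within calibration spots the stamped peak replaces the channel's
  background peak (analyte-over-matrix suppression); without this the
  1 ng spots would carry a +0.1 log10 summation bias absent from the
  linear law.
- **Batch offsets** are additive on the log10 scale, matching the
  mode-alignment correction.
- **Cohorts**: one latent lognormal(0, 0.5) deposition factor per
  treated animal scales both section abundance (0.8 ng/px per unit) and
  the physiological response, value(t) = baseline + effect · d ·
  (1 − e^(−t/30 min)) + noise, applied on the log10 scale for
  PaO2/PaCO2 and additively otherwise (PaO2/Cdyn/pH/VT improve, PaCO2/
  PIP/MAP fall). Baselines reflect severe surfactant deficiency after
  15 minutes of ventilation (PaO2 55 mmHg, PaCO2 115 mmHg, pH 7.05,
  Cdyn 0.13 mL/kg/cmH2O, PIP 34 cmH2O).

**Not emulated**: MALDI physics (laser ablation, crystallization,
per-pixel ion suppression on tissue), isotope envelopes, m/z drift,
3D lung geometry, spatially correlated noise, and any coupling between
ventilation settings and the imaging data beyond the single latent
factor. Passing tests therefore demonstrate the pipeline's correctness
and statistical calibration under its stated assumptions — not
robustness to instrument artifacts absent from the generator.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which the statistical properties are identifiable:
sections of 40×40–60×60 pixels (a 350 µm raster over a few cm of
tissue), calibration slides of 31×71 pixels with ~6% spot coverage,
50 seeded repetitions for calibration recovery, 100 cohorts for
association sign recovery, and 500 cohorts for the null calibration of
the group test.

## Known limitations

- The background-cluster mean retains a small positive contamination
  from 1 ng spot pixels that genuinely overlap the background
  distribution; the recovered intercept is accordingly biased low by
  ~0.02 log10 units at the default design (visible in the acceptance
  output, still well inside the confidence intervals).
- CI inversion ignores random-effect variance (above).
- The two-component mixture assumes exactly one background and one
  signal population per slide and ion.
- Tissue segmentation assumes tissue is the brighter and larger TIC
  class; slides where tissue covers under ~10% of pixels would be
  misread as homogenate-covered.
- Whether the density mode should be estimated from all pixels or only
  background-cluster pixels is ambiguous; both are implemented, with
  all-pixels the documented default.
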