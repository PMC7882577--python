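# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data calibrations do and do not
establish about real tissue and recordings.

## Coordinate and unit conventions

Physical coordinates are micrometres, origin at the field corner; voxel
(row *i*, col *j*, section *k*) has its centre at
`((j+0.5)·px, (i+0.5)·px, (k+0.5)·Δz)`. Pairing distances are always
computed in physical µm on the anisotropic grid (xy ≈ 58.7 nm, z 150 nm
confocal / 70 nm array tomography), never in voxel units. Densities use
1 mm³ = 10⁹ µm³; charge uses 1 pA·s = 1 pC.

## Synthetic image generator

The generator reproduces the statistical structure the analysis assumes,
not the optics of a particular microscope.

* **Geometry.** Defaults follow the source acquisitions: 58.7 nm pixels
  (184.58 µm fields at 3144² px), 150 nm z-step over ~2 µm (14 planes) for
  confocal; 70 nm physical sections for array-tomography ribbons. The
  default field is a 512-px (30 µm) crop — the package's working problem
  size; the full 3144² field is supported but slow.
* **Populations.** Channel densities default to measured human
  motor-cortex control values: ~4.17e8 presynaptic and ~3.73e8
  postsynaptic puncta/mm³ with ~2.59e8 colocalized pairs/mm³
  (colocalization fraction 0.621) for the excitatory-like pair; an
  inhibitory-like set (1.63e8 / 2.15e8, 9.22e7 pairs) and a mouse-scale
  inhibitory set (3.26e7 / 4.30e7, 1.84e7 pairs — single-channel values
  scaled from the human single:paired ratios, since only the paired mouse
  density is published) are provided as constants. A configurable fraction
  of presynaptic puncta receives a partner displaced by an isotropic
  Gaussian offset (default SD 0.15 µm); all remaining puncta are uniform.
* **Rendering.** Each punctum is a Gaussian-blurred ellipsoid rendered
  analytically per object (ball of radius r approximated as a Gaussian of
  σ = r/2, added in quadrature with the PSF σ); this is statistically
  equivalent to full-field convolution at the puncta scale and linear in
  the object count. Default punctum radius 0.2 µm; PSF σ = (0.1, 0.1,
  0.2) µm, i.e. lateral FWHM ≈ 0.24 µm and axial FWHM ≈ 0.47 µm,
  consistent with a 1.4-NA oil objective. In ribbon mode the z-profile is
  flat and a punctum appears on exactly the sections its z-extent
  (centre ± radius) intersects, emulating physical sectioning.
* **Noise.** The source material reports no noise statistics, so these are
  the package's stated assumptions: background 10 a.u., peak intensity
  50 a.u., Poisson shot noise on the intensity plus Gaussian read noise
  (SD 2 a.u.) — peak SNR ≈ 6–8.
* **Artifacts.** "Flicker" objects confined to a single section (the class
  the persistence filter removes) default to 10 % of the puncta density in
  ribbon mode and 0 in confocal mode, configurable.

Not emulated (and therefore not established by any passing test):
spectral bleed-through, section loss or registration error in ribbons,
intensity heterogeneity between puncta, non-Gaussian PSF tails, tissue
autofluorescence structure.

## Segmentation and the persistence filter

The source analysis names only "automated local thresholding" with
per-channel parameters; algorithm and window are configuration here.
Default: Niblack-style `I > μ_w + k·σ_w` with window radius 8 px
(17 px ≈ 1 µm) and `k = 2.0`; local mean and local median with a fixed
offset are alternatives. `k = 2.0` and a 2-px minimum footprint were
calibrated on synthetic ground truth (maximising pair-density fidelity);
smaller `k` floods the foreground under Poisson noise, larger `k`
self-masks puncta because the blob inflates the local SD within its own
window. A numerical guard adds `1e-8 × max(1, max|I|)` to the threshold:
the moving-sum filters can place the local mean a few ulp below the pixel
value on perfectly flat regions, which otherwise produces spurious
foreground on noise-free images.

Objects are per-section 8-connected components linked across consecutive
sections by ≥ 1 px footprint overlap (transitive); one object may own
several in-plane components on a section once linking merges branches.
Centroids are unweighted voxel-centre means. The persistence filter keeps
exactly the objects whose section span contains ≥ 2 consecutive indices;
it is idempotent and order-preserving.

Known limitation: touching puncta are not split (no watershed), so at
human-cortex densities ~5–10 % of puncta merge with a neighbour, biasing
recovered densities down by roughly that amount (see calibration below).

## Pairing and densities

Candidate cross-channel pairs within the radius are sorted by ascending
centre distance (ties broken by id) and accepted greedily one-to-one —
this prevents one punctum from being counted against many partners; an
any-within-radius mode exists for sensitivity analysis. A pair is counted
in the ROI containing its presynaptic centroid. The analysed volume is the
kept-ROI area (10 × 10 µm grid minus exclusions) times stack depth.

**Chance pairing is a regime property, not a bug.** The probability that a
random presynaptic punctum has a chance partner within *d* is
≈ ρ_post·(4/3)πd³. At human densities (ρ ≈ 2–4e8/mm³) with d = 0.5 µm this
is ~10–20 %, and with d = 1.0 µm it saturates (> 1) — one-to-one pairing
then approaches min(n_pre, n_post) regardless of true colocalization. The
recovery calibrations therefore run at d = 0.5 µm, and the chance-floor
calibration at mouse-scale densities, the regime the 0.5 µm rule belongs
to. Interpreting absolute densities from real human material at d = 1.0 µm
requires a chance-level control (e.g. channel rotation), which is outside
this package's scope.

**Calibration results** (five seeds each, 512×512×14 stacks, defaults):
estimated pair density within −11…−6 % of truth (merging losses partly
offset by chance pairing); with colocalization 0 at mouse-scale densities
the spurious-pair density is 3–6 % of the mean single-channel density.

## Morphometry

Cell density is count/area with optional compartment masks. Signal area is
the thresholded foreground area; with soma exclusion, connected components
whose equivalent diameter reaches 20 µm (configurable) are removed first.
Axonal density is the number of distinct foreground runs along a
rasterised 100 µm line — the automatable analogue of a manual crossing
count, invariant to fiber thickness while crossings remain disjoint; the
measure is reported as raw crossings (no normalisation is defined for it).
The perilesion compartment is the set of non-lesion pixels within 150 µm
Euclidean distance of the lesion (distance transform in physical µm); the
three masks tile the field exactly.

## Miniature-PSC detection

The kernel is `w(t) ∝ (1 − e^(−t/τ_r))(m·e^(−t/τ_d1) + (1−m)·e^(−t/τ_d2))`,
normalised to unit peak; defaults τ_r = 0.5 ms, τ_d1 = 3 ms, τ_d2 = 12 ms,
m = 0.7, 50 ms length at 20 kHz. With m = 1 the peak time has the closed
form τ_r·ln(1 + τ_d1/τ_r), used as a test oracle.

Detection follows the scaled-template method: at each lag, the
least-squares `a·w + b` fit has closed-form `a`, `b`, and residual; the
criterion is `a / SD(residual)` (scale- and offset-invariant). Numerical
choices that matter:

* **Short fit window.** The sliding fit uses only the first
  τ_r + (m·τ_d1 + (1−m)·τ_d2) ms of the kernel (default ≈ 6 ms). With the
  full 50 ms tail in the fit, a neighbouring event 10–40 ms away inflates
  the residual and masks a perfectly good event — at 2 Hz this costs ~8 %
  recall. Amplitude (= fitted scale, which is unbiased, unlike the raw
  windowed maximum) and charge still use the full kernel window.
* **One candidate per excursion.** Each contiguous above-threshold stretch
  of the criterion yields one candidate at its argmax; candidates closer
  than one rise time merge. Overlapping events within ~4 ms are not
  decomposed.
* **Charge.** Per-event integral of (signal − fitted local baseline) over
  the kernel window, truncated at the next detected onset so overlapping
  tails are not double-counted; total charge is the sum over events (not a
  whole-trace integral, hence robust to drift).
* **Noise SD.** Standard deviation of event-free samples after removing a
  0.5 s moving-average baseline; a MAD-based estimator is available.
* **Perfect fits.** The residual SD is floored at 1e-12 so a noise-free
  injected event produces a (numerically huge) criterion rather than 0/0.

Calibration at the study's recording conditions (300 s, 20 kHz, 2 Hz
events of 20 ± 5 pA in 2 pA noise, threshold 5): recall ≥ 0.95,
precision ≈ 1.0 at ±2 ms onset tolerance, mean amplitude within ~3 %,
total charge within ~5 % of injected; zero false positives on 200 s of
pure Gaussian noise. Sub-threshold events (criterion < 5, i.e. amplitude
below ~10 pA at this noise level) are invisible by construction — the
threshold trades sensitivity against specificity exactly as in practice.

QC applies the three printed rejection rules (200 pA holding current,
30 MΩ series resistance, 20 % series-resistance change) and reports every
violated rule.

## Group statistics

Per-subject values are means over that subject's stacks (aggregation order
fixed: ROIs → stack → subject → group). `group_stats` reports n, mean,
SEM (= SD/√n), and *both* change conventions — percent reduction
`(ref − g)/ref × 100` and percent-of-reference `g/ref × 100` — because
published text and legends mix them (a ~57 % *remaining* value can be
misread as a ~58 % *reduction*). Omnibus tests (Welch t, Mann–Whitney,
one-way ANOVA, Kruskal–Wallis) are delegated to scipy.stats; post-hoc
correction is deliberately not applied by default.

## Problem sizes

Working sizes were chosen so the full suite runs in well under an hour on
one CPU: 512-px (30 µm) stack crops for density recovery (five seeds),
mouse-scale density stacks for the chance floor, one 300 s trace for
detection scoring, 1000-object and 100-instance enumeration oracles for the
persistence filter and pairing. All are the package's own choices and are
set in `tests/test_acceptance.py` and `scripts/acceptance.py`.

## Event generator (ephys)

Poisson onsets at the configured rate, drawn uniformly over
[0, duration − kernel length] so every kernel fits inside the trace (a
~0.02 % rate deflation at the defaults); amplitudes are normal truncated
at zero (no polarity flips; truncation is flagged in the truth); inward
events are negative deflections, outward positive; Gaussian baseline noise
and optional linear drift. Not emulated: 1/f and line noise, seal
instability, series-resistance filtering of event kinetics,
amplitude–kinetics correlations.
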