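# Methods

`oxidrs` implements a simulation-to-inference pipeline for probe-based
diffuse reflectance spectroscopy (DRS) of skin: a three-layer tissue model
with Monte-Carlo photon transport generates dual-distance reflectance
spectra, a measurement-noise model corrupts them, and small neural networks
trained on the synthetic data map measured spectra directly to red-blood-cell
(RBC) oxygen saturation and RBC tissue fraction — without an intermediate
per-wavelength optical-property inversion.

## Tissue model

Skin is modeled as three plane-parallel layers sharing one reduced
scattering spectrum:

1. **Epidermis** — variable thickness `t_epi`, bloodless, absorbing through
   melanin, beta-carotene and lycopene.  Melanin follows a power law
   `mu_a,mel = 48.42 mm^-1 * (lambda/550 nm)^-beta_mel`, where `beta_mel`
   encodes the eumelanin/pheomelanin balance.  Carotenoids absorb only below
   ~550 nm.
2. **Upper dermis** — fixed 0.2 mm, blood tissue fraction
   `f_blood*(1+r_blood)`, saturation `s_o2 + delta_o2/2`, mean vessel
   diameter `d_avg*(1-r_d)`.
3. **Deep dermis** — semi-infinite, the complementary blood fraction,
   saturation and (larger) vessel diameter.

Whole-blood absorption is the convex combination of fully saturated,
reduced and met-hemoglobin curves at 145 g Hb/L.  Because hemoglobin is
confined to vessels, layer absorption is corrected by the vessel-packaging
factor `(1 - exp(-D*mu_a,blood))/(D*mu_a,blood)`.  Reduced scattering is a
Mie power law plus a Rayleigh `lambda^-4` term, equal to `alpha` at 600 nm.
Fifteen parameters control one realization; all lengths are mm, absorption
and scattering 1/mm, fractions dimensionless (percent only at I/O
boundaries).

### Chromophore tables

The shipped absorption tables (`src/oxidrs/data/*.tsv`) are **synthetic
approximations**: monotone-cubic interpolations through approximate anchor
values of widely used molar-extinction compilations for oxy-, deoxy- and
met-hemoglobin (scaled to 145 g Hb/L via `mu_a = ln(10)*eps*c/M`), and
Gaussian band shapes for the carotenoids (relative concentration scale,
negligible above 550 nm).  They reproduce the qualitative band structure
(the 542/577 nm oxyhemoglobin doublet, the 555 nm deoxyhemoglobin band, the
met-hemoglobin feature near 630 nm) but are not digitized literature
curves; every table can be replaced by a user file of the same two-column
format (`ChromophoreTable.from_files`).  Since the same tables generate both
training and evaluation data, pipeline-level results are self-consistent
under this substitution.

## White Monte Carlo and the path-length table

Photon transport is simulated once per grid node (epidermis thickness x
reduced scattering) with **zero absorption** ("white" Monte Carlo),
storing per-layer path lengths of collected photons; absorption for any
chromophore composition is applied afterwards through Beer-Lambert
weighting, so one table serves every wavelength and parameter draw.

* Geometry: 200 um source and detector fibers, NA 0.37, center-center
  separations 0.4 and 1.2 mm; glass probe face (n = 1.5) on tissue
  (n = 1.4), Fresnel reflection at the surface.  Launch directions are
  uniform in the fiber acceptance cone; collection requires exit within the
  fiber radial band and the acceptance cone (half-angle `asin(NA/n)`).
* Scattering: Henyey-Greenstein, g = 0.8, `mu_s = mu_s'/(1-g)` (only the
  reduced scattering is parameterized).
* Variance reduction: the geometry is rotationally symmetric about the
  source axis, so each escaping photon inside a detector's radial band is
  recorded with weight equal to the azimuthal arc fraction covered by the
  fiber face.  This is exact in expectation and collects ~25x more records
  than discrete-fiber detection at equal cost.
* Termination: total path capped at 200 mm.  The cap removes a small tail
  of very long (absorption-irrelevant) paths and bounds runtime.
* Interpolation: node intensities (and absorption-weighted per-layer path
  sums) are interpolated bilinearly in `(t_epi, log mu_s')`.  Queries
  outside the grid are refused, never extrapolated.
* Seeding: one master seed; per-node seeds from a documented counter
  scheme; fixed seeds give bit-identical tables.

The default production grid is 6 epidermis nodes x 8 scattering nodes at
1e7 photons per node (`oxidrs pipeline`).  Tests and the bundled acceptance
experiment use coarser, smaller tables (see "Problem sizes" below); an
oracle test checks that interpolated off-grid reflectance agrees with a
fresh direct simulation within combined Monte-Carlo error.

## Spectra, targets and calibration scale

For each parameter draw, the layer absorption triplet and `mu_s'` are
evaluated on the 28-wavelength grid (475-750 nm, evenly spaced; the exact
spacing is a package choice) and turned into the two channel spectra.
Spectra are expressed on a white-calibrated scale: detected fractions are
divided by a per-channel reference, taken as the absorption-free detected
fraction at the center of the lookup grid, which puts typical tissue
spectra at O(0.1-1) as after white calibration of a measurement.

Targets reflect what the detected photons actually sampled: each photon's
per-layer path share, weighted by its Beer-Lambert survival, is averaged
with equal weight over both channels and all wavelengths (both choices are
switchable: geometric weighting, per-channel weights).  The RBC tissue
fraction is the hematocrit (0.43) times the path-weighted blood fraction;
the saturation target is blood-weighted across the two dermal layers
because saturation is a property of the blood actually probed, and is
undefined (NaN, excluded downstream) when the sampled volume contains no
blood.

The conversion to hemoglobin concentration is
`c_Hb = f_RBC[%] * 53.5 uM` (`345/64500 * 1e4 = 53.49`).

## Noise model

Three components, applied in fixed order (additive measurement noise,
multiplicative residual, multiplicative color tilt):

* **Measurement noise** `eta(lambda)*xi_w`, `xi_w ~ N(0,1)`, with `eta` the
  relative standard deviation of repeated white-reference spectra
  (`estimate_eta`).  The default is a flat `eta = 0.002` on the
  white-calibrated scale.  `eta` is instrument specific; the default was
  chosen so that the pipeline reproduces the qualitative noise behavior of
  a low-pass-filtered dual-spectrometer system: noise visibly degrades
  naive (clean-trained) inversion while remaining learnable, and a few
  percent of the darkest (high-melanin/high-blood) spectra become unusable.
  A larger default (e.g. 0.01) makes one in six spectra fail the
  noisy-spectrum exclusion rule, which is inconsistent with the intended
  regime; configure `noise.eta` (scalar or curve file) to match a specific
  instrument.
* **Residual model**: per-wavelength multiplication by
  `N(m(lambda), s(lambda))`, encoding the small systematic mismatch
  (generally below 1%) between fitted tissue models and real skin spectra.
  The default curves are smooth synthetic stand-ins anchored at the
  short-channel point (742 nm: mean 0.995, sd 0.007); instrument-derived
  curves can be supplied as files.  The residual component is off in the
  phantom-style configuration (`NoiseSpec.phantom()`), mirroring how such
  systems are validated on liquid phantoms.
* **Color-calibration tilt**: multiplication by a straight line in
  wavelength with unit mean over 475-750 nm whose end-to-end relative
  difference is `xi_slope - 1`, `xi_slope ~ N(1, 0.05)`; one draw shared by
  both channels (per-channel draws and a geometric alternative are
  switchable).

## Dataset generation and exclusion

Parameters are drawn iid from configurable marginals with rejection of
physically invalid combinations.  The shipped defaults (uniform saturation
over [0,1], log-uniform blood fraction 5e-4..0.05, log-uniform `alpha`
0.75..6 /mm, etc.) are the package's own choice of wide, plausible skin
ranges; they are configuration, not literature values.

Two exclusion rules mark records unusable for evaluation:

* **Noisy spectrum**: on the long (1.2 mm) channel, adjacent points
  differing by >50% of the larger of the pair in more than two pairs;
  nonpositive pair maxima count as violations.
* **Weak hemoglobin signature** (saturation task only): the blood-contrast
  statistic — one minus the mean 520-590 nm ratio between the clean
  long-channel spectrum and its bloodless counterpart — falls below a
  threshold.  The threshold (default 0.035) is a calibrated configuration
  value: it was set, once, so that the fraction of records surviving both
  exclusions for the saturation task is near 86% under the default
  generator and noise configuration, matching the intended operating
  regime of the exclusion.

## Inverse networks

Each target has its own network: 56 inputs (28 wavelengths x 2 channels,
each channel divided by its own mean — removing inter-channel calibration),
25 tanh hidden nodes, linear output in percent, truncated to [0, 100]% for
saturation and [0, inf)% for RBC fraction.  Variants: long-channel-only
(28 inputs), absolute-intensity (no mean normalization) and an
extended-wavelength grid (475-850 nm) when datasets on that grid are
supplied.

Training minimizes MSE with Levenberg-Marquardt: analytic Jacobian for the
one-hidden-layer architecture, damped normal equations (`lambda_LM` start
1e-3, x10 on rejection, /10 on acceptance), optional seeded per-iteration
subsampling for large training sets.  Data are split 70/15/15 into
train/validation/selection; training stops after six consecutive
validation failures and returns the best-validation weights.  At least ten
restarts from different seeded initializations are trained (configurable),
stopping early once the selection-split RMS of the three best agrees
within 2.5% relative; the lowest-selection-RMS network is returned.  The
selection split — not the final evaluation set — drives restart selection,
a deliberate choice that keeps the evaluation set untouched by model
selection.

## Problem sizes

Full-scale runs (1e7 photons/node, 1e5 training models, >= 10 restarts)
are a `pipeline` configuration choice.  The bundled acceptance experiment
runs the same pipeline at reduced sizes chosen as a package design point:
a 4 x 6 node table at 1.5e5 photons/node, 9,000 training and 3,000
evaluation models, two to four restarts with an LM iteration cap of 200
(the README's worked example uses a slightly larger 2e5 / 12,000 / 4,000
configuration).  At these scales the noise-grid orderings of the full
method are reproduced; absolute errors are larger than a full-scale run
would give.  Experiments with a 1e6 photons/node table showed the
path-length-table Monte-Carlo noise is not the limiting factor at this
training size.

## What the synthetic data do and do not show

All training and evaluation data come from the same forward model, so the
reported accuracies measure inversion quality under the model's own
assumptions (plane layers, shared scattering spectrum, the shipped
chromophore approximations, the three noise components).  They do not
measure model-to-tissue mismatch beyond what the residual component
encodes, nor instrument effects outside the noise model (stray light,
wavelength registration, detector nonlinearity).  Phantom and in-vivo
validation require measured data and are out of scope; the package
supports them through the calibration front end (`oxidrs predict` on
calibrated spectra).

## Numerical choices and limitations

* Bilinear interpolation acts on node intensities, not on path-length
  histograms; the grid-node identity (interpolation at a node reproduces
  the node sum exactly) is tested.
* Range violations in derived layer quantities raise errors; the sampler
  rejects rather than clamps, so training targets are never silently
  biased.
* Degenerate (nonpositive) intensities after noise are permitted and
  handled by the exclusion rules; mean normalization rejects records with
  nonpositive channel means.
* The relative RMS metric drops the records with the lowest 5% of true
  values by rank (ties by record index).
* Known limitations: single scattering spectrum for all layers; no water
  or lipid absorption (the band ends at 750/850 nm); index-matched
  internal layer boundaries; no polarization, fluorescence or time
  resolution; no out-of-domain detection for the networks.
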