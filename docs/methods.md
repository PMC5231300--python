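# Methods

## Signal model and reconstruction

The package assumes a PS-OCT system that detects the backscattered field in
two orthogonal polarization channels. Per voxel the scalar reconstruction is

    R = A_co² + A_cross²                 (linear reflectivity)
    δ = arctan(A_cross / A_co)           (retardation, degrees)

With non-negative amplitudes δ is confined to 0–90°; cumulative retardation
beyond 90° folds back triangularly (`fold(δ) = δ mod 180`, mirrored above
90°). All quantitative slabs are therefore placed shallow enough that the
cumulative retardation stays below the first wrap, which is also why the
scleral fit uses only the anterior 40 px (76 µm) of the sclera.

This is a *scalar* retardation model: no optic-axis orientation, no
diattenuation, no Mueller/Jones matrix algebra. The anterior segment
(cornea) is modeled as a scalar retardation offset. The offset is measured
per A-scan at the ILM — the first tissue interface, which carries no tissue
retardation of its own — and subtracted with a triangular re-fold. The scalar
model is exact as long as offset + tissue retardation stays below 90° in
every evaluated slab; the phantom's defaults guarantee this (see below). The
choice follows from the metrics themselves: all four use retardation
magnitude only.

dB values are `10·log10` of linear intensity. Frame averaging (the
instrument's 5 repeats × 3 positions) averages channel *intensities* after a
rigid integer axial registration by cross-correlation of depth profiles; the
positions are sub-resolution apart laterally, so no lateral registration is
attempted.

## Corneal compensation window

The offset estimator fits a line to δ over a 4 px axial window starting at
the ILM and takes the intercept *at* the ILM position. A windowed median
would sit half a window into the RNFL birefringence ramp (≈0.6° bias at
9° per 30 µm); the intercept is exact on noiseless input. The per-A-scan
offset map is median-smoothed 5×5 transversely before subtraction, which
suppresses speckle noise in the estimate without biasing it.

## Segmentation

* **Noise floor** — mean dB intensity over the signal-free vitreous, ending
  5 px above the ILM (or the top 10 rows before an ILM exists). Voxel
  validity for retardation metrics is intensity > floor + 3 dB; the ILM
  *edge detector* uses a separate, stricter floor + 6 dB threshold (the two
  thresholds serve different purposes: one admits voxels to an average, the
  other must reject isolated speckle excursions).
* **ILM** — first axial position where the axially median-filtered dB
  profile exceeds floor + 6 dB for 3 consecutive samples, refined to the
  half-rise point of the local intensity edge by linear interpolation in
  linear intensity. On a partial-volume sampled step edge the half-rise
  convention is unbiased to ≲0.1 px.
* **RPE** — brightest sample in a window 50–150 px below the ILM, accepted
  only with ≥ 6 dB prominence over the window median (A-scans through the
  optic nerve canal have no RPE and yield NaN), then refined to the
  *anterior half-rise edge* of the peak. The brightest sample itself sits
  mid-layer (≈ +2 px for an 8 µm RPE); the edge convention recovers the
  anatomical top, which is what the scleral slab is anchored to.
* **Despiking** — both surfaces replace positions deviating > 10 px from
  their 5×5 neighbourhood median by that median. Genuine failures confuse
  layers ~20 px apart (e.g. an RPE candidate on the bright sclera), while
  real anatomy — the pit apex, the steep pit wall at the canal rim — stays
  below the threshold across one window; a blanket median filter would
  flatten the pit apex by several pixels.
* **Axial motion** — per-B-scan offsets are the median deviation of the ILM
  from a 2nd-order polynomial across the slow axis, estimated on the
  periphery only (outside 1.5× the depression-annulus outer radius in the
  pipeline). Without the exclusion, rows through the ONH have up to half
  their pixels on the deformed region and the estimator aliases genuine
  IOP-induced depression into "motion".
* **Registration** — one global axial shift per follow-up volume, the median
  of (current − baseline) over the periphery outside the depression annulus,
  so central deformation cannot bias it. Surfaces carry a `registered` flag;
  the depression map refuses unregistered input.

Surfaces are stored in pixels as floats, 0-based, increasing with depth;
µm conversions go through the volume geometry (axial pitch 1.9 µm/px in
tissue by default, encoding the 20 px = 38 µm instrument correspondence).

## Metrics

Annulus sizes are diameters (300/700 µm for depression, 550/870 µm for the
other three), pixel membership by centre distance. The reflectivity ratio is
computed per A-scan and then averaged over the annulus (robust to transverse
vignetting; ratio-of-means within each A-scan, so globally scale-invariant).
RNFL retardation averages voxels (not per-A-scan means) in the slab within
the annulus. The scleral fit is unweighted OLS over valid voxels, minimum 10
per A-scan, slopes retained with sign, no unwrapping. Datasets are flagged
excluded when fewer than 10% of annulus(-slab) elements are valid — the
exclusion is reported, never replaced by a fabricated value.

The superior/inferior hemifield split assigns +y to superior (configurable;
the acquisition does not fix image orientation), with the dividing line
belonging to superior.

## Statistics

Spearman ρ uses average ranks and the two-sided t-approximation for p
(appropriate at the pooled sample sizes these experiments produce; exact
permutation would add nothing at n ≈ 45). Strength bands are closed on the
left: |ρ| = 0.70 is "strong". The rank-sum test enumerates exactly for
tie-free samples up to n = 20, otherwise uses the tie-corrected normal
approximation. The two-phase description fits OLS independently below and
above a 45 mmHg breakpoint (breakpoint itself belongs to the dynamic phase).
Conversion between effective birefringence and the dimensionless
refractive-index difference is `Δn = b·λ[µm]/360`.

p-values computed on phantom series characterise the phantom, not any animal
cohort: published in-vivo p-values derive from the animals' raw data and are
not reproduction targets.

## Phantom

The generator emulates a single averaged acquisition of the albino-rat
posterior eye on a 400×128×128 grid (1.9 µm axial pitch, 1.5×1.5 mm field;
configurable — unit tests run a 300×64×64 variant). Layer stack per A-scan:
vitreous (no backscatter), ILM at 190 µm with a Gaussian pit (depth 60 µm,
σ = 100 µm) and an RPE-free canal (r < 75 µm), 30 µm RNFL, inner retina to
the RPE at ILM + 190 µm, 8 µm RPE, 30 µm choroid, sclera to the bottom.
Reflectivities (floor −75 dB): retina −40, RPE −20, choroid −45, sclera
−25 dB — i.e. 35–55 dB SNR, representative of averaged-frame imaging; at
substantially lower SNR the additive floor biases the arctan estimator
toward 45° and the corneal-offset estimate with it. Voxel reflectivity is
coverage-weighted at layer boundaries (partial-volume sampling), which is
what makes subpixel surface recovery meaningful.

Speckle: each channel's single-look intensity is exponential with the
channel's mean power; the emitted volume averages `n_looks = 15` independent
looks (the instrument's frame averaging), drawn as a gamma variate. The
additive noise floor splits evenly between channels. `n_looks = 1` gives
fully developed speckle for the statistics tests; disabling speckle and
floor gives strictly noiseless volumes that invert exactly.

IOP responses (defaults calibrated to the published dose–response):

* scleral birefringence `B(IOP) = 0.3075 + 2.75e-2·(min(IOP,45) − 14)` °/µm
  — plateau 1.16 °/µm at ≥ 45 mmHg; the 14 mmHg baseline is back-derived
  from slope and plateau, not an independently published value;
* reflectivity ratio `r(IOP) = 1.5 − 1.0e-2·(IOP − 14)` — the baseline 1.5
  is a package default (only the slope is published);
* ONH depression: 0 up to 45 mmHg, then linear to 15 µm at 105 mmHg,
  applied as a flat posterior displacement for r ≤ 350 µm with a cosine
  taper to zero at 450 µm. The flat top makes the 300/700 µm annulus mean
  equal d(IOP) by construction; the taper ring is a minority of the
  registration periphery, so the median global shift stays unbiased.

The RNFL reflectivity is not a free parameter: it is solved per A-scan so
that the protocol's 20 px slab ratio equals `r(IOP)` exactly on noiseless
volumes, given the slab's partial-volume composition.

Retardation: corneal offset (3°) plus a linear RNFL ramp to 9° at the RNFL
base, constant through the inner retina and RPE. Across the choroid the
retinal accumulation tapers back to the corneal offset and the scleral ramp
`B·depth` starts at the scleral surface. This re-referencing is deliberate:
a strictly cumulative profile with the plateau birefringence would exceed
90° inside the 40 px evaluation slab (9° + 3° + 1.16·74 µm ≈ 105°) and the
fold would bias the fitted slope by ~7%; re-referencing keeps every slab
wrap-free — the same consideration that restricts the protocol's fit to the
shallow scleral slab — while leaving all evaluated quantities unchanged. The
choroid is 30 µm so that (with the 8 µm RPE) the scleral surface sits
exactly 20 px below the RPE surface and the fit slab contains sclera only.
A configuration validator rejects parameter sets that would wrap inside an
evaluation slab.

Per-volume seeds in a series are `base_seed + index`; identical
configuration and seed give bit-identical volumes.

### What the phantom does not emulate

Vasculature and vessel shadows, motion between frames, birefringence axis
orientation, depolarization, attenuation with depth, the extraorbital
tissues behind the sclera, and any deviation of the scleral retardation
profile from depth-linearity. Passing recovery tests therefore demonstrates
correctness of the analysis chain under the stated signal model and
realistic speckle/SNR — not robustness to every artifact of in-vivo data.

## Numerical choices and degenerate inputs

Slab indexing rounds the reference surface to the nearest pixel; A-scans
whose slab leaves the volume, lacks a detected reference surface, or has
fewer than the minimum valid voxels yield NaN, and NaN propagates to masks
rather than to averages. Annulus masks reject only annuli with no possible
overlap with the field; partial coverage is handled by the valid-fraction
exclusion rule. The ILM segmentation fails loudly when more than half the
A-scans have no edge. Registration fails when less than 10% of the
periphery overlaps. Ties in the hemifield split go to superior; ties in
rank statistics use average ranks.

## Problem sizes

Default experiment: 13 pressure levels (14–45 mmHg in 5 mmHg steps, then
10 mmHg steps to 105) on the 400×128×128 grid, ~3 s per volume end to end.
Recovery experiments use 10 seeds per quantity; the unit-test suite runs the
reduced 300×64×64 grid, chosen so that the annuli and slabs retain their
physical sizes while each volume holds ~1.2 M voxels.

## Known limitations

The corneal-offset estimator and the retardation estimator share a small
speckle-induced bias toward 45° that grows as SNR falls; at the phantom's
SNR the net effect on the plateau birefringence is about −1%. The
reflectivity-ratio decline is emulated by scaling RNFL backscatter only,
whereas in tissue the decline plausibly involves directional scattering
changes. The two-phase scleral response is modeled as piecewise-linear with
a hard plateau; real tissue shows a softer transition. Registration handles
axial shifts only — lateral eye drift between acquisitions is out of scope.
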