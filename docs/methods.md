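# Methods

This note documents the models behind `ra223spect`, the parameters that
matter, and what the synthetic studies can and cannot show about real
Ra-223 imaging.

## Phantom geometry and voxelization

Coordinates are right-handed millimetres with the origin at the phantom
centre: x left→right, y posterior→anterior, z along the scanner axis.
Phantoms are ordered stacks of primitives (spheres, circular/elliptic
cylinders, boxes) inside a water body outline; where primitives overlap,
the later one wins. Voxelization uses voxel-centre membership; a
`supersample=s` option averages s³ sub-centres per voxel, giving
fractional partial-volume weights (the studies use s = 3 on the 8.8-mm
SPECT grid, s = 2 on the 4.4-mm planar grid). Voxelized totals converge
to the analytic compartment activities as the grid is refined, which the
test suite checks explicitly.

The cylinder phantom is fully specified: Ø200 × 210 mm water, axial rod
Ø45 × 200 mm at 2.0 kBq/mL. The body phantom's internal layout is not
published, so the following surrogate is **frozen** here: an elliptic
cylinder body 300 (L–R) × 200 (A–P) × 210 mm; two Ø28-mm spheres
(11.49 cm³, 15.0 kBq/mL, 350-HU contrast attenuation class) 80 mm apart
on the z axis; a tube chamber Ø30 × 150 mm (15.0 kBq/mL), long axis
left–right, 60 mm anterior of sphere 1. The defining feature — the
tube's anteroposterior projection overlaps sphere 1 and only sphere 1 —
is a tested invariant.

## Detection model

All model parameters live in `src/ra223spect/data/ra223_default.yaml`.

* **Windows**: 84 keV ± 20 %, 84 keV ± 10 %, 154 keV ± 10 %,
  269 keV ± 5 % (bounds = centre · (1 ± f)). The narrow 84-keV window
  excludes the lead Kα line at 75 keV; the wide one admits it.
* **Sensitivities** (total detected cps/Bq in air at 100 mm) are
  anchored at 1.0 × 10⁻³ for MEGP 84 ± 20 % — only ratios matter to the
  ratio metrics; the anchor just produces realistic counts in 60-s
  frames. Cross-collimator and cross-window values follow the measured
  spectrum ratios (HEGP/MEGP 99.5 % at 84 keV, 70.2 % at 154 keV,
  69.8 % at 269 keV; HEGP peak heights 29.3 %/18.9 % of the 84-keV
  cluster at 154/269 keV). The ± 20 %/± 10 % count ratio is fixed at
  2.0 — a configured surrogate for the undigitized spectra, chosen to
  reflect the near-equal yields of the 84-keV photopeak and the Kα
  line.
* **Sensitivity split**: a vial measurement in air cannot separate true
  primaries from septal penetration, so the configured sensitivity is
  the *total* rate and the background fraction bf splits it:
  primary = total · (1 − bf), pedestal = total · bf.
* **Background fractions** are the one calibrated quantity in the
  package. They were tuned once so that the simulated body-phantom
  sphere-to-background ratios fall inside the measured ranges for the
  MEGP collimator (planar ≈ 13.3, range 12.3–14.2; SPECT ≈ 34.5, range
  30.4–35.3) and then frozen: bf(84 keV) = 0.26 (MEGP) / 0.205 (HEGP),
  with larger values at the high-energy windows and HEGP < MEGP
  everywhere (thicker septa). They are not fitted per run.
* **Resolution**: FWHM(d) = √(FWHM₀² + (slope·d)²) with MEGP
  (4.0 mm, 0.045) and HEGP (5.0 mm, 0.054) — typical general-purpose
  collimator behaviour, configured not hard-coded.
* **Attenuation**: one effective linear coefficient per window and
  material class (water 0.18 cm⁻¹ and 350-HU contrast 0.21 cm⁻¹ at
  84 keV, smaller at the higher windows).
* A `REF` entry models a high-count reference bone tracer (LEHR-like
  collimator, 20× sensitivity, bf 0.10) for the clinical-correlation
  simulation only.

## Projection

Parallel-beam rotator: per view the activity and attenuation grids are
rotated about z (order-1 interpolation) so the detector faces +y, then
summed along y. A voxel contributes
`a · V_mL · 1000 · sensitivity · t · exp(−∫μ dl)` counts to its detector
column, with the line integral taken from the voxel centre to the
boundary (half of the voxel's own μ included). Collimator blur is
applied per depth slab with the depth-dependent Gaussian; kernels are
normalized, so without attenuation the image total equals the activity
total times sensitivity and time (a tested conservation law).

The **pedestal** — the structureless background from scatter and septal
penetration — is added in projection space as
`bf/(1−bf) · [0.2 · G₁₂₀mm(P₀) + 0.8 · flat(P₀)]`, where P₀ is the
*unattenuated* projection of the activity. Using the unattenuated source
reflects that the penetrating photons are high-energy and barely
attenuated; its spatial shape (120-mm FWHM Gaussian + flat floor,
weights in config) is an explicit surrogate — the physical pedestal's
shape was never modelled, only measured in aggregate.

Planar statics view the phantom from the **posterior**, the standard
orientation for spine imaging; this places the bowel tube at depth,
which is what makes its overlap inflate, rather than dominate, the
sphere-1 signal. SPECT uses a dual-head circular orbit (radius 250 mm —
a surrogate for the body-contour orbit, which would require
body-surface tracking without affecting any conclusion drawn here),
30 frames per detector at 6°, 60 s each.

Noise is Poisson per pixel; each view draws from a stream derived
deterministically as `default_rng([master_seed, view_index])`, so
changing the view count does not reshuffle earlier views.

## Reconstruction

Standard multiplicative OSEM,
`x ← x · backproject(m / forwardproject(x)) / backproject(1)`, with
angularly interleaved subsets (views i, i+5, i+10, …), uniform unit
initialization, and an ε = 10⁻¹² floor in the ratio denominator. The
reconstruction system model is deliberately mismatched to the
simulation: purely geometric (no attenuation, no pedestal, no blur),
mirroring a protocol in which neither attenuation/scatter correction nor
resolution recovery is applied to Ra-223 data. Because opposed dual-head
views of a parallel-beam geometric projector are exact left-right
mirrors, the implementation shares one rotation per opposed pair; the
result is identical to the naive loop.

After the final iteration one 3-D Butterworth low-pass
(|H(f)| = 1/√(1 + (f/fc)^(2n)), fc = 0.20 cycles/cm on the radial
physical frequency, n = 10) is applied to the volume; whether the
vendor's filter acts in 2-D per slice or in 3-D is unknowable from the
protocol description, and 3-D is chosen here (configurable). Negative
ripple is clipped to zero.

With one subset OSEM reduces exactly to MLEM (tested against an
independently coded MLEM loop), the Poisson log-likelihood is
non-decreasing over MLEM iterations, and noiseless self-consistent
projections of a uniform cylinder are recovered to within 5 %.

## Quantification conventions

* ROI/VOI membership is by pixel/voxel centre.
* Study A: a 45-mm circular ROI on the rod plus eight 45-mm background
  circles at 70-mm radius, 45° apart — clear of the rod, frozen in code.
  Hr is the rod-ROI mean; BKG the mean of the eight background means;
  SD the sample (n−1) standard deviation *of those means* (not a pooled
  pixel SD); HBR = Hr/BKG, CNR = (Hr − BKG)/SD. Replicates are 10
  evenly spaced transaxial slices within the central rod extent.
* Isocontour VOIs keep voxels ≥ f · (regional max) in the 6-connected
  component containing the maximum; the closed rule (≥) keeps f = 1
  non-empty. Threshold calibration picks the candidate (50/60/70/80 %)
  minimizing the absolute VOI-volume error summed over all provided
  tables, with ties going to the lower threshold. (On the package's own
  reconstructions, which blur more than the physical system, the
  simulated tables select 70 %; the calibration operation itself is
  exercised against the measured tables, where 60 % wins.)
* SBR = sphere mean (60 % isocontour on SPECT, 28-mm circle on planar)
  over the mean of four 48-mm background region means at frozen
  positions in the water compartment.
* LBR = lesion 60 %-isocontour mean over a 50 cm³ spherical background
  VOI mean (radius (3·50/4π)^⅓ = 22.9 mm); lesions whose regional
  maximum is below 2× the reference mean are excluded, not errored.
* All ratio metrics are invariant to global image scaling (tested).

## Synthetic clinical cohort

The clinical arm is emulated, not reproduced: each synthetic lesion is a
Ø30-mm sphere centred in a Ø120 × 130 mm uniform background compartment
(2.0 kBq/mL) that stands in for normal tissue; there is no anatomy. Per
lesion a latent log-contrast L ~ N(2.2, 0.5²) is shared between tracers
and perturbed by independent N(0, 0.35²) noise per tracer, so the
log-scale pair correlation is 0.5²/(0.5² + 0.35²) ≈ 0.67 before imaging
noise. Lesions are imaged one at a time on a 32³ grid at 4.4 mm (orbit
150 mm) under MEGP, HEGP and the reference-tracer model, reconstructed
with the standard protocol, and scored with the LBR rule above. The
imaging chain compresses contrast strongly (a true 10× lesion
reconstructs to ≈ 1.8× peak over background under the Ra-223 protocol),
which is why the lesion size and contrast distribution are set where the
inclusion rule retains most, not all, lesions — under the default seed
27/36 lesions survive for all three tracers.

## Problem sizes and defaults

The studies run at the acquisition matrix sizes of the protocol
(64³ at 8.8 mm for SPECT, 128² at 4.4 mm for planar statics). Study A
uses 10 slices per condition; study B uses 5 Poisson replicates per
collimator and concentrations {3.75, 7.5, 15} kBq/mL for the linearity
series (levels obtained by exact scaling of the noiseless expectations,
then re-noised — valid because the whole phantom scales together). The
clinical driver images 36 lesions; the test suite uses 4 to stay quick.

## Limitations

* No Monte-Carlo photon transport: the pedestal is a two-parameter
  spatial surrogate, and energy spectra enter only through per-window
  scalar ratios. Conclusions about *why* HEGP wins rest on the
  configured background fractions, not on first-principles physics.
* The body-phantom internal geometry, orbit, and background-region
  placements are surrogates; absolute metric values (e.g. HBR in the
  tens rather than units) should not be compared to clinical numbers —
  only orderings and ratios between conditions are meaningful.
* Order-1 rotation interpolation makes the backprojector only
  approximately the adjoint of the forward projector; at these matrix
  sizes the effect is far below the Poisson noise.
* Decay during acquisition, dead time, daughter-nuclide migration and
  septal-hole artifacts are ignored.
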