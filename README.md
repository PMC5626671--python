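# ra223spect

Desk-scale simulation and semi-quantitative analysis of **Ra-223 SPECT**
phantom studies.

Ra-223 dichloride is an alpha-emitting, bone-seeking therapy for
castration-resistant prostate cancer with bone metastases. Imaging the
tracer is hard: the photon yield is tiny, the emission spectrum spans
80–500 keV, and lead characteristic x-rays from the collimator (Kα 75 keV,
Kβ 85 keV) sit right next to the main 84-keV photopeak. Planar
scintigraphy additionally superimposes bowel activity on the lumbar
spine, where prostate-cancer metastases concentrate. This package
reproduces, end to end on synthetic data, the phantom analyses that
motivate acquiring Ra-223 as SPECT with a high-energy general-purpose
(HEGP) collimator and a wide 84 keV ± 20 % window:

* **Digital phantoms** — a water cylinder (Ø200 × 210 mm) with an axial
  hot rod (Ø45 × 200 mm, 2.0 kBq/mL), and a body phantom with two 28-mm
  spheres (11.5 cm³, 15.0 kBq/mL) plus a tube-shaped bowel chamber whose
  anteroposterior projection overlaps one sphere.
* **Detection model** — per-window, per-collimator sensitivities and
  septal-penetration/scatter background fractions parameterized from
  measured Ra-223 spectra (MEGP vs HEGP).
* **Projection** — parallel-beam rotator with Beer–Lambert attenuation,
  depth-dependent Gaussian collimator blur, a pedestal background, and
  Poisson noise (dual-head SPECT: 30 frames/detector at 6°, 60 s each;
  planar statics: 30 min, 128×128 at 4.4 mm).
* **Reconstruction** — OSEM (5 subsets, 10 iterations) with a purely
  geometric system model (no attenuation/scatter correction, no
  resolution recovery) followed by a 3-D Butterworth low-pass
  (cutoff 0.20 cycles/cm, order 10).
* **Quantification** — Hr, BKG, SD, hot-rod-to-background ratio
  HBR = Hr/BKG, contrast-to-noise ratio CNR = (Hr − BKG)/SD,
  sphere-to-background ratio (SBR), lesion-to-background ratio (LBR),
  isocontour VOIs (voxels ≥ f · max, 6-connected component of the
  maximum) with volume-matching threshold calibration, and
  concentration-vs-counts linearity.
* **Statistics** — Wilcoxon signed-rank (exact 2^m enumeration for ≤ 15
  nonzero differences), Friedman, Steel–Dwass all-pairs (studentized
  range; permutation fallback), paired t, Pearson correlation with
  linear regression.

## Worked example

```python
from ra223spect.studies import StudyConfig, run_study_b

report = run_study_b(StudyConfig(seed=1, n_replicates=5))
print(report.tables["metrics"].groupby("collimator")
      [["sbr_planar", "sbr_spect", "uptake_ratio_planar",
        "uptake_ratio_spect"]].median().round(2))
```

prints

```
            sbr_planar  sbr_spect  uptake_ratio_planar  uptake_ratio_spect
collimator
HEGP             16.64      37.82                 1.58                1.10
MEGP             13.53      34.39                 1.57                1.12
```

Reading: on planar images the bowel tube inflates the apparent uptake of
the overlapped sphere by ~57 % (uptake ratio 1.57–1.58), while SPECT
separates the structures (ratio ≈ 1.1). SPECT raises the
sphere-to-background ratio by a factor 2.3–2.5 over planar imaging, and
the HEGP collimator — with its lower septal-penetration background —
outperforms MEGP in both modalities.

The numbered drivers under `analysis/` run the full study sequence and
write their tables to `results/`:

```
python analysis/01_build_phantoms.py
python analysis/02_study_a_windows_collimators.py
python analysis/03_study_b_planar_vs_spect.py
python analysis/04_clinical_correlation_sim.py
```

Study A (driver 02) shows that widening the 84-keV window from ±10 % to
±20 % — admitting the lead Kα line — doubles the hot-rod counts and
raises CNR by ~30–75 % while leaving HBR within 5 %, and that HEGP gives
a lower background than MEGP at every window. Driver 04 images a
synthetic 36-lesion cohort with both Ra-223 collimators and a high-count
reference bone tracer: the lesion-wise LBRs correlate across tracers
(r ≈ 0.83) and LBR is systematically higher with HEGP (paired t,
p ≈ 1e-4).

## Layout

```
src/ra223spect/    library: phantoms, detection, projection, recon,
                   quantify, nonparam, studies, io
analysis/          numbered narrative drivers (write to results/)
scripts/           acceptance script
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    model assumptions, parameters and limitations
```
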