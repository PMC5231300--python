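# psoct-iop

Quantitative analysis of polarization-sensitive OCT (PS-OCT) volumes of the
posterior rodent eye under acute intraocular pressure (IOP) elevation.

Glaucoma research needs IOP-sensitive imaging biomarkers. When IOP is raised
acutely (14–105 mmHg by anterior-chamber cannulation), the posterior eye
responds in ways PS-OCT can measure depth-resolved: the optic nerve head (ONH)
is pushed posteriorly ("cupping"), the retinal nerve fiber layer (RNFL) loses
reflectance relative to the rest of the retina, and the collagenous sclera —
whose form birefringence tracks its biomechanical state — stiffens in a
two-phase fashion. This package implements the full analysis chain for such
experiments, plus a ground-truthed synthetic phantom generator to validate
every stage.

## What it computes

From a dual-channel (co-/cross-polarized) amplitude volume:

* **Reconstruction** — reflectivity `R = A_co² + A_cross²` and cumulative
  single-pass phase retardation `δ = arctan(A_cross / A_co)` per voxel, with δ
  restricted to the unambiguous range 0–90°; frame averaging in the
  linear-intensity domain; per-A-scan corneal (anterior segment) compensation
  using the polarization state at the internal limiting membrane (ILM).
* **Segmentation** — ILM and retinal pigment epithelium (RPE) surfaces at
  subpixel precision, noise-floor estimation from the vitreous, per-B-scan
  axial motion correction, registration of follow-up volumes to baseline, and
  ONH-centre detection.
* **Four IOP-response metrics**, each averaged in an ONH-centred annulus:
  * ONH depression (µm), 300/700 µm annulus — posterior ILM displacement vs
    the baseline acquisition;
  * RNFL/retina reflectivity ratio, 550/870 µm annulus — mean linear intensity
    in the 20 px (38 µm) slab at the ILM over the slab from ILM+20 px to the
    RPE;
  * RNFL retardation (deg), 550/870 µm annulus — mean compensated retardation
    in the slab [ILM+20 px, ILM+95 px), voxels ≥ 3 dB above the noise floor;
  * scleral birefringence (°/µm), 550/870 µm annulus — per-A-scan OLS slope of
    retardation vs depth in the 40 px (76 µm) slab starting 20 px below the
    RPE, `Δn = b·λ/360` for the dimensionless form.
* **Statistics** — Spearman ρ with strength classes (|ρ| ≥ 0.70 strong,
  0.50–0.70 moderate, 0.30–0.50 weak), OLS slopes per IOP range (14–105 and
  14–45 mmHg), a two-phase (dynamic/plateau, breakpoint 45 mmHg) scleral fit,
  and a Wilcoxon rank-sum superior/inferior hemifield comparison.

The phantom generator emits layered albino-rat posterior-eye volumes
(vitreous floor, ILM with ONH pit and RPE-free canal, ~30 µm RNFL, inner
retina, bright RPE, choroid, birefringent sclera) with fully developed
speckle, 15-look frame averaging and calibrated IOP responses, together with
a ground-truth record per volume.

## Worked example

```python
import psoct_iop as P

vol, truth = P.generate_volume(P.PhantomConfig(), iop=95, seed=0)
res = P.process_volume(vol, None, None)
bir = res["scleral_birefringence"]
print(f"{bir.mean:.3f} +- {bir.sd:.3f} deg/um (truth {truth.scleral_birefringence:.2f})")
```

prints

```
1.152 +- 0.018 deg/um (truth 1.16)
```

i.e. at a plateau pressure of 95 mmHg the pipeline recovers the phantom's
scleral birefringence of 1.16 °/µm to about 1% from a speckled volume, with
the ±SD reflecting the per-A-scan spread of the depth fits inside the
annulus. The scripts in `examples/` walk through each capability
(reconstruction + segmentation, single-volume birefringence, ONH depression,
and a full 13-level IOP series with statistics); `psoct-iop run --outdir out`
does the same from the shell and writes `metrics.csv`, `statistics.csv/json`,
en face maps and a run log.

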