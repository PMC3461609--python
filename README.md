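# ratpet

Tracer-independent, MR-template-based ROI analysis of rat brain PET.

## The problem

Quantifying regional brain uptake in small-animal PET requires regions of
interest (ROIs), and drawing ROIs directly on a PET image is observer
dependent — especially for tracers with highly specific uptake that offer no
anatomical landmarks, and on scanners whose resolution (2.3–3.4 mm FWHM) is
more than an order of magnitude coarser than MR. `ratpet` implements a
two-step workflow that avoids both an individual MR scan and tracer-specific
alignment:

1. An additional **[18F]NaF bone scan** is acquired per animal. NaF uptake in
   bone is high, so the scan shows the skull. It is rigidly coregistered
   (rotation + translation) to a population-average **MR template** carrying
   predefined brain ROIs, using skull landmarks — tympanic bullae, frontal
   bones, cranial case, parietal/occipital articulation. The template is
   first brought to subject scale by the ratio of tympanic-bulla distances
   (template 14.4 mm, study animals ≈ 11.4 mm).
2. The recovered rigid transform is **propagated unchanged to the dynamic
   tracer image** (here calibrated around a 21-frame, 44.5-min schedule), the
   template ROIs are projected through it onto the PET grid, and regional
   uptake is reported as percent injected dose per gram:

   %ID/g = C / (D · ρ) × 100,

   with C the regional mean concentration (kBq/mL), D the injected dose
   (kBq) and ρ the brain tissue density (1.045 g/mL).

Because MR voxels (0.1 × 0.1 × 0.13 mm³) and PET voxels (1.218 mm isotropic)
differ ~1390× in volume, the package also ships the **checkerboard
validation**: ROI statistics computed on synthetic images of alternating
0/1 kBq/mL voxels at both resolutions must agree in volume, mean and total
activity. Interobserver reproducibility is quantified with the two-way
mixed-effects intraclass correlation (single-rater absolute agreement ICC_A
and consistency ICC_C, with 95% CIs) and a between-observer coefficient of
variation. A **digital rat-head phantom** (ellipsoidal skull with bullae,
seven brain regions with the template's nominal volumes, monoexponential
regional washout) makes every stage testable without acquired data.

## Worked example

Simulate one animal in an unknown pose, register its NaF scan to the
template, and quantify the tracer image with the recovered transform:

```python
import numpy as np
from ratpet import (RigidTransform, register_naf_to_template,
                    project_rois, extract_tac, timepoint_uptake)
from ratpet.phantom import PhantomSpec, generate_template, generate_phantom

spec = PhantomSpec()
template = generate_template(spec)

pose = RigidTransform(rotation_deg=(8.0, -5.0, 12.0), translation_mm=(3.0, -2.0, 1.5))
animal = generate_phantom(spec, pose, template=template)

transform, report = register_naf_to_template(animal.naf, template, animal.landmarks)
print("recovered rotation (deg):", np.round(transform.rotation_deg, 3))
print("recovered translation (mm):", np.round(transform.translation_mm, 3))
print("alignment passed:", report.all_passed)

cfg = spec.quant_config()   # 9900 kBq injected dose, 1.045 g/mL
weights = project_rois(template.labels, animal.tracer.grid, transform, cfg)
tac = extract_tac(animal.tracer, weights, template.regions)
uptake = timepoint_uptake(tac, [5, 15, 45], cfg)
print(uptake.pivot(index="region", columns="time_min", values="percent_id_per_g").round(3))
```

Output:

```
recovered rotation (deg): [ 8. -5. 12.]
recovered translation (mm): [ 3.  -2.   1.5]
alignment passed: True
time_min           5.0    15.0   45.0
region
cerebellum         0.80  0.498  0.174
frontal_cortex     0.95  0.591  0.206
hippocampus        0.98  0.610  0.213
left_striatum      1.06  0.660  0.230
medulla_oblongata  0.67  0.417  0.145
posterior_cortex   0.92  0.573  0.200
right_striatum     1.04  0.647  0.226
```

The landmark fit recovers the pose exactly on noiseless input, and the
quantified 5-minute %ID/g values reproduce the uptake levels the phantom was
calibrated to (striatum highest, then hippocampus and cortex, medulla
lowest), decaying with the configured washout half-time (~16.4 min) to the
45-minute values.

The same operations are available from the shell:

```bash
ratpet simulate --seed 0 --out-dir fixtures/
ratpet register --naf fixtures/naf.nii.gz --template fixtures/template_mr.nii.gz \
    --labels fixtures/template_labels.nii.gz --landmarks fixtures/subject_landmarks.json \
    --template-landmarks fixtures/template_landmarks.json \
    --out transform.json --report report.json
ratpet quantify --dynamic fixtures/tracer.nii.gz --transform transform.json \
    --labels fixtures/template_labels.nii.gz --template fixtures/template_mr.nii.gz \
    --dose-kbq 9900 --out uptake.tsv
ratpet checkerboard --template fixtures/template_mr.nii.gz \
    --labels fixtures/template_labels.nii.gz --out checkerboard.tsv
```

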