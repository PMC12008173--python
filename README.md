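# cbmpet — cortex-based mapping of focal hypometabolism in FDG-PET

Drug-resistant focal epilepsy with a normal MRI is hard to operate on:
the epileptogenic zone must be found some other way, and interictal
FDG-PET hypometabolism is one of the strongest clues. Voxelwise
statistical mapping (the SPM-style approach) compares a patient's PET
against healthy controls in a common volumetric space, but intersubject
normalization never aligns gyri and sulci exactly, and the resulting
boundary artifacts masquerade as metabolic deficits. Cortex-based
mapping (CBM) sidesteps this by doing the statistics *on the cortical
surface*, where intersubject correspondence is established per vertex.

`cbmpet` implements both pipelines end to end, together with digital
cortical phantoms (so every stage is testable with known ground truth),
a registration-artifact quantification method, and the diagnostic
agreement statistics used to evaluate localization against surgical
outcome.

## The method

For each subject, PET is partial-volume corrected by van Cittert
iterative reblurring (PSF 4.5 mm; x_{k+1} = x_k + α(y − G_σ ∗ x_k)),
converted to SUVR relative to the cerebellum, sampled onto the cortical
surface, and smoothed along the surface with a 20 mm FWHM geodesic
kernel. A healthy template stores the vertex-wise mean μ_v and SD σ_v
of n smoothed control fields; a patient's z-map is

    z_v = (x_v − μ_v) / σ_v

and the candidate focus is the **global minimum 0.5%** of vertices —
a rank-based threshold that always flags exactly ⌈0.005·N⌉ vertices —
grouped into edge-connected clusters ranked by mean z.

The voxelwise baseline computes a single-case t-statistic per voxel,
t = (x − m̄)/(s·√(1 + 1/n)) with df = n − 1, after normalization to a
group space and 6 mm smoothing, thresholded by a ladder: p < 0.001
(clusters ≥ 20 voxels), falling back to p < 0.05, falling back to the
global-minimum voxel.

To measure registration artifacts, a morphology-only contrast model
(gray matter = +1, white matter = −1, else 0) rides through the exact
same steps as the PET data; Pearson correlation between PET-derived and
contrast-derived statistic maps quantifies the contamination per
subject and pipeline.

Localization calls are graded against the surgical field (CC when the
top cluster's peak lies inside it), crossed with seizure outcome
(Engel IA) into a 2×2 table, and summarized as sensitivity,
specificity, PPV/NPV (Clopper–Pearson CIs), Cohen's κ, and McNemar's
exact test between methods.

## Worked example

`examples/01_cortex_mapping.py` builds a hemisphere-sized spherical
phantom (2562 vertices), 23 healthy controls, and one patient with a
25% metabolic reduction over ~2% of the cortex, then runs the full
surface pipeline:

```
vertices flagged: 13 of 2562 (0.51%, the rank-based 0.5% contract)
clusters found: 1 (ranked most hypometabolic first)
top cluster: 13 vertices, mean z = -9.93, peak z at vertex 1929, area 440 mm^2
fraction of top cluster inside the true lesion: 1.00
```

Exactly ⌈0.005·2562⌉ = 13 vertices are flagged, they form a single
cluster with deeply negative z, and every flagged vertex lies inside
the injected lesion — the simulated focus is localized with full
precision. `examples/04_diagnostic_statistics.py` reproduces the
diagnostic table for a 42-patient cohort (31 seizure-free):

```
surface z-map: confusion (tp, fp, fn, tn) = (27, 1, 4, 10)
  sensitivity 0.871 (0.702-0.964), specificity 0.909
  PPV 0.964, NPV 0.714, kappa 0.717 (p = 2.42e-06)
voxel t-map: confusion (tp, fp, fn, tn) = (15, 3, 16, 8)
  sensitivity 0.484 (0.302-0.669), specificity 0.727
  PPV 0.833, NPV 0.333, kappa 0.153 (p = 0.224)
```

The other examples cover the voxelwise baseline
(`02_tmap_baseline.py`) and artifact quantification
(`03_artifact_quantification.py`, where the volume pipeline correlates
with artifacts at r ≈ 0.43 under 2 mm jitter while the surface pipeline
stays near 0.1).

A thin CLI mirrors the library (`cbmpet simulate | pvc | suvr |
template | zmap | tmap | artifact | evaluate`); identical configuration
and seed produce byte-identical reports.

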