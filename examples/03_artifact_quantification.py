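"""Quantify how much of each statistic map is registration artifact.

Pushes a morphology-only contrast model (gray = +1, white = -1) through
the identical pipeline steps as the PET data for a jittered cohort, then
correlates PET-derived and contrast-derived maps per subject.  High
correlation means the statistic map is contaminated by intersubject
misalignment rather than metabolism.
"""

import logging

from cbmpet import PhantomSpec, artifact_study

logging.getLogger("cbmpet").setLevel(logging.ERROR)

spec = PhantomSpec(mesh_subdivisions=3, jitter_amplitude_mm=2.0)
report = artifact_study(spec, n_subjects=8, n_controls=10, seed=0)

print("With 2 mm residual intersubject registration error:")
print(f"  volume pipeline (t-maps):  mean r = {report.mean_r_volume:.3f} "
      f"+/- {report.se_r_volume:.3f}")
print(f"  surface pipeline (z-maps): mean r = {report.mean_r_surface:.3f} "
      f"+/- {report.se_r_surface:.3f}")
print(f"  volume exceeds surface: {report.volume_exceeds_surface}")

null = artifact_study(
    PhantomSpec(mesh_subdivisions=3, jitter_amplitude_mm=0.0),
    n_subjects=8, n_controls=10, seed=0,
)
print("With perfect registration (zero jitter):")
print(f"  volume {null.mean_r_volume:.3f}, surface {null.mean_r_surface:.3f}")
print("The voxelwise pipeline inherits boundary artifacts from volumetric")
print("misalignment; the surface pipeline, whose residual error slides along")
print("the cortical ribbon, stays close to artifact-free.")
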