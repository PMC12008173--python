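"""Localize a focal hypometabolic lesion with cortex-based mapping.

Builds a spherical cortical phantom, simulates 23 healthy controls and
one patient carrying a 25% metabolic reduction over ~2% of the cortex,
then runs the full surface pipeline: 20 mm geodesic smoothing, healthy
template (vertex-wise mean/SD), z-transform, global-minimum 0.5%
threshold, and focus clustering.
"""

import numpy as np

from cbmpet import (
    Lesion,
    PhantomSpec,
    PipelineConfig,
    build_template,
    cbm_pipeline,
    generate_control_field,
    inject_lesion,
    make_icosphere,
    make_parcellation,
    smooth_surface_field,
)

spec = PhantomSpec(mesh_subdivisions=4)  # 2562 vertices, hemisphere-sized sphere
config = PipelineConfig()
mesh = make_icosphere(spec.mesh_subdivisions, spec.mesh_radius_mm)
parcellation = make_parcellation(mesh, spec.n_regions, seed=3)

controls = [
    smooth_surface_field(
        generate_control_field(mesh, parcellation, spec, subject_seed=100 + i),
        mesh,
        config.surface_smooth_fwhm_mm,
    )
    for i in range(23)
]
template = build_template(controls, config.sd_floor_fraction, config.surface_smooth_fwhm_mm)

# patient: healthy field with a lesion in a neocortical region
patient = generate_control_field(mesh, parcellation, spec, subject_seed=999)
cortex = np.flatnonzero(
    np.isin(parcellation, [r for r, m in spec.region_means().items() if m > 1.0])
)
lesion = Lesion(center_vertex=int(cortex[40]), geodesic_radius_mm=24.0, hypometabolism_factor=0.75)
lesioned, truth = inject_lesion(patient, mesh, lesion)

zmap, clusters = cbm_pipeline(lesioned, template, mesh, config, subject_id="patient-01")

flagged = sum(len(c) for c in clusters)
print(f"vertices flagged: {flagged} of {mesh.n_vertices} "
      f"({100 * flagged / mesh.n_vertices:.2f}%, the rank-based 0.5% contract)")
print(f"clusters found: {len(clusters)} (ranked most hypometabolic first)")
top = clusters[0]
inside = np.isin(top.vertex_ids, np.flatnonzero(truth)).mean()
print(f"top cluster: {len(top)} vertices, mean z = {top.mean_z:.2f}, "
      f"peak z at vertex {top.peak_vertex}, area {top.surface_area_mm2:.0f} mm^2")
print(f"fraction of top cluster inside the true lesion: {inside:.2f}")
print("A mean z below about -2 with the cluster inside the truth mask means the")
print("pipeline localized the simulated epileptogenic focus correctly.")
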