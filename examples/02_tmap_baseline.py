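"""Voxelwise single-case t-map baseline with the threshold ladder.

Simulates PET volumes for a control group and a patient whose gray
matter activity is reduced inside a spherical focus, computes the
one-vs-group t-statistic per voxel after 6 mm smoothing, and applies the
thresholding ladder (p < 0.001 with 20-voxel extent, then p < 0.05,
then the global minimum).
"""

import numpy as np

from cbmpet import (
    PSF,
    PhantomSpec,
    TMapSettings,
    build_volume_phantom,
    compute_suvr,
    gaussian_blur,
    make_icosphere,
    simulate_pet,
    single_case_t,
    threshold_tmap,
)

spec = PhantomSpec(mesh_subdivisions=2, mesh_radius_mm=40.0, grid_shape=(32, 32, 32))
mesh = make_icosphere(2, 40.0)
activity, labels = build_volume_phantom(mesh, spec)
smooth = PSF(6.0, 6.0)


def subject_volume(seed, lesioned=False):
    data = activity.data.copy()
    if lesioned:
        idx = np.indices(activity.shape, dtype=float)
        world = np.stack([activity.affine[c, c] * idx[c] + activity.affine[c, 3] for c in range(3)])
        focus = np.sqrt(((world - np.array([0, 0, 40.0])[:, None, None, None]) ** 2).sum(0)) < 12
        data[focus] *= 0.7
    pet = simulate_pet(activity.like(data), 3.0, 0.03, seed)
    return gaussian_blur(compute_suvr(pet, labels), smooth)


controls = [subject_volume(seed) for seed in range(15)]
patient = subject_volume(99, lesioned=True)

tmap = single_case_t(patient, controls)
clusters, rung = threshold_tmap(tmap, TMapSettings())

print(f"degrees of freedom: {tmap.df} (15 controls, one patient)")
print(f"threshold ladder fired at rung {rung} "
      f"(1: p<0.001 k=20, 2: p<0.05 k=20, 3: global minimum voxel)")
for i, c in enumerate(clusters[:3]):
    world = activity.voxel_to_world(np.asarray(c.peak_voxel))[0]
    print(f"cluster {i}: {len(c)} voxels, peak t = {c.peak_t:.1f} at {np.round(world, 1)} mm")
print("The top cluster peak should sit near (0, 0, 40) mm, the injected focus;")
print("rung 1 firing means the deficit was conclusive at the strict threshold.")
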