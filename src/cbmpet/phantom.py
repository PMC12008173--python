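"""Digital cortical phantoms.

Every downstream stage of the pipeline is testable without any download:
this module builds paired surface + volume phantoms with known ground
truth.  A sphere stands in for one cortical hemisphere (its default
radius, 85 mm, gives a surface area close to a human hemisphere's
~90,000 mm^2); a geodesic-Voronoi parcellation carries per-region mean
SUVRs patterned on the healthy control pattern (hypometabolic limbic
regions near 0.5, neocortex above 1); focal hypometabolic lesions are
injected as geodesic disks with a known multiplicative factor; and
intersubject registration error is emulated with smooth, invertible
random displacement fields.

Geodesic distance is the graph geodesic over edge lengths, which is an
adequate approximation of the surface geodesic at phantom resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import trimesh
from scipy import ndimage
from scipy.sparse.csgraph import dijkstra

from .errors import GeometryError, ValidationError
from .preprocess import PSF, gaussian_blur
from .surfaces import SurfaceMesh, VertexField
from .volumes import BACKGROUND, CEREBELLUM_REF, GRAY, WHITE, LabelVolume, VolumeImage

log = logging.getLogger("cbmpet")

__all__ = [
    "DEFAULT_REGION_MEANS",
    "PhantomSpec",
    "Lesion",
    "CohortBundle",
    "WarpField",
    "make_icosphere",
    "make_parcellation",
    "generate_control_field",
    "inject_lesion",
    "geodesic_disk",
    "build_volume_phantom",
    "simulate_pet",
    "make_jitter_warp",
    "generate_cohort",
]

# Regional mean SUVRs relative to cerebellum, patterned on the healthy
# control pattern: neocortex above 1 (frontal highest), limbic/anterior
# temporal structures physiologically hypometabolic (amygdala 0.44/0.47,
# hippocampus 0.49/0.52, temporal pole 0.50/0.51, entorhinal 0.53/0.55,
# parahippocampal 0.64/0.66).  Cycled when n_regions differs.
DEFAULT_REGION_MEANS = (
    1.30, 1.25, 1.20, 1.15, 1.10, 1.05,
    0.49, 0.52, 0.44, 0.47, 0.64, 1.08,
)


@dataclass
class PhantomSpec:
    """Study conditions for phantom generation (all lengths in mm)."""

    mesh_subdivisions: int = 4
    mesh_radius_mm: float = 85.0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    n_regions: int = 12
    region_mean_suvr: dict[int, float] | None = None
    between_subject_sd: float = 0.005
    vertex_noise_sd: float = 0.05
    noise_fwhm_mm: float = 20.0
    gm_activity: float = 1.2
    wm_activity: float = 0.7
    csf_activity: float = 0.05
    ref_activity: float = 1.0
    ribbon_half_mm: float = 3.5
    pet_noise_sd: float = 0.03
    jitter_amplitude_mm: float = 2.0
    jitter_correlation_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValidationError("n_regions must be >= 2")
        for key in ("gm_activity", "wm_activity", "csf_activity", "ref_activity"):
            if getattr(self, key) < 0:
                raise ValidationError(f"{key} must be >= 0")
        if self.gm_activity <= self.wm_activity:
            raise ValidationError("gm_activity must exceed wm_activity")

    def region_means(self) -> dict[int, float]:
        if self.region_mean_suvr is not None:
            return dict(self.region_mean_suvr)
        base = DEFAULT_REGION_MEANS
        return {r: base[r % len(base)] for r in range(self.n_regions)}


@dataclass
class Lesion:
    """Focal hypometabolism: geodesic disk scaled by factor f in (0, 1]."""

    center_vertex: int
    geodesic_radius_mm: float
    hypometabolism_factor: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.hypometabolism_factor <= 1.0:
            raise ValidationError("hypometabolism_factor must be in (0, 1]")
        if self.geodesic_radius_mm <= 0:
            raise ValidationError("geodesic_radius_mm must be > 0")


@dataclass
class WarpField:
    """Smooth displacement field (mm, per voxel) with its numeric inverse."""

    disp_mm: np.ndarray  # (3, nx, ny, nz)
    affine: np.ndarray
    inv_disp_mm: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp_mm.shape[1:]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def _sample_disp(self, disp: np.ndarray, points_world: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        vox = points_world @ inv[:3, :3].T + inv[:3, 3]
        coords = vox.T
        return np.stack(
            [ndimage.map_coordinates(disp[c], coords, order=1, mode="nearest") for c in range(3)],
            axis=1,
        )

    def displace_points(self, points_world: np.ndarray, inverse: bool = False) -> np.ndarray:
        """points + displacement interpolated at the points themselves."""
        d = self.inv_disp_mm if inverse else self.disp_mm
        pts = np.atleast_2d(np.asarray(points_world, dtype=np.float64))
        return pts + self._sample_disp(d, pts)

    def apply(self, volume: VolumeImage, inverse: bool = False, order: int = 1) -> VolumeImage:
        """Resample: out(x) = in(x + d(x)); see tmap.normalize_to_group."""
        if volume.shape != self.shape:
            raise GeometryError(
                f"warp grid {self.shape} does not match volume grid {volume.shape}"
            )
        d = self.inv_disp_mm if inverse else self.disp_mm
        idx = np.indices(volume.shape, dtype=np.float64)
        world = np.einsum("ab,b...->a...", volume.affine[:3, :3], idx)
        for c in range(3):
            world[c] += volume.affine[c, 3]
        sample_world = world + d
        inv = np.linalg.inv(volume.affine)
        sample_vox = np.einsum("ab,b...->a...", inv[:3, :3], sample_world)
        for c in range(3):
            sample_vox[c] += inv[c, 3]
        out = ndimage.map_coordinates(volume.data, sample_vox, order=order, mode="nearest")
        return volume.like(out)


def make_icosphere(subdivisions: int, radius_mm: float) -> SurfaceMesh:
    """Icosphere with 10 * 4**s + 2 vertices, all at the given radius."""
    if subdivisions < 0:
        raise ValidationError("subdivisions must be >= 0")
    if radius_mm <= 0:
        raise ValidationError("radius must be > 0")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def geodesic_distances(mesh: SurfaceMesh, sources) -> np.ndarray:
    """Graph-geodesic distances (mm) from source vertex/vertices."""
    adj = mesh.adjacency(weighted=True)
    return dijkstra(adj, directed=False, indices=sources, min_only=np.ndim(sources) > 0)


def make_parcellation(mesh: SurfaceMesh, n_regions: int, seed: int) -> np.ndarray:
    """Geodesic-Voronoi parcellation from randomly chosen seed vertices.

    Every region is non-empty and edge-connected; stray components (possible
    with exact distance ties) are reassigned to an adjacent region.
    """
    n = mesh.n_vertices
    if n_regions > n:
        raise ValidationError(f"n_regions={n_regions} exceeds vertex count {n}")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(n, size=n_regions, replace=False)
    adj = mesh.adjacency(weighted=True)
    dist, _, sources = dijkstra(
        adj, directed=False, indices=seeds, min_only=True, return_predecessors=True
    )
    seed_to_region = {int(s): r for r, s in enumerate(seeds)}
    labels = np.array([seed_to_region[int(s)] for s in sources], dtype=np.int32)
    _repair_region_connectivity(mesh, labels, seeds)
    return labels


def _repair_region_connectivity(mesh: SurfaceMesh, labels: np.ndarray, seeds) -> None:
    from scipy.sparse.csgraph import connected_components

    adj = mesh.adjacency(weighted=False)
    for r, s in enumerate(seeds):
        idx = np.flatnonzero(labels == r)
        sub = adj[idx][:, idx]
        ncomp, comp = connected_components(sub, directed=False)
        if ncomp <= 1:
            continue
        keep = comp[np.searchsorted(idx, s)]
        stray = idx[comp != keep]
        for v in stray:
            neigh = adj[v].indices
            neigh_labels = labels[neigh]
            other = neigh_labels[neigh_labels != r]
            if other.size:
                labels[v] = np.bincount(other).argmax()


def generate_control_field(
    mesh: SurfaceMesh,
    parcellation: np.ndarray,
    spec: PhantomSpec,
    subject_seed: int,
) -> VertexField:
    """One healthy subject's vertex-wise SUVR.

    value = region mean + subject offset (SD ``between_subject_sd``)
    + a spatially coherent noise field (per-vertex SD ``vertex_noise_sd``,
    correlated at ``noise_fwhm_mm``).  The offset is small by default:
    ratio normalization to the cerebellum removes most of the global
    intersubject uptake level, so what remains across subjects is mostly
    smooth regional topography — which is also what survives the 20 mm
    analysis smoothing.  With both SDs zero the field is piecewise
    constant at the region means.
    """
    means = spec.region_means()
    missing = set(np.unique(parcellation)) - set(means)
    if missing:
        raise ValidationError(f"region_mean_suvr lacks regions {sorted(missing)}")
    rng = np.random.default_rng(subject_seed)
    base = np.array([means[int(r)] for r in parcellation])
    offset = rng.normal(0.0, spec.between_subject_sd) if spec.between_subject_sd > 0 else 0.0
    values = base + offset
    if spec.vertex_noise_sd > 0:
        from .cbm import smooth_surface_field  # local import: cbm does not import phantom

        white = rng.standard_normal(mesh.n_vertices)
        noise = smooth_surface_field(VertexField(white), mesh, spec.noise_fwhm_mm).values
        sd = noise.std()
        if sd > 0:
            noise *= spec.vertex_noise_sd / sd
        values = values + noise
    return VertexField(values, units="SUVR")


def geodesic_disk(mesh: SurfaceMesh, center_vertex: int, radius_mm: float) -> np.ndarray:
    """Boolean mask of vertices within graph-geodesic radius of the center."""
    if not 0 <= center_vertex < mesh.n_vertices:
        raise ValidationError(f"center vertex {center_vertex} out of range")
    dist = dijkstra(mesh.adjacency(weighted=True), directed=False, indices=center_vertex)
    return dist <= radius_mm


def inject_lesion(
    field: VertexField, mesh: SurfaceMesh, lesion: Lesion
) -> tuple[VertexField, np.ndarray]:
    """Multiply values inside the lesion disk by the hypometabolism factor.

    Returns the lesioned field and the exact truth mask.  The center
    vertex is always in the mask (distance 0).
    """
    field.check_mesh(mesh)
    mask = geodesic_disk(mesh, lesion.center_vertex, lesion.geodesic_radius_mm)
    values = field.values.copy()
    values[mask] *= lesion.hypometabolism_factor
    return VertexField(values, units=field.units), mask


def phantom_affine(spec: PhantomSpec) -> np.ndarray:
    """Grid centered on the origin, sized to enclose cortex + cerebellum."""
    half_extent = spec.mesh_radius_mm + 25.0
    shape = np.asarray(spec.grid_shape)
    voxel = 2.0 * half_extent / shape
    affine = np.diag([voxel[0], voxel[1], voxel[2], 1.0])
    affine[:3, 3] = -voxel * (shape - 1) / 2.0
    return affine


def build_volume_phantom(
    mesh: SurfaceMesh, spec: PhantomSpec
) -> tuple[VolumeImage, LabelVolume]:
    """Voxelize the spherical cortex plus a disjoint cerebellum reference.

    Voxels within ``ribbon_half_mm`` of the sphere surface are gray
    matter, the interior white matter, the exterior background/CSF.  The
    cerebellum reference is a separate ball below the cortex, mirroring
    its use as a normalization region off the analyzed surface.
    """
    affine = phantom_affine(spec)
    shape = tuple(spec.grid_shape)
    idx = np.indices(shape, dtype=np.float64)
    world = np.einsum("ab,b...->a...", affine[:3, :3], idx)
    for c in range(3):
        world[c] += affine[c, 3]
    center = mesh.vertices.mean(axis=0)
    r = np.sqrt(sum((world[c] - center[c]) ** 2 for c in range(3)))
    R = float(np.linalg.norm(mesh.vertices - center, axis=1).mean())
    half_extent = spec.mesh_radius_mm + 25.0
    if R + spec.ribbon_half_mm > half_extent:
        raise GeometryError(
            f"grid half-extent {half_extent} mm too small for mesh radius {R} mm"
        )

    labels = np.full(shape, BACKGROUND, dtype=np.int32)
    labels[r < R - spec.ribbon_half_mm] = WHITE
    labels[np.abs(r - R) <= spec.ribbon_half_mm] = GRAY

    cereb_center = center + np.array([0.0, 0.0, -(R + spec.ribbon_half_mm + 11.0)])
    cereb_r = np.sqrt(sum((world[c] - cereb_center[c]) ** 2 for c in range(3)))
    cereb = cereb_r <= 8.0
    if not cereb.any() or (labels[cereb] != BACKGROUND).any():
        raise GeometryError("cerebellum reference does not fit disjointly in the grid")
    labels[cereb] = CEREBELLUM_REF

    activity = np.full(shape, spec.csf_activity, dtype=np.float64)
    activity[labels == GRAY] = spec.gm_activity
    activity[labels == WHITE] = spec.wm_activity
    activity[labels == CEREBELLUM_REF] = spec.ref_activity
    return VolumeImage(activity, affine), LabelVolume(labels, affine)


def simulate_pet(
    activity: VolumeImage, recon_fwhm_mm: float, noise_sd: float, seed: int
) -> VolumeImage:
    """Emulated PET measurement: reconstruction-filter blur + Gaussian noise."""
    if recon_fwhm_mm < 0:
        raise ValidationError("recon_fwhm_mm must be >= 0")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    out = gaussian_blur(activity, PSF(recon_fwhm_mm, recon_fwhm_mm))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out.like(out.data + rng.normal(0.0, noise_sd, out.shape))
    return out


def make_jitter_warp(
    grid: VolumeImage,
    amplitude_mm: float,
    correlation_length_mm: float,
    seed: int,
    max_fixed_point_iter: int = 100,
) -> WarpField:
    """Smooth random displacement field with a numeric inverse.

    ``amplitude_mm`` is the root-mean-square displacement magnitude.  The
    field is rejected if its displacement gradient reaches 1 anywhere
    (folding), and the fixed-point inverse is iterated until the
    forward-then-inverse residual is below 0.1 voxel everywhere.
    """
    if amplitude_mm < 0:
        raise ValidationError("amplitude_mm must be >= 0")
    shape = grid.shape
    voxel = grid.voxel_size
    if amplitude_mm == 0:
        zeros = np.zeros((3, *shape))
        return WarpField(zeros, grid.affine.copy(), zeros.copy())

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((3, *shape))
    sig_vox = correlation_length_mm / voxel
    disp = np.stack(
        [ndimage.gaussian_filter(noise[c], sigma=sig_vox, mode="mirror") for c in range(3)]
    )
    rms = float(np.sqrt(np.mean(np.sum(disp**2, axis=0))))
    disp *= amplitude_mm / rms

    # diffeomorphism check: inf-norm of the displacement Jacobian < 1
    jac_norm = 0.0
    for c in range(3):
        grads = np.gradient(disp[c], *voxel)
        row = sum(np.abs(g) for g in grads)
        jac_norm = max(jac_norm, float(row.max()))
    if jac_norm >= 1.0:
        raise GeometryError(
            f"jitter amplitude {amplitude_mm} mm at correlation length "
            f"{correlation_length_mm} mm produces folding "
            f"(max displacement gradient {jac_norm:.2f} >= 1); reduce the amplitude"
        )

    warp = WarpField(disp, grid.affine.copy(), np.zeros_like(disp))
    idx = np.indices(shape, dtype=np.float64)
    world = np.einsum("ab,b...->a...", grid.affine[:3, :3], idx)
    for c in range(3):
        world[c] += grid.affine[c, 3]
    pts = world.reshape(3, -1).T
    inv = np.zeros_like(pts)
    tol = 0.1 * float(voxel.min())
    for _ in range(max_fixed_point_iter):
        fwd_at = warp._sample_disp(disp, pts + inv)
        resid = inv + fwd_at
        if float(np.abs(resid).max()) < 0.5 * tol:
            break
        inv = -fwd_at
    resid_max = float(np.abs(inv + warp._sample_disp(disp, pts + inv)).max())
    if resid_max >= tol:
        raise GeometryError(
            f"warp inverse did not converge (residual {resid_max:.3g} mm >= {tol:.3g})"
        )
    warp.inv_disp_mm = inv.T.reshape(3, *shape)
    return warp


@dataclass
class CohortBundle:
    """A self-contained simulated study: controls, patients, volumes, truth."""

    mesh: SurfaceMesh
    parcellation: np.ndarray
    control_fields: list[VertexField]
    patients: list[dict]  # field, truth_mask, surgical_mask, seizure_free, lesion
    activity: VolumeImage | None = None
    labels: LabelVolume | None = None
    control_warps: list[WarpField] = dc_field(default_factory=list)
    patient_warps: list[WarpField] = dc_field(default_factory=list)
    spec: PhantomSpec | None = None


def generate_cohort(
    spec: PhantomSpec,
    n_controls: int = 23,
    n_patients: int = 10,
    lesion_radius_mm: float | None = None,
    lesion_factor: float = 0.75,
    concordant_fraction: float = 0.8,
    with_volumes: bool = False,
    seed: int | None = None,
) -> CohortBundle:
    """Simulate a full study cohort reproducible from (spec, seed) alone.

    Patients carry a lesion in a neocortical region (regional mean > 1)
    plus a surgical-field disk; a ``concordant_fraction`` of patients has
    the field centered on the lesion (and is labeled seizure-free), the
    rest have a discordant field elsewhere (not seizure-free).
    """
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)
    mesh = make_icosphere(spec.mesh_subdivisions, spec.mesh_radius_mm)
    parcellation = make_parcellation(mesh, spec.n_regions, int(master.integers(2**31)))
    if lesion_radius_mm is None:
        # disk covering about 2% of the sphere area
        lesion_radius_mm = float(np.sqrt(0.02 * 4.0) * spec.mesh_radius_mm)

    subject_seeds = master.integers(2**31, size=n_controls + n_patients)
    controls = [
        generate_control_field(mesh, parcellation, spec, int(s))
        for s in subject_seeds[:n_controls]
    ]

    means = spec.region_means()
    cortex_regions = [r for r, m in means.items() if m > 1.0]
    cortex_vertices = np.flatnonzero(np.isin(parcellation, cortex_regions))
    patients = []
    for i, s in enumerate(subject_seeds[n_controls:]):
        rng = np.random.default_rng(int(s))
        base = generate_control_field(mesh, parcellation, spec, int(s))
        center = int(rng.choice(cortex_vertices))
        lesion = Lesion(center, lesion_radius_mm, lesion_factor)
        lesioned, truth = inject_lesion(base, mesh, lesion)
        concordant = rng.random() < concordant_fraction
        if concordant:
            surg_center = center
        else:
            far = np.flatnonzero(~geodesic_disk(mesh, center, 3 * lesion_radius_mm))
            surg_center = int(rng.choice(far))
        surgical = geodesic_disk(mesh, surg_center, 1.3 * lesion_radius_mm)
        patients.append(
            {
                "field": lesioned,
                "truth_mask": truth,
                "surgical_mask": surgical,
                "seizure_free": bool(concordant),
                "lesion": lesion,
            }
        )

    bundle = CohortBundle(mesh, parcellation, controls, patients, spec=spec)
    if with_volumes:
        activity, labels = build_volume_phantom(mesh, spec)
        bundle.activity, bundle.labels = activity, labels
        warp_seeds = master.integers(2**31, size=n_controls + n_patients)
        bundle.control_warps = [
            make_jitter_warp(activity, spec.jitter_amplitude_mm, spec.jitter_correlation_mm, int(s))
            for s in warp_seeds[:n_controls]
        ]
        bundle.patient_warps = [
            make_jitter_warp(activity, spec.jitter_amplitude_mm, spec.jitter_correlation_mm, int(s))
            for s in warp_seeds[n_controls:]
        ]
    return bundle
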