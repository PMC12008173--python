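"""Cortex-based mapping: sampling, smoothing, template, z, threshold, clusters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbmpet.cbm import (
    build_template,
    cbm_pipeline,
    cluster_flagged,
    sample_volume_to_surface,
    smooth_surface_field,
    threshold_global_min,
    z_transform,
)
from cbmpet.config import PipelineConfig
from cbmpet.errors import CohortError, ConsistencyError, GeometryError, ShapeError
from cbmpet.phantom import PhantomSpec, generate_control_field, geodesic_disk, inject_lesion, Lesion
from cbmpet.surfaces import VertexField
from cbmpet.volumes import VolumeImage


def _empirical_fwhm(mesh, smoothed, center, radius=85.0):
    """Half-maximum diameter of a smoothed impulse, from the binned
    radial profile in true (arc) geodesic distance."""
    chord = np.linalg.norm(mesh.vertices - mesh.vertices[center], axis=1)
    arc = 2 * radius * np.arcsin(np.clip(chord / (2 * radius), 0, 1))
    half = smoothed.max() / 2
    centers, profile = [], []
    for r in range(40):
        sel = (arc >= r) & (arc < r + 1)
        if sel.any():
            centers.append(r + 0.5)
            profile.append(smoothed[sel].mean())
    centers, profile = np.asarray(centers), np.asarray(profile)
    j = int(np.argmax(profile < half))
    r_half = np.interp(half, [profile[j], profile[j - 1]], [centers[j], centers[j - 1]])
    return 2 * float(r_half)


def _enclosing_volume(mesh, fill=0.0, n=32):
    extent = 1.3 * np.abs(mesh.vertices).max()
    vox = 2 * extent / n
    affine = np.diag([vox, vox, vox, 1.0])
    affine[:3, 3] = -vox * (n - 1) / 2
    return VolumeImage(np.full((n, n, n), fill), affine)


class TestSampling:
    def test_constant_volume_gives_constant_field(self, mesh_s2):
        vol = _enclosing_volume(mesh_s2, fill=2.5)
        field = sample_volume_to_surface(vol, mesh_s2)
        np.testing.assert_allclose(field.values, 2.5, rtol=1e-12)

    def test_linear_ramp_reproduces_vertex_coordinates(self, mesh_s2):
        """Trilinear interpolation is exact for f(x, y, z) = x."""
        vol = _enclosing_volume(mesh_s2)
        idx = np.indices(vol.shape, dtype=np.float64)
        world_x = vol.affine[0, 0] * idx[0] + vol.affine[0, 3]
        vol = vol.like(world_x)
        field = sample_volume_to_surface(vol, mesh_s2)
        np.testing.assert_allclose(field.values, mesh_s2.vertices[:, 0], atol=1e-6)

    def test_vertex_at_voxel_center_reads_exact_value(self, rng):
        from cbmpet.surfaces import SurfaceMesh

        vol = VolumeImage(rng.random((8, 8, 8)), np.eye(4))
        tri = SurfaceMesh(
            np.array([[3.0, 4.0, 2.0], [3.0, 4.0, 3.0], [3.0, 5.0, 2.0]]),
            np.array([[0, 1, 2]]),
        )
        field = sample_volume_to_surface(vol, tri)
        assert field.values[0] == pytest.approx(vol.data[3, 4, 2], abs=1e-12)

    def test_vertex_outside_volume_is_boundary_error(self, mesh_s2):
        vol = VolumeImage(np.zeros((4, 4, 4)), np.eye(4))
        with pytest.raises(GeometryError, match="vertex"):
            sample_volume_to_surface(vol, mesh_s2)


class TestSurfaceSmoothing:
    def test_zero_fwhm_is_identity(self, mesh_s2, rng):
        field = VertexField(rng.normal(size=mesh_s2.n_vertices))
        out = smooth_surface_field(field, mesh_s2, 0.0)
        np.testing.assert_array_equal(out.values, field.values)

    def test_constant_field_is_fixed_point(self, mesh_s4):
        field = VertexField(np.full(mesh_s4.n_vertices, 3.14))
        out = smooth_surface_field(field, mesh_s4, 20.0)
        np.testing.assert_allclose(out.values, 3.14, atol=1e-12)

    def test_delta_spread_matches_target_fwhm(self, mesh_s5):
        """Empirical geodesic FWHM of the smoothed impulse within 15% of 20 mm."""
        delta = np.zeros(mesh_s5.n_vertices)
        delta[123] = 1.0
        sm = smooth_surface_field(VertexField(delta), mesh_s5, 20.0).values
        assert _empirical_fwhm(mesh_s5, sm, 123) == pytest.approx(20.0, rel=0.15)

    def test_smoothing_preserves_mean_roughly(self, mesh_s4, rng):
        field = VertexField(rng.normal(1.0, 0.1, mesh_s4.n_vertices))
        out = smooth_surface_field(field, mesh_s4, 20.0)
        assert out.values.mean() == pytest.approx(field.values.mean(), rel=1e-3)


class TestTemplate:
    def test_identical_controls_floored_everywhere(self, mesh_s2):
        fields = [VertexField(np.ones(mesh_s2.n_vertices))] * 5
        template = build_template(fields, sd_floor_fraction=0.05)
        assert template.sd_floor_applied.all()
        assert np.all(template.sigma > 0)

    def test_fewer_than_three_controls_rejected(self, mesh_s2):
        fields = [VertexField(np.full(mesh_s2.n_vertices, v)) for v in (0.9, 1.1)]
        with pytest.raises(CohortError):
            build_template(fields)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ShapeError):
            build_template([VertexField(np.ones(10)), VertexField(np.ones(11)), VertexField(np.ones(10))])

    def test_mu_recovers_generator_means(self, mesh_s4, parcellation_s4):
        """Template mean tracks the generator's regional pattern (23 controls)."""
        spec = PhantomSpec()
        fields = [
            generate_control_field(mesh_s4, parcellation_s4, spec, 700 + i) for i in range(23)
        ]
        template = build_template(fields, 0.05, smoothing_fwhm_mm=0.0)
        means = spec.region_means()
        expected = np.array([means[int(r)] for r in parcellation_s4])
        err = template.mu - expected
        se = np.std([f.values for f in fields], axis=0, ddof=1) / np.sqrt(23)
        assert np.mean(np.abs(err) <= 3 * se + 1e-9) > 0.95


class TestZTransform:
    def _template(self, n, mu=1.0, sigma=0.1):
        from cbmpet.cbm import HealthyTemplate

        return HealthyTemplate(
            mu=np.full(n, mu),
            sigma=np.full(n, sigma),
            n_controls=23,
            sd_floor_applied=np.zeros(n, bool),
            smoothing_fwhm_mm=20.0,
            sd_floor=1e-6,
        )

    def test_field_equal_to_mu_gives_zero(self):
        tpl = self._template(50)
        zm = z_transform(VertexField(np.full(50, 1.0)), tpl)
        np.testing.assert_allclose(zm.z, 0.0)

    def test_two_sigma_below_gives_minus_two(self):
        tpl = self._template(50, mu=1.0, sigma=0.1)
        zm = z_transform(VertexField(np.full(50, 0.8)), tpl)
        np.testing.assert_allclose(zm.z, -2.0)

    def test_mesh_mismatch_rejected(self):
        tpl = self._template(50)
        with pytest.raises(ShapeError):
            z_transform(VertexField(np.ones(49)), tpl)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=-3, max_value=3))
    def test_affine_equivariance(self, c):
        """Adding c*sigma_v to the field shifts every z by exactly c."""
        rng = np.random.default_rng(0)
        n = 64
        from cbmpet.cbm import HealthyTemplate

        tpl = HealthyTemplate(
            mu=rng.normal(1, 0.1, n),
            sigma=rng.uniform(0.05, 0.2, n),
            n_controls=10,
            sd_floor_applied=np.zeros(n, bool),
            smoothing_fwhm_mm=20.0,
            sd_floor=1e-6,
        )
        x = rng.normal(1, 0.1, n)
        z0 = z_transform(VertexField(x), tpl).z
        z1 = z_transform(VertexField(x + c * tpl.sigma), tpl).z
        np.testing.assert_allclose(z1 - z0, c, atol=1e-9)

    def test_leave_one_out_z_is_approximately_standard_normal(
        self, mesh_s5
    ):
        """A held-out control z-map has mean near 0 and SD near 1."""
        from cbmpet.phantom import make_parcellation

        spec = PhantomSpec(mesh_subdivisions=5)
        parcellation = make_parcellation(mesh_s5, 12, seed=3)
        fields = [
            smooth_surface_field(
                generate_control_field(mesh_s5, parcellation, spec, 100 + i), mesh_s5, 20.0
            )
            for i in range(24)
        ]
        template = build_template(fields[:23], 0.05, 20.0)
        zm = z_transform(fields[23], template)
        assert abs(zm.z.mean()) < 0.15
        assert 0.8 < zm.z.std() < 1.25


class TestThreshold:
    def test_half_percent_of_ten_thousand_is_fifty(self, rng):
        z = rng.normal(size=10000)
        assert threshold_global_min(z, 0.005).sum() == 50

    def test_zero_fraction_empty(self, rng):
        assert threshold_global_min(rng.normal(size=100), 0.0).sum() == 0

    def test_ties_broken_by_ascending_index(self):
        flagged = threshold_global_min(np.zeros(100), 0.05)
        np.testing.assert_array_equal(np.flatnonzero(flagged), np.arange(5))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=5000),
        fraction=st.sampled_from([0.0, 0.005, 0.01, 0.05, 0.5, 1.0]),
        seed=st.integers(min_value=0, max_value=100),
    )
    def test_flagged_count_is_exactly_ceil(self, n, fraction, seed):
        """Rank-based contract: |flagged| = ceil(fraction * N), any data."""
        z = np.random.default_rng(seed).normal(size=n)
        flagged = threshold_global_min(z, fraction)
        assert flagged.sum() == math.ceil(round(fraction * n, 9))

    def test_flags_the_most_negative_values(self, rng):
        z = rng.normal(size=200)
        flagged = threshold_global_min(z, 0.05)
        assert z[flagged].max() <= z[~flagged].min()


class TestClusters:
    def test_two_disjoint_patches_two_clusters(self, mesh_s4):
        a = geodesic_disk(mesh_s4, 0, 10.0)
        far = int(np.argmax(np.linalg.norm(mesh_s4.vertices - mesh_s4.vertices[0], axis=1)))
        b = geodesic_disk(mesh_s4, far, 10.0)
        assert not (a & b).any()
        z = np.where(a | b, -3.0, 0.0)
        clusters = cluster_flagged(a | b, mesh_s4, z)
        assert len(clusters) == 2

    def test_empty_flagged_set(self, mesh_s2):
        assert cluster_flagged(np.zeros(mesh_s2.n_vertices, bool), mesh_s2, np.zeros(mesh_s2.n_vertices)) == []

    def test_disk_area_close_to_analytic(self, mesh_s5):
        """One-third-triangle vertex areas sum close to the pi r^2 cap area."""
        r = 15.0
        disk = geodesic_disk(mesh_s5, 42, r)
        clusters = cluster_flagged(disk, mesh_s5, np.full(mesh_s5.n_vertices, -1.0))
        assert len(clusters) == 1
        assert clusters[0].surface_area_mm2 == pytest.approx(np.pi * r**2, rel=0.20)

    def test_sorted_most_hypometabolic_first(self, mesh_s4, rng):
        flagged = threshold_global_min(rng.normal(size=mesh_s4.n_vertices), 0.02)
        z = rng.normal(size=mesh_s4.n_vertices)
        clusters = cluster_flagged(flagged, mesh_s4, z)
        means = [c.mean_z for c in clusters]
        assert means == sorted(means)


@pytest.fixture(scope="module")
def study(mesh_s4, parcellation_s4):
    spec = PhantomSpec()
    config = PipelineConfig()
    controls = [
        smooth_surface_field(
            generate_control_field(mesh_s4, parcellation_s4, spec, 900 + i),
            mesh_s4,
            config.surface_smooth_fwhm_mm,
        )
        for i in range(23)
    ]
    template = build_template(controls, config.sd_floor_fraction, config.surface_smooth_fwhm_mm)
    return spec, config, template


class TestPipeline:

    def test_lesion_recovered_with_full_precision(self, mesh_s4, parcellation_s4, study):
        """The top cluster lands inside the truth mask; Dice sits at the
        rank-threshold cap (flagged 0.5% inside a 2% lesion)."""
        spec, config, template = study
        base = generate_control_field(mesh_s4, parcellation_s4, spec, 1234)
        cortex = np.flatnonzero(
            np.isin(parcellation_s4, [r for r, m in spec.region_means().items() if m > 1.0])
        )
        lesioned, truth = inject_lesion(base, mesh_s4, Lesion(int(cortex[10]), 24.0, 0.75))
        zmap, clusters = cbm_pipeline(lesioned, template, mesh_s4, config)
        top = np.zeros(mesh_s4.n_vertices, bool)
        top[clusters[0].vertex_ids] = True
        precision = (top & truth).sum() / top.sum()
        assert precision > 0.9
        assert clusters[0].mean_z < -2

    def test_deepening_lesion_does_not_decrease_dice(self, mesh_s4, parcellation_s4, study):
        from cbmpet.experiments import dice as dice_fn

        spec, config, template = study
        base = generate_control_field(mesh_s4, parcellation_s4, spec, 777)
        cortex = np.flatnonzero(
            np.isin(parcellation_s4, [r for r, m in spec.region_means().items() if m > 1.0])
        )
        center = int(cortex[5])
        scores = []
        for f in (0.9, 0.8, 0.7):
            lesioned, truth = inject_lesion(base, mesh_s4, Lesion(center, 24.0, f))
            _, clusters = cbm_pipeline(lesioned, template, mesh_s4, config)
            top = np.zeros(mesh_s4.n_vertices, bool)
            top[clusters[0].vertex_ids] = True
            scores.append(dice_fn(top, truth))
        assert scores[0] <= scores[1] + 1e-12 <= scores[2] + 2e-12

    def test_identical_input_identical_clusters(self, mesh_s4, parcellation_s4, study):
        spec, config, template = study
        field = generate_control_field(mesh_s4, parcellation_s4, spec, 55)
        _, a = cbm_pipeline(field, template, mesh_s4, config)
        _, b = cbm_pipeline(field, template, mesh_s4, config)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.vertex_ids, cb.vertex_ids)

    def test_smoothing_mismatch_rejected(self, mesh_s4, parcellation_s4, study):
        spec, config, template = study
        field = generate_control_field(mesh_s4, parcellation_s4, spec, 55)
        bad = PipelineConfig(surface_smooth_fwhm_mm=10.0)
        with pytest.raises(ConsistencyError):
            cbm_pipeline(field, template, mesh_s4, bad)

    def test_volume_input_accepted(self, mesh_s2, small_spec):
        from cbmpet.phantom import build_volume_phantom, make_parcellation

        activity, _ = build_volume_phantom(mesh_s2, small_spec)
        parc = make_parcellation(mesh_s2, 4, seed=1)
        spec = PhantomSpec(
            mesh_subdivisions=2, mesh_radius_mm=40.0, n_regions=4
        )
        config = PipelineConfig()
        controls = [
            smooth_surface_field(
                generate_control_field(mesh_s2, parc, spec, i), mesh_s2, 20.0
            )
            for i in range(3)
        ]
        template = build_template(controls, 0.05, 20.0)
        zmap, clusters = cbm_pipeline(activity, template, mesh_s2, config)
        assert len(zmap.z) == mesh_s2.n_vertices
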