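import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from glosscue.cli_io import DEFAULT_RADIUS
from glosscue.highlight_stats import contrasts, segment_gloss_layer
from glosscue.mesh_gen import TriangleMesh, make_sphere
from glosscue.renderer import (
    Camera,
    Material,
    PointLight,
    Scene,
    attenuation,
    build_scene,
    default_camera,
    default_stereo_cameras,
    fresnel_schlick,
    ggx_ndf,
    make_lights,
    place_lights,
    render,
    render_stereo,
    shade,
    smoothness_to_roughness,
)


class TestPlaceLights:
    def test_alpha_zero_all_central(self):
        pos = place_lights(0.0)
        np.testing.assert_allclose(pos, [[0, 0, -5]] * 3, atol=1e-12)

    def test_alpha_one_lateral_at_90deg(self):
        pos = place_lights(1.0)
        np.testing.assert_allclose(pos[1], [-5, 0, 0], atol=1e-9)
        np.testing.assert_allclose(pos[2], [5, 0, 0], atol=1e-9)

    def test_alpha_half_at_45deg(self):
        pos = place_lights(0.5)
        s = 5 * math.sin(math.pi / 4)
        np.testing.assert_allclose(pos[1], [-s, 0, -s], atol=1e-9)
        np.testing.assert_allclose(pos[2], [s, 0, -s], atol=1e-9)

    def test_all_lights_at_distance_five(self):
        for alpha in (0.0, 0.2, 0.7, 1.0):
            np.testing.assert_allclose(
                np.linalg.norm(place_lights(alpha), axis=1), 5.0, atol=1e-9
            )

    @pytest.mark.parametrize("alpha", [-0.1, 1.01])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValueError):
            place_lights(alpha)


class TestShadingTerms:
    def test_smoothness_to_roughness(self):
        assert smoothness_to_roughness(1.0) == 0.0
        assert smoothness_to_roughness(0.0) == 1.0
        assert smoothness_to_roughness(0.2) == pytest.approx(0.64)

    def test_smoothness_out_of_range(self):
        with pytest.raises(ValueError):
            smoothness_to_roughness(1.5)

    def test_ggx_maximal_at_one(self):
        # monotone increasing in n.h (largest at the mirror direction)
        for a in (0.04, 0.16, 0.36, 0.64):
            ndh = np.linspace(0.0, 1.0, 500)
            vals = ggx_ndf(ndh, a)
            assert np.all(np.diff(vals) > 0)
            assert vals[-1] == vals.max()

    def test_ggx_projected_integral_is_one(self):
        # hemispherical projected integral by 1D polar quadrature
        for a in (0.1, 0.3, 0.6):
            integral, _ = quad(
                lambda t: ggx_ndf(math.cos(t), a)
                * math.cos(t)
                * math.sin(t)
                * 2.0
                * math.pi,
                0.0,
                math.pi / 2,
            )
            assert integral == pytest.approx(1.0, abs=1e-3)

    def test_ggx_half_width_increases_with_roughness(self):
        def hwhm(a):
            peak = ggx_ndf(1.0, a)
            lo, hi = 0.0, 1.0  # bisection on cos(theta)
            for _ in range(60):
                mid = (lo + hi) / 2
                if ggx_ndf(mid, a) < peak / 2:
                    lo = mid
                else:
                    hi = mid
            return math.acos(hi)

        widths = [hwhm(a) for a in (0.04, 0.16, 0.36, 0.64)]
        assert all(w1 < w2 for w1, w2 in zip(widths, widths[1:]))

    def test_fresnel_schlick(self):
        assert fresnel_schlick(1.0, 0.04) == pytest.approx(0.04)
        assert fresnel_schlick(0.0, 0.04) == pytest.approx(1.0)
        assert fresnel_schlick(0.5, 0.04) == pytest.approx(0.04 + 0.96 * 0.5**5)

    def test_attenuation_zero_at_range(self):
        assert attenuation(10.0, 10.0) == 0.0

    def test_attenuation_one_at_source(self):
        assert attenuation(0.0, 10.0) == 1.0

    def test_attenuation_monotone(self):
        d = np.linspace(0.0, 10.0, 2000)
        vals = attenuation(d, 10.0)
        assert np.all(np.diff(vals) <= 0)

    def test_attenuation_invalid(self):
        with pytest.raises(ValueError):
            attenuation(1.0, 0.0)
        with pytest.raises(ValueError):
            attenuation(-1.0, 10.0)


class TestShade:
    def test_ambient_only_with_default_scene_values(self):
        # lights off: 0.6 * 0.5 = 0.3 per channel
        rgb = shade(
            point=(0, 0, -1),
            normal=(0, 0, -1),
            view_dir=(0, 0, -1),
            lights=[],
            material=Material(),
        )
        np.testing.assert_allclose(rgb, 0.3, atol=1e-12)

    def test_linearity_in_light_intensity(self):
        lights1 = [PointLight((0, 0, -5), intensity=0.7)]
        lights2 = [PointLight((0, 0, -5), intensity=1.4)]
        args = dict(
            point=(0, 0, -0.04),
            normal=(0, 0, -1),
            view_dir=(0, 0, -1),
            material=Material(smoothness=0.5),
            ambient_intensity=0.0,
        )
        r1 = shade(lights=lights1, **args)
        r2 = shade(lights=lights2, **args)
        np.testing.assert_allclose(r2, 2.0 * r1, rtol=1e-12)

    def test_mirror_configuration_maximizes_specular(self):
        # perturb the normal around the half-vector; specular term peaks
        # at the mirror configuration
        light = PointLight((5, 0, -5), intensity=1.0)
        point = np.zeros(3)
        view = np.array([0.0, 0.0, -1.0])
        l = light.position / np.linalg.norm(light.position)
        h = (l + view) / np.linalg.norm(l + view)
        mat = Material(smoothness=0.6, albedo=np.zeros(3))

        def spec(normal):
            return shade(
                point, normal, view, [light], mat, ambient_intensity=0.0
            )[0]

        base = spec(h)
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = h + 0.05 * rng.normal(size=3)
            n /= np.linalg.norm(n)
            assert spec(n) <= base + 1e-12

    def test_degenerate_view_returns_ambient_only(self):
        rgb = shade(
            point=(0, 0, 0),
            normal=(0, 0, -1),
            view_dir=(0, 0, 1),  # viewer behind the surface
            lights=[PointLight((0, 0, -5), intensity=1.5)],
            material=Material(),
        )
        np.testing.assert_allclose(rgb, 0.3, atol=1e-12)

    def test_no_negative_channels(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            rgb = shade(
                point=rng.normal(size=3) * 0.01,
                normal=n,
                view_dir=(0, 0, -1),
                lights=make_lights(0.3, 1.5),
                material=Material(smoothness=0.4),
            )
            assert np.all(rgb >= 0.0)


class TestRender:
    def test_empty_mesh_raises(self, camera64):
        mesh = TriangleMesh(
            np.zeros((0, 3)), np.zeros((0, 3), dtype=int), np.zeros((0, 3))
        )
        scene = Scene(mesh=mesh, material=Material(), lights=[])
        with pytest.raises(ValueError):
            render(scene, camera64)

    def test_all_background_image_is_valid(self, sphere_mesh):
        # camera looking away from the object
        cam = Camera(position=(0, 0, -1), target=(0, 0, -2), image_size=(32, 32))
        scene = Scene(mesh=sphere_mesh, material=Material(), lights=[])
        image = render(scene, cam)
        assert not image.foreground_mask.any()
        np.testing.assert_array_equal(image.luminance, 0.0)

    def test_foreground_is_a_disc(self, sphere_mesh, camera96):
        scene = build_scene(sphere_mesh, 0.6, 0.0, 1.5)
        image = render(scene, camera96, clip=False)
        mask = image.foreground_mask
        rows = np.where(mask.any(axis=1))[0]
        cols = np.where(mask.any(axis=0))[0]
        # a disc is symmetric and convex per row
        assert abs(len(rows) - len(cols)) <= 2
        for r in rows:
            cc = np.where(mask[r])[0]
            assert np.all(np.diff(cc) == 1)  # contiguous run

    def test_single_highlight_for_headlight_sphere(self, glossy_sphere_image):
        layer = segment_gloss_layer(glossy_sphere_image)
        assert layer.n_components == 1

    def test_ambient_only_constant_over_foreground(self, ambient_only_image):
        lum = ambient_only_image.luminance[ambient_only_image.foreground_mask]
        assert lum.var() == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(lum, 0.3, atol=1e-12)

    def test_clip_only_affects_pixels_at_ceiling(self, sphere_mesh, camera64):
        scene = build_scene(sphere_mesh, 0.6, 0.0, 1.5)
        clipped = render(scene, camera64, clip=True)
        unclipped = render(scene, camera64, clip=False)
        over = unclipped.rgb >= 1.0
        np.testing.assert_array_equal(clipped.rgb[~over], unclipped.rgb[~over])
        assert np.all(clipped.rgb[over] == 1.0)
        assert clipped.clipped_count == int(
            (over.any(axis=2) & unclipped.foreground_mask).sum()
        )
        assert unclipped.clipped_count == 0

    def test_energy_monotone_in_intensity(self, sphere_mesh, camera64):
        totals = []
        for intensity in (0.5, 1.0, 1.5):
            scene = build_scene(sphere_mesh, 0.4, 0.3, intensity)
            image = render(scene, camera64, clip=False)
            totals.append(image.luminance[image.foreground_mask].sum())
        assert totals[0] < totals[1] < totals[2]

    def test_peak_luminance_decreases_with_roughness(self, sphere_mesh, camera64):
        peaks = []
        for s in (0.2, 0.3, 0.4, 0.5, 0.6):
            scene = Scene(
                mesh=sphere_mesh,
                material=Material(smoothness=s),
                lights=[PointLight((0, 0, -5), intensity=1.5)],
            )
            image = render(scene, camera64, clip=False)
            peaks.append(image.luminance[image.foreground_mask].max())
        # roughness decreases with smoothness, so peaks increase along s
        assert all(p1 < p2 for p1, p2 in zip(peaks, peaks[1:]))

    def test_contrast_invariance_under_intensity_ambient_off(
        self, sphere_mesh, camera64
    ):
        images = [
            render(
                build_scene(sphere_mesh, 0.4, 0.32, i, ambient_intensity=0.0),
                camera64,
                clip=False,
            )
            for i in (0.5, 1.5)
        ]
        c0, c1 = (contrasts(im) for im in images)
        assert abs(c0.michelson - c1.michelson) < 1e-9
        assert abs(c0.space_avg_michelson - c1.space_avg_michelson) < 1e-9
        assert abs(c0.space_avg_whittle - c1.space_avg_whittle) < 1e-6

    def test_rigid_rotation_invariance(self, camera64):
        mesh = make_sphere(DEFAULT_RADIUS, resolution=24)
        rot = Rotation.from_euler("xyz", [0.4, 0.9, -0.3]).as_matrix()
        lights = make_lights(0.32, 1.5)
        material = Material(smoothness=0.5)

        scene = Scene(mesh=mesh, material=material, lights=lights)
        base = render(scene, camera64, clip=False)

        rmesh = TriangleMesh(
            mesh.vertices @ rot.T, mesh.faces, mesh.vertex_normals @ rot.T
        )
        rlights = [
            PointLight(rot @ l.position, intensity=l.intensity) for l in lights
        ]
        rcam = Camera(
            position=rot @ camera64.position,
            target=rot @ camera64.target,
            fov=camera64.fov,
            image_size=camera64.image_size,
            up=rot @ camera64.up,
        )
        rotated = render(
            Scene(mesh=rmesh, material=material, lights=rlights), rcam, clip=False
        )
        np.testing.assert_allclose(
            rotated.luminance, base.luminance, atol=1e-6
        )
        np.testing.assert_array_equal(
            rotated.foreground_mask, base.foreground_mask
        )


class TestStereo:
    def test_identical_cameras_give_identical_halves(self, sphere_mesh):
        cam = default_camera((48, 48))
        scene = build_scene(sphere_mesh, 0.5, 0.0, 1.5)
        image = render_stereo(scene, cam, cam)
        assert image.n_views == 2
        np.testing.assert_array_equal(
            image.luminance[:, :48], image.luminance[:, 48:]
        )

    def test_total_width_doubles(self, sphere_mesh):
        left, right = default_stereo_cameras((32, 32))
        scene = build_scene(sphere_mesh, 0.5, 0.0, 1.5)
        image = render_stereo(scene, left, right)
        assert image.luminance.shape == (32, 64)
        assert image.foreground_mask.shape == (32, 64)

    def test_swapping_cameras_mirrors_halves(self, sphere_mesh):
        left, right = default_stereo_cameras((32, 32))
        scene = build_scene(sphere_mesh, 0.5, 0.2, 1.5)
        a = render_stereo(scene, left, right)
        b = render_stereo(scene, right, left)
        np.testing.assert_array_equal(a.luminance[:, :32], b.luminance[:, 32:])
        np.testing.assert_array_equal(a.luminance[:, 32:], b.luminance[:, :32])

    def test_mismatched_sizes_raise(self, sphere_mesh):
        scene = build_scene(sphere_mesh, 0.5, 0.0, 1.5)
        with pytest.raises(ValueError):
            render_stereo(
                scene,
                default_camera((32, 32)),
                default_camera((48, 48)),
            )


class TestTypes:
    def test_camera_validation(self):
        with pytest.raises(ValueError):
            Camera(position=(0, 0, -1), fov=0.0)
        with pytest.raises(ValueError):
            Camera(position=(0, 0, -1), image_size=(0, 10))

    def test_material_validation(self):
        with pytest.raises(ValueError):
            Material(smoothness=1.2)

    def test_light_validation(self):
        with pytest.raises(ValueError):
            PointLight((0, 0, -5), range=0.0)
        with pytest.raises(ValueError):
            PointLight((0, 0, -5), intensity=-1.0)

    def test_scene_light_distance_invariant(self):
        lights = make_lights(0.4, 1.5)
        assert len(lights) == 3
        for l in lights:
            assert np.linalg.norm(l.position) == pytest.approx(5.0, abs=1e-9)
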