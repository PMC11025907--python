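"""Bowl-profile construction: ray definitions, intersection algebra,
profile/surface sampling and fabrication exports."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bowlscreen import geometry
from bowlscreen.geometry import (
    ProjectorModel,
    SingularityError,
    fly_ray,
    generate_profile,
    generate_surface,
    profile_point,
    projector_ray_line,
    surface_point,
)


class TestFlyRay:
    def test_vertical_at_half_pi(self):
        assert np.allclose(fly_ray(math.pi / 2), [0.0, 1.0])

    def test_approaches_horizontal_at_zero(self):
        assert np.allclose(fly_ray(1e-9), [1.0, 0.0], atol=1e-8)

    @given(st.floats(1e-6, math.pi - 1e-6))
    def test_unit_norm(self, alpha):
        assert abs(np.linalg.norm(fly_ray(alpha)) - 1.0) < 1e-12

    @pytest.mark.parametrize("alpha", [-0.1, 0.0, math.pi, 4.0])
    def test_domain_error(self, alpha):
        with pytest.raises(ValueError):
            fly_ray(alpha)


class TestProjectorRay:
    def test_horizontal_at_zero(self, model):
        point, direction = projector_ray_line(0.0, model)
        assert np.allclose(point, [model.d_proj, 0.0])
        assert direction[1] == 0.0

    def test_unit_slope_at_pi_r(self, model):
        _, direction = projector_ray_line(math.pi * model.r, model)
        assert np.isclose(direction[1] / direction[0], 1.0)

    def test_slope_monotone_in_alpha(self, model):
        alphas = np.linspace(0.1, 2.0, 50)
        slopes = [projector_ray_line(a, model)[1][1] for a in alphas]
        assert np.all(np.diff(slopes) > 0)


class TestProfilePoint:
    def test_matches_line_intersection_oracle(self, line_oracle):
        """The closed form equals a generic 2x2 line-line solve for 1000
        random parameter draws kept away from the denominator zero."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            alpha = rng.uniform(0.05, math.pi - 0.05)
            m = ProjectorModel(d_proj=rng.uniform(0.2, 5.0),
                               r_throw=rng.uniform(0.8, 2.5),
                               r_aspect=rng.uniform(1.0, 2.0))
            den = alpha - math.pi * m.r * math.tan(alpha)
            if abs(den) < 0.05 or abs(math.cos(alpha)) < 0.05:
                continue
            expected = line_oracle(np.zeros(2), fly_ray(alpha),
                                   *projector_ray_line(alpha, m))
            got = profile_point(alpha, m)
            assert np.linalg.norm(got - expected) <= 1e-9 * np.linalg.norm(expected)
            checked += 1

    def test_collinear_with_fly_ray(self, model):
        for alpha in np.linspace(0.3, 2.4, 25):
            x = profile_point(alpha, model)
            cross = x[0] * math.sin(alpha) - x[1] * math.cos(alpha)
            assert abs(cross) < 1e-9 * np.linalg.norm(x)

    def test_half_pi_limit(self, model):
        """At alpha = pi/2 the analytic limit is [0, -d_proj/(2 r)]; the
        regularized evaluation agrees with numeric continuation."""
        exact = profile_point(math.pi / 2, model)
        assert np.allclose(exact, [0.0, -model.d_proj / (2 * model.r)], atol=1e-12)
        for eps in (1e-6, -1e-6):
            near = profile_point(math.pi / 2 + eps, model)
            assert np.allclose(near, exact, atol=1e-4)

    def test_small_alpha_series(self, model):
        """First-order limit d/(1 - pi r) [1, 0]; x negative when pi r > 1."""
        x = profile_point(1e-5, model)
        expected = model.d_proj / (1.0 - math.pi * model.r)
        assert np.isclose(x[0], expected, rtol=1e-4)
        assert x[0] < 0  # screen opposite the projector for pi*r > 1
        assert abs(x[1]) < 1e-4 * abs(x[0])

    def test_singularity_error_names_alpha(self):
        m = ProjectorModel(r_throw=0.2, r_aspect=1.0)  # pi*r < 1: zero inside
        from scipy.optimize import brentq

        bad = brentq(lambda a: a - math.pi * m.r * math.tan(a), 0.7, 1.4)
        with pytest.raises(SingularityError, match="alpha"):
            profile_point(bad, m, tol=1e-3)


class TestSurfacePoint:
    def test_beta_zero_embeds_profile(self, model):
        for alpha in (0.4, 1.1, 2.2):
            p2 = profile_point(alpha, model)
            p3 = surface_point(alpha, 0.0, model)
            assert np.allclose(p3, [p2[0], p2[1], 0.0])

    def test_axis_distance_independent_of_beta(self, model):
        alpha = 1.0
        radii = [np.hypot(*surface_point(alpha, b, model)[1:]) for b in
                 np.linspace(0, 2 * math.pi, 17)]
        assert np.ptp(radii) < 1e-12

    def test_mirror_symmetry(self, model):
        a, b = 1.3, 0.7
        p = surface_point(a, b, model)
        q = surface_point(a, b + math.pi, model)
        assert np.allclose(q, [p[0], -p[1], -p[2]])


class TestGenerateProfile:
    def test_default_sampling_contract(self, model):
        prof = generate_profile(model, n=100)
        assert len(prof) == 100
        assert np.all(np.diff(prof.alphas) > 0)
        assert np.isclose(prof.alpha_min, math.radians(15))
        assert np.isclose(prof.alpha_max, math.radians(140))

    def test_every_sample_passes_intersection_oracle(self, model, line_oracle):
        prof = generate_profile(model, n=100)
        for alpha, point in zip(prof.alphas, prof.points):
            expected = line_oracle(np.zeros(2), fly_ray(alpha),
                                   *projector_ray_line(alpha, model))
            assert np.linalg.norm(point - expected) <= 1e-9 * np.linalg.norm(expected)

    def test_arc_length_second_order_convergence(self, model):
        def arc(n):
            pts = generate_profile(model, n=n).points
            return np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()

        d1 = abs(arc(100) - arc(200))
        d2 = abs(arc(200) - arc(400))
        assert d2 < d1 / 3.0  # ~4x shrink for O(1/n^2) discretization

    def test_singularity_inside_range_raises(self):
        m = ProjectorModel(r_throw=0.2, r_aspect=1.0)
        with pytest.raises(SingularityError):
            generate_profile(m, 0.3, 2.0, 50)


class TestExports:
    def test_svg_round_trip(self, model, tmp_path):
        prof = generate_profile(model, n=100)
        path = tmp_path / "profile.svg"
        geometry.export_profile_svg(prof, path, scale=1.0)
        back = geometry.parse_profile_svg(path)
        assert back.shape == (100, 2)
        assert np.max(np.abs(back - prof.points)) < 1e-6

    def test_stl_triangle_count(self, model, tmp_path):
        import trimesh

        surf = generate_surface(model, n_alpha=100, n_beta=90)
        assert len(surf.faces) == 2 * 99 * 89
        path = tmp_path / "surface.stl"
        geometry.export_surface_stl(surf, path)
        mesh = trimesh.load(path)
        assert len(mesh.faces) == 2 * 99 * 89

    def test_no_degenerate_triangles(self, model):
        surf = generate_surface(model, n_alpha=60, n_beta=40)
        tri = surf.vertices[surf.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        assert np.all(areas > 1e-12)


@settings(deadline=None, max_examples=30)
@given(alpha=st.floats(0.3, 2.3), d=st.floats(0.5, 3.0), rt=st.floats(1.0, 2.0))
def test_profile_point_on_both_rays(alpha, d, rt):
    """Property: X(alpha) lies on the observer ray and the projector ray."""
    m = ProjectorModel(d_proj=d, r_throw=rt, r_aspect=1.5)
    if abs(alpha - math.pi * m.r * math.tan(alpha)) < 0.05:
        return
    if abs(math.cos(alpha)) < 0.05:
        return
    x = profile_point(alpha, m)
    fr = fly_ray(alpha)
    assert abs(x[0] * fr[1] - x[1] * fr[0]) < 1e-9 * max(np.linalg.norm(x), 1.0)
    p, dvec = projector_ray_line(alpha, m)
    rel = x - p
    assert abs(rel[0] * dvec[1] - rel[1] * dvec[0]) < 1e-9 * max(np.linalg.norm(rel), 1.0)
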