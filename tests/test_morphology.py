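"""NURBS evaluation/area/fitting, logistic growth, light interception."""

import math

import numpy as np
import pytest

from edfm.errors import FitError, InvalidArgumentError
from edfm.morphology import (
    GrowthParams,
    NurbsSurface,
    beer_lambert_fraction,
    clamped_uniform_knots,
    basis_row,
    eval_surface,
    fit_leaf_surface,
    light_interception,
    logistic_size,
    make_horizontal_leaf_canopy,
    nurbs_cylinder_patch,
    nurbs_leaf_template,
    nurbs_plane,
    render_canopy_image,
    sample_scene_points,
    scale_organ_to_size,
    surface_area,
    tessellate,
    CanopyScene,
)


class TestLogisticSize:
    def test_inflection_is_half_max(self):
        p = GrowthParams(800.0, 0.15, 40.0)
        assert logistic_size(40.0, p) == pytest.approx(400.0)

    def test_asymptote(self):
        p = GrowthParams(800.0, 0.15, 40.0)
        assert logistic_size(1000.0, p) == pytest.approx(800.0)

    def test_printed_value_ten_pdt_past_midpoint(self):
        p = GrowthParams(1.0, 0.15, 40.0)
        assert logistic_size(50.0, p) == pytest.approx(0.8176, abs=1e-4)

    def test_strictly_increasing_and_bounded(self):
        p = GrowthParams(100.0, 0.2, 30.0)
        pdt = np.linspace(0, 100, 300)
        vals = logistic_size(pdt, p)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 100.0))


def _naive_basis(knots, degree, i, u):
    """Textbook recursive B-spline basis, independent of the package path."""
    if degree == 0:
        if knots[i] <= u < knots[i + 1]:
            return 1.0
        if u == knots[-1] and knots[i] < knots[i + 1] == u:  # right-end closure
            return 1.0
        return 0.0
    left = 0.0
    if knots[i + degree] > knots[i]:
        left = (u - knots[i]) / (knots[i + degree] - knots[i]) * _naive_basis(
            knots, degree - 1, i, u
        )
    right = 0.0
    if knots[i + degree + 1] > knots[i + 1]:
        right = (knots[i + degree + 1] - u) / (
            knots[i + degree + 1] - knots[i + 1]
        ) * _naive_basis(knots, degree - 1, i + 1, u)
    return left + right


class TestNurbsEvaluation:
    def test_corners_interpolate_control_points(self):
        surf = nurbs_leaf_template(0.7, 0.08)
        assert np.allclose(eval_surface(surf, 0, 0), surf.control_points[0, 0])
        assert np.allclose(eval_surface(surf, 1, 1), surf.control_points[-1, -1])

    def test_partition_of_unity(self):
        nu = 7
        knots = clamped_uniform_knots(nu, 3)
        for u in np.linspace(0, 1, 23):
            assert basis_row(knots, 3, nu, u).sum() == pytest.approx(1.0)

    def test_matches_naive_basis_summation_oracle(self):
        # non-rational surface: direct sum_ij N_i(u) M_j(v) P_ij
        rng = np.random.default_rng(0)
        cp = rng.normal(size=(6, 4, 3))
        surf = NurbsSurface(3, 2, cp)
        for u, v in [(0.17, 0.83), (0.5, 0.5), (0.99, 0.01), (0.0, 1.0)]:
            nu_b = np.array([_naive_basis(surf.knots_u, 3, i, u) for i in range(6)])
            nv_b = np.array([_naive_basis(surf.knots_v, 2, j, v) for j in range(4)])
            ref = np.einsum("i,j,ijk->k", nu_b, nv_b, cp)
            assert np.allclose(eval_surface(surf, u, v), ref, atol=1e-12)

    def test_domain_violation(self):
        surf = nurbs_plane(1, 1)
        with pytest.raises(InvalidArgumentError):
            eval_surface(surf, 1.2, 0.5)

    def test_invalid_grid_rejected(self):
        with pytest.raises(InvalidArgumentError):
            NurbsSurface(3, 2, np.zeros((3, 4, 3)))  # nu < degree_u + 1


class TestSurfaceArea:
    def test_planar_rectangle_exact(self):
        surf = nurbs_plane(5.0, 10.0)
        assert surface_area(surf) == pytest.approx(50.0, abs=1e-8)

    def test_uniform_scaling_quadratic(self):
        surf = nurbs_leaf_template(0.6, 0.07)
        a1 = surface_area(surf, 10)
        doubled = NurbsSurface(
            surf.degree_u, surf.degree_v, surf.control_points * 2.0, surf.weights
        )
        assert surface_area(doubled, 10) == pytest.approx(4 * a1, rel=1e-9)

    def test_quarter_cylinder_closed_form(self):
        surf = nurbs_cylinder_patch(1.0, 2.0, sweep_deg=90.0)
        assert surface_area(surf, 16) == pytest.approx(math.pi, abs=1e-4)

    def test_quadrature_error_decreases_with_order(self):
        surf = nurbs_cylinder_patch(1.0, 2.0, sweep_deg=90.0)
        errs = [abs(surface_area(surf, order) - math.pi) for order in (2, 4, 8, 16)]
        assert all(e2 <= e1 + 1e-15 for e1, e2 in zip(errs, errs[1:]))


class TestFitLeafSurface:
    @staticmethod
    def _grid_uv(nu_pts, nv_pts):
        u, v = np.meshgrid(np.linspace(0, 1, nu_pts), np.linspace(0, 1, nv_pts),
                           indexing="ij")
        return np.column_stack([u.ravel(), v.ravel()])

    def test_self_consistency_exact_parameterization(self):
        surf = nurbs_leaf_template(0.7, 0.08)
        uv = self._grid_uv(15, 9)
        pts = np.array([eval_surface(surf, u, v) for u, v in uv])
        fitted, resid = fit_leaf_surface(pts, params_uv=uv)
        assert resid < 1e-8
        assert np.allclose(fitted.control_points, surf.control_points, atol=1e-6)

    def test_planar_leaf_area_recovered(self):
        rng = np.random.default_rng(1)
        n = 400
        s = rng.random(n)
        t = rng.uniform(-1, 1, n)
        length, width = 0.5, 0.06
        pts = np.column_stack(
            [length * s, 0.5 * width * np.sin(np.pi * s) * t, np.zeros(n)]
        )
        uv = np.column_stack([s, (t + 1) / 2])
        fitted, _ = fit_leaf_surface(pts, params_uv=uv)
        lamina_area = width * length * 2 / np.pi  # integral of the width profile
        assert surface_area(fitted, 12) == pytest.approx(lamina_area, rel=1e-3)

    def test_refit_idempotence(self):
        surf = nurbs_leaf_template(0.6, 0.07)
        uv = self._grid_uv(12, 8)
        pts = np.array([eval_surface(surf, u, v) for u, v in uv])
        f1, _ = fit_leaf_surface(pts, params_uv=uv)
        pts2 = np.array([eval_surface(f1, u, v) for u, v in uv])
        f2, _ = fit_leaf_surface(pts2, params_uv=uv)
        assert np.allclose(f1.control_points, f2.control_points, atol=1e-6)

    def test_insufficient_points(self):
        with pytest.raises(FitError):
            fit_leaf_surface(np.random.default_rng(0).random((10, 3)))

    def test_degenerate_cloud(self):
        line = np.column_stack([np.linspace(0, 1, 60), np.zeros(60), np.zeros(60)])
        with pytest.raises(FitError):
            fit_leaf_surface(line)


class TestScaleOrgan:
    def test_identity_target(self):
        surf = nurbs_leaf_template(0.6, 0.07)
        a0 = surface_area(surf, 12)
        scaled = scale_organ_to_size(surf, "leaf", a0)
        assert surface_area(scaled, 12) == pytest.approx(a0, rel=5e-3)

    def test_double_area_scales_lengths_by_sqrt2(self):
        surf = nurbs_leaf_template(0.6, 0.07)
        a0 = surface_area(surf, 12)
        scaled = scale_organ_to_size(surf, "leaf", 2 * a0)
        ext0 = surf.control_points[..., 0].max() - surf.control_points[..., 0].min()
        ext1 = scaled.control_points[..., 0].max() - scaled.control_points[..., 0].min()
        assert ext1 / ext0 == pytest.approx(math.sqrt(2), rel=0.01)

    def test_internode_axial_exact(self):
        surf = nurbs_cylinder_patch(0.01, 0.08)
        scaled = scale_organ_to_size(surf, "internode", 0.12)
        z = scaled.control_points[..., 2]
        assert z.max() - z.min() == pytest.approx(0.12)

    def test_nonpositive_target(self):
        with pytest.raises(InvalidArgumentError):
            scale_organ_to_size(nurbs_plane(1, 1), "leaf", 0.0)


class TestLightInterception:
    def test_empty_canopy(self):
        scene = CanopyScene({}, (0, 0, 2, 2))
        r = light_interception(scene, 40.0, 1000)
        assert r.total == 0.0 and r.fraction == 0.0

    def test_single_opaque_leaf_geometric_ratio(self):
        # 1 m^2 horizontal square over a 4 m^2 footprint -> fraction 1/4
        sq = np.array([[0.5, 0.5, 1.0], [1.5, 0.5, 1.0], [1.5, 1.5, 1.0], [0.5, 1.5, 1.0]])
        tris = np.array([sq[[0, 1, 2]], sq[[0, 2, 3]]])
        scene = CanopyScene({"leaf": tris}, (0, 0, 2, 2))
        r = light_interception(scene, 10.0, 20000, seed=3)
        assert r.fraction == pytest.approx(0.25, abs=3 * r.mc_se + 1e-3)
        assert r.total == pytest.approx(10.0 * 4 * r.fraction)

    def test_energy_bound(self):
        scene = make_horizontal_leaf_canopy(2.0, seed=1)
        r = light_interception(scene, 40.0, 5000, seed=2)
        assert r.total <= 40.0 * scene.footprint_area + 1e-9

    def test_too_few_rays(self):
        with pytest.raises(InvalidArgumentError):
            light_interception(CanopyScene({}, (0, 0, 1, 1)), 1.0, 50)

    def test_occlusion_first_hit_only(self):
        # two stacked identical leaves: interception equals one leaf's share
        sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        mk = lambda z: np.array(
            [np.column_stack([sq[[0, 1, 2]], [z] * 3]),
             np.column_stack([sq[[0, 2, 3]], [z] * 3])]
        )
        scene = CanopyScene({"top": mk(2.0), "bottom": mk(1.0)}, (0, 0, 1, 1))
        r = light_interception(scene, 10.0, 1000, seed=0)
        assert r.fraction == pytest.approx(1.0)
        assert r.per_organ["bottom"] == 0.0


class TestBeerLambert:
    def test_zero_lai(self):
        assert beer_lambert_fraction(0.0, 0.5) == 0.0

    def test_printed_value(self):
        assert beer_lambert_fraction(2.0, 0.5) == pytest.approx(0.6321, abs=1e-4)

    def test_monotone(self):
        vals = [beer_lambert_fraction(l, 1.0) for l in np.linspace(0, 5, 40)]
        assert np.all(np.diff(vals) > 0)


def test_render_and_sample_consistency():
    scene = make_horizontal_leaf_canopy(1.0, seed=0)
    img = render_canopy_image(scene, resolution=32)
    assert img.shape == (32, 32, 3)
    assert 0 <= img.min() and img.max() <= 1
    pts = sample_scene_points(scene, 500, seed=1)
    assert pts.shape == (500, 3)
    # sampled points lie on the leaves' height band
    assert pts[:, 2].min() >= 0.5 - 1e-9 and pts[:, 2].max() <= 1.5 + 1e-9


def test_tessellation_area_converges_to_quadrature():
    surf = nurbs_leaf_template(0.7, 0.08)
    tris = tessellate(surf, nu=24, nv=12)
    ab = tris[:, 1] - tris[:, 0]
    ac = tris[:, 2] - tris[:, 0]
    mesh_area = 0.5 * np.linalg.norm(np.cross(ab, ac), axis=1).sum()
    assert mesh_area == pytest.approx(surface_area(surf, 12), rel=2e-3)
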