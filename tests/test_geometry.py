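"""Discrete curvature, height and radius feature checks."""

import numpy as np
import pytest
import trimesh

import tonguetopo as tt
from tonguetopo.geometry import (CurvatureField, UndefinedRatioError,
                                 compute_height, compute_radius,
                                 curvature_summary, discrete_curvatures)
from tonguetopo.meshes import PointSet
from tonguetopo.synthesis import PapillaSpec, make_papilla_heightfield


def grid_mesh(n=12, pitch=10.0, zfun=None):
    xs = np.arange(n) * pitch
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    z = zfun(xx, yy) if zfun else np.zeros_like(xx)
    v = np.column_stack([xx.ravel(), yy.ravel(), z.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    tris = np.concatenate([
        np.column_stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(),
                         idx[1:, 1:].ravel()]),
        np.column_stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(),
                         idx[:-1, 1:].ravel()])])
    return tt.TriangleMesh(v, tris)


def papilla_patch(spec, pitch=10.0, extent=1.3):
    """Mesh one papilla heightfield on a local grid."""
    f = make_papilla_heightfield(spec)
    half = spec.base_radius * extent
    n = int(2 * half / pitch) + 1
    m = grid_mesh(n, pitch, lambda x, y: f(x + spec.center[0] - half,
                                           y + spec.center[1] - half))
    return m


class TestDiscreteCurvatures:
    def test_flat_grid_zero_curvature(self):
        f = discrete_curvatures(grid_mesh())
        k = f.interior(f.gaussian)
        h = f.interior(f.mean)
        assert np.abs(k).max() < 1e-12
        assert np.abs(h).max() < 1e-10

    def test_icosahedron_angle_deficit(self):
        ico = trimesh.creation.icosahedron()
        m = tt.TriangleMesh(np.asarray(ico.vertices) * 500,
                            np.asarray(ico.faces))
        f = discrete_curvatures(m)
        assert np.allclose(f.angle_deficit, np.pi / 3, atol=1e-12)

    def test_sphere_gaussian_curvature(self):
        sp = trimesh.creation.icosphere(subdivisions=4, radius=500.0)
        m = tt.TriangleMesh(np.asarray(sp.vertices), np.asarray(sp.faces))
        f = discrete_curvatures(m)
        assert np.abs(f.gaussian * 500.0 ** 2 - 1.0).max() < 0.05
        # mean curvature of a sphere is 1/R
        assert np.abs(f.mean * 500.0 - 1.0).max() < 0.05

    def test_gauss_bonnet_sphere_and_torus(self):
        sp = trimesh.creation.icosphere(subdivisions=3, radius=300.0)
        m = tt.TriangleMesh(np.asarray(sp.vertices), np.asarray(sp.faces))
        total = discrete_curvatures(m).angle_deficit.sum()
        assert abs(total - 4 * np.pi) < 1e-9 * 4 * np.pi
        to = trimesh.creation.torus(major_radius=500.0, minor_radius=150.0)
        mt = tt.TriangleMesh(np.asarray(to.vertices), np.asarray(to.faces))
        assert abs(discrete_curvatures(mt).angle_deficit.sum()) < 1e-9

    def test_boundary_excluded(self):
        m = grid_mesh(6)
        f = discrete_curvatures(m)
        assert f.boundary.sum() == 20          # ring of a 6x6 grid
        assert len(f.interior(f.gaussian)) == 16


class TestCurvatureSummary:
    def field(self, k_values):
        k = np.asarray(k_values, dtype=float)
        n = len(k)
        return CurvatureField(k, np.abs(k), np.zeros(n), np.ones(n),
                              np.zeros(n, dtype=bool))

    def test_symmetric_counts(self):
        f = self.field([1.0] * 50 + [-1.0] * 50)
        s = curvature_summary(f)
        assert s.k_ratio == 1.0 and s.k_positive_ratio == 0.5

    def test_asymmetric_counts(self):
        s = curvature_summary(self.field([1.0] * 80 + [-1.0] * 20))
        assert np.isclose(s.k_ratio, 0.25)
        assert np.isclose(s.k_positive_ratio, 0.8)

    def test_all_positive(self):
        s = curvature_summary(self.field([1.0] * 10))
        assert s.k_ratio == 0.0 and s.k_positive_ratio == 1.0

    def test_zeros_counted_in_neither(self):
        s = curvature_summary(self.field([1.0, 0.0, 0.0, -1.0]))
        assert s.n_positive == 1 and s.n_negative == 1

    def test_undefined_when_all_zero(self):
        with pytest.raises(UndefinedRatioError):
            curvature_summary(self.field([0.0, 0.0]))


class TestComputeRadius:
    def test_initial_ball_suffices(self, rng):
        pts = PointSet(rng.normal(0, 20, (200, 3)))
        assert compute_radius(pts, (0, 0, 0)) == 100.0

    def test_stepping_arithmetic(self):
        # 100 points all at distance 205: first multiple-of-10 step >= 205
        dirs = np.random.default_rng(0).normal(size=(100, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        assert compute_radius(PointSet(dirs * 205.0), (0, 0, 0)) == 210.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 150, (300, 3))
        got = compute_radius(PointSet(pts), (0, 0, 0))
        d = np.linalg.norm(pts, axis=1)
        grid = 100.0 + 10.0 * np.arange(200)
        oracle = grid[np.argmax([(d <= g).sum() >= 0.9 * len(d)
                                 for g in grid])]
        assert got == oracle

    def test_monotone_under_far_points(self, rng):
        pts = rng.normal(0, 100, (200, 3))
        r1 = compute_radius(PointSet(pts), (0, 0, 0))
        more = np.vstack([pts, rng.normal(0, 100, (50, 3)) + 800.0])
        r2 = compute_radius(PointSet(more), (0, 0, 0))
        assert r2 >= r1


class TestComputeHeight:
    def test_plane_plus_peak(self, rng):
        base = np.column_stack([rng.random((300, 2)) * 400 - 200,
                                np.zeros(300)])
        pts = PointSet(np.vstack([base, [[0, 0, 300]]]))
        h = compute_height(pts, (0, 0, 300), 400.0, rng=0)
        assert abs(h - 300) < 1.0

    def test_point_on_plane(self, rng):
        base = np.column_stack([rng.random((300, 2)) * 400 - 200,
                                np.zeros(300)])
        h = compute_height(PointSet(base), base[0], 400.0, rng=0)
        assert h < 1e-6

    def test_hemisphere_height(self, rng):
        # hemisphere R=400 planted on a plane disk of radius 900
        th = rng.uniform(0, 2 * np.pi, 2000)
        rr = 900 * np.sqrt(rng.uniform(0, 1, 2000))
        plane = np.column_stack([rr * np.cos(th), rr * np.sin(th),
                                 np.zeros(2000)])
        u = rng.uniform(0, 1, 800)
        phi = rng.uniform(0, 2 * np.pi, 800)
        zz = 400 * u
        rho = np.sqrt(400 ** 2 - zz ** 2)
        dome = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), zz])
        pts = PointSet(np.vstack([plane, dome, [[0, 0, 400]]]))
        h = compute_height(pts, (0, 0, 400), 900.0, rng=0)
        assert 380 <= h <= 420


class TestPapillaCurvaturePatterns:
    def test_fungiform_sign_pattern(self):
        spec = PapillaSpec("fungiform", (0, 0), 439.0, 140.0, sharpness=2.5)
        m = papilla_patch(spec)
        f = discrete_curvatures(m)
        rho = np.linalg.norm(m.vertices[:, :2] - m.vertices[:, :2].mean(0),
                             axis=1)
        interior = ~f.boundary
        apex = interior & (rho < 0.15 * spec.base_radius)
        rim = interior & (rho > 0.8 * spec.base_radius) & \
            (rho < 0.98 * spec.base_radius)
        assert f.gaussian[apex].min() > 0
        assert (f.gaussian[rim] < 0).mean() >= 0.6

    def test_filiform_sharper_than_fungiform(self):
        fung = papilla_patch(
            PapillaSpec("fungiform", (0, 0), 439.0, 140.0, sharpness=2.5))
        fil = papilla_patch(
            PapillaSpec("filiform", (0, 0), 177.5, 170.0, sharpness=1.0,
                        spike_count=6), pitch=6.0)
        kf = discrete_curvatures(fung)
        kl = discrete_curvatures(fil)
        assert kl.interior(kl.gaussian).max() > kf.interior(kf.gaussian).max()

    def test_sharpness_increases_max_curvature(self):
        base = PapillaSpec("fungiform", (0, 0), 439.0, 140.0, sharpness=1.5)
        sharp = PapillaSpec("fungiform", (0, 0), 439.0, 140.0, sharpness=3.0)
        km1 = discrete_curvatures(papilla_patch(base))
        km2 = discrete_curvatures(papilla_patch(sharp))
        assert km2.interior(km2.gaussian).max() > km1.interior(km1.gaussian).max()
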