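"""Persistent-homology oracles and diagram-summary closed forms."""

import numpy as np
import pytest

from tonguetopo.meshes import DegenerateInputError, PointSet
from tonguetopo.topology import (PersistenceDiagram, TopoConfig,
                                 UndefinedFeatureError, bottleneck_amplitude,
                                 image_amplitude, landscape_amplitude,
                                 persistence_image, persistent_entropy,
                                 rips_persistence, short_bars,
                                 subsample_points, topo_feature_vector,
                                 wasserstein_amplitude)

from oracles import brute_force_rips, kruskal_mst_weights


def diagram(h0=(), h1=()):
    d = PersistenceDiagram()
    d.intervals[0] = np.asarray(h0, dtype=float).reshape(-1, 2)
    d.intervals[1] = np.asarray(h1, dtype=float).reshape(-1, 2)
    return d


class TestSubsample:
    def test_returns_all_when_small(self, rng):
        pts = PointSet(rng.random((500, 3)))
        assert len(subsample_points(pts, 1000, rng=0)) == 500

    def test_deterministic(self, rng):
        pts = PointSet(rng.random((50, 3)))
        a = subsample_points(pts, 20, rng=3)
        b = subsample_points(pts, 20, rng=3)
        assert np.array_equal(a.points, b.points)

    def test_inclusion_frequency_binomial(self, rng):
        # each point included with probability n/N
        pts = PointSet(np.arange(60.0).reshape(20, 3))
        n, trials = 8, 4000
        count0 = sum(0.0 in subsample_points(pts, n, rng=s).points[:, 0]
                     for s in range(trials))
        p = n / 20
        sd = np.sqrt(trials * p * (1 - p))
        assert abs(count0 - trials * p) < 3 * sd


class TestRipsPersistence:
    def test_two_points(self):
        d = rips_persistence(PointSet(np.array([[0.0, 0, 0], [0, 0, 5]])))
        assert np.allclose(d.dim(0), [[0, 5]])
        assert len(d.essential[0]) == 1
        assert len(d.dim(1)) == 0

    def test_single_point_degenerate(self):
        with pytest.raises(DegenerateInputError):
            rips_persistence(PointSet(np.array([[0.0, 0, 0]])))

    def test_unit_square_loop(self):
        sq = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        d = rips_persistence(PointSet(sq))
        assert np.allclose(d.dim(1), [[1.0, np.sqrt(2)]])

    def test_h0_count_matches_input_size(self, rng):
        pts = PointSet(rng.random((40, 3)))
        d = rips_persistence(pts)
        assert len(d.dim(0)) + len(d.essential[0]) == 40

    @pytest.mark.parametrize("seed", range(10))
    def test_h0_deaths_equal_mst_weights(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((rng.integers(20, 200), 3)) * 50
        d = rips_persistence(PointSet(pts), max_dim=0)
        assert np.allclose(np.sort(d.dim(0)[:, 1]), kruskal_mst_weights(pts),
                           atol=1e-10)

    @pytest.mark.parametrize("seed", range(12))
    def test_full_diagram_matches_boundary_reduction(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((int(rng.integers(5, 22)), 3)) * 10
        got = rips_persistence(PointSet(pts))
        expect = brute_force_rips(pts)
        for q in (0, 1):
            g = got.dim(q)
            g = g[np.lexsort((g[:, 1], g[:, 0]))] if len(g) else g
            assert len(g) == len(expect[q])
            if len(g):
                assert np.allclose(g, expect[q], atol=1e-12)

    def test_truncated_filtration_marks_essential(self):
        # circle of 12 points: the loop survives past a tight cap
        t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros(12)]) * 100
        d = rips_persistence(PointSet(pts), max_filtration=60.0)
        assert len(d.dim(1)) == 0
        assert len(d.essential[1]) == 1


class TestDiagramSummaries:
    def test_short_bars(self):
        d = diagram(h0=[(0, 5), (0, 12), (0, 3)])
        assert short_bars(d, 0) == 2
        assert short_bars(diagram(), 0) == 0

    def test_short_bars_filter_oracle(self, rng):
        bars = np.column_stack([np.zeros(100), rng.uniform(0, 30, 100)])
        d = diagram(h0=bars)
        expect = int(np.sum((bars[:, 1] > 0) & (bars[:, 1] <= 10)))
        assert short_bars(d, 0) == expect

    def test_entropy_closed_forms(self):
        assert persistent_entropy(diagram(h0=[(0, 7)]), 0) == 0.0
        four = diagram(h0=[(0, 2)] * 4)
        assert np.isclose(persistent_entropy(four, 0), np.log(4))
        two = diagram(h0=[(0, 1), (0, 3)])
        expect = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        assert np.isclose(persistent_entropy(two, 0), expect)
        assert np.isclose(persistent_entropy(two, 0, shannon=False), -expect)

    def test_entropy_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            persistent_entropy(diagram(), 0)

    def test_bottleneck_and_wasserstein(self):
        d = diagram(h0=[(0, 4)])
        assert np.isclose(bottleneck_amplitude(d, 0), 2 * np.sqrt(2))
        assert np.isclose(wasserstein_amplitude(d, 0, p=2), 2 * np.sqrt(2))
        d2 = diagram(h0=[(0, 3), (1, 5)])    # lengths 3 and 4
        assert np.isclose(wasserstein_amplitude(d2, 0, p=2),
                          np.sqrt(2) / 2 * 5)
        assert bottleneck_amplitude(diagram(), 0) == 0.0
        assert wasserstein_amplitude(diagram(), 0) == 0.0

    def test_bottleneck_wasserstein_inequality(self, rng):
        for _ in range(20):
            n = rng.integers(1, 30)
            bars = np.sort(rng.uniform(0, 10, (n, 2)), axis=1)
            d = diagram(h1=bars)
            assert bottleneck_amplitude(d, 1) <= \
                wasserstein_amplitude(d, 1) * np.sqrt(n) + 1e-12

    def test_landscape_tent_closed_form(self):
        d = diagram(h0=[(0, 2)])
        amp = landscape_amplitude(d, 0, grid_size=2000)
        assert abs(amp - np.sqrt(2 / 3)) / np.sqrt(2 / 3) < 0.01
        assert landscape_amplitude(diagram(), 0) == 0.0

    def test_landscape_monotone_in_bar_length(self):
        short = diagram(h0=[(0, 1), (2, 3)])
        long = diagram(h0=[(0, 2), (2, 4)])
        assert landscape_amplitude(long, 0) > landscape_amplitude(short, 0)

    def test_image_empty_and_positive(self):
        assert np.all(persistence_image(diagram(), 0) == 0)
        assert image_amplitude(diagram(), 0) == 0.0
        d = diagram(h0=[(0, 1), (0, 5), (2, 3)])
        img = persistence_image(d, 0)
        assert np.all(img >= 0) and image_amplitude(d, 0) > 0


class TestFeatureVector:
    def test_two_point_cloud(self):
        pts = PointSet(np.array([[0.0, 0, 0], [0, 0, 5]]))
        v = topo_feature_vector(pts, rng=0)
        assert v["short_bars_h0"] == 1.0          # bar of length 5
        assert v["persistent_entropy_h0"] == 0.0  # single bar
        assert all(v[k] == 0.0 for k in v if k.endswith("_h1"))

    def test_deterministic(self, rng):
        pts = PointSet(rng.random((60, 3)) * 100)
        cfg = TopoConfig(n_subsample=40)
        a = topo_feature_vector(pts, cfg, rng=4)
        b = topo_feature_vector(pts, cfg, rng=4)
        assert a == b

    def test_rigid_invariance(self, rng):
        pts = rng.random((60, 3)) * 100
        th = 0.8
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        cfg = TopoConfig(n_subsample=60, h1_subsample=None,
                         h1_max_filtration=None)
        a = topo_feature_vector(PointSet(pts), cfg, rng=2)
        b = topo_feature_vector(PointSet(pts @ rot.T + 7.0), cfg, rng=2)
        for k in a:
            assert abs(a[k] - b[k]) <= 1e-9 * max(abs(a[k]), 1.0), k

    def test_scale_equivariance(self, rng):
        pts = rng.random((50, 3)) * 100
        c = 3.0
        cfg = TopoConfig(n_subsample=50, h1_subsample=None,
                         h1_max_filtration=None)
        a = topo_feature_vector(PointSet(pts), cfg, rng=2)
        b = topo_feature_vector(PointSet(pts * c), cfg, rng=2)
        for k in ("amp_wasserstein_h0", "amp_wasserstein_h1",
                  "amp_bottleneck_h0", "amp_bottleneck_h1",
                  "amp_image_h0", "amp_image_h1"):
            if a[k] > 0:
                assert np.isclose(b[k] / a[k], c, rtol=1e-6), k
        # the trapezoid landscape norm scales with the extra sqrt(c) of the
        # stretched domain
        for k in ("amp_landscape_h0", "amp_landscape_h1"):
            if a[k] > 0:
                assert np.isclose(b[k] / a[k], c ** 1.5, rtol=1e-3), k
        for k in ("persistent_entropy_h0", "persistent_entropy_h1"):
            assert np.isclose(a[k], b[k], atol=1e-9), k
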