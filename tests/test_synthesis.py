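"""Synthetic surface and cohort generator checks."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import tonguetopo as tt
from tonguetopo.geometry import discrete_curvatures
from tonguetopo.synthesis import (EffectConfig, PapillaSpec, ParticipantProfile,
                                  PlacementError, draw_profiles,
                                  make_papilla_heightfield, papilla_spec_for,
                                  zero_effects)

from test_geometry import papilla_patch


class TestPapillaSpec:
    def test_fungiform_cannot_have_spikes(self):
        with pytest.raises(ValueError):
            PapillaSpec("fungiform", (0, 0), 400, 100, spike_count=3)

    def test_positive_dimensions_required(self):
        with pytest.raises(ValueError):
            PapillaSpec("filiform", (0, 0), -1, 100)
        with pytest.raises(ValueError):
            PapillaSpec("filiform", (0, 0), 100, 0)


class TestHeightfield:
    def test_fungiform_boundary_conditions(self):
        spec = PapillaSpec("fungiform", (0, 0), 439.0, 300.0)
        f = make_papilla_heightfield(spec)
        assert np.isclose(f(0.0, 0.0), 300.0)
        assert np.isclose(f(439.0, 0.0), 0.0)
        assert np.isclose(f(1000.0, 0.0), 0.0)

    def test_filiform_local_maxima_count(self):
        spec = PapillaSpec("filiform", (0, 0), 177.5, 170.0, spike_count=6)
        f = make_papilla_heightfield(spec)
        half = 185.0
        g = np.linspace(-half, half, 301)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        z = f(xx, yy)
        interior = z[1:-1, 1:-1]
        strict_max = np.ones_like(interior, dtype=bool)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                strict_max &= interior > z[1 + di:z.shape[0] - 1 + di,
                                           1 + dj:z.shape[1] - 1 + dj]
        assert strict_max.sum() == 7

    def test_deterministic_in_spec(self):
        spec = PapillaSpec("filiform", (3, 4), 177.5, 170.0, spike_count=5)
        f, g = make_papilla_heightfield(spec), make_papilla_heightfield(spec)
        x = np.linspace(-200, 200, 50)
        assert np.array_equal(f(x, x), g(x, x))


class TestGenerateSurface:
    def test_flat_when_nothing_planted(self):
        s = tt.generate_surface(2000, 2000, papilla_counts={}, noise_sd=0.0,
                                texture_sd=0.0, micro_density=0.0, seed=0,
                                undulation_amplitude=30.0)
        z = s.mesh.vertices[:, 2]
        assert z.max() - z.min() <= 60.0 + 1e-9   # three 10 µm waves
        assert s.papillae == []

    def test_exact_planted_counts(self):
        s = tt.generate_surface(4000, 4000,
                                papilla_counts={"fungiform": 3, "filiform": 10},
                                seed=1)
        types = [p.type for p in s.papillae]
        assert types.count("fungiform") == 3
        assert types.count("filiform") == 10

    def test_determinism_and_seed_sensitivity(self):
        a = tt.generate_surface(2500, 2500, papilla_counts={"filiform": 5},
                                seed=7)
        b = tt.generate_surface(2500, 2500, papilla_counts={"filiform": 5},
                                seed=7)
        c = tt.generate_surface(2500, 2500, papilla_counts={"filiform": 5},
                                seed=8)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert not np.allclose(
            np.sort([p.center[0] for p in a.papillae]),
            np.sort([p.center[0] for p in c.papillae]))

    def test_base_disks_disjoint(self):
        s = tt.generate_surface(4000, 4000,
                                papilla_counts={"fungiform": 3, "filiform": 10},
                                seed=2)
        for i, p in enumerate(s.papillae):
            for q in s.papillae[i + 1:]:
                d = np.linalg.norm(p.center - q.center)
                assert d > p.base_radius + q.base_radius

    def test_placement_error_when_overfull(self):
        with pytest.raises(PlacementError):
            tt.generate_surface(1500, 1500, papilla_counts={"fungiform": 20},
                                seed=0)

    def test_apex_prominence_invariant(self):
        s = tt.generate_surface(4000, 4000,
                                papilla_counts={"fungiform": 2, "filiform": 6},
                                noise_sd=0, seed=5)
        v2 = s.mesh.vertices[:, :2]
        for spec, apex in zip(s.papillae, s.apex_points):
            rho = np.linalg.norm(v2 - spec.center, axis=1)
            ring = (rho > 1.1 * spec.base_radius) & (rho < 1.5 * spec.base_radius)
            base = np.median(s.mesh.vertices[ring, 2])
            assert apex[2] - base >= 0.5 * spec.height


class TestCohort:
    def test_single_participant_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_profiles(1, EffectConfig(), rng)

    def test_invalid_effects_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_profiles(4, EffectConfig(gender_sharpness=-1.5), rng)

    def test_profiles_cover_genders_and_age_groups(self, rng):
        profs = draw_profiles(15, EffectConfig(), rng)
        genders = {p.gender for p in profs}
        groups = {p.age_group for p in profs}
        assert genders == {"F", "M"} and groups == {"young", "old"}

    def test_age_split_about_cutoff(self, rng):
        profs = draw_profiles(15, EffectConfig(), rng)
        young = sum(p.age_group == "young" for p in profs)
        assert 3 <= young <= 12
        for p in profs:
            assert (p.age_group == "young") == (p.age <= 28)

    def test_female_young_sharper_by_construction(self, rng):
        cfg = EffectConfig(participant_sharpness_sd=0.0,
                           participant_size_sd=0.0, spike_jitter=0)
        profs = draw_profiles(30, cfg, rng)
        f_young = [p.sharpness_multiplier for p in profs
                   if p.gender == "F" and p.age_group == "young"]
        m_old = [p.sharpness_multiplier for p in profs
                 if p.gender == "M" and p.age_group == "old"]
        if f_young and m_old:
            assert min(f_young) > max(m_old)

    def test_cohort_determinism(self):
        cfg = tt.CohortConfig(n_participants=2,
                              segments_per_participant={"fungiform": 2,
                                                        "filiform": 4,
                                                        "none": 1})
        s1, meta1 = tt.generate_cohort(cfg, seed=3)
        s2, meta2 = tt.generate_cohort(cfg, seed=3)
        assert meta1.equals(meta2)
        assert np.array_equal(s1[0].mesh.vertices, s2[0].mesh.vertices)


class TestEffectInjection:
    def _max_curvatures(self, profiles, n_each, seed):
        out = []
        rng = np.random.default_rng(seed)
        for prof in profiles:
            for _ in range(n_each):
                spec = papilla_spec_for("filiform", (0, 0), prof)
                spec.sharpness *= float(np.exp(rng.normal(0, 0.1)))
                f = discrete_curvatures(papilla_patch(spec, pitch=8.0))
                out.append(f.interior(f.gaussian).max())
        return np.asarray(out)

    def test_zero_effects_statistically_indistinguishable(self):
        # two-sample test on the max-curvature feature under zero effects:
        # with no injected effect the null should survive alpha=0.01 in the
        # vast majority of replicate draws
        passes = 0
        n_seeds = 12
        for s in range(n_seeds):
            f = ParticipantProfile("F1", "F", 25.0)
            m = ParticipantProfile("M1", "M", 33.0)
            a = self._max_curvatures([f], 30, seed=2 * s)
            b = self._max_curvatures([m], 30, seed=2 * s + 1)
            if mannwhitneyu(a, b).pvalue > 0.01:
                passes += 1
        assert passes >= n_seeds - 1

    def test_monotone_sharpness_effect(self):
        base = ParticipantProfile("F1", "F", 25.0, sharpness_multiplier=1.2)
        boosted = ParticipantProfile("F2", "F", 25.0, sharpness_multiplier=1.6)
        a = self._max_curvatures([base], 25, seed=1).mean()
        b = self._max_curvatures([boosted], 25, seed=1).mean()
        assert b > a
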