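"""Synthetic tongue surfaces with planted papillae and cohort generation.

The generator emulates the statistical structure of micro-scale tongue
scans: a gently undulating base sheet carrying sparse large dome-shaped
fungiform papillae (diameter ~878 µm), numerous small crown-shaped filiform
papillae (~355 µm, 100-200 per cm^2), non-papillated regions, measurement
noise along vertex normals, and participant/gender/age shape effects
(sharper papillae for female and younger synthetic participants, matching
the direction reported for real tongues).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .meshes import TriangleMesh

# -- papilla geometry defaults (µm) -----------------------------------------
FUNGIFORM_DIAMETER_UM = 878.0
FILIFORM_DIAMETER_UM = 355.0
FUNGIFORM_HEIGHT_UM = 140.0      # gentle dome: height ~16% of diameter
FILIFORM_HEIGHT_UM = 170.0       # crown height; taller relative to its base
DEFAULT_SPIKE_COUNT = 6          # sub-spikes on the filiform crown ring

# -- surface defaults ---------------------------------------------------------
DEFAULT_MESH_PITCH_UM = 15.0
DEFAULT_NOISE_SD_UM = 2.5
#: correlation length of the measurement-noise field, µm.  Surface noise on
#: reconstructed scans is smooth at the vertex scale, not independent per
#: vertex; uncorrelated displacement would dominate discrete curvature.
DEFAULT_NOISE_CORRELATION_UM = 60.0
DEFAULT_UNDULATION_AMPLITUDE_UM = 30.0
DEFAULT_UNDULATION_WAVELENGTH_UM = 4000.0
#: mid-frequency biological micro-relief between papillae (sd, µm); real
#: non-papillated tongue is not smooth, so "none" segments carry structure
DEFAULT_TEXTURE_SD_UM = 8.0
DEFAULT_TEXTURE_WAVELENGTH_UM = (400.0, 1000.0)
#: sharp non-papillar micro-features (folds, filament tips, debris) per
#: cm^2; they poison extreme-value curvature statistics in every class the
#: way real tissue irregularities do
DEFAULT_MICRO_DENSITY_PER_CM2 = 250.0
MICRO_RADIUS_RANGE_UM = (30.0, 60.0)
MICRO_HEIGHT_RANGE_UM = (15.0, 35.0)
#: per-papilla biological variability (lognormal sds): height varies much
#: more than footprint or profile shape between papillae on one tongue
PAPILLA_HEIGHT_JITTER_SD = 0.40
PAPILLA_SIZE_JITTER_SD = 0.12
PAPILLA_SHARPNESS_JITTER_SD = 0.10
#: per-papilla crown spike-count spread (uniform offset range)
PAPILLA_SPIKE_JITTER = 2
#: papillae per cm^2 (filiform density mid-range of the 100-200 estimate)
DEFAULT_DENSITY_PER_CM2 = {"fungiform": 15.0, "filiform": 150.0}

#: real-data class ratio template (fungiform : filiform : none)
CLASS_RATIO = {"fungiform": 414, "filiform": 1489, "none": 190}

#: cohort covariate template: 15 participants, 9 female, ages ~N(29.1, 3.7)
COHORT_N_FEMALE_FRACTION = 9 / 15
COHORT_AGE_MEAN = 29.1
COHORT_AGE_SD = 3.7
COHORT_AGE_RANGE = (22.0, 37.0)
AGE_CUTOFF = 29          # age_group: young iff age <= 28, old iff age >= 29


class PlacementError(RuntimeError):
    """Raised when the requested papilla density cannot be placed."""


def rng_stream(seed: int, *keys: str) -> np.random.Generator:
    """Deterministic per-stage RNG: one top-level seed, stage names hashed
    into the SeedSequence spawn key so every pipeline stage is replayable."""
    spawn = tuple(zlib.crc32(k.encode()) & 0x7FFFFFFF for k in keys)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn))


# ---------------------------------------------------------------------------
# Papilla height fields
# ---------------------------------------------------------------------------

@dataclass
class PapillaSpec:
    """Geometry of one planted papilla; ``center`` is its 2D base position."""

    type: str                       # "fungiform" | "filiform"
    center: np.ndarray              # (2,) µm
    base_radius: float              # µm
    height: float                   # µm
    sharpness: float = 1.0          # >= 0; scales peak curvature
    spike_count: int = 0            # filiform only

    def __post_init__(self) -> None:
        if self.type not in ("fungiform", "filiform"):
            raise ValueError(f"unknown papilla type: {self.type}")
        if self.base_radius <= 0 or self.height <= 0:
            raise ValueError("base_radius and height must be positive")
        if self.sharpness < 0:
            raise ValueError("sharpness must be >= 0")
        if self.type == "fungiform" and self.spike_count != 0:
            raise ValueError("fungiform papillae have spike_count = 0")
        self.center = np.asarray(self.center, dtype=np.float64)


def _bump(u: np.ndarray, k: float) -> np.ndarray:
    """Radial profile (1 - u^2)^k on u in [0, 1], 0 outside; C1 at the apex
    and (for k > 1) at the rim.  Larger k -> sharper peak."""
    u = np.clip(u, 0.0, 1.0)
    return (1.0 - u * u) ** k


def make_papilla_heightfield(spec: PapillaSpec):
    """Return ``f(x, y) -> z`` (µm) over the base disk, 0 outside.

    Fungiform: a single smooth dome with max ``spec.height`` at the center
    and 0 at the rim.  Filiform: a crown — a broad pedestal plus a central
    spike and ``spike_count`` sub-spikes on a ring, all sharper (higher peak
    curvature) than the fungiform dome.  Sharpness raises the profile
    exponent, which strictly increases apex curvature.
    """
    k = 1.0 + spec.sharpness
    r, h = spec.base_radius, spec.height
    cx, cy = spec.center

    if spec.type == "fungiform":
        def f(x, y):
            rho = np.hypot(np.asarray(x, float) - cx, np.asarray(y, float) - cy)
            return h * _bump(rho / r, k)
        return f

    # filiform crown: pedestal + central spike + ring of sub-spikes
    n_spikes = spec.spike_count
    ring_r = 0.55 * r
    spike_r = 0.25 * r
    core_r = 0.30 * r
    angles = 2.0 * np.pi * np.arange(max(n_spikes, 1)) / max(n_spikes, 1)
    spike_xy = np.column_stack([cx + ring_r * np.cos(angles),
                                cy + ring_r * np.sin(angles)])

    def f(x, y):
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        rho = np.hypot(x - cx, y - cy)
        z = 0.35 * h * _bump(rho / r, 2.0)                  # pedestal
        z = z + 0.65 * h * _bump(rho / core_r, k)           # central spike
        if n_spikes > 0:
            for sx, sy in spike_xy:
                z = z + 0.45 * h * _bump(np.hypot(x - sx, y - sy) / spike_r, k)
        return z

    return f


# ---------------------------------------------------------------------------
# Participants and cohort effects
# ---------------------------------------------------------------------------

@dataclass
class ParticipantProfile:
    """Latent shape offsets of one synthetic participant."""

    participant_id: str
    gender: str                      # "F" | "M"
    age: float                       # years
    size_multiplier: float = 1.0
    sharpness_multiplier: float = 1.0
    spike_offset: int = 0

    def __post_init__(self) -> None:
        if self.gender not in ("F", "M"):
            raise ValueError("gender must be 'F' or 'M'")
        if self.size_multiplier <= 0 or self.sharpness_multiplier <= 0:
            raise ValueError("multipliers must be positive")

    @property
    def age_group(self) -> str:
        return "young" if self.age < AGE_CUTOFF else "old"


NEUTRAL_PROFILE = ParticipantProfile("neutral", "F", 29.0)


@dataclass
class EffectConfig:
    """Cohort effect sizes injected into participant profiles.

    ``gender_sharpness`` / ``age_sharpness``: relative sharpness boost for
    female / young participants (0 disables the effect).  The participant-
    level sds give each synthetic individual a reproducible idiosyncratic
    size and sharpness signature; ``spike_jitter`` lets the filiform crown
    spike count vary by participant.
    """

    gender_sharpness: float = 0.20
    age_sharpness: float = 0.20
    participant_sharpness_sd: float = 0.08
    participant_size_sd: float = 0.08
    spike_jitter: int = 1

    def validate(self) -> None:
        if 1.0 + self.gender_sharpness <= 0 or 1.0 + self.age_sharpness <= 0:
            raise ValueError("effect multipliers must stay positive")
        if self.participant_sharpness_sd < 0 or self.participant_size_sd < 0:
            raise ValueError("participant sds must be >= 0")


def zero_effects() -> EffectConfig:
    return EffectConfig(gender_sharpness=0.0, age_sharpness=0.0,
                        participant_sharpness_sd=0.0, participant_size_sd=0.0,
                        spike_jitter=0)


def draw_profiles(n_participants: int, effects: EffectConfig,
                  rng: np.random.Generator) -> list[ParticipantProfile]:
    """Draw a cohort of participant profiles with gender/age covariates and
    idiosyncratic shape offsets.  Both genders and both age groups are
    guaranteed present (redrawn deterministically from the stream)."""
    if n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    effects.validate()
    for _ in range(1000):
        genders = np.where(rng.random(n_participants) < COHORT_N_FEMALE_FRACTION,
                           "F", "M")
        ages = np.round(np.clip(
            rng.normal(COHORT_AGE_MEAN, COHORT_AGE_SD, n_participants),
            *COHORT_AGE_RANGE))
        young = ages < AGE_CUTOFF
        if len(set(genders)) == 2 and 0 < young.sum() < n_participants:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("could not draw a mixed cohort")
    profiles = []
    for i in range(n_participants):
        sharp = float(np.exp(rng.normal(0.0, effects.participant_sharpness_sd)))
        size = float(np.exp(rng.normal(0.0, effects.participant_size_sd)))
        if genders[i] == "F":
            sharp *= 1.0 + effects.gender_sharpness
        if young[i]:
            sharp *= 1.0 + effects.age_sharpness
        spike = int(rng.integers(-effects.spike_jitter, effects.spike_jitter + 1)) \
            if effects.spike_jitter else 0
        profiles.append(ParticipantProfile(
            participant_id=f"P{i + 1:02d}", gender=str(genders[i]),
            age=float(ages[i]), size_multiplier=size,
            sharpness_multiplier=sharp, spike_offset=spike))
    return profiles


#: default profile sharpness by type.  The fungiform value concentrates the
#: dome inside its footprint (flat skirt at the rim) while keeping the apex
#: gently curved; the filiform crown spikes are narrow already.
BASE_SHARPNESS = {"fungiform": 2.5, "filiform": 1.0}


def papilla_spec_for(ptype: str, center, participant: ParticipantProfile,
                     base_sharpness: float | None = None) -> PapillaSpec:
    """Instantiate a papilla of the given type under a participant's latent
    shape offsets."""
    sharp = (BASE_SHARPNESS[ptype] if base_sharpness is None
             else base_sharpness) * participant.sharpness_multiplier
    if ptype == "fungiform":
        return PapillaSpec(
            "fungiform", center,
            base_radius=FUNGIFORM_DIAMETER_UM / 2 * participant.size_multiplier,
            height=FUNGIFORM_HEIGHT_UM * participant.size_multiplier,
            sharpness=sharp)
    return PapillaSpec(
        "filiform", center,
        base_radius=FILIFORM_DIAMETER_UM / 2 * participant.size_multiplier,
        height=FILIFORM_HEIGHT_UM * participant.size_multiplier,
        sharpness=sharp,
        spike_count=max(3, DEFAULT_SPIKE_COUNT + participant.spike_offset))


# ---------------------------------------------------------------------------
# Surface generation
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedSurface:
    """A generated mesh plus its ground-truth papilla annotations."""

    mesh: TriangleMesh
    papillae: list
    participant: ParticipantProfile
    noise_sd: float
    apex_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def apexes_of(self, ptype: str) -> np.ndarray:
        idx = [i for i, p in enumerate(self.papillae) if p.type == ptype]
        return self.apex_points[idx] if idx else np.empty((0, 3))


def _grid_mesh(width: float, depth: float, pitch: float):
    nx = max(int(round(width / pitch)) + 1, 2)
    ny = max(int(round(depth / pitch)) + 1, 2)
    xs = np.linspace(0.0, width, nx)
    ys = np.linspace(0.0, depth, ny)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    verts2d = np.column_stack([xx.ravel(), yy.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[:-1, 1:].ravel()
    d = idx[1:, 1:].ravel()
    tris = np.concatenate([np.column_stack([a, b, d]),
                           np.column_stack([a, d, c])])
    return verts2d, tris.astype(np.int64)


def _undulation(xy: np.ndarray, amplitude: float, wavelength: float,
                rng: np.random.Generator) -> np.ndarray:
    """Low-frequency base relief: three random plane waves."""
    z = np.zeros(len(xy))
    for _ in range(3):
        phi = rng.uniform(0, 2 * np.pi)
        lam = wavelength * rng.uniform(0.7, 1.4)
        psi = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(phi), np.sin(phi)])
        z += (amplitude / 3.0) * np.cos(2 * np.pi * (xy @ direction) / lam + psi)
    return z


def _vertex_normals(verts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    fn = np.cross(verts[tris[:, 1]] - verts[tris[:, 0]],
                  verts[tris[:, 2]] - verts[tris[:, 0]])
    vn = np.zeros_like(verts)
    for j in range(3):
        np.add.at(vn, tris[:, j], fn)
    nrm = np.linalg.norm(vn, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return vn / nrm


def _place_centers(radii: list[float], types: list[str], width: float,
                   depth: float, rng: np.random.Generator,
                   max_tries_factor: int = 400,
                   y_reserve: float = 0.0,
                   min_spacing: float = 0.0) -> list[np.ndarray]:
    """Dart-throwing placement with pairwise-disjoint base disks.

    ``y_reserve`` keeps the strip y < y_reserve papilla-free (a guaranteed
    non-papillated region for sampling 'none' segments)."""
    placed_xy: list[np.ndarray] = []
    placed_r: list[float] = []
    for ptype, r in zip(types, radii):
        if width < 2 * r or depth - y_reserve < 2 * r:
            raise PlacementError(f"surface too small for a {ptype} papilla")
        for _ in range(max_tries_factor):
            xy = np.array([rng.uniform(r, width - r),
                           rng.uniform(y_reserve + r, depth - r)])
            ok = all(np.linalg.norm(xy - q) > max(r + rq, min_spacing)
                     for q, rq in zip(placed_xy, placed_r))
            if ok:
                placed_xy.append(xy)
                placed_r.append(r)
                break
        else:
            raise PlacementError(
                f"could not place a {ptype} papilla without overlap; "
                f"lower the density or enlarge the surface")
    return placed_xy


def _texture(xy: np.ndarray, sd: float, wavelengths: tuple,
             rng: np.random.Generator, n_waves: int = 12) -> np.ndarray:
    """Mid-frequency micro-relief: superposition of random plane waves."""
    if sd <= 0:
        return np.zeros(len(xy))
    z = np.zeros(len(xy))
    for _ in range(n_waves):
        phi = rng.uniform(0, 2 * np.pi)
        lam = rng.uniform(*wavelengths)
        psi = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(phi), np.sin(phi)])
        z += np.cos(2 * np.pi * (xy @ direction) / lam + psi)
    return z * (sd / np.sqrt(n_waves / 2.0))


def _correlated_noise(shape: tuple, pitch: float, sd: float,
                      correlation: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth displacement-noise field on the vertex grid (sd in µm)."""
    from scipy.ndimage import gaussian_filter

    white = rng.standard_normal(shape)
    sigma = max(correlation / pitch, 1e-6)
    field = gaussian_filter(white, sigma, mode="reflect")
    s = field.std()
    if s > 0:
        field *= sd / s
    return field.ravel()


def generate_surface(width: float, depth: float,
                     papilla_density: dict | None = None,
                     participant: ParticipantProfile = NEUTRAL_PROFILE,
                     noise_sd: float = DEFAULT_NOISE_SD_UM,
                     mesh_pitch: float = DEFAULT_MESH_PITCH_UM,
                     seed: int = 0,
                     papilla_counts: dict | None = None,
                     undulation_amplitude: float = DEFAULT_UNDULATION_AMPLITUDE_UM,
                     texture_sd: float = DEFAULT_TEXTURE_SD_UM,
                     noise_correlation: float = DEFAULT_NOISE_CORRELATION_UM,
                     height_jitter_sd: float = PAPILLA_HEIGHT_JITTER_SD,
                     size_jitter_sd: float = PAPILLA_SIZE_JITTER_SD,
                     sharpness_jitter_sd: float = PAPILLA_SHARPNESS_JITTER_SD,
                     micro_density: float = DEFAULT_MICRO_DENSITY_PER_CM2,
                     none_reserve_um: float = 0.0,
                     min_spacing: float = 0.0,
                     ) -> AnnotatedSurface:
    """Generate one annotated surface of ``width`` x ``depth`` µm.

    The relief is a sum of low-frequency undulation, mid-frequency
    micro-relief texture, planted papillae (dart-thrown without base-disk
    overlap, at ``papilla_density`` per cm^2 or explicit ``papilla_counts``),
    and spatially correlated measurement noise of sd ``noise_sd`` µm applied
    along vertex normals.  Each papilla's height and radius carry lognormal
    biological jitter around the participant-level values; annotations store
    the jittered ground truth.  Deterministic given ``seed``.
    """
    if width <= 0 or depth <= 0 or mesh_pitch <= 0:
        raise ValueError("width, depth and mesh_pitch must be positive")
    density = dict(DEFAULT_DENSITY_PER_CM2 if papilla_density is None
                   else papilla_density)
    if any(v < 0 for v in density.values()):
        raise ValueError("densities must be >= 0")
    area_cm2 = (width / 1e4) * (depth / 1e4)
    if papilla_counts is None:
        papilla_counts = {t: int(round(density.get(t, 0.0) * area_cm2))
                          for t in ("fungiform", "filiform")}

    rng = rng_stream(seed, "surface")
    verts2d, tris = _grid_mesh(width, depth, mesh_pitch)
    nx = max(int(round(width / mesh_pitch)) + 1, 2)
    ny = max(int(round(depth / mesh_pitch)) + 1, 2)
    z = _undulation(verts2d, undulation_amplitude,
                    DEFAULT_UNDULATION_WAVELENGTH_UM, rng)
    z += _texture(verts2d, texture_sd, DEFAULT_TEXTURE_WAVELENGTH_UM, rng)

    # draw per-papilla jittered dimensions, then place
    types = [t for t in ("fungiform", "filiform")
             for _ in range(papilla_counts.get(t, 0))]
    protos = []
    for ptype in types:
        proto = papilla_spec_for(ptype, (0.0, 0.0), participant)
        proto = replace(
            proto,
            height=proto.height * float(np.exp(rng.normal(0, height_jitter_sd))),
            base_radius=proto.base_radius
            * float(np.exp(rng.normal(0, size_jitter_sd))),
            sharpness=proto.sharpness
            * float(np.exp(rng.normal(0, sharpness_jitter_sd))))
        if proto.type == "filiform":
            proto = replace(proto, spike_count=int(np.clip(
                proto.spike_count
                + rng.integers(-PAPILLA_SPIKE_JITTER, PAPILLA_SPIKE_JITTER + 1),
                3, 9)))
        protos.append(proto)
    centers = _place_centers([p.base_radius for p in protos], types,
                             width, depth, rng, y_reserve=none_reserve_um,
                             min_spacing=min_spacing)

    papillae = []
    for proto, center in zip(protos, centers):
        spec = replace(proto, center=np.asarray(center))
        f = make_papilla_heightfield(spec)
        # stamp only the local neighbourhood for speed
        near = (np.abs(verts2d[:, 0] - center[0]) <= spec.base_radius) & \
               (np.abs(verts2d[:, 1] - center[1]) <= spec.base_radius)
        z[near] += f(verts2d[near, 0], verts2d[near, 1])
        papillae.append(spec)

    # sharp non-papillar micro-features, kept off papilla cores so planted
    # ground truth stays intact
    n_micro = int(round(micro_density * area_cm2))
    if n_micro and len(verts2d):
        centers_arr = (np.asarray([p.center for p in papillae])
                       if papillae else np.empty((0, 2)))
        radii_arr = np.asarray([p.base_radius for p in papillae])
        placed = 0
        for _ in range(20 * n_micro):
            if placed >= n_micro:
                break
            xy = rng.uniform([0.0, 0.0], [width, depth])
            if len(centers_arr) and np.any(
                    np.linalg.norm(centers_arr - xy, axis=1) < radii_arr):
                continue
            mr = rng.uniform(*MICRO_RADIUS_RANGE_UM)
            mh = rng.uniform(*MICRO_HEIGHT_RANGE_UM)
            near = (np.abs(verts2d[:, 0] - xy[0]) <= mr) & \
                   (np.abs(verts2d[:, 1] - xy[1]) <= mr)
            if near.any():
                rho = np.hypot(verts2d[near, 0] - xy[0], verts2d[near, 1] - xy[1])
                z[near] += mh * _bump(rho / mr, 2.0)
            placed += 1

    verts = np.column_stack([verts2d, z])
    # apex = highest stamped vertex within the core of each papilla
    apex_points = []
    for spec in papillae:
        near = np.hypot(verts2d[:, 0] - spec.center[0],
                        verts2d[:, 1] - spec.center[1]) <= 0.35 * spec.base_radius
        sub = verts[near]
        apex_points.append(sub[np.argmax(sub[:, 2])] if len(sub)
                           else np.array([*spec.center, 0.0]))
    apex_arr = np.asarray(apex_points) if apex_points else np.empty((0, 3))

    if noise_sd > 0:
        normals = _vertex_normals(verts, tris)
        noise = _correlated_noise((nx, ny), mesh_pitch, noise_sd,
                                  noise_correlation, rng)
        verts = verts + normals * noise[:, None]

    return AnnotatedSurface(TriangleMesh(verts, tris), papillae, participant,
                            noise_sd, apex_arr)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def default_segment_counts(total: int = 60) -> dict:
    """Split a per-participant segment budget by the real class ratio."""
    s = sum(CLASS_RATIO.values())
    counts = {k: max(1, int(round(total * v / s))) for k, v in CLASS_RATIO.items()}
    return counts


@dataclass
class CohortConfig:
    n_participants: int = 15
    segments_per_participant: dict = field(default_factory=default_segment_counts)
    effects: EffectConfig = field(default_factory=EffectConfig)
    noise_sd: float = DEFAULT_NOISE_SD_UM
    mesh_pitch: float = DEFAULT_MESH_PITCH_UM
    #: usable area = packing_slack x total papilla base-disk area
    packing_slack: float = 2.8
    #: papilla-free strip depth reserved for "none" segments, µm
    none_reserve_um: float = 1700.0


def generate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    ) -> tuple[list[AnnotatedSurface], pd.DataFrame]:
    """Generate one annotated surface per participant plus a tidy metadata
    table (participant, gender, age, age_group).  Surface sizes are chosen
    so the requested papilla counts fit at realistic densities with spare
    papilla-free area for "none" segments."""
    cfg = config or CohortConfig()
    counts = cfg.segments_per_participant
    rng = rng_stream(seed, "cohort")
    profiles = draw_profiles(cfg.n_participants, cfg.effects, rng)

    n_fung = counts.get("fungiform", 0)
    n_fil = counts.get("filiform", 0)
    reserve = cfg.none_reserve_um if counts.get("none", 0) else 0.0
    # size by disk packing: usable area = slack x total base-disk area
    disk_area = (n_fung * np.pi * (FUNGIFORM_DIAMETER_UM / 2) ** 2
                 + n_fil * np.pi * (FILIFORM_DIAMETER_UM / 2) ** 2) * 1.6
    usable = cfg.packing_slack * disk_area
    side_um = float((reserve + np.sqrt(reserve ** 2 + 4 * usable)) / 2)
    side_um = max(side_um, 2 * FUNGIFORM_DIAMETER_UM + reserve)

    surfaces = []
    rows = []
    for i, prof in enumerate(profiles):
        surf = generate_surface(
            side_um, side_um,
            papilla_counts={"fungiform": n_fung, "filiform": n_fil},
            participant=prof, noise_sd=cfg.noise_sd, mesh_pitch=cfg.mesh_pitch,
            none_reserve_um=reserve,
            seed=int(rng_stream(seed, "cohort", f"surface{i}").integers(2 ** 31)))
        surfaces.append(surf)
        rows.append({"participant": prof.participant_id, "gender": prof.gender,
                     "age": prof.age, "age_group": prof.age_group})
    return surfaces, pd.DataFrame(rows)
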