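"""Synthetic phantoms: atlases, streamlines, scalar maps, cohorts.

Everything downstream of raw-image preprocessing is exercised against the
ground truth generated here: smooth probability blobs stand in for the
probabilistic subcortical atlas, box patches on the top of the grid stand
in for the six cortical target regions per hemisphere, streamlines are
simulated geometrically from mesh vertices to sampled target points, and
scalar maps carry configurable multiplicative group effects painted onto
known subregion voxels.

Ground-truth subregions are angular sectors around each structure centre
(azimuth in the y-z plane), so a vertex's true target and a voxel's true
subregion are computed from the same closed-form rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from subparc.errors import ConfigError, GeometryError
from subparc.naming import N_TARGETS, TARGET_IDS, TARGET_NAMES, feature_column
from subparc.streamlines import StreamlineSet
from subparc.volume import ScalarVolume

__all__ = [
    "PhantomSpec",
    "EffectSpec",
    "CohortSpec",
    "generate_atlas",
    "truth_parcellation",
    "vertex_truth",
    "target_profile",
    "generate_streamlines",
    "generate_subject_maps",
    "SubjectMaps",
    "generate_cohort",
    "simulate_features",
]

GROUPS = ("HC", "iRBD", "ePD")


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class StructureBlob:
    """One structure blob in the right hemisphere (mirrored for the left)."""

    centre: tuple[float, float, float]  # world mm, x > 0
    radius: float  # mm
    ramp: float = 1.5  # probability ramp half-width, mm


DEFAULT_BLOBS: dict[str, StructureBlob] = {
    "striatum": StructureBlob((10.0, 2.0, 0.0), 7.0),
    "snc": StructureBlob((7.0, -4.0, -6.0), 3.5),
    "vta": StructureBlob((2.5, -2.0, -6.0), 2.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic study grid.

    The grid is centred on the world origin; the hemispheres are mirror
    images in x. Cortical targets are six box patches per hemisphere on
    the top slab of the grid, labelled 1-6.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 1.0
    blobs: dict[str, StructureBlob] = field(default_factory=lambda: dict(DEFAULT_BLOBS))
    cortex_thickness: int = 3  # slices of the target slab
    cortex_gap: int = 1  # voxel gap between adjacent patches
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 16:
            raise ConfigError("grid_shape must be >= 16 voxels per axis")
        half = (np.array(self.grid_shape) - 1) / 2.0 * self.voxel_size
        for name, blob in self.blobs.items():
            c = np.abs(np.array(blob.centre))
            if np.any(c + blob.radius + blob.ramp >= half):
                raise ConfigError(f"blob {name!r} overflows the grid")
            if blob.radius < 0:
                raise ConfigError(f"blob {name!r} has negative radius")

    @property
    def affine(self) -> np.ndarray:
        A = np.diag([self.voxel_size] * 3 + [1.0])
        A[:3, 3] = -(np.array(self.grid_shape) - 1) / 2.0 * self.voxel_size
        return A

    def blob_centre(self, structure: str, hemisphere: str) -> np.ndarray:
        blob = self.blobs[structure.lower()]
        c = np.array(blob.centre, dtype=float)
        if hemisphere.upper() == "L":
            c[0] = -c[0]
        elif hemisphere.upper() != "R":
            raise ConfigError(f"unknown hemisphere {hemisphere!r}")
        return c


@dataclass(frozen=True)
class EffectSpec:
    """A group effect painted into one subregion of one structure.

    ``shift`` is multiplicative (0.05 = +5%); ``subject_sd`` is the SD of
    the log-scale between-subject intercept; ``voxel_sd`` is the relative
    SD of within-map voxel noise.
    """

    structure: str = "snc"
    subregion: str = "caudal_motor"
    metric: str = "md"  # which scalar map the shift is painted into
    kind: str = "surface"  # feature kind targeted (used by simulate_features)
    affected_groups: tuple[str, ...] = ("iRBD", "ePD")
    shift: float = 0.05
    subject_sd: float = 0.03
    voxel_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.shift <= -1.0:
            raise ConfigError("shift must be > -100%")
        if self.subject_sd < 0 or self.voxel_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.subregion != "total" and self.subregion not in TARGET_IDS:
            raise ConfigError(f"unknown subregion {self.subregion!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and covariate distributions."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 45, "iRBD": 19, "ePD": 26}
    )
    age_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 63.6, "iRBD": 67.1, "ePD": 67.4}
    )
    age_sd: float = 7.0
    male_fraction: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.45, "iRBD": 0.79, "ePD": 0.65}
    )
    sites: tuple[str, ...] = ("siteA",)
    moca_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 28.0, "iRBD": 26.6, "ePD": 26.9}
    )
    moca_sd: float = 1.5
    updrs_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.8, "iRBD": 2.9, "ePD": 33.2}
    )
    updrs_sd: dict[str, float] = field(
        default_factory=lambda: {"HC": 1.5, "iRBD": 2.5, "ePD": 14.0}
    )
    rbd_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 14.1, "iRBD": 43.0, "ePD": 25.8}
    )
    rbd_sd: float = 10.0
    duration_mean: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "iRBD": 3.4, "ePD": 1.7}
    )
    updrs_latent_rho: float = 0.0  # Spearman-ish coupling of UPDRS-III to latent severity
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ConfigError(f"group {g!r} must have n >= 1, got {n}")
        if not self.sites:
            raise ConfigError("at least one site required")


# ---------------------------------------------------------------------------
# atlas generation

def _world_grid(spec: PhantomSpec) -> np.ndarray:
    """(I, J, K, 3) world coordinates of voxel centres."""
    idx = np.indices(spec.grid_shape).astype(float)
    ijk = np.stack(idx, axis=-1)
    A = spec.affine
    return ijk @ A[:3, :3].T + A[:3, 3]


def blob_probability(spec: PhantomSpec, structure: str, hemisphere: str) -> ScalarVolume:
    """Smooth probability map of one blob: linear ramp, p=0.5 at the radius."""
    blob = spec.blobs[structure.lower()]
    centre = spec.blob_centre(structure, hemisphere)
    xyz = _world_grid(spec)
    r = np.linalg.norm(xyz - centre, axis=-1)
    if blob.radius == 0:
        p = np.zeros(spec.grid_shape)
        ijk = np.rint(
            np.linalg.inv(spec.affine)[:3, :3] @ centre
            + np.linalg.inv(spec.affine)[:3, 3]
        ).astype(int)
        p[tuple(ijk)] = 1.0
    else:
        p = np.clip((blob.radius + blob.ramp - r) / (2.0 * blob.ramp), 0.0, 1.0)
    return ScalarVolume(p, spec.affine)


def cortical_patches(spec: PhantomSpec) -> ScalarVolume:
    """Integer label volume: six disjoint box patches per hemisphere (1-6)."""
    nx, ny, nz = spec.grid_shape
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    z0 = nz - 1 - spec.cortex_thickness
    z1 = nz - 1
    cx = nx // 2
    n_pat = 6
    width = (ny - (n_pat + 1) * spec.cortex_gap) // n_pat
    if width < 1:
        raise ConfigError("grid too small for six cortical patches")
    for t in range(1, n_pat + 1):
        y0 = spec.cortex_gap + (t - 1) * (width + spec.cortex_gap)
        sl = (slice(None), slice(y0, y0 + width), slice(z0, z1))
        patch = np.zeros(spec.grid_shape, dtype=bool)
        patch[sl] = True
        # keep a gap column at the midline so hemispheres stay separable
        patch[cx, :, :] = False
        if np.any(labels[patch] != 0):
            raise ConfigError("overlapping cortical patches")
        labels[patch] = t
    return ScalarVolume(labels, spec.affine)


def generate_atlas(spec: PhantomSpec):
    """Build the phantom atlas.

    Returns
    -------
    probs : dict mapping (structure, hemisphere) -> probability ScalarVolume
    cortical_labels : ScalarVolume of int labels {0..6}
    """
    probs = {
        (s, h): blob_probability(spec, s, h)
        for s in spec.blobs
        for h in ("L", "R")
    }
    return probs, cortical_patches(spec)


# ---------------------------------------------------------------------------
# ground-truth subregions (angular sectors)

def _sector_of(points: np.ndarray, centre: np.ndarray, n_targets: int) -> np.ndarray:
    d = np.atleast_2d(points) - centre
    phi = np.mod(np.arctan2(d[:, 2], d[:, 1]), 2.0 * np.pi)
    return (phi / (2.0 * np.pi) * n_targets).astype(int) + 1


def truth_parcellation(
    spec: PhantomSpec, structure: str, hemisphere: str, inflate_mm: float = 3.0
) -> ScalarVolume:
    """Voxel ground truth: sector labels 1..T within the inflated blob."""
    structure = structure.lower()
    blob = spec.blobs[structure]
    centre = spec.blob_centre(structure, hemisphere)
    n_t = N_TARGETS[structure]
    xyz = _world_grid(spec)
    flat = xyz.reshape(-1, 3)
    r = np.linalg.norm(flat - centre, axis=1)
    sector = _sector_of(flat, centre, n_t)
    labels = np.where(r <= blob.radius + blob.ramp + inflate_mm, sector, 0)
    return ScalarVolume(labels.reshape(spec.grid_shape).astype(np.int16), spec.affine)


def vertex_truth(
    spec: PhantomSpec, structure: str, hemisphere: str, vertices: np.ndarray
) -> np.ndarray:
    """True generating target (1..T) of each mesh vertex."""
    centre = spec.blob_centre(structure, hemisphere)
    return _sector_of(vertices, centre, N_TARGETS[structure.lower()])


def effect_mask(
    spec: PhantomSpec,
    structure: str,
    hemisphere: str,
    subregion: str,
    inflate_mm: float = 3.0,
    margin_rad: float = 0.35,
) -> np.ndarray:
    """Boolean voxel mask where a subregion effect is painted.

    The mask covers the subregion's angular sector expanded by
    ``margin_rad`` on each side, so that the trilinear support of every
    surface vertex belonging to the sector lies entirely inside the mask.
    ``subregion="total"`` paints the whole inflated blob.
    """
    structure = structure.lower()
    blob = spec.blobs[structure]
    centre = spec.blob_centre(structure, hemisphere)
    xyz = _world_grid(spec).reshape(-1, 3)
    r = np.linalg.norm(xyz - centre, axis=1)
    radial = r <= blob.radius + blob.ramp + inflate_mm
    if subregion == "total":
        return radial.reshape(spec.grid_shape)
    n_t = N_TARGETS[structure]
    t = TARGET_IDS[subregion]
    if t > n_t:
        raise ConfigError(f"{subregion!r} is not a target of {structure!r}")
    width = 2.0 * np.pi / n_t
    lo, hi = (t - 1) * width - margin_rad, t * width + margin_rad
    d = xyz - centre
    phi = np.mod(np.arctan2(d[:, 2], d[:, 1]), 2.0 * np.pi)
    in_sector = ((phi >= lo) & (phi <= hi)) | (phi >= lo + 2 * np.pi) | (phi <= hi - 2 * np.pi)
    return (radial & in_sector).reshape(spec.grid_shape)


# ---------------------------------------------------------------------------
# streamlines

def target_profile(
    spec: PhantomSpec,
    structure: str,
    hemisphere: str,
    vertices: np.ndarray,
    dominant_p: float = 1.0,
    fail_p: float = 0.0,
) -> np.ndarray:
    """(V, T+1) per-vertex target distribution; last column = failure.

    Each vertex's true sector receives ``dominant_p`` of the non-failure
    mass; the remainder is spread uniformly over the other targets.
    """
    n_t = N_TARGETS[structure.lower()]
    truth = vertex_truth(spec, structure, hemisphere, vertices)
    prof = np.full((len(vertices), n_t + 1), 0.0)
    success = 1.0 - fail_p
    off = success * (1.0 - dominant_p) / max(n_t - 1, 1)
    prof[:, :n_t] = off
    prof[np.arange(len(vertices)), truth - 1] = success * dominant_p
    prof[:, n_t] = fail_p
    return prof


def generate_streamlines(
    mesh_vertices: np.ndarray,
    cortical_labels: ScalarVolume,
    profile: np.ndarray,
    n_seeds_per_vertex: int,
    seed: int,
    n_points: int = 8,
    curvature: float = 0.15,
) -> StreamlineSet:
    """Simulate streamlines from each vertex to sampled cortical targets.

    For every vertex, exactly ``n_seeds_per_vertex`` streamlines are drawn
    from its target distribution. Successful draws are curved polylines
    ending strictly inside the drawn patch; failures end in background at
    the bottom of the grid (label 0).
    """
    vertices = np.asarray(mesh_vertices, dtype=float).reshape(-1, 3)
    profile = np.asarray(profile, dtype=float)
    if n_seeds_per_vertex < 1:
        raise ConfigError("n_seeds_per_vertex must be >= 1")
    if profile.shape[0] != len(vertices):
        raise ConfigError("profile rows must match vertex count")
    if not np.allclose(profile.sum(axis=1), 1.0, atol=1e-8):
        raise ConfigError("profile rows must sum to 1")
    if not np.all(cortical_labels.contains_world(vertices)):
        raise GeometryError("vertex outside grid bounds")

    n_targets = profile.shape[1] - 1
    lab = cortical_labels.data
    vox_size = cortical_labels.voxel_size
    shape = np.array(cortical_labels.shape)
    cx = shape[0] // 2

    # per-(target, hemisphere) voxel centre pools in world mm
    pools: dict[tuple[int, str], np.ndarray] = {}
    for t in range(1, n_targets + 1):
        ijk = np.argwhere(lab == t)
        if ijk.size == 0:
            raise ConfigError(f"cortical target {t} has no voxels")
        world = cortical_labels.voxel_to_world(ijk)
        for hemi, sel in (("L", ijk[:, 0] < cx), ("R", ijk[:, 0] > cx)):
            pool = world[sel] if np.any(sel) else world
            pools[(t, hemi)] = pool

    # background endpoint slab at the bottom of the grid
    z_bottom = cortical_labels.voxel_to_world([[0, 0, 0]])[0, 2]

    rng = np.random.default_rng(seed)
    lines: list[np.ndarray] = []
    seeds: list[int] = []
    s = np.linspace(0.0, 1.0, n_points)[None, :, None]
    for v_idx, v in enumerate(vertices):
        hemi = "L" if v[0] < 0 else "R"
        draws = rng.choice(n_targets + 1, size=n_seeds_per_vertex, p=profile[v_idx])
        ends = np.empty((n_seeds_per_vertex, 3))
        for t in range(n_targets + 1):
            sel = draws == t
            k = int(sel.sum())
            if k == 0:
                continue
            if t == n_targets:  # failure
                e = np.tile(v, (k, 1))
                e[:, 2] = z_bottom
                ends[sel] = e
            else:
                pool = pools[(t + 1, hemi)]
                pick = pool[rng.integers(0, len(pool), size=k)]
                jitter = rng.uniform(-0.4, 0.4, size=(k, 3)) * vox_size
                ends[sel] = pick + jitter
        # quadratic Bezier with a small random perpendicular bow
        mid = 0.5 * (v + ends)
        chord = ends - v
        perp = np.cross(chord, rng.normal(size=(n_seeds_per_vertex, 3)))
        norm = np.linalg.norm(perp, axis=1, keepdims=True)
        norm[norm < 1e-12] = 1.0
        ctrl = mid + curvature * np.linalg.norm(chord, axis=1, keepdims=True) * perp / norm
        pts = (
            (1 - s) ** 2 * v[None, None, :]
            + 2 * (1 - s) * s * ctrl[:, None, :]
            + s**2 * ends[:, None, :]
        )
        lines.extend(pts)
        seeds.extend([v_idx] * n_seeds_per_vertex)
    return StreamlineSet(lines, np.array(seeds, dtype=int))


# ---------------------------------------------------------------------------
# subject scalar maps

@dataclass
class SubjectMaps:
    md: ScalarVolume
    fa: ScalarVolume
    n_clipped: int = 0


def generate_subject_maps(
    spec: PhantomSpec,
    effect: EffectSpec | None,
    group: str,
    subject_seed,
    baseline_md: float = 7.0e-4,
    baseline_fa: float = 0.40,
) -> SubjectMaps:
    """Simulate one subject's MD and FA volumes.

    The baseline field is uniform grey matter; the effect's subregion mask
    is shifted multiplicatively for affected groups; a log-normal subject
    intercept and relative Gaussian voxel noise are applied. Negative MD is
    clipped at zero (count reported); FA is clipped to [0, 1].
    """
    rng = np.random.default_rng(subject_seed)
    md = np.full(spec.grid_shape, baseline_md)
    fa = np.full(spec.grid_shape, baseline_fa)
    subj = 1.0
    if effect is not None:
        if effect.subject_sd > 0:
            subj = float(np.exp(effect.subject_sd * rng.standard_normal()))
        if group in effect.affected_groups and effect.shift != 0.0:
            mask_l = effect_mask(spec, effect.structure, "L", effect.subregion)
            mask_r = effect_mask(spec, effect.structure, "R", effect.subregion)
            mask = mask_l | mask_r
            target = md if effect.metric == "md" else fa
            target[mask] *= 1.0 + effect.shift
    md *= subj
    fa *= subj
    n_clipped = 0
    if effect is not None and effect.voxel_sd > 0:
        md *= 1.0 + effect.voxel_sd * rng.standard_normal(spec.grid_shape)
        fa *= 1.0 + effect.voxel_sd * rng.standard_normal(spec.grid_shape)
        n_clipped = int(np.sum(md < 0))
        np.clip(md, 0.0, None, out=md)
    np.clip(fa, 0.0, 1.0, out=fa)
    return SubjectMaps(
        ScalarVolume(md, spec.affine), ScalarVolume(fa, spec.affine), n_clipped
    )


# ---------------------------------------------------------------------------
# cohorts

def subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    """Independent per-subject stream; extending the cohort never perturbs
    existing subjects."""
    return np.random.default_rng([master_seed, subject_index])


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject with group, demographics and clinical scores.

    The ``latent`` column is a per-subject standard-normal severity score;
    ``updrs_latent_rho`` couples MDS-UPDRS-III to it so that features
    generated from the same latent correlate with the motor score.
    """
    rows = []
    idx = 0
    for group in sorted(spec.n_per_group):
        n = spec.n_per_group[group]
        for _ in range(n):
            rng = subject_rng(spec.seed, idx)
            u = rng.standard_normal()  # latent severity
            rho = spec.updrs_latent_rho
            w = rho * u + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
            rows.append(
                {
                    "subject_id": f"sub-{idx + 1:03d}",
                    "group": group,
                    "age": spec.age_mean[group] + spec.age_sd * rng.standard_normal(),
                    "sex": "M" if rng.random() < spec.male_fraction[group] else "F",
                    "site": spec.sites[rng.integers(0, len(spec.sites))],
                    "moca": float(
                        np.clip(
                            spec.moca_mean[group] + spec.moca_sd * rng.standard_normal(),
                            0,
                            30,
                        )
                    ),
                    "updrs3": float(
                        np.clip(spec.updrs_mean[group] + spec.updrs_sd[group] * w, 0, 132)
                    ),
                    "rbd_score": float(
                        np.clip(
                            spec.rbd_mean[group] + spec.rbd_sd * rng.standard_normal(),
                            0,
                            100,
                        )
                    ),
                    "duration": float(
                        max(0.0, spec.duration_mean[group] + 0.5 * rng.standard_normal())
                    ),
                    "latent": float(u),
                }
            )
            idx += 1
    return pd.DataFrame(rows)


def simulate_features(
    cohort: pd.DataFrame,
    effects: list[EffectSpec] | None = None,
    columns: list[str] | None = None,
    baseline_md: float = 7.0e-4,
    baseline_fa: float = 0.40,
    subject_sd: float = 0.03,
    latent_loading: float = 0.0,
    site_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a subject x feature table directly from the feature-level model.

    This is the distributional shortcut for the volumetric pipeline: each
    feature is baseline x exp(sd * noise), with multiplicative group shifts
    applied to the columns an effect targets. Used for statistical
    calibration runs where rebuilding volumes per subject is wasteful.
    """
    if columns is None:
        from subparc.naming import feature_columns

        columns = feature_columns()
    effects = effects or []
    rng = np.random.default_rng(seed)
    n, m = len(cohort), len(columns)
    base = np.array([baseline_md if c.endswith("_md") else baseline_fa for c in columns])
    z = rng.standard_normal((n, m))
    if latent_loading > 0:
        lat = cohort["latent"].to_numpy()[:, None]
        z = latent_loading * lat + np.sqrt(1 - latent_loading**2) * z
    values = base[None, :] * np.exp(subject_sd * z)
    if site_sd > 0:
        sites = sorted(cohort["site"].unique())
        offs = {s: np.exp(site_sd * rng.standard_normal()) for s in sites}
        values *= np.array([offs[s] for s in cohort["site"]])[:, None]
    group = cohort["group"].to_numpy()
    for eff in effects:
        col = feature_column(eff.structure, eff.subregion, eff.kind, eff.metric)
        hits = [j for j, c in enumerate(columns)
                if c == col or c in (f"{col}_l", f"{col}_r")]
        if not hits:
            raise ConfigError(f"effect column {col!r} not in feature namespace")
        affected = np.isin(group, list(eff.affected_groups))
        for j in hits:
            values[np.ix_(affected, [j])] *= 1.0 + eff.shift
    out = pd.DataFrame(values, columns=columns)
    out.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    return out.set_index("subject_id")
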