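"""Synthetic data generation: paired T1/T2 brain phantoms with planted
PVS-like tubes and ground truth, and simulated cohort tables.

The phantom emulates the anisotropic paediatric acquisition the pipeline
targets — 0.8x0.8x4.4 mm T1 and 0.4x0.4x4.4 mm T2 axial volumes — with an
ellipsoidal white-matter compartment inside a GM/CSF rim and thin straight
tubes that are hyperintense in T2 and hypointense in T1, rendered with
sub-voxel partial volume. The cohort simulator draws subject covariates and
log-normal PVS volumes with configurable multiplicative group effects, so
the downstream statistics have a known generative truth to recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image import BinaryMask, ImageVolume, RigidTransform, affine_from_spacing
from .quantify import grade_from_max_count, label_clusters_per_slice


class PlacementError(RuntimeError):
    """Could not place the requested number of non-overlapping tubes."""

    def __init__(self, requested: int, placed: int):
        super().__init__(
            f"placed only {placed} of {requested} tubes without overlap "
            "after bounded retries; reduce n_tubes, radii or separation"
        )
        self.requested = requested
        self.placed = placed


@dataclass(frozen=True)
class Tube:
    """A straight cylinder: endpoints in world mm and a radius in mm."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius_mm: float


# Tissue intensity levels in arbitrary scanner-like units. PVS is
# hyperintense in T2 and hypointense in T1, mimicking fluid-filled channels.
DEFAULT_TISSUE_INTENSITIES: dict[str, dict[str, float]] = {
    "t1": {"background": 0.0, "csf": 250.0, "gm": 750.0, "wm": 1000.0, "pvs": 350.0},
    "t2": {"background": 0.0, "csf": 2000.0, "gm": 1250.0, "wm": 1000.0, "pvs": 1800.0},
}


@dataclass
class PhantomConfig:
    """Configuration of a synthetic T1/T2 phantom.

    ``noise_sigma`` and ``bias_amplitude`` are fractions of the WM level
    (0.05 = 5% noise, 0.2 = 20% peak bias). ``misalignment`` is the rigid
    transform mapping T1-space mm points to T2-space mm points (identity =
    aligned); it is exactly the transform rigid registration of the T2
    onto the T1 should recover.
    Tubes may be supplied explicitly via ``tubes``; otherwise ``n_tubes``
    are placed at random inside the WM compartment.
    """

    grid_dims: tuple[int, int, int] = (128, 128, 24)
    spacing_t1: tuple[float, float, float] = (0.8, 0.8, 4.4)
    spacing_t2: tuple[float, float, float] = (0.4, 0.4, 4.4)
    n_tubes: int = 10
    tube_radius_mm: tuple[float, float] = (0.3, 1.2)
    tube_length_mm: tuple[float, float] = (5.0, 25.0)
    orientation_model: str = "isotropic"  # "isotropic" | "axis-aligned"
    tissue_intensities: dict = field(
        default_factory=lambda: {
            m: dict(v) for m, v in DEFAULT_TISSUE_INTENSITIES.items()
        }
    )
    bias_amplitude: float = 0.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # "gaussian" | "rician"
    misalignment: RigidTransform = field(default_factory=RigidTransform)
    min_separation_mm: float = 2.5
    tubes: list[Tube] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        self.spacing_t1 = tuple(float(s) for s in self.spacing_t1)
        self.spacing_t2 = tuple(float(s) for s in self.spacing_t2)
        self.tube_radius_mm = tuple(float(r) for r in self.tube_radius_mm)
        self.tube_length_mm = tuple(float(r) for r in self.tube_length_mm)
        if any(s <= 0 for s in self.spacing_t1 + self.spacing_t2):
            raise ValueError("spacings must be strictly positive")
        if any(d < 4 for d in self.grid_dims):
            raise ValueError("grid_dims too small")
        if self.n_tubes < 0:
            raise ValueError("n_tubes must be >= 0")
        if self.tube_radius_mm[0] <= 0 or self.tube_radius_mm[1] < self.tube_radius_mm[0]:
            raise ValueError("tube radius range must be positive and ordered")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 <= self.bias_amplitude < 1.0):
            raise ValueError("bias_amplitude must be in [0, 1)")
        if self.orientation_model not in ("isotropic", "axis-aligned", "inplane"):
            raise ValueError(f"unknown orientation_model {self.orientation_model!r}")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        wm_semi = self._wm_semi_axes()
        if self.tube_radius_mm[1] >= min(wm_semi):
            raise ValueError(
                "tube radius exceeds the WM compartment thickness: "
                f"max radius {self.tube_radius_mm[1]} mm vs WM semi-axes "
                f"{tuple(np.round(wm_semi, 1))} mm"
            )

    # brain geometry: concentric ellipsoids centred on the field of view
    def _extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_dims, float) * np.asarray(self.spacing_t1, float)

    def _center_mm(self) -> np.ndarray:
        return self._extent_mm() / 2.0

    def _brain_semi_axes(self) -> np.ndarray:
        return 0.46 * self._extent_mm()

    def _gm_semi_axes(self) -> np.ndarray:
        return 0.42 * self._extent_mm()

    def _wm_semi_axes(self) -> np.ndarray:
        return 0.34 * self._extent_mm()


@dataclass
class PhantomCase:
    """A generated phantom with its ground truth (all masks on the T1 grid)."""

    t1: ImageVolume
    t2: ImageVolume
    wm_mask_true: BinaryMask
    pvs_mask_true: BinaryMask
    per_slice_true_counts: list[int]
    transform_true: RigidTransform
    tubes: list[Tube]
    config: PhantomConfig


def _ellipsoid_level(points: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    q = (points - center) / semi
    return np.sum(q * q, axis=-1)


def _voxel_centers(shape, affine) -> np.ndarray:
    """(nx, ny, nz, 3) world-mm coordinates of voxel centres."""
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def _paint_tissue(points: np.ndarray, cfg: PhantomConfig, levels: dict) -> np.ndarray:
    """Base tissue intensity at world points: CSF rim / GM rim / WM core."""
    c = cfg._center_mm()
    out = np.full(points.shape[:-1], levels["background"], dtype=float)
    out[_ellipsoid_level(points, c, cfg._brain_semi_axes()) <= 1.0] = levels["csf"]
    out[_ellipsoid_level(points, c, cfg._gm_semi_axes()) <= 1.0] = levels["gm"]
    out[_ellipsoid_level(points, c, cfg._wm_semi_axes()) <= 1.0] = levels["wm"]
    return out


def _segment_point_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment p0-p1."""
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return np.linalg.norm(points - p0, axis=-1)
    t = np.clip(((points - p0) @ d) / L2, 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(points - proj, axis=-1)


def _segment_segment_distance(a0, a1, b0, b1) -> float:
    """Minimum distance between two 3D segments (dense sampling refinement)."""
    a0, a1, b0, b1 = (np.asarray(p, float) for p in (a0, a1, b0, b1))
    t = np.linspace(0, 1, 64)[:, None]
    d_ab = np.min(_segment_point_distance(a0 + t * (a1 - a0), b0, b1))
    d_ba = np.min(_segment_point_distance(b0 + t * (b1 - b0), a0, a1))
    return float(min(d_ab, d_ba))


def tube_fraction_volume(
    shape,
    affine,
    tubes: list[Tube],
    transform: RigidTransform | None = None,
    subsamples: tuple[int, int, int] = (4, 4, 2),
) -> np.ndarray:
    """Per-voxel fraction of the voxel inside any tube, in [0, 1].

    The fraction of each voxel's footprint inside a cylinder is evaluated
    on a deterministic sub-voxel grid (default 4x4x2 samples — finer
    in-plane where the voxels are small). ``transform``, if given, maps
    this grid's world points into the scene frame before the distance test
    (used to render the misaligned T2).
    """
    frac = np.zeros(shape, dtype=float)
    if not tubes:
        return frac
    A = np.asarray(affine, float)
    sub = np.stack(
        np.meshgrid(
            *[(np.arange(n) + 0.5) / n - 0.5 for n in subsamples], indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    n_sub = sub.shape[0]
    inv = np.linalg.inv(A)
    M = transform.matrix() if transform is not None else np.eye(4)
    for tube in tubes:
        # pull the tube into this grid's voxel index space to bound the work
        p0 = np.asarray(tube.p0, float)
        p1 = np.asarray(tube.p1, float)
        Minv = np.linalg.inv(M)
        q0 = (inv[:3, :3] @ (Minv[:3, :3] @ p0 + Minv[:3, 3]) + inv[:3, 3])
        q1 = (inv[:3, :3] @ (Minv[:3, :3] @ p1 + Minv[:3, 3]) + inv[:3, 3])
        sp = np.linalg.norm(A[:3, :3], axis=0)
        pad = tube.radius_mm / sp + 1.5
        lo = np.maximum(np.floor(np.minimum(q0, q1) - pad).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(q0, q1) + pad).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        idx = np.stack(
            np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"),
            axis=-1,
        ).astype(float)
        block = np.zeros(idx.shape[:-1], dtype=float)
        for off in sub:
            pts = (idx + off) @ A[:3, :3].T + A[:3, 3]
            pts = pts @ M[:3, :3].T + M[:3, 3]
            block += (_segment_point_distance(pts, p0, p1) <= tube.radius_mm)
        np.maximum(
            frac[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]], block / n_sub,
            out=frac[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]],
        )
    return frac


def _place_tubes(cfg: PhantomConfig, rng: np.random.Generator) -> list[Tube]:
    """Random non-overlapping tubes wholly inside the WM compartment."""
    center = cfg._center_mm()
    # safety margin keeps tubes clear of the WM boundary so that a
    # 1-voxel mask erosion cannot clip them
    margin = np.array([2.0 * cfg.spacing_t1[0], 2.0 * cfg.spacing_t1[1], 1.2 * cfg.spacing_t1[2]])
    semi = cfg._wm_semi_axes() - margin - cfg.tube_radius_mm[1]
    if np.any(semi <= 0):
        raise ValueError("WM compartment too small for the requested tubes")
    tubes: list[Tube] = []
    attempts = 0
    max_attempts = 400 * max(cfg.n_tubes, 1)
    while len(tubes) < cfg.n_tubes and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(*cfg.tube_radius_mm)
        length = rng.uniform(*cfg.tube_length_mm)
        if cfg.orientation_model == "isotropic":
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
        elif cfg.orientation_model == "inplane":
            ang = rng.uniform(0, 2 * np.pi)
            v = np.array([np.cos(ang), np.sin(ang), 0.0])
        else:  # axis-aligned mix: in-plane x / in-plane y / through-plane z
            v = np.eye(3)[rng.integers(0, 3)]
        mid = center + rng.uniform(-1, 1, size=3) * semi * 0.95
        p0 = mid - 0.5 * length * v
        p1 = mid + 0.5 * length * v
        # both endpoints (plus radius) must stay inside the safety ellipsoid
        lev = max(
            _ellipsoid_level(p0[None], center, semi)[0],
            _ellipsoid_level(p1[None], center, semi)[0],
        )
        if lev > 1.0:
            continue
        ok = True
        for t in tubes:
            dmin = _segment_segment_distance(
                p0, p1, np.asarray(t.p0), np.asarray(t.p1)
            )
            if dmin < r + t.radius_mm + cfg.min_separation_mm:
                ok = False
                break
        if ok:
            tubes.append(Tube(tuple(p0), tuple(p1), float(r)))
    if len(tubes) < cfg.n_tubes:
        raise PlacementError(cfg.n_tubes, len(tubes))
    return tubes


def _smooth_bias_field(points: np.ndarray, cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + a*g(x), peak |g| = 1."""
    ext = cfg._extent_mm()
    phases = rng.uniform(0, 2 * np.pi, size=3)
    g = (
        np.cos(2 * np.pi * points[..., 0] / (1.7 * ext[0]) + phases[0])
        * np.cos(2 * np.pi * points[..., 1] / (1.9 * ext[1]) + phases[1])
        + 0.5 * np.cos(2 * np.pi * points[..., 2] / (1.3 * ext[2]) + phases[2])
    )
    g /= max(np.abs(g).max(), 1e-12)
    return 1.0 + cfg.bias_amplitude * g


def generate_phantom(config: PhantomConfig) -> PhantomCase:
    """Render a paired T1/T2 phantom with ground-truth PVS masks.

    Deterministic for a fixed ``config.seed``. Structure is painted first
    (tissue ellipsoids, then tubes with partial volume), then the bias
    field is multiplied in and noise added. The T2 is sampled through
    ``config.misalignment``, so registration has a known truth to recover.
    The ground-truth PVS mask marks T1-grid voxels at least half inside a
    tube; per-slice true counts come from the same per-slice 8-connected
    clustering used downstream.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    t1_aff = affine_from_spacing(cfg.spacing_t1)
    t2_dims = tuple(
        int(round(d * s1 / s2))
        for d, s1, s2 in zip(cfg.grid_dims, cfg.spacing_t1, cfg.spacing_t2)
    )
    t2_aff = affine_from_spacing(cfg.spacing_t2)

    tubes = list(cfg.tubes) if cfg.tubes is not None else _place_tubes(cfg, rng)
    if len(tubes) != (cfg.n_tubes if cfg.tubes is None else len(tubes)):
        raise PlacementError(cfg.n_tubes, len(tubes))  # pragma: no cover

    lv_t1 = cfg.tissue_intensities["t1"]
    lv_t2 = cfg.tissue_intensities["t2"]

    # T1: native grid, no misalignment
    pts1 = _voxel_centers(cfg.grid_dims, t1_aff)
    t1_data = _paint_tissue(pts1, cfg, lv_t1)
    frac1 = tube_fraction_volume(cfg.grid_dims, t1_aff, tubes)
    t1_data += frac1 * (lv_t1["pvs"] - lv_t1["wm"])

    # T2: finer grid, scene sampled through the inverse misalignment (so
    # that resampling T2 through `misalignment` re-aligns it with the scene)
    pts2 = _voxel_centers(t2_dims, t2_aff)
    inv_mis = cfg.misalignment.inverse()
    M = inv_mis.matrix()
    pts2_scene = pts2 @ M[:3, :3].T + M[:3, 3]
    t2_data = _paint_tissue(pts2_scene, cfg, lv_t2)
    frac2 = tube_fraction_volume(t2_dims, t2_aff, tubes, transform=inv_mis)
    t2_data += frac2 * (lv_t2["pvs"] - lv_t2["wm"])

    if cfg.bias_amplitude > 0:
        t1_data *= _smooth_bias_field(pts1, cfg, rng)
        t2_data *= _smooth_bias_field(pts2_scene, cfg, rng)

    if cfg.noise_sigma > 0:
        s1 = cfg.noise_sigma * lv_t1["wm"]
        s2 = cfg.noise_sigma * lv_t2["wm"]
        if cfg.noise_model == "gaussian":
            t1_data = t1_data + rng.normal(0, s1, t1_data.shape)
            t2_data = t2_data + rng.normal(0, s2, t2_data.shape)
        else:  # Rician: magnitude of complex signal + noise
            t1_data = np.hypot(
                t1_data + rng.normal(0, s1, t1_data.shape),
                rng.normal(0, s1, t1_data.shape),
            )
            t2_data = np.hypot(
                t2_data + rng.normal(0, s2, t2_data.shape),
                rng.normal(0, s2, t2_data.shape),
            )

    wm_true = _ellipsoid_level(pts1, cfg._center_mm(), cfg._wm_semi_axes()) <= 1.0
    pvs_true = (frac1 >= 0.5) & wm_true
    wm_mask = BinaryMask(wm_true, t1_aff)
    pvs_mask = BinaryMask(pvs_true, t1_aff)
    counts = label_clusters_per_slice(pvs_mask, slice_axis=2).counts

    return PhantomCase(
        t1=ImageVolume(t1_data, t1_aff, "T1"),
        t2=ImageVolume(t2_data, t2_aff, "T2"),
        wm_mask_true=wm_mask,
        pvs_mask_true=pvs_mask,
        per_slice_true_counts=counts,
        transform_true=cfg.misalignment,
        tubes=tubes,
        config=cfg,
    )


def counting_phantom_config(
    n_tubes: int,
    grid_dims: tuple[int, int, int] = (128, 128, 24),
    noise_sigma: float = 0.0,
    seed: int = 0,
    tube_radius_mm: tuple[float, float] = (0.82, 0.88),
    max_span_slices: int = 4,
    min_separation_mm: float = 4.0,
) -> PhantomConfig:
    """Phantom with structurally unambiguous per-slice ground-truth counts.

    At 4.4 mm slices only through-plane PVS occupy a substantial fraction
    of any voxel, so the counting phantom plants punctate (slice-
    perpendicular) tubes, each snapped to an in-plane voxel centre and
    spanning whole slabs. With the default fluid-like T2 contrast and the
    default radius band (~0.85 mm on a 0.8 mm in-plane grid), each tube
    paints a plus-shaped 5-voxel cross per slab: the centre voxel is full
    (partial-volume fraction 1), the four edge-sharing neighbours are about
    three-quarters inside, and the diagonal corners stay below the
    half-volume criterion. Analytically, the local-difference detector
    (threshold 6% of WM, 8-neighbor ring) then selects exactly the voxels
    the half-volume ground-truth mask marks, with contrast margins several
    times the noise levels simulated — so per-slice counts, voxel counts
    and grades have an exact noise-free truth and a stable noisy one. T2
    is rendered directly on the T1 grid (registration accuracy is a
    separate, separately tested concern).
    """
    base = PhantomConfig(grid_dims=grid_dims)  # reuse geometry helpers
    rng = np.random.default_rng(seed)
    sp = np.asarray(base.spacing_t1)
    center = base._center_mm()
    # 3-voxel in-plane clearance: the tube cross plus its difference ring
    # must survive the 1-voxel mask erosion
    semi = base._wm_semi_axes() - np.array([3 * sp[0], 3 * sp[1], 0.0])
    nz = grid_dims[2]
    placed: list[Tube] = []
    xy: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_tubes and attempts < 500 * max(n_tubes, 1):
        attempts += 1
        r = float(rng.uniform(*tube_radius_mm))
        span = int(rng.integers(1, max_span_slices + 1))
        z0 = int(rng.integers(0, nz - span + 1))
        # slab boundaries in world mm (slab k covers [(k-0.5)dz, (k+0.5)dz])
        za = z0 * sp[2] - sp[2] / 2
        zb = (z0 + span) * sp[2] - sp[2] / 2
        i = int(rng.integers(4, grid_dims[0] - 4))
        j = int(rng.integers(4, grid_dims[1] - 4))
        x, y = i * sp[0], j * sp[1]
        # whole tube inside the safety ellipsoid, with one extra slab of
        # clearance in z so a 1-voxel 3D mask erosion cannot clip it
        lev = max(
            _ellipsoid_level(np.array([[x, y, za - sp[2]]]), center, semi)[0],
            _ellipsoid_level(np.array([[x, y, zb + sp[2]]]), center, semi)[0],
        )
        if lev > 1.0:
            continue
        p = np.array([x, y])
        if any(np.linalg.norm(p - q) < min_separation_mm for q in xy):
            continue
        placed.append(Tube((x, y, za), (x, y, zb), r))
        xy.append(p)
    if len(placed) < n_tubes:
        raise PlacementError(n_tubes, len(placed))
    return PhantomConfig(
        grid_dims=grid_dims,
        spacing_t2=base.spacing_t1,
        n_tubes=n_tubes,
        tubes=placed,
        tube_radius_mm=tube_radius_mm,
        orientation_model="axis-aligned",
        noise_sigma=noise_sigma,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Cohort simulation


@dataclass
class CohortSimParams:
    """Generative model of a case-control cohort table.

    PVS volume (in voxels) is log-normal with multiplicative effects:
    baseline is a non-ASD female; being male, being a young (< 4 y) ASD
    child, each ASD severity level above 1, and insomnia each multiply the
    volume. The visual grade derives from a latent max-slice count
    proportional to volume with multiplicative log-normal noise, so grade
    and volume are positively but imperfectly correlated. Default group
    sizes, sex ratios, comorbidity rates and effect sizes follow the
    case-control structure the analysis is designed to probe.
    """

    n_asd: int = 64
    n_control: int = 72
    male_fraction_asd: float = 0.672
    male_fraction_control: float = 0.556
    age_range: tuple[float, float] = (1.0, 9.0)
    severity_distribution: tuple[float, float, float] = (10 / 64, 18 / 64, 36 / 64)
    complex_asd_fraction: float = 0.844
    baseline_log_volume_mean: float = float(np.log(420.0))
    baseline_log_volume_sd: float = 0.61
    effect_male: float = 1.4
    effect_young_asd: float = 1.9
    effect_severity_per_level: float = 1.15
    effect_insomnia: float = 1.2
    comorbidity_rates: dict = field(
        default_factory=lambda: {
            "adhd": {"ASD": 0.156, "control": 0.042},
            "epilepsy": {"ASD": 0.141, "control": 0.111},
            "insomnia": {"ASD": 0.375, "control": 0.0},
            "intellectual_disability": {"ASD": 0.40, "control": 0.19},
        }
    )
    young_age_cutoff: float = 4.0
    volume_per_count: float = 25.0
    grade_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asd < 0 or self.n_control < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_asd == 0 and self.n_control == 0:
            raise ValueError("at least one group must be non-empty")
        for f in (self.male_fraction_asd, self.male_fraction_control):
            if not 0.0 <= f <= 1.0:
                raise ValueError("male fractions must be in [0, 1]")
        if abs(sum(self.severity_distribution) - 1.0) > 1e-6:
            raise ValueError("severity_distribution must sum to 1")
        for e in (
            self.effect_male,
            self.effect_young_asd,
            self.effect_severity_per_level,
            self.effect_insomnia,
        ):
            if e <= 0:
                raise ValueError("multiplicative effects must be > 0")


#: Column dictionary of the simulated cohort CSV.
COHORT_COLUMNS = {
    "subject_id": "unique subject identifier",
    "group": "'ASD' or 'NP-non-ASD'",
    "sex": "'M' or 'F'",
    "age_years": "age in years",
    "asd_type": "'essential', 'complex' or 'none'",
    "severity": "ASD support-need level 1-3; empty for non-ASD",
    "adhd": "0/1 comorbidity flag",
    "epilepsy": "0/1 comorbidity flag",
    "insomnia": "0/1 comorbidity flag (sleep disorder)",
    "intellectual_disability": "0/1 comorbidity flag",
    "pvs_volume_voxels": "WM-PVS volume in voxels",
    "pvs_max_slice_count": "max per-axial-slice PVS cluster count",
    "pvs_grade": "ordinal WM-PVS grade 0-4",
}


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate a cohort table (one row per subject); deterministic per seed."""
    p = params
    rng = np.random.default_rng(p.seed)
    rows = []
    sev_levels = np.array([1, 2, 3])
    for group, n, male_frac in (
        ("ASD", p.n_asd, p.male_fraction_asd),
        ("NP-non-ASD", p.n_control, p.male_fraction_control),
    ):
        gkey = "ASD" if group == "ASD" else "control"
        for i in range(n):
            male = rng.random() < male_frac
            age = float(np.round(rng.uniform(*p.age_range), 1))
            if group == "ASD":
                severity = int(rng.choice(sev_levels, p=p.severity_distribution))
                asd_type = "complex" if rng.random() < p.complex_asd_fraction else "essential"
            else:
                severity = None
                asd_type = "none"
            flags = {
                k: bool(rng.random() < rates[gkey])
                for k, rates in p.comorbidity_rates.items()
            }
            log_v = p.baseline_log_volume_mean + rng.normal(0, p.baseline_log_volume_sd)
            if male:
                log_v += np.log(p.effect_male)
            if group == "ASD" and age < p.young_age_cutoff:
                log_v += np.log(p.effect_young_asd)
            if group == "ASD" and severity is not None:
                log_v += (severity - 1) * np.log(p.effect_severity_per_level)
            if flags["insomnia"]:
                log_v += np.log(p.effect_insomnia)
            volume = float(np.exp(log_v))
            latent = (volume / p.volume_per_count) * float(
                np.exp(rng.normal(0, p.grade_noise_sd))
            )
            count = max(int(round(latent)), 0)
            rows.append(
                {
                    "subject_id": f"{gkey.lower()}-{i:04d}",
                    "group": group,
                    "sex": "M" if male else "F",
                    "age_years": age,
                    "asd_type": asd_type,
                    "severity": severity,
                    "adhd": int(flags["adhd"]),
                    "epilepsy": int(flags["epilepsy"]),
                    "insomnia": int(flags["insomnia"]),
                    "intellectual_disability": int(flags["intellectual_disability"]),
                    "pvs_volume_voxels": round(volume, 1),
                    "pvs_max_slice_count": count,
                    "pvs_grade": grade_from_max_count([count]),
                }
            )
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    df["severity"] = df["severity"].astype("Int64")
    return df
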