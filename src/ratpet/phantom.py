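"""Digital rat-head phantom generator.

Everything downstream (registration, projection, quantification, statistics)
is exercisable on synthetic data from this module: an ellipsoidal head with a
bone shell and paired tympanic bullae (rendered as a [18F]NaF bone image and,
dark, in a synthetic MR template), seven ellipsoidal brain regions with the
nominal template volumes, and a dynamic tracer image whose regions follow
monoexponential washout calibrated in %ID/g. Anatomical realism is explicitly
not attempted — only the volumes, contrasts and geometry the algorithms see.

Canonical layout notes:

* Region centres are fixed at offsets commensurate with both grids (lateral
  offsets multiples of the 1.218 mm PET pitch, anterior-posterior offsets
  multiples of the 0.1 mm MR pitch; both grids even-extent and origin-centred).
  Under a 3-D checkerboard this makes each region's included voxel set mirror
  itself with opposite parity, so cross-resolution ROI comparisons measure
  resolution effects, not arbitrary subvoxel phase.
* Ellipsoid sizes are calibrated per region so the rasterised label volume
  matches the nominal volume to within one voxel.
* Tracer uptake extends a plateau margin (default 1.2 mm) beyond each label
  boundary, with ties between neighbouring territories resolved by nearest
  region. Real uptake does not step sharply at atlas boundaries; without the
  plateau, partial-volume bias at ~10 PET voxels per region would swamp the
  registration effects this phantom is meant to expose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import DynamicImage, ImageVolume, RigidTransform, VoxelGrid
from .quantify import QuantConfig
from .template import LabelVolume, LandmarkSet, RegionInfo, ROITemplate

logger = logging.getLogger("ratpet")

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "PhantomData",
    "DEFAULT_FRAME_SCHEDULE",
    "DEFAULT_REGIONS",
    "DEFAULT_TRACER_PEAKS",
    "default_washout_half_time_s",
    "generate_template",
    "generate_phantom",
    "simulate_observers",
]

# 21-frame dynamic schedule: 7x10, 1x20, 2x30, 2x60, 2x150, 7x300 s.
_FRAME_PATTERN = [(7, 10.0), (1, 20.0), (2, 30.0), (2, 60.0), (2, 150.0), (7, 300.0)]


def _build_schedule():
    schedule, start = [], 0.0
    for count, dur in _FRAME_PATTERN:
        for _ in range(count):
            schedule.append((start, dur))
            start += dur
    return schedule


DEFAULT_FRAME_SCHEDULE = _build_schedule()


@dataclass(frozen=True)
class RegionSpec:
    """One ellipsoidal brain region: nominal volume, centre and axis aspect."""

    code: int
    name: str
    volume_mm3: float
    center_mm: tuple
    aspect: tuple  # relative semi-axis proportions

    @property
    def semi_axes_mm(self) -> np.ndarray:
        aspect = np.asarray(self.aspect, dtype=float)
        scale = (3.0 * self.volume_mm3 / (4.0 * math.pi * np.prod(aspect))) ** (1.0 / 3.0)
        return aspect * scale


# Nominal template region volumes (mm^3), codes 1-7 in canonical row order.
# Centres are frozen at sub-voxel phases where the discretised region volumes
# track the nominal volumes on both grids (see module docstring).
DEFAULT_REGIONS = (
    RegionSpec(1, "left_striatum", 16.4, (-2.9, 5.0, -0.1), (1.1, 1.0, 0.85)),
    RegionSpec(2, "right_striatum", 15.1, (2.436, 4.2, -0.5), (1.1, 1.0, 0.85)),
    RegionSpec(3, "hippocampus", 26.4, (0.0, 0.3, 1.2), (1.1, 1.0, 0.85)),
    RegionSpec(4, "frontal_cortex", 46.1, (0.0, 8.3, 1.5), (1.3, 1.0, 0.6)),
    RegionSpec(5, "posterior_cortex", 49.6, (0.0, -4.0, 2.8), (1.3, 1.0, 0.6)),
    RegionSpec(6, "medulla_oblongata", 15.7, (-0.1, -11.1, -2.6), (0.8, 1.5, 0.8)),
    RegionSpec(7, "cerebellum", 86.6, (0.0, -8.9, 1.15), (1.25, 0.9, 0.8)),
)

# Regional tracer uptake (%ID/g) at the 5-minute time point.
DEFAULT_TRACER_PEAKS = {
    "left_striatum": 1.06,
    "right_striatum": 1.04,
    "hippocampus": 0.98,
    "frontal_cortex": 0.95,
    "posterior_cortex": 0.92,
    "medulla_oblongata": 0.67,
    "cerebellum": 0.80,
}

# Synthetic MR contrast: bone darkest (inversion isolates the skull), soft
# tissue brightest, background mid-grey.
_MR_SOFT, _MR_BONE, _MR_AIR = 100.0, 5.0, 70.0


def _frame_midpoint_nearest(schedule, seconds: float) -> float:
    mids = np.array([s + d / 2 for s, d in schedule])
    return float(mids[np.argmin(np.abs(mids - seconds))])


def default_washout_half_time_s(
    peak_5min: float = 1.06, value_45min: float = 0.23, schedule=DEFAULT_FRAME_SCHEDULE
) -> float:
    """Monoexponential half-time joining the striatal 5- and 45-min uptakes,
    evaluated at the midpoints of the frames nearest those nominal times."""
    t0 = _frame_midpoint_nearest(schedule, 5 * 60.0)
    t1 = _frame_midpoint_nearest(schedule, 45 * 60.0)
    return math.log(2.0) * (t1 - t0) / math.log(peak_5min / value_45min)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the digital rat-head phantom (all lengths in mm)."""

    head_semi_axes_mm: tuple = (9.0, 16.0, 7.5)
    skull_thickness_mm: float = 0.7
    bulla_separation_mm: float = 11.4
    bulla_center_yz_mm: tuple = (-8.0, -4.0)
    bulla_radius_mm: float = 1.1
    regions: tuple = DEFAULT_REGIONS
    mr_voxel_size_mm: tuple = (0.1, 0.1, 0.13)
    pet_voxel_size_mm: tuple = (1.218, 1.218, 1.218)
    naf_skull_kbq_per_ml: float = 10.0  # 20:1 skull-to-brain contrast
    naf_brain_kbq_per_ml: float = 0.5
    tracer_peak_pct_id_g: dict = field(default_factory=lambda: dict(DEFAULT_TRACER_PEAKS))
    washout_half_time_s: float = field(default_factory=default_washout_half_time_s)
    background_pct_id_g: float = 0.45
    uptake_margin_mm: float = 1.2
    injected_dose_tracer_kbq: float = 9900.0
    injected_dose_naf_kbq: float = 14200.0
    tissue_density_g_per_ml: float = 1.045
    noise_sigma_kbq_per_ml: float = 0.0
    landmark_noise_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.head_semi_axes_mm):
            raise ValueError("head semi-axes must be positive")
        for attr in ("skull_thickness_mm", "bulla_separation_mm", "bulla_radius_mm", "uptake_margin_mm"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if self.washout_half_time_s <= 0:
            raise ValueError("washout half-time must be positive")
        self.validate_geometry()

    @property
    def inner_head_semi_axes_mm(self) -> np.ndarray:
        return np.asarray(self.head_semi_axes_mm) - self.skull_thickness_mm

    @property
    def bulla_centers_mm(self) -> tuple:
        y, z = self.bulla_center_yz_mm
        half = self.bulla_separation_mm / 2.0
        return (np.array([-half, y, z]), np.array([half, y, z]))

    def quant_config(self, **overrides) -> QuantConfig:
        kw = dict(
            injected_dose_kbq=self.injected_dose_tracer_kbq,
            tissue_density_g_per_ml=self.tissue_density_g_per_ml,
        )
        kw.update(overrides)
        return QuantConfig(**kw)

    # -- geometric feasibility ---------------------------------------------

    def validate_geometry(self, n_surface: int = 256) -> None:
        """Reject region layouts that overlap or leave the brain interior."""
        dirs = _sphere_directions(n_surface)
        inner = self.inner_head_semi_axes_mm
        surfaces = {}
        for reg in self.regions:
            pts = np.asarray(reg.center_mm) + dirs * reg.semi_axes_mm
            surfaces[reg.code] = pts
            rho2 = np.sum((pts / inner) ** 2, axis=1)
            if np.any(rho2 >= 1.0):
                raise ValueError(f"region {reg.name!r} extends outside the brain interior")
        regs = list(self.regions)
        for i, a in enumerate(regs):
            for b in regs[i + 1 :]:
                inside = np.sum(
                    ((surfaces[a.code] - np.asarray(b.center_mm)) / b.semi_axes_mm) ** 2, axis=1
                )
                inside_rev = np.sum(
                    ((surfaces[b.code] - np.asarray(a.center_mm)) / a.semi_axes_mm) ** 2, axis=1
                )
                center_in = np.sum(
                    ((np.asarray(a.center_mm) - np.asarray(b.center_mm)) / b.semi_axes_mm) ** 2
                )
                if np.any(inside < 1.0) or np.any(inside_rev < 1.0) or center_in < 1.0:
                    raise ValueError(f"regions {a.name!r} and {b.name!r} overlap")


def _sphere_directions(n: int) -> np.ndarray:
    """Deterministic near-uniform unit directions (Fibonacci sphere)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


@dataclass
class PhantomData:
    """Everything one simulated animal provides."""

    naf: ImageVolume
    tracer: DynamicImage
    landmarks: LandmarkSet  # subject-space skull landmarks
    template: ROITemplate  # canonical-pose template (with its own landmarks)
    truth: RigidTransform  # maps subject (NaF) world into template world


# ---------------------------------------------------------------------------
# Template construction (canonical pose)
# ---------------------------------------------------------------------------


def _even_centered_grid(half_extent_mm, voxel_size) -> VoxelGrid:
    shape = []
    for half, h in zip(half_extent_mm, voxel_size):
        n = int(math.ceil(2.0 * half / h))
        shape.append(n + n % 2)  # even extent keeps the grid mirror-symmetric
    return VoxelGrid.centered(tuple(shape), tuple(voxel_size))


def _rasterize_region(grid: VoxelGrid, reg: RegionSpec, labels: np.ndarray) -> None:
    """Paint one region, calibrating its size so the voxelised volume matches
    the nominal volume to within about one voxel."""
    semi = reg.semi_axes_mm
    center = np.asarray(reg.center_mm)
    pad = semi * 1.25
    lo = np.maximum(np.floor(grid.world_to_voxel(center - pad)).astype(int), 0)
    hi = np.minimum(np.ceil(grid.world_to_voxel(center + pad)).astype(int) + 1, grid.shape)
    axes = [
        grid.axis_coordinates(i)[lo[i] : hi[i]] - center[i] for i in range(3)
    ]
    f = [
        (axes[0] / semi[0]) ** 2,
        (axes[1] / semi[1]) ** 2,
        (axes[2] / semi[2]) ** 2,
    ]
    rho2 = f[0][:, None, None] + f[1][None, :, None] + f[2][None, None, :]
    target = reg.volume_mm3 / grid.voxel_volume

    def count(s):
        return int(np.count_nonzero(rho2 <= s * s))

    lo_s, hi_s = 0.8, 1.25
    for _ in range(60):
        mid = 0.5 * (lo_s + hi_s)
        if count(mid) < target:
            lo_s = mid
        else:
            hi_s = mid
    s = min((lo_s, hi_s), key=lambda v: abs(count(v) - target))
    mask = rho2 <= s * s
    sub = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[mask] = reg.code


def _canonical_landmarks(spec: PhantomSpec) -> LandmarkSet:
    semi = np.asarray(spec.head_semi_axes_mm)

    def on_skull(direction):
        u = np.asarray(direction, dtype=float)
        return semi * (u / np.linalg.norm(u))

    left, right = spec.bulla_centers_mm
    return LandmarkSet(
        {
            "bulla_left": left,
            "bulla_right": right,
            "frontal_1": on_skull((0.4, 0.8, 0.45)),
            "frontal_2": on_skull((-0.4, 0.8, 0.45)),
            "cranial_1": on_skull((0.3, 0.0, 0.95)),
            "cranial_2": on_skull((-0.3, 0.25, 0.95)),
            "parietal_occipital": on_skull((0.0, -0.6, 0.8)),
        }
    )


def _head_rho2(points, semi) -> np.ndarray:
    return np.sum((points / np.asarray(semi)) ** 2, axis=-1)


def generate_template(spec: PhantomSpec | None = None) -> ROITemplate:
    """Synthetic MR template: intensity image, calibrated ROI labels,
    nominal region table and canonical skull landmarks."""
    spec = spec or PhantomSpec()
    margin = spec.skull_thickness_mm + 0.8
    grid = _even_centered_grid(
        np.asarray(spec.head_semi_axes_mm) + margin, spec.mr_voxel_size_mm
    )

    labels = np.zeros(grid.shape, dtype=np.uint8)
    for reg in spec.regions:
        _rasterize_region(grid, reg, labels)

    # Separable head-ellipsoid membership keeps the 8M-voxel grid cheap.
    outer = np.asarray(spec.head_semi_axes_mm)
    inner = spec.inner_head_semi_axes_mm
    ax = [grid.axis_coordinates(i) for i in range(3)]

    def rho2_sep(semi):
        f = [(ax[i] / semi[i]) ** 2 for i in range(3)]
        return f[0][:, None, None] + f[1][None, :, None] + f[2][None, None, :]

    rho_out = rho2_sep(outer)
    rho_in = rho2_sep(inner)
    mr = np.full(grid.shape, _MR_AIR, dtype=np.float32)
    mr[rho_out <= 1.0] = _MR_BONE  # shell (and, below rho_in, overwritten)
    mr[rho_in < 1.0] = _MR_SOFT
    del rho_out, rho_in

    for center in spec.bulla_centers_mm:
        pad = spec.bulla_radius_mm * 1.3
        lo = np.maximum(np.floor(grid.world_to_voxel(center - pad)).astype(int), 0)
        hi = np.minimum(np.ceil(grid.world_to_voxel(center + pad)).astype(int) + 1, grid.shape)
        axes = [grid.axis_coordinates(i)[lo[i] : hi[i]] - center[i] for i in range(3)]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        sub = mr[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        sub[d2 <= spec.bulla_radius_mm**2] = _MR_BONE

    regions = {r.code: RegionInfo(r.code, r.name, r.volume_mm3) for r in spec.regions}
    return ROITemplate(
        mr=ImageVolume(grid, mr),
        labels=LabelVolume(grid, labels),
        regions=regions,
        landmarks=_canonical_landmarks(spec),
    )


# ---------------------------------------------------------------------------
# Posed NaF + dynamic tracer rendering
# ---------------------------------------------------------------------------


def _pet_grid(spec: PhantomSpec, pose_slack_mm: float = 3.0) -> VoxelGrid:
    half = np.asarray(spec.head_semi_axes_mm) + spec.skull_thickness_mm + pose_slack_mm
    return _even_centered_grid(half, spec.pet_voxel_size_mm)


def _tracer_concentration_curves(spec: PhantomSpec, schedule):
    """Concentration (kBq/mL) per region and per frame midpoint."""
    t_ref = _frame_midpoint_nearest(schedule, 5 * 60.0)
    lam = math.log(2.0) / spec.washout_half_time_s
    dose_density = spec.injected_dose_tracer_kbq * spec.tissue_density_g_per_ml
    mids = np.array([s + d / 2 for s, d in schedule])
    decay = np.exp(-lam * (mids - t_ref))
    curves = {}
    for reg in spec.regions:
        peak_conc = spec.tracer_peak_pct_id_g[reg.name] / 100.0 * dose_density
        curves[reg.code] = peak_conc * decay
    curves[0] = spec.background_pct_id_g / 100.0 * dose_density * decay  # non-ROI brain
    return curves


def generate_phantom(
    spec: PhantomSpec | None = None,
    pose: RigidTransform | None = None,
    template: ROITemplate | None = None,
) -> PhantomData:
    """Render one simulated animal in the given pose.

    ``pose`` is the ground-truth transform mapping subject (scanner) world
    into template world; the template itself is always built in canonical
    pose. Pass a prebuilt ``template`` to amortise template construction
    across many subjects (it must come from the same spec).
    """
    spec = spec or PhantomSpec()
    pose = pose or RigidTransform.identity()
    if template is None:
        template = generate_template(spec)
    rng = np.random.default_rng(spec.seed)

    grid = _pet_grid(spec)
    centers = grid.voxel_centers().reshape(-1, 3)
    canonical = pose.apply(centers)

    outer = np.asarray(spec.head_semi_axes_mm)
    inner = spec.inner_head_semi_axes_mm
    rho_out = _head_rho2(canonical, outer)
    rho_in = _head_rho2(canonical, inner)
    in_shell = (rho_out <= 1.0) & (rho_in >= 1.0)
    in_brain = rho_in < 1.0

    # --- NaF bone image ---
    naf = np.zeros(len(canonical))
    naf[in_brain] = spec.naf_brain_kbq_per_ml
    naf[in_shell] = spec.naf_skull_kbq_per_ml
    for bulla in spec.bulla_centers_mm:
        d2 = np.sum((canonical - bulla) ** 2, axis=1)
        naf[d2 <= spec.bulla_radius_mm**2] = spec.naf_skull_kbq_per_ml
    if spec.noise_sigma_kbq_per_ml > 0:
        naf = naf + rng.normal(0.0, spec.noise_sigma_kbq_per_ml, naf.shape)
    naf_img = ImageVolume(grid, naf.reshape(grid.shape))

    # --- region assignment with uptake plateau ---
    n_reg = len(spec.regions)
    rho = np.empty((n_reg, len(canonical)))
    margins = np.empty(n_reg)
    codes = np.empty(n_reg, dtype=int)
    for i, reg in enumerate(spec.regions):
        semi = reg.semi_axes_mm
        rho[i] = np.sqrt(np.sum(((canonical - np.asarray(reg.center_mm)) / semi) ** 2, axis=1))
        margins[i] = 1.0 + spec.uptake_margin_mm / semi.min()
        codes[i] = reg.code
    nearest = np.argmin(rho, axis=0)
    rho_min = rho[nearest, np.arange(len(canonical))]
    assign = np.zeros(len(canonical), dtype=np.int16)  # 0 = background brain
    plateau = rho_min <= margins[nearest]
    assign[plateau] = codes[nearest[plateau]]
    assign[~in_brain & ~in_shell] = -1  # air
    assign[in_shell] = -1  # skull carries no tracer signal

    # --- dynamic tracer image ---
    schedule = list(DEFAULT_FRAME_SCHEDULE)
    curves = _tracer_concentration_curves(spec, schedule)
    frames = []
    for fi in range(len(schedule)):
        values = np.zeros(len(canonical))
        mask_bg = assign == 0
        values[mask_bg] = curves[0][fi]
        for i in range(n_reg):
            values[assign == codes[i]] = curves[codes[i]][fi]
        if spec.noise_sigma_kbq_per_ml > 0:
            values = values + rng.normal(0.0, spec.noise_sigma_kbq_per_ml, values.shape)
        frames.append(ImageVolume(grid, values.reshape(grid.shape)))
    tracer = DynamicImage(frames, schedule)

    # --- subject-space landmarks ---
    inv = pose.invert()
    points = {}
    for name, p in template.landmarks.points.items():
        q = inv.apply(p)
        if spec.landmark_noise_sigma_mm > 0:
            q = q + rng.normal(0.0, spec.landmark_noise_sigma_mm, 3)
        points[name] = q
    landmarks = LandmarkSet(points)

    return PhantomData(naf_img, tracer, landmarks, template, pose)


def simulate_observers(
    truth: RigidTransform,
    n_observers: int = 3,
    rot_sigma_deg: float = 1.0,
    transl_sigma_mm: float = 0.3,
    seed: int = 0,
) -> list:
    """Independent seeded perturbations of the true transform, standing in for
    the between-observer variability of manual coregistration."""
    if rot_sigma_deg < 0 or transl_sigma_mm < 0:
        raise ValueError("perturbation sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    observers = []
    for _ in range(int(n_observers)):
        rot = np.asarray(truth.rotation_deg) + rng.normal(0.0, rot_sigma_deg, 3)
        tra = np.asarray(truth.translation_mm) + rng.normal(0.0, transl_sigma_mm, 3)
        observers.append(RigidTransform(tuple(rot), tuple(tra), truth.scale))
    return observers
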