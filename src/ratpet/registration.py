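"""Skull-based rigid coregistration of a [18F]NaF bone scan to the MR template.

[18F]NaF accumulates strongly in bone, so a NaF PET image shows the skull; in
the MR image the skull is the darkest tissue and becomes prominent when the
intensity scale is inverted. Both observations yield a skull point cloud, and
the manual alignment workflow they support is replaced here by a deterministic
three-step landmark fit (coarse centre shift, closed-form rotation, centre
refinement) scored against three alignment criteria:

(a) midsagittal symmetry — the bulla midpoint sits on the template midsagittal
    plane and each bulla lies in the correct hemisphere;
(b) tympanic bulla + frontal bone landmark RMS;
(c) cranial case + parietal/occipital articulation landmark RMS.

The fitted transform is then propagated unchanged to every frame of the
dynamic tracer image, which is the point of the two-step design: the tracer
image itself never needs anatomical contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import DynamicImage, GeometryError, ImageVolume, RigidTransform, VoxelGrid, apply_transform, fit_rigid_landmarks
from .template import BULLA_LEFT, BULLA_RIGHT, LandmarkSet, ROITemplate

logger = logging.getLogger("ratpet")

__all__ = [
    "SkullSurface",
    "AlignmentReport",
    "AlignmentThresholds",
    "extract_skull_surface",
    "alignment_report",
    "register_naf_to_template",
    "propagate_transform",
]


@dataclass
class SkullSurface:
    """World point cloud (mm) sampled on the skull."""

    points: np.ndarray  # (N, 3)
    source: str  # "naf_threshold" or "mr_inverted"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("skull surface must be an (N, 3) point array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("skull surface points must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class AlignmentThresholds:
    """Pass/fail limits (mm), all well below the scanner FWHM of 2.3-3.4 mm."""

    midsagittal_mm: float = 0.5
    bulla_frontal_rms_mm: float = 1.0
    cranial_rms_mm: float = 1.0


@dataclass
class AlignmentReport:
    """Quantified counterparts of the three visual alignment criteria."""

    criterion_a: float  # midsagittal-plane offset of the bulla midpoint, mm
    criterion_b: float  # bulla + frontal-bone landmark RMS, mm
    criterion_c: float  # cranial-case + parietal/occipital landmark RMS, mm
    pass_a: bool
    pass_b: bool
    pass_c: bool
    laterality_correct: bool
    thresholds: AlignmentThresholds = field(default_factory=AlignmentThresholds)
    surface_rms_mm: float | None = None  # skull point-cloud RMS, if computed

    @property
    def all_passed(self) -> bool:
        return self.pass_a and self.pass_b and self.pass_c


def extract_skull_surface(
    img: ImageVolume,
    mode: str = "naf_threshold",
    threshold_quantile: float = 0.90,
) -> SkullSurface:
    """Skull point cloud from a NaF bone image or an inverted MR image.

    ``naf_threshold`` keeps voxels strictly above the given intensity quantile
    and returns their world centres; ``mr_inverted`` first maps
    ``v -> max(v) - v`` (bone is darkest in MR) and then thresholds the same
    way.
    """
    if mode not in ("naf_threshold", "mr_inverted"):
        raise ValueError("mode must be 'naf_threshold' or 'mr_inverted'")
    if not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must be in (0, 1)")
    values = np.asarray(img.values, dtype=float)
    if values.max() == values.min():
        raise ValueError("constant image: threshold quantile is undefined")
    if mode == "mr_inverted":
        values = values.max() - values
    thr = np.quantile(values, threshold_quantile)
    idx = np.argwhere(values > thr)
    if idx.size == 0:
        raise ValueError("threshold selected no voxels")
    return SkullSurface(img.grid.voxel_to_world(idx), source=mode)


def _landmark_groups(names):
    bulla_frontal = [n for n in names if n.startswith("bulla") or n.startswith("frontal")]
    cranial = [
        n for n in names if n.startswith("cranial") or n.startswith("parietal") or n.startswith("occipital")
    ]
    return bulla_frontal, cranial


def alignment_report(
    t: RigidTransform,
    subject_lm: LandmarkSet,
    template_lm: LandmarkSet,
    thresholds: AlignmentThresholds | None = None,
    surface_rms_mm: float | None = None,
) -> AlignmentReport:
    """Score a candidate transform against the three alignment criteria."""
    thresholds = thresholds or AlignmentThresholds()
    moved = subject_lm.transformed(t)

    # (a) midsagittal symmetry: the template midsagittal plane is the
    # left-right bisector of its bulla pair.
    mid_tpl = 0.5 * (template_lm[BULLA_LEFT] + template_lm[BULLA_RIGHT])
    axis = template_lm[BULLA_LEFT] - template_lm[BULLA_RIGHT]
    axis = axis / np.linalg.norm(axis) if np.linalg.norm(axis) > 0 else np.array([1.0, 0.0, 0.0])
    mid_sub = 0.5 * (moved[BULLA_LEFT] + moved[BULLA_RIGHT])
    criterion_a = float(abs(np.dot(mid_sub - mid_tpl, axis)))
    side_left = np.dot(moved[BULLA_LEFT] - mid_tpl, axis)
    side_right = np.dot(moved[BULLA_RIGHT] - mid_tpl, axis)
    laterality = bool(side_left > 0 and side_right < 0)

    common = sorted(set(moved.points) & set(template_lm.points))
    bulla_frontal, cranial = _landmark_groups(common)

    def _rms(names):
        if not names:
            return float("nan")
        d = moved.array(names) - template_lm.array(names)
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    criterion_b = _rms(bulla_frontal)
    criterion_c = _rms(cranial)
    return AlignmentReport(
        criterion_a=criterion_a,
        criterion_b=criterion_b,
        criterion_c=criterion_c,
        pass_a=bool(criterion_a <= thresholds.midsagittal_mm and laterality),
        pass_b=bool(criterion_b <= thresholds.bulla_frontal_rms_mm),
        pass_c=bool(criterion_c <= thresholds.cranial_rms_mm),
        laterality_correct=laterality,
        thresholds=thresholds,
        surface_rms_mm=surface_rms_mm,
    )


def _surface_rms(
    t: RigidTransform,
    naf: ImageVolume,
    tpl: ROITemplate,
    threshold_quantile: float,
    max_points: int = 5000,
) -> float:
    """RMS nearest-neighbour distance between the transformed NaF skull cloud
    and the inverted-MR skull cloud (diagnostic; landmark criteria gate)."""
    subject = extract_skull_surface(naf, "naf_threshold", threshold_quantile)
    reference = extract_skull_surface(tpl.mr, "mr_inverted", threshold_quantile)
    rng = np.random.default_rng(0)

    def _thin(points):
        if len(points) > max_points:
            keep = rng.choice(len(points), size=max_points, replace=False)
            return points[keep]
        return points

    moved = t.apply(_thin(subject.points))
    tree = cKDTree(_thin(reference.points))
    dist, _ = tree.query(moved, k=1)
    return float(np.sqrt(np.mean(dist**2)))


def register_naf_to_template(
    naf: ImageVolume,
    tpl: ROITemplate,
    subject_lm: LandmarkSet,
    template_lm: LandmarkSet | None = None,
    thresholds: AlignmentThresholds | None = None,
    threshold_quantile: float = 0.90,
    compute_surface_rms: bool = False,
):
    """Fit the NaF-to-template rigid transform and score the alignment.

    Mirrors the manual protocol in three steps: (1) translate the skull centroid
    into agreement, (2) solve the rotation by the closed-form landmark fit,
    (3) refine the translation. Steps (1)-(3) together are exactly the
    least-squares landmark solution; they are staged explicitly so each step's
    intermediate transform can be inspected. Only rotation and translation are
    fitted — anatomical scale is handled beforehand by template scaling.

    Returns ``(transform, report)``. Criterion failures set report flags; they
    are not errors.
    """
    if template_lm is None:
        if tpl.landmarks is None:
            raise ValueError("template landmarks are required (argument or tpl.landmarks)")
        template_lm = tpl.landmarks
    common = sorted(set(subject_lm.points) & set(template_lm.points))
    for required in (BULLA_LEFT, BULLA_RIGHT):
        if required not in common:
            raise GeometryError(f"bulla pair must be present in both landmark sets ({required})")
    src = subject_lm.array(common)
    dst = template_lm.array(common)

    # Step 1: coarse centre shift (centroid alignment).
    step1 = RigidTransform(translation_mm=tuple(dst.mean(axis=0) - src.mean(axis=0)))
    # Step 2: rotation about the matched centroids (closed-form fit).
    # Step 3: final centre refinement (exact translation given the rotation).
    fitted = fit_rigid_landmarks(src, dst)
    logger.debug(
        "registration: coarse shift %s -> rotation %s deg, refined shift %s mm",
        np.round(step1.translation_mm, 3).tolist(),
        np.round(fitted.rotation_deg, 3).tolist(),
        np.round(fitted.translation_mm, 3).tolist(),
    )
    surface_rms = (
        _surface_rms(fitted, naf, tpl, threshold_quantile) if compute_surface_rms else None
    )
    report = alignment_report(fitted, subject_lm, template_lm, thresholds, surface_rms)
    return fitted, report


def propagate_transform(
    dyn: DynamicImage,
    t: RigidTransform,
    target: VoxelGrid,
    interpolation: str = "trilinear",
) -> DynamicImage:
    """Resample every frame with the single shared transform; schedule unchanged."""
    frames = [apply_transform(f, t, target, interpolation) for f in dyn.frames]
    return DynamicImage(frames, list(dyn.schedule))
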