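"""MR template handling: ROI label volume, landmarks, and anatomical scaling.

The ROI template couples a population-average MR intensity image with an
integer-coded label volume on the same grid. Because individual animals are
not MR-scanned, the template is brought to subject size by rescaling its voxel
dimensions with the ratio of tympanic-bulla distances (the left-right
separation of the dorsal lateral bulla surfaces, the skull's most robust
width landmark).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ImageVolume, VoxelGrid

logger = logging.getLogger("ratpet")

__all__ = [
    "RegionInfo",
    "LabelVolume",
    "ROITemplate",
    "LandmarkSet",
    "MissingLandmarkError",
    "BULLA_LEFT",
    "BULLA_RIGHT",
    "bulla_distance",
    "scale_template",
]

BULLA_LEFT = "bulla_left"
BULLA_RIGHT = "bulla_right"


class MissingLandmarkError(KeyError):
    """A required named landmark is absent from the set."""

    def __init__(self, name: str):
        super().__init__(name)
        self.landmark = name

    def __str__(self) -> str:  # structured error naming the landmark
        return f"required landmark {self.landmark!r} is missing"


@dataclass(frozen=True)
class RegionInfo:
    code: int
    name: str
    volume_mm3: float


@dataclass
class LabelVolume:
    """Integer-coded ROI map on a voxel grid; 0 is background."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer typed")
        if tuple(self.labels.shape) != self.grid.shape:
            raise ValueError("label array shape must equal grid shape")

    def codes(self) -> list:
        return sorted(int(c) for c in np.unique(self.labels) if c != 0)

    def region_voxel_count(self, code: int) -> int:
        return int(np.count_nonzero(self.labels == code))

    def region_volume_mm3(self, code: int) -> float:
        return self.region_voxel_count(code) * self.grid.voxel_volume


@dataclass
class LandmarkSet:
    """Named skull landmarks in world mm.

    Must contain the bulla pair; registration additionally expects frontal-bone
    points (``frontal_*``), cranial-case points (``cranial_*``) and at least
    one parietal/occipital articulation point.
    """

    points: dict

    def __post_init__(self) -> None:
        self.points = {str(k): np.asarray(v, dtype=float) for k, v in self.points.items()}
        for name, p in self.points.items():
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"landmark {name!r} must be a finite 3-vector")
        for required in (BULLA_LEFT, BULLA_RIGHT):
            if required not in self.points:
                raise MissingLandmarkError(required)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def names(self) -> list:
        return sorted(self.points)

    def array(self, names) -> np.ndarray:
        return np.stack([self[n] for n in names])

    def transformed(self, t) -> "LandmarkSet":
        return LandmarkSet({k: t.apply(v) for k, v in self.points.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: v.tolist() for k, v in self.points.items()}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            return cls(json.load(fh))


@dataclass
class ROITemplate:
    """MR intensity image + ROI labels + region table (+ optional landmarks)."""

    mr: ImageVolume
    labels: LabelVolume
    regions: dict  # code -> RegionInfo
    landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        if self.labels.grid != self.mr.grid:
            raise ValueError("label volume must live on the MR grid")
        present = set(self.labels.codes())
        missing = [c for c in self.regions if c not in present]
        if missing:
            raise ValueError(f"region codes absent from label volume: {missing}")

    @property
    def grid(self) -> VoxelGrid:
        return self.mr.grid

    def region_names(self) -> dict:
        return {code: info.name for code, info in self.regions.items()}


def bulla_distance(lm: LandmarkSet) -> float:
    """Euclidean distance (mm) between left and right dorsal lateral bulla points."""
    return float(np.linalg.norm(lm[BULLA_LEFT] - lm[BULLA_RIGHT]))


def scale_template(
    tpl: ROITemplate,
    template_distance: float | None = None,
    subject_distance: float | None = None,
    mode: str = "ratio",
    voxel_size=None,
) -> ROITemplate:
    """Rescale the template geometry to subject size.

    ``mode='ratio'`` multiplies every voxel dimension (and the world origin and
    landmark coordinates) by ``subject_distance / template_distance``; voxel
    values are untouched — this is a pure geometric rescale about the world
    origin. ``mode='explicit'`` sets the voxel dimensions to ``voxel_size``
    (e.g. published rounded values), with per-axis factors applied likewise.
    Nominal region volumes rescale by the product of the axis factors.
    """
    if mode == "ratio":
        if template_distance is None or subject_distance is None:
            raise ValueError("ratio mode needs template and subject bulla distances")
        if template_distance <= 0 or subject_distance <= 0:
            raise ValueError("bulla distances must be positive")
        factor = subject_distance / template_distance
        factors = np.array([factor, factor, factor])
    elif mode == "explicit":
        if voxel_size is None:
            raise ValueError("explicit mode needs the target voxel dimensions")
        voxel_size = np.asarray(voxel_size, dtype=float)
        if voxel_size.shape != (3,) or np.any(voxel_size <= 0):
            raise ValueError("explicit voxel dimensions must be three positive values")
        factors = voxel_size / np.asarray(tpl.grid.voxel_size)
        if template_distance and subject_distance:
            ratio = subject_distance / template_distance
            if not np.allclose(factors, ratio, rtol=0.05):
                logger.info(
                    "explicit voxel scaling %s differs from the pure bulla-distance "
                    "ratio %.4f (published values are typically rounded)",
                    np.round(factors, 4).tolist(),
                    ratio,
                )
    else:
        raise ValueError("mode must be 'ratio' or 'explicit'")

    def _scale_grid(grid: VoxelGrid) -> VoxelGrid:
        return VoxelGrid(
            grid.shape,
            tuple(np.asarray(grid.voxel_size) * factors),
            tuple(np.asarray(grid.origin) * factors),
        )

    volume_factor = float(np.prod(factors))
    new_regions = {
        code: replace(info, volume_mm3=info.volume_mm3 * volume_factor)
        for code, info in tpl.regions.items()
    }
    new_landmarks = None
    if tpl.landmarks is not None:
        new_landmarks = LandmarkSet({k: v * factors for k, v in tpl.landmarks.points.items()})
    return ROITemplate(
        mr=ImageVolume(_scale_grid(tpl.mr.grid), tpl.mr.values),
        labels=LabelVolume(_scale_grid(tpl.labels.grid), tpl.labels.labels),
        regions=new_regions,
        landmarks=new_landmarks,
    )
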