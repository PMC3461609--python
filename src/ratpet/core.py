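"""Volumetric grids, rigid-body transforms, resampling, and NIfTI/JSON I/O.

World convention: right-handed, millimetres, axis-aligned grids only. The world
position of voxel index ``(0, 0, 0)`` is the grid origin (voxel *centres*, not
corners). Transforms act in world space; rotations are fixed-axes Euler angles
in degrees applied in x -> y -> z order. Activity images carry concentrations
in kBq/mL (numerically equal to Bq/mm^3); MR images carry arbitrary intensity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

logger = logging.getLogger("ratpet")

__all__ = [
    "VoxelGrid",
    "ImageVolume",
    "DynamicImage",
    "RigidTransform",
    "GeometryError",
    "fit_rigid_landmarks",
    "apply_transform",
    "read_nifti",
    "write_nifti",
    "read_dynamic_nifti",
    "write_dynamic_nifti",
]

_EULER_ORDER = "xyz"  # lowercase = fixed (extrinsic) axes, applied x then y then z


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear landmarks, bad scale...)."""


# ---------------------------------------------------------------------------
# Grids and images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice embedded in world space (mm)."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        voxel_size = tuple(float(v) for v in self.voxel_size)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {shape}")
        if len(voxel_size) != 3 or any(v <= 0 for v in voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {voxel_size}")
        if not np.all(np.isfinite(origin)):
            raise ValueError(f"origin must be finite, got {origin}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel_size)
        object.__setattr__(self, "origin", origin)

    @classmethod
    def centered(cls, shape, voxel_size) -> "VoxelGrid":
        """Grid whose world centre coincides with the world origin."""
        shape = tuple(int(s) for s in shape)
        voxel_size = tuple(float(v) for v in voxel_size)
        origin = tuple(-(n - 1) / 2.0 * h for n, h in zip(shape, voxel_size))
        return cls(shape, voxel_size, origin)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def voxel_to_world(self, index) -> np.ndarray:
        """Map (possibly fractional, possibly out-of-range) indices to world mm."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.voxel_size)

    def world_to_voxel(self, world) -> np.ndarray:
        world = np.asarray(world, dtype=float)
        return (world - np.asarray(self.origin)) / np.asarray(self.voxel_size)

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis (1-D array)."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.voxel_size[axis]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape ``(*shape, 3)``."""
        axes = [self.axis_coordinates(i) for i in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


@dataclass
class ImageVolume:
    """Scalar 3-D image on a :class:`VoxelGrid` (kBq/mL or arbitrary intensity)."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.grid, self.values.copy())


@dataclass
class DynamicImage:
    """Ordered PET frames on a shared grid plus a (start_s, duration_s) schedule."""

    frames: list
    schedule: list  # [(start_s, duration_s), ...]

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.schedule):
            raise ValueError("frame count must match schedule length")
        if not self.frames:
            raise ValueError("dynamic image needs at least one frame")
        grid = self.frames[0].grid
        for f in self.frames:
            if f.grid != grid:
                raise ValueError("all frames must share one grid")
        self.schedule = [(float(s), float(d)) for s, d in self.schedule]
        prev_end = -np.inf
        prev_start = -np.inf
        for start, dur in self.schedule:
            if dur <= 0:
                raise ValueError("frame durations must be positive")
            if start <= prev_start:
                raise ValueError("frame start times must be strictly increasing")
            if start < prev_end - 1e-9:
                raise ValueError("frames must not overlap")
            prev_start, prev_end = start, start + dur
        self.schedule = list(self.schedule)

    @property
    def grid(self) -> VoxelGrid:
        return self.frames[0].grid

    @property
    def frame_midpoints_s(self) -> np.ndarray:
        return np.array([s + d / 2.0 for s, d in self.schedule])


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """World-space rigid-body map with optional per-axis scale.

    ``p' = R @ diag(scale) @ p + t`` where ``R`` is built from fixed-axes Euler
    angles (degrees, x -> y -> z). With unit scale the linear part is a proper
    rotation.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        rot = tuple(float(r) for r in self.rotation_deg)
        tra = tuple(float(t) for t in self.translation_mm)
        sca = tuple(float(s) for s in self.scale)
        if any(s <= 0 for s in sca):
            raise GeometryError(f"scale factors must be positive, got {sca}")
        if not (np.all(np.isfinite(rot)) and np.all(np.isfinite(tra))):
            raise ValueError("rotation/translation must be finite")
        object.__setattr__(self, "rotation_deg", rot)
        object.__setattr__(self, "translation_mm", tra)
        object.__setattr__(self, "scale", sca)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler(_EULER_ORDER, self.rotation_deg, degrees=True).as_matrix()

    @property
    def linear(self) -> np.ndarray:
        return self.rotation_matrix @ np.diag(self.scale)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous world-space matrix."""
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.translation_mm
        return m

    @classmethod
    def from_matrix(cls, matrix, atol: float = 1e-8) -> "RigidTransform":
        """Decompose a homogeneous matrix into rotation x diagonal scale + translation.

        Raises :class:`GeometryError` if the linear part is not of that form
        (shear, reflection, ...).
        """
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 matrix")
        lin = m[:3, :3]
        scale = np.linalg.norm(lin, axis=0)
        if np.any(scale <= 0):
            raise GeometryError("degenerate linear part")
        rot = lin / scale
        if not np.allclose(rot.T @ rot, np.eye(3), atol=max(atol, 1e-8)):
            raise GeometryError("linear part is not rotation x diagonal scale")
        if np.linalg.det(rot) < 0:
            raise GeometryError("linear part contains a reflection")
        euler = Rotation.from_matrix(rot).as_euler(_EULER_ORDER, degrees=True)
        return cls(tuple(euler), tuple(m[:3, 3]), tuple(scale))

    def apply(self, points) -> np.ndarray:
        """Apply to one point or an (N, 3) array of world points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + np.asarray(self.translation_mm)

    def apply_inverse(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float) - np.asarray(self.translation_mm)
        inv_lin = np.diag(1.0 / np.asarray(self.scale)) @ self.rotation_matrix.T
        return pts @ inv_lin.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix())

    def invert(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix()))

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix(), np.eye(4), atol=atol))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "scale": list(self.scale),
            "matrix": self.matrix().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            tuple(d["rotation_deg"]),
            tuple(d["translation_mm"]),
            tuple(d.get("scale", (1.0, 1.0, 1.0))),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_rigid_landmarks(src, dst) -> RigidTransform:
    """Closed-form least-squares rigid fit mapping ``src`` points onto ``dst``.

    Kabsch/Umeyama without scaling: minimises the sum of squared distances
    ``|R src_i + t - dst_i|^2`` over proper rotations and translations.
    Requires at least three non-collinear paired points.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("src and dst must be matching (N, 3) arrays")
    if src.shape[0] < 3:
        raise GeometryError("rigid landmark fit needs at least 3 point pairs")
    src_c = src - src.mean(axis=0)
    dst_c = dst - dst.mean(axis=0)
    # Collinear points leave a rotation about the common axis unconstrained.
    if np.linalg.matrix_rank(src_c, tol=1e-9 * max(1.0, np.abs(src_c).max())) < 2:
        raise GeometryError("landmarks are collinear; rotation is not determined")
    h = src_c.T @ dst_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    euler = Rotation.from_matrix(rot).as_euler(_EULER_ORDER, degrees=True)
    trans = dst.mean(axis=0) - rot @ src.mean(axis=0)
    return RigidTransform(tuple(euler), tuple(trans))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERP_ORDER = {"trilinear": 1, "nearest": 0}


def apply_transform(
    image: ImageVolume,
    t: RigidTransform,
    target: VoxelGrid,
    interpolation: str = "trilinear",
) -> ImageVolume:
    """Resample ``image`` onto ``target`` under world transform ``t``.

    ``t`` maps source world coordinates into target world coordinates; each
    target voxel centre is pulled back through ``t^-1`` and interpolated in the
    source. Out-of-support voxels are filled with 0 (air background).
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"interpolation must be one of {sorted(_INTERP_ORDER)}")
    if any(s <= 0 for s in t.scale):
        raise GeometryError("degenerate scale in transform")
    if t.is_identity(atol=1e-12) and target == image.grid:
        return image.copy()

    # source_index = M @ target_index + offset, both in voxel units
    inv_lin = np.diag(1.0 / np.asarray(t.scale)) @ t.rotation_matrix.T
    vs_src = np.asarray(image.grid.voxel_size)
    vs_tgt = np.asarray(target.voxel_size)
    m = (inv_lin * vs_tgt[None, :]) / vs_src[:, None]
    world_shift = np.asarray(target.origin) - np.asarray(t.translation_mm)
    offset = (inv_lin @ world_shift - np.asarray(image.grid.origin)) / vs_src
    out = ndimage.affine_transform(
        np.asarray(image.values, dtype=float),
        m,
        offset=offset,
        output_shape=target.shape,
        order=_INTERP_ORDER[interpolation],
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return ImageVolume(target, out)


# ---------------------------------------------------------------------------
# NIfTI-1 I/O (axis-aligned volumes only)
# ---------------------------------------------------------------------------


def _grid_to_affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def _affine_to_grid(affine: np.ndarray, shape) -> VoxelGrid:
    lin = affine[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
        raise ValueError("oblique/sheared NIfTI affines are not supported")
    diag = np.diag(lin)
    if np.any(diag <= 0):
        raise ValueError("negative/zero voxel sizes in affine are not supported")
    return VoxelGrid(tuple(shape[:3]), tuple(diag), tuple(affine[:3, 3]))


def write_nifti(image: ImageVolume, path, dtype=np.float32) -> None:
    nib.save(nib.Nifti1Image(np.asarray(image.values, dtype=dtype), _grid_to_affine(image.grid)), str(path))


def read_nifti(path, dtype=None) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    if dtype is not None:
        data = data.astype(dtype)
    return ImageVolume(_affine_to_grid(img.affine, data.shape), data)


def write_dynamic_nifti(dyn: DynamicImage, path, schedule_path=None, dtype=np.float32) -> None:
    """4-D NIfTI plus a JSON sidecar with the frame schedule."""
    data = np.stack([np.asarray(f.values, dtype=dtype) for f in dyn.frames], axis=-1)
    nib.save(nib.Nifti1Image(data, _grid_to_affine(dyn.grid)), str(path))
    sidecar = schedule_path if schedule_path is not None else str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "frame_start_s": [s for s, _ in dyn.schedule],
                "frame_duration_s": [d for _, d in dyn.schedule],
            },
            fh,
            indent=2,
        )


def read_dynamic_nifti(path, schedule_path=None) -> DynamicImage:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D volume, got shape {data.shape}")
    grid = _affine_to_grid(img.affine, data.shape)
    sidecar = schedule_path if schedule_path is not None else str(path) + ".json"
    with open(sidecar) as fh:
        meta = json.load(fh)
    schedule = list(zip(meta["frame_start_s"], meta["frame_duration_s"]))
    frames = [ImageVolume(grid, data[..., i]) for i in range(data.shape[-1])]
    return DynamicImage(frames, schedule)
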