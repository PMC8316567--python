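"""Core containers shared across the pipeline.

Volumes are stored as numpy arrays indexed ``[i, j, k]`` along world axes
(x, y, z), with uniform-per-axis spacing in millimetres and a world-space
origin at the centre of voxel ``[0, 0, 0]``.  Hounsfield units (HU) follow
the CT convention: water = 0, air = -1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3000.0


class RadulnaError(Exception):
    """Base class for errors raised by this package."""


class ParameterError(RadulnaError, ValueError):
    """A supplied parameter violates its contract."""


class GeometryError(RadulnaError, ValueError):
    """Requested geometry is inconsistent or does not fit the grid."""


class PairingError(RadulnaError, ValueError):
    """Two objects that must share geometry do not."""


class DegenerateInputError(RadulnaError, ValueError):
    """Input is formally valid but carries no usable signal."""


class DataError(RadulnaError, ValueError):
    """Data content violates an invariant (non-finite values, bad classes)."""


class StateError(RadulnaError, RuntimeError):
    """An operation was invoked in an invalid lifecycle state."""


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(-1)
    if v.size != 3 or not np.all(np.isfinite(v)):
        raise ParameterError(f"{name} must be 3 finite numbers, got {x!r}")
    return v


@dataclass
class CTVolume:
    """3D scalar grid in Hounsfield units with world-space geometry."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise DataError("voxels must be a 3D array")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        self.orientation = np.asarray(self.orientation, dtype=float)
        if np.any(self.spacing <= 0):
            raise ParameterError("spacing must be strictly positive")
        R = self.orientation
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise GeometryError("orientation must be an orthonormal 3x3 matrix")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise GeometryError("orientation must have determinant +1")
        if not np.all(np.isfinite(self.voxels)):
            raise DataError("HU values must be finite")
        if self.voxels.size and (
            self.voxels.min() < HU_MIN - 1e-3 or self.voxels.max() > HU_MAX + 1e-3
        ):
            raise DataError(
                f"HU outside [{HU_MIN}, {HU_MAX}]: "
                f"range [{self.voxels.min():.1f}, {self.voxels.max():.1f}]"
            )

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-space mm coordinates (..., 3) to fractional voxel indices."""
        p = np.asarray(points, dtype=float)
        local = (p - self.origin) @ self.orientation  # R^T applied from the right
        return local / self.spacing

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        i = np.asarray(idx, dtype=float)
        return (i * self.spacing) @ self.orientation.T + self.origin

    def same_grid(self, other: "CTVolume | LabelVolume") -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
            and np.allclose(self.orientation, other.orientation)
        )


@dataclass
class LabelVolume:
    """Per-voxel class grid: 0 background, 1 radius, 2 ulna."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    BACKGROUND = 0
    RADIUS = 1
    ULNA = 2

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DataError("voxels must be a 3D array")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise DataError("label voxels must be integer-typed")
        bad = np.setdiff1d(np.unique(self.voxels), [0, 1, 2])
        if bad.size:
            raise DataError(f"label classes must be in {{0,1,2}}, found {bad.tolist()}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        self.origin = _as_vec3(self.origin, "origin")
        self.orientation = np.asarray(self.orientation, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        local = (p - self.origin) @ self.orientation
        return local / self.spacing

    def mask(self, class_id: int) -> np.ndarray:
        return self.voxels == class_id

    def bone_mask(self) -> np.ndarray:
        return self.voxels > 0


@dataclass
class LandmarkSet:
    """Anatomical landmarks of the distal radius, in world mm.

    ``shaft_axis_points`` are two distinct points on the radial shaft axis,
    ordered proximal to distal, so their difference points distally.
    """

    styloid_point: np.ndarray
    sigmoid_notch_point: np.ndarray
    shaft_axis_points: np.ndarray  # (2, 3)
    articular_surface_point: np.ndarray

    def __post_init__(self) -> None:
        self.styloid_point = _as_vec3(self.styloid_point, "styloid_point")
        self.sigmoid_notch_point = _as_vec3(self.sigmoid_notch_point, "sigmoid_notch_point")
        self.articular_surface_point = _as_vec3(
            self.articular_surface_point, "articular_surface_point"
        )
        pts = np.asarray(self.shaft_axis_points, dtype=float)
        if pts.shape != (2, 3) or not np.all(np.isfinite(pts)):
            raise ParameterError("shaft_axis_points must be a finite (2, 3) array")
        if np.linalg.norm(pts[1] - pts[0]) < 1e-9:
            raise ParameterError("shaft_axis_points must be distinct")
        self.shaft_axis_points = pts

    def transformed(self, transform) -> "LandmarkSet":
        """Apply a rigid transform (object with ``.apply_points``) to all landmarks."""
        return LandmarkSet(
            styloid_point=transform.apply_points(self.styloid_point),
            sigmoid_notch_point=transform.apply_points(self.sigmoid_notch_point),
            shaft_axis_points=transform.apply_points(self.shaft_axis_points),
            articular_surface_point=transform.apply_points(self.articular_surface_point),
        )


@dataclass
class DRRImage:
    """2D image of line-integrated attenuation (dimensionless optical depth)."""

    pixels: np.ndarray
    pixel_spacing: np.ndarray
    geometry: object | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise DataError("pixels must be a 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("DRR pixels must be finite")
        sp = np.asarray(self.pixel_spacing, dtype=float).reshape(-1)
        if sp.size == 1:
            sp = np.repeat(sp, 2)
        if sp.size != 2 or np.any(sp <= 0):
            raise ParameterError("pixel_spacing must be 2 positive numbers")
        self.pixel_spacing = sp

    @property
    def shape(self) -> tuple:
        return self.pixels.shape
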