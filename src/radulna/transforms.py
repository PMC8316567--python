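"""Rigid 3D and affine 2D transforms with seeded random sampling.

Euler angles use the intrinsic Z-Y-X convention: the rotation matrix is
``Rz(rz) @ Ry(ry) @ Rx(rx)`` with angles in degrees.  A transform maps a
point ``p`` to ``R @ p + t`` (rotation about the world origin, then
translation), all in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ParameterError


def _rot_x(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class RigidTransform3D:
    """Rotation (Euler degrees about X, Y, Z) plus translation (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.rotation)) and np.all(np.isfinite(self.translation))):
            raise ParameterError("rotation and translation must be finite")

    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls()

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        R = _rot_z(self.rotation[2]) @ _rot_y(self.rotation[1]) @ _rot_x(self.rotation[0])
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.translation
        return M

    @property
    def rotation_matrix(self) -> np.ndarray:
        return self.matrix[:3, :3]

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation_matrix.T + self.translation

    def inverse_apply_points(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.translation) @ self.rotation_matrix

    def as_params(self) -> np.ndarray:
        return np.concatenate([self.rotation, self.translation])

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidTransform3D":
        p = np.asarray(params, dtype=float).reshape(6)
        return cls(rotation=p[:3], translation=p[3:])

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation.tolist(),
            "translation_mm": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform3D":
        return cls(rotation=d["rotation_deg"], translation=d["translation_mm"])


def sample_rigid_transforms(
    n: int,
    rotation_range_deg: float = 30.0,
    translation_range_mm: float = 30.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[RigidTransform3D]:
    """Draw ``n`` transforms with angles and translations uniform in
    ``[-range, +range]`` per axis."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if rotation_range_deg < 0 or translation_range_mm < 0:
        raise ParameterError("ranges must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    rots = rng.uniform(-rotation_range_deg, rotation_range_deg, size=(n, 3))
    trans = rng.uniform(-translation_range_mm, translation_range_mm, size=(n, 3))
    return [RigidTransform3D(rotation=r, translation=t) for r, t in zip(rots, trans)]


@dataclass
class Affine2D:
    """2D affine transform: translation (mm), rotation (deg), per-axis scale,
    shear (deg).  Maps image-plane points ``p -> A @ p + t`` about the image
    centre when applied to images."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rotation: float = 0.0
    scale: np.ndarray = field(default_factory=lambda: np.ones(2))
    shear: float = 0.0

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        self.scale = np.asarray(self.scale, dtype=float).reshape(2)
        if np.any(self.scale <= 0):
            raise ParameterError("scale must be strictly positive")
        if not np.isfinite(self.rotation) or not np.isfinite(self.shear):
            raise ParameterError("rotation and shear must be finite")

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 3x3 matrix (linear part: rotation @ shear @ scale)."""
        a = np.deg2rad(self.rotation)
        c, s = np.cos(a), np.sin(a)
        R = np.array([[c, -s], [s, c]])
        sh = np.array([[1.0, np.tan(np.deg2rad(self.shear))], [0.0, 1.0]])
        S = np.diag(self.scale)
        M = np.eye(3)
        M[:2, :2] = R @ sh @ S
        M[:2, 2] = self.translation
        return M

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_dict(self) -> dict:
        return {
            "translation_mm": self.translation.tolist(),
            "rotation_deg": float(self.rotation),
            "scale": self.scale.tolist(),
            "shear_deg": float(self.shear),
        }


def sample_affine2d(
    n: int,
    translation_range_mm: float = 10.0,
    rotation_range_deg: float = 10.0,
    scale_range: tuple = (0.9, 1.1),
    shear_range_deg: float = 5.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[Affine2D]:
    """Draw ``n`` affine transforms uniformly within the stated ranges."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if scale_range[0] > scale_range[1] or scale_range[0] <= 0:
        raise ParameterError(f"invalid scale range {scale_range}")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            Affine2D(
                translation=rng.uniform(-translation_range_mm, translation_range_mm, 2),
                rotation=rng.uniform(-rotation_range_deg, rotation_range_deg),
                scale=rng.uniform(scale_range[0], scale_range[1], 2),
                shear=rng.uniform(-shear_range_deg, shear_range_deg),
            )
        )
    return out
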