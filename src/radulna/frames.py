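"""Anatomical coordinate frame and geometric normalization.

The frame follows the radiographic convention for the distal radius: the
radial shaft axis is Z (pointing distally); the origin is the intersection
of Z with the distal articular surface (the articular landmark projected
onto the shaft line); X is the unit projection, onto the plane through the
origin perpendicular to Z, of the reference line running from the styloid
process to the sigmoid notch; Y completes a right-handed triad.  Because X
is built from the same two landmarks in every subject, resampling into this
frame unifies the rotation of the radius about its own axis.

Normalization resamples CT (trilinear) and labels (nearest-neighbour) onto
a canonical grid aligned with the frame whose Z extent is +/- the field-of-
view half-width (40 mm by default) about the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core import (
    CTVolume,
    GeometryError,
    LabelVolume,
    LandmarkSet,
    ParameterError,
)

DEFAULT_FOV_HALFWIDTH_MM = 40.0


@dataclass
class AnatomicalFrame:
    """Origin plus right-handed orthonormal axes, all in world mm."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise GeometryError("frame axes must be orthonormal to 1e-6")
        if np.linalg.det(R) < 0:
            raise GeometryError("frame must be right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """Columns are the frame axes expressed in world coordinates."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis], axis=1)

    def to_world(self, local: np.ndarray) -> np.ndarray:
        return np.asarray(local, dtype=float) @ self.rotation.T + self.origin

    def to_local(self, world: np.ndarray) -> np.ndarray:
        return (np.asarray(world, dtype=float) - self.origin) @ self.rotation

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        return cls(np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))


@dataclass
class NormalizedSample:
    """A phantom resampled into the canonical anatomical grid."""

    ct: CTVolume
    label: LabelVolume
    frame: AnatomicalFrame
    fov_halfwidth: float


def build_frame(lm: LandmarkSet) -> AnatomicalFrame:
    """Construct the anatomical frame from distal-radius landmarks."""
    p0, p1 = lm.shaft_axis_points
    z = p1 - p0
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ParameterError("shaft axis points must be distinct")
    z = z / nz

    # Origin: articular point projected onto the shaft line.
    origin = p0 + np.dot(lm.articular_surface_point - p0, z) * z

    ref = lm.sigmoid_notch_point - lm.styloid_point
    ref_perp = ref - np.dot(ref, z) * z
    n_perp = np.linalg.norm(ref_perp)
    if n_perp < 1e-6 * max(np.linalg.norm(ref), 1.0):
        raise GeometryError(
            "reference line (styloid -> sigmoid notch) is parallel to the shaft axis"
        )
    x = ref_perp / n_perp
    y = np.cross(z, x)
    return AnatomicalFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def normalize_volume(
    ct: CTVolume,
    label: LabelVolume,
    frame: AnatomicalFrame,
    fov_halfwidth: float = DEFAULT_FOV_HALFWIDTH_MM,
    spacing: float | tuple = 1.25,
    background_hu: float = -1000.0,
) -> NormalizedSample:
    """Resample a CT/label pair into the canonical anatomical grid.

    The canonical grid is axis-aligned in frame coordinates, centred on the
    frame origin, spanning ±fov_halfwidth along every axis.  Regions of the
    canonical grid not covered by the source volume are padded with air HU
    and background label.
    """
    if fov_halfwidth <= 0:
        raise ParameterError("fov_halfwidth must be > 0")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ParameterError("spacing must be positive")
    if ct.voxels.shape != label.voxels.shape:
        raise ParameterError("CT and label grids must match")

    n = np.maximum(np.round(2 * fov_halfwidth / spacing).astype(int) + 1, 2)
    out_origin_local = -spacing * (n - 1) / 2.0
    # Adjust so the grid spans exactly +/- fov_halfwidth along Z.
    spacing[2] = 2 * fov_halfwidth / (n[2] - 1)
    out_origin_local[2] = -fov_halfwidth

    xs = out_origin_local[0] + spacing[0] * np.arange(n[0])
    ys = out_origin_local[1] + spacing[1] * np.arange(n[1])
    zs = out_origin_local[2] + spacing[2] * np.arange(n[2])
    lx, ly, lz = np.meshgrid(xs, ys, zs, indexing="ij")
    local = np.stack([lx, ly, lz], axis=-1).reshape(-1, 3)
    world = frame.to_world(local)
    idx = ct.world_to_index(world).reshape(*n, 3)
    coords = np.moveaxis(idx, -1, 0)

    hu = map_coordinates(
        np.asarray(ct.voxels, dtype=np.float64),
        coords,
        order=1,
        mode="constant",
        cval=background_hu,
    )
    lab = map_coordinates(
        np.asarray(label.voxels, dtype=np.uint8),
        coords,
        order=0,
        mode="constant",
        cval=LabelVolume.BACKGROUND,
    )

    out_ct = CTVolume(
        voxels=hu.astype(np.float32), spacing=spacing, origin=out_origin_local
    )
    out_label = LabelVolume(
        voxels=lab.astype(np.uint8), spacing=spacing, origin=out_origin_local
    )
    return NormalizedSample(
        ct=out_ct, label=out_label, frame=frame, fov_halfwidth=float(fov_halfwidth)
    )
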