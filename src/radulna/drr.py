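"""Digitally reconstructed radiograph rendering.

A DRR pixel is the line integral of the linear attenuation coefficient mu
(1/mm) along that pixel's ray, i.e. a dimensionless optical depth.  mu is
derived from Hounsfield units by the standard affine map

    mu = global_scale * max(0, mu_water * (1 + HU / 1000))

clipped at zero (air and below attenuate nothing).  Rendering uses
fixed-step ray marching with trilinear interpolation; samples outside the
volume contribute zero, so rays that miss the volume produce zero pixels.

The default geometry is orthographic along -Y, the posteroanterior analogue
for the canonical phantom pose; a pinhole perspective mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .core import (
    CTVolume,
    DRRImage,
    DataError,
    LabelVolume,
    PairingError,
    ParameterError,
)
from .transforms import RigidTransform3D

#: mu of water at diagnostic energies, 1/mm.
MU_WATER_PER_MM = 0.02

#: Default calibration such that the reference phantom's bone DRR peaks
#: near 0.20 optical depth (see AttenuationModel docstring).
DEFAULT_GLOBAL_SCALE = 0.227


@dataclass
class AttenuationModel:
    """HU -> linear attenuation conversion.

    ``global_scale`` is a unitless calibration factor; the default is chosen
    so that bone-only DRRs of the reference wrist phantom span approximately
    [0, 0.2] optical depth, a convenient display range for 2D networks.
    """

    mu_water: float = MU_WATER_PER_MM
    global_scale: float = DEFAULT_GLOBAL_SCALE

    def __post_init__(self) -> None:
        if self.mu_water <= 0 or self.global_scale <= 0:
            raise ParameterError("mu_water and global_scale must be > 0")


@dataclass
class ProjectionGeometry:
    """Detector and ray geometry for DRR rendering.

    The detector is a regular 2D grid of ``detector_shape`` pixels with
    ``pixel_spacing`` mm pitch, centred at ``detector_center`` (world mm) and
    oriented perpendicular to ``view_direction``.  Rays travel along
    ``view_direction``; in perspective mode they emanate from a point source
    ``source_distance`` mm behind the detector centre.
    """

    mode: str = "orthographic"
    view_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))
    detector_shape: tuple = (64, 64)
    pixel_spacing: float | tuple = 1.0
    detector_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    source_distance: float = 1000.0
    step_length: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("orthographic", "perspective"):
            raise ParameterError(f"unknown projection mode {self.mode!r}")
        v = np.asarray(self.view_direction, dtype=float).reshape(3)
        n = np.linalg.norm(v)
        if not np.isfinite(n) or n < 1e-12:
            raise ParameterError("view_direction must be a nonzero vector")
        self.view_direction = v / n
        self.detector_shape = tuple(int(s) for s in self.detector_shape)
        self.pixel_spacing = np.broadcast_to(
            np.asarray(self.pixel_spacing, dtype=float), (2,)
        ).copy()
        if np.any(self.pixel_spacing <= 0):
            raise ParameterError("pixel_spacing must be positive")
        self.detector_center = np.asarray(self.detector_center, dtype=float).reshape(3)
        if self.step_length <= 0:
            raise ParameterError("step_length must be > 0")
        if self.mode == "perspective" and self.source_distance <= 0:
            raise ParameterError("source_distance must be > 0")

    def detector_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic in-plane axes (u, w) orthonormal to the view.

        u spans image rows, w image columns; (u, w, view) is right-handed.
        """
        v = self.view_direction
        ref = np.zeros(3)
        ref[int(np.argmin(np.abs(v)))] = 1.0
        u = np.cross(ref, v)
        u /= np.linalg.norm(u)
        w = np.cross(v, u)
        return u, w


def hu_to_mu(ct: CTVolume, model: AttenuationModel | None = None) -> np.ndarray:
    """Convert a HU volume to linear attenuation (1/mm), clipped at zero."""
    if model is None:
        model = AttenuationModel()
    hu = np.asarray(ct.voxels, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise DataError("HU volume contains non-finite values")
    mu = model.mu_water * (1.0 + hu / 1000.0)
    np.clip(mu, 0.0, None, out=mu)
    mu *= model.global_scale
    return mu


def _ray_grid(geom: ProjectionGeometry):
    u, w = geom.detector_axes()
    nu, nw = geom.detector_shape
    du, dw = geom.pixel_spacing
    iu = (np.arange(nu) - (nu - 1) / 2.0) * du
    iw = (np.arange(nw) - (nw - 1) / 2.0) * dw
    offsets = iu[:, None, None] * u + iw[None, :, None] * w  # (nu, nw, 3)
    pixel_pos = geom.detector_center + offsets
    return pixel_pos


def render_drr(
    mu: np.ndarray,
    geom: ProjectionGeometry,
    volume: CTVolume | None = None,
    spacing: np.ndarray | None = None,
    origin: np.ndarray | None = None,
    pose: RigidTransform3D | None = None,
) -> DRRImage:
    """Ray-march a mu volume into a DRR.

    ``mu`` is the attenuation array; grid geometry comes either from
    ``volume`` (a CTVolume sharing the grid) or explicit ``spacing``/
    ``origin``.  ``pose`` rigidly moves the volume in world space before
    projection (samples are taken at inversely transformed points), which is
    how augmentation and registration pose volumes without resampling them.
    """
    if volume is not None:
        spacing = volume.spacing
        origin = volume.origin
    if spacing is None or origin is None:
        raise ParameterError("provide either `volume` or both `spacing` and `origin`")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    mu = np.asarray(mu, dtype=np.float64)
    if geom.step_length > spacing.min() + 1e-12:
        raise ParameterError(
            f"step_length {geom.step_length} mm exceeds min voxel spacing "
            f"{spacing.min()} mm; refusing to undersample"
        )

    # March only across the volume's bounding sphere (posed volumes stay
    # within the same ball around the posed centre; widen by the pose shift).
    corners = origin + spacing * (np.asarray(mu.shape) - 1)
    radius = 0.5 * np.linalg.norm(corners - origin) + geom.step_length
    center = (origin + corners) / 2.0
    if pose is not None:
        center = pose.apply_points(center)
    v = geom.view_direction
    pixel_pos = _ray_grid(geom)  # (nu, nw, 3)

    if geom.mode == "orthographic":
        t_center = float(np.dot(center - geom.detector_center, v))
        ts = np.arange(t_center - radius, t_center + radius, geom.step_length)
        pts = pixel_pos[:, :, None, :] + ts[None, None, :, None] * v
    else:
        source = geom.detector_center - geom.source_distance * v
        dirs = pixel_pos - source  # (nu, nw, 3)
        dirs = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)
        t_center = float(np.linalg.norm(center - source))
        ts = np.arange(
            max(t_center - radius, 0.0), t_center + radius, geom.step_length
        )
        pts = source + dirs[:, :, None, :] * ts[None, None, :, None]

    if pose is not None:
        shape4 = pts.shape
        pts = pose.inverse_apply_points(pts.reshape(-1, 3)).reshape(shape4)

    idx = (pts - origin) / spacing  # fractional indices, (nu, nw, nt, 3)
    coords = np.moveaxis(idx, -1, 0)
    samples = map_coordinates(mu, coords, order=1, mode="constant", cval=0.0)
    pixels = samples.sum(axis=-1) * geom.step_length
    return DRRImage(pixels=pixels, pixel_spacing=geom.pixel_spacing, geometry=geom)


def render_ct_drr(
    ct: CTVolume,
    geom: ProjectionGeometry,
    model: AttenuationModel | None = None,
    pose: RigidTransform3D | None = None,
) -> DRRImage:
    """Full-volume DRR (soft tissue included)."""
    return render_drr(hu_to_mu(ct, model), geom, volume=ct, pose=pose)


def render_bone_drr(
    ct: CTVolume,
    label: LabelVolume,
    geom: ProjectionGeometry,
    model: AttenuationModel | None = None,
    pose: RigidTransform3D | None = None,
) -> DRRImage:
    """DRR of the segmented bones only: mu is zeroed outside bone labels."""
    if ct.voxels.shape != label.voxels.shape or not np.allclose(
        ct.spacing, label.spacing
    ) or not np.allclose(ct.origin, label.origin):
        raise PairingError("CT and label volumes do not share a grid")
    mu = hu_to_mu(ct, model)
    mu[~label.bone_mask()] = 0.0
    return render_drr(mu, geom, volume=ct, pose=pose)
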