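"""Procedural wrist phantoms: paired CT-like volume, bone labels, landmarks.

The phantom emulates a posteroanterior view of the distal forearm: two
elongated bones inside an elliptical soft-tissue envelope.

* The radius-like bone is a tapered capped cylinder (frustum) along +Z with a
  hemispherical "styloid" bump on the lateral edge of its distal cap.  The
  hemisphere sits entirely distal to the cap plane, so the analytic solid
  volume is exactly ``pi*L*(r1^2 + r1*r2 + r2^2)/3 + (2/3)*pi*a^3``.
* The ulna-like bone is a cylinder with a spherical "head" at its distal end,
  placed at a configurable azimuth about the radial axis to emulate
  forearm-rotation variability.
* Bone interiors carry trabecular HU with a cortical shell of configurable
  thickness at cortical HU; the envelope carries soft-tissue HU; everything
  else is air.

Distal is +Z in the canonical pose.  ``rasterize_phantom`` can evaluate the
implicit geometry under an arbitrary rigid pose, which yields posed volumes
free of resampling artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import (
    CTVolume,
    DRRImage,
    GeometryError,
    LabelVolume,
    LandmarkSet,
    ParameterError,
)
from .transforms import RigidTransform3D

# Distal recess of the ulna below the radius articular plane, mm.
ULNA_DISTAL_RECESS_MM = 4.0

DEFAULT_HU_LEVELS = {
    "air": -1000.0,
    "soft_tissue": 40.0,
    "trabecular": 300.0,
    "cortical": 1200.0,
}

#: Uniform sampling bounds (low, high) per spec field, in mm / degrees.
DEFAULT_POPULATION = {
    "radius_length": (70.0, 84.0),
    "radius_r_proximal": (7.0, 9.5),
    "radius_taper": (-0.35, -0.1),  # negative: distal end broader, like the metaphysis
    "radius_styloid_amp": (3.0, 5.0),
    "ulna_length": (64.0, 78.0),
    "ulna_radius": (4.5, 6.5),
    "ulna_head_amp": (6.0, 8.5),
    "inter_bone_gap": (2.0, 6.0),
    "ulna_axial_rotation": (-25.0, 25.0),
    "soft_tissue_rx": (32.0, 40.0),
    "soft_tissue_ry": (22.0, 30.0),
    "cortical_thickness": (1.5, 2.5),
}


@dataclass
class PhantomSpec:
    """Parameters fully determining one phantom's geometry and intensities."""

    seed: int = 0
    radius_length: float = 78.0
    radius_r_proximal: float = 8.0
    radius_taper: float = -0.25
    radius_styloid_amp: float = 4.0
    ulna_length: float = 70.0
    ulna_radius: float = 5.5
    ulna_head_amp: float = 7.0
    inter_bone_gap: float = 4.0
    ulna_axial_rotation: float = 15.0
    soft_tissue_rx: float = 36.0
    soft_tissue_ry: float = 26.0
    cortical_thickness: float = 2.0
    hu_levels: dict = field(default_factory=lambda: dict(DEFAULT_HU_LEVELS))

    def __post_init__(self) -> None:
        for name in (
            "radius_length",
            "radius_r_proximal",
            "radius_styloid_amp",
            "ulna_length",
            "ulna_radius",
            "ulna_head_amp",
            "inter_bone_gap",
            "soft_tissue_rx",
            "soft_tissue_ry",
            "cortical_thickness",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be strictly positive")
        if not -1.0 < self.radius_taper < 1.0:
            raise ParameterError("radius_taper must be in (-1, 1)")
        hu = self.hu_levels
        order = [hu["air"], hu["soft_tissue"], hu["trabecular"], hu["cortical"]]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ParameterError(
                "hu_levels must be ordered air < soft_tissue < trabecular < cortical"
            )

    # --- derived geometry -------------------------------------------------
    @property
    def radius_r_distal(self) -> float:
        return self.radius_r_proximal * (1.0 - self.radius_taper)

    @property
    def radius_max_r(self) -> float:
        return max(self.radius_r_proximal, self.radius_r_distal)

    @property
    def axis_separation(self) -> float:
        """Centre-to-centre distance between the two bone axes."""
        return (
            self.radius_max_r
            + max(self.ulna_radius, self.ulna_head_amp)
            + self.inter_bone_gap
        )

    @property
    def radius_axis_xy(self) -> np.ndarray:
        return np.array([self.axis_separation / 2.0, 0.0])

    @property
    def ulna_axis_xy(self) -> np.ndarray:
        th = np.deg2rad(self.ulna_axial_rotation)
        offset = self.axis_separation * np.array([-np.cos(th), -np.sin(th)])
        return self.radius_axis_xy + offset

    @property
    def radius_solid_volume(self) -> float:
        """Closed-form solid volume of the radius-like bone, mm^3."""
        r1, r2 = self.radius_r_proximal, self.radius_r_distal
        frustum = np.pi * self.radius_length * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0
        hemisphere = 2.0 / 3.0 * np.pi * self.radius_styloid_amp**3
        return float(frustum + hemisphere)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)


@dataclass
class DegradationParams:
    """Knobs of the DRR -> X-ray-like degradation model.

    ``clutter_amp`` scales seeded smooth blobs added to the image,
    emulating projections of overlapping structures (carpal bones, tendon
    sheaths) that a plain wrist phantom lacks; unlike a monotone intensity
    map, this structured clutter cannot be undone by histogram matching.
    """

    soft_tissue_weight: float = 1.0
    noise_sigma: float = 0.0
    gamma: float = 1.0
    vignette_strength: float = 0.0
    clutter_amp: float = 0.0
    n_clutter_blobs: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.gamma <= 0:
            raise ParameterError("gamma must be > 0")
        if self.clutter_amp < 0:
            raise ParameterError("clutter_amp must be >= 0")


def sample_phantom_spec(
    seed: int, population: dict | None = None
) -> PhantomSpec:
    """Draw a phantom spec from per-parameter uniform bounds, deterministically.

    ``population`` maps parameter names to ``(low, high)`` bounds; omitted
    parameters use :data:`DEFAULT_POPULATION`.
    """
    if seed < 0:
        raise ParameterError("seed must be >= 0")
    pop = dict(DEFAULT_POPULATION)
    if population:
        unknown = set(population) - set(pop)
        if unknown:
            raise ParameterError(f"unknown population parameters: {sorted(unknown)}")
        pop.update(population)
    for name, (lo, hi) in pop.items():
        if lo > hi:
            raise ParameterError(f"inverted bounds for {name}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    draws = {}
    for name in DEFAULT_POPULATION:  # fixed iteration order => reproducible
        lo, hi = pop[name]
        draws[name] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return PhantomSpec(seed=seed, **draws)


def _frustum_depth(xg, yg, zg, axis_xy, r_lo, r_hi, z_lo, z_hi):
    """Signed inside-depth of a tapered capped cylinder (positive inside)."""
    rho = np.sqrt((xg - axis_xy[0]) ** 2 + (yg - axis_xy[1]) ** 2)
    frac = np.clip((zg - z_lo) / (z_hi - z_lo), 0.0, 1.0)
    r_at = r_lo + (r_hi - r_lo) * frac
    return np.minimum(r_at - rho, np.minimum(zg - z_lo, z_hi - zg))


def _sphere_depth(xg, yg, zg, center, radius):
    d = np.sqrt((xg - center[0]) ** 2 + (yg - center[1]) ** 2 + (zg - center[2]) ** 2)
    return radius - d


def compute_landmarks(spec: PhantomSpec) -> LandmarkSet:
    """Analytic landmarks of the canonical-pose phantom."""
    L = spec.radius_length
    ax = spec.radius_axis_xy
    z_top = L / 2.0
    a = spec.radius_styloid_amp
    styloid_tip = np.array([ax[0] + spec.radius_r_distal - a, ax[1], z_top + a])
    u = spec.ulna_axis_xy - ax
    u = u / np.linalg.norm(u)
    z_notch = z_top - 3.0
    frac = (z_notch + z_top) / L
    r_at = spec.radius_r_proximal + (spec.radius_r_distal - spec.radius_r_proximal) * frac
    notch = np.array([ax[0] + u[0] * r_at, ax[1] + u[1] * r_at, z_notch])
    shaft = np.array(
        [[ax[0], ax[1], -z_top + 5.0], [ax[0], ax[1], z_top - 10.0]]
    )
    articular = np.array([ax[0], ax[1], z_top])
    return LandmarkSet(
        styloid_point=styloid_tip,
        sigmoid_notch_point=notch,
        shaft_axis_points=shaft,
        articular_surface_point=articular,
    )


def rasterize_phantom(
    spec: PhantomSpec,
    shape: tuple = (96, 96, 96),
    spacing: float | tuple = 1.0,
    pose: RigidTransform3D | None = None,
) -> tuple[CTVolume, LabelVolume, LandmarkSet]:
    """Voxelize the phantom's implicit geometry onto a centred grid.

    With ``pose`` given, the phantom is rigidly moved by it before
    voxelization (the implicit functions are evaluated at the inversely
    transformed grid points), and the returned landmarks are the posed ones.
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise ParameterError("spacing must be positive")

    origin = -spacing * (np.asarray(shape) - 1) / 2.0
    half_extent = spacing * (np.asarray(shape) - 1) / 2.0

    # Canonical-pose bone extents must fit in the grid (pose only rotates
    # within roughly the same bounding ball, checked conservatively).
    z_top = spec.radius_length / 2.0 + spec.radius_styloid_amp
    lateral = spec.axis_separation / 2.0 + max(
        spec.radius_max_r, spec.ulna_radius, spec.ulna_head_amp
    )
    if z_top > half_extent[2] + 1e-9:
        raise GeometryError(
            f"bone z-extent {z_top:.1f} mm exceeds grid half-extent "
            f"{half_extent[2]:.1f} mm"
        )
    if lateral > min(half_extent[0], half_extent[1]) + 1e-9:
        raise GeometryError(
            f"bone lateral extent {lateral:.1f} mm exceeds grid half-extent "
            f"{min(half_extent[0], half_extent[1]):.1f} mm"
        )

    xs = origin[0] + spacing[0] * np.arange(shape[0])
    ys = origin[1] + spacing[1] * np.arange(shape[1])
    zs = origin[2] + spacing[2] * np.arange(shape[2])
    xg, yg, zg = np.meshgrid(xs, ys, zs, indexing="ij")
    if pose is not None:
        pts = np.stack([xg, yg, zg], axis=-1).reshape(-1, 3)
        pts = pose.inverse_apply_points(pts).reshape(*shape, 3)
        xg, yg, zg = pts[..., 0], pts[..., 1], pts[..., 2]

    L = spec.radius_length
    rad_depth = _frustum_depth(
        xg,
        yg,
        zg,
        spec.radius_axis_xy,
        spec.radius_r_proximal,
        spec.radius_r_distal,
        -L / 2.0,
        L / 2.0,
    )
    a = spec.radius_styloid_amp
    sty_center = (
        spec.radius_axis_xy[0] + spec.radius_r_distal - a,
        spec.radius_axis_xy[1],
        L / 2.0,
    )
    sty_depth = np.where(
        zg >= L / 2.0, _sphere_depth(xg, yg, zg, sty_center, a), -np.inf
    )
    radius_depth = np.maximum(rad_depth, sty_depth)

    z_u_top = L / 2.0 - ULNA_DISTAL_RECESS_MM
    uln_depth = _frustum_depth(
        xg,
        yg,
        zg,
        spec.ulna_axis_xy,
        spec.ulna_radius,
        spec.ulna_radius,
        z_u_top - spec.ulna_length,
        z_u_top,
    )
    head_center = (spec.ulna_axis_xy[0], spec.ulna_axis_xy[1], z_u_top)
    head_depth = _sphere_depth(xg, yg, zg, head_center, spec.ulna_head_amp)
    ulna_depth = np.maximum(uln_depth, head_depth)

    soft_center = (spec.radius_axis_xy + spec.ulna_axis_xy) / 2.0
    soft = (
        ((xg - soft_center[0]) / spec.soft_tissue_rx) ** 2
        + ((yg - soft_center[1]) / spec.soft_tissue_ry) ** 2
        <= 1.0
    ) & (zg >= -L / 2.0 - 3.0) & (zg <= L / 2.0 + a + 3.0)

    hu = spec.hu_levels
    ct = np.full(shape, hu["air"], dtype=np.float32)
    ct[soft] = hu["soft_tissue"]
    t = spec.cortical_thickness
    for depth in (radius_depth, ulna_depth):
        inside = depth > 0
        ct[inside & (depth <= t)] = hu["cortical"]
        ct[depth > t] = hu["trabecular"]

    labels = np.zeros(shape, dtype=np.uint8)
    labels[ulna_depth > 0] = LabelVolume.ULNA
    labels[radius_depth > 0] = LabelVolume.RADIUS  # radius wins ties (disjoint anyway)

    lm = compute_landmarks(spec)
    if pose is not None:
        lm = lm.transformed(pose)

    ct_vol = CTVolume(voxels=ct, spacing=spacing, origin=origin)
    label_vol = LabelVolume(voxels=labels, spacing=spacing, origin=origin)
    return ct_vol, label_vol, lm


def degrade_to_xray(clean_full_drr: DRRImage, params: DegradationParams) -> DRRImage:
    """Turn a clean full-volume DRR into an "actual X-ray"-like image.

    The model applies, in order: a global soft-tissue weight, a gamma map of
    normalized intensity, seeded smooth clutter blobs (overlapping-structure
    surrogate), a radial vignette, and seeded additive Gaussian noise.
    Identity settings (weight 1, sigma 0, gamma 1, vignette 0, clutter 0)
    return the input unchanged.  Output may contain small negative values
    where noise undershoots zero background.
    """
    img = np.asarray(clean_full_drr.pixels, dtype=np.float64)
    if not np.all(np.isfinite(img)) or img.min() < 0:
        raise ParameterError("clean DRR must be finite and non-negative")
    peak = float(img.max())
    scale = peak if peak > 0 else 1.0
    out = scale * (params.soft_tissue_weight * img / scale) ** params.gamma
    h, w = img.shape
    rng = np.random.default_rng(params.seed)
    if params.clutter_amp > 0:
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        clutter = np.zeros_like(out)
        for _ in range(params.n_clutter_blobs):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            # broad blobs: strong intensity corruption, weak gradient energy
            # (overlapping soft structures are smooth compared to bone edges)
            sig = rng.uniform(0.15, 0.35) * max(h, w)
            amp = rng.uniform(0.3, 1.0) * params.clutter_amp * scale
            clutter += amp * np.exp(
                -(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sig * sig))
            )
        out = out + clutter
    if params.vignette_strength != 0.0:
        yy, xx = np.mgrid[0:h, 0:w]
        rr2 = ((yy - (h - 1) / 2) / (h / 2)) ** 2 + ((xx - (w - 1) / 2) / (w / 2)) ** 2
        out = out * (1.0 - params.vignette_strength * rr2 / 2.0)
    if params.noise_sigma > 0:
        out = out + rng.normal(0.0, params.noise_sigma, size=img.shape)
    return DRRImage(pixels=out, pixel_spacing=clean_full_drr.pixel_spacing)
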