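"""Intensity-based 2D-3D rigid registration with gradient correlation.

The similarity between two images is the mean of the Pearson correlations
of their horizontal and vertical central-difference gradient images — a
metric invariant to affine intensity rescaling, which is what makes
registering a clean bone DRR against a degraded X-ray-like target safe.

``register`` searches rigid pose space for the pose whose bone DRR best
matches the target.  Maximizing gradient correlation is reformulated as a
nonlinear least-squares problem on the unit-normalized gradient images
(algebraically the same objective), because out-of-plane rotations of
near-cylindrical bones leave only a faint, strongly curved valley in the
similarity that defeats direct scalar search; a derivative-free Powell
search on a coarsened image level serves as the capture stage when the
least-squares path starts outside its basin.  With the default orthographic
geometry, translation
along the viewing direction does not change the projection at all, so that
degree of freedom is excluded from the search by default (the capture range
for the remaining five is about 10 mm / 10 deg).  Non-convergence never
raises: the best pose seen is returned with ``converged=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import (
    CTVolume,
    DRRImage,
    DegenerateInputError,
    LabelVolume,
    PairingError,
)
from .drr import AttenuationModel, ProjectionGeometry, hu_to_mu, render_drr
from .transforms import RigidTransform3D


@dataclass
class RegistrationResult:
    transform: RigidTransform3D
    similarity: float
    iterations: int
    converged: bool


def gradient_correlation(a: DRRImage | np.ndarray, b: DRRImage | np.ndarray) -> float:
    """Mean Pearson correlation of the two central-difference gradient images."""
    pa = np.asarray(a.pixels if isinstance(a, DRRImage) else a, dtype=np.float64)
    pb = np.asarray(b.pixels if isinstance(b, DRRImage) else b, dtype=np.float64)
    if pa.shape != pb.shape:
        raise PairingError(f"image shapes differ: {pa.shape} vs {pb.shape}")
    corrs = []
    for axis in (0, 1):
        ga = np.gradient(pa, axis=axis).ravel()
        gb = np.gradient(pb, axis=axis).ravel()
        sa, sb = ga.std(), gb.std()
        if sa < 1e-14 or sb < 1e-14:
            raise DegenerateInputError(
                "constant image: gradient variance is zero along axis %d" % axis
            )
        corrs.append(float(np.mean((ga - ga.mean()) * (gb - gb.mean())) / (sa * sb)))
    return float(np.mean(corrs))


def _coarsen_geometry(geom: ProjectionGeometry) -> ProjectionGeometry:
    return ProjectionGeometry(
        mode=geom.mode,
        view_direction=geom.view_direction,
        detector_shape=tuple(max(2, s // 2) for s in geom.detector_shape),
        pixel_spacing=geom.pixel_spacing * 2.0,
        detector_center=geom.detector_center,
        source_distance=geom.source_distance,
        step_length=geom.step_length,
    )


def _block_mean_2x(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    h2, w2 = h - h % 2, w - w % 2
    return img[:h2, :w2].reshape(h2 // 2, 2, w2 // 2, 2).mean(axis=(1, 3))


def default_free_params(geom: ProjectionGeometry) -> np.ndarray:
    """Boolean mask over (rx, ry, rz, tx, ty, tz); excludes the view-axis
    translation for orthographic geometries (it is unobservable)."""
    free = np.ones(6, dtype=bool)
    if geom.mode == "orthographic":
        free[3 + int(np.argmax(np.abs(geom.view_direction)))] = False
    return free


def register(
    ct: CTVolume,
    label: LabelVolume,
    target: DRRImage,
    geom: ProjectionGeometry,
    init: RigidTransform3D | None = None,
    model: AttenuationModel | None = None,
    free_params: np.ndarray | None = None,
    max_iter: int = 60,
    moving: str = "bone",
) -> RegistrationResult:
    """Find the rigid pose whose DRR best matches ``target``.

    ``moving`` selects the rendered image driving the similarity: ``"bone"``
    (attenuation outside the bone labels zeroed) when the target is itself a
    segmented DRR, or ``"full"`` when the target is a radiograph-like image
    whose soft-tissue edges carry alignment signal too.
    """
    if ct.voxels.shape != label.voxels.shape:
        raise PairingError("CT and label volumes do not share a grid")
    if tuple(target.pixels.shape) != tuple(geom.detector_shape):
        raise PairingError("target image does not match the detector geometry")
    if moving not in ("bone", "full"):
        raise PairingError(f"unknown moving-image mode {moving!r}")
    if init is None:
        init = RigidTransform3D.identity()
    if free_params is None:
        free_params = default_free_params(geom)
    free_idx = np.flatnonzero(np.asarray(free_params, dtype=bool))

    mu = hu_to_mu(ct, model)
    if moving == "bone":
        mu[~label.bone_mask()] = 0.0
    tgt = np.asarray(target.pixels, dtype=np.float64)
    tmax = tgt.max()
    tgt_norm = tgt / tmax if tmax > 0 else tgt

    base = init.as_params()
    evals = [0]

    def _unit_gradients(pix: np.ndarray) -> list[np.ndarray] | None:
        out = []
        for axis in (0, 1):
            g = np.gradient(pix, axis=axis).ravel()
            g = g - g.mean()
            n = np.linalg.norm(g)
            if n < 1e-14:
                return None
            out.append(g / n)
        return out

    tgt_units = _unit_gradients(tgt_norm)
    if tgt_units is None:
        raise DegenerateInputError("target image has zero gradient variance")

    def render_at(p_free: np.ndarray, geom_level) -> np.ndarray:
        params = base.copy()
        params[free_idx] = p_free
        evals[0] += 1
        return render_drr(
            mu, geom_level, volume=ct, pose=RigidTransform3D.from_params(params)
        ).pixels

    # Maximizing gradient correlation == minimizing the SSD between the
    # mean-removed, unit-norm gradient images (|r|^2 = 2 * (1 - GC) per
    # axis), which a least-squares solver navigates far more reliably than
    # a direct scalar search on the nearly flat similarity ridge.
    def residuals(p_free: np.ndarray) -> np.ndarray:
        units = _unit_gradients(render_at(p_free, geom))
        if units is None:  # bones fully out of frame
            return np.full(2 * tgt_norm.size, 1.0)
        return np.concatenate([u - t for u, t in zip(units, tgt_units)])

    def gc_of(p_free: np.ndarray) -> float:
        try:
            return gradient_correlation(render_at(p_free, geom), tgt_norm)
        except DegenerateInputError:
            return -1.0

    def refine(p0: np.ndarray) -> tuple[np.ndarray, bool]:
        ls = optimize.least_squares(
            residuals,
            p0,
            diff_step=0.1,
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-14,
            max_nfev=40 * max_iter // 6 + len(p0) * 20,
        )
        return np.asarray(ls.x, dtype=float).reshape(-1), bool(ls.status > 0)

    p_init = base[free_idx].copy()
    sim_init = gc_of(p_init)
    p_best, ok_best = refine(p_init)
    sim_best = gc_of(p_best)
    if sim_best < max(0.8, sim_init):
        # Capture stage: coarse-level Powell search on the similarity, then
        # a fresh least-squares refinement from the captured pose.  Only
        # needed when the direct refinement left little correlation — e.g.
        # an initialization outside the least-squares basin.
        geom_c = _coarsen_geometry(geom)
        tgt_c = _block_mean_2x(tgt_norm)

        def coarse_obj(p_free: np.ndarray) -> float:
            try:
                return -gradient_correlation(render_at(p_free, geom_c), tgt_c)
            except DegenerateInputError:
                return 1.0

        res = optimize.minimize(
            coarse_obj,
            p_init,
            method="Powell",
            options={"maxiter": max_iter, "xtol": 1e-2, "ftol": 1e-5},
        )
        p_alt, ok_alt = refine(np.asarray(res.x, dtype=float).reshape(-1))
        sim_alt = gc_of(p_alt)
        if sim_alt > sim_best:
            p_best, ok_best, sim_best = p_alt, ok_alt, sim_alt

    final_params = base.copy()
    final_params[free_idx] = p_best
    final = RigidTransform3D.from_params(final_params)
    if sim_best < sim_init:  # ascent contract: never return worse than init
        return RegistrationResult(
            transform=init, similarity=sim_init, iterations=evals[0], converged=False
        )
    return RegistrationResult(
        transform=final,
        similarity=sim_best,
        iterations=evals[0],
        converged=ok_best,
    )


def make_registration_drr(
    ct: CTVolume,
    label: LabelVolume,
    transform: RigidTransform3D,
    geom: ProjectionGeometry,
    model: AttenuationModel | None = None,
) -> DRRImage:
    """Bone DRR rendered at a registered pose (the paired-training target)."""
    mu = hu_to_mu(ct, model)
    mu[~label.bone_mask()] = 0.0
    return render_drr(mu, geom, volume=ct, pose=transform)
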