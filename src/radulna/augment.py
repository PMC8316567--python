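"""Data augmentation and patient-level dataset splitting.

Two regimes, mirroring the two training datasets of the pipeline:

* 3D rigid augmentation for the reconstruction network: the normalized
  volume is rigidly posed (default ±30°, ±30 mm per axis) *before* DRR
  rendering, and each posed bone DRR is paired with the unposed normalized
  label — the network learns pose-robust shape recovery.
* 2D affine augmentation for translation pairs: the same sampled affine is
  applied to both members of an (X-ray-like, registration-DRR) pair so the
  pairing survives augmentation.

Splitting is patient-level throughout: all augmented items derived from one
source patient land on the same side of every train/validation/test divide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform

from .core import DRRImage, LabelVolume, PairingError, ParameterError
from .drr import AttenuationModel, ProjectionGeometry, render_bone_drr
from .frames import NormalizedSample
from .transforms import (
    Affine2D,
    RigidTransform3D,
    sample_affine2d,
    sample_rigid_transforms,
)

DEFAULT_ROTATION_RANGE_DEG = 30.0
DEFAULT_TRANSLATION_RANGE_MM = 30.0


def augment_3d(
    sample: NormalizedSample,
    geom: ProjectionGeometry,
    model: AttenuationModel | None = None,
    factor: int = 40,
    rotation_range_deg: float = DEFAULT_ROTATION_RANGE_DEG,
    translation_range_mm: float = DEFAULT_TRANSLATION_RANGE_MM,
    seed: int = 0,
) -> list[tuple[RigidTransform3D, DRRImage, LabelVolume]]:
    """Render ``factor`` rigidly posed bone DRRs of one normalized sample.

    Returns ``factor`` triples of (sampled transform, posed bone DRR,
    unposed normalized label).  Deterministic in ``seed``.
    """
    if factor < 1:
        raise ParameterError(f"factor must be >= 1, got {factor}")
    transforms = sample_rigid_transforms(
        factor, rotation_range_deg, translation_range_mm, seed=seed
    )
    out = []
    for tf in transforms:
        drr = render_bone_drr(sample.ct, sample.label, geom, model, pose=tf)
        out.append((tf, drr, sample.label))
    return out


def centered_matrix(aff: Affine2D, shape: tuple, spacing) -> np.ndarray:
    """Homogeneous mm-space map of ``aff`` applied about the image centre."""
    sp = np.asarray(spacing, dtype=float)
    c = np.array([(shape[0] - 1) / 2.0 * sp[0], (shape[1] - 1) / 2.0 * sp[1]])
    M = aff.matrix
    A, t = M[:2, :2], M[:2, 2]
    G = np.eye(3)
    G[:2, :2] = A
    G[:2, 2] = c + t - A @ c
    return G


def warp_image_matrix(img: DRRImage, G: np.ndarray) -> DRRImage:
    """Warp by a forward homogeneous mm-space affine: out(q) = in(G^-1 q)."""
    sp = img.pixel_spacing
    Ginv = np.linalg.inv(np.asarray(G, dtype=float))
    S = np.diag(sp)
    Sinv = np.diag(1.0 / sp)
    m_idx = Sinv @ Ginv[:2, :2] @ S
    off = Sinv @ Ginv[:2, 2]
    warped = affine_transform(
        img.pixels, m_idx, offset=off, order=1, mode="constant", cval=0.0
    )
    return DRRImage(pixels=warped, pixel_spacing=sp)


def _warp_image(img: DRRImage, aff: Affine2D) -> DRRImage:
    """Apply a 2D affine about the image centre (mm units), trilinear."""
    G = centered_matrix(aff, img.pixels.shape, img.pixel_spacing)
    return warp_image_matrix(img, G)


def warp_pair(
    xray: DRRImage, drr: DRRImage, aff: Affine2D
) -> tuple[DRRImage, DRRImage]:
    """Warp both members of a pair by the same affine."""
    if xray.pixels.shape != drr.pixels.shape or not np.allclose(
        xray.pixel_spacing, drr.pixel_spacing
    ):
        raise PairingError("pair members must share shape and pixel spacing")
    return _warp_image(xray, aff), _warp_image(drr, aff)


def augment_2d_pairs(
    pairs: list[tuple[DRRImage, DRRImage]],
    factor: int = 100,
    translation_range_mm: float = 10.0,
    rotation_range_deg: float = 10.0,
    scale_range: tuple = (0.9, 1.1),
    shear_range_deg: float = 5.0,
    seed: int = 0,
    return_transforms: bool = False,
):
    """Expand (X-ray, registration-DRR) pairs ``factor``-fold by shared affines.

    Output count is exactly ``len(pairs) * factor``; the same affine warps
    both members of each output pair.
    """
    if factor < 1:
        raise ParameterError(f"factor must be >= 1, got {factor}")
    rng = np.random.default_rng(seed)
    out, used = [], []
    for xray, drr in pairs:
        affs = sample_affine2d(
            factor,
            translation_range_mm,
            rotation_range_deg,
            scale_range,
            shear_range_deg,
            rng=rng,
        )
        for aff in affs:
            out.append(warp_pair(xray, drr, aff))
            used.append(aff)
    if return_transforms:
        return out, used
    return out


@dataclass
class SplitPlan:
    """Patient-level cross-validation plan.

    ``test_folds[k]`` lists the patients whose (augmented) items form fold
    k's test set; for fold k the remaining patients are divided into
    ``train_patients[k]`` and ``val_patients[k]``.  No patient ever appears
    on both sides of any divide.
    """

    folds: int
    test_folds: list = field(default_factory=list)
    train_patients: list = field(default_factory=list)
    val_patients: list = field(default_factory=list)

    def all_patients(self) -> set:
        return set().union(*map(set, self.test_folds)) if self.test_folds else set()


def make_split(
    patient_ids,
    folds: int = 4,
    val_frac: float = 0.15,
    seed: int = 0,
) -> SplitPlan:
    """Deterministic patient-level k-fold split with a validation holdout.

    Per fold, ~1/folds of patients are test; of the rest, ~``val_frac`` are
    validation and the remainder training — all at patient granularity.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ParameterError("patient ids must be unique")
    if len(ids) < folds:
        raise ParameterError(f"need at least {folds} patients, got {len(ids)}")
    if not 0 <= val_frac < 1:
        raise ParameterError("val_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_folds = [order[k::folds] for k in range(folds)]
    train_patients, val_patients = [], []
    for k in range(folds):
        rest = [p for p in order if p not in set(test_folds[k])]
        n_val = int(round(val_frac * len(rest)))
        n_val = min(max(n_val, 1 if val_frac > 0 and len(rest) > 1 else 0), len(rest) - 1)
        val_patients.append(rest[:n_val])
        train_patients.append(rest[n_val:])
    return SplitPlan(
        folds=folds,
        test_folds=test_folds,
        train_patients=train_patients,
        val_patients=val_patients,
    )
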