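"""Evaluation machinery: MAE, marching-cubes surfaces, the average
symmetric surface distance (ASD), the histogram-matched baseline, and the
multi-condition experiment report.

ASD between two surface point clouds S_A, S_B is

    ASD = ( sum_{p in A} min_{q in B} d(p,q) + sum_{q in B} min_{p in A} d(p,q) )
          / (|A| + |B|)

with d the Euclidean distance in mm.  Surfaces are marching-cubes vertex
clouds of the binarized class at iso level 0.5, scaled by voxel spacing.
Nearest neighbours are found with a KD-tree; the test suite keeps an
exhaustive double-loop oracle that must agree to 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .core import (
    DRRImage,
    DegenerateInputError,
    LabelVolume,
    ParameterError,
)


@dataclass
class SurfacePointCloud:
    """Points (mm) on one bone surface, tagged with their class id."""

    points: np.ndarray
    class_id: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.points.shape[0] < 4:
            raise DegenerateInputError(
                f"a valid surface needs >= 4 points, got {self.points.shape[0]}"
            )
        if not np.all(np.isfinite(self.points)):
            raise DegenerateInputError("surface points must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


def mae(a: DRRImage | np.ndarray, b: DRRImage | np.ndarray) -> float:
    """Mean absolute pixel difference."""
    pa = np.asarray(a.pixels if isinstance(a, DRRImage) else a, dtype=np.float64)
    pb = np.asarray(b.pixels if isinstance(b, DRRImage) else b, dtype=np.float64)
    if pa.shape != pb.shape:
        raise ParameterError(f"image shapes differ: {pa.shape} vs {pb.shape}")
    return float(np.mean(np.abs(pa - pb)))


def surface_from_label(
    label: LabelVolume, class_id: int, iso: float = 0.5
) -> SurfacePointCloud:
    """Marching-cubes vertex cloud of one class, in world mm.

    The binary mask is zero-padded by one voxel so surfaces touching the
    grid boundary close properly.
    """
    mask = (label.voxels == class_id).astype(np.float64)
    if not mask.any():
        raise DegenerateInputError(f"class {class_id} is empty in this volume")
    padded = np.pad(mask, 1, mode="constant")
    verts, _, _, _ = marching_cubes(padded, level=iso, spacing=tuple(label.spacing))
    verts = verts - label.spacing  # undo the one-voxel pad offset
    points = verts + label.origin
    return SurfacePointCloud(points=points, class_id=class_id)


def asd(sa: SurfacePointCloud, sb: SurfacePointCloud) -> float:
    """Average symmetric surface distance in mm."""
    a, b = sa.points, sb.points
    d_ab = cKDTree(b).query(a, k=1)[0]
    d_ba = cKDTree(a).query(b, k=1)[0]
    return float((d_ab.sum() + d_ba.sum()) / (len(a) + len(b)))


def histogram_match_baseline(
    xray: DRRImage, template: DRRImage, bone_mask: np.ndarray
) -> DRRImage:
    """Bone-segmented, histogram-matched baseline image.

    Within ``bone_mask``, intensities are remapped so their empirical CDF
    matches the template's within-mask CDF (256-point quantile mapping);
    outside the mask the output is exactly zero.
    """
    mask = np.asarray(bone_mask, dtype=bool)
    if mask.shape != xray.pixels.shape:
        raise ParameterError("mask shape must match image shape")
    if mask.shape != template.pixels.shape:
        raise ParameterError("template shape must match image shape")
    if not mask.any():
        raise DegenerateInputError("bone mask is empty")
    src = np.asarray(xray.pixels, dtype=np.float64)[mask]
    tmpl = np.asarray(template.pixels, dtype=np.float64)[mask]
    q = np.linspace(0.0, 1.0, 256)
    tmpl_q = np.quantile(tmpl, q)
    order = np.sort(src)
    # Empirical CDF position of each source pixel among the masked values.
    pos = np.searchsorted(order, src, side="right") - 1
    cdf = pos / max(len(src) - 1, 1)
    mapped = np.interp(cdf, q, tmpl_q)
    out = np.zeros_like(np.asarray(xray.pixels, dtype=np.float64))
    out[mask] = mapped
    return DRRImage(pixels=out, pixel_spacing=xray.pixel_spacing)


BONE_NAMES = {LabelVolume.RADIUS: "radius", LabelVolume.ULNA: "ulna"}


@dataclass
class EvalReport:
    """Per-case ASD/MAE rows plus recomputable aggregates."""

    rows: pd.DataFrame
    conditions: list = field(default_factory=list)

    def aggregates(self) -> pd.DataFrame:
        g = self.rows.groupby(["condition", "bone"])["asd_mm"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        return out.rename(columns={"mean": "asd_mean_mm", "std": "asd_sd_mm"})

    def mean_asd(self, condition: str, bone: str) -> float:
        sel = self.rows[(self.rows.condition == condition) & (self.rows.bone == bone)]
        return float(sel["asd_mm"].mean())

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def run_experiment(cases: list, reconstruct_fn) -> EvalReport:
    """Evaluate 2D-3D reconstruction for several input conditions.

    ``cases`` is a list of dicts with keys:

    * ``case_id``
    * ``truth``: ground-truth LabelVolume on the reconstruction grid
    * ``images``: mapping of condition name -> DRRImage (all cases must
      provide the same conditions)
    * optionally ``reference``: clean DRRImage against which each condition
      image's MAE is reported

    ``reconstruct_fn(image) -> LabelVolume`` is the trained reconstruction
    path.  Returns per-case, per-bone ASD rows and (if references given)
    image MAE, with aggregates recomputable from the rows.
    """
    if not cases:
        raise ParameterError("no cases given")
    conditions = sorted(cases[0]["images"].keys())
    for case in cases:
        if sorted(case["images"].keys()) != conditions:
            raise ParameterError(
                f"case {case.get('case_id')} is missing conditions: "
                f"expected {conditions}, got {sorted(case['images'].keys())}"
            )
    records = []
    for case in cases:
        truth = case["truth"]
        truth_surfaces = {
            b: surface_from_label(truth, b) for b in BONE_NAMES if (truth.voxels == b).any()
        }
        for cond in conditions:
            img = case["images"][cond]
            pred = reconstruct_fn(img)
            img_mae = (
                mae(img, case["reference"]) if case.get("reference") is not None else np.nan
            )
            for bone_id, bone_name in BONE_NAMES.items():
                if bone_id not in truth_surfaces:
                    continue
                pred_surface = surface_from_label(pred, bone_id)
                records.append(
                    {
                        "case_id": case["case_id"],
                        "condition": cond,
                        "bone": bone_name,
                        "asd_mm": asd(pred_surface, truth_surfaces[bone_id]),
                        "mae": img_mae,
                    }
                )
    return EvalReport(rows=pd.DataFrame.from_records(records), conditions=conditions)
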