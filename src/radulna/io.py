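"""File I/O: volumes as NIfTI/MetaImage via SimpleITK, DRR images as 16-bit
PNG with a JSON sidecar (pixel spacing + intensity scale), landmarks and
specs as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from PIL import Image

from .core import CTVolume, DRRImage, LabelVolume, LandmarkSet


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def save_volume(vol: CTVolume | LabelVolume, path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(vol.voxels, vol.spacing, vol.origin), str(path))


def load_ct(path: str | Path) -> CTVolume:
    img = sitk.ReadImage(str(path))
    voxels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return CTVolume(
        voxels=voxels.astype(np.float32),
        spacing=np.asarray(img.GetSpacing()),
        origin=np.asarray(img.GetOrigin()),
    )


def load_label(path: str | Path) -> LabelVolume:
    img = sitk.ReadImage(str(path))
    voxels = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return LabelVolume(
        voxels=voxels.astype(np.uint8),
        spacing=np.asarray(img.GetSpacing()),
        origin=np.asarray(img.GetOrigin()),
    )


def save_drr(img: DRRImage, path: str | Path) -> None:
    """16-bit PNG plus `<path>.json` sidecar with spacing and scale."""
    path = Path(path)
    lo = float(min(img.pixels.min(), 0.0))
    hi = float(img.pixels.max())
    span = hi - lo if hi > lo else 1.0
    quantized = np.round((img.pixels - lo) / span * 65535).astype(np.uint16)
    Image.fromarray(quantized).save(path)
    sidecar = {
        "pixel_spacing_mm": img.pixel_spacing.tolist(),
        "intensity_offset": lo,
        "intensity_span": span,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_drr(path: str | Path) -> DRRImage:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raw = np.asarray(Image.open(path), dtype=np.float64)
    pixels = raw / 65535.0 * sidecar["intensity_span"] + sidecar["intensity_offset"]
    return DRRImage(pixels=pixels, pixel_spacing=np.asarray(sidecar["pixel_spacing_mm"]))


def save_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "styloid_point": lm.styloid_point.tolist(),
                "sigmoid_notch_point": lm.sigmoid_notch_point.tolist(),
                "shaft_axis_points": lm.shaft_axis_points.tolist(),
                "articular_surface_point": lm.articular_surface_point.tolist(),
            },
            indent=2,
        )
    )


def load_landmarks(path: str | Path) -> LandmarkSet:
    d = json.loads(Path(path).read_text())
    return LandmarkSet(
        styloid_point=d["styloid_point"],
        sigmoid_notch_point=d["sigmoid_notch_point"],
        shaft_axis_points=d["shaft_axis_points"],
        articular_surface_point=d["articular_surface_point"],
    )
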