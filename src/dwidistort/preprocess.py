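"""Data preparation: resampling into reference space, prostate-centred
cropping, and training-derived min-max normalization.

Resampling standardizes DWI volumes onto the T2-weighted grid at
0.5 × 0.5 × 3 mm voxels (trilinear for images, nearest for masks).
Cropping keeps a window equal to the prostate bounding box scaled by a
factor (default 2) about its centre. Normalization min/max are pooled over
prostate-region intensities of a fitting (training) set and applied as a
fixed affine map to any other volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from nibabel import processing as nibproc

__all__ = [
    "NormalizationParams",
    "CropRecord",
    "resample_to_reference",
    "crop_to_prostate",
    "uncrop",
    "fit_normalization",
    "apply_normalization",
    "pad_to_canvas",
    "DEFAULT_SPACING_MM",
]

DEFAULT_SPACING_MM = (0.5, 0.5, 3.0)


def _check_spatial(img: nib.Nifti1Image, name: str) -> None:
    if img.affine is None:
        raise ValueError(f"{name} image has no valid spatial metadata (affine)")
    aff = np.asarray(img.affine, float)
    if not np.all(np.isfinite(aff)) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
        raise ValueError(f"{name} image has no valid spatial metadata (affine)")


def resample_to_reference(
    moving: nib.Nifti1Image,
    reference: nib.Nifti1Image,
    spacing_mm=DEFAULT_SPACING_MM,
    mode: str = "image",
) -> nib.Nifti1Image:
    """Resample ``moving`` onto the reference grid standardized to
    ``spacing_mm`` voxels.

    ``mode='image'`` uses trilinear interpolation; ``mode='mask'`` uses
    nearest-neighbour (binarity preserved). Pass ``spacing_mm=None`` to keep
    the reference grid as-is.
    """
    _check_spatial(moving, "moving")
    _check_spatial(reference, "reference")
    if mode == "image":
        order = 1
    elif mode == "mask":
        order = 0
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'image' or 'mask'")
    target = reference
    if spacing_mm is not None:
        zooms = np.asarray(reference.header.get_zooms()[:3], float)
        if not np.allclose(zooms, spacing_mm):
            target = nibproc.resample_to_output(
                reference, voxel_sizes=spacing_mm, order=1
            )
    return nibproc.resample_from_to(moving, target, order=order, cval=0.0)


@dataclass
class CropRecord:
    """Exact placement of a crop window within its original volume."""

    original_shape: tuple[int, ...]
    starts: tuple[int, ...]
    stops: tuple[int, ...]

    @property
    def slices(self) -> tuple[slice, ...]:
        return tuple(slice(a, b) for a, b in zip(self.starts, self.stops))


def crop_to_prostate(
    volume: np.ndarray, prostate_mask: np.ndarray, factor: float = 2.0
) -> tuple[np.ndarray, CropRecord]:
    """Crop to the prostate bounding box scaled by ``factor`` about its
    centre, clamped to the grid. ``factor=1`` is the exact bounding box."""
    volume = np.asarray(volume)
    mask = np.asarray(prostate_mask, bool)
    if mask.shape != volume.shape[: mask.ndim]:
        raise ValueError("mask shape must match the leading volume axes")
    if not mask.any():
        raise ValueError("prostate mask is empty")
    if factor < 1.0:
        raise ValueError("factor must be >= 1")
    starts, stops = [], []
    idx = np.nonzero(mask)
    for ax in range(mask.ndim):
        lo, hi = int(idx[ax].min()), int(idx[ax].max())
        centre = (lo + hi + 1) / 2.0
        half = (hi + 1 - lo) * factor / 2.0
        a = max(int(np.floor(centre - half)), 0)
        b = min(int(np.ceil(centre + half)), volume.shape[ax])
        starts.append(a)
        stops.append(b)
    rec = CropRecord(tuple(volume.shape), tuple(starts), tuple(stops))
    return volume[rec.slices], rec


def uncrop(cropped: np.ndarray, record: CropRecord, fill=0) -> np.ndarray:
    """Place a cropped array back into a full-size canvas."""
    out = np.full(record.original_shape, fill, dtype=np.asarray(cropped).dtype)
    out[record.slices] = cropped
    return out


@dataclass
class NormalizationParams:
    min_val: float
    max_val: float
    clip: bool = False

    def __post_init__(self) -> None:
        if not self.max_val > self.min_val:
            raise ValueError("max_val must exceed min_val (degenerate range)")


def fit_normalization(cases, clip: bool = False) -> NormalizationParams:
    """Pool prostate-region intensities over a fitting set.

    ``cases`` is an iterable of ``(volume, prostate_mask)`` pairs or of
    :class:`~dwidistort.phantom.PhantomCase` objects (whose DWI channels are
    pooled within the prostate mask).
    """
    lo, hi = np.inf, -np.inf
    n = 0
    for item in cases:
        if hasattr(item, "dwi"):  # PhantomCase
            mask = np.asarray(item.prostate_mask.data, bool)
            vals = np.asarray(item.dwi.data)[:, mask]
        else:
            volume, mask = item
            volume = np.asarray(volume)
            mask = np.asarray(mask, bool)
            if volume.shape == mask.shape:
                vals = volume[mask]
            elif volume.shape[1:] == mask.shape:  # channels-first stack
                vals = volume[:, mask]
            else:
                raise ValueError("volume and mask shapes are incompatible")
        if vals.size:
            lo = min(lo, float(vals.min()))
            hi = max(hi, float(vals.max()))
            n += vals.size
    if n == 0:
        raise ValueError("no prostate-region intensities in the fitting set")
    return NormalizationParams(lo, hi, clip=clip)


def apply_normalization(volume: np.ndarray, params: NormalizationParams) -> np.ndarray:
    out = (np.asarray(volume, float) - params.min_val) / (
        params.max_val - params.min_val
    )
    if params.clip:
        out = np.clip(out, 0.0, 1.0)
    return out


def pad_to_canvas(volume: np.ndarray, size: tuple[int, int] = (512, 512)) -> np.ndarray:
    """Zero-pad the trailing two axes to a fixed canvas, centred."""
    volume = np.asarray(volume)
    h, w = volume.shape[-2:]
    if h > size[0] or w > size[1]:
        raise ValueError(f"volume {(h, w)} larger than canvas {size}")
    pr, pc = size[0] - h, size[1] - w
    pad = [(0, 0)] * (volume.ndim - 2) + [
        (pr // 2, pr - pr // 2),
        (pc // 2, pc - pc // 2),
    ]
    return np.pad(volume, pad)
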