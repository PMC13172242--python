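"""Core 2D image containers and NIfTI helpers.

Coordinate convention (used everywhere in this package): arrays are indexed
``[row, col]``; the row axis is the anteroposterior axis, with the row index
increasing in the posterior direction, and is also the phase-encoding axis for
all distortion operations. ``spacing_mm`` is ``(row_mm, col_mm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["SliceImage", "DwiStack", "slice_to_nifti", "nifti_to_slice"]


@dataclass
class SliceImage:
    """A single 2D scalar field with physical pixel spacing.

    Parameters
    ----------
    data
        2D array, ``(rows, cols)``.
    spacing_mm
        Physical pixel size ``(row_mm, col_mm)``; both strictly positive.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"SliceImage data must be 2D, got shape {self.data.shape}")
        self.spacing_mm = (float(self.spacing_mm[0]), float(self.spacing_mm[1]))
        if min(self.spacing_mm) <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "SliceImage") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing_mm, other.spacing_mm
        )

    def copy(self) -> "SliceImage":
        return SliceImage(self.data.copy(), self.spacing_mm)

    def astype_bool(self) -> "SliceImage":
        return SliceImage(self.data.astype(bool), self.spacing_mm)


@dataclass
class DwiStack:
    """Co-registered diffusion-weighted channels sharing one grid.

    ``data`` has shape ``(n_b, rows, cols)``; ``b_values`` are the matching
    diffusion weightings in s/mm², sorted ascending.
    """

    data: np.ndarray
    b_values: np.ndarray
    spacing_mm: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"DwiStack data must be 3D, got shape {self.data.shape}")
        if self.data.shape[0] != self.b_values.size:
            raise ValueError(
                f"{self.data.shape[0]} channels but {self.b_values.size} b-values"
            )
        if self.b_values.size and self.b_values[0] < 0:
            raise ValueError("b-values must be nonnegative")
        if np.any(np.diff(self.b_values) < 0):
            raise ValueError("b-values must be sorted ascending")
        self.spacing_mm = (float(self.spacing_mm[0]), float(self.spacing_mm[1]))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]

    def channel(self, i: int) -> SliceImage:
        return SliceImage(self.data[i], self.spacing_mm)

    def same_grid(self, other) -> bool:
        return self.shape == tuple(other.shape) and np.allclose(
            self.spacing_mm, other.spacing_mm
        )

    def copy(self) -> "DwiStack":
        return DwiStack(self.data.copy(), self.b_values.copy(), self.spacing_mm)


def _affine(spacing_mm: tuple[float, float]) -> np.ndarray:
    # Rows/cols stored as the first two NIfTI axes; slice axis is a dummy.
    return np.diag([spacing_mm[0], spacing_mm[1], 1.0, 1.0])


def slice_to_nifti(img: SliceImage, dtype=np.float32) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(img.data, dtype=dtype), _affine(img.spacing_mm))


def nifti_to_slice(nifti: nib.Nifti1Image) -> SliceImage:
    data = np.asanyarray(nifti.dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError(f"expected a 2D NIfTI, got shape {data.shape}")
    zooms = nifti.header.get_zooms()[:2]
    return SliceImage(data, (float(zooms[0]), float(zooms[1])))
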