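"""Masked image-quality and overlap metrics: PSNR, S-SSIM, Dice.

PSNR is computed over mask pixels only, with the dynamic range L taken from
the reference within the mask; identical inputs return a documented 99 dB
sentinel. S-SSIM is the structure-only component of SSIM,
``s = (sigma_xy + C3) / (sigma_x * sigma_y + C3)`` with local Gaussian
windows (11 px, width 1.5 px) and ``C3 = (0.03 L)^2 / 2``; the local map is
computed on the full image and averaged over mask pixels, avoiding
window-edge bias from zeroing outside the mask. Dice is the usual
``2|A∩B| / (|A|+|B|)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import DwiStack, SliceImage

__all__ = [
    "PSNR_SENTINEL_DB",
    "MetricsReport",
    "psnr",
    "s_ssim",
    "s_ssim_map",
    "dice",
    "evaluate_case",
]

logger = logging.getLogger(__name__)

PSNR_SENTINEL_DB = 99.0

_SSIM_WIN_SIZE = 11
_SSIM_SIGMA = 1.5
_SSIM_K3 = 0.03


def _as_array(img) -> np.ndarray:
    return img.data if isinstance(img, SliceImage) else np.asarray(img)


def _check_mask(ref, test, mask) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ref = np.asarray(_as_array(ref), float)
    test = np.asarray(_as_array(test), float)
    mask = np.asarray(_as_array(mask), bool)
    if not (ref.shape == test.shape == mask.shape):
        raise ValueError("reference, test and mask must share one grid")
    if not mask.any():
        raise ValueError("evaluation mask is empty")
    return ref, test, mask


def psnr(ref, test, mask) -> float:
    """10 log10(L^2 / MSE) over mask pixels; L = ref range within the mask.

    Returns the 99 dB sentinel for identical inputs; raises on a constant
    reference (zero dynamic range).
    """
    ref, test, mask = _check_mask(ref, test, mask)
    rng = float(ref[mask].max() - ref[mask].min())
    if rng == 0.0:
        raise ValueError("reference is constant within the mask (dynamic range 0)")
    mse = float(np.mean((ref[mask] - test[mask]) ** 2))
    if mse == 0.0:
        return PSNR_SENTINEL_DB
    return min(PSNR_SENTINEL_DB, 10.0 * np.log10(rng**2 / mse))


def _gaussian_local(x: np.ndarray) -> np.ndarray:
    # 11-tap Gaussian window of width 1.5 px: radius 5 = truncate * sigma.
    radius = (_SSIM_WIN_SIZE - 1) // 2
    return ndimage.gaussian_filter(
        x, _SSIM_SIGMA, mode="reflect", truncate=radius / _SSIM_SIGMA
    )


def s_ssim_map(ref, test) -> np.ndarray:
    """Local structure-component map over the full image (C3 from the full
    reference range); used internally by :func:`s_ssim` with a masked range."""
    ref = np.asarray(_as_array(ref), float)
    test = np.asarray(_as_array(test), float)
    rng = float(ref.max() - ref.min())
    return _structure_map(ref, test, rng)


def _structure_map(ref: np.ndarray, test: np.ndarray, dynamic_range: float) -> np.ndarray:
    c3 = (_SSIM_K3 * dynamic_range) ** 2 / 2.0
    mu_x = _gaussian_local(ref)
    mu_y = _gaussian_local(test)
    var_x = np.clip(_gaussian_local(ref * ref) - mu_x**2, 0.0, None)
    var_y = np.clip(_gaussian_local(test * test) - mu_y**2, 0.0, None)
    cov = _gaussian_local(ref * test) - mu_x * mu_y
    return (cov + c3) / (np.sqrt(var_x * var_y) + c3)


def s_ssim(ref, test, mask) -> float:
    """Mean of the local structure map over mask pixels (range [-1, 1])."""
    ref, test, mask = _check_mask(ref, test, mask)
    if mask.sum() < _SSIM_WIN_SIZE**2:
        raise ValueError(
            f"mask ({int(mask.sum())} px) smaller than the "
            f"{_SSIM_WIN_SIZE}x{_SSIM_WIN_SIZE} local window"
        )
    rng = float(ref[mask].max() - ref[mask].min())
    return float(np.mean(_structure_map(ref, test, rng)[mask]))


def dice(mask_a, mask_b) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty (convention)."""
    a = np.asarray(_as_array(mask_a), bool)
    b = np.asarray(_as_array(mask_b), bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


@dataclass
class MetricsReport:
    """Per-slice, per-region metric records with mean ± sd summaries."""

    records: list[dict] = field(default_factory=list)

    def extend(self, rows) -> None:
        self.records.extend(rows)

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["case_id", "region", "severity", "metric", "b_value", "value"]
        return pd.DataFrame(self.records, columns=cols)

    def summary(self) -> pd.DataFrame:
        df = self.to_dataframe()
        if df.empty:
            return pd.DataFrame(columns=["region", "severity", "metric", "mean", "sd", "n"])
        g = df.groupby(["region", "severity", "metric"])["value"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        return out


def evaluate_case(
    ref_dwi: DwiStack,
    test_dwi: DwiStack,
    region_masks: dict[str, SliceImage],
    severity_label: str = "none",
    mask_pairs: dict[str, tuple] | None = None,
    case_id: str = "case",
) -> list[dict]:
    """Masked per-channel PSNR and S-SSIM rows plus optional Dice rows.

    One row per (b-channel, region, metric) against the matching reference
    channel, tagged with the severity label; ``mask_pairs`` adds one Dice row
    per region. Regions whose mask is missing/empty are skipped with a
    warning.
    """
    if not ref_dwi.same_grid(test_dwi) or ref_dwi.n_channels != test_dwi.n_channels:
        raise ValueError("reference and test stacks must share grid and channels")
    rows: list[dict] = []
    for region, mask in region_masks.items():
        if mask is None or not np.asarray(_as_array(mask), bool).any():
            logger.warning("case %s: region %r mask missing or empty; skipped",
                           case_id, region)
            continue
        for i, b in enumerate(ref_dwi.b_values):
            ref_ch, test_ch = ref_dwi.channel(i), test_dwi.channel(i)
            for metric, fn in (("PSNR", psnr), ("S-SSIM", s_ssim)):
                rows.append(
                    {
                        "case_id": case_id,
                        "region": region,
                        "severity": severity_label,
                        "metric": metric,
                        "b_value": float(b),
                        "value": fn(ref_ch, test_ch, mask),
                    }
                )
    if mask_pairs:
        for region, (ref_mask, test_mask) in mask_pairs.items():
            rows.append(
                {
                    "case_id": case_id,
                    "region": region,
                    "severity": severity_label,
                    "metric": "Dice",
                    "b_value": None,
                    "value": dice(ref_mask, test_mask),
                }
            )
    return rows
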