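"""Mono-exponential diffusion modelling.

Per-pixel ADC and S0 are estimated from a multi-b DWI stack by ordinary
least squares on ln S(b) = ln S0 - b * ADC (unweighted, log space). High
b-value images (conventionally b = 1500 s/mm²) are then synthesized from
the fitted maps via S(b) = S0 * exp(-b * ADC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import DwiStack, SliceImage

__all__ = ["MonoExpFit", "fit_monoexp", "synthesize_b", "DEFAULT_SIGNAL_FLOOR"]

# Pixels with any channel at or below the floor are excluded (ln 0 guard).
# In raw scanner-like units (phantom S0 ~ 10^3) this floor is effectively
# "signal present at all"; pass floor=1e-6 of the data range for data
# normalized to [0, 1].
DEFAULT_SIGNAL_FLOOR = 1e-6


@dataclass
class MonoExpFit:
    adc: SliceImage          # mm^2/s
    s0: SliceImage           # signal units
    valid_mask: SliceImage   # where the fit was performed
    r2: SliceImage | None = None


def fit_monoexp(dwi: DwiStack, floor: float = DEFAULT_SIGNAL_FLOOR) -> MonoExpFit:
    """Log-space linear least-squares fit of the mono-exponential model.

    At every pixel whose channels are all above ``floor``, ln S is regressed
    against b: slope = -ADC, intercept = ln S0. Other pixels are excluded
    from ``valid_mask`` and set to 0 in all output maps.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    b = np.asarray(dwi.b_values, float)
    if np.unique(b).size < 2:
        raise ValueError("at least 2 distinct b-values are required")
    data = np.asarray(dwi.data, float)
    valid = np.all(data > floor, axis=0)

    adc = np.zeros(dwi.shape)
    s0 = np.zeros(dwi.shape)
    r2 = np.zeros(dwi.shape)
    if valid.any():
        y = np.log(data[:, valid])                    # (n_b, n_valid)
        b_mean = b.mean()
        db = b - b_mean
        denom = np.sum(db**2)
        # shifting y by its first channel makes a constant signal give
        # slope exactly 0 (sum(db) vanishes analytically, not in floats)
        slope = (db @ (y - y[0])) / denom
        intercept = y.mean(axis=0) - slope * b_mean
        adc[valid] = -slope
        s0[valid] = np.exp(intercept)
        resid = y - (intercept[None, :] + b[:, None] * slope[None, :])
        ss_res = np.sum(resid**2, axis=0)
        ss_tot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2_vals = 1.0 - ss_res / ss_tot
        r2[valid] = np.where(ss_tot > 0, r2_vals, 1.0)

    sp = dwi.spacing_mm
    return MonoExpFit(
        adc=SliceImage(adc, sp),
        s0=SliceImage(s0, sp),
        valid_mask=SliceImage(valid, sp),
        r2=SliceImage(r2, sp),
    )


def synthesize_b(fit: MonoExpFit, b: float = 1500.0) -> SliceImage:
    """S(b) = S0 * exp(-b * ADC) on the valid mask, 0 elsewhere."""
    if b < 0:
        raise ValueError("b must be nonnegative")
    valid = fit.valid_mask.data.astype(bool)
    out = np.zeros(fit.adc.shape)
    out[valid] = fit.s0.data[valid] * np.exp(-b * fit.adc.data[valid])
    return SliceImage(out, fit.adc.spacing_mm)
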