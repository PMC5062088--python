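"""Envelope SNR: Rayleigh-regime statistics and sliding-window SNR imaging.

The envelope SNR is the ratio of the envelope mean to its population
standard deviation, ``SNR = E(R) / sqrt(E(R^2) - E(R)^2)``.  For fully
developed speckle (>= ~10 scatterers per resolution cell) the envelope is
Rayleigh distributed and ``SNR = sqrt(pi / (4 - pi)) = 1.9131``; sparser
media give pre-Rayleigh statistics (SNR below 1.91), clustered or partially
coherent media post-Rayleigh (above 1.91).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .data_model import ConfigError, EnvelopeImage, ParametricImage, ValidationError
from .texture_imaging import _box_sums, window_shape_px

__all__ = [
    "RAYLEIGH_SNR",
    "DegenerateSampleError",
    "SNREstimate",
    "envelope_snr",
    "snr_image",
    "snr_colormap",
]

#: SNR of a Rayleigh-distributed envelope, sqrt(pi / (4 - pi)).
RAYLEIGH_SNR = math.sqrt(math.pi / (4.0 - math.pi))

#: Regime boundary used for classification and display (two decimals, as the
#: boundary is conventionally quoted).
SNR_BOUNDARY = 1.91

#: Half-width of the "Rayleigh" band around the boundary.
SNR_BAND = 0.005


class DegenerateSampleError(ValueError):
    """Envelope samples have (numerically) zero variance."""


@dataclasses.dataclass
class SNREstimate:
    snr: float
    n: int
    regime: str  # "pre-rayleigh" | "rayleigh" | "post-rayleigh"


def _regime(snr: float) -> str:
    if abs(snr - SNR_BOUNDARY) <= SNR_BAND:
        return "rayleigh"
    return "pre-rayleigh" if snr < SNR_BOUNDARY else "post-rayleigh"


def envelope_snr(samples: np.ndarray) -> SNREstimate:
    """Mean over population standard deviation of envelope samples."""
    r = np.asarray(samples, dtype=float).ravel()
    if r.size < 2:
        raise ValidationError("need at least two envelope samples")
    if (r < 0).any() or not np.isfinite(r).all():
        raise ValidationError("envelope samples must be finite and nonnegative")
    m = r.mean()
    var = r.var()  # population variance
    if var <= (1e-12 * m) ** 2:
        raise DegenerateSampleError("zero-variance envelope sample")
    snr = float(m / math.sqrt(var))
    return SNREstimate(snr=snr, n=r.size, regime=_regime(snr))


def snr_image(env: EnvelopeImage, window_mm: float = 3.0, step: int = 1) -> ParametricImage:
    """Sliding-window local SNR map of an envelope image.

    The window is square in physical units (default 3 x 3 mm^2), moved in
    steps of one pixel; borders and degenerate (zero-variance) windows are
    masked invalid rather than failing globally.
    """
    cfg = env.config
    wy, wx = window_shape_px(window_mm, cfg.axial_pitch_mm, cfg.lateral_pitch_mm)
    if wy * wx < 25:
        raise ConfigError(f"window {(wy, wx)} px has fewer than 25 samples")
    H, W = env.R.shape
    if H < wy or W < wx:
        raise ConfigError(f"image {env.R.shape} smaller than window {(wy, wx)}")
    K = wy * wx
    m = _box_sums(env.R, wy, wx) / K
    m2 = _box_sums(env.R**2, wy, wx) / K
    var = m2 - m**2
    # relative threshold: fully developed speckle has var ~ 0.27 m^2, so this
    # only rejects numerically constant windows
    ok = (m2 > 0) & (var > 1e-10 * m2)
    interior = np.full(m.shape, np.nan)
    interior[ok] = m[ok] / np.sqrt(var[ok])
    hy, hx = wy // 2, wx // 2
    values = np.full((H, W), np.nan)
    mask = np.zeros((H, W), dtype=bool)
    values[hy : H - hy, hx : W - hx] = interior
    mask[hy : H - hy, hx : W - hx] = ok
    if step > 1:
        keep = np.zeros_like(mask)
        keep[hy : H - hy : step, hx : W - hx : step] = True
        mask &= keep
    values[~mask] = np.nan
    return ParametricImage(
        values=values,
        feature_name="SNR",
        valid_mask=mask,
        axial_pitch_mm=cfg.axial_pitch_mm,
        lateral_pitch_mm=cfg.lateral_pitch_mm,
    )


def snr_colormap(img: ParametricImage) -> np.ndarray:
    """Pseudocolor RGB (uint8) for an SNR image.

    Blue shading, dark to light, below the Rayleigh boundary; white within
    +/- 0.005 of 1.91; red shading, dark to light, above it.  Invalid pixels
    are black.
    """
    snr = img.values
    rgb = np.zeros(snr.shape + (3,), dtype=np.uint8)
    valid = img.valid_mask
    s = np.where(valid, snr, 0.0)

    below = valid & (s < SNR_BOUNDARY - SNR_BAND)
    t = np.clip(s / SNR_BOUNDARY, 0.0, 1.0)
    rgb[below, 0] = (200 * t[below]).astype(np.uint8)
    rgb[below, 1] = (200 * t[below]).astype(np.uint8)
    rgb[below, 2] = (128 + 127 * t[below]).astype(np.uint8)

    white = valid & (np.abs(s - SNR_BOUNDARY) <= SNR_BAND)
    rgb[white] = 255

    above = valid & (s > SNR_BOUNDARY + SNR_BAND)
    u = np.clip((s - SNR_BOUNDARY) / SNR_BOUNDARY, 0.0, 1.0)
    rgb[above, 0] = (128 + 127 * u[above]).astype(np.uint8)
    rgb[above, 1] = (200 * u[above]).astype(np.uint8)
    rgb[above, 2] = (200 * u[above]).astype(np.uint8)
    return rgb
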