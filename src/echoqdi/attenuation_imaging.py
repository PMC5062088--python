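"""Spectral-shift attenuation: block spectra, FWHM-midpoint center frequency,
CFDS parametric imaging and slope-to-attenuation conversion.

Tissue attenuation grows linearly with frequency, so a Gaussian transmit
pulse keeps a Gaussian echo spectrum whose center frequency slides down
linearly with depth:

    f_c(z) = f_o - 4 * sigma2 * beta_np * z

with ``sigma2`` the variance (MHz^2) of the pulse power spectrum and
``beta_np`` the attenuation coefficient in Np cm^-1 MHz^-1 (round-trip path
``2z``).  The center-frequency downshift is ``CFDS(z) = f_o - f_c(z)``; a
least-squares fit of CFDS against depth therefore recovers
``beta_np = slope / (4 sigma2)``.  Diffraction is neglected, so the slope is
treated as constant along the fitted depth range.

Center frequencies are located as the midpoint between the two half-maximum
crossings of the block power spectrum, with crossings interpolated linearly
between frequency bins.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import signal, stats

from .data_model import (
    AcquisitionConfig,
    ConfigError,
    LineSpec,
    ParametricImage,
    RFFrame,
    ValidationError,
)
from .phantom_simulator import DB_PER_NEPER
from .texture_imaging import window_shape_px

__all__ = [
    "BandError",
    "FitError",
    "SpectralBlock",
    "AttenuationEstimate",
    "block_power_spectrum",
    "center_frequency",
    "cfds_image",
    "cfds_slope",
    "estimate_attenuation",
    "cfds_colormap",
]


class BandError(ValueError):
    """No half-maximum crossing inside the analysis band."""


class FitError(ValueError):
    """Too few valid CFDS points (or too small a depth span) to fit a slope."""


@dataclasses.dataclass
class SpectralBlock:
    """Averaged power spectrum of an RF block with its FWHM center frequency."""

    freqs: np.ndarray  # MHz
    power: np.ndarray  # normalized to max 1
    f_c: float  # MHz, FWHM midpoint
    fwhm: tuple[float, float]  # (low, high) half-max crossings, MHz
    z_cm: float | None = None


@dataclasses.dataclass
class AttenuationEstimate:
    cfds_slope: float  # MHz / cm
    beta_np: float  # Np / cm / MHz
    beta_db: float  # dB / cm / MHz
    sigma2: float  # MHz^2 used in the conversion
    r2: float
    n_points: int


# ---------------------------------------------------------------------------
# Center-frequency estimation.


def _fc_from_power(P: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized FWHM-midpoint center frequency for rows of ``P``.

    Returns (f_c, f_lo, f_hi) with NaN where a half-maximum crossing is
    missing inside the band.  When several disjoint above-half regions exist,
    the crossings nearest the global peak are used (the peak's region).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    n, nb = P.shape
    peak_val = P.max(axis=1)
    bad = peak_val <= 0
    # normalize rows; keep all-zero rows harmless
    Pn = P / np.where(peak_val > 0, peak_val, 1.0)[:, None]
    peak = Pn.argmax(axis=1)
    idx = np.arange(nb)
    below = Pn < 0.5

    left_cand = np.where(below & (idx[None, :] < peak[:, None]), idx[None, :], -1)
    li = left_cand.max(axis=1)
    right_cand = np.where(below & (idx[None, :] > peak[:, None]), idx[None, :], nb)
    ri = right_cand.min(axis=1)

    ok = (~bad) & (li >= 0) & (ri < nb)
    f_lo = np.full(n, np.nan)
    f_hi = np.full(n, np.nan)
    rows = np.nonzero(ok)[0]
    if rows.size:
        l = li[rows]
        r = ri[rows]
        pl0 = Pn[rows, l]
        pl1 = Pn[rows, l + 1]
        f_lo[rows] = freqs[l] + (0.5 - pl0) / (pl1 - pl0) * (freqs[l + 1] - freqs[l])
        pr0 = Pn[rows, r - 1]
        pr1 = Pn[rows, r]
        f_hi[rows] = freqs[r - 1] + (pr0 - 0.5) / (pr0 - pr1) * (freqs[r] - freqs[r - 1])
    f_c = (f_lo + f_hi) / 2.0
    return f_c, f_lo, f_hi


def center_frequency(spec: SpectralBlock) -> float:
    """FWHM-midpoint center frequency of a block spectrum (MHz)."""
    power = np.asarray(spec.power, dtype=float)
    f_c, f_lo, f_hi = _fc_from_power(power[None, :], np.asarray(spec.freqs, dtype=float))
    if np.isnan(f_c[0]):
        raise BandError("no half-maximum crossing inside the band")
    above = power >= 0.5 * power.max()
    n_regions = int(above[0]) + int(np.diff(above.astype(int)).clip(min=0).sum())
    if n_regions > 1:
        warnings.warn(
            "multiple above-half-maximum regions; using the global peak's region",
            stacklevel=2,
        )
    return float(f_c[0])


def block_power_spectrum(
    block: np.ndarray,
    config: AcquisitionConfig,
    nperseg: int | None = None,
    nfft: int = 256,
    z_cm: float | None = None,
) -> SpectralBlock:
    """Averaged Hann-windowed power spectrum of an RF block.

    ``block`` is 1-D or [lines, samples]; each line contributes one segment
    per Welch position (``nperseg`` long, 50% overlap, zero-padded to
    ``nfft`` bins).  By default ``nperseg`` is the full block length, i.e. one
    segment per line, which is what the sliding-window CFDS image uses.
    The averaged spectrum is normalized to a maximum of 1.
    """
    block = np.atleast_2d(np.asarray(block, dtype=float))
    L = block.shape[1]
    if L < 32:
        raise ConfigError("block needs at least 32 axial samples")
    if not block.any():
        raise ValidationError("all-zero block has no spectrum")
    npg = L if nperseg is None else min(int(nperseg), L)
    if npg < 8:
        raise ConfigError("segment length must be >= 8 samples")
    if nfft < npg:  # zero-padding only; never truncate a segment
        nfft = 1 << int(np.ceil(np.log2(npg)))
    hop = max(npg // 2, 1)
    win = signal.get_window("hann", npg, fftbins=True)
    acc = np.zeros(nfft // 2 + 1)
    count = 0
    for s0 in range(0, L - npg + 1, hop):
        seg = block[:, s0 : s0 + npg] * win
        acc += (np.abs(np.fft.rfft(seg, n=nfft, axis=1)) ** 2).sum(axis=0)
        count += block.shape[0]
    power = acc / count
    power = power / power.max()
    freqs = np.fft.rfftfreq(nfft, d=1.0 / config.fs)  # MHz
    f_c, f_lo, f_hi = _fc_from_power(power[None, :], freqs)
    if np.isnan(f_c[0]):
        raise BandError("no half-maximum crossing inside the band")
    return SpectralBlock(
        freqs=freqs, power=power, f_c=float(f_c[0]),
        fwhm=(float(f_lo[0]), float(f_hi[0])), z_cm=z_cm,
    )


# ---------------------------------------------------------------------------
# CFDS parametric imaging.


def cfds_image(
    frame: RFFrame,
    window_mm: float = 3.0,
    nfft: int = 256,
    lines: tuple[int, int] | None = None,
    normalized: bool = False,
) -> ParametricImage:
    """Sliding-window center-frequency-downshift map, ``CFDS = f_o - f_c``.

    Per output pixel the block is the physical window centered there (default
    3 x 3 mm^2); its power spectrum averages one Hann-windowed, zero-padded
    periodogram per scan line in the window.  ``lines`` restricts the output
    to a half-open range of scan lines (the full border-valid range by
    default).  ``normalized=True`` maps ``(f_o - f_c) / f_o`` instead.
    Windows without a half-maximum crossing are masked invalid.
    """
    cfg = frame.config
    wy, wx = window_shape_px(window_mm, cfg.axial_pitch_mm, cfg.lateral_pitch_mm)
    H, W = frame.samples.shape
    if H < wy or W < wx:
        raise ConfigError(f"frame {frame.samples.shape} smaller than window {(wy, wx)}")
    hy, hx = wy // 2, wx // 2
    lo, hi = (hy, H - hy) if lines is None else lines
    lo = max(lo, hy)
    hi = min(hi, H - hy)
    if hi <= lo:
        raise ConfigError("requested line range has no valid output lines")

    in_lo, in_hi = lo - hy, hi + hy  # input lines needed
    win = signal.get_window("hann", wx, fftbins=True)
    n_pos = W - wx + 1
    nb = nfft // 2 + 1
    # per-line periodograms at every axial window position
    segs = np.lib.stride_tricks.sliding_window_view(
        frame.samples[in_lo:in_hi], wx, axis=1
    )  # [lines, n_pos, wx]
    P = np.abs(np.fft.rfft(segs * win, n=nfft, axis=2)) ** 2

    # moving sum over wy lines -> block spectra for each output line
    C = np.zeros((P.shape[0] + 1, n_pos, nb))
    np.cumsum(P, axis=0, out=C[1:])
    S = (C[wy:] - C[:-wy]) / wy  # [n_out_lines, n_pos, nb]

    freqs = np.fft.rfftfreq(nfft, d=1.0 / cfg.fs)
    f_c, _, _ = _fc_from_power(S.reshape(-1, nb), freqs)
    f_c = f_c.reshape(S.shape[0], n_pos)
    cfds = cfg.f_o - f_c
    if normalized:
        cfds = cfds / cfg.f_o

    values = np.full((H, W), np.nan)
    mask = np.zeros((H, W), dtype=bool)
    values[lo:hi, hx : hx + n_pos] = cfds
    mask[lo:hi, hx : hx + n_pos] = np.isfinite(cfds)
    values[~mask] = np.nan
    return ParametricImage(
        values=values,
        feature_name="CFDS",
        valid_mask=mask,
        axial_pitch_mm=cfg.axial_pitch_mm,
        lateral_pitch_mm=cfg.lateral_pitch_mm,
    )


def cfds_slope(
    img: ParametricImage,
    line: LineSpec,
    sigma2: float,
    lateral_halfwidth: int = 0,
    min_points: int = 10,
    min_span_cm: float = 1.0,
) -> AttenuationEstimate:
    """Least-squares CFDS-vs-depth slope along a scan line.

    ``lateral_halfwidth`` averages the CFDS profile over that many neighbor
    lines on each side before the regression (a homogeneous-strip average;
    0 reproduces a single-line fit).  The fitted slope (MHz/cm) converts to
    ``beta_np = slope / (4 sigma2)`` and ``beta_db = 8.686 beta_np``.
    """
    lo = max(0, line.line - lateral_halfwidth)
    hi = min(img.values.shape[0], line.line + lateral_halfwidth + 1)
    strip = np.where(img.valid_mask[lo:hi], img.values[lo:hi], np.nan)
    if not np.isfinite(strip).any():
        raise FitError("no valid CFDS pixels in the selected lines")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(strip, axis=0)
    z = np.arange(profile.size) * img.axial_pitch_mm / 10.0  # cm
    d0, d1 = line.depth_range_cm
    sel = np.isfinite(profile) & (z >= d0) & (z <= d1)
    if sel.sum() < min_points:
        raise FitError(f"only {int(sel.sum())} valid CFDS points; need {min_points}")
    span = z[sel].max() - z[sel].min()
    if span < min_span_cm:
        raise FitError(f"depth span {span:.2f} cm below {min_span_cm} cm")
    fit = stats.linregress(z[sel], profile[sel])
    slope = float(fit.slope)
    beta_np = slope / (4.0 * sigma2)
    return AttenuationEstimate(
        cfds_slope=slope,
        beta_np=beta_np,
        beta_db=DB_PER_NEPER * beta_np,
        sigma2=sigma2,
        r2=float(fit.rvalue**2),
        n_points=int(sel.sum()),
    )


def estimate_attenuation(
    frame: RFFrame,
    line: int | None = None,
    depth_range_cm: tuple[float, float] = (2.0, 7.0),
    window_mm: float = 3.0,
    lateral_halfwidth: int = 32,
) -> AttenuationEstimate:
    """CFDS-slope attenuation estimate on a lateral strip around one line.

    Computes the CFDS image only for the scan lines the fit needs, then
    regresses the strip-averaged CFDS profile on depth.
    """
    cfg = frame.config
    center = cfg.n_lines // 2 if line is None else line
    lo = center - lateral_halfwidth
    hi = center + lateral_halfwidth + 1
    img = cfds_image(frame, window_mm=window_mm, lines=(lo, hi))
    spec = LineSpec(line=center, depth_range_cm=depth_range_cm)
    return cfds_slope(img, spec, sigma2=cfg.sigma2, lateral_halfwidth=lateral_halfwidth)


def cfds_colormap(img: ParametricImage) -> np.ndarray:
    """Blue-to-red linear RGB map over the valid CFDS range.

    The lowest valid value maps to blue, the highest to red, intermediate
    values linearly in RGB.  A constant image renders all blue; invalid
    pixels are black.
    """
    rgb = np.zeros(img.values.shape + (3,), dtype=np.uint8)
    if not img.valid_mask.any():
        return rgb
    vals = img.values[img.valid_mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax > vmin:
        t = (img.values - vmin) / (vmax - vmin)
    else:
        t = np.zeros_like(img.values)
    t = np.clip(np.where(img.valid_mask, t, 0.0), 0.0, 1.0)
    blue = np.array([0, 0, 255], dtype=float)
    red = np.array([255, 0, 0], dtype=float)
    mix = blue[None, None, :] * (1 - t[..., None]) + red[None, None, :] * t[..., None]
    rgb[img.valid_mask] = mix[img.valid_mask].astype(np.uint8)
    return rgb
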