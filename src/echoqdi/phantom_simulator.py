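"""Synthetic RF phantoms: point-scatterer speckle with depth attenuation.

The simulator draws scatterers as a 1-D Poisson process in depth on each scan
line (lines are treated as independent), convolves the reflectivity train with
a Gaussian-modulated transmit pulse, and applies frequency-dependent
round-trip attenuation by depth-segmented spectral filtering.  The goal is to
realize, controllably, the three physical regimes the analysis stages measure:

* envelope statistics from pre-Rayleigh (sparse scatterers) through fully
  developed Rayleigh speckle (SNR -> 1.91) as density grows;
* class-dependent echogenicity via scatterer reflectivity;
* a linear-in-frequency attenuation ``exp(-beta_np * f * 2z)`` that shifts the
  Gaussian echo spectrum down by ``4 * sigma2 * beta_np * z`` at depth ``z``.

Scatterer density is specified per resolution cell.  The cell's axial extent
is ``pulse_length / 2`` — the standard axial resolution of a pulse-echo
system — so a density of ``rho`` per cell corresponds to a linear density of
``2 rho / pulse_length`` scatterers per mm of depth.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import signal

from .data_model import AcquisitionConfig, ConfigError, RFFrame, _round_half_up

__all__ = [
    "DB_PER_NEPER",
    "CapacityError",
    "PhantomSpec",
    "CLASS_PRESETS",
    "make_pulse",
    "render_line",
    "simulate_rf_frame",
    "make_class_phantom",
]

#: dB per neper (20 / ln 10); converts attenuation between conventions.
DB_PER_NEPER = 20.0 / math.log(10.0)

#: Hard cap on scatterers per scan line.
MAX_SCATTERERS_PER_LINE = 1_000_000


class CapacityError(ValueError):
    """Requested scatterer count exceeds the per-line cap."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Tissue-mimicking phantom description.

    ``scatterer_density`` counts scatterers per resolution cell (axial extent
    ``pulse_length / 2``); ``beta`` is the attenuation coefficient in
    dB cm^-1 MHz^-1; reflectivity amplitudes are Normal(amplitude_mean,
    amplitude_sd^2).
    """

    depth_extent: float = 8.0  # cm
    scatterer_density: float = 15.0  # per resolution cell
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.2
    beta: float = 0.0  # dB / cm / MHz
    class_label: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scatterer_density < 0:
            raise ConfigError("scatterer_density must be >= 0")
        if self.beta < 0:
            raise ConfigError("beta must be >= 0")
        if self.depth_extent <= 0:
            raise ConfigError("depth_extent must be > 0")
        if self.amplitude_sd < 0:
            raise ConfigError("amplitude_sd must be >= 0")


#: Severity presets: density/cell, reflectivity mean, relative reflectivity
#: spread, attenuation (dB/cm/MHz).  Attenuation values bracket the range
#: reported for normal-to-severely fatty livers in the clinical attenuation
#: literature; fatty infiltration is modelled as denser *and more uniform*
#: scattering (numerous similar-sized fat droplets).
CLASS_PRESETS = {
    "normal": {"scatterer_density": 12.0, "amplitude_mean": 1.0, "sd_ratio": 0.8, "beta": 0.55},
    "mild": {"scatterer_density": 16.0, "amplitude_mean": 1.5, "sd_ratio": 0.5, "beta": 0.80},
    "severe": {"scatterer_density": 20.0, "amplitude_mean": 2.0, "sd_ratio": 0.3, "beta": 1.10},
}


def make_class_phantom(class_label: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Phantom preset for a severity class; any field can be overridden."""
    if class_label not in CLASS_PRESETS:
        raise ValueError(
            f"unknown class {class_label!r}; expected one of {sorted(CLASS_PRESETS)}"
        )
    preset = dict(CLASS_PRESETS[class_label])
    sd_ratio = preset.pop("sd_ratio")
    preset["amplitude_sd"] = sd_ratio * preset["amplitude_mean"]
    preset.update(overrides)
    return PhantomSpec(class_label=class_label, seed=seed, **preset)


def make_pulse(config: AcquisitionConfig, dt_us: float | None = None) -> np.ndarray:
    """Gaussian-modulated sinusoid at ``f_o``.

    The pulse power spectrum is Gaussian with variance ``config.sigma2``
    (MHz^2), which for the default configuration gives an envelope FWHM
    matching ``pulse_length`` at speed of sound ``c``.  Sampled at the RF rate
    unless ``dt_us`` overrides the sample spacing; the array has odd length
    with the envelope peak at the center sample.
    """
    sigma = math.sqrt(config.sigma2)
    if config.f_o + 3.0 * sigma > config.fs / 2.0:
        raise ConfigError(
            f"pulse band f_o + 3*sigma = {config.f_o + 3 * sigma:.2f} MHz "
            f"exceeds Nyquist {config.fs / 2:.2f} MHz"
        )
    if dt_us is None:
        dt_us = 1.0 / config.fs
    # envelope exp(-4 pi^2 sigma2 t^2): std_t = 1 / (2 sqrt(2) pi sigma)
    sigma_t = 1.0 / (2.0 * math.sqrt(2.0) * math.pi * sigma)
    n_half = int(math.ceil(5.0 * sigma_t / dt_us))
    t = np.arange(-n_half, n_half + 1) * dt_us
    envelope = np.exp(-4.0 * math.pi**2 * config.sigma2 * t**2)
    return envelope * np.cos(2.0 * math.pi * config.f_o * t)


def _apply_attenuation(rf: np.ndarray, config: AcquisitionConfig, beta_db: float) -> np.ndarray:
    """Depth-dependent spectral filtering by overlap-add over 64-sample segments.

    Each segment is Hann-windowed (50% hop, constant overlap-add), padded to
    128 points, and multiplied by the round-trip amplitude attenuation
    ``exp(-beta_np * f * 2 z)`` evaluated at the segment's center depth.
    """
    seg, hop, nfft = 64, 32, 128
    beta_np = beta_db / DB_PER_NEPER  # Np / cm / MHz
    freqs = np.fft.rfftfreq(nfft, d=1.0 / config.fs)  # MHz
    n_lines, n = rf.shape
    pad = hop
    x = np.zeros((n_lines, pad + n + seg))
    x[:, pad : pad + n] = rf
    out = np.zeros((n_lines, x.shape[1] + nfft))
    win = signal.get_window("hann", seg, fftbins=True)
    for s0 in range(0, x.shape[1] - seg + 1, hop):
        z_cm = max((s0 + seg / 2.0 - pad), 0.0) * config.axial_pitch_cm
        h = np.exp(-beta_np * freqs * 2.0 * z_cm)
        chunk = x[:, s0 : s0 + seg] * win
        spec = np.fft.rfft(chunk, n=nfft, axis=1) * h
        out[:, s0 : s0 + nfft] += np.fft.irfft(spec, n=nfft, axis=1)
    return out[:, pad : pad + n]


def render_line(
    positions_mm: np.ndarray,
    amplitudes: np.ndarray,
    config: AcquisitionConfig,
    n_samples: int,
    beta: float = 0.0,
) -> np.ndarray:
    """RF signal of one scan line from explicit scatterer positions (mm)."""
    refl = np.zeros((1, n_samples))
    idx = np.array(
        [_round_half_up(z / config.axial_pitch_mm) for z in np.atleast_1d(positions_mm)]
    )
    amps = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    keep = (idx >= 0) & (idx < n_samples)
    np.add.at(refl[0], idx[keep], amps[keep])
    pulse = make_pulse(config)
    rf = signal.fftconvolve(refl, pulse[None, :], mode="same", axes=1)
    if beta > 0:
        rf = _apply_attenuation(rf, config, beta)
    return rf[0]


def simulate_rf_frame(spec: PhantomSpec, config: AcquisitionConfig | None = None) -> RFFrame:
    """Simulate one RF frame; deterministic given ``spec.seed``."""
    if config is None:
        config = AcquisitionConfig()
    rng = np.random.default_rng(spec.seed)
    depth_mm = spec.depth_extent * 10.0
    n_samples = int(round(depth_mm / config.axial_pitch_mm))
    cell_axial_mm = config.pulse_length / 2.0
    lam_per_mm = spec.scatterer_density / cell_axial_mm
    mean_count = lam_per_mm * depth_mm
    if mean_count > MAX_SCATTERERS_PER_LINE:
        raise CapacityError(
            f"expected {mean_count:.0f} scatterers per line exceeds cap "
            f"{MAX_SCATTERERS_PER_LINE}"
        )
    counts = rng.poisson(mean_count, size=config.n_lines)
    total = int(counts.sum())
    refl = np.zeros((config.n_lines, n_samples))
    if total > 0:
        positions = rng.uniform(0.0, depth_mm, size=total)
        amplitudes = rng.normal(spec.amplitude_mean, spec.amplitude_sd, size=total)
        line_idx = np.repeat(np.arange(config.n_lines), counts)
        samp_idx = np.floor(positions / config.axial_pitch_mm + 0.5).astype(np.int64)
        keep = samp_idx < n_samples
        np.add.at(refl, (line_idx[keep], samp_idx[keep]), amplitudes[keep])
        pulse = make_pulse(config)
        rf = signal.fftconvolve(refl, pulse[None, :], mode="same", axes=1)
    else:
        rf = refl
    if spec.beta > 0 and total > 0:
        rf = _apply_attenuation(rf, config, spec.beta)
    return RFFrame(samples=rf, config=config)
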