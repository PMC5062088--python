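"""Core domain types, spatial calibration and file I/O for RF ultrasound data.

Conventions used by every module in this package:

* axis 0 of an image array is the scan line (lateral position), axis 1 is the
  axial sample (depth);
* the depth of axial sample ``k`` is ``z = k * axial_pitch`` with
  ``axial_pitch = c / (2 fs)`` (round-trip echo time, 0-based indices);
* pixel rectangles are half-open index ranges ``[start, stop)``;
* frequencies are in MHz, depths in cm (pitches in mm), attenuation in
  dB cm^-1 MHz^-1 unless a name says otherwise.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "BoundsError",
    "EmptyROIError",
    "ConfigError",
    "CLASS_LABELS",
    "CLASS_RANK",
    "AcquisitionConfig",
    "RFFrame",
    "EnvelopeImage",
    "BModeImage",
    "ParametricImage",
    "ROISpec",
    "LineSpec",
    "FeatureRecord",
    "FEATURE_NAMES",
    "read_rf_frame",
    "write_rf_frame",
    "roi_to_pixels",
    "roi_mean",
    "read_feature_table",
    "write_feature_table",
]


class SchemaError(ValueError):
    """A file is missing required metadata."""


class ValidationError(ValueError):
    """Data violates a domain invariant (non-finite samples, bad labels...)."""


class BoundsError(ValueError):
    """A region of interest falls outside the image."""


class EmptyROIError(ValueError):
    """A region of interest contains no valid pixels."""


class ConfigError(ValueError):
    """Inconsistent acquisition or analysis configuration."""


#: Ordinal severity classes, least to most severe.
CLASS_LABELS = ("normal", "mild", "severe")
CLASS_RANK = {label: rank for rank, label in enumerate(CLASS_LABELS)}

#: The three per-subject features combined into the diagnostic index.
FEATURE_NAMES = ("lda_texture_index", "snr", "cfds_slope")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclasses.dataclass(frozen=True)
class AcquisitionConfig:
    """Transducer and digitizer settings attached to every RF frame.

    Parameters
    ----------
    f_o:
        Transducer center frequency in MHz.
    fs:
        RF sampling rate in MHz.
    n_lines:
        Number of scan lines per frame.
    bandwidth:
        (low, high) -6 dB band of the transducer, MHz.
    pulse_length:
        Spatial length of the transmitted pulse in mm (envelope FWHM times
        the speed of sound).
    sigma2:
        Variance of the Gaussian transmit-pulse *power* spectrum, MHz^2.
        Derived from ``pulse_length`` when not given.
    c:
        Speed of sound, m/s.
    lateral_pitch:
        Lateral spacing between adjacent scan lines, mm.
    dynamic_range:
        Log-compression dynamic range for B-mode formation, dB.
    """

    f_o: float = 3.5
    fs: float = 12.0
    n_lines: int = 128
    bandwidth: tuple[float, float] = (2.0, 5.0)
    pulse_length: float = 1.0
    sigma2: float | None = None
    c: float = 1540.0
    lateral_pitch: float = 0.47
    dynamic_range: float = 40.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bandwidth", tuple(float(b) for b in self.bandwidth))
        if self.pulse_length <= 0:
            raise ConfigError("pulse_length must be positive")
        if self.sigma2 is None:
            # Gaussian envelope: FWHM_t = pulse_length / c; the power spectrum
            # of the modulated pulse is Gaussian with std sqrt(ln 2)/(pi FWHM_t).
            fwhm_t_us = self.pulse_length / (self.c * 1e-3)
            sigma = math.sqrt(math.log(2.0)) / (math.pi * fwhm_t_us)
            object.__setattr__(self, "sigma2", sigma * sigma)
        if self.fs <= 2.0 * self.bandwidth[1]:
            raise ConfigError(
                f"sampling rate {self.fs} MHz violates Nyquist for band "
                f"{self.bandwidth} MHz"
            )
        if self.bandwidth[0] >= self.bandwidth[1]:
            raise ConfigError("bandwidth must be (low, high) with low < high")
        if self.c <= 0 or self.fs <= 0:
            raise ConfigError("c and fs must be positive")
        if self.sigma2 <= 0:
            raise ConfigError("sigma2 must be positive")
        if self.pulse_length <= 0:
            raise ConfigError("pulse_length must be positive")
        if self.dynamic_range <= 0:
            raise ConfigError("dynamic_range must be positive")
        if self.n_lines < 1:
            raise ConfigError("n_lines must be >= 1")
        if self.lateral_pitch <= 0:
            raise ConfigError("lateral_pitch must be positive")

    @property
    def axial_pitch_mm(self) -> float:
        """Depth covered by one axial sample, mm (= c / (2 fs))."""
        return self.c / (2.0 * self.fs * 1000.0)

    @property
    def axial_pitch_cm(self) -> float:
        return self.axial_pitch_mm / 10.0

    @property
    def lateral_pitch_mm(self) -> float:
        """Alias: ``lateral_pitch`` is already in mm."""
        return self.lateral_pitch

    def depth_cm(self, sample_index: np.ndarray | float) -> np.ndarray | float:
        """Depth (cm) of an axial sample index."""
        return np.asarray(sample_index) * self.axial_pitch_cm

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bandwidth"] = list(self.bandwidth)
        return d

    @classmethod
    def from_dict(cls, meta: Mapping) -> "AcquisitionConfig":
        fields = [f.name for f in dataclasses.fields(cls)]
        missing = [k for k in fields if k not in meta]
        if missing:
            raise SchemaError(f"metadata missing required field(s): {missing}")
        kwargs = {k: meta[k] for k in fields}
        kwargs["bandwidth"] = tuple(kwargs["bandwidth"])
        kwargs["n_lines"] = int(kwargs["n_lines"])
        return cls(**kwargs)


def _check_samples(samples: np.ndarray, n_lines: int) -> np.ndarray:
    samples = np.asarray(samples)
    if samples.ndim != 2:
        raise ValidationError("RF samples must be a 2-D [line, sample] array")
    if samples.shape[0] != n_lines:
        raise ValidationError(
            f"frame has {samples.shape[0]} lines, config says {n_lines}"
        )
    if samples.shape[1] < 1:
        raise ValidationError("frame needs at least one axial sample")
    if not np.isfinite(samples).all():
        raise ValidationError("RF samples contain non-finite values")
    return samples


@dataclasses.dataclass
class RFFrame:
    """Raw backscattered RF samples, one row per scan line."""

    samples: np.ndarray
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        self.samples = _check_samples(self.samples, self.config.n_lines)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclasses.dataclass
class EnvelopeImage:
    """Magnitude of the analytic RF signal (nonnegative)."""

    R: np.ndarray
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if (self.R < 0).any() or not np.isfinite(self.R).all():
            raise ValidationError("envelope must be finite and nonnegative")


@dataclasses.dataclass
class BModeImage:
    """Log-compressed, 8-bit quantized envelope image."""

    gray: np.ndarray
    config: AcquisitionConfig
    N_g: int = 256

    def __post_init__(self) -> None:
        gray = np.asarray(self.gray)
        if gray.min() < 0 or gray.max() > self.N_g - 1:
            raise ValidationError(f"gray levels must lie in [0, {self.N_g - 1}]")
        self.gray = gray.astype(np.int64)


@dataclasses.dataclass
class ParametricImage:
    """Per-pixel map of a locally estimated feature.

    ``values`` has the same shape as the source image; ``valid_mask`` marks
    pixels that carry an estimate (sliding-window borders and failed windows
    are masked out).
    """

    values: np.ndarray
    feature_name: str
    valid_mask: np.ndarray
    axial_pitch_mm: float
    lateral_pitch_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValidationError("values and valid_mask shapes differ")
        if not np.isfinite(self.values[self.valid_mask]).all():
            raise ValidationError("non-finite values inside valid_mask")


@dataclasses.dataclass(frozen=True)
class ROISpec:
    """Square region of interest given in physical coordinates.

    The default matches the measurement protocol: a 1 x 1 cm^2 square centered
    at 5 cm depth on the central scan line.
    """

    center_depth_cm: float = 5.0
    center_line: int | None = None
    side_cm: float = 1.0


@dataclasses.dataclass(frozen=True)
class LineSpec:
    """A scan line and a depth range (cm) along it."""

    line: int
    depth_range_cm: tuple[float, float] = (2.0, 7.0)

    def __post_init__(self) -> None:
        lo, hi = self.depth_range_cm
        if not lo < hi:
            raise ValidationError("depth range must be strictly increasing")


@dataclasses.dataclass
class FeatureRecord:
    """Per-subject feature triplet plus ordinal severity label."""

    subject_id: str
    lda_texture_index: float
    snr: float
    cfds_slope: float
    usfli_class: str
    covariates: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.usfli_class not in CLASS_LABELS:
            raise ValidationError(
                f"usfli_class must be one of {CLASS_LABELS}, got {self.usfli_class!r}"
            )
        for name in FEATURE_NAMES:
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"feature {name} is not finite")


# ---------------------------------------------------------------------------
# RF frame I/O: array container plus JSON metadata.


def write_rf_frame(frame: RFFrame, path: str | Path) -> Path:
    """Write a frame to ``.h5`` (dataset "rf" + attrs) or ``.npy`` + JSON sidecar.

    Round-trip is lossless: the sample dtype is preserved as stored.
    """
    path = Path(path)
    _check_samples(frame.samples, frame.config.n_lines)
    meta = frame.config.to_dict()
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("rf", data=frame.samples)
            for key, value in meta.items():
                ds.attrs[key] = value
    elif path.suffix == ".npy":
        np.save(path, frame.samples)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    else:
        raise ConfigError(f"unsupported container suffix {path.suffix!r}")
    return path


def read_rf_frame(path: str | Path) -> RFFrame:
    """Read a frame written by :func:`write_rf_frame`."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if "rf" not in f:
                raise SchemaError("container lacks dataset 'rf'")
            ds = f["rf"]
            samples = ds[...]
            meta = {k: ds.attrs[k] for k in ds.attrs}
        if "bandwidth" in meta:
            meta["bandwidth"] = tuple(np.asarray(meta["bandwidth"]).tolist())
    elif path.suffix == ".npy":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise SchemaError(f"metadata sidecar {sidecar.name} not found")
        samples = np.load(path)
        meta = json.loads(sidecar.read_text())
    else:
        raise ConfigError(f"unsupported container suffix {path.suffix!r}")
    config = AcquisitionConfig.from_dict(meta)
    return RFFrame(samples=samples, config=config)


# ---------------------------------------------------------------------------
# ROI geometry.


def _geometry(img) -> tuple[tuple[int, int], float, float]:
    """(shape, axial pitch mm, lateral pitch mm) of any image container."""
    if isinstance(img, ParametricImage):
        return img.values.shape, img.axial_pitch_mm, img.lateral_pitch_mm
    if isinstance(img, RFFrame):
        arr = img.samples
    elif isinstance(img, EnvelopeImage):
        arr = img.R
    elif isinstance(img, BModeImage):
        arr = img.gray
    else:
        raise TypeError(f"cannot infer geometry from {type(img).__name__}")
    cfg = img.config
    return arr.shape, cfg.axial_pitch_mm, cfg.lateral_pitch_mm


def roi_to_pixels(roi: ROISpec, img) -> tuple[int, int, int, int]:
    """Map a physical ROI onto half-open pixel ranges.

    Returns ``(line_start, line_stop, sample_start, sample_stop)``; each
    physical side length is honored to within one pixel pitch.
    """
    (n_lines, n_samples), ax_pitch, lat_pitch = _geometry(img)
    n_ax = max(1, _round_half_up(roi.side_cm * 10.0 / ax_pitch))
    n_lat = max(1, _round_half_up(roi.side_cm * 10.0 / lat_pitch))
    center_line = roi.center_line if roi.center_line is not None else n_lines // 2
    center_samp = _round_half_up(roi.center_depth_cm * 10.0 / ax_pitch)
    line_start = center_line - n_lat // 2
    samp_start = center_samp - n_ax // 2
    line_stop = line_start + n_lat
    samp_stop = samp_start + n_ax
    if line_start < 0 or samp_start < 0 or line_stop > n_lines or samp_stop > n_samples:
        raise BoundsError(
            f"ROI pixels [{line_start}:{line_stop}, {samp_start}:{samp_stop}] "
            f"exceed image bounds {(n_lines, n_samples)}"
        )
    return line_start, line_stop, samp_start, samp_stop


def roi_mean(img: ParametricImage, roi: ROISpec) -> float:
    """Arithmetic mean of valid pixels inside the ROI."""
    l0, l1, s0, s1 = roi_to_pixels(roi, img)
    patch = img.values[l0:l1, s0:s1]
    mask = img.valid_mask[l0:l1, s0:s1]
    if not mask.any():
        raise EmptyROIError("ROI contains no valid pixels")
    return float(patch[mask].mean())


# ---------------------------------------------------------------------------
# Subject tables.


def write_feature_table(records: Sequence[FeatureRecord], path: str | Path) -> Path:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "lda_texture_index": r.lda_texture_index,
            "snr": r.snr,
            "cfds_slope": r.cfds_slope,
            "usfli_class": r.usfli_class,
        }
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", *FEATURE_NAMES, "usfli_class"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"feature table missing columns: {sorted(missing)}")
    bad = set(df["usfli_class"]) - set(CLASS_LABELS)
    if bad:
        raise ValidationError(f"unknown severity labels: {sorted(bad)}")
    return df
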