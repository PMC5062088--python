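"""Tertile coding of the three features into the 0-6 diagnostic index.

Training subjects are split into tertiles per feature (LDA-texture index,
envelope SNR, CFDS slope); a subject scores 0/1/2 per feature for falling in
the first/second/third tertile, and the three codes sum to a quantitative
diagnostic index (QDI) between 0 and 6.  Cutoffs are fitted on training
records only and applied unchanged to held-out records.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import FEATURE_NAMES, FeatureRecord, ValidationError

__all__ = [
    "DegenerateCutoffError",
    "ScoringError",
    "QDIModel",
    "QDIScore",
    "fit_tertiles",
    "qdi_score",
    "score_table",
]


class DegenerateCutoffError(ValueError):
    """A feature is constant (or tied) so tertile cutoffs collapse."""


class ScoringError(ValueError):
    """A record lacks a finite value for a scored feature."""


@dataclasses.dataclass
class QDIModel:
    """Per-feature tertile cutoffs ``(t1, t2)`` fitted on training data.

    ``boundary="left"`` (default) assigns code 0 when ``value <= t1`` and
    code 1 when ``t1 < value <= t2``; ``boundary="right"`` uses strict
    ``value < t`` comparisons instead.
    """

    cutoffs: dict
    n_train: int
    boundary: str = "left"

    def __post_init__(self) -> None:
        if self.boundary not in ("left", "right"):
            raise ValidationError("boundary must be 'left' or 'right'")
        for feature, (t1, t2) in self.cutoffs.items():
            if not t1 < t2:
                raise DegenerateCutoffError(
                    f"cutoffs for {feature} are not increasing: {t1}, {t2}"
                )

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "cutoffs": {k: list(v) for k, v in self.cutoffs.items()},
            "n_train": self.n_train,
            "boundary": self.boundary,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "QDIModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            cutoffs={k: tuple(v) for k, v in payload["cutoffs"].items()},
            n_train=payload["n_train"],
            boundary=payload.get("boundary", "left"),
        )


@dataclasses.dataclass
class QDIScore:
    codes: dict  # feature -> 0/1/2
    total: int


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        if isinstance(r, FeatureRecord):
            rows.append({name: getattr(r, name) for name in FEATURE_NAMES})
        else:
            rows.append({name: r[name] for name in FEATURE_NAMES})
    return pd.DataFrame(rows)


def fit_tertiles(
    records, features: Sequence[str] = FEATURE_NAMES, boundary: str = "left"
) -> QDIModel:
    """Empirical 33.33rd/66.67th percentile cutoffs per feature.

    Quantiles interpolate linearly between order statistics.  Raises
    :class:`DegenerateCutoffError` if a feature is constant enough that the
    two cutoffs coincide.
    """
    df = _as_frame(records)
    if len(df) < 9:
        raise ValidationError(f"need >= 9 training records, got {len(df)}")
    cutoffs = {}
    for feature in features:
        v = np.asarray(df[feature], dtype=float)
        if not np.isfinite(v).all():
            raise ValidationError(f"non-finite training values for {feature}")
        if np.ptp(v) == 0:
            raise DegenerateCutoffError(f"feature {feature} is constant")
        t1, t2 = np.quantile(v, [1.0 / 3.0, 2.0 / 3.0], method="linear")
        if not t1 < t2:
            raise DegenerateCutoffError(f"tertile cutoffs for {feature} coincide")
        cutoffs[feature] = (float(t1), float(t2))
    return QDIModel(cutoffs=cutoffs, n_train=len(df), boundary=boundary)


def _code(value: float, t1: float, t2: float, boundary: str) -> int:
    if boundary == "left":
        return 0 if value <= t1 else (1 if value <= t2 else 2)
    return 0 if value < t1 else (1 if value < t2 else 2)


def qdi_score(model: QDIModel, record: FeatureRecord | Mapping | pd.Series) -> QDIScore:
    """Tertile codes and their 0-6 total for one record."""
    codes = {}
    for feature, (t1, t2) in model.cutoffs.items():
        if isinstance(record, FeatureRecord):
            value = getattr(record, feature, None)
        else:
            value = record.get(feature) if hasattr(record, "get") else record[feature]
        if value is None or not np.isfinite(value):
            raise ScoringError(f"record lacks a finite value for {feature}")
        codes[feature] = _code(float(value), t1, t2, model.boundary)
    return QDIScore(codes=codes, total=int(sum(codes.values())))


def score_table(model: QDIModel, df: pd.DataFrame) -> pd.DataFrame:
    """Score every row; returns a copy with per-feature code columns and ``qdi``."""
    out = df.copy()
    totals = np.zeros(len(df), dtype=int)
    for feature in model.cutoffs:
        codes = [qdi_score(model, row).codes[feature] for _, row in df.iterrows()]
        out[f"{feature}_code"] = codes
        totals += np.asarray(codes)
    out["qdi"] = totals
    return out
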