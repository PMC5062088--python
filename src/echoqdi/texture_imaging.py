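"""GLCM texture features, sliding-window texture imaging, and LDA fusion.

The gray-level co-occurrence matrix (GLCM) counts ordered pairs of gray
levels at displacement ``d`` along direction ``theta``; normalizing by the
total transition count ``K`` gives transition probabilities ``p(i, j)``.
Three Haralick features summarize each matrix, using the 1-based Haralick
index convention ``i = g + 1`` for gray level ``g``:

* autocorrelation  ``AC = sum_ij i j p(i, j)``  (gray-pair linear relation),
* sum average      ``SA = sum_k k p_{x+y}(k)``  (overall brightness),
* sum variance     ``SV = sum_k (k - SA)^2 p_{x+y}(k)``  (heterogeneity),

where ``p_{x+y}(k) = sum_{i+j=k} p(i, j)``, ``k = 2 .. 2 N_g``.  SV is
centered on SA (the variance-of-sum variant).

Because all three features are moments of the pairwise product ``i*j`` and
sum ``i+j``, the sliding-window maps are computed exactly with integral
images, without materializing a GLCM per window.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import scipy.linalg

from .data_model import (
    BModeImage,
    CLASS_LABELS,
    CLASS_RANK,
    ConfigError,
    ParametricImage,
    ValidationError,
)

__all__ = [
    "GLCM",
    "TextureFeatures",
    "LDAModel",
    "EmptyGLCMError",
    "THETA_OFFSETS",
    "compute_glcm",
    "haralick_features",
    "texture_feature_image",
    "window_shape_px",
    "fit_lda",
    "lda_index",
]


class EmptyGLCMError(ValueError):
    """Patch admits no gray-level transition at the requested (d, theta)."""


#: (line, sample) displacement per direction.  Directions differing by 180
#: degrees are equivalent after symmetrization, so each is reduced to a
#: representative with nonnegative line offset.
THETA_OFFSETS = {0: (0, 1), 45: (1, -1), 90: (1, 0), 135: (1, 1)}


@dataclasses.dataclass
class GLCM:
    """Symmetric gray-level co-occurrence counts and probabilities."""

    P: np.ndarray
    p: np.ndarray
    K: int
    N_g: int
    d: int
    theta: int


@dataclasses.dataclass
class TextureFeatures:
    AC: float
    SA: float
    SV: float
    p_xy: np.ndarray  # diagonal-sum distribution over k = 2 .. 2 N_g


def compute_glcm(window: np.ndarray, d: int = 1, theta: int = 0, n_g: int = 256) -> GLCM:
    """Symmetric GLCM of a gray-level patch at displacement ``d``, direction ``theta``.

    Each pixel pair is counted in both orders, so ``theta`` and
    ``theta + 180`` produce the same matrix.
    """
    if theta not in THETA_OFFSETS:
        raise ConfigError(f"theta must be one of {sorted(THETA_OFFSETS)}")
    window = np.asarray(window)
    if window.ndim != 2:
        raise ValidationError("patch must be 2-D")
    if window.min() < 0 or window.max() > n_g - 1:
        raise ValidationError(f"gray levels must lie in [0, {n_g - 1}]")
    a, b = (off * d for off in THETA_OFFSETS[theta])
    H, W = window.shape
    r0, r1 = max(0, -a), H - max(0, a)
    c0, c1 = max(0, -b), W - max(0, b)
    if r1 <= r0 or c1 <= c0:
        raise EmptyGLCMError(
            f"patch {window.shape} has no pairs at d={d}, theta={theta}"
        )
    i = window[r0:r1, c0:c1].ravel().astype(np.int64)
    j = window[r0 + a : r1 + a, c0 + b : c1 + b].ravel().astype(np.int64)
    counts = np.bincount(i * n_g + j, minlength=n_g * n_g) + np.bincount(
        j * n_g + i, minlength=n_g * n_g
    )
    P = counts.reshape(n_g, n_g)
    K = int(P.sum())
    return GLCM(P=P, p=P / K, K=K, N_g=n_g, d=d, theta=theta)


def haralick_features(glcm: GLCM) -> TextureFeatures:
    """AC, SA and SV of a normalized GLCM (1-based Haralick indices)."""
    p = np.asarray(glcm.p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError("GLCM probabilities are not normalized")
    n_g = glcm.N_g
    idx = np.arange(1, n_g + 1, dtype=float)
    ac = float(idx @ p @ idx)
    k_of_pair = np.add.outer(np.arange(n_g), np.arange(n_g)).ravel() + 2
    p_xy = np.bincount(k_of_pair, weights=p.ravel(), minlength=2 * n_g + 1)[2:]
    k = np.arange(2, 2 * n_g + 1, dtype=float)
    sa = float(k @ p_xy)
    sv = float(((k - sa) ** 2) @ p_xy)
    return TextureFeatures(AC=ac, SA=sa, SV=sv, p_xy=p_xy)


def _nearest_odd(x: float) -> int:
    return 2 * int(np.floor((x - 1.0) / 2.0 + 0.5)) + 1


def window_shape_px(window_mm: float, axial_pitch_mm: float, lateral_pitch_mm: float) -> tuple[int, int]:
    """(lines, samples) of a square physical window, rounded to odd counts."""
    wy = _nearest_odd(window_mm / lateral_pitch_mm)
    wx = _nearest_odd(window_mm / axial_pitch_mm)
    if wy < 3 or wx < 3:
        raise ConfigError(
            f"{window_mm} mm window maps to {(wy, wx)} px; need >= 2 px per axis"
        )
    return wy, wx


def _box_sums(arr: np.ndarray, wy: int, wx: int) -> np.ndarray:
    """Sums over all wy x wx boxes of ``arr`` (valid placements only)."""
    S = np.zeros((arr.shape[0] + 1, arr.shape[1] + 1))
    S[1:, 1:] = arr.cumsum(axis=0).cumsum(axis=1)
    return S[wy:, wx:] - S[:-wy, wx:] - S[wy:, :-wx] + S[:-wy, :-wx]


def texture_feature_image(
    bmode: BModeImage, window_mm: float = 3.0, step: int = 1
) -> tuple[ParametricImage, ParametricImage, ParametricImage]:
    """Sliding-window AC, SA and SV parametric images.

    Per output pixel, the three features of the window centered there are
    averaged over the four GLCM directions.  The border where the window
    exceeds the image is masked invalid.  Exactly equivalent to evaluating
    :func:`haralick_features` on :func:`compute_glcm` per window, but computed
    with integral images (the features are pair moments).
    """
    cfg = bmode.config
    wy, wx = window_shape_px(window_mm, cfg.axial_pitch_mm, cfg.lateral_pitch_mm)
    H, W = bmode.gray.shape
    if H < wy or W < wx:
        raise ConfigError(f"image {bmode.gray.shape} smaller than window {(wy, wx)}")
    q = bmode.gray.astype(np.float64) + 1.0  # 1-based Haralick index
    hy, hx = wy // 2, wx // 2

    ac = np.zeros((H - wy + 1, W - wx + 1))
    sa = np.zeros_like(ac)
    sv = np.zeros_like(ac)
    for a, b in THETA_OFFSETS.values():
        bb = abs(b)
        if b >= 0:
            A = q[: H - a, : W - b]
            B = q[a:, b:]
        else:  # re-anchor so the pair grid's origin matches the window corner
            A = q[: H - a, bb:]
            B = q[a:, : W - bb]
        K = (wy - a) * (wx - bb)
        sum_prod = _box_sums(A * B, wy - a, wx - bb)
        s = A + B
        sum_s = _box_sums(s, wy - a, wx - bb)
        sum_s2 = _box_sums(s * s, wy - a, wx - bb)
        mean_s = sum_s / K
        ac += sum_prod / K
        sa += mean_s
        sv += sum_s2 / K - mean_s**2
    n_dir = len(THETA_OFFSETS)
    ac /= n_dir
    sa /= n_dir
    sv /= n_dir

    images = []
    for name, interior in (("AC", ac), ("SA", sa), ("SV", sv)):
        values = np.full((H, W), np.nan)
        mask = np.zeros((H, W), dtype=bool)
        values[hy : H - hy, hx : W - hx] = interior
        mask[hy : H - hy, hx : W - hx] = True
        if step > 1:
            keep = np.zeros_like(mask)
            keep[hy : H - hy : step, hx : W - hx : step] = True
            mask &= keep
            values[~mask] = np.nan
        images.append(
            ParametricImage(
                values=values,
                feature_name=name,
                valid_mask=mask,
                axial_pitch_mm=cfg.axial_pitch_mm,
                lateral_pitch_mm=cfg.lateral_pitch_mm,
            )
        )
    return tuple(images)


# ---------------------------------------------------------------------------
# LDA fusion of (AC, SA, SV) into a single texture index.


@dataclasses.dataclass
class LDAModel:
    """Fisher discriminant direction over (AC, SA, SV).

    ``w`` is unit norm and oriented so per-class mean indices increase with
    severity rank; ``index = w . x + b`` with ``b`` centering the pooled mean
    index at zero (the absolute scale of the index is a convention).
    """

    w: np.ndarray
    b: float
    class_means: dict
    orientation: int
    class_order: tuple

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)


def fit_lda(
    features: np.ndarray,
    labels: Sequence[str],
    class_order: Sequence[str] = CLASS_LABELS,
) -> LDAModel:
    """Fit the leading discriminant of between- vs within-class scatter.

    ``w`` solves the generalized eigenproblem ``Sb w = lambda Sw w``; a ridge
    of ``1e-6 * trace(Sw)`` is added (with a warning) if ``Sw`` is singular.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    present = [c for c in class_order if (labels == c).any()]
    if len(present) < 2:
        raise ValidationError("LDA needs at least two classes")
    for c in present:
        if (labels == c).sum() < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 subjects")
    mu = X.mean(axis=0)
    n_feat = X.shape[1]
    Sw = np.zeros((n_feat, n_feat))
    Sb = np.zeros((n_feat, n_feat))
    for c in present:
        Xc = X[labels == c]
        dc = Xc - Xc.mean(axis=0)
        Sw += dc.T @ dc
        dm = (Xc.mean(axis=0) - mu)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)
    # guard against singular within-class scatter
    cond = np.linalg.cond(Sw)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("within-class scatter is singular; adding ridge", stacklevel=2)
        scale = np.trace(Sw) if np.trace(Sw) > 0 else 1.0
        Sw = Sw + 1e-6 * scale * np.eye(n_feat)
    vals, vecs = scipy.linalg.eigh(Sb, Sw)
    w = vecs[:, int(np.argmax(vals))]
    w = w / np.linalg.norm(w)
    ranks = np.array([CLASS_RANK.get(c, list(class_order).index(c)) for c in present])
    means = np.array([X[labels == c].mean(axis=0) @ w for c in present])
    orientation = 1
    if np.corrcoef(ranks, means)[0, 1] < 0:
        orientation = -1
        w = -w
    b = float(-(mu @ w))
    class_means = {c: float(X[labels == c].mean(axis=0) @ w + b) for c in present}
    return LDAModel(
        w=w, b=b, class_means=class_means, orientation=orientation,
        class_order=tuple(class_order),
    )


def lda_index(model: LDAModel, features: np.ndarray) -> np.ndarray | float:
    """Project feature triplet(s) onto the discriminant axis."""
    x = np.asarray(features, dtype=float)
    out = x @ model.w + model.b
    return float(out) if out.ndim == 0 else out
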