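"""Feature-level cohort simulation and diagnostic evaluation statistics.

The simulator draws per-class multivariate-normal triplets of
(LDA-texture index, SNR, CFDS slope) with marginal moments matching the
published group statistics and an exchangeable inter-feature correlation
``rho`` (a free parameter; the source moments are marginal only).  Evaluation
covers Mann-Whitney AUC with a seeded percentile-bootstrap CI, multinomial
logistic odds ratios with the mild class as reference, Pearson correlation,
and one-way ANOVA with a linear trend test.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import CLASS_LABELS, FEATURE_NAMES, ValidationError

__all__ = [
    "CohortSpec",
    "AUCResult",
    "ORResult",
    "TrendResult",
    "simulate_cohort",
    "auc",
    "multinomial_or",
    "pearson_r",
    "anova_trend",
    "welch_pairwise",
]

#: Published per-class (mean, sd) of each feature: normal, mild, severe.
DEFAULT_MOMENTS = {
    "lda_texture_index": {
        "normal": (2.710, 0.162),
        "mild": (2.858, 0.191),
        "severe": (3.000, 0.197),
    },
    "snr": {
        "normal": (1.820, 0.216),
        "mild": (1.965, 0.169),
        "severe": (2.053, 0.137),
    },
    "cfds_slope": {
        "normal": (0.866, 0.139),
        "mild": (0.935, 0.231),
        "severe": (1.000, 0.146),
    },
}

#: Training-set class sizes of the source cohort.
DEFAULT_TRAIN_N = {"normal": 126, "mild": 100, "severe": 88}
#: Held-out test-set class sizes.
DEFAULT_TEST_N = {"normal": 35, "mild": 27, "severe": 18}


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Per-class sample sizes and feature moments for cohort simulation."""

    n: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TRAIN_N)
    )
    moments: Mapping[str, Mapping[str, tuple]] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOMENTS.items()}
    )
    rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not -0.5 < self.rho < 1.0:
            # 3x3 exchangeable correlation is positive definite iff rho in (-1/2, 1)
            raise ValidationError(f"rho={self.rho} gives a non-PD covariance")
        for cls, count in self.n.items():
            if count < 0:
                raise ValidationError(f"negative n for class {cls}")
        for feature in FEATURE_NAMES:
            for cls, (_, sd) in self.moments[feature].items():
                if sd <= 0:
                    raise ValidationError(f"sd must be > 0 ({feature}, {cls})")


def simulate_cohort(spec: CohortSpec, id_prefix: str = "S") -> pd.DataFrame:
    """Draw a labelled feature table; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    R = np.full((3, 3), spec.rho)
    np.fill_diagonal(R, 1.0)
    rows = []
    counter = 0
    for cls in CLASS_LABELS:
        count = int(spec.n.get(cls, 0))
        if count == 0:
            continue
        means = np.array([spec.moments[f][cls][0] for f in FEATURE_NAMES])
        sds = np.array([spec.moments[f][cls][1] for f in FEATURE_NAMES])
        cov = np.outer(sds, sds) * R
        draws = rng.multivariate_normal(means, cov, size=count, method="cholesky")
        for row in draws:
            rows.append(
                {
                    "subject_id": f"{id_prefix}{counter:05d}",
                    **dict(zip(FEATURE_NAMES, row)),
                    "usfli_class": cls,
                }
            )
            counter += 1
    if not rows:
        raise ValidationError("cohort spec produced no subjects")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC / AUC.


@dataclasses.dataclass
class AUCResult:
    value: float
    ci: tuple[float, float] | None
    n_pos: int
    n_neg: int


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(scores)  # average ranks: half credit for ties
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> AUCResult:
    """Mann-Whitney AUC with a percentile-bootstrap confidence interval.

    Ties get half credit.  ``n_boot=0`` skips the CI.  Both classes must be
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    value = _auc_mann_whitney(scores, labels)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            while True:
                idx = rng.integers(0, labels.size, size=labels.size)
                if labels[idx].any() and not labels[idx].all():
                    break
            boots[b] = _auc_mann_whitney(scores[idx], labels[idx])
        lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
        ci = (float(lo), float(hi))
    return AUCResult(value=value, ci=ci, n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# Multinomial logistic odds ratios.


@dataclasses.dataclass
class ORResult:
    odds_ratio: float
    ci: tuple[float, float]
    coef: float
    se: float
    separation: bool = False


#: |coefficient| beyond which quasi-separation is flagged and the OR capped.
_SEPARATION_CAP = 15.0


def multinomial_or(
    qdi: Sequence[float],
    labels: Sequence[str],
    reference: str = "mild",
    alpha: float = 0.05,
) -> dict[str, ORResult]:
    """Per-class odds ratios per unit score from a multinomial logit.

    Maximum likelihood via Newton iterations (gradient tolerance 1e-8); the
    returned odds ratios are ``exp(coefficient)`` for each non-reference
    class against ``reference``, with Wald confidence intervals.  Divergent
    coefficients (separation) are flagged and capped.
    """
    qdi = np.asarray(qdi, dtype=float)
    labels = np.asarray(labels)
    present = [c for c in CLASS_LABELS if (labels == c).any()]
    if reference not in present:
        raise ValidationError(f"reference class {reference!r} absent")
    if len(present) < 2:
        raise ValidationError("multinomial model needs >= 2 classes present")
    if np.ptp(qdi) == 0:
        raise ValidationError("score is constant")
    categories = [reference] + [c for c in present if c != reference]
    code = {c: k for k, c in enumerate(categories)}
    y = np.array([code[c] for c in labels])
    X = sm.add_constant(qdi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MNLogit(y, X).fit(method="newton", maxiter=200, tol=1e-8, disp=0)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    out: dict[str, ORResult] = {}
    params = np.asarray(fit.params)  # [exog, J-1]
    bse = np.asarray(fit.bse)
    for j, cls in enumerate(categories[1:]):
        coef = float(params[1, j])
        se = float(bse[1, j])
        separation = (not np.isfinite(coef)) or abs(coef) > _SEPARATION_CAP or not np.isfinite(se)
        if not np.isfinite(coef):
            # complete separation: infer the direction from the group means
            sign = np.sign(
                qdi[labels == cls].mean() - qdi[labels == reference].mean()
            ) or 1.0
            coef = sign * _SEPARATION_CAP
        coef_capped = float(np.clip(coef, -_SEPARATION_CAP, _SEPARATION_CAP))
        out[cls] = ORResult(
            odds_ratio=float(np.exp(coef_capped)),
            ci=(float(np.exp(coef - z * se)), float(np.exp(coef + z * se))),
            coef=coef,
            se=se,
            separation=separation,
        )
    return out


# ---------------------------------------------------------------------------
# Correlation / trend statistics.


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValidationError("need matched inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input has undefined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclasses.dataclass
class TrendResult:
    f_stat: float
    p_anova: float
    trend_slope: float
    p_trend: float


def anova_trend(
    values: Sequence[float],
    labels: Sequence[str],
    order: Sequence[str] = CLASS_LABELS,
) -> TrendResult:
    """One-way ANOVA across ordinal groups plus a linear trend test.

    The trend test regresses the feature on the ordinal class rank
    (0, 1, 2, ...) and reports the slope's two-sided p-value.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == c] for c in order if (labels == c).any()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    if np.ptp(values) == 0:
        raise ValidationError("constant input")
    f_stat, p_anova = stats.f_oneway(*groups)
    rank_of = {c: r for r, c in enumerate(order)}
    ranks = np.array([rank_of[c] for c in labels], dtype=float)
    fit = stats.linregress(ranks, values)
    return TrendResult(
        f_stat=float(f_stat),
        p_anova=float(p_anova),
        trend_slope=float(fit.slope),
        p_trend=float(fit.pvalue),
    )


def welch_pairwise(
    values: Sequence[float],
    labels: Sequence[str],
    order: Sequence[str] = CLASS_LABELS,
) -> dict[tuple[str, str], float]:
    """Pairwise Welch t-tests with Bonferroni-corrected p-values."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    present = [c for c in order if (labels == c).any()]
    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1 :]]
    out = {}
    for a, b in pairs:
        _, p = stats.ttest_ind(values[labels == a], values[labels == b], equal_var=False)
        out[(a, b)] = float(min(1.0, p * len(pairs)))
    return out
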