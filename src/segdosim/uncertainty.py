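"""Relative measurement uncertainty as a power function of lesion volume.

Across lesions, the per-lesion coefficient of variation (CV%) of volume and
of PVC mean dose tends to fall with lesion volume. This is summarized by a
power model

    CV = alpha * v**beta

fit by ordinary least squares on the log-log scale (multiplicative error is
the natural model for CVs), with a t-test of the null beta = 0. The fitted
curve predicts the expected contouring uncertainty of an unseen lesion from
its contour volume alone. Spearman rank correlation between v and CV is
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerModelFit:
    """Fit of CV = alpha * v**beta on the log-log scale."""

    alpha: float
    beta: float
    se_beta: float
    p_beta: float
    n: int

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.p_beta <= 1:
            raise ValueError("p_beta must be in (0, 1]")


def fit_power_model(volumes_ml: Sequence[float], cv_percent: Sequence[float]) -> PowerModelFit:
    """OLS of log(CV) on log(v): alpha = exp(intercept), beta = slope.

    The volume covariate is the per-lesion mean contour volume; one point per
    lesion. Zero or negative CVs are rejected — a degenerate lesion must be
    excluded (or jittered) upstream.
    """
    v = np.asarray(volumes_ml, dtype=float)
    cv = np.asarray(cv_percent, dtype=float)
    if v.size != cv.size:
        raise ValueError("volumes and CVs must have equal length")
    if v.size < 3:
        raise ValueError("need at least 3 lesions to fit the power model")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    if np.any(cv <= 0):
        raise ValueError("non-positive CV: exclude or jitter degenerate lesions upstream")
    res = stats.linregress(np.log(v), np.log(cv))
    # constant CV: slope test is 0/0 in linregress, p comes back NaN
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return PowerModelFit(
        alpha=float(np.exp(res.intercept)),
        beta=float(res.slope),
        se_beta=float(res.stderr),
        p_beta=p,
        n=int(v.size),
    )


def predict_cv(fit: PowerModelFit, volume_ml: float) -> float:
    """Predicted CV% at a given contour volume: alpha * v**beta."""
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    return fit.alpha * v**fit.beta


def spearman_volume_cv(volumes: Sequence[float], cvs: Sequence[float]) -> float:
    """Spearman rank correlation between volume and CV (average-rank ties)."""
    v = np.asarray(volumes, dtype=float)
    c = np.asarray(cvs, dtype=float)
    if v.size != c.size or v.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.any(np.isnan(v)) or np.any(np.isnan(c)):
        raise ValueError("missing values not allowed")
    if np.ptp(v) == 0 or np.ptp(c) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(v, c).statistic)
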