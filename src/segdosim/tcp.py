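"""Propagation of dose uncertainty into tumor control probability (TCP).

TCP is modelled as a logistic function of mean absorbed dose d (Gy):

    TCP(d) = 1 / (1 + exp(-(b0 + b1 * d)))

with coefficients supplied by the user (they come from a separately fitted
dose-response analysis and are treated as fixed inputs here). For a lesion of
contour volume v with measured mean dose d, the contouring-induced dose SD is
predicted from the CV-versus-volume power model,

    SD = predict_cv(fit, v) / 100 * d,

and the induced TCP range is

    delta_TCP = TCP(d + 2*SD) - TCP(d - 2*SD),

i.e. the spread of plausible TCP values attributable to segmentation
variability alone. The lower dose bound is floored at 0 Gy. Deltas are
expressed in percentage points of probability; the effect is largest for
lesions whose dose sits near the steep mid-portion of the logistic curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .uncertainty import PowerModelFit, predict_cv


@dataclass(frozen=True)
class TCPModel:
    """Logistic dose-response: intercept b0 (logit units), slope b1 (1/Gy)."""

    b0: float
    b1: float

    def __post_init__(self):
        if not (np.isfinite(self.b0) and np.isfinite(self.b1)):
            raise ValueError("TCP coefficients must be finite")


#: Illustrative model for examples and demos (midpoint at 200 Gy). Real
#: analyses must supply coefficients from their own dose-response fit.
DEMO_TCP_MODEL = TCPModel(b0=-2.0, b1=0.01)


def tcp(model: TCPModel, dose_gy) -> float | np.ndarray:
    """Logistic TCP(d); strictly increasing in dose when b1 > 0."""
    d = np.asarray(dose_gy, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = 1.0 / (1.0 + np.exp(-(model.b0 + model.b1 * d)))
    return float(out) if out.ndim == 0 else out


def delta_tcp(
    model: TCPModel,
    power_fit: PowerModelFit,
    volume_ml: float,
    mean_dose_gy: float,
) -> dict:
    """Per-lesion TCP range induced by contouring uncertainty.

    ``power_fit`` must be the CV-versus-volume fit for the **PVC mean dose**
    (the quantity entering the TCP model). Returns a row dict with the
    predicted CV, the dose SD, TCP at the measured dose, and delta_tcp.
    """
    if mean_dose_gy < 0:
        raise ValueError("mean dose must be non-negative")
    cv = float(predict_cv(power_fit, volume_ml))
    sd = cv / 100.0 * mean_dose_gy
    lo = mean_dose_gy - 2.0 * sd
    if lo < 0:
        warnings.warn(
            f"dose - 2SD negative ({lo:.1f} Gy) at v={volume_ml:g} mL; floored at 0 Gy",
            stacklevel=2,
        )
        lo = 0.0
    hi = mean_dose_gy + 2.0 * sd
    return {
        "volume_ml": float(volume_ml),
        "mean_dose_gy": float(mean_dose_gy),
        "predicted_cv_pct": cv,
        "sd_gy": sd,
        "tcp": tcp(model, mean_dose_gy),
        "delta_tcp": abs(tcp(model, hi) - tcp(model, lo)),
    }


def delta_tcp_table(
    model: TCPModel,
    power_fit: PowerModelFit,
    lesions: pd.DataFrame,
) -> pd.DataFrame:
    """Apply :func:`delta_tcp` to a lesion table (volume_ml, mean_dose_gy)."""
    required = {"volume_ml", "mean_dose_gy"}
    if not required.issubset(lesions.columns):
        raise ValueError(f"lesion table needs columns {sorted(required)}")
    rows = [
        delta_tcp(model, power_fit, r.volume_ml, r.mean_dose_gy)
        for r in lesions.itertuples(index=False)
    ]
    return pd.DataFrame(rows)


def summarize_delta(delta_values: Sequence[float], threshold_pct: float = 25.0) -> dict:
    """Cohort summary of delta_TCP values, in percentage points.

    Returns mean, max and the fraction of lesions with delta_TCP of at least
    ``threshold_pct`` percentage points. Accepts deltas as probabilities
    (0..1) and reports them in %.
    """
    d = np.asarray(delta_values, dtype=float)
    if d.size == 0:
        raise ValueError("no delta values to summarize")
    pct = 100.0 * d
    return {
        "mean_delta_pct": float(pct.mean()),
        "max_delta_pct": float(pct.max()),
        "fraction_ge_threshold": float((pct >= threshold_pct).mean()),
        "threshold_pct": float(threshold_pct),
        "n": int(d.size),
    }
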