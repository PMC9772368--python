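"""Variance decomposition of repeated lesion measurements and reliability.

Repeated measurements y_{l,r,k} (lesion l, reader r, round k) are modelled
with a two-factor random-effects structure

    y = mu + a_l + b_{lr} + e_{lrk},
    a ~ N(0, sigma2_lesion),  b ~ N(0, sigma2_inter),  e ~ N(0, sigma2_intra)

where the reader effect is nested within lesion: sigma2_inter captures
between-reader disagreement on the same lesion and sigma2_intra the residual
within-reader (session-to-session) scatter. Estimation is by REML (statsmodels
MixedLM), with a closed-form expected-mean-squares (method-of-moments)
estimator available for balanced designs.

From the components the standard reliability coefficients (intraclass
correlations) follow:

    rho_inter = sigma2_lesion / sigma2_total
    rho_intra = (sigma2_lesion + sigma2_inter) / sigma2_total

together with the observer-variance shares
100 * sigma2_inter / (sigma2_inter + sigma2_intra) and its complement — i.e.
how the non-lesion variance splits between between-reader and within-reader
sources. The identity
inter_share = 100 * (rho_intra - rho_inter) / (1 - rho_inter) recovers the
shares from a published ICC pair alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

REQUIRED_COLUMNS = ("lesion_id", "reader_id", "round", "value")


@dataclass(frozen=True)
class VarianceComponents:
    """sigma^2 estimates (measurement units squared); total is their sum."""

    sigma2_lesion: float
    sigma2_inter: float
    sigma2_intra: float
    truncated: bool = False  # any negative MoM estimate clipped to zero

    def __post_init__(self):
        for name in ("sigma2_lesion", "sigma2_inter", "sigma2_intra"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_lesion + self.sigma2_inter + self.sigma2_intra


@dataclass(frozen=True)
class ReliabilityResult:
    """ICCs and the split of observer variance into inter/intra shares.

    Shares are NaN when the observer variance is zero (both rho equal 1).
    """

    rho_inter: float
    rho_intra: float
    inter_share_pct: float
    intra_share_pct: float


def _check_observations(obs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observations table missing columns: {missing}")
    if obs["lesion_id"].nunique() < 2:
        raise ValueError("need at least 2 lesions to separate lesion variance")
    max_rounds = obs.groupby(["lesion_id", "reader_id"])["round"].nunique().max()
    if max_rounds < 2:
        raise ValueError("sigma2_intra not estimable: no reader has repeated rounds")
    return obs


def _fit_mom_balanced(obs: pd.DataFrame) -> VarianceComponents:
    """Expected-mean-squares estimator for a balanced lesion x reader x round design."""
    counts = obs.groupby(["lesion_id", "reader_id"])["value"].count()
    n = counts.iloc[0]
    if counts.nunique() != 1:
        raise ValueError("method-of-moments requires a balanced design")
    readers_per_lesion = obs.groupby("lesion_id")["reader_id"].nunique()
    b = readers_per_lesion.iloc[0]
    if readers_per_lesion.nunique() != 1:
        raise ValueError("method-of-moments requires a balanced design")
    a = obs["lesion_id"].nunique()
    if n < 2:
        raise ValueError("sigma2_intra not estimable: no repeated rounds")

    grand = obs["value"].mean()
    lesion_means = obs.groupby("lesion_id")["value"].mean()
    cell_means = obs.groupby(["lesion_id", "reader_id"])["value"].mean()

    ss_lesion = b * n * ((lesion_means - grand) ** 2).sum()
    ss_reader = n * ((cell_means - cell_means.index.get_level_values(0).map(lesion_means)) ** 2).sum()
    merged = obs.merge(
        cell_means.rename("cell_mean"), left_on=["lesion_id", "reader_id"], right_index=True
    )
    ss_err = ((merged["value"] - merged["cell_mean"]) ** 2).sum()

    ms_lesion = ss_lesion / (a - 1)
    ms_reader = ss_reader / (a * (b - 1)) if b > 1 else 0.0
    ms_err = ss_err / (a * b * (n - 1))

    s2_intra = ms_err
    s2_inter = (ms_reader - ms_err) / n if b > 1 else 0.0
    s2_lesion = (ms_lesion - ms_reader) / (b * n) if b > 1 else (ms_lesion - ms_err) / n

    truncated = s2_inter < 0 or s2_lesion < 0
    if truncated:
        warnings.warn("negative method-of-moments variance estimate truncated to 0", stacklevel=3)
    return VarianceComponents(
        sigma2_lesion=max(s2_lesion, 0.0),
        sigma2_inter=max(s2_inter, 0.0),
        sigma2_intra=max(s2_intra, 0.0),
        truncated=truncated,
    )


def fit_variance_components(
    observations: pd.DataFrame,
    method: str = "reml",
    log_scale: bool = False,
) -> VarianceComponents:
    """Estimate (sigma2_lesion, sigma2_inter, sigma2_intra) from a long table.

    Parameters
    ----------
    observations : DataFrame
        Columns lesion_id, reader_id, round, value; one row per read.
    method : {"reml", "mom"}
        REML via a mixed model with a lesion random intercept and a
        reader-within-lesion variance component (handles unbalanced designs
        such as a single-round reader natively), or the closed-form
        expected-mean-squares estimator (balanced designs only).
    log_scale : bool
        Fit on log(value); components are then in squared log units.
    """
    obs = _check_observations(observations.copy())
    if log_scale:
        if (obs["value"] <= 0).any():
            raise ValueError("log_scale requires strictly positive values")
        obs["value"] = np.log(obs["value"])

    if np.ptp(obs["value"].to_numpy()) == 0:
        return VarianceComponents(0.0, 0.0, 0.0)

    if method == "mom":
        return _fit_mom_balanced(obs)
    if method != "reml":
        raise ValueError("method must be 'reml' or 'mom'")

    data = obs.rename(columns={"lesion_id": "lesion", "reader_id": "reader"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "value ~ 1",
            data,
            groups="lesion",
            re_formula="1",
            vc_formula={"reader": "0 + C(reader)"},
        )
        fit = model.fit(reml=True)
    s2_lesion = float(fit.cov_re.iloc[0, 0])
    s2_inter = float(fit.vcomp[0])
    s2_intra = float(fit.scale)
    truncated = s2_lesion < 0 or s2_inter < 0
    return VarianceComponents(
        sigma2_lesion=max(s2_lesion, 0.0),
        sigma2_inter=max(s2_inter, 0.0),
        sigma2_intra=max(s2_intra, 0.0),
        truncated=truncated,
    )


def reliability_coefficients(vc: VarianceComponents) -> ReliabilityResult:
    """ICCs and observer-variance shares from estimated components."""
    total = vc.sigma2_total
    if total <= 0:
        raise ValueError("sigma2_total must be positive")
    rho_inter = vc.sigma2_lesion / total
    rho_intra = (vc.sigma2_lesion + vc.sigma2_inter) / total
    observer = vc.sigma2_inter + vc.sigma2_intra
    if observer > 0:
        inter_share = 100.0 * vc.sigma2_inter / observer
        intra_share = 100.0 - inter_share
    else:
        inter_share = float("nan")
        intra_share = float("nan")
    return ReliabilityResult(
        rho_inter=rho_inter,
        rho_intra=rho_intra,
        inter_share_pct=inter_share,
        intra_share_pct=intra_share,
    )


def reliability_to_shares(rho_intra: float, rho_inter: float) -> tuple[float, float]:
    """Observer-variance shares implied by a published (rho_intra, rho_inter) pair.

    inter_share = 100 * (rho_intra - rho_inter) / (1 - rho_inter); this is the
    consistency identity linking an ICC table to its variance-share table.
    """
    if not (0 <= rho_inter <= rho_intra <= 1):
        raise ValueError("need 0 <= rho_inter <= rho_intra <= 1")
    if rho_inter == 1:
        raise ValueError("shares undefined when rho_inter = 1 (no observer variance)")
    inter = 100.0 * (rho_intra - rho_inter) / (1.0 - rho_inter)
    return inter, 100.0 - inter


def subgroup_analysis(
    observations: pd.DataFrame,
    subsets: dict[str, pd.Series | Sequence[bool]],
    method: str = "reml",
    log_scale: bool = False,
) -> pd.DataFrame:
    """Fit components and reliability per named subset of the observations.

    ``subsets`` maps a label (e.g. "small", "large", "well", "poor",
    "excl_L04") to a boolean row selector aligned with ``observations``.
    Degenerate subsets raise with the subset named.
    """
    rows = []
    for name, sel in subsets.items():
        sub = observations[np.asarray(sel, dtype=bool)]
        try:
            vc = fit_variance_components(sub, method=method, log_scale=log_scale)
            rel = reliability_coefficients(vc)
        except ValueError as exc:
            raise ValueError(f"subset {name!r}: {exc}") from exc
        rows.append(
            {
                "subset": name,
                "n_obs": len(sub),
                "sigma2_lesion": vc.sigma2_lesion,
                "sigma2_inter": vc.sigma2_inter,
                "sigma2_intra": vc.sigma2_intra,
                "rho_inter": rel.rho_inter,
                "rho_intra": rel.rho_intra,
                "inter_share_pct": rel.inter_share_pct,
                "intra_share_pct": rel.intra_share_pct,
            }
        )
    return pd.DataFrame(rows)


def simulate_observations(
    n_lesions: int,
    readers: dict[str, int],
    components: tuple[float, float, float],
    seed: int = 0,
    grand_mean: float = 0.0,
) -> pd.DataFrame:
    """Draw a long observation table directly from the random-effects model.

    Used for parameter-recovery checks: values are
    grand_mean + a_lesion + b_(lesion,reader) + e_read with the given
    (sigma2_lesion, sigma2_inter, sigma2_intra).
    """
    s2_lesion, s2_inter, s2_intra = components
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_lesions):
        a = rng.normal(0.0, np.sqrt(s2_lesion))
        for reader, n_rounds in readers.items():
            b = rng.normal(0.0, np.sqrt(s2_inter))
            for rnd in range(1, n_rounds + 1):
                e = rng.normal(0.0, np.sqrt(s2_intra))
                rows.append(
                    {
                        "lesion_id": f"L{i + 1:03d}",
                        "reader_id": reader,
                        "round": rnd,
                        "value": grand_mean + a + b + e,
                    }
                )
    return pd.DataFrame(rows)
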