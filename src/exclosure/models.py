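"""Treatment-by-time trend models.

Alpha diversity (one value per plot per occasion) is modelled per site with
a linear mixed-effects model,

    y_ij = b0 + b1*month + b2*exclusion + b3*month*exclusion + u_pair + e,

REML-fitted with a pair random intercept and Wald normal-approximation
SEs, CIs and p-values; control is the baseline (exclusion coded 1).  Beta
diversity summaries (one value per treatment per occasion) are modelled
with ordinary least squares using the same fixed-effect structure and no
random effect.  The interaction b3 — the difference between exclusion and
control in the per-month trend — is the study's effect size.

The partition components (balanced variation, abundance gradients) are
interpreted only when the *total* dissimilarity shows a significant
treatment-by-time interaction (strict p < 0.05); :func:`component_gating`
applies that rule, flagging rather than suppressing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ModelError

logger = logging.getLogger(__name__)

__all__ = ["ModelFit", "GatedReport", "fit_alpha_model", "fit_beta_model",
           "component_gating"]

TERMS = ("intercept", "month", "exclusion", "month:exclusion")


@dataclass
class ModelFit:
    """Fixed-effect estimates for one site x metric trend model.

    ``params`` etc. are length-4 arrays ordered as
    (intercept, month, exclusion, month:exclusion).
    """

    site: Optional[str]
    metric: str
    kind: str  # "alpha" (mixed model) or "beta" (OLS)
    params: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalues: np.ndarray
    sigma2_resid: float
    n_obs: int
    converged: bool
    sigma2_pairs: Optional[float] = None
    ci_level: float = 0.95
    residuals: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def interaction(self) -> float:
        return float(self.params[3])

    @property
    def interaction_se(self) -> float:
        return float(self.se[3])

    @property
    def interaction_ci(self):
        return float(self.ci_low[3]), float(self.ci_high[3])

    @property
    def p_interaction(self) -> float:
        return float(self.pvalues[3])

    @property
    def exclusion_slope(self) -> float:
        """Per-month trend in the exclusion treatment, b1 + b3."""
        return float(self.params[1] + self.params[3])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "site": self.site, "metric": self.metric, "kind": self.kind,
            "term": list(TERMS), "estimate": self.params, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.pvalues,
            "sigma2_pairs": np.nan if self.sigma2_pairs is None else float(self.sigma2_pairs),
            "sigma2_resid": self.sigma2_resid,
            "n_obs": self.n_obs, "converged": self.converged,
        })


def _design(df: pd.DataFrame) -> np.ndarray:
    excl = (df["treatment"] == "exclusion").to_numpy(float)
    month = df["month"].to_numpy(float)
    return np.column_stack([np.ones(len(df)), month, excl, month * excl])


def _single_site(df: pd.DataFrame, site):
    if site is not None:
        df = df[df["site"] == site]
    elif "site" in df.columns and df["site"].nunique() > 1:
        raise ModelError("data span multiple sites; pass site= or pre-filter")
    if "site" in df.columns and len(df):
        site = df["site"].iloc[0]
    return df, site


def _failed_fit(site, metric, kind, n_obs, ci_level, sigma2_pairs=None):
    nan4 = np.full(4, np.nan)
    return ModelFit(site=site, metric=metric, kind=kind, params=nan4.copy(),
                    se=nan4.copy(), ci_low=nan4.copy(), ci_high=nan4.copy(),
                    pvalues=nan4.copy(), sigma2_resid=np.nan, n_obs=n_obs,
                    converged=False, sigma2_pairs=sigma2_pairs, ci_level=ci_level)


def fit_alpha_model(
    records: pd.DataFrame,
    metric: str,
    site: Optional[str] = None,
    ci_level: float = 0.95,
) -> ModelFit:
    """REML mixed model for one site and one alpha metric.

    ``records`` needs columns pair, treatment, month and the metric column
    (as produced by :func:`exclosure.diversity.alpha_table`).  Flagged
    degenerate records with a missing response are dropped with a log
    entry.  Singular or non-converging fits return a ModelFit flagged
    ``converged=False`` rather than raising.
    """
    df, site = _single_site(records, site)
    if metric not in df.columns:
        raise ModelError(f"metric {metric!r} not found in records")
    keep = df[metric].notna()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("fit_alpha_model(%s, %s): dropped %d missing responses",
                    site, metric, n_drop)
    df = df[keep]
    if df["pair"].nunique() < 2:
        raise ModelError(f"need >= 2 pairs, have {df['pair'].nunique()}")
    if df["month"].nunique() < 2:
        raise ModelError(f"need >= 2 distinct months, have {df['month'].nunique()}")

    y = df[metric].to_numpy(float)
    X = _design(df)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=df["pair"].to_numpy())
            res = model.fit(reml=True)
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("fit_alpha_model(%s, %s) failed: %s", site, metric, exc)
        return _failed_fit(site, metric, "alpha", len(df), ci_level)

    conf = res.conf_int(alpha=1.0 - ci_level)
    conf = np.asarray(conf)[:4]
    resid = df.loc[:, [c for c in ("site", "pair", "plot", "treatment", "month")
                       if c in df.columns]].copy()
    resid["residual"] = np.asarray(res.resid)
    fit = ModelFit(
        site=site, metric=metric, kind="alpha",
        params=np.asarray(res.fe_params, dtype=float),
        se=np.asarray(res.bse_fe, dtype=float),
        ci_low=conf[:, 0], ci_high=conf[:, 1],
        pvalues=np.asarray(res.pvalues, dtype=float)[:4],
        sigma2_pairs=float(np.asarray(res.cov_re)[0, 0]),
        sigma2_resid=float(res.scale),
        n_obs=len(df),
        converged=bool(res.converged),
        ci_level=ci_level,
        residuals=resid,
    )
    if not np.all(np.isfinite(fit.se)):
        fit.converged = False
    return fit


def fit_beta_model(
    summaries: pd.DataFrame,
    component: str = "total",
    site: Optional[str] = None,
    ci_level: float = 0.95,
    weights: Optional[str] = None,
) -> ModelFit:
    """OLS trend model for one site and one beta-diversity component.

    ``summaries`` needs columns treatment, month and the component column
    (as produced by :func:`exclosure.beta.beta_summaries`); one value per
    treatment x occasion.  Missing (flagged) summaries are dropped with a
    log entry; each treatment must retain >= 3 distinct occasions.
    ``weights='jackknife'`` uses inverse jackknife variances (off by
    default: the summaries are modelled unweighted).
    """
    df, site = _single_site(summaries, site)
    if component not in df.columns:
        raise ModelError(f"component {component!r} not found in summaries")
    keep = df[component].notna()
    if (~keep).any():
        logger.info("fit_beta_model(%s, %s): dropped %d missing summaries",
                    site, component, int((~keep).sum()))
    df = df[keep]
    for treatment, grp in df.groupby("treatment"):
        if grp["month"].nunique() < 3:
            raise ModelError(
                f"treatment {treatment!r} has {grp['month'].nunique()} occasions; need >= 3"
            )

    y = df[component].to_numpy(float)
    X = _design(df)
    if weights == "jackknife":
        se = df[f"se_{component}"].to_numpy(float)
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            raise ModelError("jackknife weights requested but SEs are missing or zero")
        res = sm.WLS(y, X, weights=1.0 / se**2).fit()
    elif weights is None:
        res = sm.OLS(y, X).fit()
    else:
        raise ModelError(f"unknown weights option {weights!r}")

    conf = np.asarray(res.conf_int(alpha=1.0 - ci_level))
    resid = df.loc[:, [c for c in ("site", "treatment", "month") if c in df.columns]].copy()
    resid["residual"] = np.asarray(res.resid)
    return ModelFit(
        site=site, metric=component, kind="beta",
        params=np.asarray(res.params, dtype=float),
        se=np.asarray(res.bse, dtype=float),
        ci_low=conf[:, 0], ci_high=conf[:, 1],
        pvalues=np.asarray(res.pvalues, dtype=float),
        sigma2_resid=float(res.mse_resid),
        n_obs=int(res.nobs),
        converged=True,
        ci_level=ci_level,
        residuals=resid,
    )


@dataclass
class GatedReport:
    """Interpretability gate for partition components at one site."""

    site: Optional[str]
    total_p_interaction: float
    interpretable: bool
    components: Mapping[str, ModelFit]


def component_gating(fits: Mapping[str, ModelFit], alpha: float = 0.05) -> GatedReport:
    """Flag balanced/gradient fits as interpretable only when the total
    dissimilarity's treatment-by-time interaction is significant.

    The boundary case p == alpha is *non*-interpretable (strict inequality).
    Components are flagged, not removed.
    """
    if "total" not in fits:
        raise ModelError("component_gating requires a fit for 'total'")
    total = fits["total"]
    p3 = total.p_interaction
    interpretable = bool(np.isfinite(p3) and p3 < alpha)
    components = {k: v for k, v in fits.items() if k != "total"}
    return GatedReport(
        site=total.site,
        total_p_interaction=p3,
        interpretable=interpretable,
        components=components,
    )
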