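"""Cross-site comparison of treatment-by-time effect sizes.

Each site contributes one interaction estimate (b3) per diversity metric.
Sites are compared pairwise: the difference in estimates is tested with a
z-test whose standard error is reconstructed from the per-site CIs
(se = CI width / (2 z)), exactly as when only reported intervals are
available.  For Wald-normal CIs this reconstruction reproduces the model
SE; ``se_source='wald'`` uses the model SEs directly.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ModelError
from .models import ModelFit

logger = logging.getLogger(__name__)

__all__ = ["se_from_ci", "pairwise_contrasts", "forest_plot"]


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric normal CI.

    se = (ci_high - ci_low) / (2 * z_{(1+level)/2}); for level 0.95 the
    divisor is 2 * 1.959964.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if not ci_high > ci_low:
        raise ValueError(f"degenerate CI: high ({ci_high}) must exceed low ({ci_low})")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return float((ci_high - ci_low) / (2.0 * z))


def pairwise_contrasts(
    fits: Mapping[str, ModelFit],
    metric: str,
    level: float = 0.95,
    se_source: str = "ci",
) -> pd.DataFrame:
    """All unordered pairwise site contrasts of the interaction estimate.

    Parameters
    ----------
    fits
        Mapping site -> ModelFit for one metric.  Non-converged fits are
        skipped with a log entry.
    se_source
        'ci' (default) reconstructs per-site SEs from each fit's
        interaction CI via :func:`se_from_ci`; 'wald' takes the model SEs.

    Returns
    -------
    DataFrame with one row per site pair: diff = b3_x - b3_y, se_diff,
    z, two-sided normal p, and the CI of the difference.
    """
    if se_source not in ("ci", "wald"):
        raise ValueError(f"unknown se_source {se_source!r}")
    usable = {}
    for site in sorted(fits):
        fit = fits[site]
        if not fit.converged or not np.isfinite(fit.interaction):
            logger.warning("pairwise_contrasts(%s): skipping non-converged fit for %s",
                           metric, site)
            continue
        if se_source == "ci":
            se = se_from_ci(*fit.interaction_ci, level=fit.ci_level)
        else:
            se = fit.interaction_se
        usable[site] = (fit.interaction, se)
    if len(usable) < 2:
        raise ModelError(f"need converged fits for >= 2 sites, have {len(usable)}")

    z_mult = stats.norm.ppf(0.5 * (1.0 + level))
    rows = []
    for site_x, site_y in combinations(sorted(usable), 2):
        bx, sx = usable[site_x]
        by, sy = usable[site_y]
        diff = bx - by
        se_diff = float(np.hypot(sx, sy))
        z = diff / se_diff
        rows.append({
            "metric": metric, "site_x": site_x, "site_y": site_y,
            "diff": diff, "se_diff": se_diff, "z": z,
            "p": float(2.0 * stats.norm.sf(abs(z))),
            "ci_low": diff - z_mult * se_diff,
            "ci_high": diff + z_mult * se_diff,
        })
    return pd.DataFrame(rows)


def forest_plot(contrasts: pd.DataFrame, path=None, ax=None):
    """Forest plot of pairwise site differences with their CIs."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(contrasts) + 1.5))
    labels = [f"{r.metric}: {r.site_x} - {r.site_y}" for r in contrasts.itertuples()]
    y = np.arange(len(contrasts))[::-1]
    ax.errorbar(
        contrasts["diff"], y,
        xerr=[contrasts["diff"] - contrasts["ci_low"],
              contrasts["ci_high"] - contrasts["diff"]],
        fmt="o", color="k", capsize=3,
    )
    ax.axvline(0.0, linestyle="--", color="grey")
    ax.set_yticks(y)
    ax.set_yticklabels(labels)
    ax.set_xlabel("difference in treatment-by-time interaction")
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
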