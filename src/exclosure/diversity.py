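"""Plot-level alpha diversity: richness, Shannon entropy, inverse Simpson.

Following the study design this package implements, the Hellinger
transformation is applied *before* every diversity metric.  Richness is
transform-invariant (it only asks which species are present), but Shannon
and inverse Simpson computed on Hellinger-derived proportions differ from
their raw-count values; ``transformed=False`` gives the raw-count variant
for comparison.

Conventions for empty plots (no individuals recorded that occasion):
richness 0, Shannon 0, inverse Simpson missing (NaN), and a ``degenerate``
flag set — records are flagged, never silently dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .community import CommunityMatrix, hellinger_transform
from .survey import community_matrix, plot_roster, site_species

logger = logging.getLogger(__name__)

__all__ = ["alpha_indices", "alpha_table"]

ALPHA_METRICS = ("richness", "shannon", "inv_simpson")


def _proportions(values: np.ndarray) -> np.ndarray:
    """Row-wise proportions; all-zero rows stay all-zero."""
    totals = values.sum(axis=1)
    out = np.zeros_like(values, dtype=float)
    ok = totals > 0
    out[ok] = values[ok] / totals[ok, None]
    return out


def alpha_indices(matrix: CommunityMatrix, transformed: bool = True) -> pd.DataFrame:
    """Per-plot alpha diversity for one raw community matrix.

    Parameters
    ----------
    matrix
        Raw (count-valued) community matrix.
    transformed
        If True (default), Shannon and inverse Simpson are computed on the
        Hellinger-transformed rows renormalized to proportions
        p_i = h_i / sum(h); if False, on raw-count proportions.

    Returns
    -------
    DataFrame with one row per plot: richness, shannon (natural-log units),
    inv_simpson (effective species number), degenerate flag.
    """
    raw = matrix.values
    richness = (raw > 0).sum(axis=1).astype(int)
    basis = hellinger_transform(matrix).values if transformed else raw
    p = _proportions(basis)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    shannon = -(p * logp).sum(axis=1)
    simpson_conc = (p**2).sum(axis=1)
    inv_simpson = np.full(len(richness), np.nan)
    nonempty = simpson_conc > 0
    inv_simpson[nonempty] = 1.0 / simpson_conc[nonempty]
    degenerate = richness == 0
    shannon = np.where(degenerate, 0.0, shannon)
    out = pd.DataFrame(
        {
            "plot": list(matrix.plot_ids),
            "richness": richness,
            "shannon": shannon,
            "inv_simpson": inv_simpson,
            "degenerate": degenerate,
        }
    )
    if matrix.plot_meta is not None:
        out.insert(1, "pair", matrix.plot_meta.loc[out["plot"], "pair"].to_numpy())
        out.insert(2, "treatment", matrix.plot_meta.loc[out["plot"], "treatment"].to_numpy())
    if matrix.site is not None:
        out.insert(0, "site", matrix.site)
    if matrix.month is not None:
        out.insert(1, "month", matrix.month)
    return out


def alpha_table(survey: pd.DataFrame, transformed: bool = True) -> pd.DataFrame:
    """Alpha diversity for every plot x occasion in a survey table.

    Slicing is per site x occasion with the site-wide species union as
    columns; sites are processed in lexicographic order, occasions in
    increasing month order, so output is invariant to input row order.
    """
    pieces = []
    for site in sorted(survey["site"].unique()):
        roster = plot_roster(survey, site)
        species = site_species(survey, site)
        months = sorted(survey.loc[survey["site"] == site, "month"].unique())
        for month in months:
            cm = community_matrix(survey, site, month, roster=roster, species=species)
            pieces.append(alpha_indices(cm, transformed=transformed))
    out = pd.concat(pieces, ignore_index=True)
    n_degenerate = int(out["degenerate"].sum())
    if n_degenerate:
        logger.info("alpha_table: %d empty plot-occasions flagged degenerate", n_degenerate)
    return out
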