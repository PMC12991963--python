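"""Abundance-based Bray-Curtis dissimilarity and its additive partition.

For two abundance vectors the Bray-Curtis dissimilarity decomposes into a
*balanced-variation* component (some species gain what others lose —
the abundance analogue of species turnover) and an *abundance-gradient*
component (one community is a uniformly poorer version of the other — the
abundance analogue of nestedness).  With per-pair component sums

    A  = sum_s min(x_s, y_s)      shared abundance
    B  = sum_s x_s - A            abundance unique to the first plot
    C  = sum_s y_s - A            abundance unique to the second plot

the pairwise quantities are

    total    = (B + C) / (2A + B + C)
    balanced = min(B, C) / (A + min(B, C))
    gradient = total - balanced

and the multiple-site versions accumulate A, min(B, C), max(B, C) over all
unordered plot pairs:

    total    = (Smin + Smax) / (2 SA + Smin + Smax)
    balanced = Smin / (SA + Smin)
    gradient = total - balanced.

On presence/absence (0/1) matrices these reduce to the incidence-based
Sorensen / Simpson-turnover / nestedness-resultant family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .community import CommunityMatrix, hellinger_transform
from .errors import InsufficientPlotsError, UndefinedDissimilarityError
from .jackknife import _summarize
from .survey import community_matrix, plot_roster, site_species, TREATMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "BetaPartition",
    "pairwise_bray_partition",
    "multisite_bray_partition",
    "beta_summaries",
]

BETA_COMPONENTS = ("total", "balanced", "gradient")


@dataclass
class BetaPartition:
    """Multiple-site Bray-Curtis dissimilarity and its additive parts."""

    total: float
    balanced: float
    gradient: float
    n_plots: int
    site: Optional[str] = None
    month: Optional[int] = None
    treatment: Optional[str] = None
    n_dropped: int = 0
    se: dict = field(default_factory=dict)
    ci_low: dict = field(default_factory=dict)
    ci_high: dict = field(default_factory=dict)

    def component(self, name: str) -> float:
        if name not in BETA_COMPONENTS:
            raise KeyError(f"unknown component {name!r}; expected one of {BETA_COMPONENTS}")
        return getattr(self, name)


def pairwise_bray_partition(x, y) -> Tuple[float, float, float]:
    """Bray-Curtis dissimilarity between two plots, partitioned.

    Returns ``(total, balanced, gradient)``.  Identical vectors give exact
    zeros; two communities with disjoint support give (1, 1, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    a = np.minimum(x, y).sum()
    b = x.sum() - a
    c = y.sum() - a
    denom = 2 * a + b + c
    if denom == 0:
        raise UndefinedDissimilarityError(
            "dissimilarity undefined: both communities are empty"
        )
    if b == 0 and c == 0:
        return 0.0, 0.0, 0.0
    total = (b + c) / denom
    m = min(b, c)
    balanced = m / (a + m) if (a + m) > 0 else 1.0
    return float(total), float(balanced), float(total - balanced)


def _multisite_components(values: np.ndarray) -> Tuple[float, float, float]:
    """Pairwise-accumulated (sum A, sum min(B,C), sum max(B,C))."""
    totals = values.sum(axis=1)
    # A[j,k] = sum_s min(x_js, x_ks); vectorized over all plot pairs
    a = np.minimum(values[:, None, :], values[None, :, :]).sum(axis=2)
    b = totals[:, None] - a
    c = totals[None, :] - a
    iu = np.triu_indices(len(values), k=1)
    sum_a = a[iu].sum()
    sum_min = np.minimum(b, c)[iu].sum()
    sum_max = np.maximum(b, c)[iu].sum()
    return float(sum_a), float(sum_min), float(sum_max)


def multisite_bray_partition(
    matrix: Union[CommunityMatrix, np.ndarray],
    drop_empty: bool = True,
) -> BetaPartition:
    """Multiple-site Bray-Curtis dissimilarity over all plots of a matrix.

    All-zero rows (empty plots) are excluded (logged) before computing;
    fewer than two usable plots raises :class:`InsufficientPlotsError`.
    For exactly two plots the result equals :func:`pairwise_bray_partition`.
    """
    is_cm = isinstance(matrix, CommunityMatrix)
    values = matrix.values if is_cm else np.asarray(matrix, dtype=float)
    site = matrix.site if is_cm else None
    month = matrix.month if is_cm else None
    treatment = matrix.treatment if is_cm else None
    if values.ndim != 2:
        raise ValueError("matrix must be 2-D (plots x species)")
    if np.any(values < 0):
        raise ValueError("abundances must be non-negative")

    n_dropped = 0
    if drop_empty:
        nonzero = values.sum(axis=1) > 0
        n_dropped = int((~nonzero).sum())
        if n_dropped:
            logger.info(
                "multisite_bray_partition: dropped %d empty plot(s) (site=%s month=%s treatment=%s)",
                n_dropped, site, month, treatment,
            )
            values = values[nonzero]

    if values.shape[0] < 2:
        raise InsufficientPlotsError(
            f"need >= 2 non-empty plots, have {values.shape[0]} "
            f"(site={site}, month={month}, treatment={treatment})",
            site=site, month=month, treatment=treatment,
        )

    sum_a, sum_min, sum_max = _multisite_components(values)
    denom = 2 * sum_a + sum_min + sum_max
    if sum_min == 0 and sum_max == 0:
        total = balanced = 0.0
    else:
        total = (sum_min + sum_max) / denom
        balanced = sum_min / (sum_a + sum_min) if (sum_a + sum_min) > 0 else 1.0
    return BetaPartition(
        total=float(total),
        balanced=float(balanced),
        gradient=float(total - balanced),
        n_plots=int(values.shape[0]),
        site=site,
        month=month,
        treatment=treatment,
        n_dropped=n_dropped,
    )


def _jackknife_partition(values: np.ndarray, ci_level: float):
    """LOO jackknife of (total, balanced, gradient) jointly over plots."""
    full = multisite_bray_partition(values, drop_empty=False)
    theta = np.array([full.total, full.balanced, full.gradient])
    n = values.shape[0]
    loo = np.empty((n, 3))
    for i in range(n):
        part = multisite_bray_partition(np.delete(values, i, axis=0), drop_empty=False)
        loo[i] = (part.total, part.balanced, part.gradient)
    _, se, lo, hi = _summarize(theta, loo, ci_level)
    return se, lo, hi


def beta_summaries(
    survey: pd.DataFrame,
    transformed: bool = True,
    jackknife: bool = True,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """One multiple-site partition per site x occasion x treatment.

    The Hellinger transformation (when ``transformed``) is applied to the
    full site x occasion matrix before splitting by treatment; the
    transform is row-wise, so the split order is immaterial.  Occasions
    with fewer than two usable plots in a treatment yield a flagged row of
    NaNs rather than an error.  With ``jackknife=True``, plot-level
    leave-one-out SEs and approximate CIs accompany each component
    (requires >= 3 usable plots; otherwise flagged).
    """
    rows = []
    for site in sorted(survey["site"].unique()):
        roster = plot_roster(survey, site)
        species = site_species(survey, site)
        months = sorted(survey.loc[survey["site"] == site, "month"].unique())
        for month in months:
            cm = community_matrix(survey, site, month, roster=roster, species=species)
            basis = hellinger_transform(cm) if transformed else cm
            for treatment in TREATMENTS:
                plots = [p for p in basis.plot_ids if roster.loc[p, "treatment"] == treatment]
                sub = basis.select_plots(plots)
                sub.treatment = treatment
                row = {"site": site, "month": month, "treatment": treatment}
                try:
                    part = multisite_bray_partition(sub)
                except InsufficientPlotsError as exc:
                    logger.warning("beta_summaries: %s", exc)
                    row.update(
                        n_plots=np.nan, n_dropped=np.nan, flag="insufficient_plots",
                        **{c: np.nan for c in BETA_COMPONENTS},
                    )
                    rows.append(row)
                    continue
                row.update(
                    n_plots=part.n_plots,
                    n_dropped=part.n_dropped,
                    flag="ok",
                    total=part.total,
                    balanced=part.balanced,
                    gradient=part.gradient,
                )
                if jackknife:
                    usable = sub.values[sub.values.sum(axis=1) > 0]
                    if usable.shape[0] >= 3:
                        se, lo, hi = _jackknife_partition(usable, ci_level)
                        for k, comp in enumerate(BETA_COMPONENTS):
                            row[f"se_{comp}"] = se[k]
                            row[f"ci_low_{comp}"] = lo[k]
                            row[f"ci_high_{comp}"] = hi[k]
                    else:
                        row["flag"] = "no_jackknife"
                rows.append(row)
    out = pd.DataFrame(rows)
    if jackknife:
        for comp in BETA_COMPONENTS:
            for col in (f"se_{comp}", f"ci_low_{comp}", f"ci_high_{comp}"):
                if col not in out.columns:
                    out[col] = np.nan
    return out
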