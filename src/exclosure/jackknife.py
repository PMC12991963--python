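"""Plot-level leave-one-out jackknife for multiple-site statistics.

A multiple-site statistic (e.g. the multiple-site Bray-Curtis dissimilarity)
yields one value per group of plots, so its uncertainty cannot be read off
plot-level replicates directly.  The jackknife drops each plot in turn,
recomputes the statistic, forms pseudo-values

    p_i = n * theta - (n - 1) * theta_{-i},

and estimates the standard error from the pseudo-value variance.  The
approximate CI uses a normal multiplier and is centred on the full-sample
estimate (the bias-corrected pseudo-value mean is reported alongside;
``center='pseudo_mean'`` switches the centring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .community import CommunityMatrix
from .errors import JackknifeError

__all__ = ["JackknifeResult", "jackknife_statistic"]


@dataclass
class JackknifeResult:
    estimate: float
    pseudo_mean: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    loo_values: np.ndarray


def _summarize(theta, loo, ci_level, center="estimate"):
    """Pseudo-value SE and CI given the full-sample value and LOO values.

    ``theta`` and ``loo`` may be vector-valued (components in the last
    axis); the pseudo-value algebra is applied componentwise.
    """
    loo = np.asarray(loo, dtype=float)
    n = loo.shape[0]
    theta = np.asarray(theta, dtype=float)
    pseudo = n * theta - (n - 1) * loo
    pseudo_mean = pseudo.mean(axis=0)
    se = np.sqrt(((pseudo - pseudo_mean) ** 2).sum(axis=0) / (n * (n - 1)))
    z = stats.norm.ppf(0.5 * (1.0 + ci_level))
    mid = theta if center == "estimate" else pseudo_mean
    return pseudo_mean, se, mid - z * se, mid + z * se


def jackknife_statistic(
    matrix,
    statistic,
    ci_level: float = 0.95,
    center: str = "estimate",
) -> JackknifeResult:
    """Leave-one-plot-out jackknife of ``statistic`` over a community matrix.

    Parameters
    ----------
    matrix
        :class:`CommunityMatrix` or a 2-D array (plots x species).
    statistic
        Callable mapping a matrix of the same kind to a single number; it
        must be defined on every (n-1)-plot subset.
    ci_level
        CI level in (0, 1); multiplier is the normal quantile.
    center
        'estimate' (default) centres the CI on the full-sample statistic,
        'pseudo_mean' on the bias-corrected pseudo-value mean.
    """
    if not 0 < ci_level < 1:
        raise JackknifeError(f"ci_level must be in (0, 1), got {ci_level}")
    if center not in ("estimate", "pseudo_mean"):
        raise JackknifeError(f"unknown CI center {center!r}")
    is_cm = isinstance(matrix, CommunityMatrix)
    n = matrix.n_plots if is_cm else np.asarray(matrix).shape[0]
    if n < 3:
        raise JackknifeError(f"jackknife needs >= 3 plots, got {n}")

    theta = float(statistic(matrix))
    loo = np.empty(n)
    for i in range(n):
        if is_cm:
            keep = [p for j, p in enumerate(matrix.plot_ids) if j != i]
            sub = matrix.select_plots(keep)
            label = matrix.plot_ids[i]
        else:
            sub = np.delete(np.asarray(matrix, dtype=float), i, axis=0)
            label = i
        try:
            loo[i] = float(statistic(sub))
        except Exception as exc:
            raise JackknifeError(
                f"statistic failed after dropping plot {label!r}: {exc}"
            ) from exc

    pseudo_mean, se, lo, hi = _summarize(theta, loo, ci_level, center)
    return JackknifeResult(
        estimate=theta,
        pseudo_mean=float(pseudo_mean),
        se=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        n=n,
        loo_values=loo,
    )
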