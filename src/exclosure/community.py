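"""Plot-by-species community matrices and the Hellinger transformation.

A :class:`CommunityMatrix` holds the abundances of one site x survey-month
slice of the experiment (both treatments, or one), with plot and species
labels and optional per-plot metadata (pair, treatment).  The Hellinger
transformation maps each row x to sqrt(x / rowsum), the standard
pre-treatment that down-weights hyperdominant taxa and makes abundance data
compatible with Euclidean/linear methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SurveyValidationError

__all__ = ["CommunityMatrix", "hellinger_transform"]


@dataclass
class CommunityMatrix:
    """Plots x species abundance matrix for one site/occasion slice.

    Parameters
    ----------
    values
        2-D non-negative array, one row per plot, one column per species.
        Raw matrices are integer-valued counts; transformed matrices are
        real-valued.
    plot_ids, species_ids
        Unique row / column labels.
    site, month, treatment
        Slice metadata carried along for reporting (``treatment`` is None
        for mixed-treatment matrices).
    plot_meta
        Optional DataFrame indexed like ``plot_ids`` with columns ``pair``
        and ``treatment``.
    """

    values: np.ndarray
    plot_ids: tuple
    species_ids: tuple
    site: Optional[str] = None
    month: Optional[int] = None
    treatment: Optional[str] = None
    plot_meta: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.plot_ids = tuple(self.plot_ids)
        self.species_ids = tuple(self.species_ids)
        problems = []
        if self.values.ndim != 2:
            problems.append("values must be a 2-D array")
        else:
            if self.values.shape != (len(self.plot_ids), len(self.species_ids)):
                problems.append(
                    f"shape {self.values.shape} does not match "
                    f"{len(self.plot_ids)} plots x {len(self.species_ids)} species"
                )
            if not np.all(np.isfinite(self.values)):
                problems.append("values must be finite")
            elif np.any(self.values < 0):
                problems.append("values must be non-negative")
        if len(set(self.plot_ids)) != len(self.plot_ids):
            problems.append("duplicate plot labels")
        if len(set(self.species_ids)) != len(self.species_ids):
            problems.append("duplicate species labels")
        if problems:
            raise SurveyValidationError(problems)

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def row_totals(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def select_plots(self, plot_ids: Sequence) -> "CommunityMatrix":
        """Sub-matrix restricted to the given plots (order preserved)."""
        index = {p: i for i, p in enumerate(self.plot_ids)}
        rows = [index[p] for p in plot_ids]
        meta = None
        if self.plot_meta is not None:
            meta = self.plot_meta.loc[list(plot_ids)]
        treatment = self.treatment
        if meta is not None and treatment is None:
            levels = set(meta["treatment"])
            if len(levels) == 1:
                treatment = next(iter(levels))
        return replace(
            self,
            values=self.values[rows],
            plot_ids=tuple(plot_ids),
            plot_meta=meta,
            treatment=treatment,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.plot_ids), columns=list(self.species_ids)
        )


def hellinger_transform(matrix: CommunityMatrix) -> CommunityMatrix:
    """Row-wise Hellinger transformation: x_ij -> sqrt(x_ij / sum_j x_ij).

    Rows with a positive total come out with unit Euclidean norm.  All-zero
    rows (empty plots) map to all-zero rows by convention; downstream code
    flags or drops them explicitly rather than erroring here.
    """
    totals = matrix.values.sum(axis=1)
    out = np.zeros_like(matrix.values, dtype=float)
    positive = totals > 0
    out[positive] = np.sqrt(matrix.values[positive] / totals[positive, None])
    return replace(matrix, values=out)
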