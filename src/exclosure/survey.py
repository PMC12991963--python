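"""Long-format survey tables: schema, validation, IO and slicing.

The single input currency of the pipeline is a long-format table with one
row per (site, pair, plot, treatment, month, species) and a non-negative
integer count of individuals.  Zero counts are implicit: a species absent
from a plot at an occasion simply has no row.  Every pair must contain
exactly one control and one exclusion plot.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .errors import SurveyValidationError

logger = logging.getLogger(__name__)

COLUMNS = ["site", "pair", "plot", "treatment", "month", "species", "count"]
KEY = ["site", "pair", "plot", "treatment", "month", "species"]
TREATMENTS = ("control", "exclusion")

__all__ = [
    "COLUMNS",
    "TREATMENTS",
    "read_survey",
    "write_survey",
    "validate_survey",
    "plot_roster",
    "site_species",
    "community_matrix",
]


def validate_survey(table: Union[str, pd.DataFrame]) -> pd.DataFrame:
    """Validate a survey table (path or DataFrame) and return a typed copy.

    Collects *all* schema problems — missing columns, duplicate keys,
    negative or non-integer counts, unknown treatment labels, pairs lacking
    one plot per treatment — and raises :class:`SurveyValidationError`
    whose ``report`` lists each with offending row numbers (0-based data
    rows) or labels.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
        table = pd.read_csv(table)
    problems = []
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise SurveyValidationError([f"missing required columns: {missing}"])

    df = table.loc[:, COLUMNS].copy()
    df = df.reset_index(drop=True)
    for col in ("site", "pair", "plot", "treatment", "species"):
        df[col] = df[col].astype(str)

    bad_treat = ~df["treatment"].isin(TREATMENTS)
    if bad_treat.any():
        rows = df.index[bad_treat].tolist()[:10]
        problems.append(f"treatment must be one of {TREATMENTS}; bad rows {rows}")

    month = pd.to_numeric(df["month"], errors="coerce")
    if month.isna().any():
        problems.append(
            f"non-numeric month at rows {df.index[month.isna()].tolist()[:10]}"
        )
    else:
        if not np.allclose(month, np.round(month)):
            off = df.index[~np.isclose(month, np.round(month))].tolist()[:10]
            problems.append(f"non-integer month at rows {off}")
        df["month"] = month.round().astype(int)

    count = pd.to_numeric(df["count"], errors="coerce")
    if count.isna().any():
        problems.append(
            f"non-numeric count at rows {df.index[count.isna()].tolist()[:10]}"
        )
    else:
        noninteger = ~np.isclose(count, np.round(count))
        if noninteger.any():
            problems.append(
                f"non-integer count at rows {df.index[noninteger].tolist()[:10]}"
            )
        negative = count < 0
        if negative.any():
            problems.append(
                f"negative count at rows {df.index[negative].tolist()[:10]}"
            )
        if not (noninteger.any() or negative.any()):
            df["count"] = count.round().astype(int)

    dup = df.duplicated(subset=KEY, keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        problems.append(f"duplicate (site,pair,plot,treatment,month,species) keys at rows {rows}")

    # plot identity must be stable: one (site, pair, treatment) per plot label
    ident = df.groupby(["site", "plot"])[["pair", "treatment"]].nunique()
    unstable = ident[(ident["pair"] > 1) | (ident["treatment"] > 1)]
    for site, plot in unstable.index:
        problems.append(f"plot {plot!r} at site {site!r} appears under multiple pairs or treatments")

    if not problems:
        # pairing: each pair has exactly one plot per treatment
        roster = df.drop_duplicates(subset=["site", "pair", "plot", "treatment"])
        for (site, pair), grp in roster.groupby(["site", "pair"]):
            treats = sorted(grp["treatment"])
            if treats != sorted(TREATMENTS):
                problems.append(
                    f"pair {pair!r} at site {site!r} has treatments {treats}, "
                    f"expected one control and one exclusion plot"
                )

    if problems:
        raise SurveyValidationError(problems)
    return df


def read_survey(path) -> pd.DataFrame:
    """Read and validate a survey CSV."""
    return validate_survey(path)


def write_survey(survey: pd.DataFrame, path) -> None:
    survey.to_csv(path, index=False)


def plot_roster(survey: pd.DataFrame, site: str) -> pd.DataFrame:
    """Roster of plots at a site: index plot, columns pair and treatment.

    Raises if any pair does not contain exactly one plot per treatment.
    """
    sub = survey[survey["site"] == site]
    roster = (
        sub.drop_duplicates(subset=["pair", "plot", "treatment"])
        .loc[:, ["pair", "plot", "treatment"]]
        .sort_values(["pair", "treatment", "plot"])
        .reset_index(drop=True)
    )
    problems = []
    for pair, grp in roster.groupby("pair"):
        if sorted(grp["treatment"]) != sorted(TREATMENTS):
            problems.append(
                f"pair {pair!r} at site {site!r} lacks one plot per treatment"
            )
    if problems:
        raise SurveyValidationError(problems)
    return roster.set_index("plot")


def site_species(survey: pd.DataFrame, site: str) -> tuple:
    """Sorted union of species ever observed at a site."""
    return tuple(sorted(survey.loc[survey["site"] == site, "species"].unique()))


def community_matrix(
    survey: pd.DataFrame,
    site: str,
    month: int,
    roster: Optional[pd.DataFrame] = None,
    species: Optional[tuple] = None,
) -> CommunityMatrix:
    """Build the plots x species count matrix for one site x occasion.

    Rows cover the full site roster (plots with no records that month get
    all-zero rows); columns are the site-wide species union so matrices are
    comparable across occasions.
    """
    if roster is None:
        roster = plot_roster(survey, site)
    if species is None:
        species = site_species(survey, site)
    sub = survey[(survey["site"] == site) & (survey["month"] == month)]
    values = np.zeros((len(roster), len(species)), dtype=float)
    if len(sub):
        plot_index = {p: i for i, p in enumerate(roster.index)}
        sp_index = {s: j for j, s in enumerate(species)}
        rows = sub["plot"].map(plot_index)
        cols = sub["species"].map(sp_index)
        if rows.isna().any() or cols.isna().any():
            raise SurveyValidationError(
                [f"unknown plot or species labels at site {site!r}, month {month}"]
            )
        np.add.at(values, (rows.to_numpy(int), cols.to_numpy(int)), sub["count"].to_numpy(float))
    return CommunityMatrix(
        values=values,
        plot_ids=tuple(roster.index),
        species_ids=tuple(species),
        site=site,
        month=int(month),
        plot_meta=roster.copy(),
    )
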