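"""Bray-Curtis partition: pairwise, multiple-site, and survey summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import exclosure as ex
from exclosure.beta import multisite_bray_partition, pairwise_bray_partition
from exclosure.community import hellinger_transform
from exclosure.errors import InsufficientPlotsError, UndefinedDissimilarityError
from oracles import brute_multisite_partition, brute_pairwise_partition

from test_community import make_cm


def test_pairwise_hand_example():
    # A=1, B=3, C=1 -> total 4/6, balanced 1/2, gradient 1/6
    total, balanced, gradient = pairwise_bray_partition((2, 0, 2), (1, 1, 0))
    assert np.isclose(total, 4 / 6, atol=1e-12)
    assert np.isclose(balanced, 0.5, atol=1e-12)
    assert np.isclose(gradient, 1 / 6, atol=1e-12)


def test_pairwise_identity_and_disjoint():
    assert pairwise_bray_partition((3, 1, 4), (3, 1, 4)) == (0.0, 0.0, 0.0)
    assert pairwise_bray_partition((3, 0), (0, 5)) == (1.0, 1.0, 0.0)


def test_pairwise_undefined_for_two_empty_communities():
    with pytest.raises(UndefinedDissimilarityError):
        pairwise_bray_partition((0, 0), (0, 0))


def test_multisite_identical_rows_give_zero():
    part = multisite_bray_partition(np.tile([2.0, 1.0, 5.0], (4, 1)))
    assert (part.total, part.balanced, part.gradient) == (0.0, 0.0, 0.0)


def test_two_plot_reduction_is_exact():
    rows = np.array([[2.0, 0.0, 2.0], [1.0, 1.0, 0.0]])
    part = multisite_bray_partition(rows)
    pair = pairwise_bray_partition(rows[0], rows[1])
    assert (part.total, part.balanced, part.gradient) == pair


@given(arrays(np.int64, st.tuples(st.integers(3, 6), st.integers(4, 10)),
              elements=st.integers(0, 9)))
def test_multisite_matches_brute_force_oracle(values):
    values = np.asarray(values, dtype=float)
    usable = values[values.sum(axis=1) > 0]
    if len(usable) < 2:
        return
    part = multisite_bray_partition(values)
    expected = brute_multisite_partition([list(r) for r in usable])
    assert np.allclose((part.total, part.balanced, part.gradient), expected, atol=1e-12)
    assert abs(part.total - (part.balanced + part.gradient)) <= 1e-12
    assert 0 <= part.total <= 1


def test_insufficient_plots_error_carries_context():
    cm = make_cm([[0, 0], [1, 2]], site="X", month=6)
    cm.treatment = "control"
    with pytest.raises(InsufficientPlotsError) as exc:
        multisite_bray_partition(cm)
    assert exc.value.site == "X" and exc.value.month == 6


def test_zero_species_column_changes_nothing():
    rng = np.random.default_rng(4)
    values = rng.integers(0, 8, (5, 6)).astype(float)
    padded = np.hstack([values, np.zeros((5, 1))])
    a = multisite_bray_partition(values)
    b = multisite_bray_partition(padded)
    assert (a.total, a.balanced, a.gradient) == (b.total, b.balanced, b.gradient)


@given(arrays(np.int64, (5, 6), elements=st.integers(0, 9)),
       st.permutations(range(5)), st.permutations(range(6)))
def test_partition_invariant_to_plot_and_species_permutation(values, rperm, cperm):
    values = np.asarray(values, dtype=float)
    if (values.sum(axis=1) > 0).sum() < 2:
        return
    a = multisite_bray_partition(values)
    b = multisite_bray_partition(values[np.asarray(rperm)][:, np.asarray(cperm)])
    assert np.allclose((a.total, a.balanced, a.gradient),
                       (b.total, b.balanced, b.gradient), atol=1e-12)


def test_transform_then_split_equals_split_then_transform(tiny_null_survey):
    """Hellinger is row-wise, so transforming the full site matrix before
    splitting by treatment equals transforming each treatment's slice."""
    from exclosure.survey import community_matrix, plot_roster

    sv = tiny_null_survey
    site = sorted(sv["site"].unique())[0]
    month = sorted(sv["month"].unique())[0]
    cm = community_matrix(sv, site, month)
    roster = plot_roster(sv, site)
    for treatment in ("control", "exclusion"):
        plots = [p for p in cm.plot_ids if roster.loc[p, "treatment"] == treatment]
        full_first = hellinger_transform(cm).select_plots(plots)
        split_first = hellinger_transform(cm.select_plots(plots))
        assert np.allclose(full_first.values, split_first.values, atol=1e-15)


def test_summaries_bookkeeping_and_columns(tiny_null_survey):
    b = ex.beta_summaries(tiny_null_survey, jackknife=False)
    sv = tiny_null_survey
    expected = sum(sv[sv.site == s]["month"].nunique() for s in sv["site"].unique()) * 2
    assert len(b) == expected
    assert abs(b["total"] - (b["balanced"] + b["gradient"])).max() <= 1e-12


def test_summaries_invariant_to_row_order(tiny_null_survey):
    shuffled = tiny_null_survey.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = ex.beta_summaries(tiny_null_survey, jackknife=False)
    b = ex.beta_summaries(shuffled, jackknife=False)
    pd.testing.assert_frame_equal(a, b)


def test_global_count_doubling_absorbed_by_transform(tiny_null_survey):
    doubled = tiny_null_survey.copy()
    doubled["count"] = doubled["count"] * 2
    a = ex.beta_summaries(tiny_null_survey, jackknife=False)
    b = ex.beta_summaries(doubled, jackknife=False)
    pd.testing.assert_frame_equal(a, b)


def test_single_pair_yields_flagged_missing_summary():
    rows = [dict(site="X", pair="A", plot=p, treatment=t, month=0, species="sp1", count=2)
            for p, t in (("p1", "control"), ("p2", "exclusion"))]
    b = ex.beta_summaries(pd.DataFrame(rows))
    assert (b["flag"] == "insufficient_plots").all()
    assert b["total"].isna().all()


def test_jackknife_columns_present(small_homog_survey):
    b = ex.beta_summaries(small_homog_survey, jackknife=True)
    ok = b[b["flag"] == "ok"]
    assert len(ok) and np.isfinite(ok["se_total"]).all()
    width = ok["ci_high_total"] - ok["ci_low_total"]
    assert np.allclose(width, 2 * 1.959964 * ok["se_total"], rtol=1e-5)
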