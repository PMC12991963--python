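"""Treatment-by-time trend models and the component interpretability gate."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import exclosure as ex
import exclosure.models as m
from exclosure.errors import ModelError


def exact_alpha_data(beta=(10.0, 0.05, -1.0, 0.04), months=range(0, 43, 6),
                     offsets=(0.5, -0.5, 1.0, -1.0, 0.0)):
    """Noiseless responses on the model plane plus centred pair offsets."""
    b0, b1, b2, b3 = beta
    rows = []
    for i, off in enumerate(offsets):
        for excl in (0, 1):
            for t in months:
                rows.append(dict(
                    pair=f"P{i}", plot=f"P{i}.{excl}",
                    treatment="exclusion" if excl else "control", month=t,
                    response=b0 + b1 * t + b2 * excl + b3 * t * excl + off,
                ))
    return pd.DataFrame(rows)


def test_alpha_model_exact_recovery_on_noiseless_data():
    fit = m.fit_alpha_model(exact_alpha_data(), "response")
    # slope, treatment and interaction are interpolated exactly; the
    # intercept inherits ~1e-5 numerical error from the degenerate
    # zero-residual REML profile
    assert np.allclose(fit.params[1:], [0.05, -1.0, 0.04], atol=1e-6)
    assert np.isclose(fit.params[0], 10.0, atol=1e-4)


def test_treatment_relabeling_symmetry():
    df = ex.simulate_lmm_dataset((10, 0.02, -1, 0.05), n_pairs=8, seed=3)
    fit = m.fit_alpha_model(df, "response")
    swapped = df.copy()
    swapped["treatment"] = swapped["treatment"].map(
        {"control": "exclusion", "exclusion": "control"})
    fit_sw = m.fit_alpha_model(swapped, "response")
    assert np.isclose(fit_sw.params[2], -fit.params[2], atol=1e-8)
    assert np.isclose(fit_sw.params[3], -fit.params[3], atol=1e-8)
    assert np.isclose(fit_sw.params[0], fit.params[0] + fit.params[2], atol=1e-8)
    assert np.isclose(fit_sw.params[1], fit.params[1] + fit.params[3], atol=1e-8)


def test_zero_pair_variance_matches_ols():
    """Balanced design: fixed effects equal the plain OLS fit."""
    df = ex.simulate_lmm_dataset((5, 0.01, 0.5, -0.02), n_pairs=10,
                                 sd_pair=0.0, seed=7)
    fit = m.fit_alpha_model(df, "response")
    X = np.column_stack([
        np.ones(len(df)), df["month"],
        (df["treatment"] == "exclusion").astype(float),
        df["month"] * (df["treatment"] == "exclusion"),
    ])
    ols = sm.OLS(df["response"], X).fit()
    assert np.allclose(fit.params, ols.params, atol=1e-6)


def test_time_translation_property():
    df = ex.simulate_lmm_dataset((10, 0.02, -1, 0.05), n_pairs=8, seed=5)
    fit = m.fit_alpha_model(df, "response")
    shifted = df.copy()
    shifted["month"] = shifted["month"] + 12
    fit_sh = m.fit_alpha_model(shifted, "response")
    assert np.isclose(fit_sh.params[1], fit.params[1], atol=1e-8)
    assert np.isclose(fit_sh.params[3], fit.params[3], atol=1e-8)
    assert not np.isclose(fit_sh.params[0], fit.params[0], atol=1e-3)


def test_alpha_model_drops_flagged_missing_responses():
    df = ex.simulate_lmm_dataset((10, 0.0, 0.0, 0.0), n_pairs=5, seed=2)
    df.loc[df.index[:3], "response"] = np.nan
    fit = m.fit_alpha_model(df, "response")
    assert fit.n_obs == len(df) - 3


def test_alpha_model_requires_single_site():
    df = ex.simulate_lmm_dataset((1, 0, 0, 0), n_pairs=3, seed=1)
    df["site"] = np.where(df.index % 2 == 0, "A", "B")
    with pytest.raises(ModelError, match="site"):
        m.fit_alpha_model(df, "response")


def two_line_summaries(slope_c=0.001, slope_e=-0.002, months=range(0, 31, 6)):
    rows = []
    for t in months:
        rows.append(dict(treatment="control", month=t, total=0.5 + slope_c * t))
        rows.append(dict(treatment="exclusion", month=t, total=0.55 + slope_e * t))
    return pd.DataFrame(rows)


def test_beta_model_exact_two_lines():
    fit = m.fit_beta_model(two_line_summaries(), "total")
    assert np.isclose(fit.params[3], -0.003, atol=1e-10)
    assert np.isclose(fit.params[1], 0.001, atol=1e-10)
    assert abs(fit.residuals["residual"].sum()) < 1e-10


def test_beta_model_identical_series_has_no_treatment_effect():
    df = two_line_summaries(slope_c=0.001, slope_e=0.001)
    df.loc[df["treatment"] == "exclusion", "total"] = \
        df.loc[df["treatment"] == "control", "total"].to_numpy()
    fit = m.fit_beta_model(df, "total")
    assert np.allclose(fit.params[2:], 0.0, atol=1e-12)


def test_beta_model_requires_three_occasions():
    df = two_line_summaries(months=(0, 6))
    with pytest.raises(ModelError, match="occasions"):
        m.fit_beta_model(df, "total")


def test_mixed_model_residuals_sum_to_zero_within_tolerance():
    df = ex.simulate_lmm_dataset((10, 0.02, -1, 0.05), n_pairs=10, seed=5)
    fit = m.fit_alpha_model(df, "response")
    assert abs(fit.residuals["residual"].sum()) < 1e-8 * len(df)


def _fit_with_p3(p3):
    nan4 = np.full(4, np.nan)
    pv = np.array([np.nan, np.nan, np.nan, p3])
    return m.ModelFit(site="X", metric="total", kind="beta", params=nan4,
                      se=nan4, ci_low=nan4, ci_high=nan4, pvalues=pv,
                      sigma2_resid=1.0, n_obs=10, converged=True)


@pytest.mark.parametrize("p3,expected", [(0.20, False), (0.01, True), (0.05, False)])
def test_component_gating_rule(p3, expected):
    gate = m.component_gating({"total": _fit_with_p3(p3),
                               "balanced": _fit_with_p3(0.5)})
    assert gate.interpretable is expected
    assert "balanced" in gate.components


def test_component_gating_requires_total():
    with pytest.raises(ModelError, match="total"):
        m.component_gating({"balanced": _fit_with_p3(0.01)})
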